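"""Synthetic wearable cohort generator with known within-cycle structure.

Emulates daily wrist-wearable records (resting heart rate in BPM, RMSSD
heart-rate variability in ms, prior-day energy expenditure in kJ, and a
self-reported menstruation flag) for a cohort of simulated participants.
Each participant carries a smooth within-cycle oscillation of known
amplitude — RHR lowest shortly after bleeding onset and highest in the
late luteal phase, RMSSD inverted — on top of a personal baseline,
weekend and activity covariate effects, Gaussian day-to-day noise,
missing wear days and occasional outlier spikes.

Because the generator's parameters are known exactly, every downstream
stage (cycle delineation, filtering, population smooths, amplitude
statistics, covariate models) can be tested as a parameter-recovery
problem.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimConfig",
    "SimResult",
    "cycle_template",
    "effective_peak_day",
    "template_window_contrast",
    "simulate_cohort",
    "simulate_amplitude_glm_data",
    "write_cohort",
    "read_config_file",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the simulated cohort.

    Defaults reproduce the population moments of a large free-living
    menstruating cohort (cycle length 27.4 ± 2.2 days, bleeding 4.7 ± 1.0
    days, RHR 59.7 ± 7.6 BPM, RMSSD 60.4 ± 27.2 ms, daily expenditure
    7530 ± 1004 kJ) and inject a within-cycle cardiovascular amplitude of
    2.7 BPM for RHR and 4.7 ms for RMSSD, with the RHR nadir on cycle day
    5 and its peak on day 26.
    """

    n_participants: int = 100
    prop_birth_control: float = 0.0
    mean_cycle_len: float = 27.4
    sd_cycle_len: float = 2.2
    mean_bleed_len: float = 4.7
    sd_bleed_len: float = 1.0
    rhr_baseline_mean: float = 59.7
    rhr_baseline_sd: float = 7.6
    rmssd_baseline_mean: float = 60.4
    rmssd_baseline_sd: float = 27.2
    true_rhr_amp: float = 2.7
    true_rmssd_amp: float = 4.7
    bc_attenuation: float = 0.9
    nadir_day: int = 5
    peak_day: int = 26
    age_slope_rhr_amp: float = -0.04
    age_slope_rmssd_amp: float = -0.09
    weekend_rhr_effect: float = 0.9
    weekend_rmssd_effect: float = -1.8
    noise_sd_rhr: float = 2.0
    noise_sd_rmssd: float = 8.0
    p_missing_day: float = 0.02
    p_outlier_day: float = 0.01
    n_cycles_range: tuple[int, int] = (3, 5)
    rng_seed: int = 0
    # covariate population moments
    age_mean: float = 34.9
    age_sd: float = 7.3
    bmi_mean: float = 24.6
    bmi_sd: float = 4.3
    kj_mean: float = 7530.0
    kj_sd: float = 1004.0
    # small linear activity effects (per kJ above the population mean)
    kj_slope_rhr: float = 1.0e-4
    kj_slope_rmssd: float = -2.0e-4

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name in (
            "sd_cycle_len",
            "sd_bleed_len",
            "rhr_baseline_sd",
            "rmssd_baseline_sd",
            "noise_sd_rhr",
            "noise_sd_rmssd",
            "age_sd",
            "bmi_sd",
            "kj_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("prop_birth_control", "bc_attenuation", "p_missing_day", "p_outlier_day"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not (1 <= self.nadir_day < self.peak_day):
            raise ConfigError("require 1 <= nadir_day < peak_day")
        lo, hi = self.n_cycles_range
        if not (1 <= lo <= hi):
            raise ConfigError("n_cycles_range must be an increasing pair of positive ints")
        if self.nadir_day > 21:
            raise ConfigError("nadir_day must fit inside the shortest plausible cycle")


@dataclasses.dataclass
class SimResult:
    """Output tables of :func:`simulate_cohort`.

    ``daily`` has one row per observed wear-day; ``participants`` one row
    per participant with demographics and contraceptive interval;
    ``truth`` the hidden per-participant ground truth (effective injected
    amplitudes, baselines) used by recovery tests; ``truth_cycles`` the
    true cycle boundaries used to validate delineation.
    """

    daily: pd.DataFrame
    participants: pd.DataFrame
    truth: pd.DataFrame
    truth_cycles: pd.DataFrame
    config: SimConfig


def _vm_bump(day, center: float, cycle_len: float, halfwidth: float) -> np.ndarray:
    """Wrapped-Gaussian (von Mises) bump, 1 at ``center``, periodic in
    ``cycle_len``, falling to 1/2 at ``halfwidth`` days from the center."""
    kappa = np.log(2.0) / (1.0 - np.cos(2.0 * np.pi * halfwidth / cycle_len))
    ang = 2.0 * np.pi * (np.asarray(day, dtype=float) - center) / cycle_len
    return np.exp(kappa * (np.cos(ang) - 1.0))


def cycle_template(
    day,
    cycle_len: float,
    nadir_day: float,
    peak_day: float,
    nadir_halfwidth: float = 2.0,
    peak_halfwidth: float = 1.5,
):
    """Smooth unit-range within-cycle shape.

    A periodic, infinitely smooth curve built from two wrapped-Gaussian
    bumps: a trough of exactly -0.5 at ``nadir_day`` and a crest of
    exactly +0.5 at ``peak_day``, with the curve near zero between them.
    The half-depth spans default to +/-2 days around the trough and
    +/-1.5 days around the crest, emulating the published pattern of
    lowest RHR around days 3-7 (end of menstruation) and highest RHR in
    the brief late-luteal window around days 25-27.  Because the bumps
    are centred on the anchors, the day-grid extrema fall exactly on
    ``nadir_day`` and ``peak_day`` and the peak-to-nadir range is
    exactly 1, so multiplying by a true amplitude injects that
    peak-to-trough amplitude exactly.

    Parameters
    ----------
    day : scalar or array
        Cycle day (1-based; fractional values allowed).
    cycle_len : float
        Length of the cycle in days.
    nadir_day, peak_day : float
        Anchor days of the trough and crest; must satisfy
        ``0 < nadir_day < peak_day <= cycle_len``.
    """
    L = float(cycle_len)
    if not (0 < nadir_day < peak_day):
        raise ConfigError("require 0 < nadir_day < peak_day")
    if peak_day > L:
        raise ConfigError("peak_day must not exceed cycle_len")
    raw = 0.5 * _vm_bump(day, peak_day, L, peak_halfwidth) - 0.5 * _vm_bump(
        day, nadir_day, L, nadir_halfwidth
    )
    # analytic extrema at the anchors (bump cross-talk included)
    rmin = 0.5 * float(_vm_bump(nadir_day, peak_day, L, peak_halfwidth)) - 0.5
    rmax = 0.5 - 0.5 * float(_vm_bump(peak_day, nadir_day, L, nadir_halfwidth))
    out = (raw - (rmax + rmin) / 2.0) / (rmax - rmin)
    if np.isscalar(day):
        return float(out)
    return out


def effective_peak_day(peak_day: int, cycle_len: int) -> int:
    """Crest anchor actually used in a cycle of length ``cycle_len``:
    the population peak day, clamped so at least one descending day
    remains before the next onset."""
    return int(min(peak_day, cycle_len - 1))


def _window_days(anchor: float, cycle_len: int, mean_cycle_len: float) -> np.ndarray:
    """7-day window used by the amplitude oracle (independent of the
    amplitude module): anchors within 3 days of the *population mean*
    cycle end use the cycle's own final 7 days; otherwise the window is
    centred on the anchor and clamped inside the cycle."""
    L = int(cycle_len)
    a = int(round(anchor))
    if anchor >= mean_cycle_len - 3 or a >= L - 2:
        return np.arange(L - 6, L + 1)
    if a <= 3:
        return np.arange(1, 8)
    return np.arange(a - 3, a + 4)


def template_window_contrast(
    cycle_len: int,
    nadir_day: int = 5,
    peak_day: int = 26,
    mean_cycle_len: float = 27.4,
) -> float:
    """Peak-window minus nadir-window mean of the unit template.

    This is the factor by which the windowed amplitude statistic
    attenuates a true injected amplitude: 7-day window means never reach
    the template's pointwise extrema of +/-0.5, so the recoverable
    ("effective") amplitude of a cycle of length ``cycle_len`` is
    ``true_amp * template_window_contrast(cycle_len)``.  Serves as the
    brute-force oracle for amplitude recovery tests.
    """
    L = int(cycle_len)
    tpl = cycle_template(np.arange(1, L + 1), L, nadir_day, effective_peak_day(peak_day, L))
    peak_w = _window_days(peak_day, L, mean_cycle_len)
    nadir_w = _window_days(nadir_day, L, mean_cycle_len)
    return float(tpl[peak_w - 1].mean() - tpl[nadir_w - 1].mean())


def _trunc_round_normal(rng, mean, sd, lo, hi, size):
    """Rounded Gaussian draws truncated to [lo, hi] by resampling."""
    out = np.rint(rng.normal(mean, sd, size)).astype(int)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.normal(mean, sd, int(bad.sum()))).astype(int)
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimConfig) -> SimResult:
    """Simulate daily wearable records for a cohort.

    Each observed day's metric is
    ``baseline + amp * template(day) + weekend_effect * weekend
    + kj_slope * (kJ - kJ_mean) + noise``, with the RMSSD template
    sign-inverted relative to RHR.  The menstruation flag is true for the
    first ``bleed_len`` days of each cycle.  Participants on the
    contraceptive pill have their injected amplitude multiplied by
    ``1 - bc_attenuation``.  A short trailing bleeding onset closes the
    final cycle so delineation recovers exactly ``n_cycles`` cycles per
    participant.  Cycle onset days are always recorded (self-reports of
    bleeding onset anchor the cycle calendar); other days go missing at
    rate ``p_missing_day``.  Identical configs give identical tables.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    base_date = pd.Timestamp("2022-01-03")

    daily_rows: list[pd.DataFrame] = []
    part_rows = []
    truth_rows = []
    cyc_rows = []

    for i in range(cfg.n_participants):
        pid = f"P{i:05d}"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18.0, 55.0))
        bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 16.0, 45.0))
        on_bc = bool(rng.random() < cfg.prop_birth_control)
        baseline_rhr = float(max(40.0, rng.normal(cfg.rhr_baseline_mean, cfg.rhr_baseline_sd)))
        baseline_rmssd = float(max(15.0, rng.normal(cfg.rmssd_baseline_mean, cfg.rmssd_baseline_sd)))

        amp_rhr = max(0.0, cfg.true_rhr_amp + cfg.age_slope_rhr_amp * (age - cfg.age_mean))
        amp_rmssd = max(0.0, cfg.true_rmssd_amp + cfg.age_slope_rmssd_amp * (age - cfg.age_mean))
        if on_bc:
            amp_rhr *= 1.0 - cfg.bc_attenuation
            amp_rmssd *= 1.0 - cfg.bc_attenuation

        lo, hi = cfg.n_cycles_range
        n_cycles = int(rng.integers(lo, hi + 1))
        lengths = _trunc_round_normal(rng, cfg.mean_cycle_len, cfg.sd_cycle_len, 21, 35, n_cycles + 1)
        bleeds = _trunc_round_normal(rng, cfg.mean_bleed_len, cfg.sd_bleed_len, 2, 7, n_cycles + 1)
        start = base_date + pd.Timedelta(days=int(rng.integers(0, 28)))

        cursor = start
        for c in range(n_cycles + 1):
            L = int(lengths[c])
            bleed = int(bleeds[c])
            trailing = c == n_cycles
            n_days = 3 if trailing else L  # trailing onset only closes the last cycle
            days = np.arange(1, n_days + 1)
            dates = cursor + pd.to_timedelta(days - 1, unit="D")
            weekend = dates.dayofweek >= 5
            kj = rng.normal(cfg.kj_mean, cfg.kj_sd, n_days)
            tpl = cycle_template(days, L, cfg.nadir_day, effective_peak_day(cfg.peak_day, L))
            rhr = (
                baseline_rhr
                + amp_rhr * tpl
                + cfg.weekend_rhr_effect * weekend
                + cfg.kj_slope_rhr * (kj - cfg.kj_mean)
                + (rng.normal(0.0, cfg.noise_sd_rhr, n_days) if cfg.noise_sd_rhr > 0 else 0.0)
            )
            rmssd = (
                baseline_rmssd
                - amp_rmssd * tpl
                + cfg.weekend_rmssd_effect * weekend
                + cfg.kj_slope_rmssd * (kj - cfg.kj_mean)
                + (rng.normal(0.0, cfg.noise_sd_rmssd, n_days) if cfg.noise_sd_rmssd > 0 else 0.0)
            )
            # outlier spikes: +/- (4-8) x noise_sd, injected per metric
            for arr, sd in ((rhr, cfg.noise_sd_rhr), (rmssd, cfg.noise_sd_rmssd)):
                spike = rng.random(n_days) < cfg.p_outlier_day
                if spike.any():
                    k = int(spike.sum())
                    arr[spike] += rng.choice([-1.0, 1.0], k) * rng.uniform(4.0, 8.0, k) * sd
            rhr = np.maximum(rhr, 25.0)
            rmssd = np.maximum(rmssd, 1.0)
            menstruating = (days <= bleed).astype(int)

            keep = rng.random(n_days) >= cfg.p_missing_day
            keep[0] = True  # bleeding onset is always logged
            daily_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "date": dates[keep].strftime("%Y-%m-%d"),
                        "rhr_bpm": np.round(rhr[keep], 4),
                        "rmssd_ms": np.round(rmssd[keep], 4),
                        "kj_prior_day": np.round(kj[keep], 1),
                        "menstruating": menstruating[keep],
                    }
                )
            )
            if not trailing:
                cyc_rows.append(
                    {
                        "participant_id": pid,
                        "cycle_index": c,
                        "start_date": cursor.strftime("%Y-%m-%d"),
                        "length": L,
                        "bleed_length": bleed,
                    }
                )
                cursor = cursor + pd.Timedelta(days=L)

        cohort = "birth_control" if on_bc else "naturally_cycling"
        part_rows.append(
            {
                "participant_id": pid,
                "age_years": round(age, 2),
                "bmi": round(bmi, 2),
                "cohort": cohort,
                "bc_start_date": (start - pd.Timedelta(days=365)).strftime("%Y-%m-%d") if on_bc else "",
                "bc_stop_date": "",
            }
        )
        truth_rows.append(
            {
                "participant_id": pid,
                "cohort": cohort,
                "true_amp_rhr": amp_rhr,
                "true_amp_rmssd": amp_rmssd,
                "baseline_rhr": baseline_rhr,
                "baseline_rmssd": baseline_rmssd,
                "age": age,
                "bmi": bmi,
            }
        )

    daily = pd.concat(daily_rows, ignore_index=True)
    daily["date"] = pd.to_datetime(daily["date"])
    participants = pd.DataFrame(part_rows)
    truth = pd.DataFrame(truth_rows)
    truth_cycles = pd.DataFrame(cyc_rows)
    truth_cycles["start_date"] = pd.to_datetime(truth_cycles["start_date"])
    return SimResult(daily, participants, truth, truth_cycles, cfg)


def simulate_amplitude_glm_data(
    n: int,
    rng: np.random.Generator,
    intercept: float = 2.7,
    age_slope: float = -0.04,
    bmi_slope: float = 0.0,
    baseline_effect=None,
    noise_sd: float = 1.95,
    age_mean: float = 34.9,
    age_sd: float = 7.3,
    bmi_mean: float = 24.6,
    bmi_sd: float = 4.3,
    baseline_mean: float = 59.7,
    baseline_sd: float = 7.6,
) -> pd.DataFrame:
    """Draw a participant-level amplitude table directly from the
    covariate-model data-generating process.

    Used to exercise the amplitude-on-covariates GLM at sample sizes
    where running the full daily-record pipeline would be wasteful.
    ``baseline_effect`` is an optional callable mapping baseline metric
    values to an additive amplitude contribution (e.g. a hump).
    """
    age = np.clip(rng.normal(age_mean, age_sd, n), 18, 55)
    bmi = np.clip(rng.normal(bmi_mean, bmi_sd, n), 16, 45)
    baseline = rng.normal(baseline_mean, baseline_sd, n)
    amp = intercept + age_slope * (age - age_mean) + bmi_slope * (bmi - bmi_mean)
    if baseline_effect is not None:
        amp = amp + baseline_effect(baseline)
    amp = amp + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        {
            "participant_id": [f"G{i:05d}" for i in range(n)],
            "participant_amp": amp,
            "age": age,
            "bmi": bmi,
            "baseline": baseline,
        }
    )


def write_cohort(result: SimResult, outdir) -> None:
    """Write daily.csv, participants.csv, truth.csv and truth_cycles.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    daily = result.daily.copy()
    daily["date"] = daily["date"].dt.strftime("%Y-%m-%d")
    daily.to_csv(outdir / "daily.csv", index=False)
    result.participants.to_csv(outdir / "participants.csv", index=False)
    result.truth.to_csv(outdir / "truth.csv", index=False)
    tc = result.truth_cycles.copy()
    tc["start_date"] = tc["start_date"].dt.strftime("%Y-%m-%d")
    tc.to_csv(outdir / "truth_cycles.csv", index=False)


def read_config_file(path) -> SimConfig:
    """Parse a flat ``key = value`` text file into a :class:`SimConfig`."""
    fields = {f.name: f.type for f in dataclasses.fields(SimConfig)}
    kwargs = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, val = line.split("=", 1)
        elif ":" in line:
            key, val = line.split(":", 1)
        else:
            raise ConfigError(f"cannot parse config line: {raw!r}")
        key = key.strip()
        val = val.strip()
        if key not in fields:
            raise ConfigError(f"unknown config key: {key}")
        if key == "n_cycles_range":
            parts = [int(p) for p in val.replace("(", "").replace(")", "").split(",")]
            kwargs[key] = (parts[0], parts[1])
        elif key in ("n_participants", "nadir_day", "peak_day", "rng_seed"):
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    return SimConfig(**kwargs)
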