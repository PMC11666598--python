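"""Per-cycle and per-participant cardiovascular amplitude.

The cycle cardiovascular amplitude is the difference between the 7-day
mean of a metric's offsets centered on the population-expected peak day
and the 7-day mean centered on the population-expected nadir day.
Windows that would spill past the cycle edge are shifted so a full
7-day window is always used; an expected extremum lying within 3 days
of the population mean cycle end anchors to each individual cycle's
final 7 days, so cycles of every eligible length contribute equivalent
late-cycle data.  A participant's amplitude (RHR_amp or RMSSD_amp) is
the arithmetic mean of their defined cycle amplitudes.

For RHR the expected peak is late-cycle and the nadir early; for RMSSD
the roles are reversed (the curve is antiphase), so passing each
metric's own model-derived peak and nadir days makes both reduce to
peak-window mean minus nadir-window mean.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "window_for_day",
    "CycleAmplitude",
    "cycle_amplitude",
    "participant_amplitude",
    "compute_amplitudes",
    "summarize_amplitudes",
]


def window_for_day(anchor_day: int, cycle_len: int) -> tuple[int, int]:
    """Inclusive 7-day window of cycle days centered on ``anchor_day``.

    Returns [anchor-3, anchor+3] when that fits inside [1, cycle_len];
    anchors within 3 days of the cycle start clamp to days 1-7 and
    anchors within 3 days of the end (or beyond it) clamp to the final
    7 days, so the window always spans exactly 7 calendar cycle-days.
    """
    L = int(cycle_len)
    if L < 7:
        raise ValueError("cycle_len must be at least 7 days")
    a = int(anchor_day)
    if a < 1:
        raise ValueError("anchor_day must be >= 1")
    if a <= 3:
        return (1, 7)
    if a >= L - 2:
        return (L - 6, L)
    return (a - 3, a + 3)


@dataclasses.dataclass
class CycleAmplitude:
    """Amplitude of one participant-cycle (None when undefined)."""

    amplitude: float | None
    peak_mean: float | None
    nadir_mean: float | None
    n_peak_days: int
    n_nadir_days: int
    peak_window: tuple[int, int]
    nadir_window: tuple[int, int]
    windows_overlap: bool
    reason: str = ""


def _resolve_window(anchor: int, cycle_len: int, mean_cycle_len: float | None) -> tuple[int, int]:
    # population anchors near the *mean* cycle end track each cycle's own
    # final 7 days, reconciling a fixed population day with lengths 21-35
    if mean_cycle_len is not None and anchor >= mean_cycle_len - 3:
        return (int(cycle_len) - 6, int(cycle_len))
    return window_for_day(anchor, cycle_len)


def cycle_amplitude(
    offsets_by_day,
    cycle_len: int,
    peak_day: int,
    nadir_day: int,
    mean_cycle_len: float | None = None,
    min_days_per_window: int = 4,
) -> CycleAmplitude:
    """Peak-window mean minus nadir-window mean for one cycle.

    ``offsets_by_day`` maps cycle day (1-based) to offset; outlier days
    are NaN or absent.  A window with fewer than ``min_days_per_window``
    usable offsets makes the amplitude undefined for this cycle.  In a
    short cycle the two windows may overlap; the amplitude is still
    computed (overlap days contribute to both means) and flagged.
    """
    if isinstance(offsets_by_day, pd.Series):
        mapping = offsets_by_day.to_dict()
    else:
        mapping = dict(offsets_by_day)
    pw = _resolve_window(peak_day, cycle_len, mean_cycle_len)
    nw = _resolve_window(nadir_day, cycle_len, mean_cycle_len)
    overlap = pw[0] <= nw[1] and nw[0] <= pw[1]

    def window_mean(w):
        vals = [mapping[d] for d in range(w[0], w[1] + 1)
                if d in mapping and np.isfinite(mapping[d])]
        return (float(np.mean(vals)), len(vals)) if vals else (None, 0)

    p_mean, p_n = window_mean(pw)
    n_mean, n_n = window_mean(nw)
    if p_n == 0 and n_n == 0:
        return CycleAmplitude(None, None, None, 0, 0, pw, nw, overlap, "both windows empty")
    if p_n < min_days_per_window or n_n < min_days_per_window:
        return CycleAmplitude(
            None, p_mean, n_mean, p_n, n_n, pw, nw, overlap,
            f"window below {min_days_per_window} usable days",
        )
    return CycleAmplitude(p_mean - n_mean, p_mean, n_mean, p_n, n_n, pw, nw, overlap)


def participant_amplitude(cycle_amps) -> tuple[float, int, float]:
    """Mean of a participant's defined cycle amplitudes.

    Accepts CycleAmplitude objects or raw floats (None/NaN = undefined).
    Returns (participant amplitude, number of cycles used, fraction of
    used cycles with positive amplitude).  Raises if no cycle amplitude
    is defined.
    """
    vals = []
    for a in cycle_amps:
        v = a.amplitude if isinstance(a, CycleAmplitude) else a
        if v is not None and np.isfinite(v):
            vals.append(float(v))
    if not vals:
        raise ValueError("no defined cycle amplitudes")
    arr = np.asarray(vals)
    return float(arr.mean()), len(vals), float((arr > 0).mean())


def compute_amplitudes(
    offsets: pd.DataFrame,
    metric: str,
    peak_day: int,
    nadir_day: int,
    mean_cycle_len: float | None = None,
    min_days_per_window: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplitudes for every participant-cycle in an offsets table.

    Returns (participant table, cycle table).  Participants with no
    defined cycle amplitude are dropped from the participant table (they
    still appear in the cycle table with the reason for exclusion).
    """
    d = offsets[offsets["metric"] == metric]
    cyc_rows = []
    part_rows = []
    for (pid, ci), grp in d.groupby(["participant_id", "cycle_index"], sort=True):
        series = pd.Series(grp["offset"].to_numpy(), index=grp["day"].to_numpy())
        L = int(grp["cycle_len"].iloc[0])
        ca = cycle_amplitude(series, L, peak_day, nadir_day, mean_cycle_len, min_days_per_window)
        row = {
            "participant_id": pid,
            "cycle_index": ci,
            "metric": metric,
            "cycle_len": L,
            "amplitude": ca.amplitude if ca.amplitude is not None else np.nan,
            "peak_window_mean": ca.peak_mean if ca.peak_mean is not None else np.nan,
            "nadir_window_mean": ca.nadir_mean if ca.nadir_mean is not None else np.nan,
            "n_peak_days": ca.n_peak_days,
            "n_nadir_days": ca.n_nadir_days,
            "windows_overlap": ca.windows_overlap,
            "reason": ca.reason,
        }
        if "cohort" in grp.columns:
            row["cohort"] = grp["cohort"].iloc[0]
        cyc_rows.append(row)
    cycle_df = pd.DataFrame(cyc_rows)
    if cycle_df.empty:
        return pd.DataFrame(columns=["participant_id", "metric", "n_cycles_used", "participant_amp"]), cycle_df

    for pid, grp in cycle_df.groupby("participant_id", sort=True):
        defined = grp["amplitude"].dropna()
        if defined.empty:
            continue
        row = {
            "participant_id": pid,
            "metric": metric,
            "n_cycles_used": int(defined.size),
            "participant_amp": float(defined.mean()),
        }
        if "cohort" in grp.columns:
            row["cohort"] = grp["cohort"].mode().iloc[0]
        part_rows.append(row)
    return pd.DataFrame(part_rows), cycle_df


def summarize_amplitudes(participant_df: pd.DataFrame) -> dict:
    """Cohort summary: mean, SD, % positive and n of participant amplitudes."""
    amps = participant_df["participant_amp"].to_numpy(dtype=float)
    return {
        "n": int(amps.size),
        "mean": float(amps.mean()),
        "sd": float(amps.std(ddof=1)) if amps.size > 1 else np.nan,
        "pct_positive": float(100.0 * (amps > 0).mean()),
    }
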