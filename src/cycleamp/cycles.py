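"""Cycle delineation, eligibility filtering, outlier removal and
within-cycle offset normalization for daily wearable records.

A menstrual cycle runs from one self-reported bleeding onset to the day
before the next onset; day 1 is the onset day.  A single non-bleeding
day flanked by bleeding days is treated as part of the same menses
(self-reports are noisy); two or more consecutive gap days end it.

Eligibility mirrors standard menstrual-cycle research criteria: cycle
length within [21, 35] days, bleeding at most 7 days, and membership in
a run of at least two consecutive otherwise-eligible cycles whose pooled
wear fraction (days with a resting-heart-rate reading / total days) is
at least 95%.

Within each eligible participant-cycle, each metric is normalized to the
offset in absolute units from the cycle mean after removing days outside
the Tukey fences Q1 - 1.5*IQR and Q3 + 1.5*IQR (quartiles by linear
interpolation, computed per participant-cycle).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "METRIC_COLUMNS",
    "load_daily",
    "load_participants",
    "delineate_cycles",
    "build_cycle_days",
    "apply_inclusion_filters",
    "remove_outliers_iqr",
    "compute_offsets",
    "build_offsets",
    "assign_cycle_cohort",
]

METRIC_COLUMNS = {"rhr": "rhr_bpm", "rmssd": "rmssd_ms"}

# exclusion rule codes, in filtering order
CYCLE_LEN = "CYCLE_LEN"
BLEED_LEN = "BLEED_LEN"
NO_CONSECUTIVE_RUN = "NO_CONSECUTIVE_RUN"
LOW_WEAR = "LOW_WEAR"


def load_daily(path) -> pd.DataFrame:
    """Read daily.csv (participant_id, ISO date, rhr_bpm, rmssd_ms,
    kj_prior_day, menstruating)."""
    daily = pd.read_csv(path, parse_dates=["date"])
    required = {"participant_id", "date", "rhr_bpm", "rmssd_ms", "kj_prior_day", "menstruating"}
    missing = required - set(daily.columns)
    if missing:
        raise ValueError(f"daily table missing columns: {sorted(missing)}")
    dup = daily.duplicated(["participant_id", "date"])
    if dup.any():
        raise ValueError("daily table has duplicate participant-days")
    return daily


def load_participants(path) -> pd.DataFrame:
    part = pd.read_csv(path)
    for col in ("bc_start_date", "bc_stop_date"):
        if col in part.columns:
            part[col] = pd.to_datetime(part[col], errors="coerce")
    return part


def delineate_cycles(daily: pd.DataFrame) -> pd.DataFrame:
    """Delineate cycles from daily menstruation flags.

    A cycle starts on a bleeding day preceded by at least two
    non-bleeding (or unrecorded) days; bleeding runs separated by a
    single gap day are merged, and bleed_length spans the gap.  The final
    onset has no successor and closes the last cycle without starting a
    new one.  Returns one row per cycle with participant_id, cycle_index,
    start_date, end_date (last day), length and bleed_length.
    """
    rows = []
    for pid, grp in daily.sort_values("date").groupby("participant_id", sort=True):
        bleed_dates = grp.loc[grp["menstruating"].fillna(0).astype(int) == 1, "date"]
        if bleed_dates.empty:
            continue
        runs: list[list[pd.Timestamp]] = []  # [first, last] per merged menses
        for d in bleed_dates:
            if runs and (d - runs[-1][1]).days <= 2:  # gap of <=1 non-bleeding day
                runs[-1][1] = d
            else:
                runs.append([d, d])
        for k in range(len(runs) - 1):
            start = runs[k][0]
            nxt = runs[k + 1][0]
            rows.append(
                {
                    "participant_id": pid,
                    "cycle_index": k,
                    "start_date": start,
                    "end_date": nxt - pd.Timedelta(days=1),
                    "length": (nxt - start).days,
                    "bleed_length": (runs[k][1] - runs[k][0]).days + 1,
                }
            )
    cols = ["participant_id", "cycle_index", "start_date", "end_date", "length", "bleed_length"]
    return pd.DataFrame(rows, columns=cols)


def build_cycle_days(daily: pd.DataFrame, cycles: pd.DataFrame) -> pd.DataFrame:
    """Expand cycles to one row per cycle-day, joined with daily records.

    Days without a record keep NaN metrics so that wear fractions and
    missing-day handling are explicit.  Adds the cycle-day index ``day``
    (1-based) and the weekend flag derived from the calendar date.
    """
    if cycles.empty:
        return pd.DataFrame(
            columns=["participant_id", "cycle_index", "day", "date", "rhr_bpm",
                     "rmssd_ms", "kj_prior_day", "menstruating", "weekend", "cycle_len"]
        )
    frames = []
    for pid, cyc_grp in cycles.groupby("participant_id", sort=True):
        grp = daily[daily["participant_id"] == pid].set_index("date")
        for cyc in cyc_grp.itertuples():
            dates = pd.date_range(cyc.start_date, periods=cyc.length, freq="D")
            sub = grp.reindex(dates)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "cycle_index": cyc.cycle_index,
                        "day": np.arange(1, cyc.length + 1),
                        "date": dates,
                        "rhr_bpm": sub["rhr_bpm"].to_numpy(),
                        "rmssd_ms": sub["rmssd_ms"].to_numpy(),
                        "kj_prior_day": sub["kj_prior_day"].to_numpy(),
                        "menstruating": sub["menstruating"].to_numpy(),
                        "weekend": dates.dayofweek >= 5,
                        "cycle_len": cyc.length,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def apply_inclusion_filters(
    cycles: pd.DataFrame,
    cycle_days: pd.DataFrame,
    min_cycle_len: int = 21,
    max_cycle_len: int = 35,
    max_bleed: int = 7,
    min_wear: float = 0.95,
    min_consecutive: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort eligibility rules.

    A cycle is eligible iff its length lies in [min_cycle_len,
    max_cycle_len], bleeding lasts at most max_bleed days, and it belongs
    to a maximal run of at least ``min_consecutive`` back-to-back such
    cycles whose pooled wear fraction is >= ``min_wear`` (inclusive).

    Returns the cycles table with ``wear_fraction``, ``eligible`` and
    ``fail_codes`` columns plus an exclusion ledger whose per-rule counts
    (first failed rule per cycle, in rule order) sum to the number of
    cycles assessed.
    """
    cycles = cycles.copy()
    if cycles.empty:
        ledger = {
            "participants_assessed": 0, "cycles_assessed": 0,
            "cycles_excluded_cycle_len": 0, "cycles_excluded_bleed_len": 0,
            "cycles_excluded_no_consecutive_run": 0, "cycles_excluded_low_wear": 0,
            "cycles_included": 0, "participants_included": 0,
        }
        cycles["wear_fraction"] = pd.Series(dtype=float)
        cycles["eligible"] = pd.Series(dtype=bool)
        cycles["fail_codes"] = pd.Series(dtype=object)
        return cycles, ledger

    wear = (
        cycle_days.assign(has_rhr=cycle_days["rhr_bpm"].notna())
        .groupby(["participant_id", "cycle_index"])["has_rhr"]
        .mean()
        .rename("wear_fraction")
    )
    cycles = cycles.merge(wear, on=["participant_id", "cycle_index"], how="left")
    cycles["wear_fraction"] = cycles["wear_fraction"].fillna(0.0)

    cycles = cycles.sort_values(["participant_id", "cycle_index"]).reset_index(drop=True)
    len_ok = (cycles["length"] >= min_cycle_len) & (cycles["length"] <= max_cycle_len)
    bleed_ok = cycles["bleed_length"] <= max_bleed
    basic = (len_ok & bleed_ok).to_numpy()

    eligible = np.zeros(len(cycles), dtype=bool)
    in_long_run = np.zeros(len(cycles), dtype=bool)

    for _, idx in cycles.groupby("participant_id", sort=False).indices.items():
        idx = np.sort(idx)
        # maximal runs of consecutive basic-eligible cycles
        run: list[int] = []
        for j in list(idx) + [None]:
            if j is not None and basic[j] and (not run or cycles.loc[j, "cycle_index"] == cycles.loc[run[-1], "cycle_index"] + 1):
                run.append(j)
                continue
            if len(run) >= min_consecutive:
                sub = cycles.loc[run]
                pooled = (sub["wear_fraction"] * sub["length"]).sum() / sub["length"].sum()
                in_long_run[run] = True
                if pooled >= min_wear:
                    eligible[run] = True
            run = [j] if (j is not None and basic[j]) else []

    fail_codes = []
    primary = []
    for j in range(len(cycles)):
        codes = []
        if not len_ok.iloc[j]:
            codes.append(CYCLE_LEN)
        if not bleed_ok.iloc[j]:
            codes.append(BLEED_LEN)
        if basic[j] and not in_long_run[j]:
            codes.append(NO_CONSECUTIVE_RUN)
        if basic[j] and in_long_run[j] and not eligible[j]:
            codes.append(LOW_WEAR)
        fail_codes.append(codes)
        primary.append(codes[0] if codes else "")
    cycles["eligible"] = eligible
    cycles["fail_codes"] = fail_codes

    primary = pd.Series(primary)
    ledger = {
        "participants_assessed": int(cycles["participant_id"].nunique()),
        "cycles_assessed": int(len(cycles)),
        "cycles_excluded_cycle_len": int((primary == CYCLE_LEN).sum()),
        "cycles_excluded_bleed_len": int((primary == BLEED_LEN).sum()),
        "cycles_excluded_no_consecutive_run": int((primary == NO_CONSECUTIVE_RUN).sum()),
        "cycles_excluded_low_wear": int((primary == LOW_WEAR).sum()),
        "cycles_included": int(eligible.sum()),
        "participants_included": int(cycles.loc[eligible, "participant_id"].nunique()),
    }
    return cycles, ledger


def remove_outliers_iqr(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Tukey-fence outlier mask for one participant-cycle metric vector.

    Returns a keep-mask (False for missing values and for values strictly
    outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR]) and the fences.  Quartiles use
    linear interpolation between order statistics.  With fewer than 4
    non-missing values the quartiles are too unstable to trust, so no
    removal is performed and the fences are undefined (NaN).
    """
    v = np.asarray(values, dtype=float)
    present = np.isfinite(v)
    if not present.any():
        warnings.warn("all values missing; nothing to keep", stacklevel=2)
        return present, (np.nan, np.nan)
    if present.sum() < 4:
        return present, (np.nan, np.nan)
    q1, q3 = np.quantile(v[present], [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = present & (v >= lo) & (v <= hi)
    return keep, (float(lo), float(hi))


def compute_offsets(values, keep_mask=None) -> np.ndarray:
    """Offsets from the outlier-free cycle mean, in absolute units.

    Days excluded by ``keep_mask`` (missing or outlying) carry NaN.  The
    mean of surviving offsets is zero by construction.
    """
    v = np.asarray(values, dtype=float)
    if keep_mask is None:
        keep_mask, _ = remove_outliers_iqr(v)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if not keep_mask.any():
        return np.full_like(v, np.nan)
    center = v[keep_mask].mean()
    out = np.where(keep_mask, v - center, np.nan)
    return out


def assign_cycle_cohort(cycles: pd.DataFrame, participants: pd.DataFrame) -> pd.Series:
    """Cohort label per participant-cycle.

    A cycle counts as birth_control if it overlaps the participant's
    reported pill interval (open-ended stop dates extend indefinitely);
    otherwise naturally_cycling.  Participants without interval columns
    fall back to their static cohort label.
    """
    part = participants.set_index("participant_id")
    for col in ("bc_start_date", "bc_stop_date"):
        if col in part.columns and part[col].dtype == object:
            part[col] = pd.to_datetime(part[col], errors="coerce")
    labels = []
    has_interval = "bc_start_date" in part.columns
    for cyc in cycles.itertuples():
        row = part.loc[cyc.participant_id]
        label = "naturally_cycling"
        if has_interval and pd.notna(row.get("bc_start_date")):
            start = row["bc_start_date"]
            stop = row.get("bc_stop_date")
            stop = stop if pd.notna(stop) else pd.Timestamp.max
            if cyc.start_date <= stop and cyc.end_date >= start:
                label = "birth_control"
        elif "cohort" in part.columns:
            label = row["cohort"]
        labels.append(label)
    return pd.Series(labels, index=cycles.index, name="cohort")


def build_offsets(
    cycle_days: pd.DataFrame,
    cycles: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    metrics: tuple[str, ...] = ("rhr", "rmssd"),
    eligible_only: bool = True,
    remove_outliers: bool = True,
) -> pd.DataFrame:
    """Long per-day offset table for the eligible cycles.

    ``remove_outliers=False`` skips the Tukey-fence step (useful for
    noise-free data, where the fences collapse onto the flat mid-cycle
    values and would excise the genuine trough and crest).

    One row per cycle-day-with-data per metric: participant_id,
    cycle_index, day, metric, offset (NaN on outlier days), outlier flag,
    weekend, kj, cycle_len, plus age/bmi/cohort when participant
    metadata is supplied.
    """
    use = cycles
    if eligible_only and "eligible" in cycles.columns:
        use = cycles[cycles["eligible"]]
    if participants is not None and "cohort" not in use.columns:
        use = use.assign(cohort=assign_cycle_cohort(use, participants))
    meta = None
    if participants is not None:
        meta = participants.set_index("participant_id")

    key = cycle_days.set_index(["participant_id", "cycle_index"])
    frames = []
    for cyc in use.itertuples():
        try:
            sub = key.loc[(cyc.participant_id, cyc.cycle_index)]
        except KeyError:
            continue
        for metric in metrics:
            col = METRIC_COLUMNS[metric]
            vals = sub[col].to_numpy(dtype=float)
            if remove_outliers:
                keep, _ = remove_outliers_iqr(vals)
            else:
                keep = np.isfinite(vals)
            if not keep.any():
                continue  # cycle contributes nothing for this metric
            offs = compute_offsets(vals, keep)
            present = np.isfinite(vals)
            frame = pd.DataFrame(
                {
                    "participant_id": cyc.participant_id,
                    "cycle_index": cyc.cycle_index,
                    "day": sub["day"].to_numpy()[present],
                    "metric": metric,
                    "offset": offs[present],
                    "outlier": (~keep[present]).astype(int),
                    "weekend": sub["weekend"].to_numpy()[present].astype(int),
                    "kj": sub["kj_prior_day"].to_numpy(dtype=float)[present],
                    "cycle_len": cyc.length,
                }
            )
            if hasattr(cyc, "cohort"):
                frame["cohort"] = cyc.cohort
            if meta is not None:
                frame["age"] = float(meta.loc[cyc.participant_id, "age_years"])
                frame["bmi"] = float(meta.loc[cyc.participant_id, "bmi"])
            frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "cycle_index", "day", "metric", "offset",
                     "outlier", "weekend", "kj", "cycle_len"]
        )
    return pd.concat(frames, ignore_index=True)
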