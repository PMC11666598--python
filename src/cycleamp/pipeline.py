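"""End-to-end orchestration: daily records to amplitude tables.

Convenience wrapper chaining cycle delineation, eligibility filtering,
offset construction, the population model, extrema location and the
amplitude statistic, so scripts and tests can run the whole analysis
with one call.  Every stage remains individually accessible through its
own module.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from . import amplitude as amp_mod
from . import cycles as cyc_mod
from . import population as pop_mod

__all__ = ["PipelineResult", "run_pipeline", "participant_baselines"]


@dataclasses.dataclass
class PipelineResult:
    cycles: pd.DataFrame
    exclusion_ledger: dict
    offsets: pd.DataFrame
    fits: dict  # metric -> PopulationFit (None when skipped)
    partial_dependence: dict  # metric -> PartialDependence
    extrema: dict  # metric -> Extrema
    amplitudes: dict  # metric -> participant-level DataFrame
    cycle_amplitudes: dict  # metric -> cycle-level DataFrame


def participant_baselines(cycle_days: pd.DataFrame, cycles: pd.DataFrame) -> pd.DataFrame:
    """Mean raw metric value per participant over eligible cycle days,
    outlier days removed — the 'baseline' covariate of the amplitude
    GLMs."""
    eligible = cycles[cycles["eligible"]][["participant_id", "cycle_index"]]
    days = cycle_days.merge(eligible, on=["participant_id", "cycle_index"])
    rows = []
    for pid, grp in days.groupby("participant_id", sort=True):
        row = {"participant_id": pid}
        for metric, col in cyc_mod.METRIC_COLUMNS.items():
            kept = []
            for _, cyc in grp.groupby("cycle_index"):
                vals = cyc[col].to_numpy(dtype=float)
                keep, _ = cyc_mod.remove_outliers_iqr(vals)
                kept.extend(vals[keep].tolist())
            row[f"baseline_{metric}"] = float(pd.Series(kept).mean()) if kept else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    daily: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    metrics: tuple[str, ...] = ("rhr", "rmssd"),
    mean_cycle_len: float | None = None,
    fit_model: bool = True,
    adjusted: bool = False,
    basis_dim: int = 20,
    grid_step: float = 0.01,
    min_days_per_window: int = 4,
    peak_day: int | None = None,
    nadir_day: int | None = None,
    remove_outliers: bool = True,
    **filter_kwargs,
) -> PipelineResult:
    """Run delineation, filtering, modelling and amplitude computation.

    When ``peak_day``/``nadir_day`` are given they override the
    model-derived extrema (``fit_model=False`` then skips the population
    fit entirely); overrides are interpreted as RHR-phase anchors and
    swapped for RMSSD, whose curve is antiphase.  ``mean_cycle_len``
    defaults to the mean length of the eligible cycles and controls when
    a late-cycle anchor tracks each cycle's final 7 days.
    """
    cycles = cyc_mod.delineate_cycles(daily)
    cycle_days = cyc_mod.build_cycle_days(daily, cycles)
    cycles, ledger = cyc_mod.apply_inclusion_filters(cycles, cycle_days, **filter_kwargs)
    offsets = cyc_mod.build_offsets(cycle_days, cycles, participants, metrics=metrics,
                                    remove_outliers=remove_outliers)

    if mean_cycle_len is None and cycles["eligible"].any():
        mean_cycle_len = float(cycles.loc[cycles["eligible"], "length"].mean())

    fits: dict = {}
    pds: dict = {}
    extrema: dict = {}
    amplitudes: dict = {}
    cycle_amps: dict = {}
    for metric in metrics:
        if fit_model and (peak_day is None or nadir_day is None):
            fit = pop_mod.fit_population(offsets, metric=metric, adjusted=adjusted,
                                         basis_dim=basis_dim)
            pdep = pop_mod.partial_dependence_day(fit, grid_step=grid_step)
            ext = pop_mod.locate_extrema(pdep)
            fits[metric] = fit
            pds[metric] = pdep
            peak, nadir = ext.peak_day_nearest, ext.nadir_day_nearest
            extrema[metric] = ext
        else:
            fits[metric] = None
            # overrides are RHR-phase anchors; RMSSD is antiphase
            if metric == "rmssd":
                peak, nadir = nadir_day, peak_day
            else:
                peak, nadir = peak_day, nadir_day
        part_df, cyc_df = amp_mod.compute_amplitudes(
            offsets, metric, peak_day=peak, nadir_day=nadir,
            mean_cycle_len=mean_cycle_len, min_days_per_window=min_days_per_window,
        )
        amplitudes[metric] = part_df
        cycle_amps[metric] = cyc_df

    return PipelineResult(
        cycles=cycles,
        exclusion_ledger=ledger,
        offsets=offsets,
        fits=fits,
        partial_dependence=pds,
        extrema=extrema,
        amplitudes=amplitudes,
        cycle_amplitudes=cycle_amps,
    )
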