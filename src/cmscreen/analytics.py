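"""Screen analytics: normalized nuclear fold change, multi-screen
aggregation, hit ranking, time-of-death calling, density curves, and
dose–response summaries.

The screen's readout is the nuclear fold change of a well — terminal /
initial nuclei count over an analysis window (default 0–72 h) — divided
by the mean raw fold change of the plate's vehicle-control wells. The
normalized value has three printed anchors: 1 means control-like growth,
0 means the well's cells all died, and 2 means the nuclei count doubled
relative to control. Hits are compounds with mean normalized fold change
strictly above 1 across replicate screens, ranked by ascending SEM (the
reproducibility criterion), because a large mean with large between-
screen scatter is a false positive.

Wells whose counts collapse are routed to a time-of-death table and
excluded from compound means: dead wells shed fluorescent debris that
makes their nuclei counts unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .platemodel import PlateMap, WellTimeSeries

__all__ = [
    "AnalyticsError",
    "FoldChangeResult",
    "ScreenSummary",
    "DEFAULT_WINDOW",
    "nuclear_fold_change",
    "normalize_to_control",
    "fold_changes_for_plate",
    "aggregate_screens",
    "rank_hits",
    "call_death",
    "density_percent_change",
    "dose_response_table",
    "screening_midpoint_density",
]


class AnalyticsError(ValueError):
    """Raised for undefined statistics (no controls, zero initial count, ...)."""


#: Default analysis window, hours post-addition.
DEFAULT_WINDOW: tuple[float, float] = (0.0, 72.0)


@dataclass
class FoldChangeResult:
    """Raw and control-normalized nuclear fold change of one well."""

    well: str
    raw_fold_change: float
    normalized_fold_change: float | None
    t_start_h: float
    t_end_h: float


@dataclass
class ScreenSummary:
    """Per-compound aggregate over replicate screens.

    ``values`` holds the per-screen normalized fold changes that entered
    the mean (dead wells excluded, with the exclusion count recorded).
    SEM is sd/sqrt(n) with n-1 degrees of freedom, None when n < 2.
    ``death_day`` is the mean day bin over the screens in which the
    compound's well died, None if it never died.
    """

    compound_id: str
    values: list[float]
    mean: float | None
    sem: float | None
    n_screens: int
    n_excluded_dead: int = 0
    death_day: float | None = None
    phenotypes: list[str] = field(default_factory=list)


def nuclear_fold_change(
    series: WellTimeSeries, window: tuple[float, float] = DEFAULT_WINDOW
) -> float:
    """Raw fold change: count(t_end) / count(t_start).

    Both window endpoints must have been imaged; a zero initial count
    leaves the ratio undefined and raises :class:`AnalyticsError`.
    """
    t0, t1 = window
    try:
        c0, c1 = series.count_at(t0), series.count_at(t1)
    except KeyError as exc:
        raise AnalyticsError(str(exc)) from None
    if c0 == 0:
        raise AnalyticsError(
            f"fold change undefined: zero initial count in well {series.well}"
        )
    return c1 / c0


def normalize_to_control(
    raw_fold_changes: Mapping[str, float], platemap: PlateMap
) -> dict[str, float]:
    """Divide each well's raw fold change by the plate's control-well mean.

    Control wells are the plate's role=control (vehicle) wells. By
    construction the control wells' normalized values average exactly 1.
    Raises :class:`AnalyticsError` when no control well has a defined raw
    fold change.
    """
    controls = [
        w for w in platemap.control_wells() if w in raw_fold_changes
        and raw_fold_changes[w] is not None
    ]
    if not controls:
        raise AnalyticsError(f"no control well with a defined fold change on plate {platemap.plate_id!r}")
    ref = float(np.mean([raw_fold_changes[w] for w in controls]))
    if ref <= 0:
        raise AnalyticsError("control-well mean fold change is not positive")
    return {w: fc / ref for w, fc in raw_fold_changes.items()}


def fold_changes_for_plate(
    series_by_well: Mapping[str, WellTimeSeries],
    platemap: PlateMap,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> list[FoldChangeResult]:
    """Raw + normalized fold change for every well of one plate/screen.

    Wells with an undefined raw fold change (zero initial count) are
    skipped; they belong in the death table, not the fold-change table.
    """
    raw: dict[str, float] = {}
    for well, ts in series_by_well.items():
        try:
            raw[well] = nuclear_fold_change(ts, window)
        except AnalyticsError:
            continue
    normalized = normalize_to_control(raw, platemap)
    return [
        FoldChangeResult(
            well=w,
            raw_fold_change=raw[w],
            normalized_fold_change=normalized[w],
            t_start_h=window[0],
            t_end_h=window[1],
        )
        for w in sorted(raw)
    ]


def aggregate_screens(
    results: pd.DataFrame,
    phenotypes: Mapping[str, Sequence[str]] | None = None,
) -> list[ScreenSummary]:
    """Aggregate per-screen normalized fold changes into per-compound summaries.

    ``results`` is a tidy table with columns compound, screen,
    normalized_fc, and optionally died (bool) and death_day. Dead wells
    are excluded from the mean (their counts are debris-contaminated) but
    tallied, and their death days averaged. Compounds present in no
    screen are simply absent. SEM is reported only for n >= 2 screens.
    ``phenotypes`` attaches free-form manual annotation tags per compound.
    """
    required = {"compound", "screen", "normalized_fc"}
    if not required.issubset(results.columns):
        raise AnalyticsError(f"results table needs columns {sorted(required)}")
    df = results.copy()
    if "died" not in df.columns:
        df["died"] = False
    if "death_day" not in df.columns:
        df["death_day"] = np.nan
    summaries: list[ScreenSummary] = []
    for compound, grp in df.groupby("compound", sort=True):
        alive = grp[~grp["died"].astype(bool)]
        vals = [float(v) for v in alive["normalized_fc"].dropna()]
        dead = grp[grp["died"].astype(bool)]
        death_days = dead["death_day"].dropna()
        mean = float(np.mean(vals)) if vals else None
        sem = (
            float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
            if len(vals) >= 2
            else None
        )
        summaries.append(
            ScreenSummary(
                compound_id=str(compound),
                values=vals,
                mean=mean,
                sem=sem,
                n_screens=int(grp["screen"].nunique()),
                n_excluded_dead=int(len(dead)),
                death_day=float(death_days.mean()) if len(death_days) else None,
                phenotypes=list((phenotypes or {}).get(str(compound), [])),
            )
        )
    return summaries


def rank_hits(summaries: Iterable[ScreenSummary]) -> list[ScreenSummary]:
    """Hit list: compounds with mean normalized fold change strictly > 1,
    sorted by ascending SEM (most reproducible first); ties broken by
    descending mean, then compound id. Compounds without a SEM (single
    screen) sort after all compounds that have one.
    """
    hits = [s for s in summaries if s.mean is not None and s.mean > 1.0]
    return sorted(
        hits,
        key=lambda s: (
            s.sem is None,
            s.sem if s.sem is not None else 0.0,
            -s.mean,
            s.compound_id,
        ),
    )


def call_death(
    series: WellTimeSeries,
    collapse_fraction: float = 0.2,
    persistence: int = 2,
) -> tuple[bool, int | None]:
    """Call well death from count collapse; returns (died, death_day).

    Death is called when the count falls below ``collapse_fraction`` times
    the t=0 count and stays below for at least ``persistence`` consecutive
    imaging points (a below-threshold run that reaches the end of the
    series also qualifies — the well ended dead). The day bin is
    ceil(first-crossing hour / 24); a crossing at or before the first
    image is day 0 (death in the addition-to-first-image window); a first
    crossing observed at 12 or 24 h is day 1.
    """
    if not 0 < collapse_fraction <= 1:
        raise ValueError("collapse fraction must lie in (0, 1]")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    counts = series.counts
    times = series.times_h
    if len(counts) == 0:
        raise AnalyticsError("empty time series")
    c0 = int(counts[0])
    if c0 == 0:
        return True, 0
    thr = collapse_fraction * c0
    below = counts < thr
    n = len(counts)
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        run = j - i
        if run >= persistence or j == n:
            t_cross = float(times[i])
            day = 0 if t_cross <= times[0] else math.ceil(t_cross / 24.0)
            return True, int(day)
        i = j
    return False, None


def density_percent_change(
    fold_change_by_density: Mapping[float, float], fold_change_confluent: float
) -> dict[float, float]:
    """Percent change in nuclei count relative to confluent wells.

    100 * (FC_density - FC_confluent) / FC_confluent, so confluent wells
    map to exactly 0%.
    """
    if fold_change_confluent is None or not math.isfinite(fold_change_confluent) or fold_change_confluent <= 0:
        raise AnalyticsError("confluent reference fold change undefined")
    return {
        float(d): 100.0 * (fc - fold_change_confluent) / fold_change_confluent
        for d, fc in fold_change_by_density.items()
    }


def dose_response_table(results: pd.DataFrame) -> pd.DataFrame:
    """Summarize normalized fold change per (compound, concentration).

    ``results`` has columns compound, concentration_um, normalized_fc (one
    row per replicate). Returns a long-format table (compound,
    concentration_um, mean, sem, n) with concentrations ascending; no
    curve fitting — the dose series is reported as means, matching how
    follow-up concentration series are read out.
    """
    required = {"compound", "concentration_um", "normalized_fc"}
    if not required.issubset(results.columns):
        raise AnalyticsError(f"results table needs columns {sorted(required)}")
    rows = []
    for (compound, conc), grp in results.groupby(
        ["compound", "concentration_um"], sort=True
    ):
        vals = grp["normalized_fc"].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        rows.append(
            {
                "compound": compound,
                "concentration_um": float(conc),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else np.nan,
                "n": int(len(vals)),
            }
        )
    out = pd.DataFrame(rows, columns=["compound", "concentration_um", "mean", "sem", "n"])
    return out.sort_values(["compound", "concentration_um"]).reset_index(drop=True)


def screening_midpoint_density(d_hi: float, d_lo: float) -> float:
    """Screening density at the middle of the density-responsive range.

    The arithmetic midpoint (d_hi + d_lo) / 2 of the densities bracketing
    the inverse density–proliferation relationship; a plate seeded there
    can report proliferation changes in both directions.
    """
    if not (d_hi >= d_lo > 0):
        raise ValueError(f"need d_hi >= d_lo > 0, got ({d_hi}, {d_lo})")
    return (d_hi + d_lo) / 2.0
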