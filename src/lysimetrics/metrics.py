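"""Whole-plant drought-response metrics.

Builds the agronomic/physiological readout from extracted fluxes and
bilinear fits:

* **relative transpiration** (rTR): a drought plant's daily transpiration
  divided by the same-day mean of the well-watered plants of its cultivar —
  a size-corrected stress index;
* **recovery rate** (resilience): OLS slope of rTR versus day over the
  re-irrigation period, rTR/day;
* phase-wise average daily transpiration (dTR, g/day);
* agronomic **water-use efficiency**: harvested mass per unit transpired
  water.  Reported in g per kg of water — gram-per-gram ratios for cereal
  yield are O(1e-3), and the per-kilogram scale is the one practitioners
  quote;
* **harvest index**: grain / total above-ground biomass;
* Pearson correlation of cumulative transpiration with grain yield;
* a relative **water-use classification** (conserving / non-conserving /
  dynamic / intermediate) from the well-watered transpiration level and the
  post-threshold decline slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as Date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bilinear import BilinearFit

__all__ = [
    "PhaseCalendar",
    "RecoveryFit",
    "relative_transpiration",
    "recovery_rate",
    "phase_average_dtr",
    "water_use_efficiency",
    "harvest_index",
    "transpiration_yield_correlation",
    "classify_water_use",
]


@dataclass(frozen=True)
class PhaseCalendar:
    """Contiguous, ordered experimental phases.

    ``phases`` maps phase name -> (first date, last date), in protocol
    order: pre_drought, drought, recovery, post_recovery.
    """

    phases: tuple[tuple[str, Date, Date], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for name, start, end in self.phases:
            if end < start:
                raise ValueError(f"phase {name}: end before start")
            if prev_end is not None and start != prev_end + timedelta(days=1):
                raise ValueError(f"phase {name}: not contiguous with previous phase")
            prev_end = end

    @classmethod
    def from_lengths(cls, start: Date, lengths: Mapping[str, int]) -> "PhaseCalendar":
        phases, d = [], start
        for name, n in lengths.items():
            if n < 1:
                raise ValueError(f"phase {name}: length must be >= 1 day")
            phases.append((name, d, d + timedelta(days=n - 1)))
            d = d + timedelta(days=n)
        return cls(tuple(phases))

    def span(self, phase: str) -> tuple[Date, Date]:
        for name, start, end in self.phases:
            if name == phase:
                return start, end
        raise KeyError(phase)

    def phase_of(self, on_date: Date) -> str | None:
        for name, start, end in self.phases:
            if start <= on_date <= end:
                return name
        return None

    def dates(self, phase: str) -> list[Date]:
        start, end = self.span(phase)
        return [start + timedelta(days=i) for i in range((end - start).days + 1)]


def relative_transpiration(
    drought_daily: pd.DataFrame,
    control_dailies: Sequence[pd.DataFrame],
    dates: Sequence[Date] | None = None,
) -> pd.DataFrame:
    """rTR per date: drought daily transpiration / mean of control plants.

    All inputs are daily tables with columns ``date``, ``daily_tr_g`` and
    ``valid`` (the output of daily extraction).  Dates where the control
    mean is missing are skipped; a zero control mean yields NaN flagged via
    the ``zero_control`` column.
    """
    if len(control_dailies) == 0:
        raise ValueError("need at least one control plant")
    ctrl = pd.concat(
        [df[df["valid"]][["date", "daily_tr_g"]] for df in control_dailies]
    )
    ctrl_mean = ctrl.groupby("date")["daily_tr_g"].mean()
    d = drought_daily[drought_daily["valid"]]
    if dates is not None:
        d = d[d["date"].isin(set(dates))]
    rows = []
    for _, row in d.iterrows():
        if row["date"] not in ctrl_mean.index:
            continue
        m = ctrl_mean.loc[row["date"]]
        zero = m == 0
        rows.append(
            {
                "date": row["date"],
                "rtr": np.nan if zero else row["daily_tr_g"] / m,
                "zero_control": zero,
            }
        )
    return pd.DataFrame(rows, columns=["date", "rtr", "zero_control"])


@dataclass(frozen=True)
class RecoveryFit:
    """OLS line of rTR on recovery-day index (day 1 = first re-irrigated day)."""

    slope: float
    intercept: float
    n: int
    r_value: float


def recovery_rate(rtr: pd.DataFrame | Sequence[float]) -> RecoveryFit:
    """Recovery (resilience) rate: OLS slope of rTR versus time in days.

    ``rtr`` is either a frame with columns ``date`` and ``rtr`` (day index
    assigned chronologically, first date = day 1) or a plain sequence of
    rTR values on consecutive days.

    Raises
    ------
    ValueError
        With fewer than 3 valid points.
    """
    if isinstance(rtr, pd.DataFrame):
        df = rtr.dropna(subset=["rtr"]).sort_values("date")
        y = df["rtr"].to_numpy(float)
        day0 = df["date"].min()
        x = np.array([(d - day0).days + 1 for d in df["date"]], dtype=float)
    else:
        y = np.asarray(rtr, dtype=float)
        ok = np.isfinite(y)
        x = np.arange(1, len(y) + 1, dtype=float)[ok]
        y = y[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 rTR values for a recovery slope")
    res = stats.linregress(x, y)
    return RecoveryFit(
        slope=float(res.slope), intercept=float(res.intercept),
        n=len(y), r_value=float(res.rvalue),
    )


def phase_average_dtr(
    daily: pd.DataFrame, calendar: PhaseCalendar, phase: str
) -> float:
    """Average daily transpiration over a phase, g/day.

    Cumulative transpiration over the phase's valid days divided by the
    number of valid days (days excluded for missing records do not dilute
    the average).

    Raises
    ------
    ValueError
        If the phase contains no valid days.
    """
    start, end = calendar.span(phase)
    sel = daily[(daily["date"] >= start) & (daily["date"] <= end) & daily["valid"]]
    if len(sel) == 0:
        raise ValueError(f"no valid days in phase {phase!r}")
    return float(sel["daily_tr_g"].sum() / len(sel))


def water_use_efficiency(harvest_mass: float, water_used: float) -> float:
    """Agronomic WUE: harvested mass per kilogram of transpired water, g/kg.

    ``water_used`` is the cumulative transpiration over the monitored
    period in grams.

    Raises
    ------
    ValueError
        For a non-positive water amount or negative harvest.
    """
    if water_used <= 0:
        raise ValueError("water_used must be positive")
    if harvest_mass < 0:
        raise ValueError("harvest_mass must be non-negative")
    return harvest_mass / (water_used / 1000.0)


def harvest_index(grain: float, biomass: float) -> float:
    """Harvest index: grain mass / total above-ground biomass, fraction.

    Raises
    ------
    ValueError
        If biomass is non-positive or grain exceeds biomass.
    """
    if biomass <= 0:
        raise ValueError("biomass must be positive")
    if grain < 0 or grain > biomass:
        raise ValueError("grain must lie in [0, biomass]")
    return grain / biomass


def transpiration_yield_correlation(
    table: pd.DataFrame,
    water_col: str = "water_used_g",
    yield_col: str = "grain_g",
    group_col: str = "treatment",
) -> dict[str, tuple[float, float]]:
    """Pearson r (and two-sided p) of cumulative transpiration vs grain
    yield, per treatment group.

    Raises
    ------
    ValueError
        For groups with fewer than 3 plants or zero variance.
    """
    out: dict[str, tuple[float, float]] = {}
    for group, sub in table.groupby(group_col):
        x = sub[water_col].to_numpy(float)
        y = sub[yield_col].to_numpy(float)
        if len(x) < 3:
            raise ValueError(f"group {group!r}: need at least 3 plants")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"group {group!r}: zero variance")
        r, p = stats.pearsonr(x, y)
        out[str(group)] = (float(r), float(p))
    return out


def classify_water_use(
    fits: Mapping[str, BilinearFit],
    control_tr_max: Mapping[str, float],
    recovery_rates: Mapping[str, float] | None = None,
    tr_max_threshold: float | None = None,
    slope_threshold: float | None = None,
) -> dict[str, str]:
    """Relative water-use-behaviour classification per cultivar.

    A cultivar transpiring freely under ample water (well-watered
    transpiration level strictly above the cultivar median, or the supplied
    threshold) and shutting down steeply after theta_crit (decline slope
    above the median) is **non_conserving**; low level plus shallow decline
    is **conserving**; high level plus shallow decline — a cultivar that
    behaves like a conserver only once drought sets in — is **dynamic**;
    anything else is **intermediate**.  With a single cultivar the relative
    definition collapses and ``intermediate`` is returned with a warning.
    """
    names = list(fits)
    if len(names) < 2:
        warnings.warn(
            "water-use classification is relative; need >= 2 cultivars",
            stacklevel=2,
        )
        return {name: "intermediate" for name in names}
    tr_levels = np.array([control_tr_max[n] for n in names], dtype=float)
    slopes = np.array([fits[n].slope for n in names], dtype=float)
    t_tr = float(np.median(tr_levels)) if tr_max_threshold is None else tr_max_threshold
    t_sl = float(np.median(slopes)) if slope_threshold is None else slope_threshold
    out = {}
    for name, level, slope in zip(names, tr_levels, slopes):
        high, steep = level > t_tr, slope > t_sl
        if high and steep:
            label = "non_conserving"
        elif not high and not steep:
            label = "conserving"
        elif high and not steep:
            label = "dynamic"
        else:
            label = "intermediate"
        out[name] = label
    return out
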