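"""Extraction of physiological signals from gravimetric weight traces.

A lysimeter array records the weight of each pot–plant–sensor system every
few minutes.  With the soil surface covered (no evaporation), every gram the
system loses between irrigation events is water transpired by the plant.
This module turns a raw weight trace plus an irrigation-event log into
interval transpiration rates, daily transpiration sums, volumetric soil
water content (SWC) and whole-plant (canopy) conductance.

Irrigation handling
-------------------
Two modes are supported:

``"subtract"`` (default)
    The logged dose of every irrigation event is added back to the interval
    weight change, so the interval rate is the *net* plant water loss even
    while the pot is being watered.  With a trustworthy dose log this
    inverts the water balance exactly.
``"mask"``
    Intervals that overlap an irrigation event, a guard window around it
    (drainage transients), or show a weight gain are excluded.  Use when
    event times are known but dose amounts are not reliable.

Daily sums are computed from the raw dose-corrected rates so that water is
conserved exactly; the cleaned series (rolling-median smoothed, negatives
clipped) is used for instantaneous quantities such as the midday rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date, time as Time
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightSeries",
    "IrrigationLog",
    "ExtractionConfig",
    "PlantFlux",
    "interval_transpiration",
    "daily_transpiration",
    "volumetric_swc",
    "canopy_conductance",
    "midday_rate",
    "midday_swc",
    "extract_plant_flux",
    "flux_table",
]


@dataclass
class WeightSeries:
    """Timestamped system-weight trace for one plant.

    Parameters
    ----------
    plant_id:
        Identifier of the measurement unit.
    data:
        Frame with columns ``timestamp`` (datetime64) and ``weight_g``.
        Timestamps must be strictly increasing; nominal regular spacing
        with gaps is allowed.
    tare:
        Dry weight of pot + soil + sensors (+ nominal plant mass), g.
    """

    plant_id: str
    data: pd.DataFrame
    tare: float = 0.0

    def __post_init__(self) -> None:
        required = {"timestamp", "weight_g"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"WeightSeries data needs columns {sorted(required)}")
        if len(self.data) == 0:
            raise ValueError("empty weight series")
        ts = pd.to_datetime(self.data["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        self.data = self.data.assign(timestamp=ts).reset_index(drop=True)

    @property
    def timestamps(self) -> pd.Series:
        return self.data["timestamp"]

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight_g"].to_numpy(float)

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.data["timestamp"].iloc[0], self.data["timestamp"].iloc[-1]


@dataclass
class IrrigationLog:
    """Irrigation events: columns ``timestamp``, ``plant_id``, ``dose_g``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"timestamp", "plant_id", "dose_g"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"IrrigationLog needs columns {sorted(required)}")
        if len(self.data) and (self.data["dose_g"] <= 0).any():
            raise ValueError("irrigation doses must be positive")
        self.data = self.data.assign(
            timestamp=pd.to_datetime(self.data["timestamp"])
        ).reset_index(drop=True)

    def for_plant(self, plant_id: str) -> pd.DataFrame:
        sub = self.data[self.data["plant_id"] == plant_id]
        return sub.sort_values("timestamp").reset_index(drop=True)


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs for signal extraction.

    guard_minutes applies in ``mask`` mode only: intervals within this many
    minutes of an irrigation event are excluded (drainage transients).
    A day is flagged missing when less than ``min_coverage`` of its expected
    records are present after masking.
    """

    irrigation_mode: str = "subtract"  # or "mask"
    guard_minutes: float = 6.0
    smooth_width: int = 5  # rolling-median width for the cleaned rate; 1 = off
    min_coverage: float = 0.8
    midday_window: tuple[Time, Time] = (Time(15, 0), Time(17, 0))
    nominal_step_min: float | None = None  # None: use median spacing
    max_gap_factor: float = 1.5  # intervals longer than this x nominal are gaps

    def __post_init__(self) -> None:
        if self.irrigation_mode not in ("subtract", "mask"):
            raise ValueError("irrigation_mode must be 'subtract' or 'mask'")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.smooth_width < 1 or self.smooth_width % 2 == 0:
            raise ValueError("smooth_width must be an odd integer >= 1")


def interval_transpiration(
    series: WeightSeries,
    log: IrrigationLog | None = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Per-interval transpiration rates from a weight trace.

    Returns a frame with one row per record interval: ``timestamp``
    (interval start), ``dt_min``, ``rate_raw`` (g/min, dose-corrected,
    unsmoothed, unclipped — conserves water exactly), ``rate`` (cleaned:
    smoothed and clipped at zero), and ``masked``.

    Raises
    ------
    ValueError
        If the series is empty (enforced by :class:`WeightSeries`) or an
        irrigation event falls outside the series time span.
    """
    ts = series.data["timestamp"].to_numpy()
    w = series.weights
    if len(w) < 2:
        raise ValueError("need at least two records to form an interval")

    t0 = ts[:-1]
    t1 = ts[1:]
    dt_min = (t1 - t0) / np.timedelta64(60, "s")
    dweight = w[:-1] - w[1:]

    events = log.for_plant(series.plant_id) if log is not None else pd.DataFrame(
        columns=["timestamp", "dose_g"]
    )
    if len(events):
        ev_ts = events["timestamp"].to_numpy()
        if ev_ts.min() < ts[0] or ev_ts.max() >= ts[-1]:
            raise ValueError(
                f"irrigation event outside series span for {series.plant_id}"
            )

    nominal = config.nominal_step_min or float(np.median(dt_min))
    gap = dt_min > config.max_gap_factor * nominal

    masked = gap.copy()
    dose_per_interval = np.zeros_like(dweight)
    if len(events):
        ev_ts = events["timestamp"].to_numpy()
        ev_dose = events["dose_g"].to_numpy(float)
        # event belongs to the interval [t_i, t_{i+1}) containing it
        idx = np.searchsorted(t0, ev_ts, side="right") - 1
        np.add.at(dose_per_interval, idx, ev_dose)
        if config.irrigation_mode == "mask":
            guard = np.timedelta64(int(config.guard_minutes * 60), "s")
            for t_ev in ev_ts:
                masked |= (t1 > t_ev - guard) & (t0 < t_ev + guard)

    if config.irrigation_mode == "subtract":
        rate_raw = (dweight + dose_per_interval) / dt_min
    else:
        rate_raw = dweight / dt_min
        masked |= dweight < 0  # weight-gain intervals

    clean = rate_raw.copy()
    clean[masked] = np.nan
    if config.smooth_width > 1:
        clean = (
            pd.Series(clean)
            .rolling(config.smooth_width, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        clean[masked] = np.nan
    clean = np.where(np.isnan(clean), np.nan, np.maximum(clean, 0.0))

    return pd.DataFrame(
        {
            "timestamp": t0,
            "dt_min": dt_min,
            "rate_raw": rate_raw,
            "rate": clean,
            "masked": masked,
        }
    )


def daily_transpiration(
    intervals: pd.DataFrame,
    min_coverage: float = 0.8,
    nominal_step_min: float | None = None,
) -> pd.DataFrame:
    """Daily transpiration sums (g/day) from interval rates.

    Each interval is attributed to the calendar date of its start.  The sum
    uses the raw (conservative) rates of unmasked intervals.  Days covering
    less than ``min_coverage`` of 24 h with valid intervals are flagged
    invalid (excluded from downstream averages).
    """
    df = intervals.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    valid = ~df["masked"]
    contrib = np.where(valid, df["rate_raw"] * df["dt_min"], 0.0)
    covered = np.where(valid, df["dt_min"], 0.0)
    out = (
        pd.DataFrame({"date": df["date"], "tr": contrib, "cov": covered})
        .groupby("date", as_index=False)
        .sum()
    )
    out["coverage"] = out["cov"] / 1440.0
    out["valid"] = out["coverage"] >= min_coverage
    return out.rename(columns={"tr": "daily_tr_g"})[
        ["date", "daily_tr_g", "coverage", "valid"]
    ]


def volumetric_swc(
    series: WeightSeries,
    pot_volume: float,
    plant_mass_correction: float = 0.0,
    tare: float | None = None,
    tolerance: float = 25.0,
    clip: bool = True,
) -> pd.DataFrame:
    """Volumetric soil water content from system weight.

    swc(t) = (weight(t) - tare - plant_mass_correction) / pot_volume, with
    water density 1 g/cm^3, clipped to [0, 1].

    Raises
    ------
    ValueError
        If any weight falls below the tare by more than ``tolerance`` g.
    """
    tare_g = series.tare if tare is None else tare
    if pot_volume <= 0:
        raise ValueError("pot_volume must be positive")
    water = series.weights - tare_g - plant_mass_correction
    if (water < -tolerance).any():
        raise ValueError(
            f"weights below tare by more than {tolerance} g for {series.plant_id}"
        )
    swc = water / pot_volume
    if clip:
        swc = np.clip(swc, 0.0, 1.0)
    return pd.DataFrame({"timestamp": series.data["timestamp"], "swc": swc})


def canopy_conductance(
    intervals: pd.DataFrame,
    forcing: pd.DataFrame,
    on_date: Date,
) -> float:
    """Daytime mean of transpiration rate / VPD, g min^-1 kPa^-1.

    The whole-plant analogue of stomatal conductance: each unmasked daytime
    interval's cleaned rate is divided by the VPD at the interval start;
    zero or missing VPD intervals are excluded.  VPD is used in kPa without
    further normalisation (the definition is documented, not calibrated to
    any proprietary platform output).
    """
    df = intervals.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    day = df[(df["date"] == on_date) & (~df["masked"]) & df["rate"].notna()]
    if len(day) == 0:
        return float("nan")
    forc = forcing.set_index(pd.to_datetime(forcing["timestamp"]))
    vpd = forc["vpd"].reindex(pd.to_datetime(day["timestamp"])).to_numpy(float)
    light = forc["light_on"].reindex(pd.to_datetime(day["timestamp"])).to_numpy()
    ok = np.isfinite(vpd) & (vpd > 0) & (light == True)  # noqa: E712
    if not ok.any():
        return float("nan")
    return float(np.mean(day["rate"].to_numpy(float)[ok] / vpd[ok]))


def midday_rate(
    intervals: pd.DataFrame,
    on_date: Date,
    window: tuple[Time, Time] = (Time(15, 0), Time(17, 0)),
) -> float:
    """Mean cleaned transpiration rate within the stable midday window.

    Returns NaN when no unmasked interval starts inside the window
    (e.g. the window is fully masked by an irrigation guard).
    """
    ts = pd.to_datetime(intervals["timestamp"])
    sel = (
        (ts.dt.date == on_date)
        & (ts.dt.time >= window[0])
        & (ts.dt.time < window[1])
        & (~intervals["masked"])
        & intervals["rate"].notna()
    )
    if not sel.any():
        return float("nan")
    return float(intervals.loc[sel, "rate"].mean())


def midday_swc(
    swc: pd.DataFrame,
    on_date: Date,
    window: tuple[Time, Time] = (Time(15, 0), Time(17, 0)),
) -> float:
    """Mean volumetric SWC within the midday window."""
    ts = pd.to_datetime(swc["timestamp"])
    sel = (ts.dt.date == on_date) & (ts.dt.time >= window[0]) & (ts.dt.time < window[1])
    if not sel.any():
        return float("nan")
    return float(swc.loc[sel, "swc"].mean())


@dataclass
class PlantFlux:
    """Derived per-plant signals.

    Attributes
    ----------
    intervals:
        Output of :func:`interval_transpiration`.
    daily:
        Output of :func:`daily_transpiration` (date, daily_tr_g, coverage, valid).
    swc:
        Output of :func:`volumetric_swc` (timestamp, swc).
    midday:
        Per-date midday transpiration rate and SWC (date, midday_tr_g_min,
        midday_swc).
    conductance:
        Per-date canopy conductance (date, canopy_conductance).
    """

    plant_id: str
    intervals: pd.DataFrame
    daily: pd.DataFrame
    swc: pd.DataFrame
    midday: pd.DataFrame
    conductance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def daily_tr(self, on_date: Date) -> float:
        row = self.daily[self.daily["date"] == on_date]
        if len(row) == 0 or not bool(row["valid"].iloc[0]):
            return float("nan")
        return float(row["daily_tr_g"].iloc[0])


def extract_plant_flux(
    series: WeightSeries,
    log: IrrigationLog | None,
    forcing: pd.DataFrame | None,
    pot_volume: float,
    config: ExtractionConfig = ExtractionConfig(),
    plant_mass_correction: float = 0.0,
) -> PlantFlux:
    """Run the full per-plant extraction: rates, daily sums, SWC, midday, conductance."""
    intervals = interval_transpiration(series, log, config)
    daily = daily_transpiration(intervals, config.min_coverage)
    swc = volumetric_swc(series, pot_volume, plant_mass_correction)
    dates = daily["date"].tolist()

    # vectorised per-date summaries (equivalent to midday_rate / midday_swc /
    # canopy_conductance applied date by date, but one pass over the trace)
    its = pd.to_datetime(intervals["timestamp"])
    itod, idate = its.dt.time, its.dt.date
    w0, w1 = config.midday_window
    imid = (itod >= w0) & (itod < w1) & (~intervals["masked"]) & intervals["rate"].notna()
    mid_tr = (
        pd.DataFrame({"date": idate[imid], "v": intervals.loc[imid, "rate"]})
        .groupby("date")["v"]
        .mean()
    )
    sts = pd.to_datetime(swc["timestamp"])
    smid = (sts.dt.time >= w0) & (sts.dt.time < w1)
    mid_swc = (
        pd.DataFrame({"date": sts.dt.date[smid], "v": swc.loc[smid, "swc"]})
        .groupby("date")["v"]
        .mean()
    )
    midday = pd.DataFrame(
        {
            "date": dates,
            "midday_tr_g_min": mid_tr.reindex(dates).to_numpy(),
            "midday_swc": mid_swc.reindex(dates).to_numpy(),
        }
    )
    if forcing is not None:
        forc = forcing.set_index(pd.to_datetime(forcing["timestamp"]))
        vpd = forc["vpd"].reindex(its).to_numpy(float)
        light = forc["light_on"].reindex(its).fillna(False).to_numpy(bool)
        ok = (
            (~intervals["masked"]).to_numpy()
            & intervals["rate"].notna().to_numpy()
            & np.isfinite(vpd)
            & (vpd > 0)
            & light
        )
        gc = (
            pd.DataFrame(
                {"date": idate[ok], "v": intervals.loc[ok, "rate"].to_numpy() / vpd[ok]}
            )
            .groupby("date")["v"]
            .mean()
        )
        cond = pd.DataFrame(
            {"date": dates, "canopy_conductance": gc.reindex(dates).to_numpy()}
        )
    else:
        cond = pd.DataFrame(columns=["date", "canopy_conductance"])
    return PlantFlux(
        plant_id=series.plant_id,
        intervals=intervals,
        daily=daily,
        swc=swc,
        midday=midday,
        conductance=cond,
    )


def flux_table(fluxes: Iterable[PlantFlux]) -> pd.DataFrame:
    """Tidy per-plant-per-day table for CSV export.

    Columns: plant_id, date, daily_tr_g, coverage, valid, midday_tr_g_min,
    midday_swc, canopy_conductance.
    """
    rows = []
    for fl in fluxes:
        df = fl.daily.merge(fl.midday, on="date", how="left")
        if len(fl.conductance):
            df = df.merge(fl.conductance, on="date", how="left")
        else:
            df["canopy_conductance"] = np.nan
        df.insert(0, "plant_id", fl.plant_id)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
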