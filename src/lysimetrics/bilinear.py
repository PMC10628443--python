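"""Plateau-then-decline ("bilinear") regression of transpiration rate on SWC.

As soil dries, whole-plant transpiration stays at a plateau TRmax until the
volumetric soil water content falls below a critical value theta_crit, then
declines linearly.  The model fitted here is

    TR(s) = TRmax                              for s >= theta_crit
    TR(s) = TRmax - b * (theta_crit - s)       for s <  theta_crit

continuous at the breakpoint, with b >= 0.  Derived quantities:

* the **terminal drought point** — the minimum observed SWC and the fitted
  rate there, i.e. the state a plant reached at the end of the drought;
* the **trapezoid area** under the declining limb between the terminal SWC
  and theta_crit — an index (in (g/min)·(cm³/cm³)) of the water a plant
  keeps transpiring after stress onset;
* the cumulative transpired mass between the theta_crit crossing and the
  terminal day.

Breakpoint estimation profiles candidate theta_crit values on a grid
(constrained least squares at each fixed breakpoint, closed form) and then
refines with exact closed-form solutions on every admissible decline/
plateau partition near the optimum, so the reported parameters minimise the
residual sum of squares globally.  Degenerate inputs (all points in one
regime) are flagged via ``status``, never reported silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "BilinearFit",
    "fit_bilinear",
    "predict",
    "terminal_drought_point",
    "trapezoid_area",
    "TrapezoidArea",
    "cumulative_transpiration_between",
    "drought_crossing_times",
    "slope_from_geometry",
]


@dataclass
class BilinearFit:
    """Fitted bilinear water-response model.

    ``status`` is ``"ok"`` for a two-regime fit, or a degenerate marker
    (``"degenerate_plateau"``, ``"degenerate_decline"``) when all points
    fall in one regime; degenerate fits carry explicit boundary values, and
    downstream derivations refuse them.
    """

    tr_max: float
    theta_crit: float
    slope: float
    r_squared: float
    n_points: int
    sse: float = float("nan")
    swc_term: float | None = None
    tr_term: float | None = None
    status: str = "ok"

    @property
    def degenerate(self) -> bool:
        return self.status != "ok"


def predict(fit: BilinearFit, swc) -> np.ndarray:
    """Evaluate the fitted model at given SWC values."""
    s = np.asarray(swc, dtype=float)
    out = np.where(
        s >= fit.theta_crit,
        fit.tr_max,
        fit.tr_max - fit.slope * (fit.theta_crit - s),
    )
    return out if out.ndim else float(out)


def _fixed_theta_fit(s: np.ndarray, y: np.ndarray, theta: float):
    """Constrained LS at fixed breakpoint: y ~ a - b*max(0, theta-s), b>=0.

    Returns (a, b, sse).
    """
    x = np.maximum(0.0, theta - s)
    sx = x.sum()
    sxx = (x * x).sum()
    n = len(s)
    det = n * sxx - sx * sx
    if det <= 0:  # no decline-side leverage: plateau-only
        a = y.mean()
        b = 0.0
    else:
        sy = y.sum()
        sxy = (x * y).sum()
        # y = a - b x  ->  OLS on (x, y) with slope -b
        b = -(n * sxy - sx * sy) / det
        if b < 0:
            b = 0.0
            a = y.mean()
        else:
            a = (sy + b * sx) / n
    resid = y - (a - b * x)
    return a, b, float(resid @ resid)


def _partition_candidates(s, y, lo_idx):
    """Exact optimum for the partition decline=s[:k], plateau=s[k:], k=lo_idx.

    Yields (theta, a, b, sse) candidates: the unconstrained interior optimum
    when it is consistent with the partition, else nothing (interval
    endpoints are covered by fixed-theta fits at the data values).
    """
    d_s, d_y = s[:lo_idx], y[:lo_idx]
    p_y = y[lo_idx:]
    a = p_y.mean()
    # decline side: y ~ c0 + b*s
    n = len(d_s)
    sx, sy = d_s.sum(), d_y.sum()
    sxx, sxy = (d_s * d_s).sum(), (d_s * d_y).sum()
    det = n * sxx - sx * sx
    if det <= 0:
        return
    b = (n * sxy - sx * sy) / det
    c0 = (sy - b * sx) / n
    if b <= 0:
        return
    theta = (a - c0) / b
    lo, hi = s[lo_idx - 1], s[lo_idx]
    if not (lo < theta <= hi):
        return
    sse = float(((d_y - (c0 + b * d_s)) ** 2).sum() + ((p_y - a) ** 2).sum())
    yield theta, a, b, sse


def fit_bilinear(
    swc: Sequence[float] | np.ndarray,
    rate: Sequence[float] | np.ndarray,
    n_candidates: int = 200,
    min_points: int = 5,
    min_segment: int = 2,
    refine: bool = True,
) -> BilinearFit:
    """Fit the bilinear model by profiled constrained least squares.

    A breakpoint is admissible when at least ``min_segment`` points lie
    strictly below it and at least ``min_segment`` at or above it.  The
    profile is evaluated on a grid of candidates (uniform over the inner
    5th-95th percentile of observed SWC, plus every interior data value);
    with ``refine`` the exact closed-form optimum of each admissible
    partition near the grid optimum is also considered.  Tie-break: lowest
    SSE, then largest theta_crit (earlier stress onset).

    Raises
    ------
    ValueError
        For fewer than ``min_points`` points or non-finite input.
    """
    s = np.asarray(swc, dtype=float)
    y = np.asarray(rate, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("swc and rate must be 1-D arrays of equal length")
    if len(s) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(s)}")
    if not (np.isfinite(s).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    order = np.argsort(s, kind="stable")
    s, y = s[order], y[order]
    n = len(s)
    sst = float(((y - y.mean()) ** 2).sum())

    # admissible breakpoint range: > s[min_segment-1] (min_segment points
    # strictly below) and <= s[n-min_segment]
    lo_open = s[min_segment - 1]
    hi_closed = s[n - min_segment]
    if not lo_open < hi_closed:
        # cannot place a two-regime breakpoint (massive ties / too few)
        a, b, sse = _fixed_theta_fit(s, y, s[0])
        return BilinearFit(
            tr_max=float(y.mean()), theta_crit=float(s[0]), slope=0.0,
            r_squared=_r2(sse, sst), n_points=n, sse=sse,
            status="degenerate_plateau",
        )

    p_lo, p_hi = np.percentile(s, [5, 95])
    grid = np.linspace(max(p_lo, np.nextafter(lo_open, hi_closed)),
                       min(p_hi, hi_closed), n_candidates)
    interior = s[(s > lo_open) & (s <= hi_closed)]
    candidates = np.unique(np.concatenate([grid, interior, [hi_closed]]))
    candidates = candidates[(candidates > lo_open) & (candidates <= hi_closed)]

    best = None  # (sse, theta, a, b)
    for theta in candidates:
        a, b, sse = _fixed_theta_fit(s, y, theta)
        if best is None or sse < best[0] - 1e-15 or (
            abs(sse - best[0]) <= 1e-15 and theta > best[1]
        ):
            best = (sse, theta, a, b)

    if refine:
        # exact interior optima of every admissible partition
        for k in range(min_segment, n - min_segment + 1):
            if s[k - 1] == s[k]:
                continue
            for theta, a, b, sse in _partition_candidates(s, y, k) or ():
                if theta <= lo_open or theta > hi_closed:
                    continue
                if sse < best[0] - 1e-15 or (
                    abs(sse - best[0]) <= 1e-15 and theta > best[1]
                ):
                    best = (sse, theta, a, b)

    sse, theta, a, b = best
    status = "ok"
    if b == 0.0:
        # no declining limb resolved: plateau-only degenerate fit
        status = "degenerate_plateau"
        theta = float(s[0])
        a = float(y.mean())
        sse = float(((y - a) ** 2).sum())
    return BilinearFit(
        tr_max=float(a), theta_crit=float(theta), slope=float(b),
        r_squared=_r2(sse, sst), n_points=n, sse=float(sse), status=status,
    )


def _r2(sse: float, sst: float) -> float:
    if sst <= 0:
        return 1.0 if sse <= 1e-300 else 0.0
    return max(0.0, 1.0 - sse / sst)


def terminal_drought_point(
    fit: BilinearFit, swc: Sequence[float] | np.ndarray
) -> BilinearFit:
    """Locate the terminal drought point and return an updated fit.

    The terminal SWC is the minimum observed (drought-phase midday) SWC;
    the terminal rate is the fitted model evaluated there.

    Raises
    ------
    ValueError
        For a degenerate fit or empty input.
    """
    if fit.degenerate:
        raise ValueError(f"cannot derive terminal point from a {fit.status} fit")
    s = np.asarray(swc, dtype=float)
    if s.size == 0:
        raise ValueError("no SWC observations supplied")
    swc_term = float(s.min())
    tr_term = float(predict(fit, swc_term))
    return replace(fit, swc_term=swc_term, tr_term=tr_term)


@dataclass(frozen=True)
class TrapezoidArea:
    """Analytic area and its numeric-quadrature cross-check."""

    analytic: float
    quadrature: float


def trapezoid_area(fit: BilinearFit) -> TrapezoidArea:
    """Water-use index: integral of the declining limb from the terminal SWC
    to theta_crit, (g/min)·(cm³/cm³).

    Computed in closed form, 0.5*(TRmax + TR_term)*(theta_crit - SWC_term),
    and cross-checked by numeric quadrature of the fitted line.

    Raises
    ------
    ValueError
        If the terminal point has not been set or the fit is degenerate.
    """
    if fit.degenerate:
        raise ValueError(f"cannot integrate a {fit.status} fit")
    if fit.swc_term is None or fit.tr_term is None:
        raise ValueError("terminal drought point not set on this fit")
    width = fit.theta_crit - fit.swc_term
    if width < 0:
        raise ValueError("terminal SWC exceeds theta_crit")
    analytic = 0.5 * (fit.tr_max + fit.tr_term) * width
    if width == 0:
        return TrapezoidArea(0.0, 0.0)
    quad, _ = integrate.quad(
        lambda x: fit.tr_max - fit.slope * (fit.theta_crit - x),
        fit.swc_term,
        fit.theta_crit,
    )
    return TrapezoidArea(float(analytic), float(quad))


def slope_from_geometry(
    tr_max: float, theta_crit: float, terminal_point: tuple[float, float]
) -> float:
    """Decline slope implied by the plateau, breakpoint and terminal point.

    (TRmax - TR_term) / (theta_crit - SWC_term); a consistency utility for
    checking that reported parameters describe the same line.
    """
    swc_term, tr_term = terminal_point
    denom = theta_crit - swc_term
    if denom == 0:
        raise ValueError("theta_crit equals terminal SWC: slope undefined")
    return (tr_max - tr_term) / denom


def drought_crossing_times(
    midday: pd.DataFrame,
    fit: BilinearFit,
    drought_start,
    drought_end,
) -> tuple[object, object]:
    """First midday date with SWC below theta_crit, and the terminal day.

    ``midday`` needs columns ``date`` and ``midday_swc``.  Returns
    ``(t_theta, t_term)`` as dates.  Raises ``ValueError`` with status
    "no physiological drought" if SWC never crosses below theta_crit.
    """
    df = midday[(midday["date"] >= drought_start) & (midday["date"] <= drought_end)]
    below = df[df["midday_swc"] < fit.theta_crit]
    if len(below) == 0:
        raise ValueError("no physiological drought: SWC never fell below theta_crit")
    t_theta = below["date"].min()
    t_term = df["date"].max()
    return t_theta, t_term


def cumulative_transpiration_between(
    intervals: pd.DataFrame,
    t_theta,
    t_term,
) -> float:
    """Cumulative transpired mass (g) from the theta_crit crossing day to
    the end of the terminal day.

    ``t_theta`` and ``t_term`` are dates (crossing day and terminal day);
    the sum covers unmasked intervals starting within [t_theta, t_term].

    Raises
    ------
    ValueError
        If t_theta is after t_term.
    """
    if t_theta > t_term:
        raise ValueError("theta_crit crossing must precede the terminal point")
    d = pd.to_datetime(intervals["timestamp"]).dt.date
    sel = (d >= t_theta) & (d <= t_term) & (~intervals["masked"])
    sub = intervals.loc[sel]
    return float((sub["rate_raw"] * sub["dt_min"]).sum())
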