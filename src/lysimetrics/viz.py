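"""Plot of midday transpiration rate versus SWC with fitted bilinear models."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bilinear import predict
from .gravimetric import PlantFlux
from .metrics import PhaseCalendar

__all__ = ["plot_bilinear"]


def plot_bilinear(
    fluxes: Mapping[str, PlantFlux],
    design: pd.DataFrame,
    calendar: PhaseCalendar,
    fits: Mapping[str, Mapping[str, Any]],
    path: str | Path,
) -> Path:
    """One panel per cultivar: drought-phase midday points and the fitted model."""
    d_start, d_end = calendar.span("drought")
    cultivars = sorted(fits)
    fig, axes = plt.subplots(
        1, len(cultivars), figsize=(4 * len(cultivars), 3.5), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, cultivar in zip(axes, cultivars):
        pids = design[
            (design["cultivar"] == cultivar) & (design["treatment"] == "drought")
        ]["plant_id"]
        pts = pd.concat(
            [
                fluxes[p].midday[
                    (fluxes[p].midday["date"] >= d_start)
                    & (fluxes[p].midday["date"] <= d_end)
                ]
                for p in pids
            ]
        ).dropna()
        ax.plot(pts["midday_swc"], pts["midday_tr_g_min"], "o", ms=3, alpha=0.6)
        entry = fits[cultivar]
        fit = entry.get("fit")
        if fit is not None and not fit.degenerate:
            lo = entry.get("swc_term", pts["midday_swc"].min())
            s = np.linspace(lo, pts["midday_swc"].max(), 200)
            ax.plot(s, predict(fit, s), "-", lw=2)
            ax.axvline(fit.theta_crit, ls=":", color="grey")
        ax.set_title(cultivar)
        ax.set_xlabel("volumetric SWC (cm$^3$/cm$^3$)")
        ax.invert_xaxis()
    axes[0].set_ylabel("midday TR (g/min)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
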