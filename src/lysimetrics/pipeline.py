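"""End-to-end pipeline: simulate -> extract -> fit -> metrics -> report.

Each stage reads and writes plain CSV/JSON artifacts with documented
headers, so stages can be rerun or replaced independently; a manifest
(config hash, seed, package version) makes a run reproducible — identical
config and seed give bit-identical outputs.

Artifact layout under ``out_dir``::

    weights/<plant_id>.csv   timestamp, weight_g
    irrigation.csv           timestamp, plant_id, dose_g
    forcing.csv              timestamp, vpd, light_on, temperature
    design.csv               plant_id, cultivar, treatment, <phase>_start, end
    harvest.csv              plant_id, cultivar, treatment, biomass_g, grain_g, ...
    flux.csv                 plant_id, date, daily_tr_g, coverage, valid,
                             midday_tr_g_min, midday_swc, canopy_conductance
    fits.json                per-cultivar bilinear fit + derived quantities
    metrics.csv              one row per plant
    summary.json             per cultivar x treatment group summaries
    report.md                human-readable summary
    manifest.json            config hash, seed, version, artifact list
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from datetime import date as Date, datetime
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .bilinear import (
    BilinearFit,
    cumulative_transpiration_between,
    drought_crossing_times,
    fit_bilinear,
    terminal_drought_point,
    trapezoid_area,
)
from .gravimetric import (
    ExtractionConfig,
    IrrigationLog,
    PlantFlux,
    WeightSeries,
    extract_plant_flux,
    flux_table,
)
from .metrics import (
    PhaseCalendar,
    classify_water_use,
    harvest_index,
    phase_average_dtr,
    recovery_rate,
    relative_transpiration,
    transpiration_yield_correlation,
    water_use_efficiency,
)
from .synthetic import (
    PHASES,
    SimulationConfig,
    SimulatedExperiment,
    simulate_experiment,
    write_experiment,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_experiment_dir"]


class ExtractionSection(BaseModel):
    irrigation_mode: str = "subtract"
    guard_minutes: float = 6.0
    smooth_width: int = 5
    min_coverage: float = 0.8

    def to_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            irrigation_mode=self.irrigation_mode,
            guard_minutes=self.guard_minutes,
            smooth_width=self.smooth_width,
            min_coverage=self.min_coverage,
        )


class FitSection(BaseModel):
    n_candidates: int = 200
    min_points: int = 5
    min_segment: int = 2
    plot: bool = False


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run.

    With ``simulate=True`` (default) the synthetic generator produces the
    raw inputs under ``out_dir``; otherwise ``input_dir`` must point to an
    existing artifact directory with the documented layout.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: bool = True
    input_dir: str | None = None
    simulation: dict[str, Any] = Field(default_factory=dict)
    extraction: ExtractionSection = Field(default_factory=ExtractionSection)
    fit: FitSection = Field(default_factory=FitSection)

    @field_validator("simulation")
    @classmethod
    def _check_simulation(cls, v: dict[str, Any]) -> dict[str, Any]:
        overrides = dict(v)
        if "phase_lengths" in overrides:
            overrides["phase_lengths"] = tuple(overrides["phase_lengths"])
        if "start" in overrides and isinstance(overrides["start"], str):
            overrides["start"] = Date.fromisoformat(overrides["start"])
        SimulationConfig(**overrides)  # raises on invalid values
        return overrides

    def simulation_config(self) -> SimulationConfig:
        overrides = dict(self.simulation)
        overrides.setdefault("rng_seed", self.seed)
        return SimulationConfig(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_experiment_dir(path: str | Path) -> dict[str, Any]:
    """Read raw artifacts (weights/irrigation/forcing/design/harvest) from disk."""
    p = Path(path)
    design = pd.read_csv(p / "design.csv")
    for col in [f"{name}_start" for name in PHASES] + ["end"]:
        design[col] = pd.to_datetime(design[col]).dt.date
    tare = None
    truth_path = p / "ground_truth.json"
    if truth_path.exists():
        tare = json.loads(truth_path.read_text()).get("tare")
    weights = {}
    for f in sorted((p / "weights").glob("*.csv")):
        pid = f.stem
        weights[pid] = WeightSeries(
            plant_id=pid, data=pd.read_csv(f), tare=tare or 0.0
        )
    irrigation = IrrigationLog(pd.read_csv(p / "irrigation.csv"))
    forcing = pd.read_csv(p / "forcing.csv", parse_dates=["timestamp"])
    harvest = pd.read_csv(p / "harvest.csv")
    return {
        "weights": weights,
        "irrigation": irrigation,
        "forcing": forcing,
        "design": design,
        "harvest": harvest,
    }


def calendar_from_design(design: pd.DataFrame) -> PhaseCalendar:
    row = design.iloc[0]
    phases = []
    for i, name in enumerate(PHASES):
        start = row[f"{name}_start"]
        end = (
            row[f"{PHASES[i + 1]}_start"] - pd.Timedelta(days=1)
            if i + 1 < len(PHASES)
            else row["end"]
        )
        if hasattr(end, "date"):
            end = end.date()
        phases.append((name, start, end))
    return PhaseCalendar(tuple(phases))


def fit_cultivars(
    fluxes: Mapping[str, PlantFlux],
    design: pd.DataFrame,
    calendar: PhaseCalendar,
    fit_cfg: FitSection = FitSection(),
) -> dict[str, dict[str, Any]]:
    """Pooled per-cultivar bilinear fits on drought-phase midday points.

    One model per cultivar, fitted to the pooled (midday SWC, midday rate)
    points of its drought-stressed plants from the first to the last day of
    the drought phase; derives the terminal drought point, the trapezoid
    area, and the mean cumulative transpiration between the theta_crit
    crossing and the terminal day.
    """
    d_start, d_end = calendar.span("drought")
    results: dict[str, dict[str, Any]] = {}
    for cultivar, sub in design.groupby("cultivar"):
        pids = sub[sub["treatment"] == "drought"]["plant_id"].tolist()
        pts = []
        for pid in pids:
            m = fluxes[pid].midday
            m = m[(m["date"] >= d_start) & (m["date"] <= d_end)].dropna()
            pts.append(m)
        pooled = pd.concat(pts, ignore_index=True) if pts else pd.DataFrame()
        entry: dict[str, Any] = {"n_plants": len(pids)}
        if len(pooled) < fit_cfg.min_points:
            entry["status"] = "insufficient_points"
            results[str(cultivar)] = entry
            continue
        fit = fit_bilinear(
            pooled["midday_swc"], pooled["midday_tr_g_min"],
            n_candidates=fit_cfg.n_candidates, min_points=fit_cfg.min_points,
            min_segment=fit_cfg.min_segment,
        )
        entry.update(
            tr_max=fit.tr_max, theta_crit=fit.theta_crit, slope=fit.slope,
            r2=fit.r_squared, n=fit.n_points, status=fit.status,
        )
        if not fit.degenerate:
            fit = terminal_drought_point(fit, pooled["midday_swc"])
            area = trapezoid_area(fit)
            entry.update(
                swc_term=fit.swc_term, tr_term=fit.tr_term,
                area=area.analytic, area_quadrature=area.quadrature,
            )
            # cultivar-level crossing dates from the mean midday SWC path
            mean_midday = (
                pooled.groupby("date", as_index=False)["midday_swc"].mean()
            )
            try:
                t_theta, t_term = drought_crossing_times(
                    mean_midday.rename(columns={"midday_swc": "midday_swc"}),
                    fit, d_start, d_end,
                )
                cums = [
                    cumulative_transpiration_between(
                        fluxes[pid].intervals, t_theta, t_term
                    )
                    for pid in pids
                ]
                entry["cum_transpiration_g"] = float(np.mean(cums))
                entry["t_theta"] = str(t_theta)
                entry["t_term"] = str(t_term)
            except ValueError as exc:
                entry["cum_transpiration_status"] = str(exc)
        results[str(cultivar)] = {"fit": fit, **entry}
    return results


def _control_plateau_levels(
    fluxes: Mapping[str, PlantFlux], design: pd.DataFrame, calendar: PhaseCalendar
) -> dict[str, float]:
    """Well-watered transpiration level per cultivar: mean control midday rate
    over the pre-drought phase (the plateau regime by construction)."""
    start, end = calendar.span("pre_drought")
    out = {}
    for cultivar, sub in design.groupby("cultivar"):
        vals = []
        for pid in sub[sub["treatment"] == "control"]["plant_id"]:
            m = fluxes[pid].midday
            m = m[(m["date"] >= start) & (m["date"] <= end)]
            vals.extend(m["midday_tr_g_min"].dropna().tolist())
        out[str(cultivar)] = float(np.mean(vals)) if vals else float("nan")
    return out


def compute_metrics(
    fluxes: Mapping[str, PlantFlux],
    design: pd.DataFrame,
    calendar: PhaseCalendar,
    harvest: pd.DataFrame,
    fits: Mapping[str, Mapping[str, Any]],
) -> pd.DataFrame:
    """Per-plant response metrics table."""
    rec_start, rec_end = calendar.span("recovery")
    harvest_by = harvest.set_index("plant_id")
    fit_objs = {c: e["fit"] for c, e in fits.items() if "fit" in e}
    levels = _control_plateau_levels(fluxes, design, calendar)
    classes = (
        classify_water_use(fit_objs, levels) if len(fit_objs) >= 2 else {}
    )
    rows = []
    for _, plant in design.iterrows():
        pid = plant["plant_id"]
        flux = fluxes[pid]
        row: dict[str, Any] = {
            "plant_id": pid,
            "cultivar": plant["cultivar"],
            "treatment": plant["treatment"],
        }
        for name in PHASES:
            try:
                row[f"dtr_{name}_g_day"] = phase_average_dtr(
                    flux.daily, calendar, name
                )
            except ValueError:
                row[f"dtr_{name}_g_day"] = np.nan
        water_used = float(
            flux.daily.loc[flux.daily["valid"], "daily_tr_g"].sum()
        )
        row["water_used_g"] = water_used
        if plant["treatment"] == "drought":
            controls = [
                fluxes[p].daily
                for p in design[
                    (design["cultivar"] == plant["cultivar"])
                    & (design["treatment"] == "control")
                ]["plant_id"]
            ]
            rtr = relative_transpiration(flux.daily, controls)
            drought_dates = set(calendar.dates("drought"))
            rec_dates = set(calendar.dates("recovery"))
            row["rtr_drought_mean"] = float(
                rtr[rtr["date"].isin(drought_dates)]["rtr"].mean()
            )
            rec_rtr = rtr[rtr["date"].isin(rec_dates)]
            try:
                rec = recovery_rate(rec_rtr)
                row["recovery_rate_per_day"] = rec.slope
            except ValueError:
                row["recovery_rate_per_day"] = np.nan
        else:
            row["rtr_drought_mean"] = np.nan
            row["recovery_rate_per_day"] = np.nan
        if pid in harvest_by.index:
            h = harvest_by.loc[pid]
            row["biomass_g"] = float(h["biomass_g"])
            row["grain_g"] = float(h["grain_g"])
            row["harvest_index"] = harvest_index(h["grain_g"], h["biomass_g"])
            if water_used > 0:
                row["wue_biomass_g_kg"] = water_use_efficiency(
                    h["biomass_g"], water_used
                )
                row["wue_grain_g_kg"] = water_use_efficiency(
                    h["grain_g"], water_used
                )
        row["water_use_class"] = classes.get(plant["cultivar"], "")
        rows.append(row)
    return pd.DataFrame(rows)


def summarise(metrics: pd.DataFrame) -> dict[str, Any]:
    """Group summaries (mean, SE, n) per cultivar x treatment."""
    num_cols = [c for c in metrics.columns if metrics[c].dtype.kind == "f"]
    out: dict[str, Any] = {}
    for (cultivar, treatment), sub in metrics.groupby(["cultivar", "treatment"]):
        key = f"{cultivar}:{treatment}"
        entry = {"n": int(len(sub))}
        for c in num_cols:
            vals = sub[c].dropna()
            if len(vals) == 0:
                continue
            entry[c] = {
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else 0.0,
                "n": int(len(vals)),
            }
        out[key] = entry
    return out


def render_report(
    fits: Mapping[str, Mapping[str, Any]],
    summary: Mapping[str, Any],
    correlations: Mapping[str, tuple[float, float]],
) -> str:
    """Markdown summary of the fitted water-response models and group metrics."""
    lines = ["# Water-relations summary", "", "## Bilinear water-response models", ""]
    lines.append(
        "| cultivar | TRmax (g/min) | theta_crit | slope | terminal (SWC, g/min)"
        " | area | R2 | status |"
    )
    lines.append("|---|---|---|---|---|---|---|---|")
    for cultivar, e in sorted(fits.items()):
        if "tr_max" not in e:
            lines.append(f"| {cultivar} | - | - | - | - | - | - | {e.get('status')} |")
            continue
        term = (
            f"({e.get('swc_term', float('nan')):.3f}, {e.get('tr_term', float('nan')):.3f})"
            if e.get("swc_term") is not None
            else "-"
        )
        lines.append(
            f"| {cultivar} | {e['tr_max']:.3f} | {e['theta_crit']:.3f} | "
            f"{e['slope']:.3f} | {term} | {e.get('area', float('nan')):.4f} | "
            f"{e['r2']:.3f} | {e['status']} |"
        )
    lines += ["", "## Group metrics (mean +/- SE)", ""]
    for key, entry in sorted(summary.items()):
        lines.append(f"### {key} (n={entry['n']})")
        for c, v in entry.items():
            if isinstance(v, dict):
                lines.append(f"- {c}: {v['mean']:.4g} +/- {v['se']:.2g} (n={v['n']})")
        lines.append("")
    lines.append("## Transpiration-yield correlation (Pearson)")
    for group, (r, p) in sorted(correlations.items()):
        lines.append(f"- {group}: r = {r:.3f}, p = {p:.4g}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages and write every artifact plus a manifest.

    Returns the artifact paths.  Stage failures raise with the failing
    stage named; artifacts written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        if config.simulate:
            exp = simulate_experiment(config.simulation_config())
            paths = write_experiment(exp, out)
            artifacts.update(paths)
            raw = {
                "weights": exp.weights,
                "irrigation": exp.irrigation,
                "forcing": exp.forcing,
                "design": exp.design,
                "harvest": exp.harvest,
            }
            sim_cfg = exp.config
        else:
            if not config.input_dir:
                raise ValueError("input_dir required when simulate=False")
            raw = load_experiment_dir(config.input_dir)
            sim_cfg = None

        stage = "extract"
        ext_cfg = config.extraction.to_config()
        pot_volume = (
            sim_cfg.pot_volume if sim_cfg is not None
            else config.simulation_config().pot_volume
        )
        fluxes = {
            pid: extract_plant_flux(
                series, raw["irrigation"], raw["forcing"], pot_volume, ext_cfg
            )
            for pid, series in raw["weights"].items()
        }
        flux_csv = out / "flux.csv"
        flux_table(fluxes.values()).to_csv(flux_csv, index=False)
        artifacts["flux"] = flux_csv

        stage = "fit"
        calendar = calendar_from_design(raw["design"])
        fits = fit_cultivars(fluxes, raw["design"], calendar, config.fit)
        fits_json = {
            c: {k: v for k, v in e.items() if k != "fit"} for c, e in fits.items()
        }
        fits_path = out / "fits.json"
        fits_path.write_text(json.dumps({"schema": 1, "fits": fits_json}, indent=1))
        artifacts["fits"] = fits_path
        if config.fit.plot:
            from .viz import plot_bilinear

            plot_path = out / "bilinear.png"
            plot_bilinear(fluxes, raw["design"], calendar, fits, plot_path)
            artifacts["plot"] = plot_path

        stage = "metrics"
        metrics = compute_metrics(fluxes, raw["design"], calendar, raw["harvest"], fits)
        metrics_csv = out / "metrics.csv"
        metrics.to_csv(metrics_csv, index=False)
        artifacts["metrics"] = metrics_csv
        try:
            corr = transpiration_yield_correlation(
                metrics.dropna(subset=["grain_g"])
                if "grain_g" in metrics
                else metrics
            )
        except (ValueError, KeyError):
            corr = {}
        summary = summarise(metrics)
        summary_path = out / "summary.json"
        summary_path.write_text(
            json.dumps(
                {"schema": 1, "groups": summary, "correlations": corr}, indent=1
            )
        )
        artifacts["summary"] = summary_path

        stage = "report"
        report_path = out / "report.md"
        report_path.write_text(render_report(fits_json, summary, corr))
        artifacts["report"] = report_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "schema": 1,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = manifest_path
    return artifacts
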