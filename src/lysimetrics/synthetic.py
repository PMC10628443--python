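"""Synthetic gravimetric drought experiments with known ground truth.

Emulates a lysimeter-array (load-cell) phenotyping run on potted plants:
3-minute system-weight records over a four-phase protocol

* a well-watered **pre-drought** phase (nightly refill to pot capacity),
* a **drought** phase under feedback deficit irrigation — each plant
  receives a nocturnal dose equal to a fixed fraction (default 80%) of its
  *own* previous-day transpiration, so soil moisture declines gradually,
* a **recovery** phase (well-watered regime resumes),
* a **post-recovery** phase with slightly reduced irrigation.

Plant water demand follows a plateau-then-decline ("bilinear") response to
volumetric soil water content: at high SWC the plant transpires at its
cultivar-specific maximum rate TRmax (scaled by VPD and photoperiod); below
a critical SWC ``theta_crit`` the rate falls linearly with slope ``b``.
Soil evaporation is zero (covered soil), so every gram of system-weight
loss between irrigation events is transpiration.  Drought carry-over during
recovery is modelled as a demand multiplier that starts at the bilinear
reduction factor reached at the end of drought and rises linearly at the
cultivar's ``recovery_rate`` per day — making the configured recovery rate
the true slope of relative transpiration versus time.

Everything the downstream analysis estimates (daily transpiration, SWC,
theta_crit, recovery rate, ...) is emitted as ground truth, so the whole
pipeline is testable end to end without any instrument data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as Date, datetime, time as Time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gravimetric import IrrigationLog, WeightSeries

__all__ = [
    "CultivarProfile",
    "SimulationConfig",
    "SimulatedExperiment",
    "DEFAULT_PROFILES",
    "generate_forcing",
    "plant_transpiration_demand",
    "simulate_experiment",
    "write_experiment",
]

PHASES = ("pre_drought", "drought", "recovery", "post_recovery")


@dataclass(frozen=True)
class CultivarProfile:
    """Ground-truth water-use parameters of one cultivar.

    Parameters
    ----------
    tr_max:
        Midday plateau transpiration rate under non-limiting soil water,
        g/min.
    theta_crit:
        Volumetric SWC (cm^3/cm^3) below which transpiration declines.
    decline_slope:
        Decline of transpiration rate per unit SWC below theta_crit,
        (g/min)/(cm^3/cm^3).
    recovery_rate:
        True slope of relative transpiration vs time during re-irrigation,
        per day.
    biomass_potential:
        Above-ground dry biomass under well-watered conditions, g.
    harvest_index:
        Grain mass / total above-ground biomass, fraction.
    """

    name: str
    tr_max: float
    theta_crit: float
    decline_slope: float
    recovery_rate: float = 0.04
    biomass_potential: float = 120.0
    harvest_index: float = 0.35

    def __post_init__(self) -> None:
        if self.tr_max <= 0:
            raise ValueError("tr_max must be positive")
        if not 0 < self.theta_crit < 1:
            raise ValueError("theta_crit must be in (0, 1)")
        if self.decline_slope < 0:
            raise ValueError("decline_slope must be non-negative")
        if not 0 <= self.harvest_index <= 1:
            raise ValueError("harvest_index must be in [0, 1]")


#: Four contrasting cereal water-use types used as defaults: a
#: high-transpiring cultivar with a steep post-threshold decline, a
#: low-transpiring conserver with a shallow decline, and two in between.
DEFAULT_PROFILES: tuple[CultivarProfile, ...] = (
    CultivarProfile("CHAN", tr_max=0.68, theta_crit=0.557, decline_slope=2.56,
                    recovery_rate=0.035, biomass_potential=161.36, harvest_index=0.341),
    CultivarProfile("RGT", tr_max=0.57, theta_crit=0.579, decline_slope=1.71,
                    recovery_rate=0.040, biomass_potential=151.43, harvest_index=0.338),
    CultivarProfile("FORM", tr_max=0.50, theta_crit=0.476, decline_slope=1.87,
                    recovery_rate=0.041, biomass_potential=101.02, harvest_index=0.274),
    CultivarProfile("BAR", tr_max=0.47, theta_crit=0.544, decline_slope=1.17,
                    recovery_rate=0.036, biomass_potential=99.91, harvest_index=0.382),
)

#: Thousand-kernel weights (g) used when synthesising harvest tables.
_DEFAULT_TKW = {"CHAN": 50.7, "RGT": 49.33, "FORM": 53.6, "BAR": 45.6}


@dataclass(frozen=True)
class SimulationConfig:
    """Design and physics of the synthetic experiment.

    Defaults describe a realistic greenhouse protocol: 4 control + 5 drought
    replicates per cultivar, phases of 7/12/10/10 days, 3-L pots at 70%
    volumetric pot capacity, deficit irrigation at 80% of the previous
    day's transpiration, photoperiod 05:30-18:00, VPD averaging 1.7 kPa
    within 0.8-2.4 kPa, and 0.5 g Gaussian noise per weight record.
    """

    n_control: int = 4
    n_drought: int = 5
    phase_lengths: tuple[int, int, int, int] = (7, 12, 10, 10)
    start: Date = Date(2023, 1, 27)
    step_min: int = 3
    pot_capacity: float = 0.70
    soil_mass: float = 1250.0
    pot_volume: float = 3000.0
    deficit_fraction: float = 0.80
    postrecovery_fraction: float = 0.90
    noise_sd: float = 0.5
    rng_seed: int = 0
    tare: float = 500.0
    wilting_swc: float = 0.05
    night_fraction: float = 0.05
    light_start: Time = Time(5, 30)
    light_end: Time = Time(18, 0)
    vpd_mean: float = 1.7
    vpd_amplitude: float = 0.7
    vpd_noise_sd: float = 0.0
    vpd_min: float = 0.8
    vpd_max: float = 2.4
    vpd_peak_hour: float = 16.0
    temp_day: float = 23.0
    temp_night: float = 18.0
    irrigation_hour: float = 2.0
    pulse_size: float = 100.0
    drought_biomass_penalty: float = 0.5
    harvest_noise_frac: float = 0.03

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.phase_lengths):
            raise ValueError("phase lengths must be >= 1 day")
        if not 0 < self.deficit_fraction <= 1:
            raise ValueError("deficit_fraction must be in (0, 1]")
        if min(self.pot_volume, self.soil_mass, self.tare) <= 0:
            raise ValueError("masses and volumes must be positive")
        if not 0 < self.pot_capacity <= 1:
            raise ValueError("pot_capacity must be in (0, 1]")
        if self.n_control < 1 or self.n_drought < 1:
            raise ValueError("need at least one plant per treatment")
        if self.noise_sd < 0 or self.pulse_size <= 0:
            raise ValueError("noise_sd must be >= 0 and pulse_size > 0")
        if 1440 % self.step_min != 0:
            raise ValueError("step_min must divide 1440")

    @property
    def total_days(self) -> int:
        return sum(self.phase_lengths)

    @property
    def steps_per_day(self) -> int:
        return 1440 // self.step_min

    def phase_start_days(self) -> dict[str, int]:
        """Day index (0-based) on which each phase starts."""
        starts, acc = {}, 0
        for name, length in zip(PHASES, self.phase_lengths):
            starts[name] = acc
            acc += length
        return starts

    def phase_dates(self) -> dict[str, tuple[Date, Date]]:
        """First and last calendar date of each phase."""
        out = {}
        for name, d0 in self.phase_start_days().items():
            length = self.phase_lengths[PHASES.index(name)]
            out[name] = (
                self.start + timedelta(days=d0),
                self.start + timedelta(days=d0 + length - 1),
            )
        return out


def generate_forcing(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Atmospheric forcing on the 3-min grid: timestamp, vpd, light_on, temperature.

    VPD follows a sinusoid peaking mid-afternoon with the configured daily
    mean and amplitude, plus optional Gaussian noise, clipped to the
    configured physical bounds.  Reproducible for a given ``rng_seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_steps = config.total_days * config.steps_per_day + 1
    t0 = datetime.combine(config.start, Time(0, 0))
    ts = pd.date_range(t0, periods=n_steps, freq=f"{config.step_min}min")
    hours = ts.hour + ts.minute / 60.0
    vpd = config.vpd_mean + config.vpd_amplitude * np.cos(
        2 * np.pi * (hours - config.vpd_peak_hour) / 24.0
    )
    if config.vpd_noise_sd > 0:
        vpd = vpd + rng.normal(0.0, config.vpd_noise_sd, size=n_steps)
    vpd = np.clip(vpd, config.vpd_min, config.vpd_max)
    tod = ts.time
    light = np.array([(config.light_start <= t < config.light_end) for t in tod])
    t_mid = (config.temp_day + config.temp_night) / 2.0
    t_amp = (config.temp_day - config.temp_night) / 2.0
    temp = t_mid + t_amp * np.cos(2 * np.pi * (hours - config.vpd_peak_hour) / 24.0)
    return pd.DataFrame(
        {"timestamp": ts, "vpd": vpd, "light_on": light, "temperature": temp}
    )


def plant_transpiration_demand(
    profile: CultivarProfile,
    swc,
    vpd,
    light_on,
    vpd_mean: float = 1.7,
    night_fraction: float = 0.05,
    multiplier: float = 1.0,
):
    """Instantaneous transpiration demand, g/min (scalar or elementwise).

    Bilinear in SWC: ``tr_max`` at or above ``theta_crit``, declining
    linearly below it (floored at zero).  Scaled by a linear VPD response
    normalised so that f(vpd_mean) = 1, gated by the photoperiod with a
    small nocturnal fraction, and by an optional stress multiplier.

    Raises
    ------
    ValueError
        If any SWC value lies outside [0, 1].
    """
    swc_arr = np.asarray(swc, dtype=float)
    if np.any((swc_arr < 0) | (swc_arr > 1)):
        raise ValueError("swc must be within [0, 1]")
    base = np.where(
        swc_arr >= profile.theta_crit,
        profile.tr_max,
        np.maximum(
            0.0,
            profile.tr_max
            - profile.decline_slope * (profile.theta_crit - swc_arr),
        ),
    )
    f_vpd = np.asarray(vpd, dtype=float) / vpd_mean
    gate = np.where(np.asarray(light_on, dtype=bool), 1.0, night_fraction)
    out = base * f_vpd * gate * multiplier
    if np.isscalar(swc) and np.isscalar(vpd):
        return float(out)
    return out


def _bilinear_factor(profile: CultivarProfile, swc: float) -> float:
    """Fraction of TRmax available at a given SWC (the stress carry-over seed)."""
    if swc >= profile.theta_crit:
        return 1.0
    return max(
        0.0,
        (profile.tr_max - profile.decline_slope * (profile.theta_crit - swc))
        / profile.tr_max,
    )


@dataclass
class GroundTruth:
    """Everything the simulator knows that an instrument would not tell you."""

    profiles: dict[str, CultivarProfile]
    daily_transpiration: pd.DataFrame  # plant_id, date, transpiration_g
    daily_irrigation: pd.DataFrame  # plant_id, date, irrigation_g
    end_of_drought_factor: dict[str, float]  # per drought plant
    tare: float
    config: SimulationConfig

    def daily_for(self, plant_id: str) -> pd.DataFrame:
        df = self.daily_transpiration
        return df[df["plant_id"] == plant_id].reset_index(drop=True)


@dataclass
class SimulatedExperiment:
    """Bundle of everything a real run would produce, plus ground truth."""

    weights: dict[str, WeightSeries]
    irrigation: IrrigationLog
    forcing: pd.DataFrame
    design: pd.DataFrame
    harvest: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    @property
    def plant_ids(self) -> list[str]:
        return list(self.weights)


def _validate_capacity(
    config: SimulationConfig, profiles: Sequence[CultivarProfile], env: np.ndarray
) -> None:
    """Refuse profiles whose unstressed daily demand cannot be refilled."""
    spd = config.steps_per_day
    full_days = env[: config.total_days * spd].reshape(config.total_days, spd)
    max_env = float(full_days.sum(axis=1).max()) * config.step_min
    available = (config.pot_capacity - config.wilting_swc) * config.pot_volume
    for p in profiles:
        if p.tr_max * max_env > available:
            raise ValueError(
                f"profile {p.name}: daily demand {p.tr_max * max_env:.0f} g exceeds "
                f"refillable water {available:.0f} g at pot capacity"
            )


def simulate_experiment(
    config: SimulationConfig = SimulationConfig(),
    profiles: Sequence[CultivarProfile] = DEFAULT_PROFILES,
) -> SimulatedExperiment:
    """Simulate a complete multi-cultivar deficit-irrigation experiment.

    Per 3-min step each plant transpires its bilinear demand (capped by the
    water available above the wilting floor); nightly irrigation delivers
    discrete pulses — a refill to pot capacity for control plants, a dose
    of ``deficit_fraction`` x the previous day's true transpiration for
    drought plants during the drought phase.  Weight records carry i.i.d.
    Gaussian noise; the internal water balance is exact.

    Returns a :class:`SimulatedExperiment`; all randomness comes from one
    generator seeded with ``config.rng_seed``.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one cultivar profile")
    rng = np.random.default_rng(config.rng_seed)
    forcing = generate_forcing(config, rng)
    n_steps = len(forcing)
    spd = config.steps_per_day
    dt = float(config.step_min)

    f_vpd = forcing["vpd"].to_numpy() / config.vpd_mean
    gate = np.where(forcing["light_on"].to_numpy(), 1.0, config.night_fraction)
    env = f_vpd * gate  # demand multiplier per step (x tr_max x g(swc) x mult)
    _validate_capacity(config, profiles, env)

    # plant roster: per cultivar, n_control controls then n_drought drought
    plant_ids, cultivar_of, is_drought = [], [], []
    for p in profiles:
        for i in range(config.n_control):
            plant_ids.append(f"{p.name}-C{i + 1}")
            cultivar_of.append(p.name)
            is_drought.append(False)
        for i in range(config.n_drought):
            plant_ids.append(f"{p.name}-D{i + 1}")
            cultivar_of.append(p.name)
            is_drought.append(True)
    n_plants = len(plant_ids)
    prof_by_name = {p.name: p for p in profiles}
    tr_max = np.array([prof_by_name[c].tr_max for c in cultivar_of])
    theta = np.array([prof_by_name[c].theta_crit for c in cultivar_of])
    slope = np.array([prof_by_name[c].decline_slope for c in cultivar_of])
    rec_rate = np.array([prof_by_name[c].recovery_rate for c in cultivar_of])
    drought_mask = np.array(is_drought)

    starts = config.phase_start_days()
    drought_d0 = starts["drought"]
    recovery_d0 = starts["recovery"]
    post_d0 = starts["post_recovery"]
    cap_w = config.pot_capacity * config.pot_volume
    floor_w = config.wilting_swc * config.pot_volume
    irr_step = int(round(config.irrigation_hour * 60 / config.step_min))

    w = np.full(n_plants, cap_w)
    mult = np.ones(n_plants)
    m0 = np.full(n_plants, np.nan)
    remaining = np.zeros(n_plants)
    truth_tr = np.zeros((config.total_days, n_plants))
    truth_irr = np.zeros((config.total_days, n_plants))
    weights_rec = np.empty((n_steps, n_plants))
    ev_step: list[int] = []
    ev_plant: list[int] = []
    ev_dose: list[float] = []

    for t in range(n_steps):
        weights_rec[t] = config.tare + w
        if t == n_steps - 1:
            break
        day, step_in_day = divmod(t, spd)

        if step_in_day == 0:
            # stress carry-over: seeded at the first recovery morning,
            # then rising linearly at the cultivar recovery rate
            if day == recovery_d0:
                for i in np.where(drought_mask)[0]:
                    m0[i] = _bilinear_factor(
                        prof_by_name[cultivar_of[i]], w[i] / config.pot_volume
                    )
            if day >= recovery_d0:
                r = day - recovery_d0  # recovery day index, 0-based
                mult = np.where(
                    drought_mask, np.minimum(1.0, m0 + rec_rate * r), 1.0
                )

        if step_in_day == irr_step:
            # nocturnal irrigation: dose decided once per night per regime
            refill = np.maximum(0.0, cap_w - w)
            if day < drought_d0 or (recovery_d0 <= day < post_d0) or day == 0:
                dose = refill
            elif day >= post_d0:
                dose = config.postrecovery_fraction * refill
            else:  # drought phase: feedback deficit irrigation
                dose = np.where(
                    drought_mask,
                    config.deficit_fraction * truth_tr[day - 1],
                    refill,
                )
            remaining = dose.copy()

        if remaining.any():
            pulse = np.minimum(remaining, config.pulse_size)
            for i in np.where(pulse > 0)[0]:
                ev_step.append(t)
                ev_plant.append(i)
                ev_dose.append(pulse[i])
            w = w + pulse
            truth_irr[day] += pulse
            remaining = remaining - pulse

        swc = w / config.pot_volume
        base = np.where(
            swc >= theta, tr_max, np.maximum(0.0, tr_max - slope * (theta - swc))
        )
        demand = base * env[t] * mult * dt
        transp = np.minimum(demand, np.maximum(0.0, w - floor_w))
        w = w - transp
        truth_tr[day] += transp

    if config.noise_sd > 0:
        weights_rec = weights_rec + rng.normal(
            0.0, config.noise_sd, size=weights_rec.shape
        )

    ts = forcing["timestamp"]
    weights = {
        pid: WeightSeries(
            plant_id=pid,
            data=pd.DataFrame({"timestamp": ts, "weight_g": weights_rec[:, i]}),
            tare=config.tare,
        )
        for i, pid in enumerate(plant_ids)
    }
    irrigation = IrrigationLog(
        pd.DataFrame(
            {
                "timestamp": ts.iloc[ev_step].to_numpy(),
                "plant_id": [plant_ids[i] for i in ev_plant],
                "dose_g": ev_dose,
            }
        )
    )

    dates = [config.start + timedelta(days=d) for d in range(config.total_days)]
    truth_daily = pd.DataFrame(
        {
            "plant_id": np.repeat(plant_ids, config.total_days),
            "date": dates * n_plants,
            "transpiration_g": truth_tr.T.ravel(),
        }
    )
    truth_irr_df = pd.DataFrame(
        {
            "plant_id": np.repeat(plant_ids, config.total_days),
            "date": dates * n_plants,
            "irrigation_g": truth_irr.T.ravel(),
        }
    )

    phase_dates = config.phase_dates()
    design = pd.DataFrame(
        {
            "plant_id": plant_ids,
            "cultivar": cultivar_of,
            "treatment": np.where(drought_mask, "drought", "control"),
            **{
                f"{name}_start": [phase_dates[name][0]] * n_plants
                for name in PHASES
            },
            "end": [phase_dates["post_recovery"][1]] * n_plants,
        }
    )

    harvest = _synthesise_harvest(
        config, prof_by_name, plant_ids, cultivar_of, drought_mask, truth_tr, rng
    )

    truth = GroundTruth(
        profiles=prof_by_name,
        daily_transpiration=truth_daily,
        daily_irrigation=truth_irr_df,
        end_of_drought_factor={
            plant_ids[i]: float(m0[i]) for i in np.where(drought_mask)[0]
        },
        tare=config.tare,
        config=config,
    )
    return SimulatedExperiment(
        weights=weights,
        irrigation=irrigation,
        forcing=forcing,
        design=design,
        harvest=harvest,
        truth=truth,
        config=config,
    )


def _synthesise_harvest(
    config, prof_by_name, plant_ids, cultivar_of, drought_mask, truth_tr, rng
) -> pd.DataFrame:
    # biomass reduced in proportion to the cumulative transpiration deficit
    # relative to the cultivar's control mean; grain = HI x biomass.  This
    # exercises WUE/HI plumbing, it is not a crop model.
    total_tr = truth_tr.sum(axis=0)
    rows = []
    for cultivar in dict.fromkeys(cultivar_of):
        idx = [i for i, c in enumerate(cultivar_of) if c == cultivar]
        ctrl = [i for i in idx if not drought_mask[i]]
        ref = total_tr[ctrl].mean()
        prof = prof_by_name[cultivar]
        for i in idx:
            deficit = max(0.0, 1.0 - total_tr[i] / ref)
            noise = 1.0 + rng.normal(0.0, config.harvest_noise_frac)
            biomass = prof.biomass_potential * (
                1.0 - config.drought_biomass_penalty * deficit
            ) * max(noise, 0.5)
            grain = min(prof.harvest_index * biomass, biomass)
            tkw = _DEFAULT_TKW.get(cultivar, 48.0)
            spikes = int(round(12 + biomass / 8.0))
            seeds = grain / (tkw / 1000.0) / spikes
            rows.append(
                {
                    "plant_id": plant_ids[i],
                    "cultivar": cultivar,
                    "treatment": "drought" if drought_mask[i] else "control",
                    "biomass_g": biomass,
                    "grain_g": grain,
                    "tkw_g": tkw,
                    "seeds_per_spike": seeds,
                    "spikes_per_pot": spikes,
                    "water_used_g": total_tr[i],
                }
            )
    return pd.DataFrame(rows)


def write_experiment(exp: SimulatedExperiment, out_dir: str | Path) -> dict[str, Path]:
    """Write the experiment to the documented CSV/JSON layout.

    weights/<plant_id>.csv (timestamp, weight_g), irrigation.csv,
    forcing.csv, design.csv, harvest.csv, ground_truth.json.
    """
    out = Path(out_dir)
    (out / "weights").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for pid, series in exp.weights.items():
        p = out / "weights" / f"{pid}.csv"
        series.data.to_csv(p, index=False)
    paths["weights"] = out / "weights"
    for name, df in [
        ("irrigation", exp.irrigation.data),
        ("forcing", exp.forcing),
        ("design", exp.design),
        ("harvest", exp.harvest),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    truth = {
        "tare": exp.truth.tare,
        "profiles": {k: asdict(v) for k, v in exp.truth.profiles.items()},
        "end_of_drought_factor": exp.truth.end_of_drought_factor,
        "daily_transpiration": [
            {**r, "date": str(r["date"])}
            for r in exp.truth.daily_transpiration.to_dict("records")
        ],
        "config": {
            k: (str(v) if isinstance(v, (Date, Time)) else v)
            for k, v in asdict(exp.config).items()
        },
    }
    p = out / "ground_truth.json"
    p.write_text(json.dumps(truth, indent=1))
    paths["ground_truth"] = p
    return paths
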