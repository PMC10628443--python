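import numpy as np
import pandas as pd
import pytest

import lysimetrics as lm
from lysimetrics.pipeline import calendar_from_design


@pytest.fixture(scope="session")
def noiseless_exp():
    """Default full-length experiment with zero measurement noise."""
    cfg = lm.SimulationConfig(noise_sd=0.0, rng_seed=7)
    return lm.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_fluxes(noiseless_exp):
    cfg = noiseless_exp.config
    return {
        pid: lm.extract_plant_flux(
            ws, noiseless_exp.irrigation, noiseless_exp.forcing, cfg.pot_volume
        )
        for pid, ws in noiseless_exp.weights.items()
    }


@pytest.fixture(scope="session")
def noiseless_calendar(noiseless_exp):
    return calendar_from_design(noiseless_exp.design)


@pytest.fixture()
def small_config():
    """Short two-cultivar run for smoke tests."""
    return lm.SimulationConfig(
        n_control=2,
        n_drought=2,
        phase_lengths=(3, 6, 4, 2),
        noise_sd=0.5,
        rng_seed=11,
    )


@pytest.fixture()
def small_profiles():
    return (
        lm.CultivarProfile("A", tr_max=0.6, theta_crit=0.50, decline_slope=2.0,
                           recovery_rate=0.04, biomass_potential=150.0,
                           harvest_index=0.34),
        lm.CultivarProfile("B", tr_max=0.45, theta_crit=0.45, decline_slope=1.2,
                           recovery_rate=0.035, biomass_potential=100.0,
                           harvest_index=0.38),
    )


def make_weight_series(rates_g_min, step_min=3, start="2023-01-27 00:00",
                       w0=2000.0, plant_id="P1", tare=500.0):
    """Build a weight trace whose interval decrements realise given rates."""
    rates = np.asarray(rates_g_min, dtype=float)
    ts = pd.date_range(start, periods=len(rates) + 1, freq=f"{step_min}min")
    w = w0 - np.concatenate([[0.0], np.cumsum(rates * step_min)])
    return lm.WeightSeries(
        plant_id=plant_id,
        data=pd.DataFrame({"timestamp": ts, "weight_g": w}),
        tare=tare,
    )
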