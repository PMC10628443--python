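"""Extraction unit tests on hand-constructed weight traces."""

from datetime import date as Date, time as Time

import numpy as np
import pandas as pd
import pytest

import lysimetrics as lm
from lysimetrics.gravimetric import (
    canopy_conductance,
    daily_transpiration,
    interval_transpiration,
    midday_rate,
    midday_swc,
    volumetric_swc,
)

from conftest import make_weight_series

DAY = Date(2023, 1, 27)
N_DAY = 480  # 3-min intervals in 24 h


def one_day_series(rate=0.5, **kw):
    return make_weight_series([rate] * N_DAY, **kw)


def log_for(series, ts, dose):
    return lm.IrrigationLog(
        pd.DataFrame(
            {"timestamp": [ts], "plant_id": [series.plant_id], "dose_g": [dose]}
        )
    )


class TestIntervalTranspiration:
    def test_constant_decline(self):
        iv = interval_transpiration(one_day_series(0.5))
        np.testing.assert_allclose(iv["rate_raw"], 0.5, atol=1e-12)
        np.testing.assert_allclose(iv["rate"].dropna(), 0.5, atol=1e-12)
        assert not iv["masked"].any()

    def test_constant_weight_zero_rate(self):
        iv = interval_transpiration(one_day_series(0.0))
        np.testing.assert_allclose(iv["rate_raw"], 0.0, atol=1e-12)

    def test_subtract_mode_inverts_dose(self):
        ws = one_day_series(0.5)
        k = 40
        ws.data.loc[k + 1:, "weight_g"] += 100.0  # dose lands inside interval k
        ev_ts = ws.data["timestamp"].iloc[k] + pd.Timedelta(minutes=1)
        iv = interval_transpiration(ws, log_for(ws, ev_ts, 100.0))
        np.testing.assert_allclose(iv["rate_raw"], 0.5, atol=1e-9)

    def test_mask_mode_guard_locality(self):
        ws = one_day_series(0.5)
        k = 40
        ws.data.loc[k + 1:, "weight_g"] += 100.0
        ev_ts = ws.data["timestamp"].iloc[k] + pd.Timedelta(minutes=1)
        cfg = lm.ExtractionConfig(irrigation_mode="mask", guard_minutes=6.0)
        iv = interval_transpiration(ws, log_for(ws, ev_ts, 100.0), cfg)
        masked_idx = set(iv.index[iv["masked"]])
        assert k in masked_idx
        # only intervals overlapping the +-6 min guard are affected
        assert masked_idx <= set(range(k - 3, k + 4))
        far = iv.drop(index=list(range(k - 3, k + 4)))
        np.testing.assert_allclose(far["rate_raw"], 0.5, atol=1e-12)

    def test_mask_mode_masks_weight_gain(self):
        rates = [0.5] * 20
        rates[10] = -2.0  # unlogged weight gain
        iv = interval_transpiration(
            make_weight_series(rates),
            config=lm.ExtractionConfig(irrigation_mode="mask", smooth_width=1),
        )
        assert bool(iv["masked"].iloc[10])

    def test_event_outside_span_raises(self):
        ws = one_day_series(0.5)
        before = ws.data["timestamp"].iloc[0] - pd.Timedelta(hours=1)
        with pytest.raises(ValueError, match="outside"):
            interval_transpiration(ws, log_for(ws, before, 50.0))

    def test_clipping_only_in_cleaned_rate(self):
        rates = [0.5, -0.4, 0.5, -0.4, 0.5, 0.5, 0.5]
        iv = interval_transpiration(
            make_weight_series(rates), config=lm.ExtractionConfig(smooth_width=1)
        )
        assert (iv["rate_raw"] < 0).any()
        assert (iv["rate"].dropna() >= 0).all()

    def test_single_record_raises(self):
        ws = lm.WeightSeries(
            "P1",
            pd.DataFrame({"timestamp": [pd.Timestamp("2023-01-27")], "weight_g": [2000.0]}),
        )
        with pytest.raises(ValueError, match="two records"):
            interval_transpiration(ws)

    def test_nonmonotonic_timestamps_rejected(self):
        ts = pd.to_datetime(["2023-01-27 00:00", "2023-01-27 00:03", "2023-01-27 00:03"])
        with pytest.raises(ValueError, match="increasing"):
            lm.WeightSeries("P1", pd.DataFrame({"timestamp": ts, "weight_g": [3.0, 2.0, 1.0]}))


class TestDailyTranspiration:
    def test_full_day_sum(self):
        iv = interval_transpiration(one_day_series(0.5))
        daily = daily_transpiration(iv)
        assert len(daily) == 1
        assert daily["daily_tr_g"].iloc[0] == pytest.approx(720.0, abs=1e-9)
        assert daily["coverage"].iloc[0] == pytest.approx(1.0)
        assert bool(daily["valid"].iloc[0])

    def test_gap_day_flagged_invalid(self):
        ws = one_day_series(0.5)
        ws = lm.WeightSeries(
            ws.plant_id,
            ws.data.drop(index=range(100, 300)).reset_index(drop=True),
            ws.tare,
        )
        iv = interval_transpiration(ws)
        assert iv["masked"].any()  # the long bridging interval is a gap
        daily = daily_transpiration(iv)
        assert not bool(daily["valid"].iloc[0])
        assert daily["coverage"].iloc[0] < 0.8

    def test_conservation_with_noise_and_dose(self):
        """sum(rate_raw * dt) telescopes to total loss + dose, exactly."""
        rng = np.random.default_rng(5)
        rates = rng.normal(0.3, 0.4, size=N_DAY)  # includes negative intervals
        ws = make_weight_series(rates)
        k = 123
        ws.data.loc[k + 1:, "weight_g"] += 80.0
        ev_ts = ws.data["timestamp"].iloc[k] + pd.Timedelta(minutes=1)
        iv = interval_transpiration(ws, log_for(ws, ev_ts, 80.0))
        total = float((iv["rate_raw"] * iv["dt_min"]).sum())
        w = ws.weights
        assert total == pytest.approx(w[0] - w[-1] + 80.0, abs=1e-9)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        rates=st.lists(
            st.floats(-1.0, 1.0, allow_nan=False, width=32), min_size=5, max_size=60
        ),
        dose=st.floats(1.0, 500.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(rates, dose):
        ws = make_weight_series(rates)
        k = len(rates) // 2
        ws.data.loc[k + 1:, "weight_g"] += dose
        ev_ts = ws.data["timestamp"].iloc[k] + pd.Timedelta(minutes=1)
        iv = interval_transpiration(ws, log_for(ws, ev_ts, dose))
        total = float((iv["rate_raw"] * iv["dt_min"]).sum())
        w = ws.weights
        assert total == pytest.approx(w[0] - w[-1] + dose, abs=1e-6)
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestSWC:
    def test_known_value(self):
        ws = one_day_series(0.0, w0=2600.0, tare=500.0)
        swc = volumetric_swc(ws, pot_volume=3000.0)
        np.testing.assert_allclose(swc["swc"], 0.70, atol=1e-12)

    def test_tare_shift_invariance(self):
        rates = [0.5] * 50
        a = volumetric_swc(make_weight_series(rates, w0=2000.0, tare=500.0), 3000.0)
        b = volumetric_swc(make_weight_series(rates, w0=2250.0, tare=750.0), 3000.0)
        np.testing.assert_allclose(a["swc"], b["swc"], atol=1e-12)

    def test_below_tare_raises(self):
        ws = one_day_series(0.0, w0=400.0, tare=500.0)
        with pytest.raises(ValueError, match="below tare"):
            volumetric_swc(ws, 3000.0)

    def test_clipped_to_unit_interval(self):
        ws = one_day_series(0.0, w0=5000.0, tare=500.0)
        swc = volumetric_swc(ws, 3000.0)
        assert (swc["swc"] <= 1.0).all()


def _flat_forcing(ws, vpd):
    ts = ws.data["timestamp"]
    tod = pd.to_datetime(ts).dt.time
    light = (tod >= Time(5, 30)) & (tod < Time(18, 0))
    return pd.DataFrame({"timestamp": ts, "vpd": vpd, "light_on": light})


class TestConductanceAndMidday:
    def test_conductance_ratio(self):
        ws = one_day_series(0.3)
        iv = interval_transpiration(ws)
        gc = canopy_conductance(iv, _flat_forcing(ws, 1.5), DAY)
        assert gc == pytest.approx(0.3 / 1.5, abs=1e-9)

    def test_conductance_scales_inversely_with_vpd(self):
        ws = one_day_series(0.3)
        iv = interval_transpiration(ws)
        g1 = canopy_conductance(iv, _flat_forcing(ws, 1.0), DAY)
        g2 = canopy_conductance(iv, _flat_forcing(ws, 2.0), DAY)
        assert g1 == pytest.approx(2 * g2, abs=1e-9)

    def test_midday_rate_constant(self):
        iv = interval_transpiration(one_day_series(0.42))
        assert midday_rate(iv, DAY) == pytest.approx(0.42, abs=1e-9)

    def test_midday_rate_nan_outside_data(self):
        iv = interval_transpiration(one_day_series(0.42))
        assert np.isnan(midday_rate(iv, Date(2024, 1, 1)))

    def test_midday_swc_mean(self):
        ws = one_day_series(0.0, w0=2600.0, tare=500.0)
        swc = volumetric_swc(ws, 3000.0)
        assert midday_swc(swc, DAY) == pytest.approx(0.70, abs=1e-12)


class TestExtractPlantFlux:
    def test_matches_per_date_functions(self, noiseless_exp, noiseless_fluxes):
        """The vectorised extraction equals the per-date reference functions."""
        pid = noiseless_exp.plant_ids[0]
        flux = noiseless_fluxes[pid]
        for i in [2, 10, 20]:
            row = flux.midday.iloc[i]
            d = row["date"]
            assert row["midday_tr_g_min"] == pytest.approx(
                midday_rate(flux.intervals, d), nan_ok=True
            )
            assert row["midday_swc"] == pytest.approx(
                midday_swc(flux.swc, d), nan_ok=True
            )
            gc_ref = canopy_conductance(flux.intervals, noiseless_exp.forcing, d)
            gc = float(
                flux.conductance.loc[flux.conductance["date"] == d,
                                     "canopy_conductance"].iloc[0]
            )
            assert gc == pytest.approx(gc_ref, nan_ok=True)

    def test_conductance_ordering_matches_profiles(
        self, noiseless_exp, noiseless_fluxes, noiseless_calendar
    ):
        """Well-watered conductance orders cultivars by their TRmax."""
        start, end = noiseless_calendar.span("pre_drought")
        means = {}
        for cultivar in ["CHAN", "RGT", "FORM", "BAR"]:
            vals = []
            for pid, flux in noiseless_fluxes.items():
                if not pid.startswith(cultivar):
                    continue
                c = flux.conductance
                sel = c[(c["date"] >= start) & (c["date"] <= end)]
                vals.extend(sel["canopy_conductance"].dropna().tolist())
            means[cultivar] = np.mean(vals)
        assert means["CHAN"] > means["RGT"] > means["FORM"] > means["BAR"]
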