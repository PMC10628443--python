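"""Response-metric tests: rTR, recovery, dTR, WUE, HI, correlation, classes."""

import warnings
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
import pytest

from lysimetrics.bilinear import BilinearFit
from lysimetrics.metrics import (
    PhaseCalendar,
    classify_water_use,
    harvest_index,
    phase_average_dtr,
    recovery_rate,
    relative_transpiration,
    transpiration_yield_correlation,
    water_use_efficiency,
)

D0 = Date(2023, 1, 27)


def daily_frame(values, start=D0, valid=None):
    n = len(values)
    return pd.DataFrame(
        {
            "date": [start + timedelta(days=i) for i in range(n)],
            "daily_tr_g": values,
            "coverage": 1.0,
            "valid": [True] * n if valid is None else valid,
        }
    )


class TestPhaseCalendar:
    def test_from_lengths_round_trip(self):
        cal = PhaseCalendar.from_lengths(
            D0, {"pre_drought": 7, "drought": 12, "recovery": 10, "post_recovery": 10}
        )
        assert cal.span("pre_drought") == (D0, D0 + timedelta(days=6))
        assert cal.span("drought")[0] == D0 + timedelta(days=7)
        assert cal.phase_of(D0 + timedelta(days=8)) == "drought"
        assert cal.phase_of(D0 + timedelta(days=100)) is None
        assert len(cal.dates("recovery")) == 10

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            PhaseCalendar(
                (
                    ("pre_drought", D0, D0 + timedelta(days=6)),
                    ("drought", D0 + timedelta(days=9), D0 + timedelta(days=20)),
                )
            )

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError, match="end before start"):
            PhaseCalendar((("pre_drought", D0, D0 - timedelta(days=1)),))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            PhaseCalendar.from_lengths(D0, {"pre_drought": 7, "drought": 0})


class TestRelativeTranspiration:
    def test_identity_when_equal(self):
        d = daily_frame([400.0, 420.0, 410.0])
        out = relative_transpiration(d, [d.copy(), d.copy()])
        np.testing.assert_allclose(out["rtr"], 1.0, atol=1e-12)

    def test_known_ratio(self):
        # 290 / 500 = 0.58
        out = relative_transpiration(
            daily_frame([290.0]), [daily_frame([450.0]), daily_frame([550.0])]
        )
        assert out["rtr"].iloc[0] == pytest.approx(0.58, abs=1e-12)

    def test_invalid_days_excluded(self):
        d = daily_frame([400.0, 999.0, 410.0], valid=[True, False, True])
        out = relative_transpiration(d, [daily_frame([400.0, 400.0, 400.0])])
        assert len(out) == 2
        assert D0 + timedelta(days=1) not in set(out["date"])

    def test_zero_control_flagged(self):
        out = relative_transpiration(daily_frame([100.0]), [daily_frame([0.0])])
        assert bool(out["zero_control"].iloc[0])
        assert np.isnan(out["rtr"].iloc[0])

    def test_no_controls_raises(self):
        with pytest.raises(ValueError, match="control"):
            relative_transpiration(daily_frame([100.0]), [])


class TestRecoveryRate:
    def test_known_slope(self):
        fit = recovery_rate([0.50, 0.54, 0.58, 0.62])
        assert fit.slope == pytest.approx(0.04, abs=1e-12)
        assert fit.n == 4

    def test_constant_series_zero_slope(self):
        assert recovery_rate([0.7, 0.7, 0.7, 0.7]).slope == pytest.approx(0.0)

    def test_dataframe_input_uses_dates(self):
        df = pd.DataFrame(
            {
                "date": [D0 + timedelta(days=i) for i in range(4)],
                "rtr": [0.50, 0.54, 0.58, 0.62],
            }
        )
        assert recovery_rate(df).slope == pytest.approx(0.04, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            recovery_rate([0.5, 0.6])

    def test_nan_values_dropped(self):
        fit = recovery_rate([0.50, np.nan, 0.58, 0.62])
        assert fit.n == 3
        assert fit.slope == pytest.approx(0.04, abs=1e-12)


class TestPhaseAverage:
    def _cal(self):
        return PhaseCalendar.from_lengths(D0, {"drought": 4})

    def test_average_over_valid_days_only(self):
        daily = daily_frame(
            [100.0, 200.0, 999.0, 300.0], valid=[True, True, False, True]
        )
        out = phase_average_dtr(daily, self._cal(), "drought")
        assert out == pytest.approx(200.0, abs=1e-12)

    def test_no_valid_days_raises(self):
        daily = daily_frame([1.0, 2.0, 3.0, 4.0], valid=[False] * 4)
        with pytest.raises(ValueError, match="no valid days"):
            phase_average_dtr(daily, self._cal(), "drought")


class TestWUEAndHI:
    def test_wue_per_kg_scale(self):
        # 51.15 g grain over 23.144 kg water -> 2.21 g/kg
        assert water_use_efficiency(51.15, 23144.0) == pytest.approx(2.21, abs=0.01)

    def test_wue_halved_water_doubles(self):
        assert water_use_efficiency(10.0, 5000.0) == pytest.approx(
            2 * water_use_efficiency(10.0, 10000.0)
        )

    def test_wue_zero_water_raises(self):
        with pytest.raises(ValueError, match="positive"):
            water_use_efficiency(10.0, 0.0)

    def test_wue_negative_harvest_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            water_use_efficiency(-1.0, 1000.0)

    def test_harvest_index_value(self):
        assert harvest_index(33.8, 100.0) == pytest.approx(0.338)

    def test_harvest_index_bounds(self):
        assert harvest_index(0.0, 50.0) == 0.0
        assert harvest_index(50.0, 50.0) == 1.0
        with pytest.raises(ValueError):
            harvest_index(60.0, 50.0)
        with pytest.raises(ValueError):
            harvest_index(10.0, 0.0)


class TestCorrelation:
    def _table(self, x, y, group="drought"):
        return pd.DataFrame(
            {"water_used_g": x, "grain_g": y, "treatment": [group] * len(x)}
        )

    def test_perfect_positive(self):
        out = transpiration_yield_correlation(self._table([1, 2, 3, 4], [2, 4, 6, 8]))
        r, p = out["drought"]
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        out = transpiration_yield_correlation(self._table([1, 2, 3, 4], [8, 6, 4, 2]))
        assert out["drought"][0] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        x = np.array([10.0, 14.0, 11.0, 19.0, 16.0, 13.0, 21.0, 12.0, 18.0])
        y = np.array([3.0, 5.5, 4.1, 7.9, 6.2, 4.8, 8.5, 4.4, 7.1])
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = float((xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym)))
        out = transpiration_yield_correlation(self._table(x, y))
        assert out["drought"][0] == pytest.approx(r_hand, abs=1e-12)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            transpiration_yield_correlation(self._table([1, 2], [3, 4]))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            transpiration_yield_correlation(self._table([1, 1, 1], [3, 4, 5]))


def _fit(slope):
    return BilinearFit(
        tr_max=0.5, theta_crit=0.5, slope=slope, r_squared=1.0, n_points=10
    )


class TestClassification:
    LEVELS = {"CHAN": 0.68, "RGT": 0.57, "FORM": 0.50, "BAR": 0.47}
    SLOPES = {"CHAN": 2.56, "RGT": 1.71, "FORM": 1.87, "BAR": 1.17}

    def _fits(self, scale=1.0):
        return {n: _fit(s) for n, s in self.SLOPES.items()}, {
            n: v * scale for n, v in self.LEVELS.items()
        }

    def test_expected_labels(self):
        fits, levels = self._fits()
        out = classify_water_use(fits, levels)
        assert out["CHAN"] == "non_conserving"
        assert out["BAR"] == "conserving"
        assert out["RGT"] == "dynamic"
        assert out["FORM"] == "intermediate"

    def test_joint_rescale_invariance(self):
        fits, levels = self._fits(scale=2.0)
        assert classify_water_use(fits, levels) == classify_water_use(
            *self._fits()
        )

    def test_single_cultivar_warns_intermediate(self):
        with pytest.warns(UserWarning, match="relative"):
            out = classify_water_use({"CHAN": _fit(2.56)}, {"CHAN": 0.68})
        assert out == {"CHAN": "intermediate"}

    def test_explicit_thresholds(self):
        fits, levels = self._fits()
        out = classify_water_use(
            fits, levels, tr_max_threshold=0.4, slope_threshold=1.0
        )
        assert set(out.values()) == {"non_conserving"}
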