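import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pestmap.fate import (
    AiParams,
    CellEnvironment,
    degradation_factor,
    monthly_loss_grid,
    runoff_loss_percent,
    slope_interception_buffer_factor,
    soil_water_coefficient,
)


def _ai(koc=1000.0, dt50=10.0):
    return AiParams("x", "0-0", "insecticide", koc=koc, dt50_soil_days=dt50)


def brute_force_loss(q, p, f, dt50, koc, soc):
    """Independent term-by-term evaluation of the loss expression."""
    if p == 0:
        return 0.0
    kd = koc * soc / 100.0
    decay = math.exp(-3.0 * math.log(2.0) / dt50)
    return (q / p) * f * decay * 100.0 / (1.0 + kd)


class TestSoilWaterCoefficient:
    @pytest.mark.parametrize("koc,soc,expected", [
        (1000.0, 2.0, 20.0),
        (500.0, 0.0, 0.0),
        (0.0, 5.0, 0.0),
    ])
    def test_kd_relation(self, koc, soc, expected):
        assert soil_water_coefficient(koc, soc) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            soil_water_coefficient(-1.0, 2.0)


class TestDegradationFactor:
    def test_half_life_equal_to_lag_gives_half(self):
        assert degradation_factor(3.0) == pytest.approx(0.5, abs=1e-15)

    def test_persistent_compound_limit(self):
        assert degradation_factor(1e9) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_dt50_10(self):
        expected = math.exp(-3.0 * math.log(2.0) / 10.0)  # 0.812252...
        assert degradation_factor(10.0) == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.812252, abs=1e-6)

    def test_nonpositive_dt50_rejected(self):
        with pytest.raises(ValueError):
            degradation_factor(0.0)


class TestSlopeFactor:
    def test_saturates_at_one(self):
        # s >= ~20% saturates f_slope at 1
        f = slope_interception_buffer_factor(math.degrees(math.atan(0.25)))
        assert f == pytest.approx(1.0)

    def test_full_interception_zeroes_f(self):
        assert slope_interception_buffer_factor(45.0, interception_frac=1.0) == 0.0

    def test_polynomial_at_10_percent_slope(self):
        slope_deg = math.degrees(math.atan(0.10))
        expected = (0.001423 * 100.0 + 0.02153 * 10.0) * 0.8
        got = slope_interception_buffer_factor(slope_deg, interception_frac=0.2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            slope_interception_buffer_factor(10.0, buffer_frac=1.5)


class TestRunoffLoss:
    def test_no_runoff_no_loss(self):
        env = CellEnvironment(q_mm=0.0, p_mm=50.0, f_override=1.0)
        assert runoff_loss_percent(env, _ai()) == 0.0

    def test_analytic_anchor_25(self):
        # q=p, f=1, dt50=3 (decay 1/2), kd=1 -> 1 * 1 * 0.5 * 50 = 25
        env = CellEnvironment(q_mm=10.0, p_mm=10.0, soc_percent=0.1,
                              f_override=1.0)
        ai = _ai(koc=1000.0, dt50=3.0)  # kd = 1000*0.1/100 = 1
        assert runoff_loss_percent(env, ai) == pytest.approx(25.0, abs=1e-12)

    def test_worked_example(self):
        env = CellEnvironment(q_mm=30.0, p_mm=100.0, soc_percent=2.0,
                              f_override=0.5)
        got = runoff_loss_percent(env, _ai(koc=1000.0, dt50=10.0))
        assert got == pytest.approx(brute_force_loss(30, 100, 0.5, 10, 1000, 2),
                                    abs=1e-12)
        assert got == pytest.approx(0.580180, abs=1e-6)

    def test_dry_month_is_zero(self):
        env = CellEnvironment(q_mm=0.0, p_mm=0.0, f_override=1.0)
        assert runoff_loss_percent(env, _ai()) == 0.0

    def test_inconsistent_hydrology_rejected(self):
        env = CellEnvironment(q_mm=5.0, p_mm=0.0, f_override=1.0)
        with pytest.raises(ValueError):
            runoff_loss_percent(env, _ai())

    def test_nan_input_rejected(self):
        env = CellEnvironment(q_mm=float("nan"), p_mm=10.0, f_override=1.0)
        with pytest.raises(ValueError):
            runoff_loss_percent(env, _ai())

    @settings(deadline=None, max_examples=200)
    @given(q_frac=st.floats(0.0, 1.0), p=st.floats(0.1, 1000.0),
           f=st.floats(0.0, 1.0), dt50=st.floats(0.5, 1000.0),
           koc=st.floats(0.0, 1e5), soc=st.floats(0.0, 8.0))
    def test_matches_bruteforce_and_bounded(self, q_frac, p, f, dt50, koc, soc):
        q = q_frac * p
        env = CellEnvironment(q_mm=q, p_mm=p, soc_percent=soc, f_override=f)
        got = runoff_loss_percent(env, _ai(koc=koc, dt50=dt50))
        assert got == pytest.approx(brute_force_loss(q, p, f, dt50, koc, soc),
                                    abs=1e-12)
        assert 0.0 <= got <= 100.0

    def test_koc_doubling_scale_property(self):
        env = CellEnvironment(q_mm=20.0, p_mm=40.0, soc_percent=3.0,
                              f_override=0.7)
        kd = soil_water_coefficient(500.0, 3.0)
        l1 = runoff_loss_percent(env, _ai(koc=500.0))
        l2 = runoff_loss_percent(env, _ai(koc=1000.0))
        assert l2 == pytest.approx(l1 * (1 + kd) / (1 + 2 * kd), rel=1e-12)

    def test_monotonicity(self):
        env = CellEnvironment(q_mm=20.0, p_mm=40.0, soc_percent=2.0,
                              f_override=0.5)
        # non-increasing in koc, non-decreasing in dt50
        losses_koc = [runoff_loss_percent(env, _ai(koc=k)) for k in
                      (0, 10, 100, 1000, 1e4)]
        assert all(a >= b for a, b in zip(losses_koc, losses_koc[1:]))
        losses_dt = [runoff_loss_percent(env, _ai(dt50=d)) for d in
                     (1, 3, 10, 100, 1000)]
        assert all(a <= b for a, b in zip(losses_dt, losses_dt[1:]))


class TestMonthlyLossGrid:
    def test_uniform_environment_gives_uniform_grid(self, small_grid):
        loss = monthly_loss_grid(small_grid, _ai(), 0)
        assert np.allclose(loss, loss.flat[0])

    def test_grid_matches_scalar_oracle_everywhere(self, small_grid):
        rng = np.random.default_rng(3)
        q = rng.uniform(0, 30, size=(4, 4))
        small_grid.add_layer("runoff_mm[0]", q)
        ai = _ai()
        loss = monthly_loss_grid(small_grid, ai, 0)
        for r in range(4):
            for c in range(4):
                env = CellEnvironment(
                    q_mm=q[r, c], p_mm=100.0,
                    slope_deg=small_grid.layer("slope_deg")[r, c],
                    soc_percent=2.0)
                assert loss[r, c] == pytest.approx(
                    runoff_loss_percent(env, ai), abs=1e-12)

    def test_zero_runoff_cell_is_zero(self, small_grid):
        q = np.full((4, 4), 30.0)
        q[1, 2] = 0.0
        small_grid.add_layer("runoff_mm[0]", q)
        loss = monthly_loss_grid(small_grid, _ai(), 0)
        assert loss[1, 2] == 0.0
        assert loss[0, 0] > 0.0

    def test_month_out_of_range(self, small_grid):
        with pytest.raises(IndexError):
            monthly_loss_grid(small_grid, _ai(), 5)

    def test_nodata_propagates(self, small_grid):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        small_grid.masks["soc_percent"] = mask
        loss = monthly_loss_grid(small_grid, _ai(), 0)
        assert np.isnan(loss[0, 0]) and not np.isnan(loss[1, 1])
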