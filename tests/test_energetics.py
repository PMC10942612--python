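"""Aerobic performance metrics: scaling, quantile resting rate, U_crit, fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import swimlab as sl
from swimlab.simulate import truth_argmin

from conftest import make_mo2_series

masses = st.floats(min_value=1e-3, max_value=10.0)


class TestAllometricScale:
    def test_identity_for_equal_masses(self):
        assert sl.allometric_scale(250.0, 0.002, 0.002) == 250.0

    def test_halving_mass_factor(self):
        # m_measured = 2*m_target with b=0.7546 -> factor 2**0.2454.
        out = sl.allometric_scale(100.0, 0.004, 0.002)
        assert out == pytest.approx(100.0 * 2.0 ** 0.2454, rel=1e-9)

    def test_isometric_limit_is_identity(self):
        params = sl.AllometryParams(b=1.0)
        assert sl.allometric_scale(321.0, 0.009, 0.001, params) == pytest.approx(321.0)

    @settings(derandomize=True, max_examples=50)
    @given(m_a=masses, m_b=masses, m_c=masses)
    def test_composition(self, m_a, m_b, m_c):
        one = sl.allometric_scale(200.0, m_a, m_c)
        two = sl.allometric_scale(sl.allometric_scale(200.0, m_a, m_b), m_b, m_c)
        assert two == pytest.approx(one, rel=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            sl.allometric_scale(200.0, 0.0, 0.002)


class TestRestingAndAggregate:
    def test_interpolated_quantile_convention(self):
        series = make_mo2_series(np.linspace(11, 12, 5), [1, 2, 3, 4, 5])
        assert sl.mo2_rest(series, quiet_windows_h=[(10, 18)], min_samples=5) == \
            pytest.approx(1.8)

    def test_constant_series(self):
        series = make_mo2_series(np.linspace(10, 18, 20), np.full(20, 267.9))
        assert sl.mo2_rest(series) == pytest.approx(267.9)

    def test_quantile_is_robust_to_one_outlier(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(200.0, 5.0, size=50)
        base = sl.mo2_rest(make_mo2_series(np.linspace(10, 18, 50), vals))
        vals2 = np.append(vals[:-1], 5000.0)
        spiked = sl.mo2_rest(make_mo2_series(np.linspace(10, 18, 50), vals2))
        mean_shift = abs(np.mean(vals2) - np.mean(vals))
        assert abs(spiked - base) < mean_shift

    def test_aggregate_mean_and_empty_window_error(self):
        series = make_mo2_series([11.0, 15.0], [300.0, 357.0])
        assert sl.mo2_aggregate(series) == pytest.approx(328.5)
        with pytest.raises(ValueError, match="window"):
            sl.mo2_aggregate(series, window_h=(40.0, 45.0))


class TestSummary:
    def _series_from_speed_means(self, mapping):
        rows = []
        for i, (u, v) in enumerate(mapping.items()):
            rows.append((float(10 + i), "swim", u, v))
        t_rest = np.linspace(11, 17, 12)
        df = make_mo2_series(t_rest, np.full(12, 250.0), phase="rest")
        swim = pd.DataFrame(rows, columns=["t_h", "phase", "speed_bls", "mo2"])
        swim_df = make_mo2_series(
            swim["t_h"].to_numpy() + 10, swim["mo2"].to_numpy(), phase="swim"
        )
        swim_df["speed_bls"] = swim["speed_bls"].to_numpy()
        return pd.concat([df, swim_df], ignore_index=True)

    def test_min_max_bookkeeping(self):
        series = self._series_from_speed_means(
            {0.3: 280.0, 1.0: 213.0, 3.0: 280.0, 8.0: 1050.0}
        )
        plan = sl.SpeedStepPlan(speeds=(0.3, 1.0, 3.0, 8.0))
        summary = sl.summarize_energetics(series, plan, u_crit=8.0)
        assert summary.mo2_min == 213.0
        assert summary.u_opt == 1.0
        assert summary.mo2_active == 1050.0
        assert summary.aerobic_scope == 837.0

    def test_monotone_curve_puts_uopt_at_lowest_speed(self):
        series = self._series_from_speed_means({0.3: 100.0, 1.0: 200.0, 3.0: 300.0})
        plan = sl.SpeedStepPlan(speeds=(0.3, 1.0, 3.0))
        summary = sl.summarize_energetics(series, plan, u_crit=3.0)
        assert summary.u_opt == 0.3

    def test_fewer_than_three_speeds_rejected(self):
        series = self._series_from_speed_means({0.3: 100.0, 1.0: 200.0})
        with pytest.raises(ValueError, match="3 speed"):
            sl.summarize_energetics(series, sl.SpeedStepPlan(speeds=(0.3, 1.0)),
                                    u_crit=1.0)


class TestPercentScope:
    summary = sl.EnergeticsSummary(
        mo2_rest=180.0, mo2_aggregate=300.0, mo2_min=200.0, u_opt=1.3,
        mo2_active=1000.0, aerobic_scope=800.0, u_crit=8.0,
    )

    def test_endpoints(self):
        assert sl.percent_scope(200.0, self.summary) == 0.0
        assert sl.percent_scope(1000.0, self.summary) == 100.0

    def test_school_value_at_four_bls(self):
        # (472-200)/(1000-200)*100 = 34 %
        assert sl.percent_scope(472.0, self.summary) == pytest.approx(34.0)

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(min_value=-100, max_value=100))
    def test_affine_invariance(self, shift):
        shifted = sl.EnergeticsSummary(
            mo2_rest=180.0 + shift, mo2_aggregate=300.0 + shift,
            mo2_min=200.0 + shift, u_opt=1.3, mo2_active=1000.0 + shift,
            aerobic_scope=800.0, u_crit=8.0,
        )
        assert sl.percent_scope(472.0 + shift, shifted) == pytest.approx(
            sl.percent_scope(472.0, self.summary), rel=1e-9
        )


class TestUcrit:
    plan = sl.SpeedStepPlan()

    def test_completes_all_steps(self):
        assert sl.compute_ucrit(self.plan, len(self.plan.speeds) - 1) == 8.0

    def test_brett_interpolation(self):
        # Completes 6.9, fatigues 300 s into the 8.0 step.
        idx = self.plan.speeds.index(6.9)
        assert sl.compute_ucrit(self.plan, idx, 300.0) == pytest.approx(7.45)

    def test_immediate_failure_boundary(self):
        idx = self.plan.speeds.index(6.9)
        assert sl.compute_ucrit(self.plan, idx, 0.0) == 6.9

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            sl.compute_ucrit(self.plan, 99)


class TestCurveFit:
    def test_quadratic_recovered_exactly(self):
        u = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = 3.0 * u**2 - 4.0 * u + 250.0
        fit = sl.fit_mo2_speed_curve(np.column_stack([u, y]), degree=2)
        assert fit.coefficients == pytest.approx((3.0, -4.0, 250.0), rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_minimum_close_to_bruteforce_truth(self):
        params = sl.TruthCurveParams()
        plan = sl.SpeedStepPlan()
        u = np.array(plan.speeds)
        fit = sl.fit_mo2_speed_curve(
            np.column_stack([u, sl.mo2_truth(params, u)]), degree=3
        )
        u_min, _ = fit.minimum(u.min(), u.max())
        assert abs(u_min - truth_argmin(params)) < 0.25

    def test_too_few_points_rejected(self):
        pts = [(0.5, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0)]
        with pytest.raises(ValueError, match="5"):
            sl.fit_mo2_speed_curve(pts)


def test_percent_reduction():
    assert sl.percent_reduction(328.5, 212.9) == pytest.approx(35.19, abs=0.01)
    with pytest.raises(ValueError):
        sl.percent_reduction(0.0, 1.0)
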