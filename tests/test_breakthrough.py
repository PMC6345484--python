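"""Breakthrough arithmetic, cumulative sorption quadrature, lifetime scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbmt.breakthrough import (
    BreakthroughTest,
    areal_saturation,
    breakthrough_time,
    cumulative_sorption,
    integral_capacity,
    lifetime_days,
    lifetime_from_tests,
    sorption_capacity,
)
from sbmt.simulate import ColumnSimParams, simulate_breakthrough


def column(series, threshold=0.005, rho_s=122.0, q_s=0.006, m=1.0):
    return BreakthroughTest(rho_s=rho_s, q_s=q_s, m=m, series=tuple(series), threshold=threshold)


class TestBreakthroughTime:
    def test_linear_interpolation_midpoint(self):
        t = column([(100.0, 0.004), (110.0, 0.006)])
        assert breakthrough_time(t) == pytest.approx(105.0)

    def test_immediate_breakthrough(self):
        t = column([(2.0, 0.01), (4.0, 0.02)])
        assert breakthrough_time(t) == 2.0

    def test_never_broken_through_is_a_signal_not_an_error(self):
        t = column([(10.0, 0.001), (20.0, 0.002)])
        assert breakthrough_time(t) is None

    def test_logistic_crossing_matches_analytic_inverse(self):
        s, t50 = 0.2, 300.0
        times = np.arange(0.0, 400.0, 2.0) + 1.0
        series = [(float(t), 1.0 / (1.0 + math.exp(-s * (t - t50)))) for t in times]
        analytic = t50 - math.log(1.0 / 0.005 - 1.0) / s
        assert breakthrough_time(column(series)) == pytest.approx(analytic, abs=0.1)


class TestSorptionCapacity:
    def test_direct_substitution(self):
        t = column([(999.0, 0.004), (1001.0, 0.006)], rho_s=122.0, q_s=0.006, m=1.0)
        w = sorption_capacity(t, t_b=1000.0)
        assert w == pytest.approx(122.0 * 0.006 * 1000.0, rel=1e-12)
        assert sorption_capacity(t, t_b=1000.0, milligrams=True) == pytest.approx(w / 1000.0)

    def test_zero_breakthrough_time(self):
        t = column([(1.0, 0.01)])
        assert sorption_capacity(t, t_b=0.0) == 0.0

    def test_unbroken_column_raises(self):
        t = column([(10.0, 0.001)])
        with pytest.raises(ValueError, match="did not break through"):
            sorption_capacity(t)


class TestArealSaturation:
    def test_zero_capacity(self):
        assert areal_saturation(0.0, 5000.0) == 0.0

    def test_unit_surface_density(self):
        assert areal_saturation(123.4, 1.0) == 123.4

    def test_board_geometry_cross_check(self):
        # 9-mm board, bulk density 700 kg/m³ → 6.3 kg/m² = 6300 g/m²
        rho_A = 0.009 * 700 * 1000
        assert areal_saturation(100.0, rho_A) == pytest.approx(100.0 * 6300.0)


class TestCumulativeSorption:
    @pytest.mark.parametrize(
        "partition", [[24.0], [8.0, 16.0, 24.0], [2.0, 4.0, 11.0, 24.0]]
    )
    def test_partition_invariance_for_constant_flux(self, partition):
        series = [(100.0, t) for t in partition]
        assert cumulative_sorption(series) == pytest.approx(2400.0)

    def test_single_interval(self):
        assert cumulative_sorption([(148.6, 24.0)]) == pytest.approx(3566.4)

    def test_rectangle_within_quadrature_bound_of_trapezoid(self):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(1.0, 72.0, size=12))
        fluxes = rng.uniform(20.0, 160.0, size=12)
        series = list(zip(fluxes, times))
        rect = cumulative_sorption(series)
        trap = cumulative_sorption(series, rule="trapezoid")
        bound = np.max(np.abs(np.diff(np.concatenate([[fluxes[0]], fluxes])))) * times[-1] / 2
        assert abs(rect - trap) <= bound

    def test_unordered_series_rejected(self):
        with pytest.raises(ValueError):
            cumulative_sorption([(100.0, 24.0), (90.0, 12.0)])

    def test_additive_over_concatenation(self):
        a = [(120.0, 10.0), (80.0, 20.0)]
        b = [(60.0, 30.0)]
        whole = cumulative_sorption(a + b)
        # second block's first interval starts at the first block's end
        assert whole == pytest.approx(cumulative_sorption(a) + 60.0 * 10.0)


class TestLifetime:
    def test_self_consumption_in_one_window(self):
        assert lifetime_days(1000.0, 1000.0, 24.0) == pytest.approx(1.0)

    def test_linear_scaling(self):
        assert lifetime_days(2000.0, 1000.0, 24.0) == pytest.approx(2.0)

    def test_zero_consumption_signals_infinite_lifetime(self):
        assert math.isinf(lifetime_days(1000.0, 0.0, 24.0))

    @settings(deadline=None)
    @given(
        k=st.floats(min_value=0.01, max_value=100.0),
        rho=st.floats(min_value=1.0, max_value=1e6),
        dt=st.floats(min_value=1.0, max_value=1000.0),
    )
    def test_homogeneous_in_areal_saturation(self, k, rho, dt):
        base = lifetime_days(rho, 500.0, dt)
        assert lifetime_days(k * rho, 500.0, dt) == pytest.approx(k * base, rel=1e-9)


class TestCapacityOracle:
    def test_threshold_capacity_approaches_integral_as_threshold_grows(self):
        params = ColumnSimParams(capacity=1500.0, sharpness=0.05, seed=0)
        sim = simulate_breakthrough(params)
        oracle = integral_capacity(sim)
        caps = []
        for theta in (0.005, 0.05, 0.5):
            t = sim.model_copy(update={"threshold": theta})
            caps.append(sorption_capacity(t))
        assert caps == sorted(caps)  # monotone in threshold
        assert caps[-1] / oracle > 0.99

    def test_simulated_capacity_recovered_within_five_percent(self):
        params = ColumnSimParams(capacity=1500.0, sharpness=0.05, seed=0)
        sim = simulate_breakthrough(params)
        w = sorption_capacity(sim)
        assert w == pytest.approx(1500.0, rel=0.05)
        assert integral_capacity(sim) == pytest.approx(1500.0, rel=0.01)


def test_pipeline_assembles_consistent_estimate():
    params = ColumnSimParams(capacity=800.0, sharpness=1.0, m=5.0, n_points=2000)
    sim = simulate_breakthrough(params)
    est = lifetime_from_tests(sim, rho_A=6300.0, metrics_series=[(80.0, 24.0), (80.0, 48.0), (80.0, 72.0)])
    assert est.rho_Aa == pytest.approx(est.w_s * 6300.0)
    assert est.rho_Ac == pytest.approx(80.0 * 72.0)
    assert est.t_lt == pytest.approx(est.rho_Aa / est.rho_Ac * 72.0 / 24.0)
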