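"""Dwelling steady state, risk kernel linearity, calibration, Monte Carlo."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from sbmt.reporting import fitted_unit_risks
from sbmt.risk import (
    UNIT_RISK_FEMALE,
    UNIT_RISK_MALE,
    ExposureProfile,
    RoomScenario,
    default_profiles,
    fit_unit_risk,
    inhalation_risk,
    monte_carlo_risk,
    risk_reduction,
    steady_state_concentration,
)


def scenario(er: float) -> RoomScenario:
    return RoomScenario(emission_rate=er)


class TestSteadyStateConcentration:
    @pytest.mark.parametrize("er, expected", [(0.04, 53.3), (0.004, 5.3), (0.0, 0.0)])
    def test_model_dwelling(self, er, expected):
        assert round(steady_state_concentration(scenario(er)), 1) == expected

    def test_linear_in_emission_rate(self):
        assert steady_state_concentration(scenario(0.02)) == pytest.approx(
            2 * steady_state_concentration(scenario(0.01))
        )

    def test_wall_application_uses_wall_area(self):
        s = RoomScenario(emission_rate=0.01, application_surface="wall")
        assert steady_state_concentration(s) == pytest.approx(
            steady_state_concentration(scenario(0.01)) * 45.0 / 14.0
        )


class TestInhalationRisk:
    def test_male_risk_at_paint_condition(self):
        p = default_profiles()["male"]
        assert inhalation_risk(22.7, p).risk == pytest.approx(54.8e-6, rel=0.01)

    def test_zero_concentration(self):
        p = default_profiles()["female"]
        r = inhalation_risk(0.0, p)
        assert r.risk == 0.0 and r.cdi == 0.0

    def test_risk_is_cdi_times_potency(self):
        p = default_profiles()["male"]
        r = inhalation_risk(100.0, p)
        assert r.risk == pytest.approx(r.cdi * p.potency_factor, rel=1e-12)

    @settings(deadline=None)
    @given(
        c=st.floats(min_value=0.0, max_value=500.0),
        a=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_linearity(self, c, a):
        p = default_profiles()["male"]
        assert inhalation_risk(a * c, p).risk == pytest.approx(
            a * inhalation_risk(c, p).risk, rel=1e-9, abs=1e-18
        )


class TestRiskReduction:
    def test_headline_reduction(self):
        profs = default_profiles()
        assert risk_reduction(245.0, 8.0, profs["male"]) == pytest.approx(5.73e-4, rel=0.01)
        assert risk_reduction(245.0, 8.0, profs["female"]) == pytest.approx(4.84e-4, rel=0.01)

    def test_no_reduction_when_equal(self):
        assert risk_reduction(50.0, 50.0, default_profiles()["male"]) == 0.0

    def test_equals_difference_of_risks(self):
        p = default_profiles()["female"]
        lhs = risk_reduction(245.0, 8.0, p)
        rhs = inhalation_risk(245.0, p).risk - inhalation_risk(8.0, p).risk
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_ratio_identity_on_dwelling_table(self, dwelling_table):
        p = default_profiles()["male"]
        for r in dwelling_table.itertuples():
            c_s = steady_state_concentration(scenario(r.er_mg_m2_h))
            red = risk_reduction(r.c_in_te_ugm3, c_s, p)
            risk = inhalation_risk(c_s, p).risk
            assert red / risk == pytest.approx((r.c_in_te_ugm3 - c_s) / c_s, rel=1e-9)


class TestCalibration:
    def test_fitted_slopes_match_frozen_unit_risks(self):
        fitted = fitted_unit_risks()
        assert fitted["male"] == pytest.approx(UNIT_RISK_MALE, rel=1e-4)
        assert fitted["female"] == pytest.approx(UNIT_RISK_FEMALE, rel=1e-4)

    def test_default_profiles_realise_unit_risks(self):
        profs = default_profiles()
        assert profs["male"].unit_risk == pytest.approx(UNIT_RISK_MALE, rel=1e-9)
        assert profs["female"].unit_risk == pytest.approx(UNIT_RISK_FEMALE, rel=1e-9)

    def test_calibrated_solver_is_exact_for_arbitrary_targets(self):
        p = ExposureProfile.calibrated("x", 3.3e-6, body_weight=60.0, exposure_duration=30.0)
        assert p.unit_risk == pytest.approx(3.3e-6, rel=1e-12)

    def test_male_risk_cells_round_to_printed_values(self, dwelling_table):
        p = default_profiles()["male"]
        for r in dwelling_table.itertuples():
            c_s = steady_state_concentration(scenario(r.er_mg_m2_h))
            risk_e6 = inhalation_risk(c_s, p).risk * 1e6
            assert round(risk_e6, 1) == pytest.approx(r.risk_male_e6)

    def test_fit_rejects_mismatched_vectors(self):
        with pytest.raises(ValueError):
            fit_unit_risk([1.0, 2.0], [1.0])


class TestMonteCarlo:
    def test_point_masses_equal_deterministic_risk_exactly(self):
        s = scenario(0.006)
        p = default_profiles()["male"]
        point = {name: getattr(p, name) for name in
                 ("inhalation_rate", "exposure_time", "body_weight")}
        out = monte_carlo_risk(s, p, point, n=1000, seed=3)
        det = inhalation_risk(steady_state_concentration(s), p).risk
        assert out.mean == det
        assert out.sd == 0.0

    def test_seed_determinism(self):
        s = scenario(0.02)
        p = default_profiles()["female"]
        dist = {"inhalation_rate": scipy.stats.lognorm(s=0.3, scale=p.inhalation_rate)}
        a = monte_carlo_risk(s, p, dist, n=2000, seed=42)
        b = monte_carlo_risk(s, p, dist, n=2000, seed=42)
        assert a == b
        c = monte_carlo_risk(s, p, dist, n=2000, seed=43)
        assert c.mean != a.mean

    def test_linear_in_ir_matches_analytic_moments(self):
        s = scenario(0.02)
        p = default_profiles()["male"]
        mu, sigma = p.inhalation_rate, 0.1 * p.inhalation_rate
        n = 20000
        out = monte_carlo_risk(s, p, {"inhalation_rate": scipy.stats.norm(mu, sigma)}, n=n, seed=11)
        det = inhalation_risk(steady_state_concentration(s), p).risk
        slope = det / mu  # risk is linear in IR
        se_mean = slope * sigma / np.sqrt(n)
        assert abs(out.mean - det) < 3 * se_mean
        assert out.sd == pytest.approx(slope * sigma, rel=0.05)

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown exposure factor"):
            monte_carlo_risk(scenario(0.01), default_profiles()["male"], {"shoe_size": 42.0}, n=10, seed=0)

    def test_unsupported_distribution_rejected(self):
        with pytest.raises(ValueError, match="frozen"):
            monte_carlo_risk(
                scenario(0.01), default_profiles()["male"],
                {"inhalation_rate": "lognormal"}, n=10, seed=0,
            )
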