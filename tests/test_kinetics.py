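"""Rate laws: worked examples, branching logic, bounds, and the mass balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lacshift as ls
from lacshift.kinetics import (FlowSnapshot, HIGH_REGIME, LOW_REGIME,
                               RateLawError, RegimeContext, mass_balance_rhs)


# ---------------------------------------------------------------- Q_lac / Q_gln

class TestLactateRate:
    def test_high_do_sigmoid_values(self, params_A):
        # hand evaluation of k11/(k12+exp(-k13*GLN)) + k14
        assert ls.compute_qlac(10.0, HIGH_REGIME, params_A) == \
            pytest.approx(3.405e-10, rel=5e-4)
        assert ls.compute_qlac(0.0, HIGH_REGIME, params_A) == \
            pytest.approx(-3.940e-11, rel=5e-4)

    def test_low_do_is_constant(self, params_A):
        for gln in (0.0, 1.0, 50.0):
            assert ls.compute_qlac(gln, LOW_REGIME, params_A) == 8.85e-14

    def test_sign_change_at_glutamine_depletion(self, params_A):
        root = ls.qlac_zero_gln(params_A)
        assert root == pytest.approx(0.894, abs=5e-4)
        # brute-force bisection agrees with the closed form
        lo, hi = 0.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ls.compute_qlac(mid, HIGH_REGIME, params_A) < 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(root, abs=1e-9)

    def test_monotone_in_glutamine_at_high_do(self, params_A):
        grid = np.linspace(0.0, 10.0, 201)
        vals = [ls.compute_qlac(g, HIGH_REGIME, params_A) for g in grid]
        assert np.all(np.diff(vals) > 0)

    def test_overflow_guard_raises_domain_error(self, params_A):
        p = params_A.with_values(k_lac12=0.0)
        # exp(-k13*GLN) underflows to exactly 0 for large GLN
        with pytest.raises(RateLawError):
            ls.compute_qlac(1e4, HIGH_REGIME, p)
        # moderate GLN with k12=0 is fine
        assert math.isfinite(ls.compute_qlac(4.0, HIGH_REGIME, p))


class TestGlutamineRate:
    def test_high_do_value(self, params_A):
        # k_gln12 = 0 (negligible): 1.21e-12/exp(-1.67) - 4.88e-12
        assert ls.compute_qgln(1.0, HIGH_REGIME, params_A) == \
            pytest.approx(1.549e-12, rel=5e-4)

    def test_root_near_one_millimolar(self, params_A):
        assert ls.qgln_zero_gln(params_A) == pytest.approx(0.835, abs=5e-4)

    def test_low_do_constants_can_flip_sign(self, params_A, params_C):
        assert ls.compute_qgln(3.0, LOW_REGIME, params_A) == 1.57e-14
        assert ls.compute_qgln(3.0, LOW_REGIME, params_C) == -3.07e-13

    def test_no_production_above_root(self, params_A, params_C):
        for p in (params_A, params_C):
            root = ls.qgln_zero_gln(p)
            for g in np.linspace(root + 1e-6, 10, 50):
                assert ls.compute_qgln(g, HIGH_REGIME, p) > 0
            assert ls.compute_qgln(0.9 * root, HIGH_REGIME, p) < 0


# ------------------------------------------------------------------- mu / mu_d

class TestGrowthRate:
    def test_zero_glucose_stops_growth(self, params_A):
        for regime in (HIGH_REGIME, LOW_REGIME):
            for qlac in (-1e-11, 1e-11):
                assert ls.compute_mu(0.0, 5.0, 3.0, regime, qlac, params_A) == 0.0

    def test_low_do_saturating_returns_mu_max2(self, params_A):
        mu = ls.compute_mu(1e6, 0.0, 0.0, LOW_REGIME, 0.0, params_A)
        assert mu == pytest.approx(0.296, rel=1e-4)

    def test_high_do_production_branch_half_saturation(self, params_A):
        mu = ls.compute_mu(36.7, 1e3, 0.0, HIGH_REGIME, 1e-11, params_A)
        assert mu == pytest.approx(0.1355, rel=1e-3)

    def test_high_do_consumption_branch_lactate_monod(self, params_A):
        mu = ls.compute_mu(1e6, 5.0, 6.46, HIGH_REGIME, -1e-12, params_A)
        assert mu == pytest.approx(0.1355, rel=1e-3)

    def test_stirred_low_do_uses_mu_max1_with_ki_lac2(self, params_C):
        mu = ls.compute_mu(1e6, 0.0, 1.16, LOW_REGIME, 0.0, params_C)
        assert mu == pytest.approx(0.282 * 0.5, rel=1e-3)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(glc=st.floats(0, 1e3), gln=st.floats(0, 20), lac=st.floats(0, 50),
           qlac=st.floats(-1e-10, 1e-9), low=st.booleans())
    def test_bounded_by_maximum_rate(self, params_A, glc, gln, lac, qlac, low):
        regime = LOW_REGIME if low else HIGH_REGIME
        mu = ls.compute_mu(glc, gln, lac, regime, qlac, params_A)
        cap = params_A.mu_max2 if low else params_A.mu_max1
        assert 0.0 <= mu <= cap


class TestDeathRate:
    def test_vanishes_without_lactate_or_ammonia(self, params_A):
        assert ls.compute_mud(0.0, 5.0, 0.0, HIGH_REGIME, params_A) == 0.0
        assert ls.compute_mud(5.0, 0.0, 0.0, HIGH_REGIME, params_A) == 0.0

    def test_saturating_limit_is_kd(self, params_A):
        mud = ls.compute_mud(1e9, 1e9, 0.0, HIGH_REGIME, params_A)
        assert mud == pytest.approx(5.15e-2, rel=1e-6)

    def test_half_saturation_product(self, params_A):
        mud = ls.compute_mud(12.6, 6.96, 0.0, HIGH_REGIME, params_A)
        assert mud == pytest.approx(1.2875e-2, rel=1e-6)

    def test_shaken_low_do_switches_to_kd2(self, params_A):
        mud = ls.compute_mud(1e9, 1e9, 0.0, LOW_REGIME, params_A)
        assert mud == pytest.approx(3.15e-2, rel=1e-6)

    def test_stirred_uses_kd1_in_both_regimes(self, params_C):
        hi = ls.compute_mud(9.61, 6.03, 0.0, HIGH_REGIME, params_C)
        lo = ls.compute_mud(9.61, 6.03, 0.0, LOW_REGIME, params_C)
        assert hi == lo == pytest.approx(0.0449 * 0.25, rel=1e-6)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(lac=st.floats(0, 1e3), amm=st.floats(0, 1e3), glc=st.floats(0, 1e3),
           low=st.booleans())
    def test_bounded_by_kd(self, params_A, lac, amm, glc, low):
        regime = LOW_REGIME if low else HIGH_REGIME
        cap = params_A.kd2 if low else params_A.kd1
        assert 0.0 <= ls.compute_mud(lac, amm, glc, regime, params_A) <= cap


class TestProductionRate:
    def test_proportional_to_net_growth(self, params_A):
        assert ls.compute_qp(0.15, 0.05, params_A) == \
            pytest.approx(4.71e-12, rel=1e-9)

    def test_clipped_at_zero_for_negative_net_growth(self, params_A):
        assert ls.compute_qp(0.01, 0.05, params_A) == 0.0
        assert ls.compute_qp(0.05, 0.05, params_A) == 0.0


def test_mu_branch_consistent_with_qlac_root(params_A):
    """The growth branch chosen from sign(Q_lac) agrees with the closed-form
    root of the lactate sigmoid for every glutamine level."""
    root = ls.qlac_zero_gln(params_A)
    for gln in np.linspace(0, 5, 101):
        qlac = ls.compute_qlac(gln, HIGH_REGIME, params_A)
        assert (qlac > 0) == (gln > root) or abs(gln - root) < 1e-9


# ---------------------------------------------------------------- mass balance

class TestMassBalance:
    def _state(self, V=30.0, **conc):
        names = ("Xv", "Xd", "P", "GLC", "GLN", "LAC", "AMM", "HCP", "DNA")
        return np.array([V * conc.get(n, 0.0) for n in names] + [V])

    def test_closed_system_without_biomass_is_static(self, params_A):
        d = mass_balance_rhs(self._state(), HIGH_REGIME, FlowSnapshot(), params_A)
        assert np.all(d == 0.0)

    def test_pure_feed_dilution(self, params_A):
        flows = FlowSnapshot(fin=0.1, cin_glc=666.0)
        d = mass_balance_rhs(self._state(), HIGH_REGIME, flows, params_A)
        assert d[3] == pytest.approx(0.1 * 666.0)
        assert d[9] == pytest.approx(0.1)
        mask = np.ones(10, bool); mask[[3, 9]] = False
        assert np.all(d[mask] == 0.0)

    def test_glutamine_production_does_not_source_ammonia(self, params_C):
        # stirred low-DO: Q_gln = k_gln21 < 0 -> ammonia source is k_amm2 only
        y = self._state(Xv=1e10, GLC=20, GLN=2, LAC=5, AMM=2)
        d = mass_balance_rhs(y, LOW_REGIME, FlowSnapshot(), params_C)
        assert d[6] == pytest.approx(params_C.k_amm2 * 1e10 * 30.0, rel=1e-12)

    def test_ammonia_source_includes_glutamine_term_when_consuming(self, params_A):
        y = self._state(Xv=1e10, GLC=20, GLN=4)
        d = mass_balance_rhs(y, HIGH_REGIME, FlowSnapshot(), params_A)
        qgln = ls.compute_qgln(4.0, HIGH_REGIME, params_A)
        expected = (params_A.k_amm1 * qgln + params_A.k_amm2) * 1e10 * 30.0
        assert d[6] == pytest.approx(expected, rel=1e-12)

    def test_lysis_flux_saturates_at_r_dcell_V(self, params_A):
        y = self._state(Xd=1e15)
        d = mass_balance_rhs(y, HIGH_REGIME, FlowSnapshot(), params_A)
        # HCP source approaches Y_hcp_Xd * r_dcell * V at saturating Xd
        assert d[7] == pytest.approx(params_A.Y_hcp_Xd * params_A.r_dcell * 30.0,
                                     rel=1e-6)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            FlowSnapshot(fin=-0.1, cin_glc=1.0)

    def test_missing_inlet_concentration_rejected(self):
        with pytest.raises(ValueError):
            FlowSnapshot(fin=0.1)

    def test_clipping_keeps_rates_finite_on_overshoot(self, params_A):
        y = self._state(Xv=1e9, GLC=-1e-9, GLN=-1e-12, LAC=-1e-9, AMM=1.0)
        d = mass_balance_rhs(y, HIGH_REGIME, FlowSnapshot(), params_A)
        assert np.all(np.isfinite(d))
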