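"""Closed-form rate laws: worked values, algebraic identities, and
equivalence with the numerical steady-state solver (dual-route oracle)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grxkinetics import (
    KineticParameters,
    build_mutant_core,
    build_wildtype_core,
    grxss_fraction,
    hill_form_mut,
    hill_form_wt,
    rate_ratio,
    rate_ratio_limit,
    reciprocal_coefficients,
    v_mut,
    v_wt,
)
from grxkinetics.simulate import steady_state

log_positive = st.floats(min_value=-2.0, max_value=2.0).map(lambda e: 10.0 ** e)


class TestWildTypeRate:
    def test_equal_half_resistances(self):
        # k1*PSSG = k2*GSH^2 = 2 with unit Grx total -> rate 1
        assert v_wt(k1=1.0, k2=2.0, grx_tot=1.0, pssG=2.0, gsh=1.0) == pytest.approx(1.0)

    def test_zero_substrate_limits(self):
        assert v_wt(1.0, 1.0, 1.0, 0.0, 5.0) == 0.0
        assert v_wt(1.0, 1.0, 1.0, 5.0, 0.0) == 0.0

    def test_saturating_pssg_leaves_gsh_oxidation_rate(self):
        v = v_wt(1.0, 3.0, 2.0, 1e12, 4.0)
        assert v == pytest.approx(2.0 * 3.0 * 16.0, rel=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            v_wt(1.0, 1.0, 1.0, -1.0, 1.0)

    @given(
        k1=log_positive, k2=log_positive, grx_tot=log_positive,
        pssG=log_positive, gsh=log_positive,
    )
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_in_grx_total(self, k1, k2, grx_tot, pssG, gsh):
        assert v_wt(k1, k2, 2.0 * grx_tot, pssG, gsh) == pytest.approx(
            2.0 * v_wt(k1, k2, grx_tot, pssG, gsh), rel=1e-12
        )

    @given(
        k1=log_positive, k2=log_positive, pssG=log_positive, gsh=log_positive,
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_substrate(self, k1, k2, pssG, gsh):
        base = v_wt(k1, k2, 1.0, pssG, gsh)
        assert v_wt(k1, k2, 1.0, pssG * 1.5, gsh) > base
        assert v_wt(k1, k2, 1.0, pssG, gsh * 1.5) > base


class TestGrxssFraction:
    def test_balanced_rates_give_half(self):
        assert grxss_fraction(1.0, 1.0, 4.0, 2.0) == pytest.approx(0.5)

    def test_no_gsh_fully_oxidises(self):
        assert grxss_fraction(1.0, 1.0, 3.0, 0.0) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            grxss_fraction(1.0, 1.0, 0.0, 0.0)

    @given(k1=log_positive, k2=log_positive, pssG=log_positive, gsh=log_positive)
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, k1, k2, pssG, gsh):
        f = grxss_fraction(k1, k2, pssG, gsh)
        assert 0.0 <= f <= 1.0
        assert grxss_fraction(k1, k2, pssG * 2.0, gsh) >= f
        assert grxss_fraction(k1, k2, pssG, gsh * 2.0) <= f


class TestMutantRate:
    def test_equal_half_resistances(self):
        assert v_mut(k1=1.0, k2p=1.0, grx_tot=1.0, pssG=2.0, gsh=2.0) == pytest.approx(1.0)

    def test_zero_gsh_gives_zero(self):
        assert v_mut(1.0, 1.0, 1.0, 5.0, 0.0) == 0.0


class TestRateRatio:
    def test_equal_limiting_constants_give_unity(self):
        # k2*GSH == k2p at saturating PSSG
        assert rate_ratio(1.0, 0.5, 50.0, 1e12, 100.0) == pytest.approx(1.0, rel=1e-9)

    def test_limit_formula_arithmetic(self):
        assert rate_ratio_limit(k2=1.0, k2p=50.0, gsh=100.0) == pytest.approx(2.0)
        assert rate_ratio_limit(k2=0.25, k2p=25.0, gsh=100.0) == pytest.approx(1.0)

    def test_ratio_approaches_limit_at_large_pssg(self, rng):
        # draws span the realistic regime where GSH oxidation is rate
        # limiting (k1*PSSG far above k2*GSH^2 and k2p*GSH at PSSG 1e9)
        for _ in range(20):
            k1 = 10.0 ** rng.uniform(-2, 0)
            k2 = 10.0 ** rng.uniform(-6, -4)
            k2p = 10.0 ** rng.uniform(-3, -1)
            gsh = 10.0 ** rng.uniform(1, 3)
            full = rate_ratio(k1, k2, k2p, 1e9, gsh)
            limit = rate_ratio_limit(k2, k2p, gsh)
            assert full == pytest.approx(limit, rel=1e-4)

    def test_monotone_increasing_in_gsh_at_large_pssg(self):
        gsh_grid = np.logspace(1, 4, 40)
        ratios = [rate_ratio(0.073, 4.23e-6, 4.2e-3, 1e9, g) for g in gsh_grid]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestReciprocalCoefficients:
    def test_slope_is_gsh_independent(self):
        low = reciprocal_coefficients(1.0, 1.0, 1.0, gsh=10.0)
        high = reciprocal_coefficients(1.0, 1.0, 1.0, gsh=1000.0)
        assert low.slope_vs_invPSSG == high.slope_vs_invPSSG == 1.0

    def test_intercept_quarters_when_gsh_doubles(self):
        base = reciprocal_coefficients(2.0, 3.0, 0.5, gsh=7.0)
        doubled = reciprocal_coefficients(2.0, 3.0, 0.5, gsh=14.0)
        assert doubled.intercept == pytest.approx(base.intercept / 4.0)

    def test_zero_grx_total_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_coefficients(1.0, 1.0, 0.0, 1.0)


class TestHillForms:
    def test_wildtype_half_saturation_is_square_root(self):
        form = hill_form_wt(k1=1.0, k2=1.0, grx_tot=1.0, pssG=4.0)
        assert form.K_half == pytest.approx(2.0)
        assert form.n == 2

    def test_mutant_half_saturation_is_linear(self):
        form = hill_form_mut(k1=1.0, k2p=1.0, grx_tot=1.0, pssG=3.0)
        assert form.K_half == pytest.approx(3.0)
        assert form.n == 1

    def test_half_saturation_rate_is_half_maximal(self):
        form = hill_form_wt(0.073, 4.23e-6, 0.24, 70.0)
        assert form.rate(form.K_half) == pytest.approx(form.V / 2.0, rel=1e-12)

    def test_wildtype_form_is_exact_identity(self):
        k1, k2, grx_tot, pssg = 0.073, 4.23e-6, 0.24, 70.0
        form = hill_form_wt(k1, k2, grx_tot, pssg)
        for gsh in np.logspace(-2, 5, 60):
            expected = v_wt(k1, k2, grx_tot, pssg, gsh)
            assert math.isclose(form.rate(gsh), expected, rel_tol=1e-12)

    def test_mutant_form_is_exact_identity(self):
        k1, k2p, grx_tot, pssg = 0.073, 4.2e-3, 0.24, 70.0
        form = hill_form_mut(k1, k2p, grx_tot, pssg)
        for gsh in np.logspace(-2, 5, 60):
            expected = v_mut(k1, k2p, grx_tot, pssg, gsh)
            assert math.isclose(form.rate(gsh), expected, rel_tol=1e-12)


class TestOracleEquivalence:
    """Closed forms and the ODE steady-state solver agree on random draws."""

    def test_wildtype_flux_and_fraction(self, rng):
        for _ in range(30):
            k1, k2 = 10.0 ** rng.uniform(-3, 1, size=2)
            grx_tot = 10.0 ** rng.uniform(-2, 2)
            pssg, gsh = 10.0 ** rng.uniform(-1, 3, size=2)
            params = KineticParameters(k1=k1, k2_wt=k2, grx_tot=grx_tot)
            ss = steady_state(build_wildtype_core(params, pssg, gsh))
            assert ss.fluxes["v2"] == pytest.approx(
                v_wt(k1, k2, grx_tot, pssg, gsh), rel=1e-6
            )
            assert ss.state["GrxSS"] / grx_tot == pytest.approx(
                grxss_fraction(k1, k2, pssg, gsh), rel=1e-6
            )

    def test_mutant_flux(self, rng):
        for _ in range(30):
            k1, k2p = 10.0 ** rng.uniform(-3, 1, size=2)
            grx_tot = 10.0 ** rng.uniform(-2, 2)
            pssg, gsh = 10.0 ** rng.uniform(-1, 3, size=2)
            params = KineticParameters(k1=k1, k2p_mut=k2p, grx_tot=grx_tot)
            ss = steady_state(build_mutant_core(params, pssg, gsh))
            assert ss.fluxes["v2"] == pytest.approx(
                v_mut(k1, k2p, grx_tot, pssg, gsh), rel=1e-6
            )
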