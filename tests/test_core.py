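"""Unit and property tests for the model's algebraic pieces and RHS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caixsim import (
    ModelParameters,
    TreatmentEffects,
    TumorState,
    NO_TREATMENT,
    acidosis_death_factor,
    full_rhs,
    logistic_growth,
    pdl1_fraction,
    ph_from_proton,
    proton_from_ph,
    simplified_rhs,
)
from caixsim.core import full_jacobian


class TestParameterValidation:
    def test_defaults_are_valid(self):
        ModelParameters()

    @pytest.mark.parametrize("field,value", [
        ("phi", 0.0), ("K", 0.0), ("vc", 0.0), ("omega", 0.0),
        ("sigma", 1.5), ("p", -0.1), ("eta", -1.0),
    ])
    def test_out_of_range_rejected(self, field, value):
        with pytest.raises(ValueError):
            ModelParameters(**{field: value})

    def test_adaptive_pdl1_amplitude_bounded_by_constitutive(self):
        # the PD-L1+ fraction alpha + beta must stay a fraction
        with pytest.raises(ValueError, match="beta"):
            ModelParameters(alpha=0.3, beta=0.8)

    def test_knockout_and_zero_treatment_allowed(self):
        ModelParameters(q=0.0)
        TreatmentEffects(0.0, 0.0, 0.0)

    @pytest.mark.parametrize("kw", [dict(d1=1.2), dict(d3=-0.1), dict(d2=-1)])
    def test_treatment_effects_validated(self, kw):
        with pytest.raises(ValueError):
            TreatmentEffects(**kw)


class TestHelpers:
    def test_logistic_growth(self, printed_params):
        p = printed_params
        assert logistic_growth(100.0, p.K, p) == 0.0
        assert logistic_growth(0.0, 600.0, p) == 0.0
        # half-filled capacity: phi * X / 2
        val = logistic_growth(1.0, 600.0, p.replace(phi=2417.2, K=1200.0))
        assert val == pytest.approx(1208.6)
        # above capacity the rate is negative
        assert logistic_growth(10.0, 2 * p.K, p) < 0.0

    def test_pdl1_fraction_limits(self, printed_params):
        p = printed_params
        assert pdl1_fraction(0.0, p) == pytest.approx(p.alpha)  # 0.1
        assert pdl1_fraction(1e9, p) == pytest.approx(p.alpha + p.beta, rel=1e-6)
        assert pdl1_fraction(p.zeta, p) == pytest.approx(p.alpha + p.beta / 2)

    def test_pdl1_fraction_monotone(self, printed_params):
        I = np.linspace(0, 1e-2, 50)
        L = [pdl1_fraction(x, printed_params) for x in I]
        assert np.all(np.diff(L) > 0)
        assert all(printed_params.alpha <= x <= printed_params.alpha
                   + printed_params.beta for x in L)

    def test_acidosis_death_factor(self, printed_params):
        p = printed_params
        assert acidosis_death_factor(p.h_thresh, p) == 0.0
        assert acidosis_death_factor(2 * p.h_thresh, p) == pytest.approx(0.5)
        assert acidosis_death_factor(p.h_thresh / 2, p) == 0.0
        with pytest.raises(ValueError):
            acidosis_death_factor(0.0, p)

    def test_ph_conversion_published_anchors(self, printed_params):
        # threshold concentration corresponds to pH 6.7
        assert ph_from_proton(printed_params.h_thresh) == pytest.approx(6.7, abs=0.005)
        # physiological proton level corresponds to pH 7.4
        assert ph_from_proton(printed_params.h0) == pytest.approx(7.4, abs=0.005)
        assert ph_from_proton(1e-13) == pytest.approx(7.0)

    @given(st.floats(min_value=1e-15, max_value=1e-11))
    @settings(max_examples=200, deadline=None)
    def test_ph_round_trip(self, H):
        assert proton_from_ph(ph_from_proton(H)) == pytest.approx(H, rel=1e-12)


class TestTumorState:
    def test_densities_derived_from_extensive_state(self):
        s = TumorState(C=6.0, S=4.0, EV=100.0, IV=5.0, HV=1e-12)
        assert s.V == 10.0
        assert s.E == pytest.approx(10.0)
        assert s.I == pytest.approx(0.5)
        assert s.H == pytest.approx(1e-13)
        assert s.pH == pytest.approx(7.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            TumorState(C=0.0, S=0.0, EV=1.0, IV=0.0, HV=0.0)

    def test_negative_extensive_state_rejected(self):
        with pytest.raises(ValueError):
            TumorState(C=1.0, S=-0.1, EV=0.0, IV=0.0, HV=0.0)


class TestFullRHS:
    def test_sterile_tumor_reduces_to_growth_and_apoptosis(self, printed_params):
        # no T cells, no IFN-gamma, physiological protons
        p = printed_params
        C, S = 3.0, 1.0
        V = C + S
        y = np.array([C, S, 0.0, 0.0, p.h0 * V])
        dC, dS, dEV, dIV, dHV = full_rhs(0.0, y, p)
        g = p.phi * (1 - V / p.K)
        assert dC == pytest.approx(g * C + p.sigma * g * S - p.n * C)
        assert dS == pytest.approx((1 - p.sigma) * g * S)
        assert dIV == 0.0
        # proton source only: (delta + q) * V
        assert dHV == pytest.approx((p.delta + p.q) * V)

    def test_full_caix_blockade_leaves_metabolic_protons_only(self, printed_params):
        p = printed_params
        y = np.array([3.0, 1.0, 50.0, 0.2, p.h0 * 4.0])
        d_full = full_rhs(0.0, y, p, TreatmentEffects(d3=1.0))
        assert d_full[4] == pytest.approx(p.delta * 4.0)

    def test_cytokine_equation_density_identity(self, printed_params):
        # d(IV)/dt computed extensively equals r*E*V - omega*I*V
        p = printed_params
        y = np.array([5.0, 2.0, 321.0, 0.7, 2.1e-13 * 7.0])
        V = y[0] + y[1]
        dIV = full_rhs(0.0, y, p)[3]
        E, I = y[2] / V, y[3] / V
        assert dIV == pytest.approx(p.r * E * V - p.omega * I * V, rel=1e-12)

    def test_zero_effects_identical_to_no_treatment(self, printed_params):
        y = np.array([5.0, 2.0, 321.0, 0.7, 2.1e-13 * 7.0])
        lhs = full_rhs(0.0, y, printed_params, TreatmentEffects(0.0, 0.0, 0.0))
        rhs_ = full_rhs(0.0, y, printed_params, NO_TREATMENT)
        assert np.array_equal(lhs, rhs_)

    def test_vanished_tumor_rejected(self, printed_params):
        with pytest.raises(ValueError):
            full_rhs(0.0, np.array([0.0, 0.0, 1.0, 0.0, 0.0]), printed_params)

    @pytest.mark.parametrize("effects", [
        NO_TREATMENT, TreatmentEffects(d1=0.4, d2=4.0, d3=1.0),
        TreatmentEffects(d1=1.0), TreatmentEffects(d2=7.3),
    ])
    def test_analytic_jacobian_matches_finite_differences(self, printed_params, effects):
        p = printed_params.replace(phi=1.4)
        y = np.array([5.0, 2.0, 300.0, 0.4, 2.5e-13 * 7.0])
        J = full_jacobian(0.0, y, p, effects)
        Jfd = np.zeros((5, 5))
        for k in range(5):
            h = 1e-7 * max(abs(y[k]), 1e-8)
            yp, ym = y.copy(), y.copy()
            yp[k] += h
            ym[k] -= h
            Jfd[:, k] = (full_rhs(0, yp, p, effects) - full_rhs(0, ym, p, effects)) / (2 * h)
        scale = np.abs(Jfd).max()
        assert np.allclose(J, Jfd, atol=1e-5 * scale, rtol=1e-5)


class TestSimplifiedRHS:
    def test_no_tcells_means_pure_logistic_growth_and_influx(self, printed_params):
        p = printed_params
        S = 10.0
        dS, dx = simplified_rhs(0.0, np.array([S, 0.0]), p)
        assert dS == pytest.approx(p.phi * S * (1 - S / p.K))
        assert dx == pytest.approx(p.b_star * S)
        assert dx > 0

    def test_knockout_quasi_steady_protons_below_acid_threshold(self, printed_params):
        # with q = 0 the proton plateau H* = 9.98e-14 < 2e-13: acid death off
        p = printed_params.knockout()
        from caixsim.core import simplified_quasi_steady
        h = simplified_quasi_steady(p)
        assert h == pytest.approx(9.98e-14, rel=1e-12)
        assert h < p.h_thresh
        # the T-cell equation then has no acid term: residual of manual form
        S, x = 50.0, 30.0
        dx = simplified_rhs(0.0, np.array([S, x]), p)[1]
        E = x / S
        I = p.r * E / p.omega
        L = p.alpha + p.beta * I / (p.zeta + I)
        assert dx == pytest.approx(p.b_star * S - p.d * x - p.a_star * p.p * L * x)

    def test_nonpositive_tumor_rejected(self, printed_params):
        with pytest.raises(ValueError):
            simplified_rhs(0.0, np.array([0.0, 1.0]), printed_params)
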