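"""Steady-state machinery: closed forms, oracles, sweeps, phase portraits."""

import numpy as np
import pytest

from caixsim import (
    ModelParameters,
    TreatmentEffects,
    eta_sweep,
    phase_portrait,
    positive_equilibrium,
    proton_quasi_steady,
    tcell_nullcline_slope,
    tumor_nullcline_coefficient,
)
from caixsim.core import simplified_rhs
from caixsim.equilibria import (
    effective_tcell_death,
    simulate_simplified,
    tcell_quadratic_coefficients,
)
from caixsim.presets import boosted_immunity_parameters


class TestProtonQuasiSteady:
    def test_caix_expressing_acidifies_to_ph_6_6(self, printed_params):
        h = proton_quasi_steady(printed_params)
        assert h == pytest.approx(2.52316e-13, rel=1e-9)
        assert -np.log10(h * 1e6) == pytest.approx(6.6, abs=0.05)

    def test_knockout_stays_near_neutral_ph(self, printed_params):
        h = proton_quasi_steady(printed_params.knockout())
        assert h == pytest.approx(9.98e-14, rel=1e-9)
        assert -np.log10(h * 1e6) == pytest.approx(7.0, abs=0.01)

    def test_no_proton_sources_gives_physiological_level(self, printed_params):
        p = printed_params.replace(delta=0.0, q=0.0)
        assert proton_quasi_steady(p) == pytest.approx(p.h0)

    def test_full_caix_blockade_equals_knockout(self, printed_params):
        assert proton_quasi_steady(printed_params, TreatmentEffects(d3=1.0)) \
            == pytest.approx(proton_quasi_steady(printed_params.knockout()))

    def test_acid_death_folds_into_effective_rate(self, printed_params):
        p = printed_params
        h = proton_quasi_steady(p)
        assert effective_tcell_death(p) == pytest.approx(
            p.d + p.eta * (1 - p.h_thresh / h))
        # knockout: plateau below threshold, no acid death
        assert effective_tcell_death(p.knockout()) == pytest.approx(p.d)


class TestTcellNullcline:
    def test_positive_root_solves_the_quadratic(self, fitted_params):
        A, B, C = tcell_quadratic_coefficients(fitted_params)
        c1 = tcell_nullcline_slope(fitted_params)
        scale = max(abs(A) * c1**2, abs(B) * c1, abs(C))
        assert abs(-A * c1**2 + B * c1 + C) < 1e-10 * scale
        assert c1 > 0

    def test_root_matches_numeric_polynomial_oracle(self, fitted_params):
        for effects in (TreatmentEffects(), TreatmentEffects(d1=0.4, d2=4.0)):
            A, B, C = tcell_quadratic_coefficients(fitted_params, effects)
            roots = np.roots([-A, B, C])
            positive = roots[roots > 0]
            assert len(positive) == 1
            assert tcell_nullcline_slope(fitted_params, effects) \
                == pytest.approx(float(positive[0]), rel=1e-12)

    def test_degenerate_no_pd1_case_against_oracle(self, fitted_params):
        # p = 0 removes the PD-L1 coupling; same closed form must still hold
        p = fitted_params.replace(p=0.0)
        A, B, C = tcell_quadratic_coefficients(p)
        roots = np.roots([-A, B, C])
        assert tcell_nullcline_slope(p) == pytest.approx(
            float(roots[roots > 0][0]), rel=1e-12)

    def test_discriminant_and_vieta_on_random_draws(self, rng):
        # opposite-sign roots and positive discriminant for 1000 valid draws
        for _ in range(1000):
            p = ModelParameters(
                phi=float(rng.uniform(0.5, 20.0)),
                a_star=float(10 ** rng.uniform(0, 3)),
                b_star=float(10 ** rng.uniform(1, 3.77)),
                eta=float(10 ** rng.uniform(1, 6)),
                q=float(rng.uniform(0.0, 3e-12)),
                n=float(rng.uniform(0.0, 10.0)),
                p=float(rng.uniform(0.0, 1.0)),
                sigma=float(rng.uniform(0.0, 1.0)),
            )
            A, B, C = tcell_quadratic_coefficients(p)
            assert B * B + 4 * A * C > 0
            roots = np.roots([-A, B, C])
            assert roots[0] * roots[1] < 0


class TestTumorNullcline:
    def test_no_pd1_is_density_independent(self, fitted_params):
        p = fitted_params.replace(p=0.0)
        c2a = tumor_nullcline_coefficient(p, E_at_eq=0.0)
        c2b = tumor_nullcline_coefficient(p, E_at_eq=100.0)
        assert c2a == pytest.approx(p.phi / (p.a_star * p.vc))
        assert c2a == c2b

    def test_constitutive_only_at_zero_density(self, fitted_params):
        p = fitted_params
        c2 = tumor_nullcline_coefficient(p, E_at_eq=0.0)
        assert c2 == pytest.approx(p.phi / (p.a_star * p.vc * (1 - p.p * p.alpha)))

    def test_nullcline_vanishes_at_carrying_capacity(self, fitted_params):
        rep = positive_equilibrium(fitted_params)
        x_at_K = rep.c2 * fitted_params.K * (1 - fitted_params.K / fitted_params.K)
        assert x_at_K == 0.0


class TestPositiveEquilibrium:
    def test_boosted_caix_expressing_has_two_states(self, fitted_params):
        rep = positive_equilibrium(boosted_immunity_parameters(phi=fitted_params.phi))
        assert rep.origin_included
        assert rep.positive_exists
        assert 0 < rep.S_star < 1200.0
        assert rep.ES_star == pytest.approx(rep.c1 * rep.S_star)
        assert rep.positive_stable
        assert not rep.origin_attracting

    def test_boosted_knockout_leaves_only_the_origin(self, fitted_params):
        rep = positive_equilibrium(boosted_immunity_parameters(phi=fitted_params.phi).knockout())
        assert not rep.positive_exists
        assert rep.S_star is None
        assert rep.origin_attracting

    def test_equilibrium_zeroes_the_reduced_dynamics(self, fitted_params):
        p = boosted_immunity_parameters(phi=fitted_params.phi)
        rep = positive_equilibrium(p)
        dy = simplified_rhs(0.0, np.array([rep.S_star, rep.ES_star]), p)
        scale = np.array([p.phi * rep.S_star, p.b_star * rep.S_star])
        assert np.all(np.abs(dy) < 1e-8 * scale)

    def test_weak_growth_removes_positive_state(self, fitted_params):
        # slowing tumor growth pushes the tumor nullcline coefficient c2
        # below the T-cell nullcline slope c1: only the origin remains
        p = fitted_params.knockout().replace(phi=0.2)
        rep = positive_equilibrium(p)
        assert rep.c1 >= rep.c2
        assert not rep.positive_exists
        # long simplified runs from positive starts then decay toward origin
        _, states = simulate_simplified(p, (100.0, 10.0), t_final=400.0)
        assert states[-1, 0] < 1e-6

    def test_existence_is_scale_free_in_tumor_size(self, fitted_params):
        # the report is a property of parameters, not of any initial state
        p = boosted_immunity_parameters(phi=fitted_params.phi)
        a = positive_equilibrium(p)
        b = positive_equilibrium(p)
        assert a == b


class TestEtaSweep:
    def test_positive_state_exists_across_grid_and_grows_with_eta(self, fitted_params):
        p = boosted_immunity_parameters(phi=fitted_params.phi)
        reports = eta_sweep(p, eta_values=np.logspace(2, 6, 9))
        assert all(rep.positive_exists for _, rep in reports)
        s = [rep.S_star for _, rep in reports]
        assert np.all(np.diff(s) >= 0)
        assert s[-1] > s[0]

    def test_zero_eta_reduces_to_plain_death_rate(self, fitted_params):
        p = boosted_immunity_parameters(phi=fitted_params.phi)
        rep0 = eta_sweep(p, eta_values=[0.0])[0][1]
        assert rep0.d_eff == pytest.approx(p.d)
        # closed form with d_eff = d: same as manually disabling acid death
        rep_ref = positive_equilibrium(p.replace(eta=0.0))
        assert rep0.S_star == pytest.approx(rep_ref.S_star, rel=1e-12)


class TestPhasePortrait:
    def test_equilibrium_is_invariant_under_the_flow(self, fitted_params):
        p = boosted_immunity_parameters(phi=fitted_params.phi)
        rep = positive_equilibrium(p)
        _, states = simulate_simplified(
            p, (rep.S_star, rep.ES_star), t_final=100.0)
        assert np.allclose(states[:, 0], rep.S_star, rtol=1e-6)
        assert np.allclose(states[:, 1], rep.ES_star, rtol=1e-6)

    def test_caix_expressing_trajectories_reach_positive_state(self, fitted_params):
        p = boosted_immunity_parameters(phi=fitted_params.phi)
        pp = phase_portrait(p, t_final=150.0)
        rep = pp.report
        for end in pp.endpoints():
            d_pos = np.hypot(end[0] - rep.S_star, end[1] - rep.ES_star)
            d_origin = np.hypot(end[0], end[1])
            assert d_pos < d_origin

    def test_knockout_trajectories_collapse_to_origin(self, fitted_params):
        p = boosted_immunity_parameters(phi=fitted_params.phi).knockout()
        pp = phase_portrait(p, t_final=400.0)
        for end in pp.endpoints():
            assert end[0] < 1e-6  # tumor gone (S at the domain floor)

    def test_portrait_requires_positive_tumor_start(self, fitted_params):
        with pytest.raises(ValueError):
            simulate_simplified(fitted_params, (0.0, 1.0))
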