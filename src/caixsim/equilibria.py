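"""Closed-form steady states of the reduced two-variable model.

With all cancer cells treated as stem cells and protons/IFN-gamma at quasi-
steady state, the model reduces to (S, x) with x = E*S.  Setting the T-cell
equation to zero gives a quadratic in x whose positive root defines the
T-cell nullcline x = c1*S (c1 is independent of S); the tumor equation gives
the nullcline x = c2*S(1 - S/K).  The origin is always an equilibrium (as a
boundary limit point — the density formulation requires S > 0), and a
positive equilibrium

    S* = (1 - c1/c2) K,   ES* = c1 S*

exists if and only if c1 < c2.  Acidosis enters through the effective T-cell
death rate d_eff = d + eta * max(1 - h_thresh/H*, 0) with H* the quasi-steady
proton concentration; PD-L1 is evaluated self-consistently at the nullcline
T-cell density E = c1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    NO_TREATMENT,
    ModelParameters,
    TreatmentEffects,
    pdl1_fraction,
    ph_from_proton,
    simplified_quasi_steady,
    simplified_rhs,
)

__all__ = [
    "EquilibriumReport",
    "PhasePortrait",
    "proton_quasi_steady",
    "effective_tcell_death",
    "tcell_quadratic_coefficients",
    "tcell_nullcline_slope",
    "tumor_nullcline_coefficient",
    "positive_equilibrium",
    "eta_sweep",
    "phase_portrait",
    "simulate_simplified",
]


def proton_quasi_steady(
    params: ModelParameters, effects: TreatmentEffects = NO_TREATMENT
) -> float:
    """Quasi-steady proton concentration H* = (delta + q(1-d3) + v*h0)/v.

    Independent of the tumor and T-cell variables.
    """
    return simplified_quasi_steady(params, effects)


def effective_tcell_death(
    params: ModelParameters, effects: TreatmentEffects = NO_TREATMENT
) -> float:
    """T-cell death rate with the acidosis term folded in at H = H*."""
    h_star = proton_quasi_steady(params, effects)
    acid = max(1.0 - params.h_thresh / h_star, 0.0)
    return params.d + params.eta * acid


def tcell_quadratic_coefficients(
    params: ModelParameters, effects: TreatmentEffects = NO_TREATMENT
) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of the steady-state quadratic in c = x/S.

    The T-cell nullcline condition, after clearing the PD-L1 denominator and
    dividing by S^2, reads  -A c^2 + B c + C = 0  with

        A = (r/omega) (d_eff + a* p' (alpha + beta))
        B = b*' r/omega - d_eff zeta - a* p' alpha zeta
        C = b*' zeta

    where p' = p (1 - d1) and b*' = b* (1 + d2).  A and C are positive for
    valid parameters, so the discriminant B^2 + 4AC is positive and the two
    roots have opposite signs (Vieta); the positive root is c1.
    """
    p = params
    p_eff = p.p * (1.0 - effects.d1)
    b_eff = p.b_star * (1.0 + effects.d2)
    d_eff = effective_tcell_death(params, effects)
    A = (p.r / p.omega) * (d_eff + p.a_star * p_eff * (p.alpha + p.beta))
    B = b_eff * p.r / p.omega - d_eff * p.zeta - p.a_star * p_eff * p.alpha * p.zeta
    C = b_eff * p.zeta
    return A, B, C


def tcell_nullcline_slope(
    params: ModelParameters, effects: TreatmentEffects = NO_TREATMENT
) -> float:
    """Slope c1 > 0 of the T-cell nullcline x = c1 * S (S-independent)."""
    A, B, C = tcell_quadratic_coefficients(params, effects)
    disc = B * B + 4.0 * A * C
    return (B + np.sqrt(disc)) / (2.0 * A)


def tumor_nullcline_coefficient(
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
    E_at_eq: float = 0.0,
) -> float:
    """Coefficient c2 > 0 of the tumor nullcline x = c2 * S (1 - S/K).

    PD-L1 is evaluated at the IFN-gamma level sustained by the equilibrium
    T-cell density ``E_at_eq`` (I = r E / omega).
    """
    if E_at_eq < 0:
        raise ValueError("E_at_eq must be non-negative")
    p = params
    I = p.r * E_at_eq / p.omega
    L = pdl1_fraction(I, p)
    return p.phi / (p.a_star * p.vc * (1.0 - p.p * (1.0 - effects.d1) * L))


@dataclass(frozen=True)
class EquilibriumReport:
    """Steady-state structure of the reduced model for one parameter set."""

    h_star: float                     # quasi-steady proton conc. (mol/mm^3)
    d_eff: float                      # effective T-cell death rate (1/day)
    c1: float                         # T-cell nullcline slope
    c2: float                         # tumor nullcline coefficient
    positive_exists: bool
    S_star: float | None              # tumor volume at positive eq. (mm^3)
    ES_star: float | None             # T-cell coordinate x = E*S
    origin_included: bool = True
    origin_attracting: bool = False
    positive_stable: bool | None = None
    eigenvalues: tuple | None = None  # Jacobian eigenvalues at positive eq.

    @property
    def ph_star(self) -> float:
        return float(ph_from_proton(self.h_star))

    def to_dict(self) -> dict:
        d = dict(
            h_star=self.h_star, ph_star=self.ph_star, d_eff=self.d_eff,
            c1=self.c1, c2=self.c2, positive_exists=self.positive_exists,
            S_star=self.S_star, ES_star=self.ES_star,
            origin_included=self.origin_included,
            origin_attracting=self.origin_attracting,
            positive_stable=self.positive_stable,
        )
        if self.eigenvalues is not None:
            d["eigenvalues_real"] = [float(np.real(e)) for e in self.eigenvalues]
            d["eigenvalues_imag"] = [float(np.imag(e)) for e in self.eigenvalues]
        return d


def _numeric_jacobian(y, params, effects, rel=1e-6):
    J = np.zeros((2, 2))
    f0 = simplified_rhs(0.0, y, params, effects)
    for k in range(2):
        h = rel * max(abs(y[k]), 1e-8)
        yp = y.copy(); yp[k] += h
        ym = y.copy(); ym[k] -= h
        J[:, k] = (simplified_rhs(0.0, yp, params, effects)
                   - simplified_rhs(0.0, ym, params, effects)) / (2 * h)
    return J


def positive_equilibrium(
    params: ModelParameters, effects: TreatmentEffects = NO_TREATMENT
) -> EquilibriumReport:
    """Full equilibrium report: nullcline coefficients, existence, stability.

    On the T-cell nullcline the density is E = x/S = c1, so c2 is evaluated
    self-consistently at E = c1 and the closed form S* = (1 - c1/c2) K is
    exact.  The origin is labelled attracting exactly when the positive
    equilibrium does not exist (the reduced tumor equation near S = 0 grows
    at rate proportional to c2 - c1); the positive equilibrium's stability
    is assessed from the numerically differentiated Jacobian.

    Non-existence of the positive equilibrium is a valid report, not an
    error.
    """
    h_star = float(proton_quasi_steady(params, effects))
    d_eff = float(effective_tcell_death(params, effects))
    c1 = float(tcell_nullcline_slope(params, effects))
    c2 = float(tumor_nullcline_coefficient(params, effects, E_at_eq=c1))
    exists = bool(c1 < c2)
    S_star = ES_star = None
    stable = None
    eigs = None
    if exists:
        S_star = float((1.0 - c1 / c2) * params.K)
        ES_star = float(c1 * S_star)
        J = _numeric_jacobian(np.array([S_star, ES_star]), params, effects)
        ev = np.linalg.eigvals(J)
        eigs = tuple(complex(e) for e in ev)
        stable = bool(np.all(np.real(ev) < 0.0))
    return EquilibriumReport(
        h_star=h_star, d_eff=d_eff, c1=c1, c2=c2,
        positive_exists=exists, S_star=S_star, ES_star=ES_star,
        origin_attracting=not exists, positive_stable=stable,
        eigenvalues=eigs,
    )


def eta_sweep(
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
    eta_values: Sequence[float] | None = None,
) -> list[tuple[float, EquilibriumReport]]:
    """Equilibrium report as a function of the acidosis death rate eta.

    With decreasing eta the S-coordinate of the positive steady state
    decreases toward zero (a harsher acid penalty on T cells protects the
    tumor less... i.e., smaller eta means more surviving T cells and a
    smaller tumor at equilibrium).
    """
    if eta_values is None:
        eta_values = np.logspace(2, 6, 17)
    out = []
    for eta in eta_values:
        if eta < 0:
            raise ValueError("eta must be non-negative")
        rep = positive_equilibrium(params.replace(eta=float(eta)), effects)
        out.append((float(eta), rep))
    return out


def simulate_simplified(
    params: ModelParameters,
    y0: Sequence[float],
    effects: TreatmentEffects = NO_TREATMENT,
    t_final: float = 100.0,
    rtol: float = 1e-8,
    s_floor: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the reduced (S, E*S) model from a positive start.

    Stops (non-terminally recording, terminally stopping) when S decays to
    ``s_floor`` — the origin is a boundary of the density formulation.
    Returns (times, states[n, 2]).
    """
    y0 = np.asarray(y0, dtype=float)
    if y0[0] <= 0:
        raise ValueError("initial S must be positive")

    def f(t, y):
        return simplified_rhs(t, y, params, effects)

    def floor_event(t, y):
        return y[0] - s_floor

    floor_event.terminal = True
    floor_event.direction = -1
    sol = solve_ivp(f, (0.0, t_final), y0, method="LSODA", rtol=rtol,
                    atol=[1e-12, 1e-9], events=floor_event)
    if sol.status == -1:
        raise RuntimeError(f"simplified-model integration failed: {sol.message}")
    return sol.t, sol.y.T


@dataclass
class PhasePortrait:
    """Sampled trajectories and nullclines in the (S, E*S) plane."""

    report: EquilibriumReport
    trajectories: list          # list of (times, states[n,2])
    nullcline_S: np.ndarray     # S grid
    nullcline_tcell: np.ndarray  # x = c1 S
    nullcline_tumor: np.ndarray  # x = c2 S (1 - S/K)
    failures: list = field(default_factory=list)

    def endpoints(self) -> np.ndarray:
        return np.array([states[-1] for _, states in self.trajectories])


def phase_portrait(
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
    initial_conditions: Sequence[Sequence[float]] | None = None,
    t_final: float = 100.0,
    n_nullcline: int = 200,
) -> PhasePortrait:
    """Integrate the reduced model from several starts and attach nullclines.

    Per-trajectory integration failures are recorded and do not abort the
    remaining trajectories.
    """
    rep = positive_equilibrium(params, effects)
    if initial_conditions is None:
        K = params.K
        ics = [(0.05 * K, 1.0), (0.25 * K, 50.0), (0.5 * K, 200.0),
               (0.9 * K, 10.0), (0.05 * K, 400.0)]
    else:
        ics = [tuple(map(float, ic)) for ic in initial_conditions]
    trajs, failures = [], []
    for ic in ics:
        try:
            trajs.append(simulate_simplified(params, ic, effects, t_final))
        except RuntimeError as exc:  # pragma: no cover - solver failure path
            failures.append((ic, str(exc)))
    S_grid = np.linspace(0.0, params.K, n_nullcline)
    return PhasePortrait(
        report=rep,
        trajectories=trajs,
        nullcline_S=S_grid,
        nullcline_tcell=rep.c1 * S_grid,
        nullcline_tumor=rep.c2 * S_grid * (1.0 - S_grid / params.K),
        failures=failures,
    )
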