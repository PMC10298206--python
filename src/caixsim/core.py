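"""Core model definitions: parameters, treatment effects, state, and right-hand sides.

The model tracks a well-mixed tumor microenvironment (TME) with five state
variables: the volumes of cancer non-stem cells ``C`` and cancer stem cells
``S`` (mm^3), and the extensive totals of active T cells ``E*V`` (cells),
IFN-gamma ``I*V`` (pg), and protons ``H*V`` (mol), where ``V = C + S`` is the
tumor volume.  Densities (``E``, ``I``, ``H``) are derived on demand by
dividing by ``V``; the dynamics are written in the extensive products, which
avoids quotient-rule errors in the right-hand side.

Tumor growth is logistic with carrying capacity ``K``.  Stem cells divide
asymmetrically with probability ``sigma`` (the asymmetric branch feeds the
non-stem compartment).  T cells kill cancer cells at a rate proportional to
their *density*, modulated by PD-1/PD-L1 engagement; PD-L1 expression has a
constitutive part ``alpha`` and an IFN-gamma-driven adaptive part
(amplitude ``beta``, saturation ``zeta``).  Protons are produced by tumor
metabolism (``delta``) and by carbonic anhydrase IX (``q``); acidosis below
pH 6.7 (proton concentration above ``h_thresh``) kills T cells at a rate
scaling with ``eta``.

Three treatment effects enter as constants during a treatment window:
``d1`` (anti-PD-1, suppresses the PD-1+ fraction), ``d2`` (anti-CTLA-4,
multiplies T-cell influx by ``1 + d2``), and ``d3`` (anti-CAIX, suppresses
CAIX proton production).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParameters",
    "TreatmentEffects",
    "TumorState",
    "NO_TREATMENT",
    "logistic_growth",
    "pdl1_fraction",
    "acidosis_death_factor",
    "ph_from_proton",
    "proton_from_ph",
    "full_rhs",
    "full_jacobian",
    "simplified_rhs",
    "simplified_quasi_steady",
]

#: mm^3 -> L conversion for proton concentrations (1 mm^3 = 1e-6 L).
_MM3_TO_L = 1.0e6


@dataclass(frozen=True)
class TreatmentEffects:
    """Constant treatment effects applied during a treatment window.

    d1 : anti-PD-1 effect, fraction of PD-1 expression suppressed, in [0, 1].
    d2 : anti-CTLA-4 effect, increment to the T-cell influx multiplier, >= 0.
    d3 : anti-CAIX effect, fraction of CAIX proton production suppressed,
         in [0, 1].

    The all-zero value means "no treatment".
    """

    d1: float = 0.0
    d2: float = 0.0
    d3: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.d1 <= 1.0):
            raise ValueError(f"d1 must be in [0, 1], got {self.d1}")
        if self.d2 < 0.0:
            raise ValueError(f"d2 must be >= 0, got {self.d2}")
        if not (0.0 <= self.d3 <= 1.0):
            raise ValueError(f"d3 must be in [0, 1], got {self.d3}")

    @property
    def is_none(self) -> bool:
        return self.d1 == 0.0 and self.d2 == 0.0 and self.d3 == 0.0


NO_TREATMENT = TreatmentEffects()


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants and fractions of the tumor-immune-acidity model.

    Defaults reproduce the published parameter tables: literature-derived
    constants plus the fitted values of the free parameters.  The composites
    ``a_star = a*m*mu`` (T-cell killing strength) and ``b_star = b*mu``
    (T-cell infiltration) are the primitive parameters here because only the
    composites were ever fitted; configuration files may instead supply the
    individual factors ``a``, ``m``, ``mu``, ``b``, which are multiplied on
    ingest (see :mod:`caixsim.io`).

    Units: rates are per day; volumes mm^3; T cells cells/mm^3; IFN-gamma
    pg/mm^3; protons mol/mm^3.

    Note on ``phi``: the published maximal growth rate (2417.2 / day) makes
    the logistic transient saturate within hours, which is irreconcilable
    with multi-week murine growth curves.  See
    :func:`caixsim.calibration.recalibrate_phi` and docs/methods.md.
    """

    phi: float = 2417.2          # maximal tumor growth rate (1/day)
    K: float = 1200.0            # carrying capacity (mm^3)
    sigma: float = 0.42          # asymmetric-division probability
    a_star: float = 834.16       # composite killing strength a*m*mu (1/day per cells/mm^3 ... mm^3 scale via vc)
    vc: float = 6.2e-6           # volume of one tumor cell (mm^3/cell)
    p: float = 0.54              # PD-1+ fraction of tumor-infiltrating lymphocytes
    n: float = 0.799             # non-stem cancer-cell apoptosis rate (1/day)
    b_star: float = 5821.0       # composite T-cell infiltration rate b*mu (cells/mm^3/day)
    d: float = 0.406             # T-cell apoptosis rate (1/day)
    eta: float = 2485.0          # acidosis-induced T-cell death rate (1/day)
    r: float = 24.48e-4          # IFN-gamma production rate (pg/cell/day)
    omega: float = 2.4           # IFN-gamma decay rate (1/day)
    delta: float = 3.0e-13       # metabolic proton production (mol/mm^3/day)
    q: float = 7.6258e-13        # CAIX proton production (mol/mm^3/day); 0 = knockout
    v: float = 5.0               # proton flux rate (1/day)
    h0: float = 3.98e-14         # proton concentration at physiological pH (mol/mm^3)
    h_thresh: float = 2.0e-13    # proton concentration at pH 6.7 (mol/mm^3)
    alpha: float = 0.1           # constitutive PD-L1 fraction
    beta: float = 0.1            # adaptive PD-L1 amplitude (<= 1 - alpha)
    zeta: float = 0.01e-3        # IFN-gamma saturation constant (pg/mm^3)

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"parameter {f.name} must be finite, got {val}")
            if val < 0.0:
                raise ValueError(f"parameter {f.name} must be non-negative, got {val}")
        for name in ("phi", "K", "vc", "d", "omega", "v", "h0", "zeta"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in ("sigma", "p", "alpha", "beta"):
            val = getattr(self, name)
            if val > 1.0:
                raise ValueError(f"parameter {name} must be in [0, 1], got {val}")
        if self.beta > 1.0 - self.alpha:
            raise ValueError(
                f"beta must not exceed 1 - alpha (PD-L1 fraction bounded by 1): "
                f"beta={self.beta}, 1-alpha={1.0 - self.alpha}"
            )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def knockout(self) -> "ModelParameters":
        """CAIX knockout variant: q = 0, everything else unchanged."""
        return self.replace(q=0.0)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class TumorState:
    """Snapshot of the extensive state with derived densities.

    Extensive fields: C, S (mm^3), EV (cells), IV (pg), HV (mol).
    Derived: V = C + S, densities E = EV/V, I = IV/V, H = HV/V, and pH.
    The model assumes tumor existence, so V must be positive to derive
    densities.
    """

    C: float
    S: float
    EV: float
    IV: float
    HV: float

    def __post_init__(self) -> None:
        for name in ("C", "S", "EV", "IV", "HV"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"extensive state {name} must be >= 0")
        if self.C + self.S <= 0.0:
            raise ValueError("tumor volume V = C + S must be positive")

    @property
    def V(self) -> float:
        return self.C + self.S

    @property
    def E(self) -> float:
        return self.EV / self.V

    @property
    def I(self) -> float:
        return self.IV / self.V

    @property
    def H(self) -> float:
        return self.HV / self.V

    @property
    def pH(self) -> float:
        return ph_from_proton(self.H)

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.S, self.EV, self.IV, self.HV], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "TumorState":
        C, S, EV, IV, HV = (float(x) for x in y)
        return cls(C=C, S=S, EV=EV, IV=IV, HV=HV)


# ---------------------------------------------------------------------------
# Algebraic helper functions
# ---------------------------------------------------------------------------

def logistic_growth(X: float, V: float, params: ModelParameters) -> float:
    """Logistic growth rate f(X) = phi * X * (1 - V/K) of a compartment X.

    ``V`` is the total tumor volume; the rate is negative when V exceeds the
    carrying capacity.
    """
    if X < 0.0 or V < 0.0:
        raise ValueError("volumes must be non-negative")
    return params.phi * X * (1.0 - V / params.K)


def pdl1_fraction(I: float, params: ModelParameters) -> float:
    """PD-L1+ fraction L = alpha + beta * I / (zeta + I).

    Monotone increasing in the IFN-gamma concentration ``I`` and bounded in
    [alpha, alpha + beta].
    """
    if I < 0.0:
        raise ValueError("IFN-gamma concentration must be non-negative")
    return params.alpha + params.beta * I / (params.zeta + I)


def acidosis_death_factor(H: float, params: ModelParameters) -> float:
    """Acidosis kill factor max(1 - h_thresh / H, 0).

    Zero at or below the pH-6.7 proton threshold, approaching one as the TME
    becomes very acidic.
    """
    if H <= 0.0:
        raise ValueError("proton concentration must be positive")
    return max(1.0 - params.h_thresh / H, 0.0)


def ph_from_proton(H: float) -> float:
    """Convert a proton concentration in mol/mm^3 to pH (mol/L based)."""
    if np.any(np.asarray(H) <= 0.0):
        raise ValueError("proton concentration must be positive")
    return -np.log10(np.asarray(H) * _MM3_TO_L) + 0.0


def proton_from_ph(ph: float) -> float:
    """Inverse of :func:`ph_from_proton`; returns mol/mm^3."""
    return 10.0 ** (-np.asarray(ph)) / _MM3_TO_L + 0.0


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def full_rhs(
    t: float,
    y: np.ndarray,
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
) -> np.ndarray:
    """Time derivative of the five-variable model at state ``y``.

    ``y`` = (C, S, E*V, I*V, H*V).  The caller is responsible for stopping
    integration before V = C + S reaches zero (elimination event); V <= 0
    raises, because densities are undefined without a tumor.
    """
    C, S, EV, IV, HV = y
    V = C + S
    if V <= 0.0:
        raise ValueError("tumor volume must be positive inside the RHS; "
                         "integrate with an elimination event")
    E = EV / V
    I = IV / V
    H = HV / V

    p = params
    d1, d2, d3 = effects.d1, effects.d2, effects.d3

    L = p.alpha + p.beta * I / (p.zeta + I)
    growth_factor = p.phi * (1.0 - V / p.K)
    fC = growth_factor * C
    fS = growth_factor * S
    kill = p.a_star * p.vc * (1.0 - p.p * (1.0 - d1) * L)
    acid = max(1.0 - p.h_thresh / H, 0.0) if H > 0.0 else 0.0

    dC = fC + p.sigma * fS - kill * C * E - p.n * C
    dS = (1.0 - p.sigma) * fS - kill * S * E
    dEV = (
        p.b_star * (1.0 + d2) * V
        - p.d * EV
        - p.a_star * p.p * (1.0 - d1) * L * V * E
        - p.eta * EV * acid
    )
    dIV = p.r * EV - p.omega * IV
    dHV = (p.delta + p.q * (1.0 - d3)) * V - p.v * (H - p.h0) * V
    return np.array([dC, dS, dEV, dIV, dHV])


def full_jacobian(
    t: float,
    y: np.ndarray,
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
) -> np.ndarray:
    """Analytic Jacobian of :func:`full_rhs` with respect to the state.

    Used by implicit integrators; the acidosis kink at H = h_thresh is
    one-sided (derivative zero below the threshold).
    """
    C, S, EV, IV, HV = y
    V = C + S
    if V <= 0.0:
        raise ValueError("tumor volume must be positive")
    E = EV / V
    I = IV / V
    H = HV / V
    p = params
    d1, d2, d3 = effects.d1, effects.d2, effects.d3

    L = p.alpha + p.beta * I / (p.zeta + I)
    dL_dI = p.beta * p.zeta / (p.zeta + I) ** 2
    kill = p.a_star * p.vc * (1.0 - p.p * (1.0 - d1) * L)
    dkill_dL = -p.a_star * p.vc * p.p * (1.0 - d1)
    acid = max(1.0 - p.h_thresh / H, 0.0)
    dacid_dH = p.h_thresh / H**2 if H > p.h_thresh else 0.0
    g = 1.0 - V / p.K

    # density partials w.r.t. (C, S, EV, IV, HV)
    dE = np.array([-EV / V**2, -EV / V**2, 1.0 / V, 0.0, 0.0])
    dI = np.array([-IV / V**2, -IV / V**2, 0.0, 1.0 / V, 0.0])
    dH = np.array([-HV / V**2, -HV / V**2, 0.0, 0.0, 1.0 / V])
    dV = np.array([1.0, 1.0, 0.0, 0.0, 0.0])

    J = np.zeros((5, 5))
    dL_k = dL_dI * dI
    dkill_k = dkill_dL * dL_k
    dg_k = -dV / p.K

    eC = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    eS = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    eEV = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    eIV = np.array([0.0, 0.0, 0.0, 1.0, 0.0])

    J[0] = (
        p.phi * (g * eC + C * dg_k)
        + p.sigma * p.phi * (g * eS + S * dg_k)
        - dkill_k * C * E - kill * (eC * E + C * dE)
        - p.n * eC
    )
    J[1] = (
        (1.0 - p.sigma) * p.phi * (g * eS + S * dg_k)
        - dkill_k * S * E - kill * (eS * E + S * dE)
    )
    J[2] = (
        p.b_star * (1.0 + d2) * dV
        - p.d * eEV
        - p.a_star * p.p * (1.0 - d1) * (dL_k * V * E + L * dV * E + L * V * dE)
        - p.eta * (eEV * acid + EV * dacid_dH * dH)
    )
    J[3] = p.r * eEV - p.omega * eIV
    J[4] = (p.delta + p.q * (1.0 - d3)) * dV - p.v * (dH * V + (H - p.h0) * dV)
    return J


def simplified_quasi_steady(
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
) -> float:
    """Quasi-steady proton concentration H* = (delta + q(1-d3) + v*h0) / v.

    In the reduced two-variable model, protons and IFN-gamma are fast and are
    replaced by their algebraic steady states; H* is independent of the tumor
    and T-cell variables.
    """
    p = params
    return (p.delta + p.q * (1.0 - effects.d3) + p.v * p.h0) / p.v


def simplified_rhs(
    t: float,
    y: np.ndarray,
    params: ModelParameters,
    effects: TreatmentEffects = NO_TREATMENT,
) -> np.ndarray:
    """Reduced two-variable model: all cancer cells are stem cells.

    ``y`` = (S, E*S).  IFN-gamma and protons are at quasi-steady state:
    I = r*E/omega and H = H* from :func:`simplified_quasi_steady`.  Treatment
    folds into the infiltration (1 + d2), the PD-1 fraction p*(1 - d1), and
    the CAIX production q*(1 - d3).
    """
    S, x = y
    if S <= 0.0:
        raise ValueError("simplified model requires S > 0")
    p = params
    d1, d2 = effects.d1, effects.d2

    E = x / S
    I = p.r * E / p.omega
    L = p.alpha + p.beta * I / (p.zeta + I)
    H = simplified_quasi_steady(params, effects)
    acid = max(1.0 - p.h_thresh / H, 0.0)

    dS = p.phi * S * (1.0 - S / p.K) - p.a_star * p.vc * (1.0 - p.p * (1.0 - d1) * L) * S * E
    dx = (
        p.b_star * (1.0 + d2) * S
        - p.d * x
        - p.a_star * p.p * (1.0 - d1) * L * x
        - p.eta * x * acid
    )
    return np.array([dS, dx])
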