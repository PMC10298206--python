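"""Model-faithful synthetic cohort data emulating the murine study design.

Six cohorts — CAIX-expressing control, CAIX knockout, treatment-free vehicle,
anti-CAIX, checkpoint-inhibitor (ICI), and anti-CAIX+ICI — with five
measurement days each (30 points total).  Volumes are simulated from the
model at the design's true parameters and perturbed with multiplicative
Gaussian noise V * (1 + eps), eps ~ N(0, CV^2), truncated so volumes stay
positive; replicate animals are averaged, emulating cohort-mean growth
curves.  The defaults reproduce the calibration design: fitted parameter
values, per-cohort inoculation fractions, and the published measurement-day
grids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence
import warnings

import numpy as np

from . import presets
from .calibration import (
    CohortDataset,
    FitSpec,
    fitted_parameters,
    multistart_fit,
    predict_cohort,
)
from .core import ModelParameters, TreatmentEffects

__all__ = ["SyntheticDesign", "default_design", "generate", "recovery_experiment"]

#: Volumes are truncated at this fraction of the noise-free value so the
#: scaled-residual loss (which divides by data) stays defined.
TRUNCATION_FLOOR = 1e-3


@dataclass(frozen=True)
class CohortSpec:
    label: str
    caix_active: bool
    active: tuple[bool, bool, bool]
    days: tuple[float, ...]
    inoc_cells: float


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground truth and noise model for a synthetic cohort study."""

    cohorts: tuple[CohortSpec, ...]
    true_params: ModelParameters
    true_effects: TreatmentEffects = presets.FITTED_EFFECTS
    csc_fraction: float = presets.INIT_CSC_FRACTION
    cv: float = 0.10
    replicates: int = 1
    treatment_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_points(self) -> int:
        return sum(len(c.days) for c in self.cohorts)

    def replace(self, **kw) -> "SyntheticDesign":
        return replace(self, **kw)


def default_design(
    cv: float = 0.10,
    replicates: int = 1,
    true_params: ModelParameters | None = None,
) -> SyntheticDesign:
    """The six-cohort, thirty-point design of the murine calibration study.

    True parameters default to the fitted set (with the recalibrated growth
    rate, so cohort curves evolve on realistic multi-week time scales).
    """
    cohorts = tuple(
        CohortSpec(label=lbl, caix_active=c["caix_active"], active=c["active"],
                   days=tuple(c["days"]), inoc_cells=c["inoc_cells"])
        for lbl, c in presets.COHORTS.items()
    )
    return SyntheticDesign(
        cohorts=cohorts,
        true_params=true_params or fitted_parameters(),
        cv=cv,
        replicates=replicates,
    )


def generate(
    design: SyntheticDesign,
    seed: int | np.random.Generator = 0,
) -> list[CohortDataset]:
    """Simulate the design and return noisy cohort datasets.

    Reproducible bit-for-bit for a given seed.  With cv = 0 the volumes equal
    the noise-free model predictions exactly.  A cohort eliminated before its
    first measurement day is reported with a warning (its volumes would not
    be usable by the scaled loss).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for c in design.cohorts:
        cohort = CohortDataset(
            label=c.label, caix_active=c.caix_active, active=c.active,
            days=c.days, volumes=tuple(1.0 for _ in c.days))  # placeholder
        clean = predict_cohort(
            design.true_params, cohort, c.inoc_cells, design.csc_fraction,
            design.true_effects, treatment_window=design.treatment_window)
        if np.any(clean <= 0):
            warnings.warn(
                f"cohort {c.label}: tumor eliminated before a measurement day; "
                "volumes floored for loss compatibility")
            clean = np.maximum(clean, TRUNCATION_FLOOR)
        if design.cv > 0:
            eps = rng.normal(0.0, design.cv, size=(design.replicates, len(clean)))
            noisy = clean * (1.0 + eps)
            noisy = np.maximum(noisy, TRUNCATION_FLOOR * clean)
            vols = noisy.mean(axis=0)
            sem = (tuple(noisy.std(axis=0, ddof=1) / np.sqrt(design.replicates))
                   if design.replicates > 1 else None)
        else:
            vols = clean.copy()
            sem = None
        out.append(CohortDataset(
            label=c.label, caix_active=c.caix_active, active=c.active,
            days=c.days, volumes=tuple(float(v) for v in vols), sem=sem))
    return out


def _truth_vector(design: SyntheticDesign, spec: FitSpec) -> np.ndarray:
    shared = dict(
        a_star=design.true_params.a_star, b_star=design.true_params.b_star,
        eta=design.true_params.eta, n=design.true_params.n,
        q=design.true_params.q, d1=design.true_effects.d1,
        d2=design.true_effects.d2, d3=design.true_effects.d3,
        csc_fraction=design.csc_fraction,
    )
    vec = [shared[name] for name in spec.free]
    vec += [c.inoc_cells for c in design.cohorts]
    return np.asarray(vec, dtype=float)


def recovery_experiment(
    design: SyntheticDesign,
    fit_spec: FitSpec,
    seed: int = 0,
    base_params: ModelParameters | None = None,
    include_truth_start: bool = False,
) -> dict:
    """Generate -> fit -> compare: closes the calibration loop.

    Returns a report with the fitted result, per-parameter relative errors
    against the design truth, the refit loss, and the predicted-curve RMSE
    relative to the noise-free truth curves.  Identifiability is reported,
    not assumed: a parameter's relative error is meaningful only where the
    loss is locally sensitive to it (see the curvature entries).
    """
    base = base_params or design.true_params
    datasets = generate(design, seed)
    truth = _truth_vector(design, fit_spec)
    result = multistart_fit(
        datasets, fit_spec, base_params=base,
        x0=truth if include_truth_start else None)

    theta = np.array([result.best_params[n] for n in result.names])
    rel_err = {
        n: float(abs(t - f) / abs(t)) if t != 0 else float(abs(f))
        for n, t, f in zip(result.names, truth, theta)
    }

    # predicted-curve error against noise-free truth
    from .calibration import _residual_fn  # local import: private helper
    _, predict = _residual_fn(datasets, fit_spec, base)
    fitted_curves = predict(theta)
    truth_curves = predict(truth)
    rmse = float(np.sqrt(np.mean((fitted_curves - truth_curves) ** 2)))
    rel_rmse = float(np.sqrt(np.mean(
        ((fitted_curves - truth_curves) / truth_curves) ** 2)))

    # local curvature of the loss along each parameter (identifiability flag)
    curvature = {}
    def loss_at(th):
        r = (predict(th) - np.concatenate([np.asarray(c.volumes) for c in datasets])) \
            / np.concatenate([np.asarray(c.volumes) for c in datasets])
        return float(np.dot(r, r))
    l0 = loss_at(theta)
    for k, name in enumerate(result.names):
        h = max(abs(theta[k]) * 1e-2, 1e-14)
        tp = theta.copy(); tp[k] = min(tp[k] + h, fit_spec.bound_for(name)[1])
        tm = theta.copy(); tm[k] = max(tm[k] - h, fit_spec.bound_for(name)[0])
        curvature[name] = float(loss_at(tp) + loss_at(tm) - 2 * l0)

    return dict(
        result=result,
        refit_loss=result.best_loss,
        relative_errors=rel_err,
        curve_rmse=rmse,
        curve_relative_rmse=rel_rmse,
        curvature=curvature,
        seed=seed,
    )
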