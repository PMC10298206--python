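"""Packaged study presets: published parameter values, cohort design, bounds.

Static data only — no simulation here.  The fitted free-parameter values and
the literature constants together form :class:`caixsim.core.ModelParameters`'
defaults; this module additionally records the fitting bounds, the murine
cohort design used for calibration, the illustration settings of the
phase-portrait figure, the treatment doses of the therapy-comparison
experiments, and the published long-horizon volume anchors used to
recalibrate the growth rate (see :func:`caixsim.calibration.recalibrate_phi`).
"""

from __future__ import annotations

from .core import ModelParameters, TreatmentEffects

__all__ = [
    "printed_parameters",
    "boosted_immunity_parameters",
    "FIT_BOUNDS",
    "COHORTS",
    "COHORT_LABELS",
    "INOC_CELL_COUNT",
    "DEFAULT_INOC_FRACTION",
    "STUDY_DOSES",
    "GROWTH_ANCHORS",
    "CTRL_KO_DAYS",
    "TREATMENT_DAYS",
]

#: Number of tumor cells inoculated subcutaneously in the murine experiments.
INOC_CELL_COUNT = 5.0e5

#: Standardized inoculation fraction used for therapy comparison.
DEFAULT_INOC_FRACTION = 0.1

#: Fitted fraction of initiating cells that are stem cells.
INIT_CSC_FRACTION = 3.083e-5

#: Measurement days for the CAIX-expressing vs knockout growth comparison.
CTRL_KO_DAYS = (6.0, 8.0, 11.0, 13.0, 15.0)

#: Measurement days for the treatment-cohort comparison.
TREATMENT_DAYS = (10.0, 12.0, 14.0, 17.0, 19.0)

#: Treatment doses of the therapy-window experiments.
STUDY_DOSES = TreatmentEffects(d1=0.4, d2=4.0, d3=1.0)


def printed_parameters() -> ModelParameters:
    """The published parameter set: literature constants + fitted values.

    Note: with the printed growth rate phi = 2417.2 / day the logistic
    transient saturates within hours; for multi-week dynamics use
    :func:`caixsim.calibration.fitted_parameters`, which recalibrates phi
    against the published long-horizon volumes.
    """
    return ModelParameters()


def boosted_immunity_parameters(phi: float | None = None) -> ModelParameters:
    """Phase-portrait illustration settings: a boosted immune response.

    T-cell infiltration raised to b* = 3e4 (an immunotherapy-boosted immune
    response) and the acidosis impact raised to eta = 1e6 to separate the
    steady states visually; all other values from the fitted set.  ``phi``
    defaults to the printed value; pass the recalibrated rate for dynamics
    on realistic time scales.
    """
    p = ModelParameters(b_star=3.0e4, eta=1.0e6)
    if phi is not None:
        p = p.replace(phi=phi)
    return p


#: Fitting bounds of the free parameters (lower, upper), as published.
#: Inoculation fractions are bounded in [0, 1] per cohort; the model is
#: undefined at an exactly zero initial volume, so optimizers clip the lower
#: bound to a tiny positive epsilon.
FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "a_star": (0.0, 1.0e3),
    "b_star": (0.0, 6.0e3),
    "eta": (0.0, 1.0e6),
    "n": (0.0, 10.0),
    "q": (5.0e-13, 3.0e-12),
    "d1": (0.0, 1.0),
    "d2": (0.0, 20.0),
    "d3": (0.0, 1.0),
    "csc_fraction": (0.0, 1.0),
    "inoc_cells": (0.0, 1.0),
}

#: Six murine cohorts: label -> (CAIX active, (d1,d2,d3) active flags,
#: measurement days, fitted inoculation fraction).  The published per-cohort
#: inoculation-fraction symbols map as: ic_ctrl -> ctrl, ic_caixko -> caixko,
#: ic_v (vehicle) -> TF, ic_s (SLC-0111) -> aCAIX, ic_pc -> ICI,
#: ic_pcs -> aCAIX+ICI.
COHORTS: dict[str, dict] = {
    "ctrl": dict(caix_active=True, active=(False, False, False),
                 days=CTRL_KO_DAYS, inoc_cells=0.210),
    "caixko": dict(caix_active=False, active=(False, False, False),
                   days=CTRL_KO_DAYS, inoc_cells=0.336),
    "TF": dict(caix_active=True, active=(False, False, False),
               days=TREATMENT_DAYS, inoc_cells=0.044),
    "aCAIX": dict(caix_active=True, active=(False, False, True),
                  days=TREATMENT_DAYS, inoc_cells=0.027),
    "ICI": dict(caix_active=True, active=(True, True, False),
                days=TREATMENT_DAYS, inoc_cells=0.007),
    "aCAIX+ICI": dict(caix_active=True, active=(True, True, True),
                      days=TREATMENT_DAYS, inoc_cells=0.004),
}

COHORT_LABELS = tuple(COHORTS)

#: Fitted treatment-effect values (applied on cohorts where active).
FITTED_EFFECTS = TreatmentEffects(d1=0.028, d2=0.011, d3=0.066)

#: Published long-horizon tumor-volume summaries (mm^3) used to recalibrate
#: the growth rate phi: each entry is
#: (inoc_cells fraction, CAIX knockout?, statistic, day horizon, volume).
#: "max" is the maximum over the run; "end" the volume at the horizon.
GROWTH_ANCHORS = (
    (0.1, False, "max", 200.0, 1179.0),    # standardized control, peak volume
    (0.336, True, "end", 200.0, 759.0),    # knockout cohort, plateau
    (0.210, False, "end", 200.0, 1179.0),  # control cohort, plateau
)
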