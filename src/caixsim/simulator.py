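"""Forward simulation of the full model under piecewise-constant treatment.

Integration is segment-by-segment at treatment-window boundaries so the
solver never sees a discontinuous right-hand side, with a terminal event that
stops the run when the tumor volume falls below the elimination threshold
(the model is undefined at V = 0).  A stiff-capable integrator (LSODA by
default) is required: rate constants span thirteen orders of magnitude and
the acidosis response is fast compared with cell turnover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (
    NO_TREATMENT,
    ModelParameters,
    TreatmentEffects,
    TumorState,
    full_jacobian,
    full_rhs,
    ph_from_proton,
)
from . import presets

__all__ = [
    "InoculationSpec",
    "TreatmentSchedule",
    "Trajectory",
    "SolverOptions",
    "initial_state",
    "simulate",
    "run_treatment_arms",
    "dose_sweep",
    "detect_elimination",
    "ARM_NAMES",
]

#: Default elimination threshold (mm^3) — well below one cell volume.
ELIMINATION_THRESHOLD = 1.0e-6

#: Per-component absolute tolerances for (C, S, E*V, I*V, H*V).  Scaled to
#: the typical magnitude of each extensive variable (volumes up to ~1e3 mm^3,
#: T cells up to ~1e5, IFN-gamma ~1e1 pg, protons ~1e-10 mol).
DEFAULT_ATOL = (1.0e-12, 1.0e-12, 1.0e-7, 1.0e-10, 1.0e-22)

DEFAULT_RTOL = 1.0e-8


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = DEFAULT_RTOL
    atol: tuple = DEFAULT_ATOL
    elimination_threshold: float = ELIMINATION_THRESHOLD
    use_jacobian: bool = True
    max_step: float = np.inf


@dataclass(frozen=True)
class InoculationSpec:
    """How many inoculated cells initiate the tumor, and their composition.

    ``n_inoculated`` cells are injected; only the fraction ``inoc_cells``
    initiates the tumor, and a fraction ``csc_fraction`` of those initiating
    cells are cancer stem cells.  Initial tumor volume is
    V0 = n_inoculated * inoc_cells * vc.
    """

    n_inoculated: float = presets.INOC_CELL_COUNT
    inoc_cells: float = presets.DEFAULT_INOC_FRACTION
    csc_fraction: float = presets.INIT_CSC_FRACTION

    def __post_init__(self) -> None:
        if self.n_inoculated <= 0:
            raise ValueError("n_inoculated must be positive")
        if not (0.0 <= self.inoc_cells <= 1.0):
            raise ValueError("inoc_cells must be in [0, 1]")
        if not (0.0 <= self.csc_fraction <= 1.0):
            raise ValueError("csc_fraction must be in [0, 1]")

    def initial_volume(self, params: ModelParameters) -> float:
        return self.n_inoculated * self.inoc_cells * params.vc


class TreatmentSchedule:
    """Ordered, non-overlapping treatment windows with constant effects.

    Windows use the half-open convention [t_start, t_end): effects switch on
    at t_start and off at t_end.  Outside all windows the effects are zero.
    """

    def __init__(self, windows: Sequence[tuple[float, float, TreatmentEffects]] = ()):
        wins = sorted(((float(a), float(b), e) for a, b, e in windows), key=lambda w: w[0])
        for (a, b, _e) in wins:
            if not a < b:
                raise ValueError(f"window must have t_start < t_end, got [{a}, {b})")
        for (_, b0, _), (a1, _, _) in zip(wins, wins[1:]):
            if a1 < b0:
                raise ValueError("treatment windows must not overlap")
        self.windows = tuple(wins)

    @classmethod
    def single(cls, t_start: float, t_end: float, effects: TreatmentEffects) -> "TreatmentSchedule":
        return cls([(t_start, t_end, effects)])

    def effects_at(self, t: float) -> TreatmentEffects:
        for a, b, e in self.windows:
            if a <= t < b:
                return e
        return NO_TREATMENT

    def boundaries(self, t0: float, t1: float) -> list[float]:
        pts = {t0, t1}
        for a, b, _ in self.windows:
            for t in (a, b):
                if t0 < t < t1:
                    pts.add(t)
        return sorted(pts)

    def to_list(self) -> list[dict]:
        return [dict(t_start=a, t_end=b, d1=e.d1, d2=e.d2, d3=e.d3)
                for a, b, e in self.windows]


@dataclass
class Trajectory:
    """Integrated solution of the full model.

    ``times`` are strictly increasing days; ``states`` is a (n, 5) array of
    extensive state rows (C, S, E*V, I*V, H*V).  If the tumor was eliminated,
    no states are reported after ``t_eliminated``.
    """

    times: np.ndarray
    states: np.ndarray
    eliminated: bool
    t_eliminated: float | None
    diagnostics: list = field(default_factory=list)

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    @property
    def final_state(self) -> TumorState:
        return TumorState.from_array(self.states[-1])

    @property
    def final_volume(self) -> float:
        return float(self.V[-1])

    def volume_at(self, days: Sequence[float]) -> np.ndarray:
        """Tumor volume at the requested days (zero after elimination)."""
        days = np.asarray(days, dtype=float)
        out = np.interp(days, self.times, self.V, right=float(self.V[-1]))
        if self.eliminated and self.t_eliminated is not None:
            out[days >= self.t_eliminated] = 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        V = self.V
        with np.errstate(divide="ignore"):
            H = self.states[:, 4] / V
            pH = np.where(H > 0, -np.log10(np.maximum(H, 1e-300) * 1e6), np.nan)
        return pd.DataFrame({
            "t": self.times,
            "C": self.states[:, 0],
            "S": self.states[:, 1],
            "V": V,
            "EV": self.states[:, 2],
            "IV": self.states[:, 3],
            "HV": self.states[:, 4],
            "E": self.states[:, 2] / V,
            "I": self.states[:, 3] / V,
            "H": H,
            "pH": pH,
        })


def initial_state(inoc: InoculationSpec, params: ModelParameters) -> TumorState:
    """Inoculation state: tumor split between CC and CSC; no immune
    infiltrate, no cytokine, physiological pH.

    E*V(0) = I*V(0) = 0 and H(0) = h0: infiltration and acidification build
    up through the dynamics within days given the fast rates.
    """
    V0 = inoc.initial_volume(params)
    if V0 <= 0.0:
        raise ValueError("initial tumor volume must be positive "
                         "(inoc_cells = 0 leaves the model undefined)")
    return TumorState(
        C=(1.0 - inoc.csc_fraction) * V0,
        S=inoc.csc_fraction * V0,
        EV=0.0,
        IV=0.0,
        HV=params.h0 * V0,
    )


def detect_elimination(state, threshold: float = ELIMINATION_THRESHOLD) -> bool:
    """True iff the tumor volume is strictly below the threshold."""
    if isinstance(state, TumorState):
        V = state.V
    else:
        y = np.asarray(state, dtype=float)
        V = float(y[0] + y[1]) if y.ndim == 1 else float(y)
    return V < threshold


def simulate(
    params: ModelParameters,
    inoc: InoculationSpec | None = None,
    schedule: TreatmentSchedule | None = None,
    t_final: float = 200.0,
    solver: SolverOptions | None = None,
    t_eval: Sequence[float] | None = None,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the full model from inoculation to ``t_final`` days.

    The time axis is split at treatment-window boundaries; each segment is
    integrated with constant effects.  A terminal event ends the run if the
    volume drops below the elimination threshold.  ``t_eval`` optionally
    restricts the reported time points (always including segment ends);
    otherwise all solver steps are reported.

    Raises RuntimeError if the solver fails to converge on any segment.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    solver = solver or SolverOptions()
    schedule = schedule or TreatmentSchedule()
    if y0 is None:
        inoc = inoc or InoculationSpec()
        y0 = initial_state(inoc, params).as_array()
    else:
        y0 = np.asarray(y0, dtype=float)

    thr = solver.elimination_threshold

    def elim_event(t, y):
        return y[0] + y[1] - thr

    elim_event.terminal = True
    elim_event.direction = -1

    bounds = schedule.boundaries(0.0, float(t_final))
    times = [np.array([0.0])]
    states = [y0[None, :]]
    diagnostics = []
    eliminated = False
    t_elim = None
    y = y0

    for a, b in zip(bounds[:-1], bounds[1:]):
        eff = schedule.effects_at(a)

        def f(t, yy, _e=eff):
            return full_rhs(t, yy, params, _e)

        kwargs = dict(
            method=solver.method,
            rtol=solver.rtol,
            atol=list(solver.atol),
            events=elim_event,
            max_step=solver.max_step,
        )
        if solver.use_jacobian and solver.method in ("LSODA", "BDF", "Radau"):
            kwargs["jac"] = lambda t, yy, _e=eff: full_jacobian(t, yy, params, _e)
        if t_eval is not None:
            te = np.asarray(t_eval, dtype=float)
            seg = np.unique(np.concatenate([te[(te > a) & (te <= b)], [b]]))
            kwargs["t_eval"] = seg
        sol = solve_ivp(f, (a, b), y, **kwargs)
        sol_t = np.asarray(sol.t)
        sol_y = np.asarray(sol.y)
        diagnostics.append(dict(segment=(a, b), status=sol.status,
                                message=sol.message, nfev=sol.nfev,
                                njev=sol.njev, nsteps=sol_t.size))
        if sol.status == -1:
            raise RuntimeError(
                f"integration failed on segment [{a}, {b}): {sol.message}")
        if sol_t.size > 0:
            keep = sol_t > a
            times.append(sol_t[keep])
            states.append(sol_y.T[keep])
            y = sol_y[:, -1]
        if sol.status == 1:  # elimination event fired
            eliminated = True
            t_elim = float(sol.t_events[0][0])
            break

    return Trajectory(
        times=np.concatenate(times),
        states=np.vstack(states),
        eliminated=eliminated,
        t_eliminated=t_elim,
        diagnostics=diagnostics,
    )


#: Treatment-arm names of the therapy-comparison experiments.
ARM_NAMES = ("control", "aCAIX", "ICI", "aCAIX+aPD1", "aCAIX+aCTLA4", "aCAIX+ICI")


def _arm_effects(arm: str, doses: TreatmentEffects) -> TreatmentEffects:
    table = {
        "control": TreatmentEffects(),
        "aCAIX": TreatmentEffects(d3=doses.d3),
        "ICI": TreatmentEffects(d1=doses.d1, d2=doses.d2),
        "aCAIX+aPD1": TreatmentEffects(d1=doses.d1, d3=doses.d3),
        "aCAIX+aCTLA4": TreatmentEffects(d2=doses.d2, d3=doses.d3),
        "aCAIX+ICI": TreatmentEffects(d1=doses.d1, d2=doses.d2, d3=doses.d3),
    }
    return table[arm]


def run_treatment_arms(
    params: ModelParameters,
    inoc: InoculationSpec | None = None,
    duration: float = 14.0,
    doses: TreatmentEffects = presets.STUDY_DOSES,
    t_start: float = 20.0,
    t_final: float = 200.0,
    solver: SolverOptions | None = None,
) -> Mapping[str, Trajectory]:
    """Six therapy arms: control, monotherapies, and combinations.

    Tumors grow untreated until ``t_start`` (day 20); each arm then receives
    its subset of the dose triplet over [t_start, t_start + duration), and
    the run continues to ``t_final``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    inoc = inoc or InoculationSpec()
    out = {}
    for arm in ARM_NAMES:
        eff = _arm_effects(arm, doses)
        sched = (TreatmentSchedule() if eff.is_none
                 else TreatmentSchedule.single(t_start, t_start + duration, eff))
        out[arm] = simulate(params, inoc, sched, t_final=t_final, solver=solver)
    return out


def dose_sweep(
    params: ModelParameters,
    inoc: InoculationSpec | None = None,
    d1_grid: Sequence[float] | None = None,
    d2_grid: Sequence[float] | None = None,
    caix_knockout: bool = False,
    duration: float = 90.0,
    t_start: float = 20.0,
    eval_day: float = 200.0,
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """Endpoint tumor volume over a grid of checkpoint-inhibitor doses.

    Each grid cell simulates treatment with (d1, d2) over
    [t_start, t_start + duration) and reports the volume at ``eval_day``.
    Knockout mode sets q = 0.  Returns a long-format frame with columns
    d1, d2, volume, eliminated.
    """
    if d1_grid is None:
        d1_grid = np.linspace(0.0, 1.0, 11)
    if d2_grid is None:
        d2_grid = np.linspace(0.0, 20.0, 11)
    inoc = inoc or InoculationSpec()
    pars = params.knockout() if caix_knockout else params
    rows = []
    for d1 in d1_grid:
        for d2 in d2_grid:
            eff = TreatmentEffects(d1=float(d1), d2=float(d2))
            sched = (TreatmentSchedule() if eff.is_none
                     else TreatmentSchedule.single(t_start, t_start + duration, eff))
            traj = simulate(pars, inoc, sched, t_final=eval_day, solver=solver)
            vol = 0.0 if traj.eliminated else traj.final_volume
            rows.append(dict(d1=float(d1), d2=float(d2), volume=vol,
                             eliminated=traj.eliminated))
    return pd.DataFrame(rows)
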