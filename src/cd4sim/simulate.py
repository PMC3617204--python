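"""Time-course integration, steady states, and parameter scans.

Three simulation modes are supported: plain time courses, parameter scans
(endpoint readouts across a grid of values of one kinetic constant or one
boundary input), and the combined scan-of-time-courses mode in which a full
trajectory is retained for every grid value.

The integrator is a stiff-capable implicit solver (LSODA) with tight
default tolerances (rtol 1e-8, atol 1e-10): the Hill nonlinearities and the
separation between receptor-level (minutes-hours) and transcriptional
(tens of hours) timescales make the system moderately stiff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import CompiledModel, ModelDefinition

DEFAULT_T_END = 100.0       # hours; default simulation horizon
DEFAULT_N_POINTS = 1000
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SolverError(RuntimeError):
    """Integration failure; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time-indexed state of all dynamic species from one simulation."""

    time: np.ndarray                    # hours, strictly increasing
    states: np.ndarray                  # (n_time, n_dynamic) levels in a.u.
    species_ids: list[str]              # column order of `states`
    boundary_levels: dict[str, float]   # inputs held fixed during the run
    solver: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._col = {sid: j for j, sid in enumerate(self.species_ids)}

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.states[:, self._col[species_id]]

    @property
    def final_state(self) -> dict[str, float]:
        return {sid: float(self.states[-1, j]) for sid, j in self._col.items()}

    def at_time(self, t: float) -> dict[str, float]:
        """State interpolated at time t (linear)."""
        return {
            sid: float(np.interp(t, self.time, self.states[:, j]))
            for sid, j in self._col.items()
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns time, species, level."""
        frames = [
            pd.DataFrame({"time": self.time, "species": sid, "level": self[sid]})
            for sid in self.species_ids
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ScanResult:
    """Per-grid-value readouts of a parameter scan."""

    parameter: str
    grid: np.ndarray
    readouts: pd.DataFrame              # one row per grid value, readout columns
    trajectories: list[Trajectory] | None = None
    failures: list[tuple[float, str]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        df = self.readouts.copy()
        df.insert(0, self.parameter, self.grid)
        df.to_csv(path, index=False)


def _resolve_scan_target(model: ModelDefinition, name: str) -> str:
    """A scan target is either a kinetic parameter or a boundary species."""
    if name in model.parameters:
        return "parameter"
    try:
        sp = model.species_by_id(name)
    except KeyError:
        raise KeyError(f"{name!r} is neither a model parameter nor a species")
    if not sp.is_boundary:
        raise KeyError(f"species {name!r} is dynamic; only boundary levels can be scanned")
    return "boundary"


def simulate_time_course(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None = None,
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
    *,
    initial_state: Mapping[str, float] | None = None,
    knockout: Iterable[str] = (),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    compiled: CompiledModel | None = None,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the model on [0, t_end] with boundary species clamped.

    Parameters
    ----------
    model : ModelDefinition
    recipe : mapping species id -> level
        Boundary levels (the stimulus); only boundary species may be keyed.
    t_end, n_points : horizon (h) and output-grid size.
    initial_state : optional dynamic-state override (species id -> level),
        used to continue from a previously committed state.
    knockout : species (or parameter) ids made signaling-dead.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    doses = dict(recipe or {})
    for sid, level in doses.items():
        if level < 0:
            raise ValueError(f"dose for {sid} must be >= 0")
        if not model.species_by_id(sid).is_boundary:
            raise ValueError(f"recipe keys must be boundary species; {sid} is dynamic")

    cm = compiled if compiled is not None else CompiledModel(model, knockout=knockout)
    y0 = cm.y0.copy()
    if initial_state:
        for sid, level in initial_state.items():
            y0[cm.dynamic_ids.index(sid)] = level

    f = cm.rhs_for(doses)
    grid = np.asarray(t_eval, float) if t_eval is not None else np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        f, (0.0, max(t_end, grid[-1])), y0, method="LSODA", t_eval=grid, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SolverError(
            f"integration failed: {sol.message}",
            last_time=float(sol.t[-1]) if sol.t.size else 0.0,
        )
    return Trajectory(
        time=sol.t,
        states=sol.y.T,
        species_ids=list(cm.dynamic_ids),
        boundary_levels=doses,
        solver={
            "method": "LSODA",
            "rtol": rtol,
            "atol": atol,
            "success": bool(sol.success),
            "nfev": int(sol.nfev),
        },
    )


def steady_state(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None = None,
    *,
    knockout: Iterable[str] = (),
    tol: float = 1e-8,
    t_max: float = 20000.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> dict[str, float]:
    """Steady state reached from the initial condition under a recipe.

    Integrates in expanding windows until the RHS infinity-norm falls below
    ``tol``, then polishes with a Newton-type root solve.  Raises
    :class:`SolverError` on non-convergence, suggesting a time-course run.
    """
    doses = dict(recipe or {})
    cm = CompiledModel(model, knockout=knockout)
    f = cm.rhs_for(doses)
    y = cm.y0.copy()
    t0, window = 0.0, 200.0
    while t0 < t_max:
        sol = solve_ivp(f, (t0, t0 + window), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(f"integration failed at t={sol.t[-1]:.1f}", float(sol.t[-1]))
        y = sol.y[:, -1]
        t0 += window
        window *= 2.0
        if np.max(np.abs(f(t0, y))) < tol:
            break
    else:
        raise SolverError(
            "steady state not reached; consider simulate_time_course with a long horizon",
            t_max,
        )
    # Newton polish; accept only a root in the immediate neighborhood of the
    # integrated state (unstimulated pool species leave the Jacobian singular
    # along neutral directions, where hybr may wander to a different branch)
    res = root(lambda x: f(0.0, x), y, method="hybr")
    if (
        res.success
        and np.all(res.x > -1e-9)
        and np.max(np.abs(f(0.0, res.x))) < tol
        and np.max(np.abs(res.x - y)) < 1e-3 * (1.0 + np.max(np.abs(y)))
    ):
        y = res.x
    return {sid: float(max(v, 0.0)) for sid, v in zip(cm.dynamic_ids, y)}


def parameter_scan(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None,
    parameter: str,
    grid: Sequence[float],
    readouts: Sequence[str],
    *,
    t_end: float = DEFAULT_T_END,
    n_points: int = 200,
    initial_state: Mapping[str, float] | None = None,
    knockout: Iterable[str] = (),
) -> ScanResult:
    """Endpoint readouts across a grid of one parameter or boundary input.

    Each grid point re-simulates from the same initial state (unless a
    continue-from ``initial_state`` is supplied, as in the plasticity
    protocol).  Per-point solver failures are recorded and the scan
    continues.
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    kind = _resolve_scan_target(model, parameter)
    grid_arr = np.asarray(list(grid), float)
    rows, failures = [], []
    for value in grid_arr:
        try:
            if kind == "parameter":
                m = model.with_parameters({parameter: float(value)})
                doses = dict(recipe or {})
            else:
                m = model
                doses = dict(recipe or {})
                doses[parameter] = float(value)
            traj = simulate_time_course(
                m, doses, t_end=t_end, n_points=n_points,
                initial_state=initial_state, knockout=knockout,
            )
            end = traj.final_state
            rows.append({r: end[r] for r in readouts})
        except SolverError as err:
            failures.append((float(value), str(err)))
            rows.append({r: np.nan for r in readouts})
    return ScanResult(
        parameter=parameter,
        grid=grid_arr,
        readouts=pd.DataFrame(rows),
        failures=failures,
    )


def scan_time_course(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None,
    parameter: str,
    grid: Sequence[float],
    t_end: float = DEFAULT_T_END,
    *,
    n_points: int = DEFAULT_N_POINTS,
    initial_state: Mapping[str, float] | None = None,
    knockout: Iterable[str] = (),
) -> list[Trajectory]:
    """Combined scan x time-course: one full trajectory per grid value."""
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    kind = _resolve_scan_target(model, parameter)
    out = []
    for value in grid:
        if kind == "parameter":
            m = model.with_parameters({parameter: float(value)})
            doses = dict(recipe or {})
        else:
            m = model
            doses = dict(recipe or {})
            doses[parameter] = float(value)
        out.append(
            simulate_time_course(
                m, doses, t_end=t_end, n_points=n_points,
                initial_state=initial_state, knockout=knockout,
            )
        )
    return out
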