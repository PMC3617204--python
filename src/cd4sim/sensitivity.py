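"""Local sensitivity analysis normalized as control coefficients.

Central finite differences of readout levels with respect to kinetic
constants, normalized as C[y, p] = (p/y) * dy/dp, the control-coefficient
convention of metabolic control analysis.  Defaults follow a time-course
subtask: readouts are evaluated at t = 100 h; a steady-state mode is
available.  The default parameter set is the per-reaction primary rate
constant (vmax for Hill laws, k for mass action), i.e. sensitivities with
respect to the reaction rates of the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelDefinition
from .simulate import simulate_time_course, steady_state

DELTA_FACTOR = 1e-4     # relative finite-difference step
DELTA_MIN = 1e-12       # absolute step floor


@dataclass
class SensitivityReport:
    coefficients: pd.DataFrame          # readouts x parameters, normalized C
    raw_derivatives: pd.DataFrame       # dy/dp (same shape)
    unnormalized: list[tuple[str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def ranking(self) -> pd.Series:
        """Parameters sorted by aggregate |C| (max over readouts); ties
        broken by parameter name."""
        agg = self.coefficients.abs().max(axis=0)
        order = sorted(agg.index, key=lambda p: (-agg[p], p))
        return agg.loc[order]

    def to_csv(self, path) -> None:
        self.coefficients.to_csv(path)


def primary_rate_constants(model: ModelDefinition) -> list[str]:
    """One rate constant per reaction: vmax for Hill laws, k for mass action."""
    names = []
    for rxn in model.reactions:
        law = rxn.rate_law
        names.append(law.k if law.kind == "mass_action" else law.vmax)
    return names


def local_sensitivities(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None,
    readouts: Sequence[str],
    parameters: Sequence[str] | None = None,
    *,
    delta_factor: float = DELTA_FACTOR,
    delta_min: float = DELTA_MIN,
    t_eval: float = 100.0,
    mode: str = "time_course",
    rtol: float = 1e-8,
) -> SensitivityReport:
    """Normalized local sensitivities of readouts with respect to parameters.

    Central finite differences with per-parameter step
    ``max(delta_factor * |p|, delta_min)``.  Readouts with zero value are
    reported as unnormalized derivatives and flagged in the report rather
    than dividing by zero.

    Parameters
    ----------
    mode : "time_course" (readouts at ``t_eval`` hours, the default) or
        "steady_state".
    """
    if delta_factor <= 0:
        raise ValueError("delta_factor must be positive")
    params = list(parameters) if parameters is not None else primary_rate_constants(model)
    for p in params:
        if p not in model.parameters:
            raise KeyError(f"unknown parameter {p!r}")

    def evaluate(m: ModelDefinition) -> np.ndarray:
        if mode == "steady_state":
            state = steady_state(m, recipe)
        else:
            traj = simulate_time_course(m, recipe, t_end=t_eval, n_points=50, rtol=rtol)
            state = traj.final_state
        return np.array([state[r] for r in readouts], float)

    y0 = evaluate(model)
    derivs = np.zeros((len(readouts), len(params)))
    for j, pname in enumerate(params):
        p = model.parameters[pname]
        h = max(delta_factor * abs(p), delta_min)
        y_plus = evaluate(model.with_parameters({pname: p + h}))
        y_minus = evaluate(model.with_parameters({pname: max(p - h, 1e-300)}))
        derivs[:, j] = (y_plus - y_minus) / (2 * h)

    coeffs = np.zeros_like(derivs)
    unnormalized = []
    for i, r in enumerate(readouts):
        for j, pname in enumerate(params):
            p = model.parameters[pname]
            if y0[i] == 0.0:
                coeffs[i, j] = derivs[i, j]
                unnormalized.append((r, pname))
            else:
                coeffs[i, j] = (p / y0[i]) * derivs[i, j]

    return SensitivityReport(
        coefficients=pd.DataFrame(coeffs, index=list(readouts), columns=params),
        raw_derivatives=pd.DataFrame(derivs, index=list(readouts), columns=params),
        unnormalized=unnormalized,
        metadata={
            "delta_factor": delta_factor,
            "delta_min": delta_min,
            "mode": mode,
            "t_eval": t_eval,
        },
    )


def rank_parameters(report: SensitivityReport) -> list[str]:
    """Parameters ordered by aggregate |C|, name-stable tie-break."""
    return list(report.ranking().index)


def flux_control_coefficients(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None,
    flux_reaction: str,
    parameters: Sequence[str],
    *,
    delta_factor: float = DELTA_FACTOR,
    delta_min: float = DELTA_MIN,
) -> dict[str, float]:
    """Control coefficients of a steady-state reaction flux.

    C_J[p] = (p/J) dJ/dp via central differences on the steady-state flux of
    ``flux_reaction``; on an unbranched chain the coefficients of the chain
    steps sum to one (the classical summation theorem).
    """
    from .model import CompiledModel

    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    if flux_reaction not in rxn_index:
        raise KeyError(f"unknown reaction {flux_reaction!r}")

    def flux(m: ModelDefinition) -> float:
        state = steady_state(m, recipe)
        cm = CompiledModel(m)
        y = np.array([state[sid] for sid in cm.dynamic_ids])
        levels = cm.full_levels(y, dict(recipe or {}))
        return float(cm.reaction_rates(levels)[rxn_index[flux_reaction]])

    j0 = flux(model)
    out = {}
    for pname in parameters:
        p = model.parameters[pname]
        h = max(delta_factor * abs(p), delta_min)
        jp = flux(model.with_parameters({pname: p + h}))
        jm = flux(model.with_parameters({pname: p - h}))
        d = (jp - jm) / (2 * h)
        out[pname] = (p / j0) * d if j0 != 0 else d
    return out


def trajectory_correlations(
    model: ModelDefinition,
    recipe: Mapping[str, float] | None,
    reference_species: str = "PPARG_a",
    *,
    t_end: float = 100.0,
    n_points: int = 200,
) -> pd.Series:
    """Pearson correlation of every dynamic species' trajectory against a
    reference species over a time course (an alternative reading of
    "correlation of all the variables against activated PPARγ")."""
    traj = simulate_time_course(model, recipe, t_end=t_end, n_points=n_points)
    ref = traj[reference_species]
    out = {}
    for sid in traj.species_ids:
        x = traj[sid]
        sx, sr = np.std(x), np.std(ref)
        out[sid] = float(np.corrcoef(x, ref)[0, 1]) if sx > 0 and sr > 0 else np.nan
    return pd.Series(out).sort_values(ascending=False)
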