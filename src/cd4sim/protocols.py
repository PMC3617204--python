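"""Named in-silico experiments: induction, agonist scans, knockout, plasticity.

The four canonical induction recipes follow the stimulus table of the
differentiation literature:

* Th1   — external IFN-γ + IL-12 + IL-18, with anti-IL-4 antibody
* Th2   — external IL-4, with anti-IFN-γ antibody
* Th17  — external IL-6 + TGF-β
* iTreg — external IL-2 + TGF-β

Doses are single calibrated saturating levels (1.0 a.u.), stored here as
named constants so every shipped scenario is reproducible.

Perturbations come in two kinds: ``knockout`` (the target node is made
signaling-dead: its level is zeroed inside every rate law, i.e. downstream
signaling is blocked while the state dimension stays fixed) and
``agonist_clamp`` (a boundary input — for PPARγ the pioglitazone-like
ligand ``PIO`` — is clamped at a given level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import ModelDefinition
from .phenotype import (
    LINEAGE_MARKER_SETS,
    PhenotypeCall,
    calibrate_marker_scales,
    classify_phenotype,
)
from .simulate import (
    DEFAULT_T_END,
    ScanResult,
    Trajectory,
    parameter_scan,
    scan_time_course,
    simulate_time_course,
)

#: saturating dose used for every external stimulus, in a.u.
SATURATING_DOSE = 1.0

#: canonical stimulus recipes per lineage
CANONICAL_RECIPES: dict[str, dict[str, float]] = {
    "Th1": {
        "IFNG_e": SATURATING_DOSE,
        "IL12_e": SATURATING_DOSE,
        "IL18_e": SATURATING_DOSE,
        "aIL4": SATURATING_DOSE,
    },
    "Th2": {"IL4_e": SATURATING_DOSE, "aIFNG": SATURATING_DOSE},
    "Th17": {"IL6_e": SATURATING_DOSE, "TGFB_e": SATURATING_DOSE},
    "iTreg": {"IL2_e": SATURATING_DOSE, "TGFB_e": SATURATING_DOSE},
}

#: species id of the agonist input driving PPARγ activation
AGONIST_INPUT = "PIO"

#: species id of the activated PPARγ node (knockout target)
PPARG_ACTIVE = "PPARG_a"

#: endpoint readouts tracked across the PPARγ experiments
PPAR_READOUTS = ("FOXP3", "IL17_s", "RORGT", "STAT3_p")


@dataclass(frozen=True)
class StimulusRecipe:
    """External cytokine/antibody doses defining an in-silico milieu."""

    doses: dict[str, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        for sid, level in self.doses.items():
            if level < 0:
                raise ValueError(f"dose for {sid} must be >= 0")


@dataclass(frozen=True)
class PerturbationSpec:
    """A knockout or an agonist clamp applied to the model."""

    kind: str                       # "knockout" | "agonist_clamp"
    target: str                     # species or parameter id
    level: float = 0.0              # clamp value for agonist_clamp

    def __post_init__(self) -> None:
        if self.kind not in ("knockout", "agonist_clamp"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("clamp level must be >= 0")


# cache of classifier normalization constants, keyed by model name
_SCALE_CACHE: dict[str, dict[str, float]] = {}


def marker_scales_for(model: ModelDefinition) -> dict[str, float]:
    """Classifier normalization constants for a model, calibrated once from
    the model's own canonical inductions and cached by model name."""
    if model.name not in _SCALE_CACHE:
        _SCALE_CACHE[model.name] = calibrate_marker_scales(model)
    return _SCALE_CACHE[model.name]


def induce_phenotype(
    model: ModelDefinition,
    lineage: str,
    *,
    t_end: float = DEFAULT_T_END,
    n_points: int = 400,
    knockout: Sequence[str] = (),
    recipe_override: Mapping[str, float] | None = None,
) -> tuple[Trajectory, PhenotypeCall]:
    """Apply the canonical recipe for a lineage and classify the endpoint.

    An endpoint that fails the dominance rule is returned as a
    naive_mixed call with its per-lineage scores, never as an exception.
    """
    if lineage not in CANONICAL_RECIPES:
        raise KeyError(f"unknown lineage {lineage!r}; expected one of {sorted(CANONICAL_RECIPES)}")
    recipe = dict(recipe_override) if recipe_override is not None else CANONICAL_RECIPES[lineage]
    traj = simulate_time_course(model, recipe, t_end=t_end, n_points=n_points, knockout=knockout)
    call = classify_phenotype(traj.final_state, marker_scales=marker_scales_for(model))
    return traj, call


def commitment_time(traj: Trajectory, marker: str = "RORGT", fraction: float = 0.95) -> float:
    """Time at which a marker first reaches ``fraction`` of its plateau.

    Used as the default switch time for the plasticity protocol: the cell
    is regarded as fully differentiated when the lineage's master regulator
    has reached 95% of its induction plateau.
    """
    levels = traj[marker]
    plateau = levels[-1]
    if plateau <= 0:
        raise ValueError(f"marker {marker} shows no induction plateau")
    idx = np.argmax(levels >= fraction * plateau)
    return float(traj.time[idx])


def ppar_activation_scan(
    model: ModelDefinition,
    agonist_grid: Sequence[float],
    *,
    t_commit: float | None = None,
    t_end: float = DEFAULT_T_END,
) -> ScanResult:
    """Agonist dose scan applied to a committed Th17 cell.

    The model is first driven to a committed Th17 state under the canonical
    IL-6 + TGF-β recipe; each agonist grid value is then applied and the
    simulation continued to ``t_end``.  Readouts are the endpoint FOXP3,
    IL-17, RORγt and phospho-STAT3 levels.  Grid value 0 reproduces the
    unperturbed Th17 endpoint.
    """
    grid = np.asarray(list(agonist_grid), float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("agonist grid must be ascending")
    base, _ = induce_phenotype(model, "Th17", t_end=t_end)
    if t_commit is None:
        t_commit = commitment_time(base)
    committed = base.at_time(t_commit)
    return parameter_scan(
        model,
        CANONICAL_RECIPES["Th17"],
        AGONIST_INPUT,
        grid,
        PPAR_READOUTS,
        t_end=t_end - t_commit,
        initial_state=committed,
    )


def ppar_knockout_compare(
    model: ModelDefinition,
    lineage: str,
    *,
    target: str = PPARG_ACTIVE,
    t_end: float = DEFAULT_T_END,
    readouts: Sequence[str] = ("RORGT", "IL17_s", "FOXP3"),
) -> dict[str, dict[str, float]]:
    """Endpoint readouts of intact vs knockout differentiation.

    Runs the canonical induction for ``lineage`` on the wild-type model and
    on a model with the target node (activated PPARγ by default) made
    signaling-dead, and returns ``{"wild_type": {...}, "knockout": {...}}``.
    """
    if lineage not in CANONICAL_RECIPES:
        raise KeyError(f"unknown lineage {lineage!r}")
    wt_traj, _ = induce_phenotype(model, lineage, t_end=t_end)
    ko_traj, _ = induce_phenotype(model, lineage, t_end=t_end, knockout=[target])
    wt, ko = wt_traj.final_state, ko_traj.final_state
    return {
        "wild_type": {r: wt[r] for r in readouts},
        "knockout": {r: ko[r] for r in readouts},
    }


def plasticity_switch(
    model: ModelDefinition,
    t_switch: float | None = None,
    agonist_level: float = 2.0,
    *,
    t_end: float = DEFAULT_T_END,
    n_points: int = 400,
) -> Trajectory:
    """Th17 → iTreg switch protocol.

    Simulates Th17 induction on [0, t_switch] (default: the time at which
    RORγt reaches 95% of its induction plateau), then clamps the PPARγ
    agonist input at ``agonist_level`` and continues to ``t_end``.  The two
    segments are concatenated into one trajectory; ``agonist_level = 0``
    reproduces the uninterrupted Th17 induction.
    """
    recipe = dict(CANONICAL_RECIPES["Th17"])
    if t_switch is None:
        base, _ = induce_phenotype(model, "Th17", t_end=t_end)
        t_switch = commitment_time(base)
    if not 0 < t_switch < t_end:
        raise ValueError(f"t_switch must lie in (0, {t_end}); got {t_switch}")
    n1 = max(int(n_points * t_switch / t_end), 16)
    pre = simulate_time_course(model, recipe, t_end=t_switch, n_points=n1)
    post_recipe = dict(recipe)
    post_recipe[AGONIST_INPUT] = float(agonist_level)
    post = simulate_time_course(
        model, post_recipe, t_end=t_end - t_switch,
        n_points=n_points - n1 + 1, initial_state=pre.final_state,
    )
    time = np.concatenate([pre.time, post.time[1:] + t_switch])
    states = np.concatenate([pre.states, post.states[1:]], axis=0)
    traj = Trajectory(
        time=time,
        states=states,
        species_ids=pre.species_ids,
        boundary_levels=post_recipe,
        solver={"segments": [pre.solver, post.solver], "t_switch": t_switch},
    )
    return traj


def apply_perturbations(
    model: ModelDefinition,
    recipe: Mapping[str, float],
    perturbations: Sequence[PerturbationSpec],
) -> tuple[dict[str, float], list[str]]:
    """Resolve perturbations into an adjusted recipe and a knockout list."""
    doses = dict(recipe)
    knockouts: list[str] = []
    for p in perturbations:
        if p.kind == "knockout":
            knockouts.append(p.target)
        else:
            if not model.species_by_id(p.target).is_boundary:
                raise ValueError(
                    f"agonist_clamp target {p.target!r} must be a boundary input"
                )
            doses[p.target] = p.level
    return doses, knockouts
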