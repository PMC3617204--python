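"""Synthetic stimulus-response data with known ground truth.

The original calibration measurements behind the differentiation model are
not deposited, so testability rests on this module: it simulates stimulus
recipes with known parameters, samples observations at stated times, and
applies multiplicative log-normal noise (flow-cytometry-like readouts are
positive with roughly constant coefficient of variation).  CV = 0
reproduces the simulation exactly; every dataset records its generator
seed in its provenance tag.

The module also builds a small receptor→transcription-factor induction
motif used for parameter-recovery experiments, and the machine-readable
fate fixture (per lineage: markers that must rise, master regulators that
must stay suppressed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CalibrationDataset, Experiment, Observation
from .model import ModelDefinition, RateLaw, Reaction, Species
from .simulate import simulate_time_course

#: per-lineage expected marker movements: markers that rise under the
#: canonical recipe, and the opposing master regulators that must stay
#: suppressed (below their own induced levels)
FATE_TABLE = {
    "Th1": {"up": ["TBET", "IFNG_s"], "suppressed": ["GATA3", "RORGT", "FOXP3"]},
    "Th2": {"up": ["GATA3", "IL4_s"], "suppressed": ["TBET", "RORGT", "FOXP3"]},
    "Th17": {"up": ["RORGT", "IL17_s", "STAT3_p"], "suppressed": ["TBET", "GATA3", "FOXP3"]},
    "iTreg": {"up": ["FOXP3"], "suppressed": ["TBET", "GATA3", "RORGT"]},
}


@dataclass
class GeneratorSpec:
    """Recipe roster, observation design and noise model for a dataset."""

    recipes: dict[str, dict[str, float]]        # label -> boundary doses
    times: Sequence[float]                      # observation times, hours
    observed_species: Sequence[str]
    cv: float = 0.05                            # log-normal noise CV
    seed: int = 0
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("noise CV must be >= 0")
        if any(t < 0 for t in self.times):
            raise ValueError("observation times must be >= 0")


def generate_calibration_dataset(model: ModelDefinition, spec: GeneratorSpec) -> CalibrationDataset:
    """Simulate each recipe and emit noisy observations.

    Noise is multiplicative log-normal with the requested CV, unbiased in
    log-space (mean log-deviation 0); CV = 0 returns the simulated values
    exactly.  Byte-identical for identical seeds.
    """
    m = model.with_parameters(spec.parameter_overrides) if spec.parameter_overrides else model
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log(1.0 + spec.cv**2)))
    t_max = max(spec.times)
    # solver output grid contains the exact observation times, so CV = 0
    # reproduces the simulation with no interpolation error
    grid = np.unique(np.concatenate([[0.0], np.asarray(spec.times, float)]))
    experiments = []
    for label in sorted(spec.recipes):
        recipe = spec.recipes[label]
        traj = simulate_time_course(m, recipe, t_end=t_max, t_eval=grid)
        if traj.time[-1] < t_max - 1e-9:
            raise ValueError("observation time beyond simulation horizon")
        obs = []
        for sid in spec.observed_species:
            levels = np.interp(spec.times, traj.time, traj[sid])
            if spec.cv > 0:
                noise = np.exp(rng.normal(0.0, sigma, size=len(levels)))
                levels = levels * noise
            for t, v in zip(spec.times, levels):
                obs.append(Observation(species=sid, time=float(t), value=float(v), weight=spec.weight))
        experiments.append(Experiment(recipe=dict(recipe), observations=tuple(obs), label=label))
    return CalibrationDataset(
        experiments=experiments,
        provenance=f"synthetic(seed={spec.seed}, cv={spec.cv})",
    )


def generate_fate_fixture(model: ModelDefinition) -> dict:
    """Machine-readable stimulus→fate table for the four lineages.

    For each lineage: the canonical recipe, the markers expected to rise,
    and the opposing master regulators expected to stay suppressed.
    """
    from .model import validate_model
    from .protocols import CANONICAL_RECIPES

    report = validate_model(model)
    if not report.passed:
        raise ValueError(f"model failed validation:\n{report.summary()}")
    fixture = {}
    for lineage, expectations in FATE_TABLE.items():
        fixture[lineage] = {
            "recipe": dict(CANONICAL_RECIPES[lineage]),
            "up": list(expectations["up"]),
            "suppressed": list(expectations["suppressed"]),
        }
    return fixture


def write_fate_fixture(model: ModelDefinition, path) -> None:
    with open(path, "w") as fh:
        json.dump(generate_fate_fixture(model), fh, indent=2)


# ---------------------------------------------------------------------------
# small ground-truth motif for parameter-recovery experiments
# ---------------------------------------------------------------------------

def build_induction_motif() -> ModelDefinition:
    """A minimal cytokine→receptor→transcription-factor induction motif.

    Boundary ligand L_e activates a receptor pool (R → R_a, Hill in L_e);
    active receptor drives transcription of a factor TF from a gene source;
    TF decays first-order.  Used as the ground-truth model for
    parameter-recovery experiments: with observations of R_a and TF over a
    few doses, the four constants {activation vmax, transcription vmax,
    transcription km, decay k} are identifiable.
    """
    species = [
        Species("L_e", "external ligand", "external_cytokine", 0.0, True),
        Species("gene_TF", "TF gene locus", "gene_source", 1.0, True),
        Species("deg_TF", "degraded TF", "degradation_product", 0.0, True),
        Species("R", "receptor", "receptor", 1.0),
        Species("R_a", "activated receptor", "receptor", 0.0),
        Species("TF", "transcription factor", "transcription_factor", 0.0),
    ]
    reactions = [
        Reaction(
            id="m1_R_act",
            substrates=(("R", 1.0),),
            products=(("R_a", 1.0),),
            modifiers=("L_e",),
            rate_law=RateLaw(kind="hill", vmax="m1_vmax", km="m1_km", n="m1_n", driver="L_e"),
        ),
        Reaction(
            id="m2_TF_syn",
            substrates=(("gene_TF", 1.0),),
            products=(("TF", 1.0),),
            modifiers=("R_a",),
            rate_law=RateLaw(kind="hill", vmax="m2_vmax", km="m2_km", n="m2_n", driver="R_a"),
        ),
        Reaction(
            id="m3_TF_deg",
            substrates=(("TF", 1.0),),
            products=(("deg_TF", 1.0),),
            rate_law=RateLaw(kind="mass_action", k="m3_k"),
        ),
    ]
    parameters = {
        "m1_vmax": 0.8,
        "m1_km": 0.4,
        "m1_n": 1.0,
        "m2_vmax": 0.5,
        "m2_km": 0.3,
        "m2_n": 2.0,
        "m3_k": 0.1,
    }
    return ModelDefinition(
        species=species,
        reactions=reactions,
        parameters=parameters,
        name="induction_motif",
        metadata={"purpose": "ground-truth motif for parameter recovery"},
    )


#: default recovery experiment design: three ligand doses, eight times
RECOVERY_FREE_PARAMS = ("m1_vmax", "m2_vmax", "m2_km", "m3_k")


def recovery_generator_spec(cv: float = 0.05, seed: int = 0) -> GeneratorSpec:
    """Stimulus-response design for the standard recovery experiment."""
    return GeneratorSpec(
        recipes={
            "dose_low": {"L_e": 0.2},
            "dose_mid": {"L_e": 0.6},
            "dose_high": {"L_e": 1.5},
        },
        times=[2.0, 5.0, 10.0, 18.0, 30.0, 45.0],
        observed_species=["R_a", "TF"],
        cv=cv,
        seed=seed,
    )
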