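"""Phenotype classification from master-regulator and cytokine levels.

A state is called Th1, Th2, Th17 or iTreg when its lineage score dominates
the runner-up by a configurable ratio; otherwise the call is naive_mixed.
The lineage score is the geometric mean of the lineage's normalized
master-regulator and signature-cytokine levels (FOXP3 alone for iTreg,
which has no single exclusive signature cytokine in the network readouts).
Marker levels are normalized by each marker's level under its own canonical
induction so that markers with different absolute scales contribute
comparably; scores are then normalized to sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

#: lineage -> tuple of marker species averaged geometrically
LINEAGE_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "Th1": ("TBET", "IFNG_s"),
    "Th2": ("GATA3", "IL4_s"),
    "Th17": ("RORGT", "IL17_s"),
    "iTreg": ("FOXP3",),
}

#: marker levels at the endpoint of each marker's own canonical induction of
#: the reference model (recomputable with `calibrate_marker_scales`); used to
#: put markers on a common scale before scoring
DEFAULT_MARKER_SCALES: dict[str, float] = {
    "TBET": 3.58,
    "IFNG_s": 4.02,
    "GATA3": 4.29,
    "IL4_s": 5.92,
    "RORGT": 1.10,
    "IL17_s": 1.08,
    "FOXP3": 5.15,
}

#: small floor so all-zero states yield equal scores instead of 0/0
_EPS = 1e-9


@dataclass
class PhenotypeCall:
    label: str                      # Th1 | Th2 | Th17 | iTreg | naive_mixed
    scores: dict[str, float]        # per-lineage, normalized to sum 1
    markers: dict[str, float] = field(default_factory=dict)

    def __str__(self) -> str:
        s = ", ".join(f"{k}={v:.3f}" for k, v in self.scores.items())
        return f"{self.label} ({s})"


def classify_phenotype(
    state: Mapping[str, float],
    *,
    marker_scales: Mapping[str, float] | None = None,
    dominance_ratio: float = 2.0,
    min_induction: float = 0.02,
) -> PhenotypeCall:
    """Classify a model state into one of the four lineages or naive_mixed.

    Parameters
    ----------
    state : mapping species id -> level
        Must contain every marker species.
    marker_scales : normalization constants per marker (defaults to the
        scales calibrated on the reference model's canonical inductions).
    dominance_ratio : the top lineage score must exceed the runner-up by
        this ratio, otherwise the call is naive_mixed.
    min_induction : absolute floor on the top lineage's unnormalized score
        (in units of its own induced scale).  A state whose best marker set
        sits below this fraction of its canonical induction level is naive
        regardless of ratios — without the floor, an uninduced state would
        be attributed to whichever lineage decays slowest.  Calls are
        therefore scale-invariant only above the naive floor.
    """
    scales = dict(DEFAULT_MARKER_SCALES)
    if marker_scales:
        scales.update(marker_scales)
    markers: dict[str, float] = {}
    raw: dict[str, float] = {}
    for lineage, marker_ids in LINEAGE_MARKER_SETS.items():
        logs = []
        for sid in marker_ids:
            if sid not in state:
                raise KeyError(f"state is missing marker species {sid!r}")
            level = max(float(state[sid]), 0.0)
            markers[sid] = level
            logs.append(math.log(level / scales[sid] + _EPS))
        raw[lineage] = math.exp(sum(logs) / len(logs))
    total = sum(raw.values())
    scores = {k: v / total for k, v in raw.items()}
    ordered = sorted(scores, key=lambda k: (-scores[k], k))
    top, runner = ordered[0], ordered[1]
    dominant = scores[runner] > 0 and scores[top] / scores[runner] >= dominance_ratio
    if dominant and raw[top] >= min_induction:
        label = top
    else:
        label = "naive_mixed"
    return PhenotypeCall(label=label, scores=scores, markers=markers)


def calibrate_marker_scales(model) -> dict[str, float]:
    """Recompute normalization constants from the model's own inductions.

    Each marker's scale is its endpoint level under its own lineage's
    canonical recipe, floored to avoid degenerate scales.
    """
    from .protocols import CANONICAL_RECIPES
    from .simulate import simulate_time_course

    scales: dict[str, float] = {}
    for lineage, marker_ids in LINEAGE_MARKER_SETS.items():
        traj = simulate_time_course(model, CANONICAL_RECIPES[lineage], n_points=200)
        end = traj.final_state
        for sid in marker_ids:
            scales[sid] = max(end[sid], 1e-6)
    return scales
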