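"""Reaction-network domain model and ODE right-hand-side assembly.

A :class:`ModelDefinition` holds the species roster, the reactions with
their rate-law assignments, and a named map of all kinetic constants.
Dynamic (non-boundary) species are governed by ODEs assembled as the
stoichiometry-weighted sum of reaction rates; boundary species (external
cytokines, neutralizing antibodies, gene sources, degradation products,
agonist inputs) contribute to rates but are held fixed.

Rate laws reference kinetic constants *by name*; the values live in
``ModelDefinition.parameters`` so that parameter scans, knockouts and
calibration can rebind values without touching the network structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from ._kernels import HAVE_NUMBA, reaction_rates_kernel, rhs_kernel

#: use the JIT kernels when numba is importable
_USE_KERNELS = HAVE_NUMBA

#: roles a species may take in the network
ROLES = (
    "external_cytokine",
    "neutralizing_antibody",
    "receptor",
    "signal_transducer",
    "transcription_factor",
    "secreted_cytokine",
    "gene_source",
    "degradation_product",
    "agonist_ligand",
)

#: roles that must always be boundary inputs
_BOUNDARY_ROLES = {
    "external_cytokine",
    "neutralizing_antibody",
    "gene_source",
    "degradation_product",
    "agonist_ligand",
}


class StructuralError(ValueError):
    """Raised when a model references unknown species or is otherwise malformed."""


@dataclass(frozen=True)
class Species:
    """A molecular species of the network.

    ``is_boundary`` species are inputs held fixed (or scanned) during
    integration and receive no ODE.
    """

    id: str
    name: str
    role: str
    initial_level: float = 0.0
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown species role {self.role!r} for {self.id}")
        if self.initial_level < 0:
            raise ValueError(f"species {self.id}: initial_level must be >= 0")
        if self.role in _BOUNDARY_ROLES and not self.is_boundary:
            raise ValueError(f"species {self.id} with role {self.role} must be boundary")


@dataclass(frozen=True)
class RateLaw:
    """Rate-law assignment; constants are referenced by parameter name.

    ``kind`` is ``"mass_action"`` (constant ``k``; rate over the reaction's
    substrates) or ``"hill"`` (``vmax``, ``km``, ``n`` with a driving species
    plus multiplicative saturating co-activator and inhibitor factors).
    """

    kind: str
    k: str | None = None
    vmax: str | None = None
    km: str | None = None
    n: str | None = None
    driver: str | None = None
    inhibitors: tuple[tuple[str, str], ...] = ()      # (species id, ki parameter)
    coactivators: tuple[tuple[str, str], ...] = ()    # (species id, ka parameter)

    def __post_init__(self) -> None:
        if self.kind == "mass_action":
            if self.k is None:
                raise ValueError("mass_action law requires rate constant name k")
        elif self.kind == "hill":
            if None in (self.vmax, self.km, self.n, self.driver):
                raise ValueError("hill law requires vmax, km, n and a driver species")
        else:
            raise ValueError(f"unknown rate-law kind {self.kind!r}")

    def referenced_species(self) -> tuple[str, ...]:
        ids: list[str] = []
        if self.driver is not None:
            ids.append(self.driver)
        ids.extend(sid for sid, _ in self.coactivators)
        ids.extend(sid for sid, _ in self.inhibitors)
        return tuple(ids)

    def referenced_parameters(self) -> tuple[str, ...]:
        names = [p for p in (self.k, self.vmax, self.km, self.n) if p is not None]
        names.extend(p for _, p in self.coactivators)
        names.extend(p for _, p in self.inhibitors)
        return tuple(names)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    rate_law: RateLaw
    modifiers: tuple[str, ...] = ()

    def referenced_species(self) -> tuple[str, ...]:
        ids = [sid for sid, _ in self.substrates]
        ids += [sid for sid, _ in self.products]
        ids += list(self.modifiers)
        ids += list(self.rate_law.referenced_species())
        return tuple(ids)


@dataclass
class ModelDefinition:
    """Species, reactions and kinetic constants of a reaction network."""

    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, float]
    time_unit: str = "h"
    name: str = "model"
    metadata: dict = field(default_factory=dict)

    # -- convenience -------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def dynamic_species(self) -> list[Species]:
        return [s for s in self.species if not s.is_boundary]

    @property
    def boundary_species(self) -> list[Species]:
        return [s for s in self.species if s.is_boundary]

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def copy(self) -> "ModelDefinition":
        return ModelDefinition(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=dict(self.parameters),
            time_unit=self.time_unit,
            name=self.name,
            metadata=dict(self.metadata),
        )

    def with_parameters(self, updates: Mapping[str, float]) -> "ModelDefinition":
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        m = self.copy()
        m.parameters.update(updates)
        return m

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        """Human-auditable JSON document (species, reactions, parameters)."""
        doc = {
            "name": self.name,
            "time_unit": self.time_unit,
            "metadata": self.metadata,
            "species": [
                {
                    "id": s.id,
                    "name": s.name,
                    "role": s.role,
                    "initial_level": s.initial_level,
                    "is_boundary": s.is_boundary,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "substrates": [list(t) for t in r.substrates],
                    "products": [list(t) for t in r.products],
                    "modifiers": list(r.modifiers),
                    "rate_law": {
                        "kind": r.rate_law.kind,
                        "k": r.rate_law.k,
                        "vmax": r.rate_law.vmax,
                        "km": r.rate_law.km,
                        "n": r.rate_law.n,
                        "driver": r.rate_law.driver,
                        "inhibitors": [list(t) for t in r.rate_law.inhibitors],
                        "coactivators": [list(t) for t in r.rate_law.coactivators],
                    },
                }
                for r in self.reactions
            ],
            "parameters": self.parameters,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelDefinition":
        doc = json.loads(text)
        species = [Species(**s) for s in doc["species"]]
        reactions = []
        for r in doc["reactions"]:
            rl = r["rate_law"]
            law = RateLaw(
                kind=rl["kind"],
                k=rl.get("k"),
                vmax=rl.get("vmax"),
                km=rl.get("km"),
                n=rl.get("n"),
                driver=rl.get("driver"),
                inhibitors=tuple((a, b) for a, b in rl.get("inhibitors", [])),
                coactivators=tuple((a, b) for a, b in rl.get("coactivators", [])),
            )
            reactions.append(
                Reaction(
                    id=r["id"],
                    substrates=tuple((a, b) for a, b in r["substrates"]),
                    products=tuple((a, b) for a, b in r["products"]),
                    modifiers=tuple(r.get("modifiers", ())),
                    rate_law=law,
                )
            )
        return cls(
            species=species,
            reactions=reactions,
            parameters=dict(doc["parameters"]),
            time_unit=doc.get("time_unit", "h"),
            name=doc.get("name", "model"),
            metadata=doc.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# dependency graph & validation
# ---------------------------------------------------------------------------

def dependency_graph(model: ModelDefinition) -> nx.DiGraph:
    """Species-level digraph: edges from rate-influencing species to the
    species whose levels the reaction changes (substrates and products)."""
    g = nx.DiGraph()
    g.add_nodes_from(model.species_ids)
    for rxn in model.reactions:
        sources = {sid for sid, _ in rxn.substrates}
        sources.update(rxn.modifiers)
        sources.update(rxn.rate_law.referenced_species())
        targets = {sid for sid, _ in rxn.substrates}
        targets.update(sid for sid, _ in rxn.products)
        for s in sources:
            for t in targets:
                if s != t:
                    g.add_edge(s, t, reaction=rxn.id)
    return g


@dataclass
class ValidationReport:
    n_species: int
    n_reactions: int
    n_odes: int
    dangling_references: list[str] = field(default_factory=list)
    nonpositive_constants: list[str] = field(default_factory=list)
    negative_initials: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    unreachable_species: list[str] = field(default_factory=list)
    role_violations: list[str] = field(default_factory=list)
    missing_parameters: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (
            self.dangling_references
            or self.nonpositive_constants
            or self.negative_initials
            or self.duplicate_ids
            or self.unreachable_species
            or self.role_violations
            or self.missing_parameters
        )

    def summary(self) -> str:
        lines = [
            f"species:   {self.n_species}",
            f"reactions: {self.n_reactions}",
            f"ODEs:      {self.n_odes}",
            f"status:    {'PASS' if self.passed else 'FAIL'}",
        ]
        for label, items in [
            ("dangling references", self.dangling_references),
            ("non-positive constants", self.nonpositive_constants),
            ("negative initial levels", self.negative_initials),
            ("duplicate ids", self.duplicate_ids),
            ("unreachable species", self.unreachable_species),
            ("role violations", self.role_violations),
            ("missing parameters", self.missing_parameters),
        ]:
            if items:
                lines.append(f"  {label}: {', '.join(items)}")
        return "\n".join(lines)


def validate_model(model: ModelDefinition) -> ValidationReport:
    """Structural validation: counts, dangling references, constant signs,
    reachability.  Report-based; never raises."""
    ids = model.species_ids
    known = set(ids)
    report = ValidationReport(
        n_species=len(ids),
        n_reactions=len(model.reactions),
        n_odes=len(model.dynamic_species),
    )

    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            report.duplicate_ids.append(sid)
        seen.add(sid)

    for s in model.species:
        if s.initial_level < 0:
            report.negative_initials.append(s.id)
        if s.role in _BOUNDARY_ROLES and not s.is_boundary:
            report.role_violations.append(s.id)

    for rxn in model.reactions:
        for sid in rxn.referenced_species():
            if sid not in known:
                report.dangling_references.append(f"{rxn.id}:{sid}")
        for pname in rxn.rate_law.referenced_parameters():
            if pname not in model.parameters:
                report.missing_parameters.append(f"{rxn.id}:{pname}")

    for pname, value in model.parameters.items():
        if value <= 0:
            report.nonpositive_constants.append(pname)

    g = dependency_graph(model)
    report.unreachable_species = sorted(
        sid for sid in ids if g.degree(sid) == 0
    )
    return report


# ---------------------------------------------------------------------------
# RHS assembly
# ---------------------------------------------------------------------------

class CompiledModel:
    """Index-resolved form of a model for fast repeated rate evaluation.

    ``knockout`` species have their levels forced to zero inside every rate
    law (driver, co-activator, inhibitor and mass-action occurrences alike),
    making the node signaling-dead while keeping the state dimension fixed.
    """

    def __init__(
        self,
        model: ModelDefinition,
        knockout: Iterable[str] = (),
    ) -> None:
        self.model = model
        self.index = {s.id: i for i, s in enumerate(model.species)}
        if len(self.index) != len(model.species):
            raise StructuralError("duplicate species ids")
        self.dynamic_ids = [s.id for s in model.dynamic_species]
        self.dyn_index = np.array([self.index[sid] for sid in self.dynamic_ids])
        self.n_species = len(model.species)
        self.n_dynamic = len(self.dynamic_ids)

        self.base_levels = np.array([s.initial_level for s in model.species], float)
        self.y0 = self.base_levels[self.dyn_index].copy()

        self.keep_mask = np.ones(self.n_species)
        for sid in knockout:
            if sid in self.index:
                self.keep_mask[self.index[sid]] = 0.0
            elif sid not in model.parameters:
                raise StructuralError(f"knockout target {sid!r} is neither species nor parameter")
        self.knockout_params = {
            sid for sid in knockout if sid in model.parameters
        }

        p = dict(model.parameters)
        for name in self.knockout_params:
            p = dict(p)
            p[name] = 0.0
        self._params = p

        # vectorized per-reaction arrays.  Every reaction rate is a base term
        # (k for mass action, vmax * Hill fraction for Hill laws) times the
        # product of its substrate levels (first-order pools: a modulated
        # conversion cannot outrun a finite substrate; gene-source substrates
        # are clamped at 1 so transcription reduces to the pure Hill form)
        # times saturating co-activator and inhibitor factors.
        n_rxn = len(model.reactions)
        self.n_reactions = n_rxn
        self.stoich = np.zeros((self.n_dynamic, n_rxn))
        dyn_pos = {sid: j for j, sid in enumerate(self.dynamic_ids)}
        ma_idx, ma_k = [], []
        h_idx, h_vmax, h_km, h_n, h_driver = [], [], [], [], []
        sub_rxn, sub_idx, sub_st = [], [], []
        co_rxn, co_idx, co_ka = [], [], []
        in_rxn, in_idx, in_ki = [], [], []
        for jr, rxn in enumerate(model.reactions):
            for sid in rxn.referenced_species():
                if sid not in self.index:
                    raise StructuralError(f"reaction {rxn.id} references unknown species {sid!r}")
            law = rxn.rate_law
            for sid, st in rxn.substrates:
                sub_rxn.append(jr)
                sub_idx.append(self.index[sid])
                sub_st.append(st)
            if law.kind == "mass_action":
                ma_idx.append(jr)
                ma_k.append(p[law.k] if law.k not in self.knockout_params else 0.0)
            else:
                h_idx.append(jr)
                h_vmax.append(p[law.vmax] if law.vmax not in self.knockout_params else 0.0)
                h_km.append(p[law.km])
                h_n.append(p[law.n])
                h_driver.append(self.index[law.driver])
                for sid, pn in law.coactivators:
                    co_rxn.append(jr)
                    co_idx.append(self.index[sid])
                    co_ka.append(p[pn])
                for sid, pn in law.inhibitors:
                    in_rxn.append(jr)
                    in_idx.append(self.index[sid])
                    in_ki.append(p[pn])
            for sid, st in rxn.substrates:
                if sid in dyn_pos:
                    self.stoich[dyn_pos[sid], jr] -= st
            for sid, st in rxn.products:
                if sid in dyn_pos:
                    self.stoich[dyn_pos[sid], jr] += st
        self._ma = (np.array(ma_idx, np.int64), np.array(ma_k, float))
        self._hill = (
            np.array(h_idx, np.int64), np.array(h_vmax, float), np.array(h_km, float),
            np.array(h_n, float), np.array(h_driver, np.int64),
        )
        self._subs = (
            np.array(sub_rxn, np.int64), np.array(sub_idx, np.int64), np.array(sub_st, float)
        )
        self._coact = (
            np.array(co_rxn, np.int64), np.array(co_idx, np.int64), np.array(co_ka, float)
        )
        self._inhib = (
            np.array(in_rxn, np.int64), np.array(in_idx, np.int64), np.array(in_ki, float)
        )
        self._kernel_args = (
            self.n_reactions, *self._ma, *self._hill, *self._subs, *self._coact, *self._inhib
        )

    # -- evaluation --------------------------------------------------------
    def full_levels(self, y: np.ndarray, boundary: Mapping[str, float] | None = None) -> np.ndarray:
        levels = self.base_levels.copy()
        levels[self.dyn_index] = y
        if boundary:
            for sid, value in boundary.items():
                levels[self.index[sid]] = value
        return levels

    def reaction_rates(self, levels: np.ndarray) -> np.ndarray:
        lv = np.maximum(levels, 0.0) * self.keep_mask
        if _USE_KERNELS:
            return reaction_rates_kernel(lv, *self._kernel_args)
        return self._reaction_rates_numpy(lv)

    def _reaction_rates_numpy(self, lv: np.ndarray) -> np.ndarray:
        rates = np.zeros(self.n_reactions)
        ma_idx, ma_k = self._ma
        if ma_idx.size:
            rates[ma_idx] = ma_k
        h_idx, vmax, km, n, driver = self._hill
        if h_idx.size:
            d = lv[driver]
            pos = d > 0.0
            # Hill fraction via the log of (d/km)^n, stable for large n
            t = np.zeros_like(d)
            t[pos] = n[pos] * (np.log(d[pos]) - np.log(km[pos]))
            t = np.clip(t, -700.0, 700.0)
            r = np.exp(t)
            frac = np.where(pos, r / (1.0 + r), 0.0)
            rates[h_idx] = vmax * frac
        sub_rxn, sub_idx, sub_st = self._subs
        if sub_rxn.size:
            np.multiply.at(rates, sub_rxn, lv[sub_idx] ** sub_st)
        co_rxn, co_idx, co_ka = self._coact
        if co_rxn.size:
            x = lv[co_idx]
            np.multiply.at(rates, co_rxn, x / (co_ka + x))
        in_rxn, in_idx, in_ki = self._inhib
        if in_rxn.size:
            np.multiply.at(rates, in_rxn, in_ki / (in_ki + lv[in_idx]))
        return rates

    def rhs(self, t: float, y: np.ndarray, boundary: Mapping[str, float] | None = None) -> np.ndarray:
        levels = self.full_levels(y, boundary)
        return self.stoich @ self.reaction_rates(levels)

    def rhs_for(self, boundary: Mapping[str, float] | None = None) -> Callable[[float, np.ndarray], np.ndarray]:
        """Bind boundary levels once and return f(t, y) for the integrator."""
        levels = self.base_levels.copy()
        if boundary:
            for sid, value in boundary.items():
                levels[self.index[sid]] = value
        dyn_index = self.dyn_index
        stoich = self.stoich
        if _USE_KERNELS:
            kernel_args = self._kernel_args
            keep = self.keep_mask

            def f(t: float, y: np.ndarray) -> np.ndarray:
                return rhs_kernel(y, levels, dyn_index, keep, stoich, *kernel_args)

            return f

        rates = self._reaction_rates_numpy
        keep = self.keep_mask

        def f(t: float, y: np.ndarray) -> np.ndarray:
            lv = levels.copy()
            lv[dyn_index] = y
            return stoich @ rates(np.maximum(lv, 0.0) * keep)

        return f


def assemble_rhs(
    model: ModelDefinition, knockout: Iterable[str] = ()
) -> Callable[[float, np.ndarray, Mapping[str, float] | None], np.ndarray]:
    """Derivative function ``(t, y_dynamic, boundary_levels) -> dy/dt``.

    The derivative is the stoichiometry-weighted sum of reaction rates;
    boundary species contribute to rates but have zero derivative by
    construction (they are simply absent from the dynamic state vector).

    Raises
    ------
    StructuralError
        If any reaction references an unknown species id.
    """
    compiled = CompiledModel(model, knockout=knockout)
    return compiled.rhs
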