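"""SBML Level 3 Version 2 import/export of reaction-network models.

The writer emits a standard SBML document: species carry the
boundary-condition attribute, kinetic constants are global parameters, and
every kinetic law is serialized as MathML (mass action as k·Π S^st; Hill
laws as vmax·d^n/(km^n+d^n) times substrate, co-activator and inhibitor
factors).  Each reaction additionally carries a structured annotation in
the package namespace recording the rate-law descriptor, so that the full
Hill form round-trips exactly.

The reader accepts SBML Level 2 or 3.  Reactions with the package
annotation are reconstructed from it; without an annotation, plain
mass-action MathML (a product of one parameter and species powers) is
parsed structurally and anything else is rejected with a clear message, as
are documents using events, rules, constraints or function definitions.
"""

from __future__ import annotations

import numpy as np
from lxml import etree

from .model import ModelDefinition, RateLaw, Reaction, Species

SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
CD4SIM_NS = "urn:cd4sim:ratelaw"

_UNSUPPORTED = ("ListOfEvents", "listOfEvents", "listOfRules", "listOfConstraints",
                "listOfFunctionDefinitions")


class SBMLError(ValueError):
    """Malformed or unsupported SBML input."""


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _math_ci(parent, name: str) -> None:
    etree.SubElement(parent, f"{{{MATHML_NS}}}ci").text = f" {name} "


def _math_power(parent, name: str, exponent: float) -> None:
    if exponent == 1.0:
        _math_ci(parent, name)
        return
    ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(ap, f"{{{MATHML_NS}}}power")
    _math_ci(ap, name)
    cn = etree.SubElement(ap, f"{{{MATHML_NS}}}cn")
    cn.text = f" {_fmt(exponent)} "


def _hill_math(parent, rxn: Reaction) -> None:
    """vmax * d^n/(km^n + d^n) * Π S^st * Π (C/(ka+C)) * Π (ki/(ki+I))."""
    law = rxn.rate_law
    times = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(times, f"{{{MATHML_NS}}}times")
    _math_ci(times, law.vmax)

    frac = etree.SubElement(times, f"{{{MATHML_NS}}}apply")
    etree.SubElement(frac, f"{{{MATHML_NS}}}divide")
    num = etree.SubElement(frac, f"{{{MATHML_NS}}}apply")
    etree.SubElement(num, f"{{{MATHML_NS}}}power")
    _math_ci(num, law.driver)
    _math_ci(num, law.n)
    den = etree.SubElement(frac, f"{{{MATHML_NS}}}apply")
    etree.SubElement(den, f"{{{MATHML_NS}}}plus")
    for base in (law.km, law.driver):
        ap = etree.SubElement(den, f"{{{MATHML_NS}}}apply")
        etree.SubElement(ap, f"{{{MATHML_NS}}}power")
        _math_ci(ap, base)
        _math_ci(ap, law.n)

    for sid, st in rxn.substrates:
        _math_power(times, sid, st)
    for sid, ka in law.coactivators:
        frac2 = etree.SubElement(times, f"{{{MATHML_NS}}}apply")
        etree.SubElement(frac2, f"{{{MATHML_NS}}}divide")
        _math_ci(frac2, sid)
        plus = etree.SubElement(frac2, f"{{{MATHML_NS}}}apply")
        etree.SubElement(plus, f"{{{MATHML_NS}}}plus")
        _math_ci(plus, ka)
        _math_ci(plus, sid)
    for sid, ki in law.inhibitors:
        frac2 = etree.SubElement(times, f"{{{MATHML_NS}}}apply")
        etree.SubElement(frac2, f"{{{MATHML_NS}}}divide")
        _math_ci(frac2, ki)
        plus = etree.SubElement(frac2, f"{{{MATHML_NS}}}apply")
        etree.SubElement(plus, f"{{{MATHML_NS}}}plus")
        _math_ci(plus, ki)
        _math_ci(plus, sid)


def _mass_action_math(parent, rxn: Reaction) -> None:
    law = rxn.rate_law
    if not rxn.substrates:
        _math_ci(parent, law.k)
        return
    times = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(times, f"{{{MATHML_NS}}}times")
    _math_ci(times, law.k)
    for sid, st in rxn.substrates:
        _math_power(times, sid, st)


def write_sbml(model: ModelDefinition, path) -> None:
    """Write a model as an SBML L3V2 document (deterministic output)."""
    nsmap = {None: SBML_L3V2_NS, "cd4sim": CD4SIM_NS}
    sbml = etree.Element(f"{{{SBML_L3V2_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "2")
    mdl = etree.SubElement(sbml, f"{{{SBML_L3V2_NS}}}model")
    mdl.set("id", model.name.replace("-", "_"))
    mdl.set("name", model.name)

    comps = etree.SubElement(mdl, f"{{{SBML_L3V2_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_L3V2_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("constant", "true")
    comp.set("size", "1")
    comp.set("spatialDimensions", "3")

    lspecies = etree.SubElement(mdl, f"{{{SBML_L3V2_NS}}}listOfSpecies")
    for s in model.species:
        el = etree.SubElement(lspecies, f"{{{SBML_L3V2_NS}}}species")
        el.set("id", s.id)
        el.set("name", s.name)
        el.set("compartment", "cell")
        el.set("initialConcentration", _fmt(s.initial_level))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "true" if s.is_boundary else "false")
        el.set("constant", "false")
        ann = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}annotation")
        role = etree.SubElement(ann, f"{{{CD4SIM_NS}}}role")
        role.text = s.role

    lparams = etree.SubElement(mdl, f"{{{SBML_L3V2_NS}}}listOfParameters")
    for pname in sorted(model.parameters):
        el = etree.SubElement(lparams, f"{{{SBML_L3V2_NS}}}parameter")
        el.set("id", pname)
        el.set("value", _fmt(model.parameters[pname]))
        el.set("constant", "true")

    lrxns = etree.SubElement(mdl, f"{{{SBML_L3V2_NS}}}listOfReactions")
    for rxn in model.reactions:
        el = etree.SubElement(lrxns, f"{{{SBML_L3V2_NS}}}reaction")
        el.set("id", rxn.id)
        el.set("reversible", "false")

        ann = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}annotation")
        law = rxn.rate_law
        rl = etree.SubElement(ann, f"{{{CD4SIM_NS}}}rateLaw")
        rl.set("kind", law.kind)
        if law.kind == "mass_action":
            rl.set("k", law.k)
        else:
            rl.set("vmax", law.vmax)
            rl.set("km", law.km)
            rl.set("n", law.n)
            rl.set("driver", law.driver)
            for sid, ka in law.coactivators:
                sub = etree.SubElement(rl, f"{{{CD4SIM_NS}}}coactivator")
                sub.set("species", sid)
                sub.set("ka", ka)
            for sid, ki in law.inhibitors:
                sub = etree.SubElement(rl, f"{{{CD4SIM_NS}}}inhibitor")
                sub.set("species", sid)
                sub.set("ki", ki)

        if rxn.substrates:
            lr = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}listOfReactants")
            for sid, st in rxn.substrates:
                ref = etree.SubElement(lr, f"{{{SBML_L3V2_NS}}}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", _fmt(st))
                ref.set("constant", "true")
        if rxn.products:
            lp = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}listOfProducts")
            for sid, st in rxn.products:
                ref = etree.SubElement(lp, f"{{{SBML_L3V2_NS}}}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", _fmt(st))
                ref.set("constant", "true")
        if rxn.modifiers:
            lm = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}listOfModifiers")
            for sid in rxn.modifiers:
                ref = etree.SubElement(lm, f"{{{SBML_L3V2_NS}}}modifierSpeciesReference")
                ref.set("species", sid)

        kl = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
        if law.kind == "mass_action":
            _mass_action_math(math, rxn)
        else:
            _hill_math(math, rxn)

    tree = etree.ElementTree(sbml)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.split("}")[-1]


def _parse_mass_action_math(math_el, species_ids: set[str], param_ids: set[str]):
    """Parse k * Π species^st MathML into (k name, substrates)."""
    children = [c for c in math_el if isinstance(c.tag, str)]
    if len(children) != 1:
        raise SBMLError("kinetic law math must have a single root expression")
    root_el = children[0]

    def ci_name(el) -> str:
        return (el.text or "").strip()

    factors: list[tuple[str, float]] = []

    def walk_factor(el) -> None:
        tag = _local(el.tag)
        if tag == "ci":
            factors.append((ci_name(el), 1.0))
        elif tag == "apply":
            sub = [c for c in el if isinstance(c.tag, str)]
            op = _local(sub[0].tag)
            if op == "times":
                for c in sub[1:]:
                    walk_factor(c)
            elif op == "power":
                base, expo = sub[1], sub[2]
                if _local(base.tag) != "ci" or _local(expo.tag) != "cn":
                    raise SBMLError("unsupported power expression in kinetic law")
                factors.append((ci_name(base), float(expo.text)))
            else:
                raise SBMLError(
                    f"unsupported operator <{op}> in un-annotated kinetic law; "
                    "only mass-action products are parsed structurally"
                )
        else:
            raise SBMLError(f"unsupported MathML element <{tag}> in kinetic law")

    walk_factor(root_el)
    k_name, substrates = None, []
    for name, expo in factors:
        if name in param_ids:
            if k_name is not None:
                raise SBMLError("mass-action law must contain exactly one rate constant")
            k_name = name
        elif name in species_ids:
            substrates.append((name, expo))
        else:
            raise SBMLError(f"unknown identifier {name!r} in kinetic law")
    if k_name is None:
        raise SBMLError("mass-action law must reference a rate constant")
    return k_name, tuple(substrates)


def read_sbml(path) -> ModelDefinition:
    """Read an SBML Level 2/3 document into a :class:`ModelDefinition`.

    Raises
    ------
    SBMLError
        On malformed XML, unsupported constructs (events, rules,
        constraints, function definitions), or kinetic laws that are
        neither package-annotated nor plain mass action.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as err:
        raise SBMLError(f"malformed XML: {err}") from err
    root_el = tree.getroot()
    if _local(root_el.tag) != "sbml":
        raise SBMLError("not an SBML document")
    level = root_el.get("level")
    if level not in ("2", "3"):
        raise SBMLError(f"unsupported SBML level {level!r}; expected 2 or 3")
    for el in root_el.iter():
        if isinstance(el.tag, str) and _local(el.tag) in _UNSUPPORTED:
            raise SBMLError(f"unsupported SBML construct <{_local(el.tag)}>")

    mdl = next((c for c in root_el if isinstance(c.tag, str) and _local(c.tag) == "model"), None)
    if mdl is None:
        raise SBMLError("document has no <model> element")

    def find_list(name):
        el = next((c for c in mdl if isinstance(c.tag, str) and _local(c.tag) == name), None)
        return [] if el is None else [c for c in el if isinstance(c.tag, str)]

    species: list[Species] = []
    for el in find_list("listOfSpecies"):
        if _local(el.tag) != "species":
            continue
        boundary = el.get("boundaryCondition", "false") == "true" or el.get("constant") == "true"
        init = el.get("initialConcentration", el.get("initialAmount", "0"))
        role = None
        for sub in el.iter(f"{{{CD4SIM_NS}}}role"):
            role = (sub.text or "").strip()
        if role is None:
            role = "external_cytokine" if boundary else "signal_transducer"
        species.append(
            Species(
                id=el.get("id"),
                name=el.get("name", el.get("id")),
                role=role,
                initial_level=float(init),
                is_boundary=boundary,
            )
        )
    species_ids = {s.id for s in species}

    parameters: dict[str, float] = {}
    for el in find_list("listOfParameters"):
        if _local(el.tag) == "parameter":
            parameters[el.get("id")] = float(el.get("value"))

    reactions: list[Reaction] = []
    for el in find_list("listOfReactions"):
        if _local(el.tag) != "reaction":
            continue
        rid = el.get("id")
        subs, prods, mods = [], [], []
        ann_law = None
        math_el = None
        for c in el:
            if not isinstance(c.tag, str):
                continue
            tag = _local(c.tag)
            if tag == "listOfReactants":
                subs = [
                    (r.get("species"), float(r.get("stoichiometry", "1")))
                    for r in c if isinstance(r.tag, str)
                ]
            elif tag == "listOfProducts":
                prods = [
                    (r.get("species"), float(r.get("stoichiometry", "1")))
                    for r in c if isinstance(r.tag, str)
                ]
            elif tag == "listOfModifiers":
                mods = [r.get("species") for r in c if isinstance(r.tag, str)]
            elif tag == "annotation":
                for rl in c.iter(f"{{{CD4SIM_NS}}}rateLaw"):
                    ann_law = rl
            elif tag == "kineticLaw":
                for m in c:
                    if isinstance(m.tag, str) and _local(m.tag) == "math":
                        math_el = m
        if ann_law is not None:
            kind = ann_law.get("kind")
            if kind == "mass_action":
                law = RateLaw(kind="mass_action", k=ann_law.get("k"))
            else:
                law = RateLaw(
                    kind="hill",
                    vmax=ann_law.get("vmax"),
                    km=ann_law.get("km"),
                    n=ann_law.get("n"),
                    driver=ann_law.get("driver"),
                    coactivators=tuple(
                        (e.get("species"), e.get("ka"))
                        for e in ann_law if _local(e.tag) == "coactivator"
                    ),
                    inhibitors=tuple(
                        (e.get("species"), e.get("ki"))
                        for e in ann_law if _local(e.tag) == "inhibitor"
                    ),
                )
        else:
            if math_el is None:
                raise SBMLError(f"reaction {rid} has no kinetic law")
            k_name, parsed_subs = _parse_mass_action_math(
                math_el, species_ids, set(parameters)
            )
            law = RateLaw(kind="mass_action", k=k_name)
            if not subs:
                subs = list(parsed_subs)
        reactions.append(
            Reaction(
                id=rid,
                substrates=tuple(subs),
                products=tuple(prods),
                modifiers=tuple(mods),
                rate_law=law,
            )
        )

    return ModelDefinition(
        species=species,
        reactions=reactions,
        parameters=parameters,
        name=mdl.get("name", mdl.get("id", "model")),
        metadata={"source": "sbml"},
    )
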