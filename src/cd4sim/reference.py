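"""Reference CD4+ T cell differentiation network.

The network reconstructs the cytokine-to-transcription-factor signaling
architecture driving differentiation of a naive CD4+ T cell into the four
classical fates:

* Th1   — IFN-γ/IL-12/IL-18 → JAK/STAT1 + STAT4 (+ IL-18/NF-κB) → T-bet → IFN-γ
* Th2   — IL-4 → STAT6 → GATA3 → IL-4
* Th17  — IL-6 + TGF-β → STAT3 + SMAD3 → RORγt (with BATF, IRF4, HIF1α) → IL-17, IL-21
* iTreg — TGF-β + IL-2 → SMAD3 + STAT5 → FOXP3 → IL-10, TGF-β

plus the PPARγ node: a ligand-activated nuclear receptor with a small basal
activity that represses STAT3 phosphorylation, RORγt transcription and IL-17
production while enhancing FOXP3 transcription.  The four master regulators
mutually repress each other, which makes each cytokine recipe drive the
system to a single dominant fate.

Structure: 93 species total, of which 60 are dynamic (one ODE each) and 33
are fixed boundary inputs — 10 external cytokines, 2 neutralizing
antibodies, the PPARγ agonist, 10 gene sources and 10 degradation products
(the source/sink glyph species produced by graphical pathway editors).
There are 52 reactions: receptor activation/deactivation, kinase and STAT
(de)phosphorylation, latent-factor activation, Hill-type transcription with
saturating co-activator and inhibitor factors, and first-order decay.

All levels are dimensionless arbitrary units, time is in hours.  Kinetic
constants are package-calibrated to reproduce the qualitative fate table
and the PPARγ perturbation behaviors; the model metadata carries a
``"recalibrated"`` flag to record that provenance.
"""

from __future__ import annotations

from .model import ModelDefinition, RateLaw, Reaction, Species

#: canonical marker species for each lineage (master regulator, signature cytokine)
LINEAGE_MARKERS = {
    "Th1": ("TBET", "IFNG_s"),
    "Th2": ("GATA3", "IL4_s"),
    "Th17": ("RORGT", "IL17_s"),
    "iTreg": ("FOXP3", None),
}

#: master regulator transcription factors
MASTER_REGULATORS = ("TBET", "GATA3", "RORGT", "FOXP3")


class _Builder:
    def __init__(self) -> None:
        self.species: list[Species] = []
        self.reactions: list[Reaction] = []
        self.parameters: dict[str, float] = {}

    def sp(self, sid: str, name: str, role: str, init: float = 0.0, boundary: bool = False) -> None:
        self.species.append(
            Species(id=sid, name=name, role=role, initial_level=init, is_boundary=boundary)
        )

    def param(self, rid: str, suffix: str, value: float) -> str:
        name = f"{rid}_{suffix}"
        self.parameters[name] = value
        return name

    def mass(self, rid: str, sub: str, prod: str, k: float) -> None:
        law = RateLaw(kind="mass_action", k=self.param(rid, "k", k))
        self.reactions.append(
            Reaction(id=rid, substrates=((sub, 1.0),), products=((prod, 1.0),), rate_law=law)
        )

    def hill(
        self,
        rid: str,
        sub: str,
        prod: str,
        driver: str,
        vmax: float,
        km: float,
        n: float = 1.0,
        coact: list[tuple[str, float]] | None = None,
        inhib: list[tuple[str, float]] | None = None,
    ) -> None:
        law = RateLaw(
            kind="hill",
            vmax=self.param(rid, "vmax", vmax),
            km=self.param(rid, "km", km),
            n=self.param(rid, "n", n),
            driver=driver,
            coactivators=tuple(
                (sid, self.param(rid, f"ka_{sid}", ka)) for sid, ka in (coact or [])
            ),
            inhibitors=tuple(
                (sid, self.param(rid, f"ki_{sid}", ki)) for sid, ki in (inhib or [])
            ),
        )
        modifiers = tuple(
            dict.fromkeys(
                [driver]
                + [sid for sid, _ in (coact or [])]
                + [sid for sid, _ in (inhib or [])]
            )
        )
        self.reactions.append(
            Reaction(
                id=rid,
                substrates=((sub, 1.0),),
                products=((prod, 1.0),),
                modifiers=modifiers,
                rate_law=law,
            )
        )


def build_reference_model() -> ModelDefinition:
    """Construct the reference differentiation network (deterministic).

    Returns a model with 93 species, 52 reactions and a 60-dimensional
    dynamic state.
    """
    b = _Builder()

    # ---- boundary inputs: external cytokines -----------------------------
    for sid, name in [
        ("IFNG_e", "external IFN-gamma"),
        ("IL12_e", "external IL-12"),
        ("IL18_e", "external IL-18"),
        ("IL4_e", "external IL-4"),
        ("IL6_e", "external IL-6"),
        ("TGFB_e", "external TGF-beta"),
        ("IL2_e", "external IL-2"),
        ("IL21_e", "external IL-21"),
        ("IL23_e", "external IL-23"),
        ("IL10_e", "external IL-10"),
    ]:
        b.sp(sid, name, "external_cytokine", 0.0, boundary=True)

    # neutralizing antibodies (inhibit receptor engagement of their target)
    b.sp("aIL4", "anti-IL-4 neutralizing antibody", "neutralizing_antibody", 0.0, True)
    b.sp("aIFNG", "anti-IFN-gamma neutralizing antibody", "neutralizing_antibody", 0.0, True)

    # PPARγ agonist (pioglitazone-like ligand input)
    b.sp("PIO", "PPAR-gamma agonist (pioglitazone)", "agonist_ligand", 0.0, True)

    # gene sources and degradation products (pathway-editor source/sink glyphs)
    _genes = ["TBET", "GATA3", "RORGT", "FOXP3", "IFNG", "IL4", "IL17", "IL21", "IL10", "TGFB"]
    for g in _genes:
        b.sp(f"gene_{g}", f"{g} gene locus", "gene_source", 1.0, True)
    for g in _genes:
        b.sp(f"deg_{g}", f"degraded {g}", "degradation_product", 0.0, True)

    # ---- dynamic species -------------------------------------------------
    receptors = [
        ("IFNGR", "IFN-gamma receptor"),
        ("IL12R", "IL-12 receptor"),
        ("IL18R", "IL-18 receptor"),
        ("IL4R", "IL-4 receptor"),
        ("IL6R", "IL-6 receptor"),
        ("TGFBR", "TGF-beta receptor"),
        ("IL2R", "IL-2 receptor"),
        ("IL21R", "IL-21 receptor"),
        ("IL23R", "IL-23 receptor"),
    ]
    for sid, name in receptors:
        b.sp(sid, name, "receptor", 1.0)
        b.sp(f"{sid}_a", f"activated {name}", "receptor", 0.0)

    for sid, name in [("JAK1", "JAK1"), ("JAK2", "JAK2"), ("JAK3", "JAK3"), ("TYK2", "TYK2")]:
        b.sp(sid, name, "signal_transducer", 1.0)
        b.sp(f"{sid}_a", f"active {name}", "signal_transducer", 0.0)

    for sid, name in [
        ("STAT1", "STAT1"), ("STAT4", "STAT4"), ("STAT6", "STAT6"),
        ("STAT3", "STAT3"), ("STAT5", "STAT5"),
    ]:
        b.sp(sid, name, "signal_transducer", 1.0)
        b.sp(f"{sid}_p", f"phosphorylated {name}", "signal_transducer", 0.0)
    b.sp("SMAD3", "SMAD3", "signal_transducer", 1.0)
    b.sp("SMAD3_a", "activated SMAD3", "signal_transducer", 0.0)

    for sid, name in [
        ("TBET", "T-bet"), ("GATA3", "GATA3"), ("RORGT", "ROR-gamma-t"), ("FOXP3", "FOXP3"),
    ]:
        b.sp(sid, name, "transcription_factor", 0.01)

    for sid, name in [
        ("IFNG_s", "secreted IFN-gamma"), ("IL4_s", "secreted IL-4"),
        ("IL17_s", "secreted IL-17"), ("IL21_s", "secreted IL-21"),
        ("IL10_s", "secreted IL-10"), ("TGFB_s", "secreted TGF-beta"),
    ]:
        b.sp(sid, name, "secreted_cytokine", 0.0)

    b.sp("PPARG", "PPAR-gamma", "transcription_factor", 1.0)
    b.sp("PPARG_a", "activated PPAR-gamma", "transcription_factor", 0.0)

    for sid, name in [
        ("IRF4", "IRF4"), ("BATF", "BATF"), ("RUNX3", "RUNX3"),
        ("NFKB", "NF-kB"), ("HIF1A", "HIF-1-alpha"),
    ]:
        b.sp(sid, name, "transcription_factor", 1.0)
        b.sp(f"{sid}_a", f"active {name}", "transcription_factor", 0.0)

    # ---- reactions -------------------------------------------------------
    # receptor activation by external cytokines (r01-r09)
    b.hill("r01_IFNGR_act", "IFNGR", "IFNGR_a", "IFNG_e", 1.0, 0.3, inhib=[("aIFNG", 0.1)])
    b.hill("r02_IL12R_act", "IL12R", "IL12R_a", "IL12_e", 1.0, 0.3)
    b.hill("r03_IL18R_act", "IL18R", "IL18R_a", "IL18_e", 1.0, 0.3)
    b.hill("r04_IL4R_act", "IL4R", "IL4R_a", "IL4_e", 1.0, 0.3, inhib=[("aIL4", 0.1)])
    b.hill("r05_IL6R_act", "IL6R", "IL6R_a", "IL6_e", 1.0, 0.3, inhib=[("IL10_e", 1.0)])
    b.hill("r06_TGFBR_act", "TGFBR", "TGFBR_a", "TGFB_e", 1.0, 0.3)
    b.hill("r07_IL2R_act", "IL2R", "IL2R_a", "IL2_e", 1.0, 0.3)
    b.hill("r08_IL21R_act", "IL21R", "IL21R_a", "IL21_e", 1.0, 0.3)
    b.hill("r09_IL23R_act", "IL23R", "IL23R_a", "IL23_e", 1.0, 0.3)

    # receptor turnover / desensitization (r10-r12)
    b.mass("r10_IL6R_deact", "IL6R_a", "IL6R", 0.05)
    b.mass("r11_TGFBR_deact", "TGFBR_a", "TGFBR", 0.05)
    b.mass("r12_IL2R_deact", "IL2R_a", "IL2R", 0.05)

    # receptor-associated kinase activation (r13-r16)
    b.hill("r13_JAK1_act", "JAK1", "JAK1_a", "IFNGR_a", 1.0, 0.3)
    b.hill("r14_JAK2_act", "JAK2", "JAK2_a", "IL12R_a", 1.0, 0.3)
    b.hill("r15_JAK3_act", "JAK3", "JAK3_a", "IL2R_a", 1.0, 0.2)
    b.hill("r16_TYK2_act", "TYK2", "TYK2_a", "IL23R_a", 1.0, 0.3)

    # STAT phosphorylation and SMAD activation (r17-r23)
    b.hill("r17_STAT1_phos", "STAT1", "STAT1_p", "JAK1_a", 1.0, 0.3)
    b.hill("r18_STAT4_phos", "STAT4", "STAT4_p", "JAK2_a", 1.0, 0.3)
    b.hill("r19_STAT6_phos", "STAT6", "STAT6_p", "IL4R_a", 1.0, 0.3)
    b.hill("r20_STAT3_phos", "STAT3", "STAT3_p", "IL6R_a", 1.2, 0.3, inhib=[("PPARG_a", 0.08)])
    b.hill("r21_STAT5_phos", "STAT5", "STAT5_p", "JAK3_a", 1.0, 0.3)
    b.hill("r22_SMAD3_act", "SMAD3", "SMAD3_a", "TGFBR_a", 1.0, 0.3)
    b.mass("r23_STAT3_dephos", "STAT3_p", "STAT3", 0.3)

    # latent-factor activation (r24-r28)
    b.hill("r24_IRF4_act", "IRF4", "IRF4_a", "STAT3_p", 0.5, 0.4)
    b.hill("r25_BATF_act", "BATF", "BATF_a", "STAT3_p", 0.5, 0.4)
    b.hill("r26_RUNX3_act", "RUNX3", "RUNX3_a", "TBET", 0.5, 1.0)
    b.hill("r27_NFKB_act", "NFKB", "NFKB_a", "IL18R_a", 0.5, 0.4)
    b.hill("r28_HIF1A_act", "HIF1A", "HIF1A_a", "STAT3_p", 0.5, 0.4)

    # master-regulator transcription (r29-r33) and decay (r34-r37)
    b.hill(
        "r29_TBET_syn", "gene_TBET", "TBET", "STAT1_p", 0.30, 0.4, 2.0,
        coact=[("STAT4_p", 0.2)],
        inhib=[("GATA3", 0.4), ("RORGT", 0.4), ("FOXP3", 0.4)],
    )
    b.hill(
        "r30_GATA3_syn", "gene_GATA3", "GATA3", "STAT6_p", 0.30, 0.4, 2.0,
        inhib=[("TBET", 0.4), ("RORGT", 0.4), ("FOXP3", 0.4)],
    )
    b.hill(
        "r31_RORGT_syn", "gene_RORGT", "RORGT", "STAT3_p", 0.35, 0.4, 2.0,
        coact=[("SMAD3_a", 0.2)],
        inhib=[("PPARG_a", 0.30), ("FOXP3", 0.4), ("TBET", 0.4), ("GATA3", 0.4)],
    )
    b.hill(
        "r32_FOXP3_syn", "gene_FOXP3", "FOXP3", "SMAD3_a", 0.30, 0.4, 2.0,
        coact=[("STAT5_p", 0.2)],
        inhib=[("STAT3_p", 0.12), ("HIF1A_a", 0.3), ("RORGT", 0.6)],
    )
    b.hill(
        "r33_FOXP3_ppar_syn", "gene_FOXP3", "FOXP3", "PPARG_a", 0.30, 0.15, 1.0,
        coact=[("SMAD3_a", 0.2)],
        inhib=[("STAT3_p", 0.3)],
    )
    b.mass("r34_TBET_deg", "TBET", "deg_TBET", 0.06)
    b.mass("r35_GATA3_deg", "GATA3", "deg_GATA3", 0.06)
    b.mass("r36_RORGT_deg", "RORGT", "deg_RORGT", 0.06)
    b.mass("r37_FOXP3_deg", "FOXP3", "deg_FOXP3", 0.06)

    # signature-cytokine production (r38-r43) and clearance (r44-r49)
    b.hill(
        "r38_IFNG_syn", "gene_IFNG", "IFNG_s", "TBET", 0.5, 1.0, 2.0,
        coact=[("RUNX3_a", 0.2), ("NFKB_a", 0.2)],
        inhib=[("GATA3", 0.5)],
    )
    b.hill("r39_IL4_syn", "gene_IL4", "IL4_s", "GATA3", 0.5, 1.0, 2.0, inhib=[("TBET", 0.5)])
    b.hill(
        "r40_IL17_syn", "gene_IL17", "IL17_s", "RORGT", 0.5, 1.0, 2.0,
        coact=[("BATF_a", 0.2)],
        inhib=[("PPARG_a", 0.30), ("FOXP3", 0.5)],
    )
    b.hill("r41_IL21_syn", "gene_IL21", "IL21_s", "RORGT", 0.3, 1.0, 2.0, coact=[("IRF4_a", 0.2)])
    b.hill("r42_IL10_syn", "gene_IL10", "IL10_s", "FOXP3", 0.4, 1.0, 2.0)
    b.hill("r43_TGFB_syn", "gene_TGFB", "TGFB_s", "FOXP3", 0.3, 1.0, 2.0)
    b.mass("r44_IFNG_clear", "IFNG_s", "deg_IFNG", 0.08)
    b.mass("r45_IL4_clear", "IL4_s", "deg_IL4", 0.08)
    b.mass("r46_IL17_clear", "IL17_s", "deg_IL17", 0.08)
    b.mass("r47_IL21_clear", "IL21_s", "deg_IL21", 0.08)
    b.mass("r48_IL10_clear", "IL10_s", "deg_IL10", 0.08)
    b.mass("r49_TGFB_clear", "TGFB_s", "deg_TGFB", 0.08)

    # PPARγ activation cycle (r50-r52): small basal activity plus
    # ligand-driven activation by the agonist input
    b.mass("r50_PPARG_basal_act", "PPARG", "PPARG_a", 0.02)
    b.hill("r51_PPARG_ligand_act", "PPARG", "PPARG_a", "PIO", 2.0, 0.5, 2.0)
    b.mass("r52_PPARG_deact", "PPARG_a", "PPARG", 0.2)

    model = ModelDefinition(
        species=b.species,
        reactions=b.reactions,
        parameters=b.parameters,
        name="cd4_differentiation_reference",
        metadata={
            "calibration": "recalibrated",
            "description": "CD4+ T cell differentiation network (Th1/Th2/Th17/iTreg "
                           "with PPARg control), package-calibrated constants",
        },
    )
    return model
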