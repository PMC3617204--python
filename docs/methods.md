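# Methods notes

## The model

`cd4sim` models the cytokine-instructed differentiation of a single naive
CD4+ T cell as a deterministic reaction network. The canonical signaling
axis is reproduced for each lineage: an external cytokine engages its
receptor, the receptor activates a receptor-associated kinase, the kinase
phosphorylates a STAT, and the phosphorylated STAT drives transcription of
a master regulator, which in turn drives the lineage's signature cytokine.

* Th1: IFN-γ → IFNGR → JAK1 → STAT1, with IL-12 → IL12R → JAK2 → STAT4 as a
  required co-signal and IL-18 → IL18R → NF-κB boosting IFN-γ production;
  STAT1-P (with STAT4-P) drives T-bet; T-bet drives IFN-γ with RUNX3.
* Th2: IL-4 → IL4R → STAT6 → GATA3 → IL-4.
* Th17: IL-6 → IL6R → STAT3 plus TGF-β → TGFBR → SMAD3; RORγt transcription
  requires both (STAT3-P as driver, SMAD3-a as co-activator). BATF, IRF4
  and HIF-1α are activated downstream of STAT3 and feed IL-17/IL-21
  production and FOXP3 repression.
* iTreg: TGF-β → SMAD3 plus IL-2 → IL2R → JAK3 → STAT5; FOXP3 transcription
  is driven by SMAD3-a gated on STAT5-P, with a second, PPARγ-driven
  transcription route (see below). FOXP3 drives IL-10 and TGF-β.
* The four master regulators mutually repress one another's transcription,
  which makes commitment winner-take-all under saturating stimuli.

IL-21 and IL-23 receptor arms (IL21R, IL23R → TYK2) are present and respond
to their external inputs but are quiescent under the four canonical
recipes.

PPARγ exists as an inactive pool and an active form. A small basal
activation (k = 0.02/h against deactivation 0.2/h, i.e. ~9% active at
rest) represents ligand-independent activity; the boundary input `PIO`
(an agonist of the thiazolidinedione class) drives additional activation
through a Hill term. Active PPARγ (i) inhibits STAT3 phosphorylation,
(ii) inhibits RORγt transcription, (iii) inhibits IL-17 production, and
(iv) drives a second FOXP3 transcription route. Points (i)–(iii) produce
the knockout phenotype (removing basal PPARγ lifts a brake on Th17);
point (iv) plus the collapse of STAT3/HIF-1α repression produces the
Th17→iTreg switch under agonist.

### Structural accounting

93 species = 60 dynamic + 33 boundary. The boundary roster is 10 external
cytokines, 2 neutralizing antibodies (anti-IL-4, anti-IFN-γ, modeled as
saturating inhibitors of their target receptor's engagement), the agonist
input, 10 gene-source species and 10 degradation-product species. Gene
sources and degradation products are the source/sink glyph species that
graphical pathway editors emit for synthesis and decay arrows; they are
clamped and serve to anchor transcription and clearance reactions. The 52
reactions split into 9 receptor activations, 3 receptor desensitizations,
4 kinase activations, 6 STAT/SMAD activations + 1 STAT3 dephosphorylation,
5 latent-factor activations, 5 master-regulator transcription reactions +
4 decays, 6 cytokine production reactions + 6 clearances, and the 3-step
PPARγ activation cycle.

### Rate laws

Two primitives (module `kinetics`): mass action `k·Π S^s`, and a Hill law
`vmax·d^n/(K^n+d^n)` with multiplicative saturating inhibitor factors
`Ki/(Ki+I)`. The Hill law is extended with the mirror-image saturating
co-activator factor `C/(Ka+C)`: a single-driver Hill term cannot express
AND-type requirements (Th17 needs IL-6 *and* TGF-β; Th1 needs IFN-γ *and*
IL-12), and the bounded multiplicative factor preserves monotonicity and
the [0, vmax] bound. Hill terms are evaluated through log((d/K)^n) so
large Hill coefficients cannot overflow.

In the assembled network every Hill-driven conversion is additionally
first-order in its substrate pool, so a modulated conversion cannot drive
a finite pool negative; transcription reactions consume a gene source
clamped at 1 and therefore reduce to the pure Hill form.

### Units and initial state

All levels are dimensionless arbitrary units calibrated against
flow-cytometry-like relative readouts; time is in hours. Receptor, kinase,
STAT and latent-factor pools start at 1; active forms at 0; master
regulators at a naive baseline of 0.01; secreted cytokines at 0.
Saturating stimulus doses are 1.0 a.u. The default horizon is 100 h with
1000 output points.

## Parameterization

The original calibration measurements behind this network are not publicly
deposited, so the shipped constants are package-calibrated: rate constants
were chosen on a common scale (receptor/kinase/STAT activation vmax ≈ 1/h,
transcription vmax 0.25–0.35/h against decay 0.06/h, cytokine clearance
0.08/h, cross-repression Ki ≈ 0.4) and adjusted until the model reproduces
the qualitative fate table and the PPARγ perturbation behaviors; the model
metadata carries `calibration: "recalibrated"` to record this provenance.
The testable claims of the model are qualitative orderings (which fate
wins, which markers rise or fall, monotone dose responses), not absolute
levels, and the test suite asserts exactly those orderings.

Parameters that matter most (confirmed by the control-coefficient
ranking): the PPARγ basal activation/deactivation pair, which sets the
resting brake on the Th17 program; the PPARγ-driven FOXP3 route's vmax;
and the RORγt/IL-17 synthesis and decay constants.

## Simulation

LSODA (stiff-capable, via scipy) with rtol 1e-8 / atol 1e-10. On linear
systems with closed forms the integrated error is below 1e-6, and halving
the tolerances moves reference-network endpoints by < 0.1% — both asserted
in the suite. Steady states are found by integrating in doubling windows
until the RHS infinity-norm falls below tolerance, then Newton-polishing;
the polish is accepted only in the immediate neighborhood of the
integrated state because unstimulated pool species leave the Jacobian
singular along neutral directions (any STAT5 level is steady when IL-2 is
absent), where a root solver may wander to a different branch.

Scans re-initialize from the same initial state per grid point unless a
continue-from state is supplied; the plasticity protocol uses that to
perturb a committed Th17 state. A scan target may be a kinetic parameter
or a boundary input level.

## Protocols and classification

The PPARγ dose scan and the plasticity switch scan the agonist *input*
rather than hard-clamping active PPARγ, so that grid value 0 is exactly
the unperturbed cell. Knockout makes the target node signaling-dead by
zeroing its level inside every rate law — silencing what it drives *and*
lifting what it represses — while keeping the state dimension fixed. The
default switch time is when RORγt reaches 95% of its induction plateau
(~13 h under saturating IL-6 + TGF-β); "fully differentiated" has no
sharper operational definition in a deterministic single-cell model.

The classifier scores each lineage by the geometric mean of its normalized
markers (T-bet/IFN-γ, GATA3/IL-4, RORγt/IL-17, FOXP3 alone — the network
gives iTreg no exclusive secreted marker), normalizing each marker by its
level under its own canonical induction. A call requires the top score to
beat the runner-up by a dominance ratio (default 2) *and* to exceed an
absolute induction floor (default 2% of the marker's induced scale);
without the floor an uninduced state would be attributed to whichever
lineage's markers decay slowest. Calls are therefore scale-invariant only
above the naive floor. Both thresholds are exposed as configuration.

## Sensitivity analysis

Normalized local sensitivities C[y,p] = (p/y)·∂y/∂p by central finite
differences with step max(delta_factor·|p|, delta_min), defaults 1e-4 and
1e-12, evaluated on time-course endpoints at t = 100 h (a steady-state
mode is available). Central differences are second-order accurate at
negligible cost. The default parameter set is the per-reaction primary
rate constant (vmax or k), i.e. sensitivity with respect to reaction
rates; readouts with a zero baseline are reported as raw derivatives and
flagged rather than normalized. A trajectory-correlation utility
(`trajectory_correlations`) is provided as the alternative reading of
"correlation of every variable against active PPARγ"; the control
coefficients are the primary interpretation. Steady-state flux control
coefficients verify the classical summation theorem on an unbranched
chain.

## Calibration

The objective is the weighted sum of squared residuals between simulated
and observed levels, simulating each experiment under its recipe and
reading the trajectory at the observation times (solver failures
contribute a large penalty rather than aborting the optimizer). The
particle swarm is global-best with constriction-style weights (inertia
0.729, cognitive = social = 1.494), positions in log-parameter space —
rate constants span orders of magnitude — with velocities clamped to half
the box and positions clipped to bounds. Defaults are swarm 30 × 300
iterations; the full-scale setting of 50 × 3000 is a flag away. Runs are
bit-reproducible given a seed.

Parameter recovery is demonstrated on a three-reaction
ligand→receptor→transcription-factor motif with three ligand doses, six
observation times and observations of the active receptor and the factor:
four free constants (two vmax, one Km, one decay k) are recovered from 5%
log-normal noise within 20% median relative error over five optimizer
seeds. The motif, not the 93-species network, is the recovery testbed: the
full network's constants are not identifiable from endpoint-style data and
a swarm of this size, and the recovery property being tested is the
optimizer/objective machinery, not the network itself.

## Synthetic data

The generator simulates stimulus recipes with known parameters and applies
multiplicative log-normal noise with a given CV — positive,
flow-cytometry-like readouts with approximately constant relative error —
unbiased in log space; CV = 0 returns the simulation exactly (the solver
is evaluated at the exact observation times). Every dataset embeds its
generator seed and CV in its provenance tag. What synthetic data cannot
establish: correctness of the network topology against real measurements,
absolute concentration scales, cell-to-cell variability, or measurement
artifacts (spillover, gating); passing recovery tests shows the estimation
machinery works on data of the assumed noise structure, not that the
biological parameter values are right.

## SBML

Models round-trip through SBML L3V2: boundary species use the standard
boundary-condition attribute, constants are global parameters, kinetic
laws are serialized as MathML. Because the saturating-modifier Hill form
is not a named SBML rate law, each reaction also carries a structured
annotation in the package namespace from which the rate law is
reconstructed exactly on read; foreign documents without the annotation
are accepted when their kinetic laws are plain mass-action products, and
anything else (events, rules, constraints, function definitions, other
algebra) is rejected with a clear message rather than mis-read.

## Known limitations

* Single-cell, deterministic, instructive-signals-only: no TCR-proximal
  signaling, co-stimulation, proliferation, cell-cell competition or
  stochastic commitment.
* Cross-repression constants are symmetric defaults, not lineage-specific
  fits; double-positive (FOXP3+RORγt+) intermediates are not modeled as a
  discrete class.
* Neutralizing antibodies are saturating inhibitors of receptor
  engagement, not explicit binding species.
* The agonist input is a clamped level; pharmacokinetics of an actual drug
  are out of scope.
* Steady states of quiescent pool species are initial-condition-dependent
  (neutral directions); the steady-state solver therefore reports the
  state reached from the model's initial condition.
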