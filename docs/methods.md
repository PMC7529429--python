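# Methods

This note records the models, algorithms, conventions and design choices
behind `phasegem`, in the order the pipeline uses them.

## Scope and model representation

`phasegem` analyses compartmented genome-scale metabolic models (GEMs) of
organisms with a biphasic lifestyle: a free-swimming, energy-driven *attack
phase* (AP) and an intracellular, biosynthesis-driven *growth phase* (GP),
as in predatory bacteria that grow inside a prey's periplasm.  A `Model`
holds metabolites (elemental formula, charge, compartment — cytoplasm `c`,
periplasm `p`, extracellular `e`, with ids suffixed `_c/_p/_e` in the
BIGG-style namespace), reactions (stoichiometry, flux bounds in
mmol·gDW⁻¹·h⁻¹, Boolean gene–protein–reaction rules), a gene set and an
objective reaction.  Reversibility is encoded purely by the bounds: a
reaction is reversible iff its lower bound is negative; defaults are
(−1000, 1000) for reversible and (0, 1000) for irreversible reactions.
Exchange reactions are single-metabolite boundary reactions on an
extracellular species; negative flux is uptake.

Three serialisations round-trip stably: SBML Level 3 + FBC v2 (bounds,
gene-product associations and objective through the FBC package), a
canonical TSV table pair (one reaction per row with an arrow-grammar
equation string; a permissive `column_map` lets differently-headed
spreadsheets load without editing), and a single-file JSON dump.  SBML
stoichiometries round-trip to the writing library's text precision (~15
significant digits); the TSV writer emits full-precision floats.

### Structural quality checks

*Balance*: for each non-boundary reaction the per-element imbalance is
Σᵢ coeffᵢ·countᵢ(e) and likewise for charge; boundary reactions are
reported `skipped` (they are net importers by design) and reactions with a
formula-less participant `unverifiable` — never silently "balanced".
*Dead ends*: a metabolite is dead-end iff, over all reactions (reversible
ones counting as both producer and consumer), it is only produced or only
consumed; the reactions touching dead-end metabolites can never carry
steady-state flux.

GPR rules are Boolean trees with `and` = enzyme complex (all subunits
required) and `or` = isoenzymes (any suffices); `and` binds tighter than
`or`, keywords are case-insensitive, and the empty rule (orphan reaction)
evaluates true under every expression state — orphans are retained on
physiological evidence and carry no expression evidence against them.

## Flux balance analysis

FBA solves max/min v_obj subject to S·v = 0 and α ≤ v ≤ β with scipy's
HiGHS backend.  Numerical conventions, fixed package-wide:

* reported fluxes with |v| < 1e−9 are cleaned to exactly 0 (stabilises the
  zero-flux classification used by reduction and pruning);
* every optimal solution is certified in tests to ‖S·v‖∞ ≤ 1e−6 and bound
  satisfaction to 1e−9;
* "no growth" means objective < 1e−6 h⁻¹ (absolute);
* only the objective *value* is contract-stable — the flux vector may be
  any of the alternate optima, so nothing downstream asserts individual
  fluxes of a single FBA solve unless the optimum is unique.

Flux variability analysis (FVA) reports per-reaction [min, max] flux with
an optional constraint v_obj ≥ fraction × optimum; fraction ≤ 0 drops the
constraint entirely (whole-polytope scan).  Media are applied by setting
the lower bound of each listed exchange to −uptake and closing the uptake
of every other exchange; secretion bounds are untouched.

The single-reaction deletion screen suppresses each reaction (bounds
(0,0)), re-solves, and flags a deletion lethal when mutant/wild-type falls
below a threshold ratio, 0.10 by default.  The objective reaction is always
skipped and exchange reactions are skipped by default (configurable).  The
screen refuses a non-growing wild type.

## Biomass and maintenance

The biomass reaction drains the monomer pool of one gram of dry weight:
for monomer *i* of macromolecule class *c* with class mass fraction f_c,
mole fraction x_i and molar mass MW_i (g/mol),

    coeff_i = 1000 · f_c · x_i / Σ_j x_j·MW_j      [mmol·gDW⁻¹]

which closes mass exactly: Σ |coeff_i|·MW_i = 1000 mg per gDW.  Growth-
associated maintenance (GAM, mmol ATP per gDW) is folded in as
gam × (atp + h2o → adp + pi + h); the product is one unit of a biomass
pseudo-metabolite drained by a demand reaction, so the objective is an
ordinary column of S.  Non-growth maintenance (NGAM) is a standalone ATPM
reaction with lower bound = ngam — a forced housekeeping drain — and ATPM
doubles as the maximisable attack-phase objective.  Polymerisation water
loss is ignored (monomer masses are used as given); compositions with
condensation already accounted for can simply supply residue masses.
GAM/NGAM are configuration, not constants.

## Expression-constrained reduction (condition-specific models)

A gene counts as *expressed* when its RPKM ≥ 10 (boundary inclusive); an
alternative top-quartile percentile mode is provided because a fixed cutoff
and a quartile rule are genuinely different readings of the same
convention, with the fixed cutoff as default.  Expression is used only as
expressed/not-expressed — magnitudes never become continuous penalties.

Reduction of the source model to a phase-specific sub-model proceeds as:

1. **U** = reactions whose GPR evaluates false under the expressed set;
   orphans and exchanges are exempt (no expression evidence).
2. Minimise Σ_{j∈U} |v_j| subject to S·v = 0, bounds, the phase medium and
   v_obj ≥ fraction × optimum (auxiliary variables t_j ≥ |v_j|); call the
   optimum P*.
3. With the penalty budget Σ t_j ≤ P*(1+1e−6), probe each j ∈ U for its
   maximal |v_j| (two LPs); remove j when that maximum is below the cutoff
   1e−9 + (budget − P*).  The cutoff absorbs the budget slack: a reaction
   outside every minimum-penalty support can still exhibit flux up to the
   slack P*·1e−6, so a fixed 1e−9 cutoff would wrongly keep it whenever
   P* > 0.  The rule is deliberately conservative — a reaction used by
   *some* penalty-optimal flux state is kept, so interchangeable
   alternative paths survive ties.
4. Iteratively prune reactions blocked under the phase medium (FVA range
   [0,0], no objective constraint) until a fixpoint, keeping the phase
   objective itself.
5. Verify the reduced model still attains fraction × optimum (an internal
   invariant; its violation is a bug, not a result).

The objective fraction defaults to 0.9: high enough to preserve phase
functionality, low enough not to over-prune degenerate optima.  Removals
are recorded with reasons (`unsupported-zero-flux` vs
`blocked-after-pruning`) so either "after pruning" or "before pruning"
model sizes can be reported.

## Flux sampling

The steady-state polytope {v : S·v = 0, α ≤ v ≤ β} is sampled with
artificial-centering hit-and-run (ACHR), chosen over plain hit-and-run for
mixing on the elongated polytopes that condition-specific models produce.
No objective constraint is imposed — the sampler characterises the whole
solution space independently of the objective used to build the model.
Warm-up points are the FVA extreme solutions; each step draws a direction
through the running centre, intersects the chord with the bounds exactly
(tolerance 1e−9), and draws the next point uniformly on the chord.  Points
are re-projected onto the null space of S every 1000 steps to control
drift, every emitted sample is certified to ‖S·v‖∞ ≤ 1e−6, and the chain is
a pure function of (model, n, seed, thinning) — bit-identical reruns.
Defaults: 2000 effective samples, thinning 100.  Zero-dimensional polytopes
return the unique point with a warning; empty polytopes raise.  The
per-reaction *median* of the samples is the phase's reference flux.

## Phenotype screens

*Auxotrophy*: on a rich medium that grows the model, close one component's
uptake at a time; the component is an essential nutrient iff growth falls
below 1e−6 h⁻¹.  The default scan set is the medium's organic components
(water, protons, inorganic ions and CO₂ exempt: closing them tests medium
bookkeeping, not biosynthesis).  *Carbon sources*: growth on a minimal
medium supplemented with a single source at a stated uptake.
*Essentiality comparison*: the essential sets of several organisms are
restricted to a focal model's reaction namespace (identity by shared id;
no fuzzy matching), combined per lifestyle group by union (a reaction
essential in any member counts for the group; intersection available), and
partitioned into shared / A-exclusive / B-exclusive; the model↔reaction
bipartite graph exports to GraphML.

## The synthetic generator

The generator emulates, at desk scale, the structures the pipeline is
built to analyse, with exact ground truth:

* a 3-compartment core: glucose uptake through the periplasm, a lumped
  glycolytic chain, a TCA-like cycle whose decarboxylative branch (CS,
  ACONT, ICDH) is separable from the lower branch (AKGDH, SDH2), lumped
  respiration at P/O = 2, anaplerosis (pyruvate carboxylase and
  oxaloacetate decarboxylase), lumped gluconeogenesis, and overflow
  secretion of pyruvate and acetate;
* reversible two-step biosynthesis branches (precursor + NH₄⁺ + ATP →
  intermediate → monomer) cycling over pyruvate/α-ketoglutarate/
  oxaloacetate/acetate-family precursors — reversibility lets imported
  monomers be catabolised for carbon and energy, the "glutamate as fuel"
  mode of the growth phase;
* designed *deletions* of whole branches (exact auxotrophies), *isoenzyme
  steps* realised as two parallel reaction copies with one gene each (so
  the redundancy is visible to reaction-level deletion screens; the
  disjunction of the two genes is the step's effective rule), *complex
  steps* with two-gene AND rules, and designed dead-end metabolites;
* a biomass objective assembled by the biomass builder (protein 0.85 +
  carbohydrate 0.15 by mass; glutamate-family monomers get a low protein
  mole fraction so the rich medium leaves them in excess as the
  growth-phase energy source), GAM 10, NGAM 1.

All species use BIGG-style charged formulas (e.g. ATP C10H12N5O13P3,
charge −4) and every reaction except the biomass pseudo-reaction is
elementally and charge balanced by hand and re-verified by the package's
own checker in the test suite.

**Media.**  The minimal medium is glucose (10 mmol·gDW⁻¹·h⁻¹) plus
inorganics; the rich medium is every monomer at 10 mmol·gDW⁻¹·h⁻¹ plus
inorganics, *without* free sugar.  The rich medium deliberately emulates a
prey cytoplasm, where amino acids are the dominant carbon and energy
source; with sugar present the growth-phase optimum would lean on
glycolysis enough that the expression-unsupported glycolytic/decarboxylative
block ceases to be removable at the 0.9 objective fraction, which would
erase the phase shift the generator exists to exhibit.  This is the
generator's study-condition choice, fixed once at design time.

**Expression.**  AP-like profiles express the catabolic/respiratory genes
(glycolysis, PDH, full TCA, respiration, anaplerotic PC); GP-like profiles
express biosynthesis, gluconeogenesis, OADC; the lower TCA branch,
respiration and PC are expressed in both.  Values are log-normal around
120 RPKM (expressed) and 1.5 RPKM (silent), clamped to the correct side of
the 10 RPKM cutoff, and seed-deterministic.

**What the toy does not emulate** — and hence what passing tests do not
show about real data: genome-scale size and redundancy (63 vs ~1000
reactions), thermodynamic and kinetic constraints, cofactor diversity
beyond one NAD(H) pool, membrane energetics (respiration is a lumped
cytoplasmic reaction), noise and mapping ambiguity of real RNA-seq, and
annotation error.  Results on the toy validate the *algorithms* (they
recover designed ground truth exactly), not any biological claim about a
particular organism.

## Verification strategy and problem sizes

The oracles are independent of the code paths they check: FBA objective
values on 200 random bounded toy networks (≤ 20 reactions) are compared to
an independent constraint-based stack (cobra + GLPK) at 1e−6 relative,
with the models travelling through the package's own SBML writer so
serialisation is cross-validated in the same stroke; deletion screens on
50 random generator specs are compared to exhaustive enumeration on that
stack; the reduction's removed set is verified per-reaction by
budget-constrained flux probes on the independent stack *and* by exhaustive
subset search (|U| ≤ 12) over removable sets; the sampler is checked
against closed-form uniform laws on interval polytopes (median 5 ± 0.2 and
a Kolmogorov–Smirnov test at α = 0.01 on [0,10] with n = 5000); biomass
coefficients are checked against the 1 gDW mass identity on 100 random
compositions (±1e−3 mg).  Sampling runs in tests use 300–5000 samples with
thinning 1–10; pipeline defaults are 1000 × thinning 10.  These sizes give
sub-minute oracle suites while keeping every Monte Carlo tolerance
comfortably non-marginal.

## Known limitations

* Gene-level (MILP) deletions are out of scope; the screen deletes
  reactions, so OR-redundant single reactions are only seen as redundant
  when modelled as parallel columns.
* The reduction implements the expression-penalty scheme described above;
  turnover-metabolite constraints of richer context-extraction
  formulations are not included.
* The sampler offers no convergence diagnostics beyond seed-reproducible
  medians within FVA envelopes; heavily elongated genome-scale polytopes
  would need thinning and sample counts tuned upward.
* SBML subsystem annotations are not written (subsystems survive table and
  JSON round-trips only).
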