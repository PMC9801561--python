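# Methods

## The model and its assumptions

A model is a stoichiometric network at steady state: metabolites with
elemental formulas and charges, reactions with exact (rational)
stoichiometric coefficients, flux bounds in mmol·gDW⁻¹·h⁻¹, boolean
AND/OR gene–protein–reaction (GPR) rules, and a linear objective —
typically one biomass pseudo-reaction whose flux is the growth rate in
h⁻¹. All flux analyses solve variations of the LP

maximise c·v  s.t.  S·v = 0,  lb ≤ v ≤ ub.

Assumptions inherited from the constraint-based framework: steady
state (no metabolite accumulation), no kinetic rate laws, no
thermodynamic potentials beyond irreversibility bounds, no enzyme
capacity or transcriptional regulation. The last point matters for
phenotype prediction: a pathway that is genetically present but
repressed will be called growth-positive in silico, a systematic
source of false positives that the concordance report can only count,
not correct.

Sign conventions follow the BiGG ecosystem: exchange reactions are
written `1 metabolite_e →` with negative flux meaning uptake; media
are maps exchange-id → maximum uptake magnitude; bounds omitted by an
input file default to ±1000.

## Orthology

Hits are kept when percent identity ≥ `pid_min` (default 80, inclusive)
and alignment-length coverage ≥ `cov_min` (default 0.25, inclusive).
The coverage denominator is the query length by default and is
configurable (`query` | `subject` | `shorter`) because the convention
"alignment length of at least 25%" does not name its denominator. The
best hit per query is chosen by bitscore, ties broken by smaller
e-value, then lexicographically smaller subject id — the tie-break is
this package's own documented choice, made so results are reproducible
across input orderings. A pair is orthologous iff it is the best hit
in both directions; BBH output is therefore a partial injection.

## Reconstruction semantics

"Remove reactions whose genes lack homology" is ambiguous between
*any* absent gene and an *unsatisfiable* GPR. The default here is
GPR-satisfiability: the rule is rewritten through the ortholog map,
unmapped genes become FALSE, the tree is boolean-simplified, and the
reaction survives iff the result is satisfiable — so an isozyme pair
with one surviving gene keeps its reaction. `strict=True` gives the
harsher any-absent-gene semantics. Artificial genes (spontaneous-
reaction pseudo-genes) are declared per run and always count as
present, kept verbatim in rewritten rules.

Augmentation processes references in the declared order; a reaction id
already present is never overwritten (first-come provenance), and a
later same-id reaction with different stoichiometry is logged as a
conflict. Bounds of added reactions are copied from the contributing
reference, not reset. Gene-independent (empty-GPR) reference reactions
are imported only with `include_spontaneous=True`: augmentation is
driven by gene homology, but full-union recovery experiments need the
flag on, since a spontaneous reaction dropped from the base strain can
only re-enter through a reference.

## Curation

*Balance*: residual per element = Σ coeff · formula count (products
minus reactants), plus a charge residual. Any participant with a
missing formula, a missing charge, or the rest-group pseudo-element
"R" (carrier-bound intermediates of secondary-metabolite pathways)
makes the reaction *unbalanceable*: the audit reports, it never
auto-fixes, and it deliberately leaves R-group reactions unresolved
because the carrier's protein domain has no meaningful elemental
composition.

*Duplicates*: reactions group iff their stoichiometries are identical
after canonicalisation, where the canonical form is orientation-free
(a reaction and its mirror hash identically), so duplicates of
opposite directionality are caught. GPR and bound differences are
reported per group but never block grouping.

*Energy-generating cycles*: all exchange lower bounds are clamped to 0
and all forced demands (positive lower bounds, e.g. ATP maintenance)
are relaxed to 0; each currency's dissipation reaction is maximised.
Any optimum above 1e-6 flags a cycle, with the nonzero-flux support of
one optimal solution reported. Default currencies: ATP, NADH, NADPH,
FADH2 and the proton-motive force; only currencies whose metabolites
the model contains are probed.

*Gap filling*: MILP with one binary usage indicator per universal
reaction, minimising the number of additions subject to steady state
and objective flux ≥ `min_flux` (default 1e-2 — small enough to mean
"feasible", large enough to clear solver tolerances). Solutions are
cardinality-minimal; further equally-minimal sets are enumerated with
no-good cuts. The test suite checks minimality against exhaustive
subset search on universes this size.

## Numerical choices

One LP backend (HiGHS through scipy) behind a minimal contract: load
matrix, set bounds and objective, solve, read the primal. Feasibility
is the solver's own (≈1e-9); the package's reporting tolerance is
1e-6 — every optimal solution is checked for ‖S·v‖∞ ≤ 1e-6 and bound
feasibility before being returned. pFBA splits each flux into
non-negative forward/backward parts and minimises their sum with the
objective held at ≥ fraction·optimum (a 1e-9 slack avoids spurious
infeasibility); the reported total Σ|v| is unique even when individual
fluxes are degenerate, so all downstream claims are phrased on
objective values, pFBA totals or FVA intervals, never on individual
FBA fluxes. Fixing a flux at a previously solved optimum always leaves
the same 1e-9 slack.

Growth thresholds: a knockout is essential below 5% of wild-type
growth, applied to the objective value; plate predictions use the same
5% rule against the base-medium wild type; activity indices call
growth at ≥ 3 (inclusive); concordance accuracy is displayed to one
decimal. ¹³C containment rescales model fluxes so the
normalisation-basis uptake equals 100 units and keeps signs — the
basis exchange itself appears as −100 under the uptake-negative
convention. Measured effluxes (e.g. acetate) can be pinned through
`fixed_fluxes` before analysis.

FSEOF defaults are this package's own, since the procedure's grid is
rarely stated: 10 steps from the product flux at the unconstrained
biomass optimum up to 90% of the product's theoretical maximum, pFBA
at each step (plain FBA would inject degenerate-optimum noise into the
profiles), ordinary-least-squares slope, and classification only for
sign-consistent monotone profiles with |slope| > 1e-6. No slope cutoff
is applied beyond that; ranking takes the 10 highest and 10 lowest
slopes after removing an explicit exclusion list (bulk
water/CO₂/proton transport dominates otherwise). A product with zero
theoretical maximum (e.g. an oxygen-dependent pathway under an
anaerobic medium) returns a diagnostic result, not an exception.
Biomass sensitivity pins biomass to f·μ* for f on a [0, 1] grid and
maximises the product, recording pFBA fluxes and FVA intervals for a
watch list; LP failures at single grid points are collected without
aborting the sweep.

## What the synthetic data emulates — and what it does not

`synth.make_template_model` builds a ~24-reaction network emulating
the shape of a reference-quality bacterial GEM: glucose uptake chain,
two parallel glycolytic isozymes (`g1`/`g2`), a respiration route (5
ATP per triose, oxygen-dependent) against a fermentation route (1 ATP,
reversible, supports growth on lactate), ammonium assimilation into an
amino acid, a biomass pseudo-reaction (1 triose + 1 amino acid + 30
ATP), an ATP maintenance demand (lb 1), and a three-step siderophore
pathway whose carrier-bound intermediates carry "R" so the balance
audit's unbalanceable branch is always exercised. ATP/ADP/phosphate
use real formulas and charges, and every hydrolysis/synthesis is
proton- and water-coupled consistently, so all non-carrier internal
reactions are exactly mass- and charge-balanced and the network is
provably free of energy-generating cycles. Default medium: glucose 10,
O₂ 20, ammonium 50 mmol·gDW⁻¹·h⁻¹ — glucose-limited aerobic growth at
1.427 h⁻¹, fermentative growth at 0.594 h⁻¹.

The panel generator drops each non-core reaction per strain with a
stated probability (core = reactions essential on the default medium,
never dropped, so every strain remains viable) and renames genes with
a strain prefix. Hit tables plant true orthologs at 95% identity with
full-length alignments and dominant bitscores, and decoys that fail
either the identity filter (50%) or the coverage filter (short
alignments), with bitscores below every true hit so best-hit mutuality
survives even if the filters are loosened. Plates draw activity from
{5..9} for growth and {0..2} for no-growth with calls flipped at a
stated rate and a fixed unmapped fraction; flux tables are the model's
own rescaled pFBA solution plus Gaussian noise of stated CV. Every
generator is a pure function of (parameters, seed) with a named
pseudorandom stream, so outputs are byte-reproducible and adding a
generator never perturbs existing fixtures.

What passing these tests shows: the algorithms are correct against
independent oracles (truth tables, exhaustive search, closed-form LPs,
cobrapy) under conditions where the ground truth is known exactly.
What it does not show: performance on genome-scale inputs (thousands
of reactions), robustness to the annotation noise, paralogy and
horizontal transfer of real alignment data, or biological accuracy of
any particular curation decision — real models add regulatory,
kinetic and annotation error modes the generators deliberately omit.

## Problem sizes

The shipped analyses and tests use a 6-strain panel at dropout 0.3, a
200-well plate at flip rate 0.2, 13 measured fluxes, 10-point FSEOF
grids and 21-point sensitivity grids; the full suite (including the
double-deletion screens over all viable gene pairs of the template)
solves a few thousand small LPs. These sizes were chosen so every
planted truth is recoverable exactly and every oracle (exhaustive
subset search, pairwise screens) stays brute-forceable.

## Known limitations

- The phenotype swap removes the default source of the well's element
  class only; wells whose nutrient spans several element classes are
  handled by their class label alone, and molar plate concentrations
  are not converted to uptake rates (one configurable uptake bound,
  default 10, applies to every well).
- No regulatory layer: repressed-but-present pathways surface as false
  positives by design.
- FVA containment uses signed fluxes; measurements reported as
  magnitudes must be sign-matched to the model's convention first.
- Gap filling is unweighted (pure cardinality); no likelihood or
  annotation evidence enters the MILP.
- The SBML writer emits Level 3 + FBC v2 with notes-based subsystem/
  provenance/annotation transport; no other SBML extensions are
  supported.
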