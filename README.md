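# gemforge

Multi-reference reconstruction and analysis of genome-scale metabolic
models (GEMs), written for systems biologists who assemble a
strain-specific model from a panel of curated reference models and then
interrogate it with constraint-based methods.

The workflow it implements, end to end:

1. **Orthology** — pairwise protein alignment hit tables (12-column
   tabular layout) are filtered at ≥ 80% identity and ≥ 25% query
   coverage, best hits are taken by bitscore, and mutual best hits
   (BBH) define orthologs; per-strain BBH maps assemble into a binary
   gene × strain orthology matrix.
2. **Reconstruction** — a base model is *reduced* to the reactions
   whose gene–protein–reaction (GPR) rule stays satisfiable under the
   ortholog map (spontaneous reactions and artificial genes such as the
   `S0001` convention are exempt), then *augmented* from further
   reference models in a declared order with first-come provenance, so
   every reaction's origin is accounted for.
3. **Curation audits** — duplicate reactions (identical stoichiometry
   up to orientation), elemental/charge balance (reactions touching
   rest-group "R" metabolites or missing formulas are *unbalanceable*,
   reported rather than guessed), energy-generating cycles (closed
   system, maximise a currency dissipation reaction; any positive
   optimum is a thermodynamically infeasible loop), cardinality-minimal
   MILP gap filling, and targeted removals/deactivations.
4. **Flux analysis** — FBA, parsimonious FBA and flux variability
   analysis over one LP contract (HiGHS via scipy):

   maximise **c·v** subject to **S v = 0**, **lb ≤ v ≤ ub**,

   with pFBA minimising Σ|v| at a fraction of the optimum and FVA
   reporting per-reaction [min, max] with **c·v ≥ f·optimum** appended.
   Media are applied by closing all exchange lower bounds and opening
   stated uptakes (negative exchange flux = uptake); anaerobiosis
   closes the oxygen exchange.
5. **Validation** — phenotype-plate concordance (activity index ≥ 3 =
   observed growth; predicted growth = FBA ≥ 5% of wild type after an
   element-class nutrient swap; confusion matrix with one-decimal
   accuracy) and ¹³C flux containment (measured net fluxes, normalised
   to carbon uptake = 100, checked against FVA intervals over
   thresholds 90–99%).
6. **Strain design** — gene/reaction essentiality and synthetic-lethal
   screens (pairs drawn only from individually viable genes), and FSEOF
   (flux scanning with enforced objective function): step the product
   flux toward its maximum, re-maximise biomass, take pFBA fluxes, and
   classify reactions with sign-consistent monotone profiles by the
   least-squares slope of their flux against product flux —
   amplification (> 0) or attenuation (< 0) targets.

Everything runs on synthetic fixtures with planted ground truth
(`gemforge.synth`): a ~24-reaction template network, a reference panel
with controlled reaction dropout, hit tables whose decoys straddle the
identity/coverage filters, phenotype plates with a controlled
label-flip rate, and flux tables built from the model's own pFBA
solution plus noise. No downloads are required.

## Worked example

```python
from gemforge import flux, synth

model = synth.make_template_model(0)
constrained = flux.apply_medium(model, synth.default_medium())

print(flux.fba(constrained).objective_value)            # 1.427083333333333
print(flux.fba(flux.apply_medium(model, synth.default_medium(),
                                 aerobic=False)).objective_value)  # 0.59375

screen = flux.single_gene_deletion(constrained)
print(sorted(screen.essential))                          # ['gA', 'gN', 'gT']

pairs = flux.double_gene_deletion(constrained, single=screen)
print(sorted(pairs.essential))   # [('g1', 'g2'), ('gF', 'gR'), ('gF', 's0001')]
```

The template grows at 1.427 h⁻¹ aerobically (respiration yields 5 ATP
per triose) and 0.594 h⁻¹ fermentatively (1 ATP per triose, oxygen
closed). The glucose transporter (`gT`), ammonium transporter (`gN`)
and amino-acid synthesis (`gA`) genes are essential; the parallel
glycolytic isozymes `g1`/`g2` are a synthetic-lethal pair, as are the
respiration/fermentation routes (`gR`/`gF`).

The numbered drivers under `analysis/` run the whole study in order —
simulate inputs, build the orthology matrix, reconstruct and audit the
draft, score phenotype concordance, validate fluxes, screen
essentiality, and predict FSEOF targets — writing tables under
`results/`:

```
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_orthology_matrix.py
python analysis/03_reconstruct_draft.py
...
python analysis/07_fseof_targets.py
```

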