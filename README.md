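# scopa

Pollen-load diet analysis for wild bees: from microscope-quantified scopal
loads to host-range (lecty) categories, standardised diet breadth, and
diet-breadth–occupancy statistics.

## The problem

Direct observation of flower visits underestimates what bees actually
collect: many bees are not flower constant, forage far from the recorder,
and visit flowers (tree canopies especially) nobody watches. Microscopic
analysis of the scopal pollen load of individually collected females
measures the diet by volume instead. This package implements the analysis
chain used in such studies, for ecologists characterising bee diets on
farmland or elsewhere:

1. **Quantification.** Each load has a size scored in eighths of a full
   load and a percentage composition by volume. Constituents under 1% are
   excluded as probable contamination and the rest renormalised; each
   taxon's percentage is then corrected by load size,
   `w(t) = (size/8) × p(t)`, so a full 8/8 load of 50% *Centaurea nigra* /
   50% *Leucanthemum vulgare* weighs 50 per species and a 2/8 load that is
   100% *Hypochaeris radicata* weighs 25. Summing weights across a species'
   loads gives its diet profile (percent of pollen volume per plant taxon
   and family, plus per-load pure/presence percentages).

2. **Lecty classification.** Two standard oligolecty criteria are applied
   at genus and family level — ≥95% of pollen volume from one taxon
   (Müller), and ≥90% of females carrying pure loads of one taxon
   (Sipes–Tepedino). Both passing at genus level ⇒ narrowly oligolectic;
   both at family level ⇒ broadly oligolectic; disagreement resolves to the
   less specialised side: polylectic with a strong preference (top family
   ≥70% of volume), mesolectic (≤2 families at ≥1%), or polylectic s.s.
   Classification needs at least 3 loads.

3. **Rarefaction.** Diet breadth is standardised across unequal samples by
   an integer transform (percentage × n_loads × 10, rounded, giving
   tenth-of-a-load units; 40% at n=14 → 5.6 loads → 56 units) followed by
   subsampling without replacement (1000 draws) to 12 and to 3 standardised
   loads. The hypergeometric closed form
   `E[S] = Σ_t 1 − C(N−N_t, n)/C(N, n)` is provided as oracle and fast path.

4. **Statistics.** Mann–Whitney rank-sum tests (W = pairs where the first
   sample exceeds the second, ties ½) compare observation- vs pollen-derived
   breadth; an OLS Gaussian linear model (optionally with bee family and
   farm-type factors) and Spearman's rank correlation relate rarefied
   breadth to the number of farms a species occupies.

5. **Simulation.** A synthetic foraging-survey generator with known ground
   truth: per-bee Dirichlet diets over a family-structured plant community,
   a flower-constancy mixture producing pure and mixed loads, discrete load
   sizes, and farm occupancy increasing with true diet breadth — used for
   parameter-recovery validation of the whole pipeline.

Reference tables from a published survey of 31 farmland solitary bee
species are packaged as fixtures (`scopa.fixtures`, provenance in
`src/scopa/data/README.md`) and anchor the tests.

## A worked example

```python
from scopa import classify_table
from scopa.fixtures import host_spectrum_profiles

profiles, printed = host_spectrum_profiles()
table = classify_table(profiles, printed_categories=printed)
print(f"{int(table['match'].sum())}/{len(table)} published categories reproduced")
```

prints `30/31 published categories reproduced`. The one discordance is a
documented property of the rules, not a bug: *Andrena alfkenella* passes the
volume criterion (97% Apiaceae) but fails the pure-load criterion (33.3% <
90), and the stated lower-specialisation combination rule then yields
"polylectic with a strong preference", whereas the published table prints
"broadly oligolectic" for that row.

Each script in `examples/` is a self-contained narrative: weighting single
loads, classifying the reference table, rarefying a diet (Monte-Carlo vs
closed form, e.g. `E[pollen types] = 4.971 ± 0.168` at 12 loads vs `4.967`
exact), the observation-vs-pollen comparison (`W = 211.5, p = 0.0012` for
plant species; `W = 151.5` for families), and a full synthetic survey run
(100% category recovery at 15 loads/bee; breadth–occupancy slope positive
and significant).

There is also a thin CLI:

```bash
scopa simulate --out survey --seed 4
scopa run --loads survey/loads.csv --taxonomy survey/taxonomy.csv \
          --occurrence survey/occurrence.csv --bee-families survey/truth.csv \
          --out analysis
scopa report analysis
```

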