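# Methods

## Load quantification

A scopal load is a composition: taxon percentages by volume summing to 100
(±0.5 to absorb one-decimal rounding in field and reference data).
Constituents below 1% of the load are excluded as probable contamination
**before any further analysis**, and the survivors are renormalised to 100.
Renormalisation is a design choice — the protocol only says such
constituents are excluded — made to keep loads compositional so that the
subsequent size correction is unaffected by removed contamination. A
consequence adopted deliberately: a 99.5/0.5 load counts as a *pure* load
after filtering, since the pure-load statistic belongs to the "further
analysis" the exclusion precedes.

The size correction multiplies each percentage by `size/8`, where size is
the load's visually scored eighths (1–8). Units are percent-load units: a
full load totals 100, so the published worked examples come out exactly
(50/50 → 50 each; a 2/8 pure load → 25). Aggregation across a species'
loads is **volume-weighted** — shares are ratios of summed weights, not
averages of per-load compositions — because the corrected weights are the
quantity that reflects total pollen collected. Pure-load and presence
percentages are per-load counts (after filtering) at species, genus and
family level; pure ≤ presence always.

Genus-level bookkeeping: taxa identifiable only to genus are their own
genus-level bucket; taxa identifiable only to family fall back to the
family label at genus level. This matches how mixed-resolution pollen data
are actually recorded.

## Lecty classification

Thresholds (all configurable via `LectyConfig`, defaults in parentheses):

| parameter | default | meaning |
|---|---|---|
| `volume_threshold` | 95% | volume criterion: top taxon share at a level |
| `pure_threshold` | 90% | pure-load criterion: top pure-load percentage |
| `strong_pref_threshold` | 70% | top-family share for "strong preference" |
| `mesolectic_family_count` | 2 | max families (≥1% of volume) for mesolecty |
| `min_loads` | 3 | smallest classifiable sample |

The decision tree: both criteria at genus ⇒ narrow oligolecty; both at
family ⇒ broad oligolecty; otherwise strong preference (top family ≥70%),
then mesolecty (≤2 families), then polylecty s.s. When exactly one
oligolecty criterion passes, the species falls through to the polylectic
branches — the "lower degree of specialisation" resolution of criterion
disagreement. The strong-preference check precedes the mesolecty check;
the reference table requires this ordering (a two-family diet with a 95.3%
top share is printed as strong preference, while a two-family diet with a
67.8% top share is mesolectic).

The 70% and "exactly two families" values are calibration choices: the
category definitions defer to supplementary sources not reproduced here,
and these are the unique round values consistent with every row of the
reference table — the fixture brackets the strong-preference cutoff between
68.1 (printed polylectic s.s.) and 73.1 (printed strong preference), and a
regression test asserts the concordance is unchanged for any cutoff in
(68.1, 73.1].

A lattice subtlety, inherent in the published categories rather than
introduced here: specialisation rank is not globally monotone in the top
family's share. For a two-family diet, growing the top share crosses from
mesolectic (rank 3) into strong preference (rank 2). The monotonicity
property is therefore asserted only for diets spanning more than
`mesolectic_family_count` families, where it genuinely holds.

Classification refuses samples under `min_loads` rather than guessing;
small samples (3–9 loads) remain classifiable but should be read against
prior knowledge, since a handful of loads can over- or under-represent a
family.

## Rarefaction

The integer transform maps percentage shares to tenth-of-a-load units:
`count(t) = round(share(t)/100 × n_loads × 10)`, rounding half away from
zero (exposed as an option; half-even is available). Zero counts drop out.
The Monte-Carlo rarefier pools the units and draws `10 × target_loads` of
them without replacement, 1000 times by default, under a caller-supplied
seed; it reports the mean and SD of the distinct-taxon count.

`rarefy_exact` computes the expectation in closed form,
`E[S] = Σ_t 1 − C(N−N_t, n)/C(N, n)`, in log-space for stability. It is the
test oracle (itself checked against brute-force enumeration on tiny pools)
and a fast path; the resampling implementation is kept because the
downstream SD and the study's stated procedure are resampling-based.

Two analysis tiers mirror the study design: species with ≥10 loads rarefied
to 12, species with ≥3 loads rarefied to 3. The first target exceeds the
tier's own minimum; how 10–11-load species were handled in the original
design is unstated, so the pipeline requires a species' pooled units to
cover the target subsample and otherwise excludes it with a logged reason
(a 10-load species has ~100 units < 120 and is excluded from the 12-load
tier). No species is ever subsampled beyond its own data.

## Statistics

The Mann–Whitney W follows the convention "pairs where the first sample
exceeds the second, ties ½" (so complementarity `W(x,y)+W(y,x)=|x||y|`
holds, and identical samples of size n score n²/2). P-values use the
normal approximation with midrank tie correction and continuity correction
(scipy's asymptotic method); an exact option exists for tie-free data, but
heavy ties in count data make the asymptotic form the default. The
breadth–occupancy model is ordinary least squares with treatment-coded
categorical factors (reference = alphabetically first level) and raises on
rank-deficient designs. Spearman's rho uses midranks and refuses constant
input.

## The synthetic generator

`ScenarioConfig` defaults emulate the reference survey's scale: 93 plant
species in 32 families, 31 bee species, 19 farms, and a 5/31 share of true
single-family specialists. Per-bee diets are symmetric-Dirichlet
(concentration 0.3 for polylects, so diets are sparse; concentration 1
within the host family for oligolects). Loads follow a flower-constancy
mixture: with probability `constancy` (default 0.45, matching the observed
mean share of pure loads across the reference species) a load is 100% one
host drawn from the diet; otherwise it is a normalised 20-grain multinomial
sample (so mixed loads carry a handful of constituents at multiples of 5%).
Load sizes are uniform on 1..8 eighths — no distribution is reported for
real loads, so the least-informative choice is used and exposed in config.
Occupancy is Bernoulli per farm with presence probability increasing
linearly in the rank of true diet breadth between 0.15 and 0.95; this
encodes only the monotone association the statistics must recover, not any
particular effect size. Every synthetic plant species is its own genus, so
genus-level and species-level statistics coincide in synthetic data; narrow
vs broad oligolecty then turns on whether one species dominates the host
family.

Ground truth applies the same decision tree to the *exact* generative
profile, with analytic pure/presence probabilities (`c·P + (1−c)·P^m` and
`c·P + (1−c)(1−(1−P)^m)` for a group with diet mass P and grain count m).

What the generator does **not** emulate: phenology and seasonal turnover,
spatial foraging structure, farm-management effects beyond a label,
between-individual diet variation within a bee species, and measurement
error in the visual load-size score. Passing recovery tests therefore show
the pipeline is consistent and unbiased under its own assumptions, not that
those assumptions hold in any particular field system.

Recovery behaviour worth knowing: with 10 loads the oligolectic *status*
(narrow-or-broad vs not) is recovered essentially always at high constancy,
but the narrow/broad boundary itself flips stochastically whenever the true
top host holds roughly 75–95% of a single-family diet — the genus-level
pure-load count sits near its 90% threshold at that sample size.
`recovery_experiment` therefore reports both the exact five-category match
rate and the status match rate.

## Numerical choices and degenerate inputs

- Sum-to-100 tolerance ±0.5 throughout (rounded percentages).
- Taxon labels match case-insensitively after whitespace collapsing.
- Ties in `top()` break alphabetically for determinism.
- Empty genus-level data (family-only profiles) make the genus criteria
  fail rather than error, which is the correct reading of "no evidence of
  genus-level specialisation".
- All randomness flows through explicit integer seeds (numpy Generator);
  identical seeds give byte-identical simulation files and identical
  rarefaction results.
- Problem sizes in the validation suite (e.g. 200 classification replicates,
  100 simulated surveys for the slope-recovery check, 300–1000 rarefaction
  resamples) are chosen so the full suite completes in well under a minute
  of simulation time while keeping Monte-Carlo error far below the margins
  being asserted.

## Known limitations

- The reference fixture is family-level, so genus-level criteria can be
  evaluated on it only where the published row pins the genus down; the
  packaged data README documents exactly which rows those are.
- Published per-species rarefied values cannot be recomputed: they require
  the raw species-level load data, which was never published. The
  rarefaction code is instead validated against its closed form and by
  simulation.
- The headline field regression (occupancy on rarefied breadth) is likewise
  not reproducible from published material, since per-species farm counts
  appear only in a figure; the model code is validated on synthetic survey
  data with a known positive association.
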