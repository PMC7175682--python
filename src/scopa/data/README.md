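# Reference fixtures

Two reference tables hand-transcribed from a published pollen-load survey of
solitary bees on 19 lowland farms in Hampshire and West Sussex, southern
England (surveys 2013-2015; scopal loads collected in 2015 and quantified by
light microscopy). They serve as validation fixtures for the classification
and statistics code; they are inputs, not computed outputs.

## host_spectrum_composition.csv / host_spectrum_species.csv

The published host-plant spectrum of the 31 bee species with at least three
analysed pollen loads.

- `host_spectrum_composition.csv` — one row per (bee species, plant family):
  the aggregated, load-size-weighted percentage of pollen volume per family.
  `other` pools families individually below the table's reporting cutoff.
- `host_spectrum_species.csv` — per-species metadata: number of loads `n_loads`,
  number of localities the loads came from `n_localities` (stored but unused in
  any computation), the percentage of pure loads of the preferred host
  (`pure_load_pct`), the percentage of loads containing the preferred host
  (`presence_pct`), the published host-range category (`printed_category`), and
  the preferred host with its taxonomic level. `genus_top_share_pct` /
  `genus_pure_pct` are filled only where the published row pins down
  genus-level values: the two single-host specialists (Andrena florea on
  Bryonia dioica, Melitta tricincta on Odontites vernus; both 100) and
  Lasioglossum villosulum (top genus Hypochaeris at 49.3% of volume). Empty
  cells mean genus-level composition was not published; the genus-level
  oligolecty criterion cannot pass for those rows, which is consistent with
  every published category.

Transcription notes:

- Three compositions as published do not close to 100 (Andrena bicolor 98.7,
  A. haemorrhoa 98.2) or overshoot (Halictus tumulorum as extracted). For
  those rows the residual `other` share was recomputed by difference so the
  composition sums to 100.0 (bicolor other 3.3, haemorrhoa other 4.8,
  tumulorum other 0.6 with Rubiaceae read as 6.8). No host-range category is
  sensitive to these residuals.
- The published table prints "Narroly oligolectic" (sic) for A. florea; the
  fixture stores the canonical label.

## diet_breadth.csv

Per-species diet breadth (the 29 species above excluding the two single-host
specialists), counted two ways: plant species and plant families recorded by
direct flower-visit observation versus detected in pollen loads, plus the
published rarefied richness at a standardised 12 pollen loads for the 17
species with at least 10 loads. The transcription reproduces the published
column means (6.9, 13.6, 3.4, 7.6; rarefied 12.9) and the published
Mann-Whitney statistics (W = 211.5 for plant species, 151.5 for families).
The accompanying text quotes the standard error of observed plant species as
0.9 while the table's average row prints 1.0; the value computed from this
transcription is 0.98, matching the table.

The per-species rarefied values cannot be recomputed here: they require the
raw species-level load data, which was not published. They are stored for
reference and used only in the breadth-occurrence examples.
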