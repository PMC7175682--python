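"""Filter and size-weight single pollen loads.

Builds two loads — a full (8/8) mixed load and a quarter (2/8) pure load —
and prints their size-corrected taxon weights in percent-load units (a full
load totals 100). The weights are what the diet-profile aggregation sums:
they make a bee that came home nearly empty count for less than one with a
full scopa.
"""

from scopa import PollenLoad, filter_minor_constituents, weight_load

full_mixed = PollenLoad(
    load_id="ex1", bee_species="Lasioglossum leucozonium", farm_id="farm01",
    round_id="round2", load_size_eighths=8,
    constituents={"Centaurea nigra": 49.7, "Leucanthemum vulgare": 49.7,
                  "Veronica persica": 0.6},  # sub-1% contamination
).validate()

quarter_pure = PollenLoad(
    load_id="ex2", bee_species="Lasioglossum villosulum", farm_id="farm01",
    round_id="round2", load_size_eighths=2,
    constituents={"Hypochaeris radicata": 100.0},
).validate()

for load in (full_mixed, quarter_pure):
    weighted = weight_load(filter_minor_constituents(load))
    print(f"{load.load_id}: size {load.load_size_eighths}/8")
    for taxon, w in weighted.weights.items():
        print(f"  {taxon:22s} weight {w:6.1f}")

print(
    "\nThe 0.6% Veronica constituent was removed as likely contamination and"
    "\nthe rest renormalised, so the 50/50 full load weighs 50 per species;"
    "\nthe pure quarter load weighs 25: a quarter of a full load's 100."
)
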