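"""Compare diet breadth measured by observation vs pollen-load analysis.

Uses the packaged per-species breadth table (29 species): the number of
plant species and families each bee was seen visiting for pollen, against
the number detected microscopically in its scopal loads. Pollen analysis
consistently detects more hosts; the Mann-Whitney rank-sum test quantifies
the difference.
"""

from scopa import rank_sum_test, summarise_breadth
from scopa.fixtures import load_diet_breadth

table = load_diet_breadth()
summary = summarise_breadth(
    table,
    columns=["obs_plant_species", "pollen_plant_species",
             "obs_plant_families", "pollen_plant_families"],
)
print(summary.round(2).to_string())

for label, (a, b) in {
    "plant species": ("obs_plant_species", "pollen_plant_species"),
    "plant families": ("obs_plant_families", "pollen_plant_families"),
}.items():
    fit = rank_sum_test(table[a], table[b])
    print(f"{label:14s}: W = {fit.statistic:.1f}, p = {fit.pvalue:.4f}")

print(
    "\nW counts observation-vs-pollen pairs where observation is larger"
    "\n(ties half); values far below the null 29^2/2 = 420.5 show pollen"
    "\nanalysis detects significantly more host taxa than direct observation."
)
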