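"""Simulate a foraging survey and run the whole pipeline over it.

Generates a synthetic community (default: 93 plant species in 32 families,
31 bee species on 19 farms) with known ground truth, writes the survey files,
runs quantification -> classification -> rarefaction -> statistics, and
compares the estimated host-range categories with the truth.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from scopa import run_pipeline
from scopa.simulate import ScenarioConfig, generate_scenario

out = Path(tempfile.mkdtemp(prefix="scopa_survey_"))
scenario = generate_scenario(ScenarioConfig(seed=20260920))
paths = scenario.write(out / "survey")
run_dir = run_pipeline(
    paths["loads"], paths["taxonomy"], out / "analysis",
    occurrence_path=paths["occurrence"], bee_families_path=paths["truth"],
    n_resamples=1000, seed=1,
)

truth = scenario.ground_truth().set_index("bee_species")
estimated = pd.read_csv(run_dir / "classification.csv").set_index("bee_species")
joined = estimated.join(truth[["true_category", "true_breadth", "true_farm_count"]])
agree = (joined["category"] == joined["true_category"]).mean()
print(joined[["category", "true_category", "n_loads"]].head(8).to_string())
print(f"\ncategory recovery over {len(joined)} bee species: {agree:.0%}")

stats = json.loads((run_dir / "stats.json").read_text())
tier = stats["tier_12_loads"]
print(
    f"breadth-occurrence model ({tier['formula']}):\n"
    f"  slope = {tier['coefficients']['rarefied_breadth']:.3f}, "
    f"t = {tier['tvalues']['rarefied_breadth']:.2f}, "
    f"p = {tier['pvalues']['rarefied_breadth']:.2g}, "
    f"adj R^2 = {tier['adj_r_squared']:.3f}"
)
print(
    "\nA positive, significant slope recovers the generative rule that bees"
    "\nwith broader true diets occupy more farms. Outputs written under:"
    f"\n{run_dir}"
)
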