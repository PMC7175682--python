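"""Synthetic foraging-survey generator with known ground truth.

Generates load-level data with the statistical structure the analysis
pipeline assumes, standing in for a field survey: each bee species has a
true diet (a probability vector over a family-structured plant community,
Dirichlet-distributed; optionally confined to one host family for oligolect
ground truth). A scopal load is produced by a simple flower-constancy
mixture: with probability ``constancy`` the whole load comes from a single
host species drawn from the true diet, otherwise the composition is a
normalised multinomial sample of grains from the true diet. Load sizes are
discrete eighths (1/8 ... 8/8). Frequency of occurrence is generated as a
binomial over farms with presence probability increasing in true diet
breadth, producing the monotone breadth-occurrence association the
statistics module must recover without asserting any particular effect size.

Defaults mirror the survey the pipeline was built around: 93 plant species
in 32 families, 31 bee species, 19 farms, a handful of true specialists
among mostly polylectic bees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lecty import LectyCategory, LectyConfig, classify
from .quantify import DietProfile, aggregate_profile
from .rarefaction import integer_transform, rarefy_exact
from .records import (
    PlantTaxon,
    PollenLoad,
    Taxonomy,
    write_loads,
    write_occurrence,
    write_taxonomy,
)
from .stats import gaussian_linear_fit

__all__ = [
    "ScenarioConfig",
    "BeeTruth",
    "SyntheticScenario",
    "generate_scenario",
    "generate_loads",
    "recovery_experiment",
]

BEE_FAMILIES = ("Andrenidae", "Halictidae", "Melittidae")


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of a synthetic foraging survey.

    The community and survey sizes default to the study conditions
    (93 plant species / 32 families detected in loads, 31 characterisable
    bee species, 19 farms). ``constancy`` is the probability a load is a
    single-host (pure) load; its default matches the observed mean share of
    pure loads across characterised species (~45%). ``mixture_grains`` is
    the multinomial sample size for mixed loads; ``dirichlet_concentration``
    the symmetric concentration of polylect diets (sparse, so a bee uses a
    modest subset of the community). ``oligolect_fraction`` is the share of
    bee species whose true diet is confined to a single host family (5 of 31
    in the reference survey).
    """

    n_plant_species: int = 93
    n_families: int = 32
    n_bee_species: int = 31
    n_loads_per_bee: int = 15
    n_farms: int = 19
    constancy: float = 0.45
    dirichlet_concentration: float = 0.3
    within_family_concentration: float = 1.0
    oligolect_fraction: float = 5 / 31
    mixture_grains: int = 20
    occurrence_p_min: float = 0.15
    occurrence_p_max: float = 0.95
    breadth_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_plant_species:
            raise ValueError("more families than plant species")
        if not 0 < self.constancy <= 1:
            raise ValueError("constancy must be in (0, 1]")
        if min(self.n_plant_species, self.n_bee_species, self.n_farms,
               self.n_loads_per_bee, self.mixture_grains) < 1:
            raise ValueError("all counts must be positive")


@dataclass
class BeeTruth:
    """Ground truth for one synthetic bee species."""

    bee_species: str
    bee_family: str
    template: str  # "oligolect" | "polylect"
    diet: np.ndarray  # probability over plant species
    host_family: str = ""
    true_category: LectyCategory | None = None
    true_breadth: int = 0
    true_farm_count: int = 0


@dataclass
class SyntheticScenario:
    """A generated community, bee set and occurrence table with ground truth."""

    config: ScenarioConfig
    taxonomy: Taxonomy
    species_labels: list[str]
    bees: list[BeeTruth]
    occurrence: list[dict]

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bee_species": [b.bee_species for b in self.bees],
                "bee_family": [b.bee_family for b in self.bees],
                "template": [b.template for b in self.bees],
                "host_family": [b.host_family for b in self.bees],
                "true_category": [b.true_category.value for b in self.bees],
                "true_breadth": [b.true_breadth for b in self.bees],
                "true_farm_count": [b.true_farm_count for b in self.bees],
            }
        )

    def all_loads(self) -> list[PollenLoad]:
        loads: list[PollenLoad] = []
        for bee in self.bees:
            loads.extend(generate_loads(bee, self))
        return loads

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit taxonomy.csv, loads.csv, occurrence.csv, truth.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "taxonomy": out / "taxonomy.csv",
            "loads": out / "loads.csv",
            "occurrence": out / "occurrence.csv",
            "truth": out / "truth.csv",
        }
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        write_loads(self.all_loads(), paths["loads"])
        write_occurrence(self.occurrence, paths["occurrence"])
        self.ground_truth().to_csv(paths["truth"], index=False)
        return paths


def _make_taxonomy(config: ScenarioConfig, rng: np.random.Generator) -> tuple[Taxonomy, list[str]]:
    # every synthetic plant species gets its own genus; families are filled
    # round-robin first (so none is empty), then at random
    families = [f"Family{i + 1:02d}" for i in range(config.n_families)]
    assignment = [families[i % config.n_families] for i in range(config.n_plant_species)]
    rng.shuffle(assignment)
    taxonomy = Taxonomy()
    labels = []
    for i in range(config.n_plant_species):
        genus = f"Genus{i + 1:03d}"
        label = f"{genus} flora"
        taxonomy.add(PlantTaxon(label, genus, assignment[i], "species"))
        labels.append(label)
    return taxonomy, labels


def _true_profile(bee: BeeTruth, scenario: SyntheticScenario) -> DietProfile:
    """The bee's exact diet profile under the generative model.

    Volume shares are the true diet probabilities; the pure-load and
    presence percentages are the analytic per-load probabilities implied by
    the constancy mixture: a load is pure for a taxon group with probability
    c P + (1 - c) P^m and contains it with probability c P + (1 - c)
    (1 - (1 - P)^m), P being the group's total diet probability.
    """
    cfg = scenario.config
    c, m = cfg.constancy, cfg.mixture_grains
    taxonomy = scenario.taxonomy
    labels = scenario.species_labels

    groups = {"species": {}, "genus": {}, "family": {}}
    for label, p in zip(labels, bee.diet):
        if p <= 0:
            continue
        taxon = taxonomy.lookup(label)
        for level, key in (
            ("species", taxon.label),
            ("genus", taxon.genus_label),
            ("family", taxon.family),
        ):
            groups[level][key] = groups[level].get(key, 0.0) + float(p)

    profile = DietProfile(bee_species=bee.bee_species, n_loads=cfg.n_loads_per_bee)
    for level, probs in groups.items():
        shares = {k: 100.0 * p for k, p in probs.items()}
        if level == "species":
            profile.species_level = shares
        elif level == "genus":
            profile.genus_level = shares
        else:
            profile.family_level = shares
        profile.pure_load_pct[level] = {
            k: 100.0 * (c * p + (1 - c) * p**m) for k, p in probs.items()
        }
        profile.presence_pct[level] = {
            k: 100.0 * (c * p + (1 - c) * (1 - (1 - p) ** m)) for k, p in probs.items()
        }
    return profile


def generate_scenario(
    config: ScenarioConfig, lecty_config: LectyConfig = LectyConfig()
) -> SyntheticScenario:
    """Draw a synthetic scenario: community, true diets, occurrence, truth.

    Reproducible: the same config (including seed) yields byte-identical
    written files.
    """
    rng = np.random.default_rng([config.seed, 0])
    taxonomy, labels = _make_taxonomy(config, rng)
    by_family: dict[str, list[int]] = {}
    for i, label in enumerate(labels):
        by_family.setdefault(taxonomy.family_of(label), []).append(i)

    n_oligo = int(round(config.oligolect_fraction * config.n_bee_species))
    bees: list[BeeTruth] = []
    for b in range(config.n_bee_species):
        template = "oligolect" if b < n_oligo else "polylect"
        diet = np.zeros(config.n_plant_species)
        host_family = ""
        if template == "oligolect":
            host_family = sorted(by_family)[rng.integers(len(by_family))]
            members = by_family[host_family]
            diet[members] = rng.dirichlet(
                np.full(len(members), config.within_family_concentration)
            )
        else:
            diet = rng.dirichlet(
                np.full(config.n_plant_species, config.dirichlet_concentration)
            )
        bees.append(
            BeeTruth(
                bee_species=f"Apis{'um' if template == 'oligolect' else 'a'} bee{b + 1:02d}",
                bee_family=BEE_FAMILIES[b % len(BEE_FAMILIES)],
                template=template,
                diet=diet,
                host_family=host_family,
            )
        )

    scenario = SyntheticScenario(
        config=config, taxonomy=taxonomy, species_labels=labels, bees=bees,
        occurrence=[],
    )

    # ground truth: classify the exact profile; breadth above the floor
    for bee in bees:
        bee.true_category = classify(_true_profile(bee, scenario), lecty_config).category
        bee.true_breadth = int(np.sum(bee.diet >= config.breadth_floor))

    # occurrence: presence probability increases linearly with the rank of
    # true diet breadth; farm-level presence is Bernoulli (binomial count)
    breadths = np.array([b.true_breadth for b in bees], dtype=float)
    order = pd.Series(breadths).rank(method="average").to_numpy()
    span = max(len(bees) - 1, 1)
    p_occ = config.occurrence_p_min + (
        config.occurrence_p_max - config.occurrence_p_min
    ) * (order - 1) / span
    occ_rng = np.random.default_rng([config.seed, 1])
    occurrence = []
    for bee, p in zip(bees, p_occ):
        present = occ_rng.random(config.n_farms) < p
        bee.true_farm_count = int(present.sum())
        for f in np.flatnonzero(present):
            occurrence.append(
                {
                    "bee_species": bee.bee_species,
                    "farm_id": f"farm{f + 1:02d}",
                    "n_sightings": int(1 + occ_rng.poisson(1.5)),
                }
            )
    scenario.occurrence = occurrence
    return scenario


def generate_loads(
    bee: BeeTruth,
    scenario: SyntheticScenario,
    n_loads: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PollenLoad]:
    """Generate one bee species' scopal loads under the constancy mixture.

    Each load draws its size uniformly from 1..8 eighths; with probability
    ``constancy`` it is 100% one host species drawn from the true diet,
    otherwise a normalised multinomial grain sample (proportions rounded to
    0.1%, largest constituent absorbing the rounding drift).
    """
    cfg = scenario.config
    if n_loads is None:
        n_loads = cfg.n_loads_per_bee
    if rng is None:
        idx = next(i for i, b in enumerate(scenario.bees) if b is bee)
        rng = np.random.default_rng([cfg.seed, 2, idx])
    labels = scenario.species_labels
    loads: list[PollenLoad] = []
    for j in range(n_loads):
        size = int(rng.integers(1, 9))
        farm = f"farm{int(rng.integers(cfg.n_farms)) + 1:02d}"
        rnd = f"round{int(rng.integers(1, 5))}"
        if rng.random() < cfg.constancy:
            host = labels[int(rng.choice(len(labels), p=bee.diet))]
            constituents = {host: 100.0}
        else:
            counts = rng.multinomial(cfg.mixture_grains, bee.diet)
            nz = np.flatnonzero(counts)
            props = {
                labels[i]: round(100.0 * counts[i] / cfg.mixture_grains, 1)
                for i in nz
            }
            drift = 100.0 - sum(props.values())
            biggest = max(props, key=lambda t: (props[t], t))
            props[biggest] = round(props[biggest] + drift, 1)
            constituents = props
        loads.append(
            PollenLoad(
                load_id=f"{bee.bee_species}|{j + 1:03d}",
                bee_species=bee.bee_species,
                farm_id=farm,
                round_id=rnd,
                load_size_eighths=size,
                constituents=constituents,
            ).validate()
        )
    return loads


def _estimate_category(
    bee: BeeTruth,
    scenario: SyntheticScenario,
    n_loads: int,
    rng: np.random.Generator,
    lecty_config: LectyConfig,
) -> LectyCategory:
    loads = generate_loads(bee, scenario, n_loads=n_loads, rng=rng)
    profile = aggregate_profile(loads, scenario.taxonomy)
    return classify(profile, lecty_config).category


def recovery_experiment(
    base_config: ScenarioConfig | None = None,
    n_loads_values: Sequence[int] = (3, 10, 20),
    n_replicates: int = 200,
    slope_replicates: int = 0,
    slope_target_loads: int = 12,
    seed: int = 0,
    lecty_config: LectyConfig = LectyConfig(),
) -> dict:
    """Parameter-recovery harness over the full pipeline.

    For each value of ``n_loads``, draws ``n_replicates`` scenarios/bees,
    runs quantification + classification on freshly generated loads, and
    reports the rate at which the estimated category equals the ground
    truth, split by template (oligolect / polylect). If
    ``slope_replicates`` > 0, additionally simulates whole surveys, computes
    exactly-rarefied diet breadth per bee at ``slope_target_loads`` loads,
    fits the occupancy ~ breadth Gaussian linear model, and reports the
    fraction of replicates with a positive fitted slope.

    Returns a dict with keys ``category_recovery`` (DataFrame) and, when
    requested, ``slope_positive_rate`` / ``slope_replicates``.
    """
    base = base_config or ScenarioConfig()
    rows = []
    for n_loads in n_loads_values:
        scen_cfg = dataclasses.replace(base, seed=seed + 101 * n_loads)
        scenario = generate_scenario(scen_cfg, lecty_config)
        rng = np.random.default_rng([seed, 3, n_loads])
        exact: dict[str, list[int]] = {"oligolect": [], "polylect": []}
        status: dict[str, list[int]] = {"oligolect": [], "polylect": []}
        for r in range(n_replicates):
            bee = scenario.bees[r % len(scenario.bees)]
            if n_loads < lecty_config.min_loads:
                continue
            est = _estimate_category(bee, scenario, n_loads, rng, lecty_config)
            exact[bee.template].append(int(est == bee.true_category))
            status[bee.template].append(
                int(est.is_oligolectic == bee.true_category.is_oligolectic)
            )
        for template, hits in exact.items():
            if hits:
                rows.append(
                    {
                        "n_loads": n_loads,
                        "template": template,
                        # exact five-category match
                        "recovery_rate": float(np.mean(hits)),
                        # oligolectic-vs-not status match (insensitive to the
                        # narrow/broad boundary, which flips at small n when
                        # one host species dominates the true diet)
                        "status_recovery_rate": float(np.mean(status[template])),
                        "n_replicates": len(hits),
                    }
                )
    report: dict = {"category_recovery": pd.DataFrame(rows)}

    if slope_replicates > 0:
        positives = 0
        for r in range(slope_replicates):
            scen_cfg = dataclasses.replace(base, seed=seed + 7919 + r)
            scenario = generate_scenario(scen_cfg, lecty_config)
            data = []
            for bee in scenario.bees:
                loads = generate_loads(bee, scenario)
                profile = aggregate_profile(loads, scenario.taxonomy)
                counts = integer_transform(
                    profile.species_level, profile.n_loads, bee_species=bee.bee_species
                )
                breadth = rarefy_exact(counts, slope_target_loads * 10)
                data.append(
                    {
                        "bee_species": bee.bee_species,
                        "rarefied_breadth": breadth,
                        "n_farms": bee.true_farm_count,
                        "bee_family": bee.bee_family,
                    }
                )
            fit = gaussian_linear_fit(pd.DataFrame(data))
            positives += int(fit.coefficients["rarefied_breadth"] > 0)
        report["slope_positive_rate"] = positives / slope_replicates
        report["slope_replicates"] = slope_replicates
    return report
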