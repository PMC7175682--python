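"""Turn raw scopal loads into weighted diet profiles.

The quantification follows the standard pollen-load protocol: constituents
below a 1% contamination threshold are excluded and the rest renormalised;
each load's percentages are then corrected by its size so that a full (8/8)
load contributes weight 100 and, e.g., a quarter (2/8) load composed 100% of
one species contributes weight 25 for that species. Aggregating the weights
across all loads of a bee species yields its diet profile: the percentage of
total pollen volume per plant taxon and per plant family, together with the
percentage of loads that are *pure* for a taxon (100% of the filtered load)
and the percentage of loads merely *containing* it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import PollenLoad, Taxonomy, ValidationError

__all__ = [
    "WeightedLoad",
    "DietProfile",
    "filter_minor_constituents",
    "weight_load",
    "aggregate_profile",
    "count_families",
    "MINOR_THRESHOLD",
]

#: Default contamination threshold: constituents under 1% of the load are
#: excluded before any further analysis.
MINOR_THRESHOLD = 1.0

LEVELS = ("species", "genus", "family")


@dataclass
class WeightedLoad:
    """A load's size-corrected taxon weights, in percent-load units.

    weight(taxon) = (load_size_eighths / 8) x proportion_pct, so a full load
    totals 100 and a half load totals 50.
    """

    load_id: str
    bee_species: str
    weights: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.weights.values())


@dataclass
class DietProfile:
    """Aggregated diet of one bee species.

    ``species_level`` / ``genus_level`` / ``family_level`` map a taxon (at
    that level) to its percentage of the species' total pollen volume; each
    level sums to 100. ``pure_load_pct`` and ``presence_pct`` are keyed by
    level then taxon: the percentage of loads that are entirely one taxon
    (after the minor-constituent filter) and the percentage of loads
    containing it. Pure never exceeds presence.
    """

    bee_species: str
    n_loads: int
    species_level: dict[str, float] = field(default_factory=dict)
    genus_level: dict[str, float] = field(default_factory=dict)
    family_level: dict[str, float] = field(default_factory=dict)
    pure_load_pct: dict[str, dict[str, float]] = field(default_factory=dict)
    presence_pct: dict[str, dict[str, float]] = field(default_factory=dict)

    def shares(self, level: str) -> dict[str, float]:
        return {
            "species": self.species_level,
            "genus": self.genus_level,
            "family": self.family_level,
        }[level]

    def top(self, level: str) -> tuple[str, float]:
        """(taxon, share) with the largest volume share at ``level``."""
        shares = self.shares(level)
        if not shares:
            return ("", 0.0)
        taxon = max(sorted(shares), key=lambda t: shares[t])
        return taxon, shares[taxon]


def filter_minor_constituents(
    load: PollenLoad, threshold: float = MINOR_THRESHOLD
) -> PollenLoad:
    """Drop constituents under ``threshold`` percent and renormalise to 100.

    Constituents at exactly the threshold are kept. Renormalisation keeps
    the load compositional so downstream weighting is unaffected by removed
    contamination.
    """
    kept = {t: p for t, p in load.constituents.items() if p >= threshold}
    if not kept:
        raise ValidationError(
            f"load {load.load_id!r}: all constituents below {threshold}%"
        )
    total = sum(kept.values())
    rescaled = {t: 100.0 * p / total for t, p in kept.items()}
    return PollenLoad(
        load_id=load.load_id,
        bee_species=load.bee_species,
        farm_id=load.farm_id,
        round_id=load.round_id,
        load_size_eighths=load.load_size_eighths,
        constituents=rescaled,
    )


def weight_load(load: PollenLoad) -> WeightedLoad:
    """Correct a (filtered) load's percentages by its size.

    A full 8/8 load of 50% Centaurea nigra / 50% Leucanthemum vulgare yields
    weights {C. nigra: 50, L. vulgare: 50}; a 2/8 load that is 100%
    Hypochaeris radicata yields {H. radicata: 25}.
    """
    factor = load.load_size_eighths / 8.0
    return WeightedLoad(
        load_id=load.load_id,
        bee_species=load.bee_species,
        weights={t: factor * p for t, p in load.constituents.items()},
    )


def _level_key(taxon_label: str, level: str, taxonomy: Taxonomy) -> str:
    if level == "species":
        return taxonomy.lookup(taxon_label).label
    if level == "genus":
        return taxonomy.genus_of(taxon_label)
    return taxonomy.family_of(taxon_label)


def aggregate_profile(
    loads: Sequence[PollenLoad],
    taxonomy: Taxonomy,
    minor_threshold: float = MINOR_THRESHOLD,
    prefiltered: bool = False,
) -> DietProfile:
    """Aggregate one bee species' loads into a :class:`DietProfile`.

    Shares are weighted by pollen volume (the size-corrected weights), not by
    load counts, so a full load counts eight times a one-eighth load. The
    pure-load and presence percentages are per-load statistics computed after
    the minor-constituent filter, at species, genus and family level.

    Raises on an empty collection or on loads from mixed bee species.
    """
    if not loads:
        raise ValidationError("aggregate_profile: empty load collection")
    bee = loads[0].bee_species
    if any(l.bee_species != bee for l in loads):
        raise ValidationError("aggregate_profile: loads from more than one bee species")

    filtered = loads if prefiltered else [
        filter_minor_constituents(l, minor_threshold) for l in loads
    ]
    weighted = [weight_load(l) for l in filtered]

    profile = DietProfile(bee_species=bee, n_loads=len(loads))
    for level in LEVELS:
        totals: dict[str, float] = {}
        pure: dict[str, int] = {}
        present: dict[str, int] = {}
        for load, wload in zip(filtered, weighted):
            by_key: dict[str, float] = {}
            for taxon, w in wload.weights.items():
                key = _level_key(taxon, level, taxonomy)
                by_key[key] = by_key.get(key, 0.0) + w
            for key, w in by_key.items():
                totals[key] = totals.get(key, 0.0) + w
                present[key] = present.get(key, 0) + 1
            if len(by_key) == 1:
                (only,) = by_key
                pure[only] = pure.get(only, 0) + 1
        grand = sum(totals.values())
        shares = {k: 100.0 * v / grand for k, v in totals.items()}
        if level == "species":
            profile.species_level = shares
        elif level == "genus":
            profile.genus_level = shares
        else:
            profile.family_level = shares
        n = len(loads)
        profile.pure_load_pct[level] = {
            k: 100.0 * pure.get(k, 0) / n for k in totals
        }
        profile.presence_pct[level] = {
            k: 100.0 * present[k] / n for k in totals
        }
    return profile


def count_families(profile: DietProfile, minor_threshold: float = MINOR_THRESHOLD) -> int:
    """Number of plant families holding at least ``minor_threshold`` percent
    of the species' total pollen volume.

    Used to operationalise mesolecty (a diet spread over a very small number
    of families). The boundary counts: a family at exactly 1.0% is included.
    """
    return sum(1 for share in profile.family_level.values() if share >= minor_threshold)
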