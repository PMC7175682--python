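"""Host-range (lecty) classification of bee diets.

Two field-standard criteria for oligolecty are evaluated on a bee species'
diet profile:

- **volume criterion** (Müller): at least 95% of the pollen volume comes
  from one plant genus or family;
- **pure-load criterion** (Sipes-Tepedino): at least 90% of females carry
  pure loads of one genus or family.

A species is called *narrowly oligolectic* if both criteria hold at genus
level, *broadly oligolectic* if both hold at family level. When the two
criteria disagree, the category with the lower degree of specialisation is
used, i.e. the species falls through to the polylectic branches: *polylectic
with a strong preference* if the top family still holds at least 70% of the
volume, *mesolectic* if the diet spans no more than two plant families (at
or above 1% of volume each), otherwise *polylectic sensu stricto*.

Classification requires a minimum of three loads; smaller samples are
refused rather than classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .quantify import DietProfile, count_families

__all__ = [
    "LectyCategory",
    "LectyConfig",
    "CriterionVerdict",
    "LectyResult",
    "InsufficientSampleError",
    "criterion_volume",
    "criterion_pure_loads",
    "classify",
    "classify_table",
]

from enum import Enum


class LectyCategory(str, Enum):
    """Host-range categories, ordered from most to least specialised."""

    NARROWLY_OLIGOLECTIC = "narrowly_oligolectic"
    BROADLY_OLIGOLECTIC = "broadly_oligolectic"
    MESOLECTIC = "mesolectic"
    POLYLECTIC_STRONG_PREFERENCE = "polylectic_strong_preference"
    POLYLECTIC_SS = "polylectic_ss"

    @property
    def rank(self) -> int:
        """Specialisation rank: 5 (narrow oligolecty) down to 1 (polylecty s.s.)."""
        return _RANK[self]

    @property
    def is_oligolectic(self) -> bool:
        return self in (
            LectyCategory.NARROWLY_OLIGOLECTIC,
            LectyCategory.BROADLY_OLIGOLECTIC,
        )


_RANK = {
    LectyCategory.NARROWLY_OLIGOLECTIC: 5,
    LectyCategory.BROADLY_OLIGOLECTIC: 4,
    LectyCategory.MESOLECTIC: 3,
    LectyCategory.POLYLECTIC_STRONG_PREFERENCE: 2,
    LectyCategory.POLYLECTIC_SS: 1,
}


class InsufficientSampleError(ValueError):
    """Sample below the minimum number of loads required for classification."""


@dataclass(frozen=True)
class LectyConfig:
    """Thresholds of the classification decision tree.

    volume_threshold and pure_threshold are the two oligolecty criteria.
    strong_pref_threshold is the minimum top-family volume share for
    "polylectic with a strong preference"; mesolectic_family_count is the
    maximum number of families (>= 1% of volume) for mesolecty. min_loads is
    the smallest sample a species may be classified from.
    """

    volume_threshold: float = 95.0
    pure_threshold: float = 90.0
    strong_pref_threshold: float = 70.0
    mesolectic_family_count: int = 2
    min_loads: int = 3

    def __post_init__(self) -> None:
        for name in ("volume_threshold", "pure_threshold", "strong_pref_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.min_loads < 1:
            raise ValueError("min_loads must be >= 1")


@dataclass(frozen=True)
class CriterionVerdict:
    criterion: str  # "volume_95" | "pure_loads_90"
    level: str  # "genus" | "family"
    passes: bool
    supporting_value: float
    taxon: str = ""


@dataclass
class LectyResult:
    bee_species: str
    category: LectyCategory
    preferred_host: str
    verdicts: list[CriterionVerdict] = field(default_factory=list)
    top_family_share: float = 0.0
    n_families: int = 0
    n_loads: int = 0


def criterion_volume(
    profile: DietProfile, level: str, cfg: LectyConfig = LectyConfig()
) -> CriterionVerdict:
    """Volume criterion at ``level``: max share >= volume_threshold."""
    taxon, share = profile.top(level)
    return CriterionVerdict(
        criterion="volume_95",
        level=level,
        passes=share >= cfg.volume_threshold,
        supporting_value=share,
        taxon=taxon,
    )


def criterion_pure_loads(
    profile: DietProfile, level: str, cfg: LectyConfig = LectyConfig()
) -> CriterionVerdict:
    """Pure-load criterion at ``level``: max pure-load percentage >= pure_threshold."""
    pure = profile.pure_load_pct.get(level, {})
    if pure:
        taxon = max(sorted(pure), key=lambda t: pure[t])
        value = pure[taxon]
    else:
        taxon, value = "", 0.0
    return CriterionVerdict(
        criterion="pure_loads_90",
        level=level,
        passes=value >= cfg.pure_threshold,
        supporting_value=value,
        taxon=taxon,
    )


def classify(profile: DietProfile, cfg: LectyConfig = LectyConfig()) -> LectyResult:
    """Assign a host-range category to one bee species' diet profile.

    Decision tree:

    1. both criteria pass at genus level  -> narrowly oligolectic
    2. both criteria pass at family level -> broadly oligolectic
    3. top family share >= strong_pref_threshold -> polylectic with a strong preference
    4. at most ``mesolectic_family_count`` families at >= 1% of volume -> mesolectic
    5. otherwise -> polylectic s.s.

    A species for which exactly one oligolecty criterion passes falls through
    to steps 3-5 (the lower-specialisation resolution of the disagreement).
    """
    if profile.n_loads < cfg.min_loads:
        raise InsufficientSampleError(
            f"{profile.bee_species}: {profile.n_loads} loads < minimum {cfg.min_loads}"
        )
    v_gen = criterion_volume(profile, "genus", cfg)
    p_gen = criterion_pure_loads(profile, "genus", cfg)
    v_fam = criterion_volume(profile, "family", cfg)
    p_fam = criterion_pure_loads(profile, "family", cfg)
    verdicts = [v_gen, p_gen, v_fam, p_fam]

    top_family, top_share = profile.top("family")
    n_fam = count_families(profile)

    if v_gen.passes and p_gen.passes:
        category, preferred = LectyCategory.NARROWLY_OLIGOLECTIC, v_gen.taxon
    elif v_fam.passes and p_fam.passes:
        category, preferred = LectyCategory.BROADLY_OLIGOLECTIC, top_family
    elif top_share >= cfg.strong_pref_threshold:
        category, preferred = LectyCategory.POLYLECTIC_STRONG_PREFERENCE, top_family
    elif n_fam <= cfg.mesolectic_family_count:
        category, preferred = LectyCategory.MESOLECTIC, top_family
    else:
        category, preferred = LectyCategory.POLYLECTIC_SS, top_family

    return LectyResult(
        bee_species=profile.bee_species,
        category=category,
        preferred_host=preferred,
        verdicts=verdicts,
        top_family_share=top_share,
        n_families=n_fam,
        n_loads=profile.n_loads,
    )


def classify_table(
    profiles: Sequence[DietProfile],
    cfg: LectyConfig = LectyConfig(),
    printed_categories: dict[str, str] | None = None,
) -> "pandas.DataFrame":
    """Classify a collection of profiles; optionally compare against a
    reference column of printed categories.

    Returns a DataFrame with one row per species (category, preferred host,
    supporting numbers) and, when ``printed_categories`` is given, columns
    ``printed_category`` and ``match`` forming a concordance report.
    """
    import pandas as pd

    rows = []
    for profile in profiles:
        res = classify(profile, cfg)
        row = {
            "bee_species": res.bee_species,
            "category": res.category.value,
            "preferred_host": res.preferred_host,
            "top_family_share_pct": round(res.top_family_share, 1),
            "n_families": res.n_families,
            "n_loads": res.n_loads,
            "volume_pass": any(
                v.passes for v in res.verdicts if v.criterion == "volume_95"
            ),
            "pure_pass": any(
                v.passes for v in res.verdicts if v.criterion == "pure_loads_90"
            ),
        }
        if printed_categories is not None:
            printed = printed_categories.get(res.bee_species, "")
            row["printed_category"] = printed
            row["match"] = printed == res.category.value
        rows.append(row)
    return pd.DataFrame(rows)
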