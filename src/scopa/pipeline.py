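"""End-to-end orchestration: loads -> profiles -> categories -> rarefied
breadth -> breadth-occurrence statistics, with a reproducibility manifest.

Species enter each stage only if they meet its sample-size rule: at least 3
loads for classification; rarefaction runs in two tiers mirroring the study
design — species with >= 10 loads standardised to 12 loads, species with
>= 3 loads standardised to 3 loads — with the guard that a species' pooled
integer units must cover the target subsample (so a 10-load species whose
rounding leaves it short of 120 units is excluded from tier A rather than
oversampled). Exclusions are recorded, not silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .lecty import InsufficientSampleError, LectyConfig, classify
from .quantify import aggregate_profile
from .rarefaction import UNITS_PER_LOAD, integer_transform, rarefy
from .records import farm_occurrence, read_loads, read_occurrence, read_taxonomy
from .stats import gaussian_linear_fit, spearman_rank

__all__ = ["run_pipeline", "report", "TIERS"]

#: (minimum loads, rarefaction target in loads) for the two analysis tiers.
TIERS = ((10, 12), (3, 3))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    loads_path: str | Path,
    taxonomy_path: str | Path,
    out_dir: str | Path,
    occurrence_path: str | Path | None = None,
    bee_families_path: str | Path | None = None,
    lecty_config: LectyConfig = LectyConfig(),
    n_resamples: int = 1000,
    seed: int = 0,
) -> Path:
    """Run the full analysis and write its outputs under ``out_dir``.

    Outputs: profiles.csv, classification.csv, rarefaction.csv, stats.json
    (when occurrence data are given), exclusions.csv and manifest.json.
    Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    taxonomy = read_taxonomy(taxonomy_path)
    loads = read_loads(loads_path, taxonomy)
    occurrence = read_occurrence(occurrence_path) if occurrence_path else None
    bee_families: dict[str, str] = {}
    if bee_families_path:
        fam_df = pd.read_csv(bee_families_path)
        bee_families = dict(zip(fam_df["bee_species"], fam_df["bee_family"]))

    by_species: dict[str, list] = {}
    for load in loads:
        by_species.setdefault(load.bee_species, []).append(load)

    exclusions: list[dict] = []
    profile_rows: list[dict] = []
    class_rows: list[dict] = []
    rare_rows: list[dict] = []
    profiles = {}
    for bee, bee_loads in by_species.items():
        profile = aggregate_profile(bee_loads, taxonomy)
        profiles[bee] = profile
        for level in ("species", "family"):
            for taxon, share in sorted(profile.shares(level).items()):
                profile_rows.append(
                    {
                        "bee_species": bee,
                        "level": level,
                        "taxon": taxon,
                        "share_pct": round(share, 1),
                        "pure_pct": round(profile.pure_load_pct[level][taxon], 1),
                        "presence_pct": round(profile.presence_pct[level][taxon], 1),
                        "n_loads": profile.n_loads,
                    }
                )

        try:
            res = classify(profile, lecty_config)
        except InsufficientSampleError:
            exclusions.append(
                {
                    "bee_species": bee,
                    "stage": "classification",
                    "reason": f"{profile.n_loads} loads < minimum {lecty_config.min_loads}",
                }
            )
        else:
            v_fam = next(
                v for v in res.verdicts
                if v.criterion == "volume_95" and v.level == "family"
            )
            p_fam = next(
                v for v in res.verdicts
                if v.criterion == "pure_loads_90" and v.level == "family"
            )
            class_rows.append(
                {
                    "bee_species": bee,
                    "category": res.category.value,
                    "preferred_host": res.preferred_host,
                    "top_family_share_pct": round(res.top_family_share, 1),
                    "pure_pct": round(p_fam.supporting_value, 1),
                    "presence_pct": round(
                        profile.presence_pct["family"].get(res.preferred_host, 0.0), 1
                    ),
                    "n_loads": res.n_loads,
                    "volume_pass": v_fam.passes,
                    "pure_pass": p_fam.passes,
                }
            )

        counts = integer_transform(profile.species_level, profile.n_loads, bee_species=bee)
        for min_loads, target in TIERS:
            if profile.n_loads < min_loads:
                continue
            if counts.total_units < target * UNITS_PER_LOAD:
                exclusions.append(
                    {
                        "bee_species": bee,
                        "stage": f"rarefaction_{target}",
                        "reason": (
                            f"{counts.total_units} units < target "
                            f"{target * UNITS_PER_LOAD}"
                        ),
                    }
                )
                continue
            rb = rarefy(counts, target, n_resamples=n_resamples, seed=seed)
            rare_rows.append(
                {
                    "bee_species": bee,
                    "target_loads": rb.target_loads,
                    "expected_richness": round(rb.expected_richness, 3),
                    "resample_sd": round(rb.resample_sd, 3),
                    "n_resamples": rb.n_resamples,
                    "seed": rb.seed,
                }
            )

    pd.DataFrame(profile_rows).to_csv(out / "profiles.csv", index=False)
    pd.DataFrame(class_rows).to_csv(out / "classification.csv", index=False)
    rare_df = pd.DataFrame(
        rare_rows,
        columns=[
            "bee_species", "target_loads", "expected_richness",
            "resample_sd", "n_resamples", "seed",
        ],
    )
    rare_df.to_csv(out / "rarefaction.csv", index=False)
    pd.DataFrame(
        exclusions, columns=["bee_species", "stage", "reason"]
    ).to_csv(out / "exclusions.csv", index=False)

    stats_report: dict = {}
    if occurrence is not None and not rare_df.empty:
        for min_loads, target in TIERS:
            tier = rare_df[rare_df["target_loads"] == target].copy()
            if tier.empty:
                continue
            tier["n_farms"] = [
                farm_occurrence(occurrence, b) for b in tier["bee_species"]
            ]
            tier["rarefied_breadth"] = tier["expected_richness"]
            key = f"tier_{target}_loads"
            try:
                if target == TIERS[0][1]:
                    tier["bee_family"] = [
                        bee_families.get(b, "unknown") for b in tier["bee_species"]
                    ]
                    with_family = bool(bee_families) and tier["bee_family"].nunique() > 1
                    fit = gaussian_linear_fit(tier, include_bee_family=with_family)
                else:
                    fit = spearman_rank(tier)
            except ValueError as exc:
                stats_report[key] = {"error": str(exc)}
            else:
                stats_report[key] = fit.to_dict()
                stats_report[key]["n_species"] = int(len(tier))
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=2, sort_keys=True)

    inputs = {"loads": Path(loads_path), "taxonomy": Path(taxonomy_path)}
    if occurrence_path:
        inputs["occurrence"] = Path(occurrence_path)
    if bee_families_path:
        inputs["bee_families"] = Path(bee_families_path)
    manifest = {
        "scopa_version": __version__,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "lecty_config": dataclasses.asdict(lecty_config),
        "n_resamples": n_resamples,
        "seed": seed,
        "outputs": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def report(out_dir: str | Path) -> str:
    """Render a human-readable summary of a pipeline run."""
    out = Path(out_dir)
    classification = out / "classification.csv"
    if not classification.exists():
        raise FileNotFoundError(f"no pipeline outputs under {out}")
    cls = pd.read_csv(classification)
    lines = ["Host-range classification", "=" * 26]
    if cls.empty:
        lines.append("(no species met the minimum sample size)")
    else:
        lines.append(cls.to_string(index=False))
    rare_path = out / "rarefaction.csv"
    if rare_path.exists():
        rare = pd.read_csv(rare_path)
        if not rare.empty:
            lines += ["", "Rarefied diet breadth", "=" * 21, rare.to_string(index=False)]
    stats_path = out / "stats.json"
    if stats_path.exists():
        lines += ["", "Breadth-occurrence statistics", "=" * 29,
                  stats_path.read_text().rstrip()]
    excl_path = out / "exclusions.csv"
    if excl_path.exists():
        excl = pd.read_csv(excl_path)
        if not excl.empty:
            lines += ["", "Exclusions", "=" * 10, excl.to_string(index=False)]
    return "\n".join(lines)
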