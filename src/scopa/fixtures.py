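"""Packaged reference fixtures (see data/README.md for provenance).

``load_host_spectrum()`` returns the published per-species host-plant
spectrum of 31 farmland solitary bee species as (profiles, metadata):
family-level diet profiles suitable for :func:`scopa.lecty.classify` plus
the published categories. ``load_diet_breadth()`` returns the paired
observation-vs-pollen diet-breadth table of the 29 non-single-host species.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quantify import DietProfile

__all__ = ["load_host_spectrum", "load_diet_breadth", "host_spectrum_profiles"]


def _data_path(name: str):
    return resources.files("scopa.data").joinpath(name)


def load_host_spectrum() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(composition, species) DataFrames of the host-spectrum fixture."""
    with resources.as_file(_data_path("host_spectrum_composition.csv")) as p:
        composition = pd.read_csv(p)
    with resources.as_file(_data_path("host_spectrum_species.csv")) as p:
        species = pd.read_csv(p)
    return composition, species


def load_diet_breadth() -> pd.DataFrame:
    """Paired per-species diet-breadth counts (observation vs pollen loads)."""
    with resources.as_file(_data_path("diet_breadth.csv")) as p:
        return pd.read_csv(p)


def host_spectrum_profiles() -> tuple[list[DietProfile], dict[str, str]]:
    """Reconstruct :class:`DietProfile` objects from the host-spectrum fixture.

    The published table is family-level, so ``species_level`` is left empty
    and ``genus_level`` carries only the entries the published row pins down
    (the single-host specialists, where the preferred species *is* the genus
    share, plus the one species with a published top-genus share). Pure-load
    and presence percentages refer to the preferred host at family level
    and, where applicable, genus level.

    Returns (profiles, printed_categories keyed by bee species).
    """
    composition, species = load_host_spectrum()
    profiles: list[DietProfile] = []
    printed: dict[str, str] = {}
    for _, row in species.iterrows():
        bee = row["bee_species"]
        fam_rows = composition[composition["bee_species"] == bee]
        family_level = dict(zip(fam_rows["family"], fam_rows["share_pct"]))
        top_family = max(sorted(family_level), key=lambda f: family_level[f])

        genus_level: dict[str, float] = {}
        pure_genus: dict[str, float] = {}
        if pd.notna(row["genus_top_share_pct"]):
            host = row["preferred_host"]
            genus = host.split()[0] if row["preferred_host_level"] == "species" else host
            genus_level[genus] = float(row["genus_top_share_pct"])
            if pd.notna(row["genus_pure_pct"]):
                pure_genus[genus] = float(row["genus_pure_pct"])

        pure_family = (
            {top_family: float(row["pure_load_pct"])}
            if row["preferred_host_level"] == "family"
            or row["preferred_host_level"] == "species"
            else {}
        )
        presence_family = {top_family: float(row["presence_pct"])}

        profiles.append(
            DietProfile(
                bee_species=bee,
                n_loads=int(row["n_loads"]),
                species_level={},
                genus_level=genus_level,
                family_level=family_level,
                pure_load_pct={"family": pure_family, "genus": pure_genus, "species": {}},
                presence_pct={"family": presence_family, "genus": {}, "species": {}},
            )
        )
        printed[bee] = row["printed_category"]
    return profiles, printed
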