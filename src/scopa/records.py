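"""Data model and delimited-text I/O for pollen loads, plant taxonomy and
farm occurrence records.

A *pollen load* is the scopal (pollen-brush) load of one collected female
bee: its size visually scored in eighths of a full load (1/8 ... 8/8) plus
the percentage composition of the load by volume across plant taxa. Pollen
is not always identifiable to species under the light microscope, so taxa
carry a resolution level (species, genus or family).

File schemas (all plain CSV with headers):

- loads:      ``load_id,bee_species,farm_id,round_id,load_size_eighths,plant_taxon,proportion_pct``
  (one row per load constituent; rows of a load share a ``load_id``)
- taxonomy:   ``taxon_label,genus,family,resolution``
- occurrence: ``bee_species,farm_id,n_sightings``
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ValidationError",
    "PlantTaxon",
    "Taxonomy",
    "PollenLoad",
    "read_taxonomy",
    "write_taxonomy",
    "read_loads",
    "write_loads",
    "read_occurrence",
    "write_occurrence",
    "farm_occurrence",
    "PROPORTION_SUM_TOL",
]

#: Constituent proportions of a load must sum to 100 within this tolerance.
#: Set to absorb percentages rounded to one decimal in field/reference data.
PROPORTION_SUM_TOL = 0.5


class ValidationError(ValueError):
    """Raised when an input file or record violates the data contract."""


def _canon(label: str) -> str:
    """Canonical form for taxon-label matching: trimmed, case-folded."""
    return " ".join(label.split()).casefold()


@dataclass(frozen=True)
class PlantTaxon:
    """A plant taxon at the resolution pollen could be identified to."""

    label: str
    genus: str
    family: str
    resolution: str = "species"  # species | genus | family

    def __post_init__(self) -> None:
        if self.resolution not in ("species", "genus", "family"):
            raise ValidationError(
                f"taxon {self.label!r}: unknown resolution {self.resolution!r}"
            )
        if not self.family:
            raise ValidationError(f"taxon {self.label!r}: family must be non-empty")
        if self.resolution == "species" and not (self.label and self.genus):
            raise ValidationError(
                f"species-level taxon needs non-empty label and genus: {self.label!r}"
            )

    @property
    def genus_label(self) -> str:
        """Genus-level bucket; family-resolution taxa fall back to the family."""
        return self.genus if self.genus else self.family


class Taxonomy:
    """Lookup table of plant taxa, unique by canonical label."""

    def __init__(self, taxa: Iterable[PlantTaxon] = ()) -> None:
        self._taxa: dict[str, PlantTaxon] = {}
        for t in taxa:
            self.add(t)

    def add(self, taxon: PlantTaxon) -> None:
        key = _canon(taxon.label)
        if key in self._taxa:
            raise ValidationError(f"duplicate taxon label {taxon.label!r}")
        self._taxa[key] = taxon

    def lookup(self, label: str) -> PlantTaxon:
        try:
            return self._taxa[_canon(label)]
        except KeyError:
            raise ValidationError(f"unknown taxon label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return _canon(label) in self._taxa

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self):
        return iter(self._taxa.values())

    def family_of(self, label: str) -> str:
        return self.lookup(label).family

    def genus_of(self, label: str) -> str:
        return self.lookup(label).genus_label


@dataclass
class PollenLoad:
    """One bee's scopal load: size in eighths plus percentage composition.

    ``constituents`` maps taxon label -> percent of the load by volume; the
    percentages must sum to 100 within :data:`PROPORTION_SUM_TOL`.
    """

    load_id: str
    bee_species: str
    farm_id: str
    round_id: str
    load_size_eighths: int
    constituents: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "PollenLoad":
        if not 1 <= int(self.load_size_eighths) <= 8:
            raise ValidationError(
                f"load {self.load_id!r}: load_size_eighths must be in 1..8, "
                f"got {self.load_size_eighths}"
            )
        if not self.constituents:
            raise ValidationError(f"load {self.load_id!r}: no constituents")
        for taxon, pct in self.constituents.items():
            if not 0 < pct <= 100:
                raise ValidationError(
                    f"load {self.load_id!r}: proportion for {taxon!r} must be "
                    f"in (0, 100], got {pct}"
                )
        total = sum(self.constituents.values())
        if abs(total - 100.0) > PROPORTION_SUM_TOL:
            raise ValidationError(
                f"load {self.load_id!r}: constituent proportions sum to "
                f"{total:.2f}, expected 100 ± {PROPORTION_SUM_TOL}"
            )
        return self


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a plant taxonomy table from CSV.

    Raises :class:`ValidationError` on duplicate labels, missing families, or
    a missing required column.
    """
    taxonomy = Taxonomy()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"taxon_label", "genus", "family"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"taxonomy file {path}: required columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            label = (row["taxon_label"] or "").strip()
            family = (row["family"] or "").strip()
            genus = (row["genus"] or "").strip()
            resolution = (row.get("resolution") or "").strip()
            if not resolution:
                # infer: no genus -> family-level, no space in label -> genus
                if not genus:
                    resolution = "family"
                elif _canon(label) == _canon(genus):
                    resolution = "genus"
                else:
                    resolution = "species"
            if not family:
                raise ValidationError(f"taxonomy row {i}: missing family for {label!r}")
            taxonomy.add(PlantTaxon(label, genus, family, resolution))
    return taxonomy


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon_label", "genus", "family", "resolution"])
        for t in taxonomy:
            w.writerow([t.label, t.genus, t.family, t.resolution])


def read_loads(path: str | Path, taxonomy: Taxonomy | None = None) -> list[PollenLoad]:
    """Read pollen loads from a one-row-per-constituent CSV.

    Rows sharing a ``load_id`` are grouped into one :class:`PollenLoad`;
    first-appearance order of loads is preserved. If ``taxonomy`` is given,
    every taxon label is resolved against it and unknown labels raise
    :class:`ValidationError` naming the offending row.
    """
    loads: dict[str, PollenLoad] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {
            "load_id", "bee_species", "farm_id", "round_id",
            "load_size_eighths", "plant_taxon", "proportion_pct",
        }
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(f"loads file {path}: required columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            load_id = row["load_id"].strip()
            taxon_label = row["plant_taxon"].strip()
            if taxonomy is not None:
                try:
                    taxon_label = taxonomy.lookup(taxon_label).label
                except ValidationError:
                    raise ValidationError(
                        f"loads file row {i}: unknown taxon label {taxon_label!r}"
                    ) from None
            try:
                size = int(row["load_size_eighths"])
                pct = float(row["proportion_pct"])
            except ValueError as exc:
                raise ValidationError(f"loads file row {i}: {exc}") from None
            if load_id not in loads:
                loads[load_id] = PollenLoad(
                    load_id=load_id,
                    bee_species=row["bee_species"].strip(),
                    farm_id=row["farm_id"].strip(),
                    round_id=row["round_id"].strip(),
                    load_size_eighths=size,
                )
            load = loads[load_id]
            if taxon_label in load.constituents:
                raise ValidationError(
                    f"loads file row {i}: duplicate constituent {taxon_label!r} "
                    f"in load {load_id!r}"
                )
            if size != load.load_size_eighths:
                raise ValidationError(
                    f"loads file row {i}: inconsistent load size for load {load_id!r}"
                )
            load.constituents[taxon_label] = pct
    out = []
    for load in loads.values():
        try:
            out.append(load.validate())
        except ValidationError as exc:
            raise ValidationError(str(exc)) from None
    return out


def write_loads(loads: Iterable[PollenLoad], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "load_id", "bee_species", "farm_id", "round_id",
            "load_size_eighths", "plant_taxon", "proportion_pct",
        ])
        for load in loads:
            for taxon, pct in load.constituents.items():
                w.writerow([
                    load.load_id, load.bee_species, load.farm_id, load.round_id,
                    load.load_size_eighths, taxon, repr(float(pct)),
                ])


def read_occurrence(path: str | Path) -> list[dict]:
    """Read survey occurrence rows (bee_species, farm_id, n_sightings)."""
    rows = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"bee_species", "farm_id", "n_sightings"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"occurrence file {path}: required columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            key = (row["bee_species"].strip(), row["farm_id"].strip())
            if key in seen:
                raise ValidationError(
                    f"occurrence file row {i}: duplicate (bee_species, farm_id) {key}"
                )
            seen.add(key)
            n = int(row["n_sightings"])
            if n < 0:
                raise ValidationError(f"occurrence file row {i}: n_sightings < 0")
            rows.append({"bee_species": key[0], "farm_id": key[1], "n_sightings": n})
    return rows


def write_occurrence(rows: Iterable[Mapping], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bee_species", "farm_id", "n_sightings"])
        for r in rows:
            w.writerow([r["bee_species"], r["farm_id"], r["n_sightings"]])


def farm_occurrence(occurrence: Iterable[Mapping], bee_species: str) -> int:
    """Number of distinct farms where ``bee_species`` was sighted at least once.

    This is the frequency-of-occurrence measure used against diet breadth:
    a farm counts if the species was recorded there at least once over the
    whole survey period. An absent species scores 0.
    """
    farms = {
        r["farm_id"]
        for r in occurrence
        if r["bee_species"] == bee_species and r["n_sightings"] >= 1
    }
    return len(farms)
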