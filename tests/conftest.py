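import pytest

from scopa.records import PlantTaxon, PollenLoad, Taxonomy


@pytest.fixture
def taxonomy() -> Taxonomy:
    """Small plant taxonomy spanning several families and resolutions."""
    return Taxonomy(
        [
            PlantTaxon("Centaurea nigra", "Centaurea", "Asteraceae"),
            PlantTaxon("Leucanthemum vulgare", "Leucanthemum", "Asteraceae"),
            PlantTaxon("Hypochaeris radicata", "Hypochaeris", "Asteraceae"),
            PlantTaxon("Bryonia dioica", "Bryonia", "Cucurbitaceae"),
            PlantTaxon("Trifolium repens", "Trifolium", "Fabaceae"),
            PlantTaxon("Daucus carota", "Daucus", "Apiaceae"),
            PlantTaxon("Brassica", "Brassica", "Brassicaceae", resolution="genus"),
        ]
    )


@pytest.fixture
def make_load():
    """Factory for valid pollen loads with minimal boilerplate."""

    counter = {"n": 0}

    def _make(constituents, size=8, bee="Andrena test", farm="farmA", rnd="round1"):
        counter["n"] += 1
        return PollenLoad(
            load_id=f"L{counter['n']:03d}",
            bee_species=bee,
            farm_id=farm,
            round_id=rnd,
            load_size_eighths=size,
            constituents=dict(constituents),
        ).validate()

    return _make
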