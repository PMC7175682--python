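"""Load filtering, size weighting and diet-profile aggregation."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from scopa.quantify import (
    aggregate_profile,
    count_families,
    filter_minor_constituents,
    weight_load,
)
from scopa.quantify import DietProfile
from scopa.records import ValidationError


class TestMinorConstituentFilter:
    @pytest.mark.parametrize(
        "before, after",
        [
            # sub-1% contamination removed and the rest renormalised
            ({"Centaurea nigra": 99.5, "Trifolium repens": 0.5}, {"Centaurea nigra": 100.0}),
            # nothing below the threshold: unchanged
            (
                {"Centaurea nigra": 50.0, "Trifolium repens": 50.0},
                {"Centaurea nigra": 50.0, "Trifolium repens": 50.0},
            ),
            # exactly 1% is kept (threshold is strict "less than")
            (
                {"Centaurea nigra": 97.0, "Trifolium repens": 2.0, "Bryonia dioica": 1.0},
                {"Centaurea nigra": 97.0, "Trifolium repens": 2.0, "Bryonia dioica": 1.0},
            ),
        ],
    )
    def test_examples(self, make_load, before, after):
        filtered = filter_minor_constituents(make_load(before))
        assert filtered.constituents == pytest.approx(after)

    def test_all_below_threshold_rejected(self, make_load):
        load = make_load({"Centaurea nigra": 100.0})
        load.constituents = {"Centaurea nigra": 0.4, "Trifolium repens": 0.3}
        with pytest.raises(ValidationError, match="below"):
            filter_minor_constituents(load)


class TestWeighting:
    @pytest.mark.parametrize(
        "size, composition, expected",
        [
            # full load, 50/50 of two Asteraceae
            (8, {"Centaurea nigra": 50.0, "Leucanthemum vulgare": 50.0},
             {"Centaurea nigra": 50.0, "Leucanthemum vulgare": 50.0}),
            # quarter load, one species
            (2, {"Hypochaeris radicata": 100.0}, {"Hypochaeris radicata": 25.0}),
            # half load, 30/70
            (4, {"Centaurea nigra": 30.0, "Trifolium repens": 70.0},
             {"Centaurea nigra": 15.0, "Trifolium repens": 35.0}),
        ],
    )
    def test_size_correction(self, make_load, size, composition, expected):
        weighted = weight_load(make_load(composition, size=size))
        assert weighted.weights == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        size=st.integers(min_value=1, max_value=8),
        split=st.floats(min_value=1.0, max_value=99.0),
    )
    def test_weight_conservation(self, make_load, size, split):
        """Total weight of a load equals 100 x size/8."""
        load = make_load(
            {"Centaurea nigra": split, "Trifolium repens": 100.0 - split}, size=size
        )
        assert weight_load(load).total == pytest.approx(100.0 * size / 8)


class TestAggregation:
    def test_two_pure_loads_two_families(self, make_load, taxonomy):
        loads = [
            make_load({"Centaurea nigra": 100.0}),
            make_load({"Bryonia dioica": 100.0}),
        ]
        profile = aggregate_profile(loads, taxonomy)
        assert profile.family_level == pytest.approx(
            {"Asteraceae": 50.0, "Cucurbitaceae": 50.0}
        )
        assert profile.pure_load_pct["family"]["Asteraceae"] == pytest.approx(50.0)
        assert profile.presence_pct["family"]["Asteraceae"] == pytest.approx(50.0)

    def test_repeated_pure_load_is_fully_specialised(self, make_load, taxonomy):
        loads = [make_load({"Bryonia dioica": 100.0}) for _ in range(3)]
        profile = aggregate_profile(loads, taxonomy)
        assert profile.family_level == pytest.approx({"Cucurbitaceae": 100.0})
        assert profile.pure_load_pct["family"]["Cucurbitaceae"] == pytest.approx(100.0)
        assert profile.presence_pct["family"]["Cucurbitaceae"] == pytest.approx(100.0)

    def test_volume_weighted_not_count_weighted(self, make_load, taxonomy):
        # a full load (weight 100) and a quarter load (weight 25):
        # shares are 100/125 and 25/125, not 50/50
        loads = [
            make_load({"Centaurea nigra": 100.0}, size=8),
            make_load({"Trifolium repens": 100.0}, size=2),
        ]
        profile = aggregate_profile(loads, taxonomy)
        assert profile.species_level == pytest.approx(
            {"Centaurea nigra": 80.0, "Trifolium repens": 20.0}
        )

    def test_empty_and_mixed_species_rejected(self, make_load, taxonomy):
        with pytest.raises(ValidationError, match="empty"):
            aggregate_profile([], taxonomy)
        loads = [
            make_load({"Centaurea nigra": 100.0}, bee="Andrena a"),
            make_load({"Centaurea nigra": 100.0}, bee="Andrena b"),
        ]
        with pytest.raises(ValidationError, match="more than one bee"):
            aggregate_profile(loads, taxonomy)

    @settings(max_examples=25, deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        sizes=st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=5),
        split=st.floats(min_value=2.0, max_value=98.0),
    )
    def test_scale_invariance_under_duplication(self, make_load, taxonomy, sizes, split):
        """Duplicating every load leaves all profile percentages unchanged."""
        base = [
            make_load(
                {"Centaurea nigra": split, "Bryonia dioica": 100.0 - split}, size=s
            )
            for s in sizes
        ]
        doubled = base + [
            make_load(dict(l.constituents), size=l.load_size_eighths) for l in base
        ]
        p1 = aggregate_profile(base, taxonomy)
        p2 = aggregate_profile(doubled, taxonomy)
        assert p2.species_level == pytest.approx(p1.species_level)
        assert p2.family_level == pytest.approx(p1.family_level)
        for level in ("species", "family"):
            assert p2.pure_load_pct[level] == pytest.approx(p1.pure_load_pct[level])
            assert p2.presence_pct[level] == pytest.approx(p1.presence_pct[level])

    @settings(max_examples=25, deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        splits=st.lists(
            st.tuples(
                st.floats(min_value=5.0, max_value=95.0),
                st.integers(min_value=1, max_value=8),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_family_level_is_pushforward_and_pure_below_presence(
        self, make_load, taxonomy, splits
    ):
        loads = [
            make_load(
                {
                    "Centaurea nigra": s / 2,
                    "Leucanthemum vulgare": s / 2,
                    "Trifolium repens": 100.0 - s,
                },
                size=size,
            )
            for s, size in splits
        ]
        profile = aggregate_profile(loads, taxonomy)
        # family shares are the sums of their species' shares
        ast = (
            profile.species_level["Centaurea nigra"]
            + profile.species_level["Leucanthemum vulgare"]
        )
        assert profile.family_level["Asteraceae"] == pytest.approx(ast)
        assert sum(profile.family_level.values()) == pytest.approx(100.0)
        for level in ("species", "genus", "family"):
            for taxon, pure in profile.pure_load_pct[level].items():
                assert pure <= profile.presence_pct[level][taxon] + 1e-9


class TestCountFamilies:
    @pytest.mark.parametrize(
        "family_level, expected",
        [
            ({"Asteraceae": 67.8, "Brassicaceae": 32.0, "other": 0.2}, 2),
            ({"Fabaceae": 100.0}, 1),
            ({"F1": 50.0, "F2": 49.0, "F3": 1.0}, 3),  # boundary: 1.0 counts
        ],
    )
    def test_families_at_or_above_one_percent(self, family_level, expected):
        profile = DietProfile(bee_species="x", n_loads=5, family_level=family_level)
        assert count_families(profile) == expected
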