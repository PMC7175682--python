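"""Host-range classification: criteria, decision tree, fixture concordance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scopa.fixtures import host_spectrum_profiles
from scopa.lecty import (
    InsufficientSampleError,
    LectyCategory,
    LectyConfig,
    classify,
    classify_table,
    criterion_pure_loads,
    criterion_volume,
)
from scopa.quantify import DietProfile


def profile(family_level, pure_family=None, genus_level=None, pure_genus=None, n_loads=20):
    return DietProfile(
        bee_species="test bee",
        n_loads=n_loads,
        family_level=dict(family_level),
        genus_level=dict(genus_level or {}),
        pure_load_pct={"family": dict(pure_family or {}), "genus": dict(pure_genus or {}), "species": {}},
        presence_pct={"family": {}, "genus": {}, "species": {}},
    )


class TestCriteria:
    @pytest.mark.parametrize(
        "family_level, passes",
        [
            ({"Apiaceae": 97.0, "other": 3.0}, True),
            ({"Fabaceae": 100.0}, True),
            ({"Fabaceae": 94.9, "Rosaceae": 5.1}, False),  # boundary
        ],
    )
    def test_volume_criterion(self, family_level, passes):
        verdict = criterion_volume(profile(family_level), "family")
        assert verdict.passes is passes
        assert verdict.supporting_value == pytest.approx(max(family_level.values()))

    @pytest.mark.parametrize(
        "pure, passes",
        [
            ({"Asteraceae": 71.4}, False),
            ({"Cucurbitaceae": 100.0}, True),
            ({"Fabaceae": 89.9}, False),  # boundary
        ],
    )
    def test_pure_load_criterion(self, pure, passes):
        verdict = criterion_pure_loads(
            profile({"Asteraceae": 100.0}, pure_family=pure), "family"
        )
        assert verdict.passes is passes

    def test_empty_genus_level_fails_quietly(self):
        verdict = criterion_volume(profile({"Asteraceae": 100.0}), "genus")
        assert not verdict.passes and verdict.supporting_value == 0.0


class TestDecisionTree:
    def test_volume_pass_pure_fail_resolves_downward(self):
        # both-criteria disagreement falls to the less specialised branch
        res = classify(
            profile({"Asteraceae": 95.3, "Ranunculaceae": 4.7}, pure_family={"Asteraceae": 71.4})
        )
        assert res.category is LectyCategory.POLYLECTIC_STRONG_PREFERENCE
        assert res.preferred_host == "Asteraceae"

    def test_single_genus_diet_is_narrowly_oligolectic(self):
        res = classify(
            profile(
                {"Cucurbitaceae": 100.0},
                pure_family={"Cucurbitaceae": 100.0},
                genus_level={"Bryonia": 100.0},
                pure_genus={"Bryonia": 100.0},
            )
        )
        assert res.category is LectyCategory.NARROWLY_OLIGOLECTIC
        assert res.preferred_host == "Bryonia"

    def test_single_family_many_genera_is_broadly_oligolectic(self):
        res = classify(
            profile(
                {"Asteraceae": 100.0},
                pure_family={"Asteraceae": 100.0},
                genus_level={"Hypochaeris": 49.3, "Leontodon": 34.8, "Crepis": 14.0, "other": 1.9},
            )
        )
        assert res.category is LectyCategory.BROADLY_OLIGOLECTIC

    def test_two_family_diet_without_preference_is_mesolectic(self):
        res = classify(
            profile({"Asteraceae": 67.8, "Brassicaceae": 32.0, "other": 0.2},
                    pure_family={"Asteraceae": 42.9})
        )
        assert res.category is LectyCategory.MESOLECTIC

    def test_spread_diet_is_polylectic_ss(self):
        res = classify(
            profile(
                {"Brassicaceae": 65.7, "Aceraceae": 19.6, "Apiaceae": 5.4,
                 "Rosaceae": 4.2, "other": 5.1},
                pure_family={"Brassicaceae": 55.6},
            )
        )
        assert res.category is LectyCategory.POLYLECTIC_SS

    def test_small_samples_are_refused(self):
        with pytest.raises(InsufficientSampleError):
            classify(profile({"Asteraceae": 100.0}, pure_family={"Asteraceae": 100.0}, n_loads=2))

    def test_classify_is_deterministic(self):
        p = profile({"Asteraceae": 80.0, "Rosaceae": 20.0}, pure_family={"Asteraceae": 50.0})
        assert classify(p).category is classify(p).category


class TestMonotonicity:
    @settings(max_examples=60, deadline=None)
    @given(
        s1=st.floats(min_value=34.0, max_value=99.0),
        s2=st.floats(min_value=34.0, max_value=99.0),
        pure=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_rank_non_decreasing_in_top_share(self, s1, s2, pure):
        """With >2 families in the diet, raising the top family's volume share
        (pure-load fraction and family count held fixed) never makes the
        classification less specialised.

        Restricted to three-family diets: for exactly-two-family diets the
        category lattice itself is non-monotone (a two-family diet crosses
        from mesolectic down to strong-preference as the top share grows),
        which the reference survey's own categories exhibit.
        """
        lo, hi = sorted((s1, s2))

        def rank(top):
            rest = (100.0 - top) / 2
            res = classify(
                profile(
                    {"F1": top, "F2": rest, "F3": rest},
                    pure_family={"F1": pure},
                )
            )
            return res.category.rank

        assert rank(hi) >= rank(lo)


class TestFixtureConcordance:
    def test_published_categories_reproduced_with_one_discordance(self):
        """The decision tree reproduces the published host-range column for
        30 of 31 species; the single rule-vs-print discordance is the
        Apiaceae specialist whose pure-load criterion fails (33.3% < 90) so
        the lower-specialisation rule yields strong preference, not broad
        oligolecty."""
        profiles, printed = host_spectrum_profiles()
        table = classify_table(profiles, printed_categories=printed)
        mismatches = table.loc[~table["match"], "bee_species"].tolist()
        assert mismatches == ["Andrena alfkenella"]

    @pytest.mark.parametrize("threshold", [68.2, 70.0, 73.1])
    def test_concordance_stable_across_strong_preference_thresholds(self, threshold):
        """Any strong-preference cutoff in (68.1, 73.1] yields the same
        concordance: the fixture brackets it with a polylectic s.s. top share
        of 68.1 and a strong-preference top share of 73.1."""
        profiles, printed = host_spectrum_profiles()
        cfg = LectyConfig(strong_pref_threshold=threshold)
        table = classify_table(profiles, cfg=cfg, printed_categories=printed)
        assert table.loc[~table["match"], "bee_species"].tolist() == ["Andrena alfkenella"]

    def test_empty_input_yields_empty_report(self):
        assert classify_table([], printed_categories={}).empty
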