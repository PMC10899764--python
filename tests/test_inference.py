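"""Protection-pattern prediction, gel consistency, hypothesis elimination
and selection-design auditing."""

import pytest
from hypothesis import given, settings, strategies as st

from mtasekit.digestion import UNCUT_CIRCULAR, FragmentSet, digest
from mtasekit.inference import (HypothesisSpace, ObservedPattern, context_coverage,
                                infer_specificities, patterns_consistent,
                                predict_pattern, selection_suitability)
from mtasekit.methylation import MTaseSpecificity, apply_methylation
from mtasekit.sequence import CIRCULAR, DuplexSequence
from mtasekit.synthetic import PlantedSite, make_random_plasmid


class TestPredictPattern:
    @pytest.mark.parametrize("cores,expected", [
        ({"CG"}, (4486, 1935)),
        ({"CA"}, (4486, 1935)),
        ({"CC"}, (6421,)),
        ({"CT"}, (3986, 2435)),
    ])
    def test_fixture_protection_patterns(self, alw44i_fixture, enzymes, cores, expected):
        fs = predict_pattern(alw44i_fixture, MTaseSpecificity.simple(cores), enzymes["Alw44I"])
        assert fs.fragments == expected

    def test_ct_pattern_contains_2435(self, alw44i_fixture, enzymes):
        fs = predict_pattern(alw44i_fixture, MTaseSpecificity.simple({"CT"}), enzymes["Alw44I"])
        assert 2435 in fs.fragments


class TestPatternsConsistent:
    def test_within_five_percent(self):
        predicted = FragmentSet("cut", (4486, 1935), (1, 2))
        ok, matching = patterns_consistent(predicted, ObservedPattern("Alw44I", (4500, 1900)))
        assert ok
        assert all(hit for _, _, hit in matching)

    def test_absent_band_argument(self):
        predicted = FragmentSet("cut", (4486, 1935), (1, 2))
        ok, _ = patterns_consistent(predicted, ObservedPattern("Alw44I", (5921,)))
        assert not ok

    def test_identical_lists_at_zero_tolerance(self):
        predicted = FragmentSet("cut", (4486, 1935), (1, 2))
        ok, _ = patterns_consistent(predicted, ObservedPattern("Alw44I", (4486, 1935)), rel_tol=0)
        assert ok

    def test_uncut_flag_matches_only_zero_cuts(self):
        uncut_pred = FragmentSet(UNCUT_CIRCULAR, (), ())
        cut_pred = FragmentSet("cut", (3000,), (5,))
        assert patterns_consistent(uncut_pred, ObservedPattern("X", uncut=True))[0]
        assert not patterns_consistent(cut_pred, ObservedPattern("X", uncut=True))[0]

    def test_full_length_linear_matches_any_single_cut(self):
        pred = FragmentSet("cut", (6421,), (100,))
        assert patterns_consistent(pred, ObservedPattern("X", full_length_linear=True))[0]

    def test_tolerance_bounds(self):
        pred = FragmentSet("cut", (100,), (1,))
        with pytest.raises(ValueError):
            patterns_consistent(pred, ObservedPattern("X", (100,)), rel_tol=0.5)


class TestInferSpecificities:
    def test_cg_and_ca_both_explain_the_4486_band(self, alw44i_fixture, enzymes):
        obs = [ObservedPattern("Alw44I", (4486, 1935))]
        result = infer_specificities(alw44i_fixture, obs, enzymes=enzymes)
        names = {c.name for c in result.consistent}
        assert {"CA", "CG"} <= names
        # parsimony: singletons rank before supersets
        assert [c.name for c in result.consistent[:2]] == ["CA", "CG"]

    def test_cut_aa_flanked_xmii_site_eliminates_ca(self, enzymes):
        plasmid = make_random_plasmid(3000, [
            PlantedSite("GTGCAC", "GTGCAC", 500, "A", "G"),
            PlantedSite("GTMKAC", "GTAGAC", 1500, "A", "A"),
        ], seed=2)
        xmi_truth = predict_pattern(plasmid, MTaseSpecificity.simple({"CG"}), enzymes["XmiI"])
        assert xmi_truth.n_cuts == 1   # CG methylation leaves the A/A-flanked site cuttable
        obs = [
            ObservedPattern("Alw44I", uncut=True),           # the A/G-flanked site is protected
            ObservedPattern("XmiI", full_length_linear=True),
        ]
        result = infer_specificities(plasmid, obs, enzymes=enzymes, rel_tol=0.0)
        names = {c.name for c in result.consistent}
        assert "CG" in names
        assert "CA" not in names

    def test_unmethylated_observations_report_no_methylation(self, alw44i_fixture, enzymes):
        obs = [ObservedPattern("Alw44I", (3986, 1935, 500))]
        result = infer_specificities(alw44i_fixture, obs, enzymes=enzymes, rel_tol=0.0)
        assert [c.name for c in result.consistent] == ["none"]
        assert result.message == "no methylation detected"

    def test_adding_observations_never_enlarges_consistent_set(self, alw44i_fixture, enzymes):
        obs1 = [ObservedPattern("Alw44I", (4486, 1935))]
        obs2 = obs1 + [ObservedPattern("BsuRI", tuple(
            predict_pattern(alw44i_fixture, MTaseSpecificity.simple({"CG"}),
                            enzymes["BsuRI"]).fragments))]
        r1 = infer_specificities(alw44i_fixture, obs1, enzymes=enzymes, rel_tol=0.0)
        r2 = infer_specificities(alw44i_fixture, obs2, enzymes=enzymes, rel_tol=0.0)
        assert {c.name for c in r2.consistent} <= {c.name for c in r1.consistent}

    @given(true_cores=st.sets(st.sampled_from(["CG", "CA", "CC", "CT"]), min_size=1),
           seed=st.integers(min_value=0, max_value=30))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_soundness_true_specificity_always_among_results(self, alw44i_fixture,
                                                             enzymes, true_cores, seed):
        """For observations equal to the true predicted patterns at zero
        tolerance, the generating specificity is never eliminated."""
        del seed  # plasmid fixed; the hypothesis grid is what varies
        truth = MTaseSpecificity.simple(true_cores)
        obs = []
        for name in ("Alw44I", "BsuRI", "Hin6I"):
            fs = predict_pattern(alw44i_fixture, truth, enzymes[name])
            if fs.status == UNCUT_CIRCULAR:
                obs.append(ObservedPattern(name, uncut=True))
            else:
                obs.append(ObservedPattern(name, fs.fragments))
        result = infer_specificities(alw44i_fixture, obs, enzymes=enzymes, rel_tol=0.0)
        assert truth.name in {c.name for c in result.consistent}

    def test_requires_observations(self, alw44i_fixture, enzymes):
        with pytest.raises(ValueError):
            infer_specificities(alw44i_fixture, [], enzymes=enzymes)


class TestContextCoverage:
    def test_alw44i_fixture_covers_all_four_contexts(self, alw44i_fixture, enzymes):
        cover = context_coverage(alw44i_fixture, enzymes["Alw44I"])
        assert dict(cover) == {"CA": 1, "CG": 1, "CC": 3, "CT": 1}

    def test_selection_fixture_covers_ch_and_excludes_cg(self, selection_fixture, enzymes):
        cover = context_coverage(selection_fixture, enzymes["Eco47I"])
        assert set(cover) == {"CA", "CC", "CT"}

    def test_single_site_plasmid_yields_two_contexts(self, enzymes):
        plasmid = make_random_plasmid(2000, [PlantedSite("GTGCAC", "GTGCAC", 700, "A", "T")],
                                      seed=4)
        cover = context_coverage(plasmid, enzymes["Alw44I"])
        assert sum(cover.values()) == 2

    def test_multiset_size_is_twice_the_palindromic_site_count(self, selection_fixture, enzymes):
        cover = context_coverage(selection_fixture, enzymes["Eco47I"])
        assert sum(cover.values()) == 6


class TestSelectionSuitability:
    def test_eco47i_selection_is_suitable_for_ch(self, selection_fixture, enzymes):
        report = selection_suitability(selection_fixture, enzymes["Eco47I"],
                                       desired={"CA", "CC", "CT"}, forbidden={"CG"})
        assert report.suitable

    def test_alw44i_fixture_unsuitable_when_cg_forbidden(self, alw44i_fixture, enzymes):
        report = selection_suitability(alw44i_fixture, enzymes["Alw44I"],
                                       desired={"CA"}, forbidden={"CG"})
        assert not report.suitable
        assert report.forbidden_present == ("CG",)

    def test_internal_cc_route_is_flagged(self, selection_fixture, enzymes):
        report = selection_suitability(selection_fixture, enzymes["Eco47I"],
                                       desired={"CA"}, forbidden=set())
        assert any("internal CC" in route for route in report.secondary_routes)

    def test_overlapping_desired_forbidden_rejected(self, selection_fixture, enzymes):
        with pytest.raises(ValueError):
            selection_suitability(selection_fixture, enzymes["Eco47I"], {"CA"}, {"CA"})
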