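"""Reference profiles, pattern classification, matching, coherence checks."""

import numpy as np
import pytest

import emospec as es
from emospec.love import VARIANT_LEXICON, label_tuple


@pytest.fixture(scope="module")
def mapping56():
    return es.build_mapping("2:5x6")


@pytest.fixture(scope="module")
def mapping55():
    return es.build_mapping("2:5x5")


class TestBuildMapping:
    def test_grid_cardinalities(self, mapping56, mapping55):
        assert len(mapping56.profiles) == 30
        assert len(mapping55.profiles) == 25

    def test_unsupported_spec_lists_alternatives(self):
        with pytest.raises(ValueError, match="2:5x6"):
            es.build_mapping("3:5x5x4")

    def test_no_duplicate_label_tuples(self, mapping56):
        tuples = [p.labels for p in mapping56.profiles]
        assert len(set(tuples)) == len(tuples)

    def test_lexicon_contains_all_printed_terms(self, mapping56):
        expected = {"happiness", "distress", "concern", "optimism", "excitement",
                    "frustration", "anger", "fear", "neutral", "satisfaction",
                    "high optimism", "neutral/slight concern"}
        assert expected <= mapping56.all_terms()

    def test_unnamed_profiles_are_user_assignable(self, mapping56):
        unnamed = [p for p in mapping56.profiles if p.term is None]
        assert unnamed  # the full 30-term lexicon is not canonical
        mapping = es.build_mapping("2:5x6")
        mapping.assign_term(unnamed[0].labels, "custom")
        assert mapping.profile_for(unnamed[0].labels).term == "custom"


class TestLexicon:
    @pytest.mark.parametrize("labels,term", [
        (("average", "increased"), "excitement"),
        (("average", "decreased_to_negative"), "fear"),
        (("average", "decreased_to_average"), "anger"),
        (("positive", "positive"), "happiness"),
        (("negative", "negative"), "distress"),
        (("average", "negative"), "concern"),
        (("average", "positive"), "optimism"),
        (("decreased", "average"), "frustration"),
        (("average", "average"), "neutral"),
        (("increased", "decreased_to_average"), "satisfaction"),
    ])
    def test_term_for_label_tuple(self, mapping56, labels, term):
        assert mapping56.term_for(labels) == term

    def test_intensity_variants(self, mapping56):
        assert mapping56.term_for(("average", "positive"),
                                  means=np.array([0.0, 2.0])) == "high optimism"
        assert mapping56.term_for(("average", "average"),
                                  means=np.array([0.0, -0.4])) == "neutral/slight concern"
        assert mapping56.term_for(("average", "average"),
                                  means=np.array([0.0, 0.0])) == "neutral"


class TestClassifyPatterns:
    def test_zero_window_is_neutral(self, mapping56):
        labels = es.classify_patterns(np.zeros((20, 2)))
        assert label_tuple(labels) == ("average", "average")
        assert mapping56.term_for(label_tuple(labels)) == "neutral"

    def test_expectation_ramps_name_excitement_anger_fear(self, mapping56):
        W = 20
        up = np.column_stack([np.zeros(W), np.linspace(0, 1, W)])
        down_avg = np.column_stack([np.zeros(W), np.linspace(1, 0, W)])
        down_neg = np.column_stack([np.zeros(W), np.linspace(0, -1, W)])
        for window, term in ((up, "excitement"), (down_avg, "anger"),
                             (down_neg, "fear")):
            labels = label_tuple(es.classify_patterns(window))
            assert mapping56.term_for(labels) == term

    def test_high_intensity_levels(self):
        w = np.column_stack([np.zeros(20), np.full(20, 2.0)])
        labels = es.classify_patterns(w)
        assert labels[1].label == "positive" and labels[1].intensity == "high"

    @pytest.mark.parametrize("spec_name", ["2:5x6", "2:5x5"])
    def test_template_round_trip_every_profile(self, spec_name):
        mapping = es.build_mapping(spec_name)
        counts = (5, 6) if spec_name == "2:5x6" else (5, 5)
        for profile in mapping.profiles:
            labels = es.classify_patterns(profile.template,
                                          pattern_counts=counts)
            assert label_tuple(labels) == profile.labels, profile.profile_id

    def test_level_shift_below_half_tau_is_invisible(self):
        mapping = es.build_mapping("2:5x6")
        band = es.BandConfig()
        for profile in mapping.profiles:
            if not profile.is_stable:
                continue
            shifted = profile.template + band.tau / 2 * 0.9
            got = label_tuple(es.classify_patterns(shifted, band))
            assert got == profile.labels

    def test_robust_to_small_noise(self):
        """>=95% of noisy template draws keep their generating labels."""
        mapping = es.build_mapping("2:5x6")
        rng = np.random.default_rng(42)
        hits = total = 0
        for profile in mapping.profiles:
            for _ in range(40):
                noisy = profile.template + rng.normal(0, 0.1, size=(20, 2))
                total += 1
                if label_tuple(es.classify_patterns(noisy)) == profile.labels:
                    hits += 1
        assert hits / total >= 0.95

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            es.classify_patterns(np.zeros((20, 3)))


class TestMatchProfile:
    def test_template_matches_itself_with_zero_distance(self, mapping56):
        for profile in mapping56.profiles[::7]:
            ranked = es.match_profile(profile.template, mapping56)
            assert ranked[0][0].profile_id == profile.profile_id
            assert ranked[0][1] == 0.0

    def test_raw_scale_prototype_via_norms(self, mapping56):
        norms = es.HomeostatNorms(("reward", "state_value"),
                                  np.array([0.67, 62.41]), np.array([5.6, 18.99]), 0)
        tpl = mapping56.profile_by_term("fear").template
        raw = tpl * norms.sd + norms.mean
        ranked = es.match_profile(raw, mapping56, norms)
        assert ranked[0][0].term == "fear"
        assert ranked[0][1] == pytest.approx(0.0, abs=1e-18)

    def test_distance_decreases_with_noise(self, mapping56, rng):
        tpl = mapping56.profile_by_term("excitement").template
        dists = []
        for sd in (1.0, 0.5, 0.1):
            noisy = tpl + rng.normal(0, sd, size=tpl.shape)
            d = dict((p.profile_id, d) for p, d in es.match_profile(noisy, mapping56))
            dists.append(d["average|increased"])
        assert dists[0] > dists[1] > dists[2]

    def test_ranking_invariant_to_profile_order(self, mapping56):
        probe = np.column_stack([np.linspace(0, 1, 20), np.zeros(20)])
        r1 = [p.profile_id for p, _ in es.match_profile(probe, mapping56)]
        shuffled = es.build_mapping("2:5x6")
        shuffled.profiles = shuffled.profiles[::-1]
        r2 = [p.profile_id for p, _ in es.match_profile(probe, shuffled)]
        assert r1 == r2

    def test_w_mismatch_rejected(self, mapping56):
        with pytest.raises(ValueError, match="shape"):
            es.match_profile(np.zeros((10, 2)), mapping56)


class TestCoherence:
    def test_natural_narrative_passes(self, mapping56):
        script = [{"state": "neutral", "event": "calm flight"},
                  {"state": "excitement", "event": "an opportunity arises"},
                  {"state": "optimism", "event": "and seems to hold"},
                  {"state": "anger", "event": "suddenly it vanishes"},
                  {"state": "neutral", "event": "back to normal"}]
        report = es.validate_coherence(mapping56, [script])
        assert report.passed

    def test_beyond_scope_transition_flagged(self, mapping56):
        script = [{"state": "positive|average", "event": "doing well"},
                  {"state": "increased|average", "event": "rewards rise further"}]
        report = es.validate_coherence(mapping56, [script])
        assert any("beyond-scope" in v for v in report.violations)

    def test_negative_to_decreased_flagged(self, mapping56):
        script = [{"state": "average|negative", "event": "low expectations"},
                  {"state": "average|decreased_to_negative", "event": "fall again"}]
        report = es.validate_coherence(mapping56, [script])
        assert any("beyond-scope" in v for v in report.violations)

    def test_abrupt_jump_warned_not_violated(self, mapping56):
        script = [{"state": "happiness", "event": "all good"},
                  {"state": "distress", "event": "sudden catastrophe"}]
        report = es.validate_coherence(mapping56, [script])
        assert report.passed
        assert any("abrupt" in w for w in report.warnings)

    def test_unstable_ending_flagged(self, mapping56):
        script = [{"state": "neutral", "event": "calm"},
                  {"state": "excitement", "event": "opportunity"}]
        report = es.validate_coherence(mapping56, [script])
        assert any("ends in unstable" in v for v in report.violations)

    def test_full_coverage_reports_no_unused(self, mapping56):
        scripts = []
        for profile in mapping56.profiles:
            scripts.append([{"state": "neutral", "event": "start"},
                            {"state": profile.profile_id, "event": "visit"},
                            {"state": "neutral", "event": "end"}])
        report = es.validate_coherence(mapping56, scripts)
        assert report.unused_profiles == []

    def test_unknown_state_raises(self, mapping56):
        with pytest.raises(KeyError, match="unknown"):
            es.validate_coherence(mapping56, [[{"state": "serenity", "event": "?"}]])
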