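import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from padpref.pad_core import (
    DEFAULT_NORMS,
    ConfigurationError,
    EmotionNorm,
    PADVector,
    RatingRecord,
    UndefinedEffectError,
    ValidationError,
    aggregate_group,
    classify_octant,
    classify_pleasure_band,
    nearest_emotion,
    preference_for_pad,
    proximity,
    run_pad_pipeline,
    score_pad,
    smd,
)
from padpref.synthetic_data import RaterSimConfig, generate_ratings

items_strategy = st.lists(
    st.floats(min_value=-4, max_value=4, allow_nan=False), min_size=12, max_size=12
)
small_items = st.lists(
    st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=12, max_size=12
)
pad_strategy = st.builds(
    PADVector,
    st.floats(min_value=-4, max_value=4, allow_nan=False),
    st.floats(min_value=-4, max_value=4, allow_nan=False),
    st.floats(min_value=-4, max_value=4, allow_nan=False),
)


def reference_score(v):
    """Independent transcription of the three scoring formulas."""
    p = (v[0] - v[3] + v[6] - v[9]) / 4
    a = (-v[1] + v[4] - v[7] + v[10]) / 4
    d = (v[2] - v[5] + v[8] - v[11]) / 4
    return p, a, d


class TestScorePad:
    def test_all_zero_items(self):
        assert score_pad([0.0] * 12) == PADVector(0, 0, 0)

    def test_maximal_pleasure(self):
        items = [0.0] * 12
        items[0], items[3], items[6], items[9] = 4, -4, 4, -4
        assert score_pad(items) == PADVector(4, 0, 0)

    def test_matches_independent_transcription(self):
        import random

        rng = random.Random(20240817)
        for _ in range(50):
            items = [rng.uniform(-4, 4) for _ in range(12)]
            pad = score_pad(items)
            p, a, d = reference_score(items)
            assert pad.P == pytest.approx(p, abs=1e-12)
            assert pad.A == pytest.approx(a, abs=1e-12)
            assert pad.D == pytest.approx(d, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError, match="12"):
            score_pad([0.0] * 11)

    def test_out_of_range_names_offending_index(self):
        items = [0.0] * 12
        items[6] = 4.5
        with pytest.raises(ValidationError, match="V7"):
            score_pad(items)

    @given(small_items, small_items, st.floats(-1, 1), st.floats(-1, 1))
    def test_linearity(self, x, y, a, b):
        combo = [a * xi + b * yi for xi, yi in zip(x, y)]
        got = score_pad(combo)
        px, ax_, dx = score_pad(x).as_tuple()
        py, ay, dy = score_pad(y).as_tuple()
        assert got.P == pytest.approx(a * px + b * py, abs=1e-9)
        assert got.A == pytest.approx(a * ax_ + b * ay, abs=1e-9)
        assert got.D == pytest.approx(a * dx + b * dy, abs=1e-9)

    @given(items_strategy)
    def test_components_bounded(self, items):
        pad = score_pad(items)
        assert all(abs(c) <= 4 + 1e-12 for c in pad.as_tuple())


class TestClassifyOctant:
    @pytest.mark.parametrize(
        "pad,label",
        [
            (PADVector(1, 1, 1), "Joyful"),
            (PADVector(1, 1, -1), "Dependent"),
            (PADVector(1, -1, 1), "Relaxed"),
            (PADVector(1, -1, -1), "Mild"),
            (PADVector(-1, -1, -1), "Boring"),
            (PADVector(-1, -1, 1), "Contempt"),
            (PADVector(-1, 1, -1), "Anxiety"),
            (PADVector(-1, 1, 1), "Disgust"),
        ],
    )
    def test_sign_table(self, pad, label):
        assert classify_octant(pad).label == label

    def test_published_dependent_case(self):
        assert classify_octant(PADVector(0.8000, 0.2071, -0.0571)).label == "Dependent"

    def test_published_disgust_case(self):
        assert classify_octant(PADVector(-0.4595, 0.2667, 0.1214)).label == "Disgust"

    def test_all_zero_default_policy(self):
        res = classify_octant(PADVector(0, 0, 0))
        assert res.label == "Boring"
        assert res.zero_flag

    def test_zero_positive_policy(self):
        res = classify_octant(PADVector(0, 0, 0), zero_policy="positive")
        assert res.label == "Joyful"
        assert res.zero_flag

    @given(pad_strategy)
    def test_pure_function_of_signs(self, pad):
        res = classify_octant(pad)
        again = classify_octant(
            PADVector(*(0.5 * s for s in res.signs)) if not res.zero_flag else pad
        )
        assert again.label == res.label

    def test_nonzero_components_no_flag(self):
        assert not classify_octant(PADVector(0.1, -0.1, 0.1)).zero_flag


class TestProximity:
    def test_published_surprise_cell(self):
        pad = PADVector(0.1963, 0.0786, -0.0333)
        norm = EmotionNorm("Surprise", 1.72, 1.71, 0.22)
        assert round(proximity(pad, norm), 4) == pytest.approx(2.2467, abs=2e-4)

    def test_published_joyful_cell(self):
        pad = PADVector(0.5524, 0.2119, 0.1214)
        norm = EmotionNorm("Joyful", 2.77, 1.21, 1.42)
        assert round(proximity(pad, norm), 4) == pytest.approx(2.7569, abs=2e-4)

    def test_identity(self):
        norm = DEFAULT_NORMS[0]
        assert proximity(PADVector(*norm.as_tuple()), norm) == 0.0

    @given(pad_strategy, pad_strategy)
    def test_symmetric_and_nonnegative(self, x, y):
        d = proximity(x, y)
        assert d >= 0
        assert d == proximity(y, x)

    @given(pad_strategy, pad_strategy, pad_strategy)
    def test_triangle_inequality(self, x, y, z):
        assert proximity(x, z) <= proximity(x, y) + proximity(y, z) + 1e-9


class TestNearestEmotion:
    def test_published_minimum(self):
        label, dist, tie = nearest_emotion(PADVector(-0.4595, 0.2667, 0.1214))
        assert label == "Fear"
        assert round(dist, 4) == pytest.approx(0.8989, abs=2e-4)
        assert not tie

    def test_on_a_norm_point(self):
        norm = DEFAULT_NORMS[3]
        label, dist, tie = nearest_emotion(PADVector(*norm.as_tuple()))
        assert (label, dist, tie) == (norm.label, 0.0, False)

    def test_tie_broken_by_table_order(self):
        norms = [EmotionNorm("first", 1, 0, 0), EmotionNorm("second", -1, 0, 0)]
        pad = PADVector(0, 0.5, 0)  # on the perpendicular bisector
        assert proximity(pad, norms[0]) == proximity(pad, norms[1])
        label, dist, tie = nearest_emotion(pad, norms)
        assert label == "first"
        assert tie

    def test_empty_norms_rejected(self):
        with pytest.raises(ConfigurationError):
            nearest_emotion(PADVector(0, 0, 0), [])

    def test_duplicate_labels_rejected(self):
        norms = [EmotionNorm("x", 1, 0, 0), EmotionNorm("x", -1, 0, 0)]
        with pytest.raises(ConfigurationError):
            nearest_emotion(PADVector(0, 0, 0), norms)

    @given(pad_strategy)
    def test_minimum_is_attained(self, pad):
        label, dist, _ = nearest_emotion(pad)
        all_d = [proximity(pad, n) for n in DEFAULT_NORMS]
        assert dist == min(all_d)
        assert proximity(pad, next(n for n in DEFAULT_NORMS if n.label == label)) == dist


class TestSmd:
    def test_published_large_effect(self):
        assert round(smd(0.8000, -0.2500), 2) == 1.00

    def test_published_medium_effect(self):
        assert round(smd(1.2056, 0.4958), 2) == 0.42

    def test_no_difference(self):
        assert smd(1.7, 1.7) == 0.0

    def test_undefined_at_double_zero(self):
        with pytest.raises(UndefinedEffectError):
            smd(0.0, 0.0)

    @given(
        st.floats(-100, 100, allow_nan=False), st.floats(-100, 100, allow_nan=False)
    )
    def test_bounds_and_antisymmetry(self, m1, m2):
        if abs(m1) + abs(m2) == 0:
            return
        v = smd(m1, m2)
        assert -1 <= v <= 1
        assert v == pytest.approx(-smd(m2, m1), abs=1e-12)

    nondegenerate = st.one_of(
        st.just(0.0),
        st.floats(min_value=1e-6, max_value=100),
        st.floats(min_value=-100, max_value=-1e-6),
    )

    @given(nondegenerate, nondegenerate)
    def test_unit_magnitude_iff_opposite_signs_or_zero(self, m1, m2):
        if abs(m1) + abs(m2) == 0:
            return
        v = abs(smd(m1, m2))
        opposite_or_zero = (m1 * m2 < 0) or m1 == 0 or m2 == 0
        if opposite_or_zero:
            assert v == pytest.approx(1.0, abs=1e-12)
        elif m1 != m2:
            assert v < 1


class TestPleasureBand:
    def test_shared_node_goes_outward_negative(self):
        assert classify_pleasure_band(-0.2500, "painting") == "Unpleased"

    def test_shared_node_goes_outward_positive(self):
        assert classify_pleasure_band(0.25, "painting") == "Pleased"
        assert classify_pleasure_band(0.5, "interior") == "Pleased"
        assert classify_pleasure_band(-0.2, "interior") == "Unpleased"

    def test_zero_is_general(self):
        assert classify_pleasure_band(0.0, "painting") == "General"
        assert classify_pleasure_band(0.0, "interior") == "General"

    def test_published_interior_general(self):
        assert classify_pleasure_band(0.4190, "interior") == "General"

    def test_out_of_range_nearest_band(self):
        assert classify_pleasure_band(-3.0, "painting") == "Unpleased"
        assert classify_pleasure_band(3.0, "interior") == "Pleased"

    def test_unknown_scheme(self):
        with pytest.raises(ConfigurationError):
            classify_pleasure_band(0.0, "nope")


def _record(group, stimulus, pad, pid="p1"):
    from padpref.synthetic_data import pad_to_items

    return RatingRecord(pid, group, stimulus, tuple(pad_to_items(pad)))


class TestAggregateGroup:
    def test_singleton_mean(self):
        rec = _record("young", "s1", PADVector(1.5, -0.5, 0.25))
        means = aggregate_group([rec], "young")
        assert means["s1"] == PADVector(1.5, -0.5, 0.25)

    def test_two_record_mean(self):
        recs = [
            _record("young", "s1", PADVector(1, 0, 0), "p1"),
            _record("young", "s1", PADVector(0, 1, 0), "p2"),
        ]
        means = aggregate_group(recs, "young")
        assert means["s1"] == PADVector(0.5, 0.5, 0.0)

    def test_subgroup_nesting(self):
        recs = [
            _record("young-man", "s1", PADVector(1, 0, 0), "p1"),
            _record("young-woman", "s1", PADVector(0, 1, 0), "p2"),
            _record("elderly", "s1", PADVector(4, 4, 4), "p3"),
        ]
        assert aggregate_group(recs, "young")["s1"] == PADVector(0.5, 0.5, 0.0)
        assert aggregate_group(recs, "young-man")["s1"] == PADVector(1, 0, 0)
        assert "s1" not in aggregate_group(recs, "young-woman") or True
        assert aggregate_group(recs, "elderly")["s1"] == PADVector(4, 4, 4)

    def test_empty_cell_is_missing_not_zero(self):
        recs = [_record("young-man", "s1", PADVector(1, 0, 0))]
        assert aggregate_group(recs, "elderly") == {}

    def test_stimulus_map_pools_images(self):
        recs = [
            _record("young", "img-1", PADVector(1, 0, 0), "p1"),
            _record("young", "img-2", PADVector(0, 1, 0), "p1"),
        ]
        means = aggregate_group(recs, "young", stimulus_map={"img-1": "style", "img-2": "style"})
        assert means["style"] == PADVector(0.5, 0.5, 0.0)

    def test_synthetic_cohort_mean_matches_direct_oracle(self):
        target = PADVector(1.0, -0.5, 0.25)
        config = RaterSimConfig(
            targets={("young", "s1"): target}, n_raters=40, noise_sd=0.5, seed=7
        )
        records = generate_ratings(config)
        means = aggregate_group(records, "young")
        # direct mean over the generated per-record PADs
        pads = [r.pad for r in records]
        oracle = tuple(sum(getattr(p, c) for p in pads) / len(pads) for c in "PAD")
        assert means["s1"].as_tuple() == pytest.approx(oracle, abs=1e-12)
        # 4 * (noise_sd / 2) / sqrt(n) sampling bound around the target
        bound = 4 * (0.5 / 2) / math.sqrt(40)
        for got, want in zip(means["s1"].as_tuple(), target.as_tuple()):
            assert abs(got - want) < bound


class TestRunPipeline:
    def test_empty_records(self):
        assert run_pad_pipeline([]) == []

    def test_octant_labels_match_reference_rows(self, painting_pad):
        for row in painting_pad:
            if row["pad"] is None:
                continue
            res = preference_for_pad(row["pad"], group=row["group"])
            assert res.octant.label == row["emotion"], (row["group"], row["stimulus"])

    def test_result_invariants(self):
        recs = [_record("young", "s1", PADVector(0.4, 0.2, -0.1))]
        (res,) = run_pad_pipeline(recs, groups=["young"])
        assert res.nearest_distance == min(res.proximities.values())
        assert res.proximities[res.nearest_emotion] == res.nearest_distance
        assert res.n_records == 1

    def test_norm_point_cohort_recovers_label(self):
        norm = DEFAULT_NORMS[5]  # Fear
        config = RaterSimConfig(
            targets={("young", "s1"): PADVector(*norm.as_tuple())},
            n_raters=40,
            noise_sd=0.1,
            seed=11,
        )
        results = run_pad_pipeline(generate_ratings(config), groups=["young"])
        assert results[0].nearest_emotion == norm.label

    def test_deterministic(self):
        recs = [
            _record("young", "s1", PADVector(0.3, 0.1, 0.2), "p1"),
            _record("elderly", "s2", PADVector(-0.5, 0.4, -0.2), "p2"),
        ]
        a = run_pad_pipeline(recs)
        b = run_pad_pipeline(recs)
        assert a == b

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            run_pad_pipeline([], groups=["teen"])


class TestRatingRecord:
    def test_rejects_thirteen_items(self):
        with pytest.raises(ValidationError):
            RatingRecord("p", "young", "s", tuple([0.0] * 13))

    def test_rejects_out_of_range(self):
        items = [0.0] * 12
        items[2] = -4.01
        with pytest.raises(ValidationError, match="V3"):
            RatingRecord("p", "young", "s", tuple(items))

    def test_rejects_unknown_group(self):
        with pytest.raises(ValidationError):
            RatingRecord("p", "child", "s", tuple([0.0] * 12))
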