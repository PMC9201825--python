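"""NMS / soft-NMS / WBF against exhaustive references and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wheatkit.boxes import Box, DetectionSet, iou
from wheatkit.fusion import FusionConfig, ensemble, nms, soft_nms, wbf


def random_dets(rng, n=10, image_id="im", hi=40):
    boxes = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, hi - 5, 2)
        w, h = rng.uniform(1, 8, 2)
        boxes.append(Box(x0, y0, x0 + w, y0 + h, score=float(rng.uniform(0.05, 1.0))))
    return DetectionSet(image_id, hi + 10, hi + 10, boxes, "prediction:m")


def reference_nms(boxes, thr):
    """Exhaustive O(n^2) greedy NMS, coded independently of the library."""
    order = sorted(boxes, key=lambda b: (-b.score, b.y_min, b.x_min, b.x_max))
    kept = []
    for b in order:
        if all(iou(b, k) <= thr for k in kept):
            kept.append(b)
    return kept


class TestNMS:
    def test_single_box_passthrough(self):
        d = DetectionSet("im", 10, 10, [Box(1, 1, 3, 3, score=0.7)])
        assert nms(d).boxes == d.boxes

    def test_identical_boxes_keep_highest_score(self):
        d = DetectionSet(
            "im", 10, 10,
            [Box(1, 1, 3, 3, score=0.8), Box(1, 1, 3, 3, score=0.9)],
        )
        out = nms(d, FusionConfig(method="nms", iou_threshold=0.5))
        assert [b.score for b in out.boxes] == [0.9]

    def test_missing_scores_rejected(self):
        d = DetectionSet("im", 10, 10, [Box(1, 1, 3, 3)])
        with pytest.raises(ValueError):
            nms(d)

    @given(st.integers(0, 500))
    def test_matches_exhaustive_reference(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dets(rng, n=10)
        out = nms(d, FusionConfig(method="nms", iou_threshold=0.5))
        ref = reference_nms(d.boxes, 0.5)
        assert out.boxes == ref

    def test_output_is_subset_of_input(self, rng):
        d = random_dets(rng, n=25)
        out = nms(d)
        assert all(b in d.boxes for b in out.boxes)

    def test_threshold_extremes(self):
        a = Box(0, 0, 4, 4, score=0.9)
        b = Box(1, 1, 5, 5, score=0.8)   # heavy overlap with a
        dup = Box(0, 0, 4, 4, score=0.7)  # exact duplicate of a
        far = Box(20, 20, 24, 24, score=0.6)
        d = DetectionSet("im", 30, 30, [a, b, dup, far], "prediction:m")
        near_one = nms(d, FusionConfig(method="nms", iou_threshold=0.999))
        assert set(near_one.boxes) == {a, b, far}  # only the exact duplicate dies
        near_zero = nms(d, FusionConfig(method="nms", iou_threshold=1e-9))
        assert set(near_zero.boxes) == {a, far}  # maximal non-overlapping greedy set


class TestSoftNMS:
    def test_non_overlapping_scores_unchanged(self):
        d = DetectionSet(
            "im", 30, 30,
            [Box(0, 0, 2, 2, score=0.9), Box(10, 10, 12, 12, score=0.4)],
            "prediction:m",
        )
        out = soft_nms(d)
        assert sorted(b.score for b in out.boxes) == [0.4, 0.9]

    def test_gaussian_decay_closed_form(self):
        # full overlap against the top box: factor exp(-1/sigma) = exp(-2)
        d = DetectionSet(
            "im", 10, 10,
            [Box(1, 1, 3, 3, score=0.9), Box(1, 1, 3, 3, score=0.8)],
            "prediction:m",
        )
        out = soft_nms(d, FusionConfig(method="soft_nms", soft_mode="gaussian", sigma=0.5))
        scores = sorted(b.score for b in out.boxes)
        assert scores[1] == 0.9
        assert scores[0] == pytest.approx(0.8 * math.exp(-2.0))

    def test_linear_decay_only_above_threshold(self):
        a = Box(0, 0, 4, 4, score=0.9)
        b = Box(2, 0, 6, 4, score=0.8)  # IoU = 8/24 = 1/3
        d = DetectionSet("im", 10, 10, [a, b], "prediction:m")
        below = soft_nms(d, FusionConfig(method="soft_nms", soft_mode="linear", iou_threshold=0.5))
        assert sorted(x.score for x in below.boxes) == [0.8, 0.9]
        above = soft_nms(d, FusionConfig(method="soft_nms", soft_mode="linear", iou_threshold=0.25))
        assert min(x.score for x in above.boxes) == pytest.approx(0.8 * (1 - 1 / 3))

    @given(st.integers(0, 300))
    def test_scores_pointwise_never_increase(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dets(rng, n=12)
        out = soft_nms(d, FusionConfig(method="soft_nms", score_floor=0.0))
        # score_floor=0 keeps every box; match survivors to originals by geometry
        orig = {(b.x_min, b.y_min, b.x_max, b.y_max): b.score for b in d.boxes}
        assert len(out.boxes) == len(d.boxes)
        for b in out.boxes:
            assert b.score <= orig[(b.x_min, b.y_min, b.x_max, b.y_max)] + 1e-12

    def test_score_floor_drops_boxes(self):
        d = DetectionSet(
            "im", 10, 10,
            [Box(1, 1, 3, 3, score=0.9), Box(1, 1, 3, 3, score=0.2)],
            "prediction:m",
        )
        out = soft_nms(d, FusionConfig(method="soft_nms", sigma=0.1, score_floor=0.05))
        assert [b.score for b in out.boxes] == [0.9]


class TestWBF:
    def test_single_model_disjoint_is_identity_on_coordinates(self, rng):
        boxes = [Box(10 * i, 0, 10 * i + 4, 4, score=float(rng.uniform(0.1, 1))) for i in range(5)]
        d = DetectionSet("im", 60, 10, boxes, "prediction:m")
        fused = wbf([d], FusionConfig(method="wbf", n_models=1))
        assert len(fused) == 5
        coords = {(f.box.x_min, f.box.y_min, f.box.x_max, f.box.y_max) for f in fused}
        assert coords == {(b.x_min, b.y_min, b.x_max, b.y_max) for b in boxes}
        for f in fused:
            assert f.fused_score == pytest.approx(f.contributing[0][1].score)

    def test_weighted_mean_hand_computed(self):
        d = DetectionSet(
            "im", 10, 10,
            [Box(0, 0, 2, 2, score=0.9), Box(0, 0, 4, 2, score=0.3)],
            "prediction:m",
        )
        fused = wbf([d], FusionConfig(method="wbf", iou_threshold=0.4, n_models=1))
        assert len(fused) == 1
        assert fused[0].box.x_max == pytest.approx((0.9 * 2 + 0.3 * 4) / 1.2)  # = 2.5
        assert fused[0].fused_score == pytest.approx(0.6)

    def test_cluster_count_never_exceeds_input(self, rng):
        for _ in range(20):
            d = random_dets(rng, n=15)
            fused = wbf([d], FusionConfig(method="wbf"))
            assert len(fused) <= 15
            assert sum(len(f.contributing) for f in fused) == 15  # box mass preserved

    def test_fused_coords_within_member_bounds(self, rng):
        for _ in range(10):
            d = random_dets(rng, n=12)
            for f in wbf([d], FusionConfig(method="wbf")):
                xs = [b.x_min for _, b in f.contributing]
                assert min(xs) - 1e-9 <= f.box.x_min <= max(xs) + 1e-9

    def test_mismatched_image_ids_rejected(self):
        d1 = DetectionSet("a", 10, 10, [Box(0, 0, 1, 1, score=0.5)], "prediction:m1")
        d2 = DetectionSet("b", 10, 10, [Box(0, 0, 1, 1, score=0.5)], "prediction:m2")
        with pytest.raises(ValueError):
            wbf([d1, d2])
        with pytest.raises(ValueError):
            wbf([])


class TestEnsemble:
    def test_identical_models_reproduce_coordinates(self):
        boxes = [Box(0, 0, 4, 4, score=0.8), Box(10, 10, 14, 14, score=0.6)]
        m1 = [DetectionSet("im", 20, 20, list(boxes), "prediction:m1")]
        m2 = [DetectionSet("im", 20, 20, list(boxes), "prediction:m2")]
        (out,) = ensemble([m1, m2], FusionConfig(method="wbf", n_models=2))
        got = sorted((b.x_min, b.y_min, b.x_max, b.y_max) for b in out.boxes)
        want = sorted((b.x_min, b.y_min, b.x_max, b.y_max) for b in boxes)
        assert np.allclose(got, want, atol=1e-9)
        assert all(b.score == pytest.approx(s) for b, s in zip(out.sorted_boxes(), [0.8, 0.6]))

    def test_partial_model_coverage_rescales_score(self):
        m1 = [DetectionSet("im", 20, 20, [Box(0, 0, 4, 4, score=0.8)], "prediction:m1")]
        m2 = [DetectionSet("im", 20, 20, [], "prediction:m2")]
        (out,) = ensemble([m1, m2], FusionConfig(method="wbf", n_models=2))
        assert [b.score for b in out.boxes] == [pytest.approx(0.4)]  # 0.8 * 1/2

    @given(st.integers(0, 200))
    def test_nms_ensemble_equals_concatenated_single_model(self, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = random_dets(rng, 6), random_dets(rng, 6)
        cfg = FusionConfig(method="nms")
        (fused,) = ensemble([[d1], [d2]], cfg)
        concat = DetectionSet("im", 50, 50, d1.boxes + d2.boxes, "prediction:m")
        assert fused.boxes == nms(concat, cfg).boxes

    def test_images_in_only_some_models_still_output(self):
        m1 = [DetectionSet("a", 10, 10, [Box(0, 0, 2, 2, score=0.5)], "prediction:m1")]
        m2 = [DetectionSet("b", 10, 10, [Box(0, 0, 2, 2, score=0.7)], "prediction:m2")]
        out = ensemble([m1, m2], FusionConfig(method="wbf", n_models=2))
        assert [d.image_id for d in out] == ["a", "b"]


def test_config_validation():
    with pytest.raises(ValueError):
        FusionConfig(method="magic")
    with pytest.raises(ValueError):
        FusionConfig(iou_threshold=1.5)
    with pytest.raises(ValueError):
        FusionConfig(sigma=0.0)
    assert FusionConfig(method="nms").iou_threshold == 0.5
    assert FusionConfig(method="wbf").iou_threshold == 0.55
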