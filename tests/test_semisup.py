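"""Warm-up schedules and pseudo-labeling workflows."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wheatkit.boxes import Box, DetectionSet
from wheatkit.semisup import (
    PseudoLabelRun,
    ScheduleSpec,
    filter_pseudo_labels,
    lr_at,
    lr_curve,
    run_pseudo_label,
    sweep_threshold,
)
from wheatkit.synthetic import PredictionNoiseSpec, SceneSpec, generate_scenes, simulate_predictions


class TestSchedules:
    def test_ramp_start_value(self):
        s = ScheduleSpec(base_lr=0.4, warmup_iters=10, warmup_start_factor=0.25)
        assert lr_at(s, 0) == pytest.approx(0.1)

    def test_ramp_reaches_base_lr(self):
        s = ScheduleSpec(base_lr=0.4, warmup_iters=10, warmup_start_factor=0.25)
        assert lr_at(s, 10) == pytest.approx(0.4)

    def test_cosine_floor_at_t_max(self):
        s = ScheduleSpec(base_lr=1.0, decay="cosine", t_max=50, eta_min=0.01)
        assert lr_at(s, 50) == pytest.approx(0.01)
        assert lr_at(s, 120) == pytest.approx(0.01)  # clamped beyond the period

    def test_cosine_midpoint(self):
        s = ScheduleSpec(base_lr=1.0, decay="cosine", t_max=50, eta_min=0.0)
        assert lr_at(s, 25) == pytest.approx(0.5)

    def test_multistep_drop_at_milestone(self):
        s = ScheduleSpec(base_lr=1.0, warmup_iters=5, decay="multistep",
                         milestones=(10, 20), gamma=0.1)
        assert lr_at(s, 14) == pytest.approx(1.0)   # post-warmup iter 9
        assert lr_at(s, 15) == pytest.approx(0.1)   # post-warmup iter 10
        assert lr_at(s, 25) == pytest.approx(0.01)

    def test_curve_shape_warmup_then_decay(self):
        s = ScheduleSpec(base_lr=1.0, warmup_iters=20, warmup_start_factor=0.05,
                         decay="cosine", t_max=80, eta_min=0.0)
        curve = lr_curve(s, 100)
        ramp, decay = curve[:21], curve[20:]
        assert all(b >= a for a, b in zip(ramp, ramp[1:]))      # non-decreasing ramp
        assert all(b <= a + 1e-12 for a, b in zip(decay, decay[1:]))  # monotone decay
        assert (curve > 0).all()

    def test_multistep_piecewise_constant_after_warmup(self):
        s = ScheduleSpec(base_lr=1.0, warmup_iters=10, decay="multistep",
                         milestones=(30,), gamma=0.5)
        curve = lr_curve(s, 60)
        assert len(np.unique(np.round(curve[10:40], 12))) == 1
        assert len(np.unique(np.round(curve[40:], 12))) == 1

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ScheduleSpec(base_lr=0.0)
        with pytest.raises(ValueError):
            ScheduleSpec(milestones=(5, 5))
        with pytest.raises(ValueError):
            ScheduleSpec(decay="linear")


def preds_fixture():
    boxes = [
        Box(0, 0, 10, 10, score=0.9),
        Box(20, 20, 30, 30, score=0.2),
        Box(40, 40, 50, 50, score=0.1),
    ]
    return [DetectionSet("im", 100, 100, boxes, "prediction:m")]


class TestFilterPseudoLabels:
    def test_default_threshold_keeps_two_of_three(self):
        (out,) = filter_pseudo_labels(preds_fixture(), 0.15)
        assert len(out) == 2
        assert all(b.score is None for b in out.boxes)
        assert out.source == "pseudo_label"

    def test_zero_threshold_keeps_all(self):
        (out,) = filter_pseudo_labels(preds_fixture(), 0.0)
        assert len(out) == 3

    def test_impossible_threshold_keeps_image_as_background(self):
        (out,) = filter_pseudo_labels(preds_fixture(), 1.0 + 1e-9)
        assert len(out) == 0
        assert out.image_id == "im"

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    def test_monotone_in_threshold(self, thresholds):
        counts = [
            len(filter_pseudo_labels(preds_fixture(), t)[0]) for t in sorted(thresholds)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


def separated_preds_and_truths(seed, n_images=6):
    """Truths with confident jitter-free predictions scored >= 0.8 plus
    decoys scored <= 0.3 — any threshold in (0.3, 0.8] separates perfectly."""
    rng = np.random.default_rng(seed)
    truths, preds = [], []
    for i in range(n_images):
        boxes = [
            Box(x, y, x + 12, y + 12)
            for x, y in rng.uniform(0, 80, (int(rng.integers(3, 8)), 2))
        ]
        t = DetectionSet(f"im{i}", 100, 100, boxes, "ground_truth")
        pboxes = [
            Box(b.x_min, b.y_min, b.x_max, b.y_max, score=float(rng.uniform(0.8, 1.0)))
            for b in boxes
        ]
        for _ in range(int(rng.integers(1, 4))):
            x, y = rng.uniform(0, 90, 2)
            pboxes.append(Box(x, y, x + 5, y + 5, score=float(rng.uniform(0.05, 0.3))))
        truths.append(t)
        preds.append(DetectionSet(f"im{i}", 100, 100, pboxes, "prediction:m"))
    return preds, truths


def separates(best, preds):
    """The returned cut keeps every confident true box and drops every decoy."""
    max_decoy = max(b.score for p in preds for b in p.boxes if b.score < 0.5)
    min_true = min(b.score for p in preds for b in p.boxes if b.score >= 0.5)
    return max_decoy < best <= min_true


class TestSweepThreshold:
    def test_recovers_separating_threshold(self):
        preds, truths = separated_preds_and_truths(seed=0)
        grid = np.round(np.arange(0.05, 0.96, 0.05), 2)
        best, curve = sweep_threshold(preds, truths, grid)
        assert separates(best, preds)
        assert len(curve) == len(grid)

    def test_single_point_grid(self):
        preds, truths = separated_preds_and_truths(seed=1)
        best, curve = sweep_threshold(preds, truths, [0.4])
        assert best == 0.4 and len(curve) == 1

    def test_ties_break_toward_lower_threshold(self):
        preds, truths = separated_preds_and_truths(seed=2)
        best, curve = sweep_threshold(preds, truths, [0.35, 0.4, 0.45, 0.5])
        assert best == 0.35  # all four thresholds separate; lowest wins

    def test_refine_stays_inside_separating_band(self):
        preds, truths = separated_preds_and_truths(seed=3)
        grid = np.round(np.arange(0.05, 0.96, 0.05), 2)
        best, _ = sweep_threshold(preds, truths, grid, refine=True)
        assert separates(best, preds)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold([], [], [])

    def test_recovery_rate_over_seeded_runs(self):
        hits = 0
        runs = 40
        for seed in range(runs):
            preds, truths = separated_preds_and_truths(seed=seed, n_images=4)
            best, _ = sweep_threshold(preds, truths, np.round(np.arange(0.05, 0.96, 0.05), 2))
            hits += separates(best, preds)
        assert hits / runs >= 0.95


class StubPredictor:
    """Deterministic predict_fn: returns the hidden truth, scored high, plus
    one low-scored decoy per image."""

    def __init__(self, truth_by_id, decoy_score=0.05):
        self.truth_by_id = truth_by_id
        self.decoy_score = decoy_score
        self.calls = 0

    def __call__(self, image_ids):
        self.calls += 1
        out = []
        for image_id in image_ids:
            t = self.truth_by_id[image_id]
            boxes = [
                Box(b.x_min, b.y_min, b.x_max, b.y_max, score=0.9) for b in t.boxes
            ]
            boxes.append(Box(0, 0, 3, 3, score=self.decoy_score))
            out.append(DetectionSet(image_id, t.image_width, t.image_height,
                                    boxes, "prediction:stub"))
        return out


class TestRunPseudoLabel:
    def _setup(self):
        spec = SceneSpec(image_size=(64, 64), count_mean=5, count_sd=2, count_max=10,
                         empty_image_prob=0.0, seed=11)
        scenes = generate_scenes(spec, 6, render=False)
        truths = {s.boxes.image_id: s.boxes for s in scenes}
        labeled = [truths[k] for k in sorted(truths)[:2]]
        unlabeled = sorted(truths)[2:]
        return truths, labeled, unlabeled

    def test_empty_unlabeled_returns_labeled(self):
        truths, labeled, _ = self._setup()
        stub = StubPredictor(truths)
        for strategy in "ABC":
            merged, audit = run_pseudo_label(strategy, labeled, [], stub)
            assert merged == labeled
        assert stub.calls == 0

    def test_strategy_a_recovers_hidden_truth_above_threshold(self):
        truths, labeled, unlabeled = self._setup()
        stub = StubPredictor(truths)
        merged, audit = run_pseudo_label("A", labeled, unlabeled,
                                         stub, PseudoLabelRun(strategy="A", threshold=0.15))
        pseudo = [d for d in merged if d.source == "pseudo_label"]
        assert len(pseudo) == len(unlabeled)
        for p in pseudo:
            want = truths[p.image_id].sorted_boxes()
            got = p.sorted_boxes()
            assert [(b.x_min, b.y_min, b.x_max, b.y_max) for b in got] == [
                (b.x_min, b.y_min, b.x_max, b.y_max) for b in want
            ]  # decoy at 0.05 filtered out, truth boxes recovered exactly

    def test_strategy_b_round_count_in_audit(self):
        truths, labeled, unlabeled = self._setup()
        stub = StubPredictor(truths)
        cfg = PseudoLabelRun(strategy="B", iterations=3)
        merged, audit = run_pseudo_label("B", labeled, unlabeled, stub, cfg)
        assert len(audit) == 3
        assert stub.calls == 3
        assert [a["round"] for a in audit] == [0, 1, 2]

    def test_strategy_c_never_writes_trusted_pool(self):
        truths, labeled, unlabeled = self._setup()
        stub = StubPredictor(truths)
        merged_c, _ = run_pseudo_label("C", labeled, unlabeled, stub)
        # pseudo labels are merged for training...
        assert sum(d.source == "pseudo_label" for d in merged_c) == len(unlabeled)
        # ...but a second C run starts from the same labeled-only pool
        merged_again, _ = run_pseudo_label("C", labeled, unlabeled, stub)
        assert [d.image_id for d in merged_again] == [d.image_id for d in merged_c]

    def test_strategy_b_iterations_validation(self):
        with pytest.raises(ValueError):
            PseudoLabelRun(strategy="B", iterations=0)
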