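"""Detection scoring: greedy IoU matching and threshold-averaged precision.

Two styles are offered and labeled explicitly in the report:

* ``gwhd`` — the Global Wheat Head competition measure: per image and IoU
  threshold, precision = TP / (TP + FP + FN); averaged over images first,
  then over thresholds (default 0.50:0.05:0.75). An image with neither
  truths nor predictions scores 1 by convention. This is the quantity
  reported as "mAP" when benchmarking against that leaderboard.
* ``coco_ap`` — standard 101-point interpolated average precision per
  threshold, averaged over thresholds.

Matching is greedy in descending prediction score: each prediction claims
the unmatched truth of highest IoU provided that IoU reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import DetectionSet, iou_matrix

__all__ = ["EvalConfig", "EvalReport", "match", "gwhd_precision", "coco_ap", "evaluate"]


def default_thresholds() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.50, 0.751, 0.05), 2))


@dataclass
class EvalConfig:
    iou_thresholds: Sequence[float] = field(default_factory=default_thresholds)
    style: str = "gwhd"  # gwhd | coco_ap

    def __post_init__(self) -> None:
        t = list(self.iou_thresholds)
        if not t or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("iou_thresholds must be non-empty and strictly increasing")
        if any(not (0.0 < x < 1.0) for x in t):
            raise ValueError("iou_thresholds must lie in (0, 1)")
        if self.style not in ("gwhd", "coco_ap"):
            raise ValueError(f"unknown style {self.style!r}")
        self.iou_thresholds = tuple(t)


@dataclass
class EvalReport:
    style: str
    per_threshold: dict[float, float]
    map_value: float
    per_image: dict[str, dict[float, tuple[int, int, int]]]  # id -> thr -> (TP, FP, FN)


def _score_sorted(preds: DetectionSet):
    for b in preds.boxes:
        if b.score is None:
            raise ValueError(f"unscored prediction in {preds.image_id!r}")
    return sorted(preds.boxes, key=lambda b: (-b.score, b.y_min, b.x_min))


def match(preds: DetectionSet, truths: DetectionSet, thr: float) -> tuple[int, int, int]:
    """Greedy score-ordered one-to-one matching; returns (TP, FP, FN)."""
    p = _score_sorted(preds)
    t = truths.boxes
    if not p:
        return 0, 0, len(t)
    if not t:
        return 0, len(p), 0
    m = iou_matrix(p, t)
    taken = np.zeros(len(t), dtype=bool)
    tp = 0
    for i in range(len(p)):
        row = np.where(taken, -1.0, m[i])
        j = int(np.argmax(row))
        if row[j] >= thr:
            taken[j] = True
            tp += 1
    return tp, len(p) - tp, len(t) - tp


def _pair_by_image(
    preds: Sequence[DetectionSet], truths: Sequence[DetectionSet]
) -> list[tuple[DetectionSet, DetectionSet]]:
    pmap = {d.image_id: d for d in preds}
    tmap = {d.image_id: d for d in truths}
    pairs = []
    for image_id in sorted(set(pmap) | set(tmap)):
        p = pmap.get(image_id)
        t = tmap.get(image_id)
        ref = p or t
        empty = DetectionSet(image_id, ref.image_width, ref.image_height)
        pairs.append((p or empty, t or empty))
    return pairs


def gwhd_precision(
    preds: Sequence[DetectionSet],
    truths: Sequence[DetectionSet],
    cfg: EvalConfig | None = None,
) -> EvalReport:
    """Competition-style averaged precision TP/(TP+FP+FN).

    Averaging order: images inner, thresholds outer.
    """
    cfg = cfg or EvalConfig()
    pairs = _pair_by_image(preds, truths)
    per_image: dict[str, dict[float, tuple[int, int, int]]] = {}
    per_threshold: dict[float, float] = {}
    for thr in cfg.iou_thresholds:
        vals = []
        for p, t in pairs:
            tp, fp, fn = match(p, t, thr)
            per_image.setdefault(p.image_id, {})[thr] = (tp, fp, fn)
            denom = tp + fp + fn
            vals.append(1.0 if denom == 0 else tp / denom)
        per_threshold[thr] = float(np.mean(vals))
    map_value = float(np.mean(list(per_threshold.values())))
    return EvalReport("gwhd", per_threshold, map_value, per_image)


def coco_ap(
    preds: Sequence[DetectionSet],
    truths: Sequence[DetectionSet],
    cfg: EvalConfig | None = None,
) -> EvalReport:
    """101-point interpolated AP per IoU threshold, averaged over thresholds.

    Predictions are ranked globally by score; precision at each recall point
    r in {0, 0.01, ..., 1} is the maximum precision at recall >= r.
    """
    cfg = cfg or EvalConfig()
    pairs = _pair_by_image(preds, truths)
    n_truth = sum(len(t) for _, t in pairs)
    per_threshold: dict[float, float] = {}
    per_image: dict[str, dict[float, tuple[int, int, int]]] = {}
    recall_grid = np.linspace(0.0, 1.0, 101)
    for thr in cfg.iou_thresholds:
        records = []  # (score, tie-break, is_tp)
        for p, t in pairs:
            sorted_p = _score_sorted(p)
            tp_count = 0
            if sorted_p:
                m = iou_matrix(sorted_p, t.boxes) if t.boxes else np.zeros((len(sorted_p), 0))
                taken = np.zeros(len(t.boxes), dtype=bool)
                for i, b in enumerate(sorted_p):
                    hit = False
                    if m.shape[1]:
                        row = np.where(taken, -1.0, m[i])
                        j = int(np.argmax(row))
                        if row[j] >= thr:
                            taken[j] = True
                            hit = True
                    tp_count += hit
                    records.append((b.score, p.image_id, i, hit))
            per_image.setdefault(p.image_id, {})[thr] = (
                tp_count, len(sorted_p) - tp_count, len(t.boxes) - tp_count,
            )
        if n_truth == 0:
            per_threshold[thr] = 0.0 if records else 1.0
            continue
        if not records:
            per_threshold[thr] = 0.0
            continue
        records.sort(key=lambda r: (-r[0], r[1], r[2]))
        hits = np.array([r[3] for r in records], dtype=float)
        tp_cum = np.cumsum(hits)
        fp_cum = np.cumsum(1.0 - hits)
        recall = tp_cum / n_truth
        precision = tp_cum / (tp_cum + fp_cum)
        # monotone envelope, then sample at the 101 recall points
        prec_env = np.maximum.accumulate(precision[::-1])[::-1]
        ap = 0.0
        for r in recall_grid:
            mask = recall >= r - 1e-12
            ap += prec_env[mask].max() if mask.any() else 0.0
        per_threshold[thr] = ap / len(recall_grid)
    map_value = float(np.mean(list(per_threshold.values())))
    return EvalReport("coco_ap", per_threshold, map_value, per_image)


def evaluate(
    preds: Sequence[DetectionSet],
    truths: Sequence[DetectionSet],
    cfg: EvalConfig | None = None,
) -> EvalReport:
    cfg = cfg or EvalConfig()
    fn = gwhd_precision if cfg.style == "gwhd" else coco_ap
    return fn(preds, truths, cfg)
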