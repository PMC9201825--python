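"""Suppression and fusion of redundant detections.

Three post-processing strategies over scored boxes:

* classical greedy non-maximum suppression (NMS),
* soft-NMS, which decays overlapping scores with a penalty function
  (gaussian ``s * exp(-iou^2 / sigma)`` or linear ``s * (1 - iou)``)
  instead of removing boxes outright, and
* weighted boxes fusion (WBF), which keeps every box and replaces each
  overlap cluster by the confidence-weighted mean of its members — useful
  when ensembling several detectors whose boxes are all somewhat off.

Tie-breaking is deterministic everywhere: equal scores are ordered by
(y_min, x_min), identical boxes by model id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .boxes import Box, DetectionSet, iou, iou_matrix

__all__ = ["FusionConfig", "FusedBox", "nms", "soft_nms", "wbf", "ensemble"]

_DEFAULT_IOU_THR = {"nms": 0.5, "soft_nms": 0.5, "wbf": 0.55}


@dataclass
class FusionConfig:
    """Parameters shared by the suppression/fusion methods.

    iou_threshold defaults to 0.5 for (soft-)NMS and 0.55 for WBF when left
    unset; these defaults are this package's, chosen as the common practice
    values, and every constant is overridable.
    """

    method: str = "nms"  # nms | soft_nms | wbf
    iou_threshold: float | None = None
    soft_mode: str = "gaussian"  # linear | gaussian
    sigma: float = 0.5
    score_floor: float = 1e-3
    n_models: int = 1

    def __post_init__(self) -> None:
        if self.method not in _DEFAULT_IOU_THR:
            raise ValueError(f"unknown fusion method {self.method!r}")
        if self.iou_threshold is None:
            self.iou_threshold = _DEFAULT_IOU_THR[self.method]
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.score_floor < 1.0):
            raise ValueError("score_floor must lie in [0, 1)")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.soft_mode not in ("linear", "gaussian"):
            raise ValueError(f"unknown soft_mode {self.soft_mode!r}")


@dataclass
class FusedBox:
    """A WBF output box together with the cluster that produced it."""

    box: Box
    fused_score: float
    contributing: list[tuple[str, Box]] = field(default_factory=list)


def _require_scores(dets: DetectionSet) -> None:
    for b in dets.boxes:
        if b.score is None:
            raise ValueError(f"box without score in {dets.image_id!r}; fusion needs scores")


def _score_order(boxes: Sequence[Box]) -> list[int]:
    """Indices in descending score, ties broken by (y_min, x_min)."""
    return sorted(
        range(len(boxes)),
        key=lambda i: (-boxes[i].score, boxes[i].y_min, boxes[i].x_min, boxes[i].x_max),
    )


def nms(dets: DetectionSet, cfg: FusionConfig | None = None) -> DetectionSet:
    """Greedy NMS: keep descending-score boxes, drop any with IoU > threshold
    against an already-kept box. Output sorted by score."""
    cfg = cfg or FusionConfig(method="nms")
    _require_scores(dets)
    order = _score_order(dets.boxes)
    boxes = [dets.boxes[i] for i in order]
    kept: list[Box] = []
    if boxes:
        m = iou_matrix(boxes, boxes)
        kept_idx: list[int] = []
        for i in range(len(boxes)):
            if all(m[i, j] <= cfg.iou_threshold for j in kept_idx):
                kept_idx.append(i)
        kept = [boxes[i] for i in kept_idx]
    return replace(dets, boxes=kept)


def soft_nms(dets: DetectionSet, cfg: FusionConfig | None = None) -> DetectionSet:
    """Soft-NMS: decay overlapping scores instead of removing boxes.

    Iteratively selects the highest-scoring unprocessed box and decays every
    remaining box's score by the penalty function; boxes whose decayed score
    falls below ``score_floor`` are dropped.
    """
    cfg = cfg or FusionConfig(method="soft_nms")
    _require_scores(dets)
    pending = [dets.boxes[i] for i in _score_order(dets.boxes)]
    scores = [b.score for b in pending]
    out: list[Box] = []
    while pending:
        top = int(np.argmax(scores))  # first max wins; list is pre-ordered for ties
        box = pending.pop(top)
        s = scores.pop(top)
        out.append(replace(box, score=s))
        if not pending:
            break
        overlaps = iou_matrix([box], pending)[0]
        new_scores = []
        new_pending = []
        for b, sc, ov in zip(pending, scores, overlaps):
            if cfg.soft_mode == "gaussian":
                sc = sc * float(np.exp(-(ov**2) / cfg.sigma))
            elif ov > cfg.iou_threshold:
                sc = sc * (1.0 - ov)
            if sc >= cfg.score_floor:
                new_pending.append(b)
                new_scores.append(sc)
        pending, scores = new_pending, new_scores
    out.sort(key=lambda b: (-b.score, b.y_min, b.x_min))
    return replace(dets, boxes=out)


def _weighted_mean_box(members: list[tuple[str, Box]]) -> tuple[Box, float]:
    ws = np.array([b.score for _, b in members])
    coords = np.array([[b.x_min, b.y_min, b.x_max, b.y_max] for _, b in members])
    fused = (ws[:, None] * coords).sum(axis=0) / ws.sum()
    return Box(*fused, score=float(ws.mean())), float(ws.mean())


def wbf(
    dets_per_model: Sequence[DetectionSet], cfg: FusionConfig | None = None
) -> list[FusedBox]:
    """Weighted boxes fusion across one or more models' detections.

    Every box joins exactly one cluster (greedy match by IoU > threshold
    against the running fused boxes, in descending score order); fused
    coordinates are the score-weighted mean of the cluster, and the fused
    score is the mean member score rescaled by
    ``min(cluster_size, n_models) / n_models``.
    """
    cfg = cfg or FusionConfig(method="wbf")
    if not dets_per_model:
        raise ValueError("wbf needs at least one model's detections")
    ids = {d.image_id for d in dets_per_model}
    if len(ids) != 1:
        raise ValueError(f"wbf inputs refer to different images: {sorted(ids)}")
    for d in dets_per_model:
        _require_scores(d)

    tagged: list[tuple[str, Box]] = []
    for k, d in enumerate(dets_per_model):
        model_id = d.source if d.source.startswith("prediction:") else f"model_{k}"
        tagged.extend((model_id, b) for b in d.boxes)
    tagged.sort(key=lambda t: (-t[1].score, t[1].y_min, t[1].x_min, t[0]))

    clusters: list[list[tuple[str, Box]]] = []
    fused_boxes: list[Box] = []
    for model_id, b in tagged:
        best_j, best_iou = -1, cfg.iou_threshold
        for j, fb in enumerate(fused_boxes):
            ov = iou(b, fb)
            if ov > best_iou:
                best_j, best_iou = j, ov
        if best_j < 0:
            clusters.append([(model_id, b)])
            fused_boxes.append(replace(b))
        else:
            clusters[best_j].append((model_id, b))
            fused_boxes[best_j], _ = _weighted_mean_box(clusters[best_j])

    out = []
    for members, fb in zip(clusters, fused_boxes):
        mean_score = float(np.mean([b.score for _, b in members]))
        scale = min(len(members), cfg.n_models) / cfg.n_models
        fused_score = mean_score * scale
        out.append(
            FusedBox(
                box=replace(fb, score=min(fused_score, 1.0)),
                fused_score=fused_score,
                contributing=members,
            )
        )
    out.sort(key=lambda f: (-f.fused_score, f.box.y_min, f.box.x_min))
    return out


def _fused_to_set(image: DetectionSet, fused: list[FusedBox]) -> DetectionSet:
    return replace(image, boxes=[f.box for f in fused], source="prediction:fused")


def ensemble(
    model_sets: Sequence[Sequence[DetectionSet]], cfg: FusionConfig | None = None
) -> list[DetectionSet]:
    """Fuse per-image predictions of several models into one prediction set.

    ``model_sets`` holds one collection of DetectionSets per model. Images
    present in only some models still produce output. Under (soft-)NMS the
    models' boxes are concatenated per image first, which is definitionally
    equivalent to single-model suppression of the union.
    """
    if not model_sets:
        raise ValueError("ensemble needs at least one model")
    cfg = cfg or FusionConfig(method="wbf", n_models=len(model_sets))
    by_image: dict[str, list[DetectionSet]] = {}
    for sets in model_sets:
        for d in sets:
            by_image.setdefault(d.image_id, []).append(d)
    out = []
    for image_id in sorted(by_image):
        group = by_image[image_id]
        if cfg.method == "wbf":
            out.append(_fused_to_set(group[0], wbf(group, cfg)))
        else:
            merged = replace(group[0], boxes=[b for d in group for b in d.boxes])
            fn: Callable = nms if cfg.method == "nms" else soft_nms
            out.append(replace(fn(merged, cfg), source="prediction:fused"))
    return out
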