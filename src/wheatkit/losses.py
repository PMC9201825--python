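"""Composite single-stage detection loss and deterministic label smoothing.

The loss follows the YOLO-family decomposition over a K x K grid with M
predicted boxes per cell:

    total = coord + objectness + classification

* coord — squared center/size error per responsible box, scaled by
  ``(2 - w*h)`` so small boxes weigh more, weighted by ``lambda_coord``;
  alternatively a complete-IoU (CIoU) regression term (``coord_mode="ciou"``).
* objectness — binary cross-entropy on the confidence of responsible boxes
  plus a ``lambda_noobj``-weighted term on non-responsible ones.
* classification — per-class binary cross-entropy on responsible cells over
  the two classes {positive, negative}.

Label smoothing replaces a binary target y with ``eps*(1-y) + (1-eps)*y``.
Randomly flipping each label with probability eps and averaging the
cross-entropy over flips has the same expected loss, so the deterministic
replacement is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import Box, ciou_loss

__all__ = [
    "LossBatch",
    "SmoothingSpec",
    "LossBreakdown",
    "bbox_coord_loss",
    "objectness_loss",
    "classification_loss",
    "total_loss",
    "smooth_labels",
]


@dataclass
class LossBatch:
    """Gridded prediction/target values for one loss evaluation.

    Shapes (C = K*K grid cells, M boxes per cell):
      pred_xywh, true_xywh : (C, M, 4) — center x, center y, width, height;
                             sizes normalized to [0, 1] so (2 - w*h) is in [1, 2]
      pred_conf, true_conf : (C, M) objectness in [0, 1]
      pred_class, true_class : (C, n_classes) per-class probabilities
      obj_mask : (C, M) in {0, 1}; 1 marks the box responsible for a target.
                 The no-object mask is its complement.
    """

    K: int
    M: int
    pred_xywh: np.ndarray
    true_xywh: np.ndarray
    pred_conf: np.ndarray
    true_conf: np.ndarray
    pred_class: np.ndarray
    true_class: np.ndarray
    obj_mask: np.ndarray
    lambda_coord: float = 5.0
    lambda_noobj: float = 0.5
    eps: float = 1e-7  # probability clamp floor for logs

    def __post_init__(self) -> None:
        C = self.K * self.K
        arrays = {
            "pred_xywh": (C, self.M, 4),
            "true_xywh": (C, self.M, 4),
            "pred_conf": (C, self.M),
            "true_conf": (C, self.M),
            "obj_mask": (C, self.M),
        }
        for name, shape in arrays.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        self.pred_class = np.asarray(self.pred_class, dtype=float)
        self.true_class = np.asarray(self.true_class, dtype=float)
        if self.pred_class.shape != self.true_class.shape or self.pred_class.shape[0] != C:
            raise ValueError("class arrays must share shape (K*K, n_classes)")
        if not np.isin(self.obj_mask, (0.0, 1.0)).all():
            raise ValueError("obj_mask entries must be 0 or 1")
        if self.lambda_coord < 0 or self.lambda_noobj < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def noobj_mask(self) -> np.ndarray:
        return 1.0 - self.obj_mask

    @property
    def cell_obj_mask(self) -> np.ndarray:
        """1 for grid cells containing at least one responsible box."""
        return (self.obj_mask.sum(axis=1) > 0).astype(float)

    @classmethod
    def perfect(cls, K: int = 2, M: int = 2, **kw) -> "LossBatch":
        """A batch whose predictions equal their targets (loss at the clamp floor)."""
        rng = np.random.default_rng(kw.pop("seed", 0))
        C = K * K
        xywh = np.stack(
            [
                rng.uniform(0, 1, (C, M)),
                rng.uniform(0, 1, (C, M)),
                rng.uniform(0.05, 1, (C, M)),
                rng.uniform(0.05, 1, (C, M)),
            ],
            axis=-1,
        )
        obj = (rng.uniform(size=(C, M)) < 0.5).astype(float)
        conf = obj.copy()
        n_classes = kw.pop("n_classes", 2)
        cls_true = np.zeros((C, n_classes))
        cls_true[:, 0] = 1.0
        return cls(
            K=K,
            M=M,
            pred_xywh=xywh.copy(),
            true_xywh=xywh.copy(),
            pred_conf=conf.copy(),
            true_conf=conf.copy(),
            pred_class=cls_true.copy(),
            true_class=cls_true.copy(),
            obj_mask=obj,
            **kw,
        )


@dataclass(frozen=True)
class SmoothingSpec:
    """Label-smoothing error rate; beyond 0.5 the labels invert on average."""

    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError(f"epsilon must lie in [0, 0.5), got {self.epsilon}")


@dataclass(frozen=True)
class LossBreakdown:
    coord: float
    objectness: float
    classification: float

    @property
    def total(self) -> float:
        return self.coord + self.objectness + self.classification


def _bce(pred: np.ndarray, true: np.ndarray, eps: float) -> np.ndarray:
    """Elementwise binary cross-entropy, sign-normalized to be >= 0."""
    if eps <= 0:
        if np.any((pred <= 0) | (pred >= 1)):
            raise ValueError("probabilities at 0/1 require a positive clamp floor")
        p = pred
    else:
        p = np.clip(pred, eps, 1.0 - eps)
    return -(true * np.log(p) + (1.0 - true) * np.log(1.0 - p))


def bbox_coord_loss(batch: LossBatch) -> float:
    """Scaled squared center/size error over responsible boxes.

    Each responsible box contributes
    ``(2 - w*h) * [(x - x̂)^2 + (y - ŷ)^2 + (w - ŵ)^2 + (h - ĥ)^2]``,
    all weighted by ``lambda_coord``. The ``(2 - w*h)`` factor (sizes
    normalized to [0, 1]) up-weights small boxes, which dominate dense
    wheat-head scenes.
    """
    pw, ph = batch.pred_xywh[..., 2], batch.pred_xywh[..., 3]
    scale = 2.0 - pw * ph
    sq = ((batch.pred_xywh - batch.true_xywh) ** 2).sum(axis=-1)
    return float(batch.lambda_coord * (batch.obj_mask * scale * sq).sum())


def _ciou_coord_loss(batch: LossBatch) -> float:
    """Mean CIoU regression loss over responsible pairs, lambda_coord-weighted."""
    idx = np.argwhere(batch.obj_mask > 0)
    if len(idx) == 0:
        return 0.0
    vals = []
    for i, j in idx:
        px, py, pw, ph = batch.pred_xywh[i, j]
        tx, ty, tw, th = batch.true_xywh[i, j]
        pred = Box(px - pw / 2, py - ph / 2, px + pw / 2, py + ph / 2)
        true = Box(tx - tw / 2, ty - th / 2, tx + tw / 2, ty + th / 2)
        vals.append(ciou_loss(pred, true))
    return float(batch.lambda_coord * np.mean(vals))


def objectness_loss(batch: LossBatch) -> float:
    """Confidence cross-entropy: responsible boxes at weight 1, the rest at
    ``lambda_noobj``."""
    bce = _bce(batch.pred_conf, batch.true_conf, batch.eps)
    return float((batch.obj_mask * bce).sum() + batch.lambda_noobj * (batch.noobj_mask * bce).sum())


def classification_loss(batch: LossBatch) -> float:
    """Per-class binary cross-entropy over cells holding a responsible box."""
    bce = _bce(batch.pred_class, batch.true_class, batch.eps)
    return float((batch.cell_obj_mask[:, None] * bce).sum())


def total_loss(batch: LossBatch, coord_mode: str = "mse") -> LossBreakdown:
    """Full loss breakdown. ``coord_mode="ciou"`` swaps the squared-error
    coordinate term for the mean CIoU regression loss over responsible pairs."""
    if coord_mode == "mse":
        coord = bbox_coord_loss(batch)
    elif coord_mode == "ciou":
        coord = _ciou_coord_loss(batch)
    else:
        raise ValueError(f"unknown coord_mode {coord_mode!r}")
    return LossBreakdown(
        coord=coord,
        objectness=objectness_loss(batch),
        classification=classification_loss(batch),
    )


def smooth_labels(
    labels: Sequence[float] | np.ndarray, spec: SmoothingSpec | float = SmoothingSpec()
) -> np.ndarray:
    """Deterministic label smoothing: y' = eps*(1-y) + (1-eps)*y elementwise."""
    if not isinstance(spec, SmoothingSpec):
        spec = SmoothingSpec(float(spec))
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0 or 1)")
    return spec.epsilon * (1.0 - y) + (1.0 - spec.epsilon) * y
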