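"""Axis-aligned box data model and the IoU / GIoU / CIoU geometry family.

Coordinate convention: continuous pixel coordinates, origin at the top-left,
boxes stored as corners ``(x_min, y_min, x_max, y_max)``. Areas are plain
products ``(x_max - x_min) * (y_max - y_min)`` — no half-open pixel semantics,
so the representation is lossless for the continuous widths/heights of the
Global Wheat Head (GWHD) CSV dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Box",
    "DetectionSet",
    "CIoUParams",
    "BoxValidationError",
    "DegenerateGeometryError",
    "iou",
    "giou",
    "ciou_params",
    "ciou_loss",
    "iou_matrix",
]


class BoxValidationError(ValueError):
    """An invalid box: negative extent or an out-of-range score."""


class DegenerateGeometryError(ValueError):
    """Geometry undefined for this pair (e.g. a zero-size enclosing box)."""


@dataclass(frozen=True)
class Box:
    """One detection or ground-truth rectangle.

    ``score`` is the detector confidence in [0, 1]; ground-truth boxes carry
    ``score=None``. The dataset has a single foreground class, so ``label``
    defaults to ``"wheat_head"``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float | None = None
    label: str = "wheat_head"

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.x_min, self.y_min, self.x_max, self.y_max)
        ):
            raise BoxValidationError(f"non-finite coordinates: {self}")
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise BoxValidationError(
                f"negative extent: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise BoxValidationError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @classmethod
    def from_xywh(
        cls,
        x: float,
        y: float,
        w: float,
        h: float,
        score: float | None = None,
        label: str = "wheat_head",
    ) -> "Box":
        """Build from top-left corner plus width/height (the GWHD/COCO layout)."""
        if w < 0 or h < 0:
            raise BoxValidationError(f"negative width/height: w={w}, h={h}")
        return cls(x, y, x + w, y + h, score=score, label=label)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)

    def clipped(self, width: float, height: float) -> "Box":
        """Clip to the frame [0, width] x [0, height]."""
        return replace(
            self,
            x_min=min(max(self.x_min, 0.0), width),
            y_min=min(max(self.y_min, 0.0), height),
            x_max=min(max(self.x_max, 0.0), width),
            y_max=min(max(self.y_max, 0.0), height),
        )

    def shifted(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )


@dataclass
class DetectionSet:
    """All boxes attached to one image.

    ``source`` tags provenance: ``"ground_truth"``, ``"pseudo_label"``, or
    ``"prediction:<model-id>"``.
    """

    image_id: str
    image_width: float
    image_height: float
    boxes: list[Box] = field(default_factory=list)
    source: str = "ground_truth"
    clipped: bool = False  # set when clip_to_frame() altered any coordinate

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[Box]:
        return iter(self.boxes)

    def clip_to_frame(self) -> "DetectionSet":
        """Return a copy with every box clipped to the image frame.

        Out-of-frame boxes are clipped, never silently dropped; the ``clipped``
        flag records whether any coordinate changed.
        """
        new_boxes = [b.clipped(self.image_width, self.image_height) for b in self.boxes]
        changed = any(nb != b for nb, b in zip(new_boxes, self.boxes))
        return DetectionSet(
            image_id=self.image_id,
            image_width=self.image_width,
            image_height=self.image_height,
            boxes=new_boxes,
            source=self.source,
            clipped=self.clipped or changed,
        )

    def sorted_boxes(self) -> list[Box]:
        """Deterministic geometric ordering: (y_min, x_min, y_max, x_max)."""
        return sorted(self.boxes, key=lambda b: (b.y_min, b.x_min, b.y_max, b.x_max))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _intersection_area(a: Box, b: Box) -> float:
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    return iw * ih


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when the union has zero area."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def giou(a: Box, b: Box) -> float:
    """Generalized IoU: IoU minus the enclosing-box slack ratio; lies in [-1, 1]."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    ew = max(a.x_max, b.x_max) - min(a.x_min, b.x_min)
    eh = max(a.y_max, b.y_max) - min(a.y_min, b.y_min)
    enclose = ew * eh
    if enclose <= 0.0:
        return 0.0
    iou_val = inter / union if union > 0.0 else 0.0
    return iou_val - (enclose - union) / enclose


@dataclass(frozen=True)
class CIoUParams:
    """Intermediate quantities of the complete-IoU score.

    rho2   squared distance between the two box centers (pixel^2)
    c2     squared diagonal of the smallest enclosing box (pixel^2)
    nu     aspect-ratio consistency term, (4/pi^2) (arctan(w_t/h_t) - arctan(w_p/h_p))^2
    alpha  trade-off weight nu / ((1 - IoU) + nu), in [0, 1]
    """

    iou: float
    rho2: float
    c2: float
    nu: float
    alpha: float


def ciou_params(pred: Box, truth: Box) -> CIoUParams:
    """Compute the CIoU decomposition for a prediction/ground-truth pair.

    Requires positive widths and heights on both boxes (the aspect-ratio term
    is undefined otherwise) and a non-degenerate enclosing box.
    """
    if pred.width <= 0 or pred.height <= 0 or truth.width <= 0 or truth.height <= 0:
        raise DegenerateGeometryError("CIoU needs positive width and height")
    ew = max(pred.x_max, truth.x_max) - min(pred.x_min, truth.x_min)
    eh = max(pred.y_max, truth.y_max) - min(pred.y_min, truth.y_min)
    c2 = ew * ew + eh * eh
    if c2 <= 0.0:
        raise DegenerateGeometryError("zero-size enclosing box")
    (pcx, pcy), (tcx, tcy) = pred.center, truth.center
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    iou_val = iou(pred, truth)
    nu = (4.0 / math.pi**2) * (
        math.atan(truth.width / truth.height) - math.atan(pred.width / pred.height)
    ) ** 2
    denom = (1.0 - iou_val) + nu
    alpha = nu / denom if denom > 0.0 else 0.0
    return CIoUParams(iou=iou_val, rho2=rho2, c2=c2, nu=nu, alpha=alpha)


def ciou_loss(pred: Box, truth: Box) -> float:
    """Complete-IoU regression loss: 1 - IoU + rho^2/c^2 + alpha*nu.

    Zero exactly when the boxes coincide; always >= 1 - IoU because both
    penalty terms are non-negative.
    """
    p = ciou_params(pred, truth)
    return (1.0 - p.iou) + p.rho2 / p.c2 + p.alpha * p.nu


def iou_matrix(boxes_a: Sequence[Box] | Iterable[Box], boxes_b: Sequence[Box]) -> "np.ndarray":
    """Pairwise IoU matrix, shape (len(a), len(b)). Vectorized for fusion/eval."""
    import numpy as np

    a = list(boxes_a)
    b = list(boxes_b)
    if not a or not b:
        return np.zeros((len(a), len(b)))
    ax = np.array([[bb.x_min, bb.y_min, bb.x_max, bb.y_max] for bb in a])
    bx = np.array([[bb.x_min, bb.y_min, bb.x_max, bb.y_max] for bb in b])
    iw = np.minimum(ax[:, None, 2], bx[None, :, 2]) - np.maximum(ax[:, None, 0], bx[None, :, 0])
    ih = np.minimum(ax[:, None, 3], bx[None, :, 3]) - np.maximum(ax[:, None, 1], bx[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (ax[:, 2] - ax[:, 0]) * (ax[:, 3] - ax[:, 1])
    area_b = (bx[:, 2] - bx[:, 0]) * (bx[:, 3] - bx[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return out
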