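"""Box-aware data amplification for wheat-head detection training sets.

Operators:

* ``simple_amplify`` — the 15x scheme: five sub-windows per image (four
  corners plus center), each emitted as {crop, horizontal flip, vertical
  flip}, with an HSV color shift applied to every output. Crop windows are
  adjusted (grown toward straddling boxes) so no ground-truth box is severed;
  boxes whose surviving visible fraction falls below ``min_box_visibility``
  are dropped as a last resort.
* ``cutout`` — blank random rectangles with a constant fill; labels untouched.
* ``cutmix_with_background`` — graft a rectangular patch from a box-free
  background donor over the source image (1:1 mixing = half the area in
  expectation), clipping or dropping the covered boxes.
* ``mosaic`` — stitch four samples around a jittered center point, remapping
  and clipping boxes per tile.
* ``hsv_shift`` — bounded perturbation of hue (wrapped), saturation and value.

Images are float arrays in [0, 1], shape (H, W, 3). Every operator is
deterministic given the config seed and records its lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

from .boxes import Box, DetectionSet

__all__ = [
    "AugmentConfig",
    "AugmentedSample",
    "simple_amplify",
    "cutout",
    "cutmix_with_background",
    "mosaic",
    "hsv_shift",
]


@dataclass
class AugmentConfig:
    crop_count: int = 5
    crop_fraction: float = 0.6
    hsv_shift: tuple[float, float, float] = (0.02, 0.15, 0.15)
    cutout_holes: tuple[int, int] = (1, 4)
    cutout_size: tuple[float, float] = (0.08, 0.2)
    cutout_fill: float = 114.0 / 255.0
    cutmix_ratio: float = 0.5  # donor patch area fraction; 0.5 = 1:1 mixing
    mosaic_tiles: int = 4
    min_box_visibility: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must lie in (0, 1]")
        if not (0.0 < self.min_box_visibility <= 1.0):
            raise ValueError("min_box_visibility must lie in (0, 1]")
        if not (0.0 < self.cutmix_ratio < 1.0):
            raise ValueError("cutmix_ratio must lie in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class AugmentedSample:
    """An image, its boxes, and the operator chain that produced it."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    boxes: DetectionSet
    lineage: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 3 or self.image.shape[-1] != 3:
            raise ValueError("image must be (H, W, 3)")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def with_step(self, op: str, **params) -> list[dict]:
        return self.lineage + [{"op": op, "source": self.boxes.image_id, **params}]


def _visibility(box: Box, window: tuple[float, float, float, float]) -> float:
    """Fraction of the box's area inside an (x0, y0, x1, y1) window."""
    if box.area <= 0:
        return 0.0
    x0, y0, x1, y1 = window
    iw = min(box.x_max, x1) - max(box.x_min, x0)
    ih = min(box.y_max, y1) - max(box.y_min, y0)
    if iw <= 0 or ih <= 0:
        return 0.0
    return (iw * ih) / box.area


def _crop(sample: AugmentedSample, window: tuple[int, int, int, int],
          min_vis: float, op: str) -> AugmentedSample:
    x0, y0, x1, y1 = window
    img = sample.image[y0:y1, x0:x1].copy()
    boxes = []
    for b in sample.boxes.boxes:
        if _visibility(b, window) < min_vis:
            continue
        boxes.append(
            b.shifted(-x0, -y0).clipped(x1 - x0, y1 - y0)
        )
    ds = DetectionSet(
        image_id=f"{sample.boxes.image_id}_{op}",
        image_width=x1 - x0,
        image_height=y1 - y0,
        boxes=boxes,
        source=sample.boxes.source,
    )
    return AugmentedSample(img, ds, sample.with_step(op, window=list(window)))


def _adjust_window(
    sample: AugmentedSample, window: tuple[int, int, int, int]
) -> tuple[int, int, int, int]:
    """Grow a candidate crop window until no box straddles its boundary.

    A box partially inside the window is absorbed by extending the window to
    the union of the two rectangles (clamped to the frame). Growing can only
    pull in more straddlers, so iterate to a fixed point; the frame bounds
    the growth. Boxes wholly outside are left alone.
    """
    x0, y0, x1, y1 = (float(v) for v in window)
    changed = True
    while changed:
        changed = False
        for b in sample.boxes.boxes:
            vis = _visibility(b, (x0, y0, x1, y1))
            if 0.0 < vis < 1.0:
                x0 = min(x0, np.floor(b.x_min))
                y0 = min(y0, np.floor(b.y_min))
                x1 = max(x1, np.ceil(b.x_max))
                y1 = max(y1, np.ceil(b.y_max))
                changed = True
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, sample.width), min(y1, sample.height)
    return int(x0), int(y0), int(x1), int(y1)


def _flip_h(sample: AugmentedSample) -> AugmentedSample:
    w = sample.width
    boxes = [
        dc_replace(b, x_min=w - b.x_max, x_max=w - b.x_min) for b in sample.boxes.boxes
    ]
    ds = dc_replace(sample.boxes, boxes=boxes, image_id=sample.boxes.image_id + "_hflip")
    return AugmentedSample(sample.image[:, ::-1].copy(), ds, sample.with_step("hflip"))


def _flip_v(sample: AugmentedSample) -> AugmentedSample:
    h = sample.height
    boxes = [
        dc_replace(b, y_min=h - b.y_max, y_max=h - b.y_min) for b in sample.boxes.boxes
    ]
    ds = dc_replace(sample.boxes, boxes=boxes, image_id=sample.boxes.image_id + "_vflip")
    return AugmentedSample(sample.image[::-1].copy(), ds, sample.with_step("vflip"))


def hsv_shift(
    sample: AugmentedSample,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
    deltas: tuple[float, float, float] | None = None,
) -> AugmentedSample:
    """Shift hue (wrapped mod 1), saturation and value (clipped) by bounded
    amounts; boxes are untouched. Explicit ``deltas`` override the random draw."""
    rng = rng if rng is not None else cfg.rng()
    if deltas is None:
        deltas = tuple(rng.uniform(-m, m) for m in cfg.hsv_shift)
    dh, ds_, dv = deltas
    if (dh, ds_, dv) == (0.0, 0.0, 0.0):
        img = sample.image.copy()
    else:
        hsv = rgb2hsv(np.clip(sample.image, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + ds_, 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] + dv, 0.0, 1.0)
        img = hsv2rgb(hsv)
    return AugmentedSample(
        img, dc_replace(sample.boxes), sample.with_step("hsv", deltas=list(deltas))
    )


def simple_amplify(sample: AugmentedSample, cfg: AugmentConfig) -> list[AugmentedSample]:
    """Emit ``3 * crop_count`` variants: each sub-window as {crop, h-flip,
    v-flip}, all HSV-shifted. The default five windows (corners + center)
    at ``crop_fraction`` of each side give the 15-image amplification."""
    rng = cfg.rng()
    H, W = sample.height, sample.width
    ch, cw = int(round(H * cfg.crop_fraction)), int(round(W * cfg.crop_fraction))
    if ch < 1 or cw < 1 or ch > H or cw > W:
        raise ValueError(f"crop size {cw}x{ch} invalid for image {W}x{H}")
    anchors = [
        (0, 0),
        (W - cw, 0),
        (0, H - ch),
        (W - cw, H - ch),
        ((W - cw) // 2, (H - ch) // 2),
    ]
    if cfg.crop_count <= 5:
        anchors = anchors[: cfg.crop_count]
    else:
        extra = cfg.crop_count - 5
        anchors += [
            (int(rng.integers(0, W - cw + 1)), int(rng.integers(0, H - ch + 1)))
            for _ in range(extra)
        ]
    out: list[AugmentedSample] = []
    for k, (ax, ay) in enumerate(anchors):
        window = _adjust_window(sample, (ax, ay, ax + cw, ay + ch))
        cropped = _crop(sample, window, cfg.min_box_visibility, f"crop{k}")
        for variant in (cropped, _flip_h(cropped), _flip_v(cropped)):
            out.append(hsv_shift(variant, cfg, rng=rng))
    return out


def cutout(
    sample: AugmentedSample, cfg: AugmentConfig, rng: np.random.Generator | None = None
) -> AugmentedSample:
    """Blank k random rectangles with the configured fill; boxes unchanged."""
    rng = rng if rng is not None else cfg.rng()
    k = int(rng.integers(cfg.cutout_holes[0], cfg.cutout_holes[1] + 1))
    img = sample.image.copy()
    H, W = sample.height, sample.width
    holes = []
    for _ in range(k):
        side = rng.uniform(*cfg.cutout_size) * min(H, W)
        hw, hh = int(round(side)), int(round(side))
        x0 = int(rng.integers(0, max(W - hw, 0) + 1))
        y0 = int(rng.integers(0, max(H - hh, 0) + 1))
        img[y0 : y0 + hh, x0 : x0 + hw] = cfg.cutout_fill
        holes.append([x0, y0, x0 + hw, y0 + hh])
    return AugmentedSample(
        img, dc_replace(sample.boxes), sample.with_step("cutout", holes=holes)
    )


def cutmix_with_background(
    spiked: AugmentedSample,
    background: AugmentedSample,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> AugmentedSample:
    """Graft a background-donor patch over the source image.

    The donor must be box-free (that is the point: enriching backgrounds).
    The patch covers ``cutmix_ratio`` of the image area. Boxes under the
    patch are clipped where the patch shaves a full-width/height strip off
    the box, kept as-is when partially shadowed but still sufficiently
    visible, and dropped below ``min_box_visibility``.
    """
    if len(background.boxes) != 0:
        raise ValueError("cutmix background donor must contain no boxes")
    rng = rng if rng is not None else cfg.rng()
    H, W = spiked.height, spiked.width
    if background.height < H or background.width < W:
        raise ValueError("background donor smaller than the target frame")
    f = float(np.sqrt(cfg.cutmix_ratio))
    pw, ph = int(round(W * f)), int(round(H * f))
    x0 = int(rng.integers(0, W - pw + 1))
    y0 = int(rng.integers(0, H - ph + 1))
    x1, y1 = x0 + pw, y0 + ph
    img = spiked.image.copy()
    img[y0:y1, x0:x1] = background.image[y0:y1, x0:x1]

    boxes = []
    for b in spiked.boxes.boxes:
        clipped = _clip_box_against_patch(b, (x0, y0, x1, y1))
        if clipped is None:
            continue
        if clipped.area < cfg.min_box_visibility * b.area:
            continue
        boxes.append(clipped)
    ds = dc_replace(
        spiked.boxes, boxes=boxes, image_id=spiked.boxes.image_id + "_cutmix"
    )
    lineage = spiked.with_step(
        "cutmix", patch=[x0, y0, x1, y1], donor=background.boxes.image_id
    )
    return AugmentedSample(img, ds, lineage)


def _clip_box_against_patch(
    b: Box, patch: tuple[int, int, int, int]
) -> Box | None:
    """Largest axis-aligned sub-box of ``b`` avoiding ``patch`` when the patch
    cuts an edge strip; ``b`` unchanged when untouched; None when swallowed."""
    x0, y0, x1, y1 = patch
    iw = min(b.x_max, x1) - max(b.x_min, x0)
    ih = min(b.y_max, y1) - max(b.y_min, y0)
    if iw <= 0 or ih <= 0:
        return b  # disjoint
    covers_w = x0 <= b.x_min and b.x_max <= x1
    covers_h = y0 <= b.y_min and b.y_max <= y1
    if covers_w and covers_h:
        return None  # fully swallowed
    candidates = []
    if not covers_w:  # vertical strips survive left/right of the patch
        if b.x_min < x0:
            candidates.append(dc_replace(b, x_max=min(b.x_max, x0)))
        if b.x_max > x1:
            candidates.append(dc_replace(b, x_min=max(b.x_min, x1)))
    if not covers_h:
        if b.y_min < y0:
            candidates.append(dc_replace(b, y_max=min(b.y_max, y0)))
        if b.y_max > y1:
            candidates.append(dc_replace(b, y_min=max(b.y_min, y1)))
    return max(candidates, key=lambda c: c.area)


def mosaic(
    samples: Sequence[AugmentedSample],
    cfg: AugmentConfig,
    canvas_size: tuple[int, int] | None = None,
    center: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> AugmentedSample:
    """Stitch four samples into one canvas around a jittered center point.

    Each tile is taken from its sample's top-left region (cropped to fit its
    quadrant); boxes are remapped into canvas coordinates, clipped to the
    tile, and filtered by ``min_box_visibility``. The center is drawn
    uniformly within the central 50% of the canvas unless given.
    """
    if len(samples) < cfg.mosaic_tiles:
        raise ValueError(f"mosaic needs {cfg.mosaic_tiles} samples, got {len(samples)}")
    if cfg.mosaic_tiles != 4:
        raise ValueError("only 4-tile mosaic is supported")
    samples = list(samples)[:4]
    rng = rng if rng is not None else cfg.rng()
    if canvas_size is None:
        canvas_size = (samples[0].height * 2, samples[0].width * 2)
    CH, CW = canvas_size
    if center is None:
        cx = int(rng.integers(CW // 4, 3 * CW // 4 + 1))
        cy = int(rng.integers(CH // 4, 3 * CH // 4 + 1))
    else:
        cx, cy = center
    canvas = np.zeros((CH, CW, 3), dtype=np.float64)
    regions = [  # (x0, y0, x1, y1) per quadrant: TL, TR, BL, BR
        (0, 0, cx, cy),
        (cx, 0, CW, cy),
        (0, cy, cx, CH),
        (cx, cy, CW, CH),
    ]
    boxes: list[Box] = []
    for s, (x0, y0, x1, y1) in zip(samples, regions):
        tw, th = x1 - x0, y1 - y0
        if tw <= 0 or th <= 0:
            continue
        src = s.image[: min(th, s.height), : min(tw, s.width)]
        canvas[y0 : y0 + src.shape[0], x0 : x0 + src.shape[1]] = src
        window = (0.0, 0.0, float(src.shape[1]), float(src.shape[0]))
        for b in s.boxes.boxes:
            if _visibility(b, window) < cfg.min_box_visibility:
                continue
            boxes.append(
                b.clipped(window[2], window[3]).shifted(x0, y0)
            )
    ds = DetectionSet(
        image_id="mosaic_" + "_".join(s.boxes.image_id for s in samples),
        image_width=CW,
        image_height=CH,
        boxes=boxes,
        source=samples[0].boxes.source,
    )
    lineage = [
        {
            "op": "mosaic",
            "center": [cx, cy],
            "sources": [s.boxes.image_id for s in samples],
        }
    ]
    return AugmentedSample(canvas, ds, lineage)
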