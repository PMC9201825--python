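"""Synthetic wheat-field scenes and a degraded-prediction simulator.

The generator emulates the data regime of field phenotyping imagery: each
image carries a number of wheat spikes drawn from a truncated normal
distribution (typical images hold 20-60 spikes, a small fraction hold none,
and a hard cap bounds the densest images), rendered as oriented, textured
ellipses with awn strokes on a green-brown noise background, degraded by
motion blur, illumination gain/offset, and mutual occlusion. Every rendered
spike gets a tight bounding box; annotations use the GWHD CSV dialect.

``simulate_predictions`` turns ground truth into scored detector output with
controllable localization jitter, misses and decoys — the knob set used to
exercise fusion, evaluation and pseudo-labeling without a trained network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .augment import AugmentedSample
from .boxes import Box, DetectionSet

__all__ = [
    "SceneSpec",
    "PredictionNoiseSpec",
    "sample_counts",
    "generate_layout",
    "render_scene",
    "generate_scenes",
    "simulate_predictions",
    "write_scene_images",
]


@dataclass
class SceneSpec:
    """Parameters of the synthetic wheat-field generator.

    Count distribution defaults follow the field regime: mean 40, sd 15,
    truncated at 0 and a hard cap of 116 boxes, with a small probability of
    a completely empty (background-only) image. Spike geometry and nuisance
    ranges are calibrations chosen to look like canopy imagery at the
    default 512 px scale; they rescale linearly with image size.
    """

    image_size: tuple[int, int] = (512, 512)  # (height, width)
    count_mean: float = 40.0
    count_sd: float = 15.0
    count_max: int = 116
    empty_image_prob: float = 49.0 / 3000.0
    spike_length: tuple[float, float] = (0.055, 0.11)  # fraction of min side
    spike_width: tuple[float, float] = (0.02, 0.042)
    texture_amplitude: float = 0.12
    blur_sigma: tuple[float, float] = (0.0, 1.5)  # motion/wind blur, px
    illum_gain: tuple[float, float] = (0.75, 1.25)
    illum_offset: tuple[float, float] = (-0.06, 0.06)
    occlusion_overlap: float = 0.35  # max tolerated center crowding fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_max < 0 or self.count_sd <= 0:
            raise ValueError("count_max must be >= 0 and count_sd > 0")
        if not (0.0 <= self.empty_image_prob <= 1.0):
            raise ValueError("empty_image_prob must lie in [0, 1]")


@dataclass
class PredictionNoiseSpec:
    """Degradation model applied to ground truth to fake detector output.

    Scores are Beta-distributed: kept true boxes from ``true_score_ab``
    (high mode), decoys from ``decoy_score_ab`` (low mode).
    """

    localization_jitter: float = 0.0  # sd of corner noise, fraction of box size
    miss_rate: float = 0.0
    decoy_rate: float = 0.0  # expected spurious boxes per image
    true_score_ab: tuple[float, float] = (8.0, 2.0)
    decoy_score_ab: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.decoy_rate < 0 or self.localization_jitter < 0:
            raise ValueError("rates must be non-negative")


def sample_counts(spec: SceneSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-image box counts: truncated-normal draws on [0, count_max], with an
    extra atom of probability ``empty_image_prob`` at exactly zero."""
    out = np.empty(n, dtype=int)
    for i in range(n):
        if rng.uniform() < spec.empty_image_prob:
            out[i] = 0
            continue
        while True:  # rejection sampling inside the truncation bounds
            c = rng.normal(spec.count_mean, spec.count_sd)
            if 0.0 <= c <= spec.count_max:
                out[i] = int(round(c))
                break
    return out


def _spike_geometry(spec: SceneSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    m = min(spec.image_size)
    length = rng.uniform(*spec.spike_length) * m
    width = rng.uniform(*spec.spike_width) * m
    theta = rng.uniform(0.0, math.pi)
    return length, width, theta


def generate_layout(
    spec: SceneSpec, rng: np.random.Generator, image_id: str, count: int | None = None
) -> tuple[DetectionSet, list[tuple[float, float, float, float, float]]]:
    """Place spikes (centers, sizes, orientations) and derive tight boxes.

    Placement is uniform with a mild crowding rule: a candidate whose center
    falls within ``occlusion_overlap`` of an existing spike's half-length is
    still accepted (mutual occlusion is a feature of the regime), but exact
    center collisions are re-drawn.
    Returns the ground-truth DetectionSet and the spike parameter list
    (cx, cy, half_len, half_wid, theta) for the renderer.
    """
    H, W = spec.image_size
    if count is None:
        count = int(sample_counts(spec, 1, rng)[0])
    spikes = []
    boxes = []
    for _ in range(count):
        length, width, theta = _spike_geometry(spec, rng)
        a, b = length / 2.0, width / 2.0
        if 2 * a >= min(H, W) or 2 * b >= min(H, W):
            raise ValueError("spike larger than frame")
        # tight half-extents of a rotated ellipse
        hx = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
        hy = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
        for _attempt in range(50):
            cx = rng.uniform(hx, W - hx)
            cy = rng.uniform(hy, H - hy)
            too_close = any(
                (cx - sx) ** 2 + (cy - sy) ** 2 < (spec.occlusion_overlap * sa) ** 2
                for sx, sy, sa, _, _ in spikes
            )
            if not too_close:
                break
        spikes.append((cx, cy, a, b, theta))
        boxes.append(Box(cx - hx, cy - hy, cx + hx, cy + hy))
    ds = DetectionSet(
        image_id=image_id, image_width=W, image_height=H, boxes=boxes,
        source="ground_truth",
    )
    return ds, spikes


def render_scene(
    spec: SceneSpec,
    spikes: Sequence[tuple[float, float, float, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Render spikes over a green-brown noise background; returns (H, W, 3)
    float in [0, 1]."""
    H, W = spec.image_size
    base = np.array([0.32, 0.42, 0.18])  # muted field green-brown
    noise = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), sigma=max(2.0, H / 40.0))
    noise = noise / (np.abs(noise).max() + 1e-9)
    img = base[None, None, :] + 0.08 * noise[..., None]
    img += 0.02 * rng.normal(size=(H, W, 3))  # sensor grain

    spike_color = np.array([0.78, 0.72, 0.40])  # straw yellow
    yy, xx = np.mgrid[0:H, 0:W]
    for cx, cy, a, b, theta in spikes:
        hx = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
        hy = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
        x0, x1 = int(max(cx - hx - 2, 0)), int(min(cx + hx + 3, W))
        y0, y1 = int(max(cy - hy - 2, 0)), int(min(cy + hy + 3, H))
        lx = xx[y0:y1, x0:x1] - cx
        ly = yy[y0:y1, x0:x1] - cy
        u = lx * math.cos(theta) + ly * math.sin(theta)
        v = -lx * math.sin(theta) + ly * math.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not mask.any():
            continue
        # kernel-row speckle along the spike axis
        texture = spec.texture_amplitude * np.cos(2.0 * math.pi * u / max(2.0 * b, 1.0))
        shade = rng.uniform(0.85, 1.1)
        patch = img[y0:y1, x0:x1]
        colored = shade * spike_color[None, None, :] * (1.0 + texture[..., None])
        patch[mask] = colored[mask]
        # a few awn strokes poking past the tip
        for _ in range(3):
            t = rng.uniform(0.6, 1.25)
            ang = theta + rng.uniform(-0.25, 0.25)
            px = cx + t * a * math.cos(ang)
            py = cy + t * a * math.sin(ang)
            ix, iy = int(px), int(py)
            if 0 <= ix < W and 0 <= iy < H:
                img[iy, ix] = spike_color * 0.9

    sigma = rng.uniform(*spec.blur_sigma)
    if sigma > 0.0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0.0))
    gain = rng.uniform(*spec.illum_gain)
    offset = rng.uniform(*spec.illum_offset)
    return np.clip(img * gain + offset, 0.0, 1.0)


def generate_scenes(
    spec: SceneSpec, n: int, render: bool = True
) -> list[AugmentedSample]:
    """Generate ``n`` scenes (bit-reproducible for a fixed spec.seed).

    With ``render=False`` only layouts/annotations are produced and images
    are 1x1 placeholders — enough for fusion/evaluation/pseudo-label work
    that never looks at pixels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    counts = sample_counts(spec, n, rng)
    out = []
    for i in range(n):
        image_id = f"scene_{i:05d}"
        ds, spikes = generate_layout(spec, rng, image_id, count=int(counts[i]))
        if render:
            img = render_scene(spec, spikes, rng)
        else:
            img = np.zeros((1, 1, 3))
        out.append(AugmentedSample(img, ds, [{"op": "generate", "seed": spec.seed, "index": i}]))
    return out


def write_scene_images(samples: Sequence[AugmentedSample], out_dir: str | Path) -> list[Path]:
    """Write scenes as PNGs named after their image ids."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in samples:
        arr = (np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        p = out_dir / f"{s.boxes.image_id}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths


def simulate_predictions(
    truths: Sequence[DetectionSet], spec: PredictionNoiseSpec
) -> list[DetectionSet]:
    """Degrade ground truth into scored detector-style predictions.

    Per image: each truth box is kept with probability ``1 - miss_rate``,
    its corners jittered by gaussian noise with sd ``localization_jitter``
    times the box side, and scored from the high Beta mode; Poisson(decoy_rate)
    spurious boxes with low-mode scores are added. Output boxes are clipped
    to the frame and sorted by score.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for t in truths:
        boxes: list[Box] = []
        for b in t.boxes:
            if rng.uniform() < spec.miss_rate:
                continue
            jx = spec.localization_jitter * max(b.width, 1e-6)
            jy = spec.localization_jitter * max(b.height, 1e-6)
            x0, x1 = sorted(
                (b.x_min + rng.normal(0, jx), b.x_max + rng.normal(0, jx))
            )
            y0, y1 = sorted(
                (b.y_min + rng.normal(0, jy), b.y_max + rng.normal(0, jy))
            )
            score = float(rng.beta(*spec.true_score_ab))
            boxes.append(
                Box(x0, y0, x1, y1, score=score).clipped(t.image_width, t.image_height)
            )
        for _ in range(rng.poisson(spec.decoy_rate)):
            w = rng.uniform(0.02, 0.12) * t.image_width
            h = rng.uniform(0.02, 0.12) * t.image_height
            x0 = rng.uniform(0, t.image_width - w)
            y0 = rng.uniform(0, t.image_height - h)
            boxes.append(
                Box(x0, y0, x0 + w, y0 + h, score=float(rng.beta(*spec.decoy_score_ab)))
            )
        boxes.sort(key=lambda b: (-b.score, b.y_min, b.x_min))
        out.append(
            DetectionSet(
                image_id=t.image_id,
                image_width=t.image_width,
                image_height=t.image_height,
                boxes=boxes,
                source="prediction:simulated",
            )
        )
    return out
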