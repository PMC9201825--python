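"""Warm-up learning-rate schedules and pseudo-labeling workflows.

Schedules: a linear warm-up ramp from ``base_lr * warmup_start_factor`` to
``base_lr`` over ``warmup_iters`` iterations, followed by either MultiStepLR
(piecewise-constant decay by ``gamma`` at each milestone) or cosine
annealing to ``eta_min``.

Pseudo-labeling: a detector's confident predictions on unlabeled images are
promoted to training annotations. The confidence cut matters — too high and
many true spikes stay unlabeled (poisoning the background class), too low
and wrong boxes leak in — so the threshold is found by a sliding sweep that
maximizes a validation metric, optionally refined by a finer second sweep,
with a conventional default of 0.15. Three workflows are provided:

* A — one round; accepted pseudo labels join a trusted pool merged with the
      labeled data.
* B — as A, iterated for several rounds, re-predicting and re-filtering
      each round while the trusted pool accumulates.
* C — one round; pseudo labels are merged for training but never enter the
      trusted pool.

The detector itself is an injected callable, so these procedures run against
any prediction source (including the synthetic simulator in tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Sequence

import numpy as np

from .boxes import DetectionSet
from .evaluation import EvalConfig, evaluate

__all__ = [
    "ScheduleSpec",
    "PseudoLabelRun",
    "lr_at",
    "lr_curve",
    "filter_pseudo_labels",
    "sweep_threshold",
    "run_pseudo_label",
]


@dataclass
class ScheduleSpec:
    base_lr: float = 0.01
    warmup_iters: int = 0
    warmup_start_factor: float = 0.1
    decay: str = "multistep"  # multistep | cosine
    milestones: tuple[int, ...] = ()  # iterations counted after warm-up
    gamma: float = 0.1
    t_max: int = 100
    eta_min: float = 0.0

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not (0.0 < self.warmup_start_factor <= 1.0):
            raise ValueError("warmup_start_factor must lie in (0, 1]")
        if self.decay not in ("multistep", "cosine"):
            raise ValueError(f"unknown decay {self.decay!r}")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


def lr_at(spec: ScheduleSpec, t: int) -> float:
    """Learning rate at iteration ``t`` (0-based)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if spec.warmup_iters > 0 and t < spec.warmup_iters:
        frac = t / spec.warmup_iters
        return spec.base_lr * (spec.warmup_start_factor + (1.0 - spec.warmup_start_factor) * frac)
    tp = t - spec.warmup_iters
    if spec.decay == "multistep":
        k = sum(1 for m in spec.milestones if tp >= m)
        return spec.base_lr * spec.gamma**k
    tt = min(tp, spec.t_max)
    return spec.eta_min + (spec.base_lr - spec.eta_min) * (1.0 + math.cos(math.pi * tt / spec.t_max)) / 2.0


def lr_curve(spec: ScheduleSpec, n_iters: int) -> np.ndarray:
    return np.array([lr_at(spec, t) for t in range(n_iters)])


# ---------------------------------------------------------------------------
# Pseudo-labeling
# ---------------------------------------------------------------------------


@dataclass
class PseudoLabelRun:
    strategy: str = "A"  # A | B | C
    threshold: float = 0.15
    sweep_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
    iterations: int = 1  # rounds (strategy B)
    metric: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if self.strategy not in ("A", "B", "C"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        if self.strategy == "B" and self.iterations < 1:
            raise ValueError("strategy B needs iterations >= 1")


def filter_pseudo_labels(
    preds: Sequence[DetectionSet], threshold: float
) -> list[DetectionSet]:
    """Keep boxes scoring >= threshold as pseudo ground truth (scores
    stripped). Images emptied by the cut are retained as background
    pseudo-images."""
    out = []
    for d in preds:
        kept = [
            dc_replace(b, score=None)
            for b in d.boxes
            if b.score is not None and b.score >= threshold
        ]
        out.append(dc_replace(d, boxes=kept, source="pseudo_label"))
    return out


def sweep_threshold(
    preds: Sequence[DetectionSet],
    truths: Sequence[DetectionSet],
    grid: Sequence[float],
    metric: EvalConfig | None = None,
    refine: bool = False,
) -> tuple[float, np.ndarray]:
    """Sliding-threshold search: evaluate the metric at every grid point.

    Returns the argmax threshold (ties to the lower value — low thresholds
    are preferred in this regime) and the metric curve over the grid. With
    ``refine=True`` a second, 10x finer sweep spanning one coarse step on
    each side of the argmax is run and its winner returned.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    metric = metric or EvalConfig()

    def metric_at(thr: float) -> float:
        cut = [
            dc_replace(d, boxes=[b for b in d.boxes if b.score >= thr]) for d in preds
        ]
        return evaluate(cut, truths, metric).map_value

    curve = np.array([metric_at(t) for t in grid])
    best_i = int(np.argmax(curve))  # argmax returns the first = lowest on ties
    best = grid[best_i]
    if refine and len(grid) > 1:
        step = grid[1] - grid[0]
        fine = np.linspace(max(best - step, 0.0), min(best + step, 1.0), 21)
        fine_curve = np.array([metric_at(t) for t in fine])
        best = float(fine[int(np.argmax(fine_curve))])
    return best, curve


def run_pseudo_label(
    strategy: str,
    labeled: Sequence[DetectionSet],
    unlabeled: Sequence[str],
    predict_fn: Callable[[Sequence[str]], list[DetectionSet]],
    cfg: PseudoLabelRun | None = None,
) -> tuple[list[DetectionSet], list[dict]]:
    """Run one pseudo-labeling workflow.

    ``unlabeled`` is a list of image ids; ``predict_fn`` maps ids to scored
    DetectionSets (an external detector's output, or a stub in tests).
    Returns the merged training annotation set and a per-round audit log.
    """
    cfg = cfg or PseudoLabelRun(strategy=strategy)
    if strategy != cfg.strategy:
        cfg = dc_replace(cfg, strategy=strategy)
    trusted_pseudo: dict[str, DetectionSet] = {}  # latest accepted labels per image
    merged: list[DetectionSet] = list(labeled)
    audit: list[dict] = []
    rounds = cfg.iterations if strategy == "B" else 1
    for r in range(rounds):
        if not unlabeled:
            audit.append({"round": r, "n_images": 0, "n_pseudo_boxes": 0,
                          "threshold": cfg.threshold})
            continue
        preds = predict_fn(list(unlabeled))
        pseudo = filter_pseudo_labels(preds, cfg.threshold)
        audit.append({
            "round": r,
            "n_images": len(pseudo),
            "n_pseudo_boxes": sum(len(p) for p in pseudo),
            "threshold": cfg.threshold,
        })
        if strategy in ("A", "B"):
            # re-filtering each round replaces that image's earlier labels
            for p in pseudo:
                trusted_pseudo[p.image_id] = p
            merged = list(labeled) + [trusted_pseudo[k] for k in sorted(trusted_pseudo)]
        else:  # C: merged for training, trusted pool untouched
            merged = list(labeled) + pseudo
    return merged, audit
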