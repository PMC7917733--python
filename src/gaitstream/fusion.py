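"""Weighted score fusion of the two streams and the evaluation surface."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import ActionLabel, ScoreVector

__all__ = [
    "FusionWeight",
    "EvalReport",
    "fuse_scores",
    "select_weight",
    "evaluate",
    "DEFAULT_WEIGHT_GRID",
]

DEFAULT_WEIGHT_GRID: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class FusionWeight:
    """Relative weight of the outline stream against the skeleton stream;
    strictly inside (0, 1)."""

    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight < 1.0:
            raise ValueError(f"fusion weight must lie in (0, 1), got {self.weight}")

    def __float__(self) -> float:
        return self.weight


def _as_probs(v: Union[ScoreVector, Sequence[float]]) -> np.ndarray:
    if isinstance(v, ScoreVector):
        return v.probs
    return ScoreVector(np.asarray(v, dtype=float)).probs


def fuse_scores(
    yp: Union[ScoreVector, Sequence[float]],
    ys: Union[ScoreVector, Sequence[float]],
    w: Union[FusionWeight, float],
) -> ScoreVector:
    """Convex combination y = w * yp + (1 - w) * ys of the outline (yp)
    and skeleton (ys) stream scores."""
    if not isinstance(w, FusionWeight):
        w = FusionWeight(float(w))
    p = _as_probs(yp)
    s = _as_probs(ys)
    return ScoreVector(w.weight * p + (1.0 - w.weight) * s)


@dataclass
class EvalReport:
    """Per-class accuracies and confusion counts for one prediction set."""

    per_class_accuracy: np.ndarray  # (3,)
    average_accuracy: float
    confusion: np.ndarray  # (3, 3) counts, rows = true class
    n_clips: int

    def to_dict(self) -> Dict:
        return {
            "labels": [l.name.lower() for l in ActionLabel],
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
            "average_accuracy": float(self.average_accuracy),
            "confusion": self.confusion.astype(int).tolist(),
            "n_clips": int(self.n_clips),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        names = [l.name.lower() for l in ActionLabel]
        width = max(len(n) for n in names) + 2
        lines = ["confusion matrix (rows = true, cols = predicted)"]
        header = " " * width + "".join(f"{n:>{width}}" for n in names)
        lines.append(header)
        for i, n in enumerate(names):
            row = f"{n:>{width}}" + "".join(
                f"{int(c):>{width}}" for c in self.confusion[i]
            )
            lines.append(row)
        for i, n in enumerate(names):
            lines.append(f"accuracy[{n}] = {self.per_class_accuracy[i]:.4f}")
        lines.append(f"average accuracy = {self.average_accuracy:.4f}  (n={self.n_clips})")
        return "\n".join(lines)


def evaluate(
    preds: Sequence[Union[ScoreVector, Sequence[float]]],
    labels: Sequence[int],
) -> EvalReport:
    """Confusion matrix and per-class accuracy under the argmax rule
    (ties broken toward the lowest class index)."""
    if len(preds) != len(labels):
        raise ValueError(f"{len(preds)} predictions vs {len(labels)} labels")
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    k = len(ActionLabel)
    confusion = np.zeros((k, k), dtype=int)
    for p, y in zip(preds, labels):
        pred = int(np.argmax(_as_probs(p)))
        confusion[int(y), pred] += 1
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, np.diag(confusion) / row_sums, np.nan)
    avg = float(np.nanmean(per_class))
    return EvalReport(
        per_class_accuracy=per_class,
        average_accuracy=avg,
        confusion=confusion,
        n_clips=len(preds),
    )


def select_weight(
    outline_preds: Sequence[Union[ScoreVector, Sequence[float]]],
    skeleton_preds: Sequence[Union[ScoreVector, Sequence[float]]],
    labels: Sequence[int],
    grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
) -> FusionWeight:
    """Grid-search the fusion weight maximizing validation average
    per-class accuracy; ties break toward 0.5."""
    if len(grid) == 0:
        raise ValueError("empty weight grid")
    if not (len(outline_preds) == len(skeleton_preds) == len(labels)) or len(labels) == 0:
        raise ValueError("validation predictions/labels must be non-empty and aligned")
    best: Optional[FusionWeight] = None
    best_key: Optional[Tuple[float, float]] = None
    for g in grid:
        w = FusionWeight(float(g))
        fused = [fuse_scores(p, s, w) for p, s in zip(outline_preds, skeleton_preds)]
        acc = evaluate(fused, labels).average_accuracy
        key = (acc, -abs(w.weight - 0.5))
        if best_key is None or key > best_key:
            best_key = key
            best = w
    assert best is not None
    return best
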