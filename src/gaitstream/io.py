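"""Readers and writers for the keypoint, mask, and report formats.

Keypoint CSV dialect: one row per frame with columns
``clip_id, frame_idx, x0, y0, v0, ..., x17, y17, v17``.
The JSON mirror stores the same fields per clip; the HDF5 container
stores one group per clip with datasets ``coords`` (T, 18, 2),
``visible`` (T, 18) and optionally ``masks`` (T, H, W), plus attrs
``label``, ``fps``, ``seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .core import (
    N_LANDMARKS,
    ActionLabel,
    AngleSeries,
    PoseSequence,
    SchemaError,
    SkeletonSchema,
)
from .synthetic import ClipBundle

__all__ = [
    "ParseError",
    "read_keypoints",
    "write_keypoints_csv",
    "write_keypoints_json",
    "write_bundles_hdf5",
    "read_bundles_hdf5",
    "write_angle_series_csv",
    "write_mask_png",
    "read_mask_png",
    "RunConfig",
]

logger = logging.getLogger(__name__)

_COORD_COLS = [f"{a}{i}" for i in range(N_LANDMARKS) for a in ("x", "y", "v")]
_CSV_COLS = ["clip_id", "frame_idx", *_COORD_COLS]


class ParseError(ValueError):
    """Malformed keypoint file; message carries the offending line."""


def write_keypoints_csv(path: Union[str, Path], sequences: Sequence[PoseSequence]) -> None:
    rows = []
    for seq in sequences:
        for t in range(seq.n_frames):
            row: Dict[str, object] = {"clip_id": seq.clip_id, "frame_idx": t}
            for i in range(N_LANDMARKS):
                row[f"x{i}"] = seq.coords[t, i, 0]
                row[f"y{i}"] = seq.coords[t, i, 1]
                row[f"v{i}"] = int(seq.visible[t, i])
            rows.append(row)
    # %.17g guarantees bit-exact float round trips through the text format
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False, float_format="%.17g")


def _sequences_from_table(df: pd.DataFrame, fps: float,
                          labels: Optional[Dict[str, str]] = None) -> List[PoseSequence]:
    missing = [c for c in _CSV_COLS if c not in df.columns]
    extra_coords = [c for c in df.columns if c.startswith(("x", "y", "v"))
                    and c not in _COORD_COLS and c[1:].isdigit()]
    if missing or extra_coords:
        raise SchemaError(
            f"keypoint table must have exactly {N_LANDMARKS} landmark column triples; "
            f"missing={missing[:6]} unexpected={extra_coords[:6]}"
        )
    out = []
    for clip_id, g in df.groupby("clip_id", sort=False):
        g = g.sort_values("frame_idx")
        n = len(g)
        coords = np.empty((n, N_LANDMARKS, 2))
        visible = np.empty((n, N_LANDMARKS), dtype=bool)
        for i in range(N_LANDMARKS):
            coords[:, i, 0] = g[f"x{i}"].to_numpy(dtype=float)
            coords[:, i, 1] = g[f"y{i}"].to_numpy(dtype=float)
            visible[:, i] = g[f"v{i}"].to_numpy(dtype=float) > 0.5
        label = None
        if labels and str(clip_id) in labels:
            label = ActionLabel.from_name(labels[str(clip_id)])
        out.append(
            PoseSequence(clip_id=str(clip_id), coords=coords, visible=visible,
                         fps=fps, label=label)
        )
    return out


def _read_keypoints_csv(path: Path, fps: float) -> List[PoseSequence]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    bad = df[df["frame_idx"].isna()] if "frame_idx" in df.columns else df
    if "frame_idx" in df.columns and len(bad):
        lines = (bad.index + 2).tolist()[:10]  # +2: header and 1-based
        raise ParseError(f"{path}: malformed rows at lines {lines}")
    return _sequences_from_table(df, fps)


def write_keypoints_json(path: Union[str, Path], sequences: Sequence[PoseSequence]) -> None:
    payload = []
    for seq in sequences:
        payload.append(
            {
                "clip_id": seq.clip_id,
                "fps": seq.fps,
                "label": seq.label.name.lower() if seq.label is not None else None,
                "coords": np.where(np.isfinite(seq.coords), seq.coords, None).tolist(),
                "visible": seq.visible.astype(int).tolist(),
            }
        )
    Path(path).write_text(json.dumps(payload))


def _read_keypoints_json(path: Path, fps: float) -> List[PoseSequence]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    out = []
    for entry in payload:
        coords = np.array(
            [[[np.nan if v is None else float(v) for v in pt] for pt in frame]
             for frame in entry["coords"]]
        )
        if coords.ndim != 3 or coords.shape[1:] != (N_LANDMARKS, 2):
            raise SchemaError(
                f"{path}: clip {entry.get('clip_id')!r} has landmark shape "
                f"{coords.shape[1:]}, expected ({N_LANDMARKS}, 2)"
            )
        label = entry.get("label")
        out.append(
            PoseSequence(
                clip_id=str(entry["clip_id"]),
                coords=coords,
                visible=np.asarray(entry["visible"], dtype=bool),
                fps=float(entry.get("fps", fps)),
                label=ActionLabel.from_name(label) if label else None,
            )
        )
    return out


def read_keypoints(path: Union[str, Path], fps: float = 30.0) -> List[PoseSequence]:
    """Read pose sequences from CSV, JSON, or HDF5 (by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_keypoints_csv(path, fps)
    if suffix == ".json":
        return _read_keypoints_json(path, fps)
    if suffix in (".h5", ".hdf5"):
        return [b.pose for b in read_bundles_hdf5(path)]
    raise ParseError(f"unsupported keypoint format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# HDF5 clip bundles
# ---------------------------------------------------------------------------

def write_bundles_hdf5(path: Union[str, Path], bundles: Sequence[ClipBundle]) -> None:
    with h5py.File(path, "w") as fh:
        for b in bundles:
            g = fh.create_group(b.pose.clip_id)
            g.create_dataset("coords", data=b.pose.coords)
            g.create_dataset("visible", data=b.pose.visible)
            if b.masks is not None:
                g.create_dataset("masks", data=b.masks.astype(np.uint8))
            g.attrs["label"] = int(b.label)
            g.attrs["fps"] = b.pose.fps
            g.attrs["seed"] = b.seed


def read_bundles_hdf5(path: Union[str, Path]) -> List[ClipBundle]:
    out = []
    with h5py.File(path, "r") as fh:
        for clip_id in fh:
            g = fh[clip_id]
            label = ActionLabel(int(g.attrs["label"]))
            pose = PoseSequence(
                clip_id=clip_id,
                coords=g["coords"][()],
                visible=g["visible"][()].astype(bool),
                fps=float(g.attrs["fps"]),
                label=label,
            )
            masks = g["masks"][()] if "masks" in g else None
            out.append(
                ClipBundle(pose=pose, masks=masks, label=label,
                           seed=int(g.attrs["seed"]))
            )
    return out


def write_angle_series_csv(path: Union[str, Path], series: Sequence[AngleSeries]) -> None:
    rows = []
    for s in series:
        for t in range(len(s)):
            rows.append(
                {
                    "clip_id": s.clip_id,
                    "frame_idx": t,
                    "front_deg": s.front[t],
                    "hind_deg": s.hind[t],
                    "valid": int(s.valid[t]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mask_png(path: Union[str, Path], mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def read_mask_png(path: Union[str, Path]) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration; written next to every
    output artifact for reproducibility."""

    data_dir: str = "data"
    output_dir: str = "out"
    seed: int = 0
    n_per_class: int = 20
    split: float = 0.5
    jitter_sd: float = 1.0
    invalid_prob: float = 0.02
    fps: float = 30.0
    frame_range: Tuple[int, int] = (60, 240)
    canvas: Tuple[int, int] = (128, 128)
    # outline stream (desk-scale: a few epochs at a conservative lr are
    # enough on synthetic outlines, and keep single-CPU runtime sane)
    vgg_epochs: int = 3
    vgg_lr: float = 0.001
    vgg_batch_size: int = 32
    frames_per_clip: int = 3
    fill_silhouette: bool = False
    # skeleton stream (denser training stride than the inference default:
    # more windows per clip stabilizes the small-sample LSTM fit)
    lstm_epochs: int = 150
    lstm_lr: float = 0.002
    lstm_hidden: int = 32
    lstm_window: int = 90
    lstm_stride: int = 15
    # fusion
    weight_grid: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("frame_range", "canvas", "weight_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
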