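"""Spatial stream: outline extraction from binary masks and a small
VGG-style CNN classifier over 112x112 contour rasters.

The classifier is a three-block 3x3 conv stack (64/128/256 channels,
each block followed by a 2x2 stride-2 max pool) with two fully-connected
layers and a softmax head, trained with Adam on cross-entropy.  It is
implemented on the in-package numpy backend because no deep-learning
framework is available in the target environment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from skimage.draw import line as draw_line
from skimage.transform import resize

from . import _nn
from .core import ActionLabel, ScoreVector

__all__ = [
    "OUTLINE_SIZE",
    "OutlineImage",
    "TinyVGGConfig",
    "TinyVGG",
    "EmptyMaskError",
    "extract_outline",
    "rasterize_outline",
    "outline_image_from_mask",
    "softmax",
    "fit_tiny_vgg",
    "predict_outline_clip",
    "vgg16_param_count",
]

logger = logging.getLogger(__name__)

OUTLINE_SIZE = 112


class EmptyMaskError(ValueError):
    """Mask contains no foreground pixels."""


@dataclass
class OutlineImage:
    """112x112 single-channel raster of an object contour, values in [0,1]."""

    raster: np.ndarray
    clip_id: str = ""
    frame_idx: int = 0

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.float32)
        if self.raster.shape != (OUTLINE_SIZE, OUTLINE_SIZE):
            raise ValueError(
                f"raster must be {OUTLINE_SIZE}x{OUTLINE_SIZE}, got {self.raster.shape}"
            )
        if self.raster.min() < 0 or self.raster.max() > 1:
            raise ValueError("raster values must lie in [0, 1]")


def extract_outline(mask: np.ndarray) -> np.ndarray:
    """Boundary polygon of the largest connected foreground component.

    Marching squares (sub-pixel, level 0.5) on the padded component
    mask; returns an (N, 2) array of (row, col) vertices forming a
    closed, non-self-intersecting polygon for simply-connected masks.
    """
    mask = np.asarray(mask)
    binary = mask > 0
    if not binary.any():
        raise EmptyMaskError("mask has no foreground pixels")
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    component = labels == counts.argmax()
    padded = np.pad(component.astype(float), 1)
    contours = measure.find_contours(padded, level=0.5)
    # keep the contour enclosing the largest area (outer boundary)
    def shoelace(poly: np.ndarray) -> float:
        r, c = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, 1)) - np.dot(c, np.roll(r, 1)))

    contour = max(contours, key=shoelace)
    return contour - 1.0  # undo padding offset


def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (N, 2) vertices."""
    r, c = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, 1)) - np.dot(c, np.roll(r, 1)))


def rasterize_outline(
    polygon: np.ndarray, canvas: Tuple[int, int]
) -> OutlineImage:
    """Draw the contour as a 1-px stroke, resize to 112x112, renormalize.

    ``canvas`` is the (h, w) of the source mask the polygon came from, so
    the outline keeps its position and scale relative to that frame.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.size == 0:
        raise ValueError("empty polygon")
    h, w = canvas
    img = np.zeros((h, w), dtype=np.float32)
    pts = np.clip(np.rint(polygon), 0, [h - 1, w - 1]).astype(int)
    for k in range(len(pts)):
        r0, c0 = pts[k]
        r1, c1 = pts[(k + 1) % len(pts)]
        rr, cc = draw_line(r0, c0, r1, c1)
        img[rr, cc] = 1.0
    out = resize(
        img, (OUTLINE_SIZE, OUTLINE_SIZE), order=1, anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)
    peak = out.max()
    if peak > 0:
        out /= peak
    return OutlineImage(raster=np.clip(out, 0.0, 1.0))


def outline_image_from_mask(
    mask: np.ndarray, clip_id: str = "", frame_idx: int = 0, fill: bool = False
) -> OutlineImage:
    """Convenience: mask -> outline polygon -> 112x112 raster.

    With ``fill=True`` the resized filled silhouette is used instead of
    the 1-px contour stroke.
    """
    if fill:
        binary = (np.asarray(mask) > 0).astype(np.float32)
        if not binary.any():
            raise EmptyMaskError("mask has no foreground pixels")
        out = resize(
            binary, (OUTLINE_SIZE, OUTLINE_SIZE), order=1, anti_aliasing=False,
            preserve_range=True,
        ).astype(np.float32)
        peak = out.max()
        if peak > 0:
            out /= peak
        img = OutlineImage(raster=np.clip(out, 0.0, 1.0))
    else:
        poly = extract_outline(mask)
        img = rasterize_outline(poly, canvas=np.asarray(mask).shape)
    img.clip_id = clip_id
    img.frame_idx = frame_idx
    return img


def softmax(logits: Sequence[float]) -> ScoreVector:
    """Class probabilities exp(z_n) / sum_k exp(z_k), max-subtracted."""
    logits = np.asarray(logits, dtype=float)
    if logits.shape != (len(ActionLabel),):
        raise ValueError(f"expected {len(ActionLabel)} logits, got {logits.shape}")
    return ScoreVector(_nn.stable_softmax(logits))


@dataclass(frozen=True)
class TinyVGGConfig:
    """Three 3x3 conv blocks (stride 1) each followed by a 2x2 stride-2
    max pool, then two fully-connected layers."""

    conv_channels: Tuple[int, int, int] = (64, 128, 256)
    fc_hidden: int = 256
    n_classes: int = 3
    in_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("Tiny VGG has exactly three conv blocks")
        if min(self.conv_channels) < 1 or self.fc_hidden < 1 or self.n_classes < 2:
            raise ValueError("invalid layer sizes")

    def feature_map_shapes(
        self, input_hw: Tuple[int, int] = (OUTLINE_SIZE, OUTLINE_SIZE)
    ) -> List[Tuple[int, int, int]]:
        """(h, w, channels) after each conv+pool block."""
        h, w = input_hw
        shapes = []
        for c in self.conv_channels:
            h, w = h // 2, w // 2
            shapes.append((h, w, c))
        return shapes

    def param_count(self, input_hw: Tuple[int, int] = (OUTLINE_SIZE, OUTLINE_SIZE)) -> int:
        n = 0
        cin = self.in_channels
        for c in self.conv_channels:
            n += 3 * 3 * cin * c + c
            cin = c
        fh, fw, fc = self.feature_map_shapes(input_hw)[-1]
        n += fh * fw * fc * self.fc_hidden + self.fc_hidden
        n += self.fc_hidden * self.n_classes + self.n_classes
        return n


def vgg16_param_count(
    input_hw: Tuple[int, int] = (OUTLINE_SIZE, OUTLINE_SIZE),
    in_channels: int = 1,
    n_classes: int = 3,
) -> int:
    """Parameter count of a standard VGG16 (13 conv + 3 FC, 4096-wide
    hidden FCs) at the given input size, for the lightweight-model
    comparison."""
    cfg = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
           512, 512, 512, "M", 512, 512, 512, "M"]
    n = 0
    cin = in_channels
    h, w = input_hw
    for v in cfg:
        if v == "M":
            h, w = h // 2, w // 2
        else:
            n += 3 * 3 * cin * v + v
            cin = v
    n += h * w * cin * 4096 + 4096
    n += 4096 * 4096 + 4096
    n += 4096 * n_classes + n_classes
    return n


class TinyVGG:
    """Numpy implementation of the three-block tiny VGG classifier."""

    def __init__(self, config: Optional[TinyVGGConfig] = None, seed: int = 0,
                 input_hw: Tuple[int, int] = (OUTLINE_SIZE, OUTLINE_SIZE)):
        self.config = config or TinyVGGConfig()
        self.input_hw = input_hw
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = self.config
        self.params: Dict[str, np.ndarray] = {}
        cin = c.in_channels
        for b, cout in enumerate(c.conv_channels):
            self.params[f"w{b}"] = _nn.he_init(rng, (3, 3, cin, cout), 9 * cin)
            self.params[f"b{b}"] = np.zeros(cout, dtype=_nn.F32)
            cin = cout
        fh, fw, fc = c.feature_map_shapes(input_hw)[-1]
        flat = fh * fw * fc
        self.params["wf1"] = _nn.he_init(rng, (flat, c.fc_hidden), flat)
        self.params["bf1"] = np.zeros(c.fc_hidden, dtype=_nn.F32)
        self.params["wf2"] = _nn.he_init(rng, (c.fc_hidden, c.n_classes), c.fc_hidden)
        self.params["bf2"] = np.zeros(c.n_classes, dtype=_nn.F32)
        self.train_log: List[Dict[str, float]] = []

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, keep: bool = False):
        """x: (B, H, W) float32 in [0,1].  Returns logits (B, K)."""
        a = x[..., None].astype(_nn.F32)
        cache = []
        for b in range(3):
            y, xp = _nn.conv3x3_forward(a, self.params[f"w{b}"], self.params[f"b{b}"])
            pre = y
            _nn.relu(y)
            pooled, mask = _nn.maxpool2_forward(y)
            cache.append((xp, pre, mask))
            a = pooled
        B = a.shape[0]
        flat = a.reshape(B, -1)
        h1 = flat @ self.params["wf1"] + self.params["bf1"]
        h1r = np.maximum(h1, 0)
        logits = h1r @ self.params["wf2"] + self.params["bf2"]
        if keep:
            return logits, (cache, a.shape, flat, h1r)
        return logits

    def _backward(self, dlogits: np.ndarray, ctx) -> Dict[str, np.ndarray]:
        cache, pooled_shape, flat, h1r = ctx
        grads: Dict[str, np.ndarray] = {}
        grads["wf2"] = h1r.T @ dlogits
        grads["bf2"] = dlogits.sum(axis=0)
        dh1 = (dlogits @ self.params["wf2"].T) * (h1r > 0)
        grads["wf1"] = flat.T @ dh1
        grads["bf1"] = dh1.sum(axis=0)
        da = (dh1 @ self.params["wf1"].T).reshape(pooled_shape)
        for b in range(2, -1, -1):
            xp, pre, mask = cache[b]
            dy = _nn.maxpool2_backward(da, mask)
            dy *= pre > 0
            da, dw, db = _nn.conv3x3_backward(dy, xp, self.params[f"w{b}"])
            grads[f"w{b}"] = dw
            grads[f"b{b}"] = db
        return grads

    # -- public API ---------------------------------------------------------

    def predict_proba(self, images: Sequence[np.ndarray], batch_size: int = 32
                      ) -> np.ndarray:
        """Per-image class probabilities, shape (N, n_classes)."""
        x = _stack_rasters(images)
        out = []
        for s in range(0, len(x), batch_size):
            logits = self._forward(x[s:s + batch_size])
            out.append(_nn.stable_softmax(logits))
        return np.concatenate(out, axis=0)

    def predict_scores(self, images: Sequence[np.ndarray]) -> List[ScoreVector]:
        return [ScoreVector(p) for p in self.predict_proba(images)]

    def fit(
        self,
        images: Sequence[np.ndarray],
        labels: Sequence[int],
        epochs: int = 30,
        lr: float = 0.01,
        batch_size: int = 32,
        seed: int = 0,
    ) -> "TinyVGG":
        x = _stack_rasters(images)
        y = np.asarray([int(l) for l in labels])
        present = set(y.tolist())
        if len(present) < self.config.n_classes:
            raise ValueError(
                f"training data covers classes {sorted(present)}; "
                f"need all {self.config.n_classes}"
            )
        rng = np.random.default_rng(seed)
        opt = _nn.Adam(self.params, lr=lr)
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for s in range(0, n, batch_size):
                idx = order[s:s + batch_size]
                xb, yb = x[idx], y[idx]
                logits, ctx = self._forward(xb, keep=True)
                probs = _nn.stable_softmax(logits)
                losses.append(_nn.cross_entropy(probs, yb))
                correct += int((probs.argmax(axis=1) == yb).sum())
                dlogits = (probs - np.eye(self.config.n_classes)[yb]) / len(yb)
                grads = self._backward(dlogits.astype(_nn.F32), ctx)
                opt.step(grads)
            self.train_log.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "acc": correct / n}
            )
            logger.info(
                "tinyvgg epoch %d loss %.4f acc %.3f",
                epoch, self.train_log[-1]["loss"], self.train_log[-1]["acc"],
            )
        return self

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        """Weights to .npz with a JSON sidecar holding config and seed."""
        np.savez(path, **self.params)
        sidecar = {
            "config": {
                "conv_channels": list(self.config.conv_channels),
                "fc_hidden": self.config.fc_hidden,
                "n_classes": self.config.n_classes,
                "in_channels": self.config.in_channels,
            },
            "seed": self.seed,
            "input_hw": list(self.input_hw),
            "train_log": self.train_log,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "TinyVGG":
        with open(str(path) + ".json") as fh:
            sc = json.load(fh)
        cfg = TinyVGGConfig(
            conv_channels=tuple(sc["config"]["conv_channels"]),
            fc_hidden=sc["config"]["fc_hidden"],
            n_classes=sc["config"]["n_classes"],
            in_channels=sc["config"]["in_channels"],
        )
        model = cls(cfg, seed=sc["seed"], input_hw=tuple(sc["input_hw"]))
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for k in model.params:
            model.params[k] = data[k].astype(_nn.F32)
        model.train_log = sc.get("train_log", [])
        return model

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _stack_rasters(images: Sequence) -> np.ndarray:
    arrs = [im.raster if isinstance(im, OutlineImage) else np.asarray(im) for im in images]
    return np.stack(arrs).astype(_nn.F32)


def fit_tiny_vgg(
    images: Sequence[OutlineImage],
    labels: Sequence[int],
    config: Optional[TinyVGGConfig] = None,
    epochs: int = 30,
    lr: float = 0.01,
    batch_size: int = 32,
    seed: int = 0,
) -> TinyVGG:
    """Train the tiny VGG on outline rasters.  Non-convergence is not an
    error; the per-epoch loss/accuracy log lives on ``model.train_log``."""
    model = TinyVGG(config, seed=seed)
    return model.fit(images, labels, epochs=epochs, lr=lr,
                     batch_size=batch_size, seed=seed)


def predict_outline_clip(model: TinyVGG, frames: Sequence[OutlineImage]) -> ScoreVector:
    """Clip-level score: arithmetic mean of per-frame probabilities."""
    if len(frames) == 0:
        raise ValueError("cannot score an empty clip")
    probs = model.predict_proba(frames)
    mean = probs.mean(axis=0)
    return ScoreVector(mean / mean.sum())
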