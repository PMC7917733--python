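"""Temporal stream: windowed knee-angle sequences classified by an LSTM,
plus k-means key-frame selection for the labeling workflow."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize
from sklearn.cluster import KMeans

from . import _nn
from .core import ActionLabel, AngleSeries, ScoreVector

__all__ = [
    "SequenceSample",
    "LSTMConfig",
    "LSTMClassifier",
    "TooShortClipError",
    "prepare_sequences",
    "fit_lstm",
    "predict_skeleton_clip",
    "select_keyframes",
]

logger = logging.getLogger(__name__)


class TooShortClipError(ValueError):
    """Clip has fewer than 2 frames of angle data."""


@dataclass
class SequenceSample:
    """One LSTM input window: T x 2 normalized (front, hind) angles.

    ``length`` is the number of real (unpadded) timesteps; features
    beyond it are zero padding.
    """

    features: np.ndarray  # (T, 2) in [0, 1]
    length: int
    label: Optional[ActionLabel] = None
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[1] != 2:
            raise ValueError(f"features must be (T, 2), got {self.features.shape}")
        if self.length < 2:
            raise TooShortClipError("a sequence sample needs length >= 2")
        real = self.features[: self.length]
        if real.min() < 0 or real.max() > 1:
            raise ValueError("normalized features must lie in [0, 1]")


@dataclass(frozen=True)
class LSTMConfig:
    hidden_size: int = 32
    n_layers: int = 1
    window: int = 90
    stride: int = 45
    n_classes: int = 3
    use_first_difference: bool = False

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 1 <= self.stride <= self.window:
            raise ValueError("stride must lie in [1, window]")
        if self.n_layers != 1:
            raise ValueError("only single-layer LSTMs are supported")


def prepare_sequences(
    series: AngleSeries, config: Optional[LSTMConfig] = None
) -> List[SequenceSample]:
    """Normalize angles by 180 and slice into overlapping windows.

    A clip shorter than one window yields a single zero-padded sample
    with its true length recorded.
    """
    config = config or LSTMConfig()
    n = len(series)
    if n < 2:
        raise TooShortClipError(f"clip {series.clip_id!r} has {n} frames")
    feats = np.stack([series.front, series.hind], axis=1) / 180.0
    w, s = config.window, config.stride
    samples: List[SequenceSample] = []
    if n < w:
        padded = np.zeros((w, 2), dtype=np.float32)
        padded[:n] = feats
        samples.append(SequenceSample(padded, length=n, clip_id=series.clip_id))
    else:
        for start in range(0, n - w + 1, s):
            samples.append(
                SequenceSample(feats[start:start + w], length=w, clip_id=series.clip_id)
            )
    return samples


class LSTMClassifier:
    """Single-layer LSTM -> linear -> softmax over gait classes."""

    def __init__(self, config: Optional[LSTMConfig] = None, seed: int = 0):
        self.config = config or LSTMConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        d_in = 4 if self.config.use_first_difference else 2
        self.lstm = _nn.LSTMParams.init(rng, d_in, self.config.hidden_size)
        s = 1.0 / np.sqrt(self.config.hidden_size)
        self.w_out = rng.uniform(
            -s, s, (self.config.hidden_size, self.config.n_classes)
        ).astype(_nn.F32)
        self.b_out = np.zeros(self.config.n_classes, dtype=_nn.F32)
        self.train_log: List[Dict[str, float]] = []

    def _params(self) -> Dict[str, np.ndarray]:
        return {
            "wx": self.lstm.wx, "wh": self.lstm.wh, "b": self.lstm.b,
            "w_out": self.w_out, "b_out": self.b_out,
        }

    def _inputs(self, samples: Sequence[SequenceSample]) -> Tuple[np.ndarray, np.ndarray]:
        x = np.stack([s.features for s in samples]).astype(_nn.F32)
        if self.config.use_first_difference:
            d = np.diff(x, axis=1, prepend=x[:, :1, :])
            x = np.concatenate([x, d], axis=2)
        lengths = np.array([s.length for s in samples])
        return x, lengths

    def predict_proba(self, samples: Sequence[SequenceSample]) -> np.ndarray:
        x, lengths = self._inputs(samples)
        h, _ = _nn.lstm_forward(x, self.lstm, lengths)
        return _nn.stable_softmax(h @ self.w_out + self.b_out)

    def fit(
        self,
        samples: Sequence[SequenceSample],
        labels: Sequence[int],
        epochs: int = 50,
        lr: float = 0.001,
        batch_size: int = 64,
        seed: int = 0,
    ) -> "LSTMClassifier":
        y = np.asarray([int(l) for l in labels])
        present = set(y.tolist())
        if len(present) < self.config.n_classes:
            raise ValueError(
                f"training data covers classes {sorted(present)}; "
                f"need all {self.config.n_classes}"
            )
        x, lengths = self._inputs(samples)
        rng = np.random.default_rng(seed)
        params = self._params()
        opt = _nn.Adam(params, lr=lr)
        sched = _nn.ReduceLROnPlateau(opt, factor=10.0, patience=8)
        n = len(x)
        eye = np.eye(self.config.n_classes)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for s in range(0, n, batch_size):
                idx = order[s:s + batch_size]
                xb, yb, lb = x[idx], y[idx], lengths[idx]
                h, caches = _nn.lstm_forward(xb, self.lstm, lb)
                logits = h @ self.w_out + self.b_out
                probs = _nn.stable_softmax(logits)
                losses.append(_nn.cross_entropy(probs, yb))
                correct += int((probs.argmax(axis=1) == yb).sum())
                dlogits = ((probs - eye[yb]) / len(yb)).astype(_nn.F32)
                dh = dlogits @ self.w_out.T
                _, dwx, dwh, db = _nn.lstm_backward(dh, caches, self.lstm, lb)
                grads = {
                    "wx": dwx, "wh": dwh, "b": db,
                    "w_out": h.T @ dlogits, "b_out": dlogits.sum(axis=0),
                }
                opt.step(grads, clip_norm=1.0)
            mean_loss = float(np.mean(losses))
            sched.step(mean_loss)
            self.train_log.append(
                {"epoch": epoch, "loss": mean_loss, "acc": correct / n, "lr": opt.lr}
            )
            logger.info("lstm epoch %d loss %.4f acc %.3f", epoch, mean_loss, correct / n)
        return self

    def save(self, path: str) -> None:
        np.savez(path, **self._params())
        sidecar = {
            "config": {
                "hidden_size": self.config.hidden_size,
                "n_layers": self.config.n_layers,
                "window": self.config.window,
                "stride": self.config.stride,
                "n_classes": self.config.n_classes,
                "use_first_difference": self.config.use_first_difference,
            },
            "seed": self.seed,
            "train_log": self.train_log,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "LSTMClassifier":
        with open(str(path) + ".json") as fh:
            sc = json.load(fh)
        model = cls(LSTMConfig(**sc["config"]), seed=sc["seed"])
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        model.lstm.wx = data["wx"].astype(_nn.F32)
        model.lstm.wh = data["wh"].astype(_nn.F32)
        model.lstm.b = data["b"].astype(_nn.F32)
        model.w_out = data["w_out"].astype(_nn.F32)
        model.b_out = data["b_out"].astype(_nn.F32)
        model.train_log = sc.get("train_log", [])
        return model


def fit_lstm(
    samples: Sequence[SequenceSample],
    labels: Sequence[int],
    config: Optional[LSTMConfig] = None,
    epochs: int = 50,
    lr: float = 0.001,
    batch_size: int = 64,
    seed: int = 0,
) -> LSTMClassifier:
    """Train the sequence classifier (Adam, cross-entropy, lr reduced
    tenfold on plateau)."""
    model = LSTMClassifier(config, seed=seed)
    return model.fit(samples, labels, epochs=epochs, lr=lr,
                     batch_size=batch_size, seed=seed)


def predict_skeleton_clip(
    model: LSTMClassifier, series: AngleSeries, config: Optional[LSTMConfig] = None
) -> ScoreVector:
    """Clip-level score: mean of window-level probabilities."""
    config = config or model.config
    samples = prepare_sequences(series, config)
    probs = model.predict_proba(samples)
    mean = probs.mean(axis=0)
    return ScoreVector(mean / mean.sum())


def select_keyframes(
    frames: Sequence[np.ndarray], k: int, seed: int = 0,
    downscale: Tuple[int, int] = (16, 16),
) -> List[int]:
    """Representative frame indices by k-means over downscaled rasters.

    Returns the index of the frame nearest each cluster centroid,
    sorted ascending with duplicates removed.
    """
    n = len(frames)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of frames ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    vecs = np.stack(
        [
            resize(np.asarray(f, dtype=float), downscale, order=1,
                   anti_aliasing=False, preserve_range=True).ravel()
            for f in frames
        ]
    )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(vecs)
    picks = set()
    for centroid in km.cluster_centers_:
        d = np.linalg.norm(vecs - centroid, axis=1)
        picks.add(int(d.argmin()))
    return sorted(picks)
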