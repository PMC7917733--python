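"""End-to-end glue: simulate -> train both streams -> fuse -> evaluate.

Used by the ``demo`` CLI subcommand and by the benchmark tests.  The
outline stream trains on a per-clip subsample of silhouette-outline
frames (``frames_per_clip``) to keep the CNN affordable on one CPU;
clip-level scores average the per-frame probabilities of the same
subsample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ActionLabel, AngleSeries, PoseFrame, ScoreVector, angle_series
from .fusion import EvalReport, FusionWeight, evaluate, fuse_scores, select_weight
from .io import RunConfig
from .outline import TinyVGG, TinyVGGConfig, outline_image_from_mask, predict_outline_clip
from .skeleton import (
    LSTMClassifier,
    LSTMConfig,
    predict_skeleton_clip,
    prepare_sequences,
)
from .synthetic import ClipBundle, make_dataset, render_silhouette

logger = logging.getLogger(__name__)


def clip_outline_frames(bundle: ClipBundle, frames_per_clip: int,
                        canvas: Tuple[int, int] = (128, 128),
                        fill: bool = False) -> List:
    """Evenly-spaced silhouette-outline rasters for one clip.

    Masks are rendered on demand from the pose when the bundle carries
    none; frames that fail to render (occluded leg landmark making a
    disconnected blob is fine, an empty pose is not) are skipped.
    """
    n = bundle.pose.n_frames
    idx = np.linspace(0, n - 1, frames_per_clip).round().astype(int)
    images = []
    for t in np.unique(idx):
        if bundle.masks is not None:
            mask = bundle.masks[t]
        else:
            mask = render_silhouette(
                PoseFrame(bundle.pose.coords[t], bundle.pose.visible[t]),
                limb_width=6.0, canvas=canvas,
            )
        images.append(
            outline_image_from_mask(mask, clip_id=bundle.pose.clip_id,
                                    frame_idx=int(t), fill=fill)
        )
    return images


@dataclass
class TwoStreamResult:
    """Everything the demo pipeline produces."""

    outline_model: TinyVGG
    skeleton_model: LSTMClassifier
    weight: FusionWeight
    outline_report: EvalReport
    skeleton_report: EvalReport
    fused_report: EvalReport
    config: RunConfig


def angle_series_for(bundles: Sequence[ClipBundle]) -> List[AngleSeries]:
    return [angle_series(b.pose) for b in bundles]


def train_skeleton_stream(
    train: Sequence[ClipBundle], config: RunConfig, seed: Optional[int] = None
) -> LSTMClassifier:
    lstm_cfg = LSTMConfig(hidden_size=config.lstm_hidden, window=config.lstm_window,
                          stride=config.lstm_stride)
    samples, labels = [], []
    for b in train:
        for s in prepare_sequences(angle_series(b.pose), lstm_cfg):
            samples.append(s)
            labels.append(int(b.label))
    from .skeleton import fit_lstm

    return fit_lstm(samples, labels, config=lstm_cfg, epochs=config.lstm_epochs,
                    lr=config.lstm_lr, seed=config.seed if seed is None else seed)


def train_outline_stream(
    train: Sequence[ClipBundle], config: RunConfig, seed: Optional[int] = None,
    vgg_config: Optional[TinyVGGConfig] = None,
) -> TinyVGG:
    images, labels = [], []
    for b in train:
        frames = clip_outline_frames(b, config.frames_per_clip, config.canvas,
                                     fill=config.fill_silhouette)
        images.extend(frames)
        labels.extend([int(b.label)] * len(frames))
    from .outline import fit_tiny_vgg

    return fit_tiny_vgg(images, labels, config=vgg_config, epochs=config.vgg_epochs,
                        lr=config.vgg_lr, batch_size=config.vgg_batch_size,
                        seed=config.seed if seed is None else seed)


def predict_streams(
    bundles: Sequence[ClipBundle],
    outline_model: Optional[TinyVGG],
    skeleton_model: Optional[LSTMClassifier],
    config: RunConfig,
) -> Tuple[List[ScoreVector], List[ScoreVector], List[int]]:
    """Per-clip (outline, skeleton) score pairs plus integer labels."""
    yp, ys, labels = [], [], []
    for b in bundles:
        labels.append(int(b.label))
        if outline_model is not None:
            frames = clip_outline_frames(b, config.frames_per_clip, config.canvas,
                                         fill=config.fill_silhouette)
            yp.append(predict_outline_clip(outline_model, frames))
        if skeleton_model is not None:
            ys.append(predict_skeleton_clip(skeleton_model, angle_series(b.pose)))
    return yp, ys, labels


def run_demo(config: RunConfig) -> TwoStreamResult:
    """Full synthetic pipeline from one seed: simulate, train both
    streams, pick the fusion weight on the training clips, evaluate all
    three models on the held-out clips."""
    logger.info("simulating dataset: %d clips/class, seed %d",
                config.n_per_class, config.seed)
    train, test = make_dataset(
        n_per_class=config.n_per_class, split=config.split, seed=config.seed,
        jitter_sd=config.jitter_sd, invalid_prob=config.invalid_prob,
        frame_range=config.frame_range, fps=config.fps, canvas=config.canvas,
    )
    logger.info("training skeleton stream on %d clips", len(train))
    skeleton_model = train_skeleton_stream(train, config)
    logger.info("training outline stream on %d clips", len(train))
    outline_model = train_outline_stream(train, config)

    yp_tr, ys_tr, y_tr = predict_streams(train, outline_model, skeleton_model, config)
    weight = select_weight(yp_tr, ys_tr, y_tr, grid=config.weight_grid)
    logger.info("selected fusion weight %.2f", weight.weight)

    yp_te, ys_te, y_te = predict_streams(test, outline_model, skeleton_model, config)
    fused = [fuse_scores(p, s, weight) for p, s in zip(yp_te, ys_te)]
    return TwoStreamResult(
        outline_model=outline_model,
        skeleton_model=skeleton_model,
        weight=weight,
        outline_report=evaluate(yp_te, y_te),
        skeleton_report=evaluate(ys_te, y_te),
        fused_report=evaluate(fused, y_te),
        config=config,
    )
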