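"""Kinematic synthetic-gait simulator.

Generates labeled stick-figure quadruped clips whose knee bending angles
follow per-class sinusoidal regimes (standing confined to roughly
140-160 degrees, galloping sweeping widely, ambling intermediate), plus
silhouette masks rendered from the skeleton.  Stands in for the
unavailable real video dataset so the full two-stream pipeline can be
trained and evaluated at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .core import (
    N_LANDMARKS,
    ActionLabel,
    PoseFrame,
    PoseSequence,
    SkeletonSchema,
)

__all__ = [
    "GaitParams",
    "ClipBundle",
    "DEFAULT_GAIT_PARAMS",
    "SCALE_PX",
    "simulate_clip",
    "render_silhouette",
    "make_dataset",
    "EmptyPoseError",
]

#: pixels per model unit (femur = tibia = 1 model unit, body = 2)
SCALE_PX = 30.0

#: model-unit segment lengths
BODY_LEN = 2.0
FEMUR_LEN = 1.0
TIBIA_LEN = 1.0

#: skeleton edges used for silhouette rendering: (i, j, half-width in model units)
_EDGES: Tuple[Tuple[int, int, float], ...] = (
    (0, 1, 0.10),   # nose - head_top
    (1, 2, 0.14),   # head - neck
    (2, 3, 0.20),   # neck - withers
    (3, 4, 0.30),   # withers - spine_mid (torso)
    (4, 5, 0.30),   # spine_mid - croup (torso)
    (5, 6, 0.12),   # croup - tail_base
    (6, 7, 0.07),   # tail
    (7, 8, 0.05),
    (9, 10, 0.10),  # front leg
    (10, 11, 0.08),
    (11, 12, 0.07),
    (13, 14, 0.11),  # hind leg
    (14, 15, 0.08),
    (15, 16, 0.07),
    (3, 9, 0.14),   # shoulder attachment
    (5, 13, 0.14),  # hip attachment
    (4, 17, 0.26),  # belly
)


class EmptyPoseError(ValueError):
    """Fewer than 2 visible landmarks: nothing to render."""


@dataclass(frozen=True)
class GaitParams:
    """Oscillator parameters for one gait class.

    The knee angle of each visible leg follows
    ``theta(t) = mean_angle + amplitude * sin(2*pi*frequency*t + phase)``
    with the front leg lagging the hind leg by ``phase_lag_front_hind``.
    """

    label: ActionLabel
    mean_angle: float
    amplitude: float  # degrees, half peak-to-peak
    frequency: float  # cycles / second
    phase_lag_front_hind: float = math.pi / 2
    jitter_sd: float = 0.0  # px
    invalid_prob: float = 0.0  # per-frame probability of one occluded leg landmark
    gallop_speed: float = 0.0  # horizontal body translation, px / frame

    def __post_init__(self) -> None:
        # 180 is allowed as the closed upper end: a fully extended leg is a
        # valid bending angle, and the galloping regime sweeps up to it
        if not (0 < self.mean_angle - self.amplitude
                and self.mean_angle + self.amplitude <= 180):
            raise ValueError("mean_angle +/- amplitude must stay inside (0, 180]")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not 0 <= self.invalid_prob <= 0.3:
            raise ValueError("invalid_prob must lie in [0, 0.3]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


#: per-class defaults matching the reported angle regimes:
#: standing 140-160 deg, galloping centred mid-range with a 100-deg sweep,
#: ambling intermediate (its exact range is a free choice).
DEFAULT_GAIT_PARAMS: Dict[ActionLabel, GaitParams] = {
    ActionLabel.STANDING: GaitParams(
        label=ActionLabel.STANDING, mean_angle=150.0, amplitude=10.0, frequency=0.4
    ),
    ActionLabel.AMBLING: GaitParams(
        label=ActionLabel.AMBLING, mean_angle=140.0, amplitude=40.0, frequency=1.0
    ),
    ActionLabel.GALLOPING: GaitParams(
        label=ActionLabel.GALLOPING, mean_angle=130.0, amplitude=50.0, frequency=2.0,
        gallop_speed=4.0
    ),
}


def default_params(
    label: ActionLabel, jitter_sd: float = 0.0, invalid_prob: float = 0.0, **overrides
) -> GaitParams:
    """Default params for a class with noise knobs applied."""
    return replace(
        DEFAULT_GAIT_PARAMS[ActionLabel(label)],
        jitter_sd=jitter_sd,
        invalid_prob=invalid_prob,
        **overrides,
    )


@dataclass
class ClipBundle:
    """One simulated clip: pose sequence, optional per-frame masks, label."""

    pose: PoseSequence
    masks: Optional[np.ndarray]  # (T, H, W) uint8 in {0, 1}, or None
    label: ActionLabel
    seed: int

    def __post_init__(self) -> None:
        if self.masks is not None and len(self.masks) != self.pose.n_frames:
            raise ValueError("mask count must equal pose frame count")


def _leg_landmarks(hip: np.ndarray, theta_deg: float, femur_dir_deg: float
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward kinematics for one leg in pixel coordinates (y down).

    ``femur_dir_deg`` is the femur direction measured from straight-down,
    positive towards the animal's front (negative x here).  The tibia is
    placed so the interior knee angle equals ``theta_deg`` exactly, with
    the knee flexing backwards (ankle behind the femur line).
    """
    a = math.radians(femur_dir_deg)
    femur_u = np.array([-math.sin(a), math.cos(a)])  # y grows downward
    knee = hip + FEMUR_LEN * SCALE_PX * femur_u
    # rotate the knee->hip direction by -theta so the interior angle is theta
    phi = math.radians(180.0 - theta_deg)
    cos_p, sin_p = math.cos(phi), math.sin(phi)
    # rotate femur_u by phi (clockwise in screen coords = backwards flexion)
    tibia_u = np.array(
        [cos_p * femur_u[0] - sin_p * femur_u[1],
         sin_p * femur_u[0] + cos_p * femur_u[1]]
    )
    ankle = knee + TIBIA_LEN * SCALE_PX * tibia_u
    paw = ankle + 0.25 * SCALE_PX * tibia_u
    return knee, ankle, paw


def _pose_at(
    t: float,
    params: GaitParams,
    origin: np.ndarray,
    perpendicular_view: bool,
) -> np.ndarray:
    """Landmark coordinates (18, 2) of the stick model at time t seconds."""
    s = SCALE_PX
    w = 2.0 * math.pi * params.frequency
    coords = np.zeros((N_LANDMARKS, 2))
    # torso along +x, hind end at origin
    croup = origin + np.array([0.0, 0.0])
    withers = origin + np.array([BODY_LEN * s, 0.0])
    spine_mid = 0.5 * (croup + withers)
    neck = withers + np.array([0.35 * s, -0.35 * s])
    head_top = neck + np.array([0.30 * s, -0.25 * s])
    nose = head_top + np.array([0.35 * s, 0.15 * s])
    tail_base = croup + np.array([-0.20 * s, -0.10 * s])
    tail_mid = tail_base + np.array([-0.45 * s, -0.10 * s])
    tail_tip = tail_mid + np.array([-0.45 * s, 0.05 * s])
    belly = spine_mid + np.array([0.0, 0.45 * s])

    theta_hind = params.mean_angle + params.amplitude * math.sin(w * t)
    theta_front = params.mean_angle + params.amplitude * math.sin(
        w * t + params.phase_lag_front_hind
    )
    if perpendicular_view:
        # spine pointing into the screen: every leg projects to a straight line
        theta_hind = theta_front = 180.0
    # legs swing about the vertical in proportion to gait amplitude
    swing = 12.0 * (params.amplitude / 50.0)
    dir_hind = swing * math.sin(w * t)
    dir_front = -swing * math.sin(w * t + params.phase_lag_front_hind)
    hind_hip = croup + np.array([0.05 * s, 0.15 * s])
    front_hip = withers + np.array([-0.05 * s, 0.15 * s])
    hk, ha, hp = _leg_landmarks(hind_hip, theta_hind, dir_hind)
    fk, fa, fp = _leg_landmarks(front_hip, theta_front, dir_front)

    coords[0] = nose
    coords[1] = head_top
    coords[2] = neck
    coords[3] = withers
    coords[4] = spine_mid
    coords[5] = croup
    coords[6] = tail_base
    coords[7] = tail_mid
    coords[8] = tail_tip
    coords[9] = front_hip
    coords[10] = fk
    coords[11] = fa
    coords[12] = fp
    coords[13] = hind_hip
    coords[14] = hk
    coords[15] = ha
    coords[16] = hp
    coords[17] = belly
    return coords


#: leg landmark indices eligible for random occlusion
_LEG_LANDMARKS = (9, 10, 11, 12, 13, 14, 15, 16)


def simulate_clip(
    params: GaitParams,
    n_frames: int = 120,
    fps: float = 30.0,
    seed: int = 0,
    clip_id: Optional[str] = None,
    render_masks: bool = True,
    canvas: Tuple[int, int] = (128, 128),
    perpendicular_view: bool = False,
) -> ClipBundle:
    """Simulate one labeled clip; deterministic given all arguments.

    The knee angles follow the programmed sinusoid exactly when
    ``jitter_sd == 0``; Gaussian pixel jitter is added to every landmark
    otherwise, and with probability ``invalid_prob`` one random leg
    landmark per frame is marked non-visible.  Galloping clips translate
    horizontally at ``gallop_speed`` px/frame.  With
    ``perpendicular_view=True`` the legs project to straight lines (the
    degenerate camera geometry), regardless of gait.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    if clip_id is None:
        clip_id = f"{params.label.name.lower()}-{seed}"
    coords = np.empty((n_frames, N_LANDMARKS, 2))
    visible = np.ones((n_frames, N_LANDMARKS), dtype=bool)
    origin0 = np.array([0.0, 0.0])
    for t_idx in range(n_frames):
        t = t_idx / fps
        origin = origin0 + np.array([params.gallop_speed * t_idx, 0.0])
        c = _pose_at(t, params, origin, perpendicular_view)
        if params.jitter_sd > 0:
            c = c + rng.normal(0.0, params.jitter_sd, c.shape)
        if params.invalid_prob > 0 and rng.random() < params.invalid_prob:
            lm = int(rng.choice(_LEG_LANDMARKS))
            visible[t_idx, lm] = False
            c[lm] = np.nan
        coords[t_idx] = c
    pose = PoseSequence(
        clip_id=clip_id, coords=coords, visible=visible, fps=fps, label=params.label
    )
    masks = None
    if render_masks:
        masks = np.stack(
            [
                render_silhouette(
                    PoseFrame(coords[t], visible[t]), limb_width=6.0, canvas=canvas
                )
                for t in range(n_frames)
            ]
        )
    return ClipBundle(pose=pose, masks=masks, label=params.label, seed=seed)


def render_silhouette(
    pose: PoseFrame,
    limb_width: float = 3.0,
    canvas: Tuple[int, int] = (128, 128),
) -> np.ndarray:
    """Rasterize the stick skeleton as filled capsules into a binary mask.

    Visible landmarks are autoscaled (aspect preserved) to fit the
    canvas with a margin; each skeleton edge becomes a thick bar plus
    end disks, so a fully visible pose yields one connected foreground
    component.  ``limb_width`` scales the edge half-widths.
    """
    h, w = canvas
    vis_idx = np.flatnonzero(pose.visible)
    if len(vis_idx) < 2:
        raise EmptyPoseError("need at least 2 visible landmarks to render")
    pts = pose.coords[vis_idx]
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    margin = 0.12
    scale = min((w - 1) * (1 - 2 * margin) / span[0], (h - 1) * (1 - 2 * margin) / span[1])
    offset = np.array([w, h]) * margin

    def to_canvas(p: np.ndarray) -> np.ndarray:
        q = (p - lo) * scale + offset
        return q  # (x, y) in canvas pixels

    mask = np.zeros((h, w), dtype=np.uint8)
    # limb_width is the full stroke width (canvas px) of a leg segment
    # (relative half-width 0.10); thicker edges scale proportionally.
    for i, j, half_w in _EDGES:
        if not (pose.visible[i] and pose.visible[j]):
            continue
        p0 = to_canvas(pose.coords[i])
        p1 = to_canvas(pose.coords[j])
        r_px = (half_w / 0.10) * (limb_width / 2.0)
        d = p1 - p0
        norm = math.hypot(*d)
        if norm > 1e-9:
            n = np.array([-d[1], d[0]]) / norm * r_px
            quad = np.array([p0 + n, p1 + n, p1 - n, p0 - n])
            rr, cc = draw_polygon(quad[:, 1], quad[:, 0], shape=mask.shape)
            mask[rr, cc] = 1
        for p in (p0, p1):
            rr, cc = draw_disk((p[1], p[0]), max(r_px, 1.0), shape=mask.shape)
            mask[rr, cc] = 1
    if mask.sum() == 0:
        raise EmptyPoseError("pose rendered to an empty mask")
    return mask


def make_dataset(
    n_per_class: int,
    split: float = 0.5,
    seed: int = 0,
    jitter_sd: float = 0.0,
    invalid_prob: float = 0.0,
    frame_range: Tuple[int, int] = (60, 240),
    fps: float = 30.0,
    render_masks: bool = False,
    canvas: Tuple[int, int] = (128, 128),
    params_by_class: Optional[Dict[ActionLabel, GaitParams]] = None,
) -> Tuple[List[ClipBundle], List[ClipBundle]]:
    """Balanced, disjoint train/test collections of simulated clips.

    Per-clip frame counts are drawn uniformly from ``frame_range``
    (default 2-8 s at 30 FPS).  All randomness flows from ``seed``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if not 0 < split < 1:
        raise ValueError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(n_per_class * split))
    n_train = min(max(n_train, 1), n_per_class - 1)
    train: List[ClipBundle] = []
    test: List[ClipBundle] = []
    for label in ActionLabel:
        if params_by_class is not None and label in params_by_class:
            p = replace(
                params_by_class[label], jitter_sd=jitter_sd, invalid_prob=invalid_prob
            )
        else:
            p = default_params(label, jitter_sd=jitter_sd, invalid_prob=invalid_prob)
        for k in range(n_per_class):
            n_frames = int(rng.integers(frame_range[0], frame_range[1] + 1))
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip = simulate_clip(
                p,
                n_frames=n_frames,
                fps=fps,
                seed=clip_seed,
                clip_id=f"{label.name.lower()}-{k:04d}",
                render_masks=render_masks,
                canvas=canvas,
            )
            (train if k < n_train else test).append(clip)
    return train, test
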