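"""Shared domain types and the knee bending-angle geometry.

Coordinates are image-pixel coordinates (origin top-left, y increases
downward).  The bending angle is the interior angle at the knee between
the femur (hip-knee) and tibia (knee-ankle) segments, computed by the
law of cosines; it is invariant to the axis convention so no flip is
applied anywhere.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ActionLabel",
    "SkeletonSchema",
    "PoseFrame",
    "PoseSequence",
    "AngleSeries",
    "ScoreVector",
    "DegenerateGeometryError",
    "InvalidClipError",
    "SchemaError",
    "N_LANDMARKS",
    "SEGMENT_EPS",
    "MAX_INVALID_FRACTION",
    "bending_angle",
    "angle_series",
]

N_LANDMARKS = 18

#: minimum leg-segment length in pixels below which geometry is degenerate
SEGMENT_EPS = 1e-9

#: a clip with more than this fraction of invalid frames (either leg) is rejected
MAX_INVALID_FRACTION = 0.30


class DegenerateGeometryError(ValueError):
    """A leg segment collapsed to (near) zero length."""


class InvalidClipError(ValueError):
    """Too many invalid frames to produce a usable angle series."""


class SchemaError(ValueError):
    """Landmark layout does not match the 18-point skeleton schema."""


class ActionLabel(enum.IntEnum):
    """The three gait classes, with stable integer encoding."""

    STANDING = 0
    AMBLING = 1
    GALLOPING = 2

    @classmethod
    def from_name(cls, name: str) -> "ActionLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown action label {name!r}") from None


#: default ordered landmark names.  The hind-leg triple occupies 0-based
#: indices 13/14/15 (hip/knee/ankle); the front-leg triple mirrors it at
#: 9/10/11.  Both triples are configurable via SkeletonSchema.
DEFAULT_LANDMARK_NAMES: Tuple[str, ...] = (
    "nose",
    "head_top",
    "neck",
    "withers",
    "spine_mid",
    "croup",
    "tail_base",
    "tail_mid",
    "tail_tip",
    "front_hip",
    "front_knee",
    "front_ankle",
    "front_paw",
    "hind_hip",
    "hind_knee",
    "hind_ankle",
    "hind_paw",
    "belly",
)


@dataclass(frozen=True)
class SkeletonSchema:
    """Names of the 18 tracked landmarks and the two knee triples.

    Each triple is (hip_idx, knee_idx, ankle_idx), 0-based, knee in the
    middle.
    """

    landmark_names: Tuple[str, ...] = DEFAULT_LANDMARK_NAMES
    front_knee_triple: Tuple[int, int, int] = (9, 10, 11)
    hind_knee_triple: Tuple[int, int, int] = (13, 14, 15)

    def __post_init__(self) -> None:
        if len(self.landmark_names) != N_LANDMARKS:
            raise SchemaError(
                f"expected {N_LANDMARKS} landmark names, got {len(self.landmark_names)}"
            )
        idx = (*self.front_knee_triple, *self.hind_knee_triple)
        if len(set(idx)) != 6:
            raise SchemaError("knee triples must contain 6 distinct indices")
        if not all(0 <= i < N_LANDMARKS for i in idx):
            raise SchemaError("triple index out of range [0, 18)")
        for t in (self.front_knee_triple, self.hind_knee_triple):
            if len(t) != 3:
                raise SchemaError("each knee triple must have 3 indices")

    def to_json(self) -> str:
        return json.dumps(
            {
                "landmark_names": list(self.landmark_names),
                "front_knee_triple": list(self.front_knee_triple),
                "hind_knee_triple": list(self.hind_knee_triple),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SkeletonSchema":
        d = json.loads(text)
        return cls(
            landmark_names=tuple(d["landmark_names"]),
            front_knee_triple=tuple(d["front_knee_triple"]),
            hind_knee_triple=tuple(d["hind_knee_triple"]),
        )


@dataclass
class PoseFrame:
    """One frame of 18 landmark coordinates with a visibility flag each.

    Non-visible landmarks carry NaN coordinates and must never enter
    angle computation.
    """

    coords: np.ndarray  # (18, 2) float
    visible: np.ndarray  # (18,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise SchemaError(f"coords must be (18, 2), got {self.coords.shape}")
        if self.visible.shape != (N_LANDMARKS,):
            raise SchemaError(f"visible must be (18,), got {self.visible.shape}")


@dataclass
class PoseSequence:
    """Ordered per-frame landmark sets for one clip.

    Coordinates are stored densely as (T, 18, 2); ``frames`` iterates
    PoseFrame views.
    """

    clip_id: str
    coords: np.ndarray  # (T, 18, 2)
    visible: np.ndarray  # (T, 18)
    fps: float = 30.0
    label: Optional[ActionLabel] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_LANDMARKS, 2):
            raise SchemaError(f"coords must be (T, 18, 2), got {self.coords.shape}")
        if self.visible.shape != self.coords.shape[:2]:
            raise SchemaError("visible must be (T, 18) matching coords")
        if self.n_frames < 2:
            raise ValueError("a pose sequence needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.label is not None:
            self.label = ActionLabel(self.label)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frames(self) -> Iterator[PoseFrame]:
        for t in range(self.n_frames):
            yield PoseFrame(self.coords[t], self.visible[t])


@dataclass
class AngleSeries:
    """Per-frame (front, hind) knee bending angles in degrees.

    ``valid[t]`` is False where either leg's angle was interpolated or
    extrapolated rather than measured.
    """

    front: np.ndarray
    hind: np.ndarray
    valid: np.ndarray
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.front = np.asarray(self.front, dtype=float)
        self.hind = np.asarray(self.hind, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.front)
        if not (len(self.hind) == len(self.valid) == n):
            raise ValueError("front/hind/valid must have equal length")
        for arr in (self.front, self.hind):
            v = arr[self.valid]
            if v.size and (np.any(v <= 0) or np.any(v > 180)):
                raise ValueError("valid angles must lie in (0, 180]")

    def __len__(self) -> int:
        return len(self.front)


@dataclass
class ScoreVector:
    """Per-class probabilities over the three actions; sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(ActionLabel),):
            raise ValueError(f"probs must have shape (3,), got {self.probs.shape}")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(self.probs.sum()) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {self.probs.sum()}")

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.probs, dtype=dtype)

    def argmax(self) -> ActionLabel:
        # ties resolve to the lowest class index (np.argmax convention)
        return ActionLabel(int(np.argmax(self.probs)))

    def __getitem__(self, label) -> float:
        return float(self.probs[int(label)])


def bending_angle(hip, knee, ankle) -> float:
    """Interior knee angle in degrees by the law of cosines.

    With L12 = |hip-knee|, L23 = |knee-ankle| and L13 = |hip-ankle| the
    angle is arccos((L12^2 + L23^2 - L13^2) / (2 L12 L23)); the cosine
    argument is clamped to [-1, 1] so collinear points return exactly
    180 degrees.

    Raises
    ------
    DegenerateGeometryError
        If either leg segment is shorter than ``SEGMENT_EPS`` or any
        coordinate is non-finite.
    """
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    if not (np.all(np.isfinite(hip)) and np.all(np.isfinite(knee)) and np.all(np.isfinite(ankle))):
        raise DegenerateGeometryError("non-finite landmark coordinates")
    l12 = math.hypot(*(hip - knee))
    l23 = math.hypot(*(knee - ankle))
    if l12 <= SEGMENT_EPS or l23 <= SEGMENT_EPS:
        raise DegenerateGeometryError(
            f"leg segment collapsed (femur={l12:.3g}, tibia={l23:.3g})"
        )
    l13 = math.hypot(*(hip - ankle))
    c = (l12 * l12 + l23 * l23 - l13 * l13) / (2.0 * l12 * l23)
    c = min(1.0, max(-1.0, c))
    ang = math.degrees(math.acos(c))
    # exact collinearity maps to the closed upper end of (0, 180]
    return ang if ang > 0.0 else np.nextafter(0.0, 1.0)


def _leg_angles(
    seq: PoseSequence, triple: Tuple[int, int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame angle + validity for one knee triple (no interpolation)."""
    hip_i, knee_i, ankle_i = triple
    n = seq.n_frames
    ang = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for t in range(n):
        if not (
            seq.visible[t, hip_i] and seq.visible[t, knee_i] and seq.visible[t, ankle_i]
        ):
            continue
        try:
            ang[t] = bending_angle(
                seq.coords[t, hip_i], seq.coords[t, knee_i], seq.coords[t, ankle_i]
            )
        except DegenerateGeometryError:
            continue
        ok[t] = True
    return ang, ok


def _fill_invalid(ang: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Linear interpolation of invalid interior frames; edge copy outside."""
    if ok.all():
        return ang
    idx = np.flatnonzero(ok)
    out = ang.copy()
    out[~ok] = np.interp(np.flatnonzero(~ok), idx, ang[idx])
    return out


def angle_series(seq: PoseSequence, schema: Optional[SkeletonSchema] = None) -> AngleSeries:
    """Extract the (front, hind) bending-angle series of a clip.

    Frames where any triple landmark is non-visible or the geometry is
    degenerate are marked invalid and filled by linear interpolation
    between the nearest valid neighbours (edges copy the nearest valid
    value).

    Raises
    ------
    InvalidClipError
        If more than 30% of frames are invalid for either leg.
    """
    if schema is None:
        schema = SkeletonSchema()
    front, ok_f = _leg_angles(seq, schema.front_knee_triple)
    hind, ok_h = _leg_angles(seq, schema.hind_knee_triple)
    n = seq.n_frames
    for name, ok in (("front", ok_f), ("hind", ok_h)):
        bad = 1.0 - ok.mean()
        if bad > MAX_INVALID_FRACTION:
            raise InvalidClipError(
                f"clip {seq.clip_id!r}: {bad:.0%} of frames invalid for {name} leg "
                f"(limit {MAX_INVALID_FRACTION:.0%})"
            )
        if not ok.any():
            raise InvalidClipError(f"clip {seq.clip_id!r}: no valid {name}-leg frames")
    return AngleSeries(
        front=_fill_invalid(front, ok_f),
        hind=_fill_invalid(hind, ok_h),
        valid=ok_f & ok_h,
        clip_id=seq.clip_id,
    )
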