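import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstream.core import (
    ActionLabel,
    AngleSeries,
    DegenerateGeometryError,
    InvalidClipError,
    PoseFrame,
    PoseSequence,
    SchemaError,
    ScoreVector,
    SkeletonSchema,
    angle_series,
    bending_angle,
)


def oracle_angle(hip, knee, ankle) -> float:
    """Independent vector-angle oracle: atan2 of |cross| / dot."""
    u = np.asarray(hip, dtype=float) - np.asarray(knee, dtype=float)
    v = np.asarray(ankle, dtype=float) - np.asarray(knee, dtype=float)
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return math.degrees(math.atan2(abs(cross), dot))


class TestActionLabel:
    def test_exactly_three_classes(self):
        assert len(ActionLabel) == 3

    def test_stable_encoding(self):
        assert int(ActionLabel.STANDING) == 0
        assert int(ActionLabel.AMBLING) == 1
        assert int(ActionLabel.GALLOPING) == 2

    def test_from_name(self):
        assert ActionLabel.from_name("galloping") is ActionLabel.GALLOPING
        with pytest.raises(ValueError):
            ActionLabel.from_name("trotting")


class TestSkeletonSchema:
    def test_default_triples(self, schema):
        assert schema.hind_knee_triple == (13, 14, 15)
        assert schema.front_knee_triple == (9, 10, 11)
        assert len(schema.landmark_names) == 18

    def test_knee_is_middle_element(self, schema):
        assert schema.landmark_names[schema.hind_knee_triple[1]] == "hind_knee"
        assert schema.landmark_names[schema.front_knee_triple[1]] == "front_knee"

    def test_rejects_wrong_landmark_count(self):
        with pytest.raises(SchemaError):
            SkeletonSchema(landmark_names=("a",) * 17)

    def test_rejects_overlapping_triples(self):
        with pytest.raises(SchemaError):
            SkeletonSchema(front_knee_triple=(13, 14, 15))

    def test_json_roundtrip(self, schema):
        assert SkeletonSchema.from_json(schema.to_json()) == schema


class TestScoreVector:
    def test_valid(self):
        sv = ScoreVector(np.array([0.2, 0.3, 0.5]))
        assert sv.argmax() is ActionLabel.GALLOPING

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            ScoreVector(np.array([0.2, 0.3, 0.6]))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ScoreVector(np.array([-0.1, 0.6, 0.5]))

    def test_argmax_tie_breaks_low_index(self):
        assert ScoreVector(np.array([0.4, 0.4, 0.2])).argmax() is ActionLabel.STANDING


class TestBendingAngle:
    def test_collinear_is_180(self):
        assert bending_angle((0, 0), (1, 0), (2, 0)) == 180.0

    def test_perpendicular_is_90(self):
        assert bending_angle((0, 0), (1, 0), (1, 1)) == pytest.approx(90.0, abs=1e-12)

    def test_derived_120(self):
        # frozen from the atan2 oracle
        hip, knee, ankle = (0, 0), (2, 0), (3, math.sqrt(3))
        assert oracle_angle(hip, knee, ankle) == pytest.approx(120.0, abs=1e-12)
        assert bending_angle(hip, knee, ankle) == pytest.approx(120.0, abs=1e-12)

    def test_degenerate_femur(self):
        with pytest.raises(DegenerateGeometryError):
            bending_angle((1, 1), (1, 1), (2, 2))

    def test_degenerate_tibia(self):
        with pytest.raises(DegenerateGeometryError):
            bending_angle((0, 0), (1, 1), (1, 1 + 1e-12))

    def test_nonfinite_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            bending_angle((np.nan, 0), (1, 0), (2, 0))

    def test_adversarial_near_collinear_stays_in_range(self):
        # cosine argument can exceed 1 without clamping
        for eps in (1e-16, 1e-13, 1e-10):
            a = bending_angle((0, 0), (1, eps), (2, 0))
            assert 0 < a <= 180.0


finite_coord = st.floats(min_value=-1e4, max_value=1e4, allow_nan=False)
point = st.tuples(finite_coord, finite_coord)


def _nondegenerate(hip, knee, ankle) -> bool:
    # non-degenerate = segments not tiny, not near-collinear, and segment
    # lengths within 3 decades of each other (the law-of-cosines loses
    # precision under extreme length ratios, as any implementation would)
    u = np.subtract(hip, knee)
    v = np.subtract(ankle, knee)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu < 1e-3 or nv < 1e-3:
        return False
    if max(nu, nv) / min(nu, nv) > 1e3:
        return False
    cos = float(np.dot(u, v) / (nu * nv))
    return abs(cos) < 0.999


class TestBendingAngleProperties:
    @settings(max_examples=300, deadline=None)
    @given(hip=point, knee=point, ankle=point)
    def test_matches_oracle(self, hip, knee, ankle):
        if not _nondegenerate(hip, knee, ankle):
            return
        assert bending_angle(hip, knee, ankle) == pytest.approx(
            oracle_angle(hip, knee, ankle), abs=1e-9
        )

    @settings(max_examples=200, deadline=None)
    @given(
        hip=point, knee=point, ankle=point,
        theta=st.floats(0, 2 * math.pi),
        tx=st.floats(-100, 100), ty=st.floats(-100, 100),
        scale=st.floats(0.1, 10.0),
    )
    def test_rigid_and_scale_invariance(self, hip, knee, ankle, theta, tx, ty, scale):
        if not _nondegenerate(hip, knee, ankle):
            return
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        pts = np.array([hip, knee, ankle])
        moved = (pts @ rot.T) * scale + np.array([tx, ty])
        a0 = bending_angle(*pts)
        a1 = bending_angle(*moved)
        assert a1 == pytest.approx(a0, abs=1e-7)

    @settings(max_examples=200, deadline=None)
    @given(hip=point, knee=point, ankle=point)
    def test_symmetric_in_hip_ankle_swap(self, hip, knee, ankle):
        if not _nondegenerate(hip, knee, ankle):
            return
        assert bending_angle(hip, knee, ankle) == pytest.approx(
            bending_angle(ankle, knee, hip), abs=1e-9
        )

    @settings(max_examples=300, deadline=None)
    @given(hip=point, knee=point, ankle=point)
    def test_range(self, hip, knee, ankle):
        u = np.subtract(hip, knee)
        v = np.subtract(ankle, knee)
        if np.hypot(*u) <= 1e-9 or np.hypot(*v) <= 1e-9:
            return
        assert 0 < bending_angle(hip, knee, ankle) <= 180.0


def _make_sequence(front_pts, hind_pts, visible=None, n=None):
    """Build a PoseSequence where only the two knee triples matter.

    ``front_pts``/``hind_pts``: list of (hip, knee, ankle) per frame.
    """
    n = n or len(front_pts)
    coords = np.zeros((n, 18, 2))
    # spread unused landmarks out so they are never degenerate
    coords[:, :, 0] = np.arange(18) * 10.0
    vis = np.ones((n, 18), dtype=bool)
    for t in range(n):
        for (triple, pts) in (((9, 10, 11), front_pts[t]), ((13, 14, 15), hind_pts[t])):
            for k, p in zip(triple, pts):
                coords[t, k] = p
    if visible is not None:
        vis = visible
    return PoseSequence(clip_id="test", coords=coords, visible=vis)


class TestAngleSeries:
    def test_all_collinear(self, schema):
        pts = [((0, 0), (1, 0), (2, 0))] * 10
        seq = _make_sequence(pts, pts)
        s = angle_series(seq, schema)
        assert np.allclose(s.front, 180.0)
        assert np.allclose(s.hind, 180.0)
        assert s.valid.all()

    def test_interpolation_midpoint(self, schema):
        def frame_for(angle_deg):
            a = math.radians(angle_deg)
            return ((1.0, 0.0), (0.0, 0.0), (math.cos(a), math.sin(a)))

        pts = [frame_for(100)] * 5 + [frame_for(100)] + [frame_for(120)] * 4
        vis = np.ones((10, 18), dtype=bool)
        vis[5, 14] = False  # hind knee hidden in frame 5
        # frame 4 yields 100 deg, frame 6 yields 120 deg for the hind leg
        hind = [frame_for(100)] * 5 + [frame_for(110)] + [frame_for(120)] * 4
        seq = _make_sequence(pts, hind, visible=vis)
        s = angle_series(seq, schema)
        assert s.hind[5] == pytest.approx(110.0, abs=1e-9)
        assert not s.valid[5]
        assert s.valid[4] and s.valid[6]

    def test_sinusoid_matches_per_frame_oracle(self, schema):
        rng = np.random.default_rng(42)
        n = 20
        angles = 150 + 10 * np.sin(np.linspace(0, 4 * math.pi, n))
        pts = []
        for a in angles:
            r = math.radians(a)
            pts.append(((1.0, 0.0), (0.0, 0.0), (math.cos(r), math.sin(r))))
        seq = _make_sequence(pts, pts)
        s = angle_series(seq, schema)
        expected = [oracle_angle(*p) for p in pts]
        assert np.allclose(s.hind, expected, atol=1e-9)
        assert s.hind.min() == pytest.approx(angles.min(), abs=1e-9)
        assert s.hind.max() == pytest.approx(angles.max(), abs=1e-9)

    def test_leading_trailing_invalid_copy_nearest(self, schema):
        def frame_for(angle_deg):
            a = math.radians(angle_deg)
            return ((1.0, 0.0), (0.0, 0.0), (math.cos(a), math.sin(a)))

        pts = [frame_for(100)] * 10
        vis = np.ones((10, 18), dtype=bool)
        vis[0, 15] = False
        vis[9, 15] = False
        seq = _make_sequence(pts, pts, visible=vis)
        s = angle_series(seq, schema)
        assert s.hind[0] == pytest.approx(100.0)
        assert s.hind[9] == pytest.approx(100.0)
        assert not s.valid[0] and not s.valid[9]

    def test_too_many_invalid_rejected(self, schema):
        pts = [((0, 0), (1, 0), (2, 0))] * 10
        vis = np.ones((10, 18), dtype=bool)
        vis[:4, 14] = False  # 40% of hind-knee frames hidden
        seq = _make_sequence(pts, pts, visible=vis)
        with pytest.raises(InvalidClipError):
            angle_series(seq, schema)

    def test_angle_series_invariants(self, schema):
        pts = [((0, 0), (1, 0), (1.5, 1))] * 10
        seq = _make_sequence(pts, pts)
        s = angle_series(seq, schema)
        assert len(s) == seq.n_frames
        assert np.all(s.front > 0) and np.all(s.front <= 180)


class TestPoseTypes:
    def test_pose_frame_shape_validation(self):
        with pytest.raises(SchemaError):
            PoseFrame(np.zeros((17, 2)), np.ones(17, dtype=bool))

    def test_sequence_needs_two_frames(self):
        with pytest.raises(ValueError):
            PoseSequence("x", np.zeros((1, 18, 2)), np.ones((1, 18), dtype=bool))

    def test_sequence_fps_positive(self):
        with pytest.raises(ValueError):
            PoseSequence("x", np.zeros((3, 18, 2)), np.ones((3, 18), dtype=bool), fps=0)
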