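"""Pelvis/hip frame construction and homogeneous transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gaitgen.exceptions import AlignmentError, GaitgenError, GeometryError
from gaitgen.frames import (
    MarkerSeries,
    acp_in_hip,
    build_hip_frame,
    build_pelvis_frame,
    frame_to_transform,
    world_point_to_frame,
)

RASIS = np.array([0.0, -10.0, 100.0])
LASIS = np.array([0.0, 10.0, 100.0])
SACRAL = np.array([-15.0, 0.0, 100.0])


class TestPelvisFrame:
    def test_symmetric_configuration(self):
        f = build_pelvis_frame(RASIS, LASIS, SACRAL)
        np.testing.assert_allclose(f.origin, [0, 0, 100])
        np.testing.assert_allclose(f.y_axis, [0, 1, 0], atol=1e-12)
        # z chosen inferior relative to world up
        assert f.z_axis @ [0, 0, 1] < 0

    def test_axes_orthonormal_and_right_handed(self):
        f = build_pelvis_frame([3.1, -9.2, 98.0], [2.9, 10.5, 101.0], [-12.0, 0.7, 103.0])
        R = f.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_markers_rejected(self):
        with pytest.raises(GeometryError):
            build_pelvis_frame([0, 0, 0], [0, 2, 0], [0, 1, 0])
        with pytest.raises(GeometryError):
            build_pelvis_frame([1, 1, 1], [1, 1, 1], [2, 2, 2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_equivariance(self, seed):
        """Rotating all markers rotates every frame axis identically."""
        Q = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        base = build_pelvis_frame(RASIS, LASIS, SACRAL)
        rot = build_pelvis_frame(Q @ RASIS, Q @ LASIS, Q @ SACRAL, world_up=Q @ [0, 0, 1])
        for ax in ("x_axis", "y_axis", "z_axis"):
            np.testing.assert_allclose(getattr(rot, ax), Q @ getattr(base, ax), atol=1e-9)


class TestHipFrame:
    def test_axes_copied_origin_moved(self):
        pelvis = build_pelvis_frame(RASIS, LASIS, SACRAL)
        hip = build_hip_frame(pelvis, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(hip.x_axis, pelvis.x_axis)
        np.testing.assert_array_equal(hip.y_axis, pelvis.y_axis)
        np.testing.assert_array_equal(hip.z_axis, pelvis.z_axis)
        np.testing.assert_allclose(hip.origin, [1, 2, 3])

    def test_hjc_at_pelvis_origin_reproduces_pelvis(self):
        pelvis = build_pelvis_frame(RASIS, LASIS, SACRAL)
        hip = build_hip_frame(pelvis, pelvis.origin)
        np.testing.assert_array_equal(hip.origin, pelvis.origin)

    def test_nonfinite_hjc_rejected(self):
        pelvis = build_pelvis_frame(RASIS, LASIS, SACRAL)
        with pytest.raises(GaitgenError):
            build_hip_frame(pelvis, [np.nan, 0, 0])


class TestHomTransform:
    def test_identity_and_translation(self):
        f = build_pelvis_frame(RASIS, LASIS, SACRAL)
        t = frame_to_transform(f)
        np.testing.assert_allclose(t.matrix[3], [0, 0, 0, 1])
        np.testing.assert_allclose(t.matrix[:3, 3], f.origin)
        np.testing.assert_allclose(t.matrix[:3, :3], f.rotation)

    def test_world_point_round_trip(self, rng):
        for _ in range(50):
            markers = rng.normal(0, 20, (3, 3))
            try:
                f = build_pelvis_frame(*markers)
            except GeometryError:
                continue
            t = frame_to_transform(f)
            p = rng.normal(0, 50, 3)
            local = world_point_to_frame(t, p)
            np.testing.assert_allclose(t.apply(local), p, atol=1e-9)

    def test_pure_translation(self):
        from gaitgen.frames import HomTransform

        t = HomTransform(rotation=np.eye(3), translation=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(world_point_to_frame(t, [1, 2, 3]), [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(world_point_to_frame(t, [4, 5, 6]), [3, 3, 3], atol=1e-12)


def _series(name, positions, times=None):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions)) * 0.01
    return MarkerSeries(name=name, times=times, positions=positions)


class TestAcpInHip:
    def test_static_identity_configuration(self):
        n = 5
        out = acp_in_hip(
            ajc=_series("ajc", np.tile([10.0, 0, 80.0], (n, 1))),
            rasis=_series("r", np.tile(RASIS, (n, 1))),
            lasis=_series("l", np.tile(LASIS, (n, 1))),
            sacral=_series("s", np.tile(SACRAL, (n, 1))),
            hjc=_series("h", np.zeros((n, 3))),
        )
        assert out.name == "ACP"
        # frame axes: y left, z down, x = y x z (posterior); point (10, 0, 80)
        expected = np.array([10.0, 0.0, 80.0]) @ np.column_stack(
            [[-1, 0, 0], [0, 1, 0], [0, 0, -1]]
        )
        np.testing.assert_allclose(out.positions, np.tile(expected, (n, 1)), atol=1e-9)

    def test_common_translation_removed(self):
        n = 20
        drift = np.outer(np.arange(n), [5.0, 0.0, 0.0])
        base = {
            "ajc": np.tile([12.0, -3.0, 75.0], (n, 1)),
            "rasis": np.tile(RASIS, (n, 1)),
            "lasis": np.tile(LASIS, (n, 1)),
            "sacral": np.tile(SACRAL, (n, 1)),
            "hjc": np.tile([0.0, -9.0, 92.0], (n, 1)),
        }
        moved = {k: v + drift for k, v in base.items()}
        still = acp_in_hip(**{k: _series(k, v) for k, v in base.items()})
        translated = acp_in_hip(**{k: _series(k, v) for k, v in moved.items()})
        np.testing.assert_allclose(still.positions, translated.positions, atol=1e-9)

    def test_global_rigid_motion_invariance(self, rng):
        """A rigid rotation+translation of all markers leaves hip-frame ACP unchanged."""
        n = 30
        base = {
            "ajc": rng.normal([10, -5, 70], 2.0, (n, 3)),
            "rasis": np.tile(RASIS, (n, 1)),
            "lasis": np.tile(LASIS, (n, 1)),
            "sacral": np.tile(SACRAL, (n, 1)),
            "hjc": np.tile([0.0, -9.0, 92.0], (n, 1)),
        }
        Q = Rotation.random(rng=rng).as_matrix()
        d = rng.normal(0, 30, 3)
        moved = {k: v @ Q.T + d for k, v in base.items()}
        ref = acp_in_hip(**{k: _series(k, v) for k, v in base.items()})
        rig = acp_in_hip(
            **{k: _series(k, v) for k, v in moved.items()}, world_up=Q @ [0, 0, 1]
        )
        np.testing.assert_allclose(ref.positions, rig.positions, atol=1e-9)

    def test_recovers_programmed_hip_relative_trajectory(self, noise_free_trial):
        """On a noise-free synthetic trial the ACP equals the generator's ground truth."""
        m = noise_free_trial.markers
        out = acp_in_hip(m["R.AJC"], m["R.Asis"], m["L.Asis"], m["V.Sacral"], m["R.HJC"])
        np.testing.assert_allclose(
            out.positions, noise_free_trial.acp_true.positions, atol=1e-8
        )

    def test_mismatched_time_bases_rejected(self):
        a = _series("a", np.zeros((5, 3)))
        b = _series("b", np.zeros((5, 3)), times=np.arange(5) * 0.02)
        with pytest.raises(AlignmentError):
            acp_in_hip(a, b, a, a, a)


@settings(derandomize=True, max_examples=50)
@given(
    angles=st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
    point=st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
    shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
)
def test_round_trip_property(angles, point, shift):
    """world -> frame -> world is the identity for any rigid transform."""
    from gaitgen.frames import HomTransform

    R = Rotation.from_euler("xyz", angles).as_matrix()
    t = HomTransform(rotation=R, translation=np.array(shift))
    p = np.array(point)
    np.testing.assert_allclose(t.apply(world_point_to_frame(t, p)), p, atol=1e-9)


def test_marker_series_validation():
    with pytest.raises(GaitgenError):
        MarkerSeries("m", times=[0.0, 0.0], positions=np.zeros((2, 3)))
    with pytest.raises(GaitgenError):
        MarkerSeries("m", times=[0.0, 0.1], positions=np.full((2, 3), np.nan))
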