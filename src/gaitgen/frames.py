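"""Anatomical coordinate frames and the world->hip homogeneous transformation.

The ankle center position (ACP) is the trajectory of the ankle joint center
(AJC) expressed relative to the pelvis.  A pelvis frame {P} is built from the
three Helen Hayes pelvis markers:

* origin: midpoint of R.Asis and L.Asis,
* y axis: from R.Asis toward L.Asis,
* z axis: normal of the plane through R.Asis, L.Asis and the sacral marker,
  with its sign chosen inferior (negative projection on the world up axis),
* x axis: y x z, after which y is re-orthogonalized as z x x.

The resulting rotation is right-handed (det = +1).  Note that with y pointing
to the subject's left and z inferior, the right-handed completion points x
*posteriorly*; the frame is used consistently throughout the package, so only
the sign convention of the ACP X channel depends on this choice.

The hip frame {H} shares the pelvis axes and sits at the hip joint center
(HJC); the AJC is mapped into {H} through the inverse of the rigid transform
T_WH whose columns are the frame axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, GaitgenError, GeometryError

__all__ = [
    "RigidFrame",
    "HomTransform",
    "MarkerSeries",
    "build_pelvis_frame",
    "build_hip_frame",
    "frame_to_transform",
    "world_point_to_frame",
    "acp_in_hip",
]

_ORTHO_TOL = 1e-9


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0.0:
        raise GeometryError(f"cannot normalize zero or non-finite {what}")
    return v / n


@dataclass(frozen=True)
class RigidFrame:
    """An orthonormal right-handed frame expressed in world coordinates (cm)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise GaitgenError(f"RigidFrame.{name} must be a 3-vector")
            if not np.all(np.isfinite(getattr(self, name))):
                raise GeometryError(f"RigidFrame.{name} contains non-finite values")
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("frame axes are not orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 rotation with the frame axes as columns (frame -> world)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass(frozen=True)
class HomTransform:
    """Rigid transform T_WH mapping hip-frame coordinates to world coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GaitgenError("HomTransform requires a 3x3 rotation and a 3-vector")
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("HomTransform rotation is not orthonormal")

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix; bottom row exactly (0, 0, 0, 1)."""
        T = np.zeros((4, 4))
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        T[3, 3] = 1.0
        return T

    def apply(self, p_frame) -> np.ndarray:
        """Forward map: hip-frame point -> world point."""
        p = np.asarray(p_frame, dtype=float)
        return p @ self.rotation.T + self.translation


@dataclass
class MarkerSeries:
    """One labelled marker trajectory: times (s, strictly increasing), positions (n, 3) cm."""

    name: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise GaitgenError(f"MarkerSeries '{self.name}': positions must be (n, 3)")
        if self.times.shape != (self.positions.shape[0],):
            raise GaitgenError(f"MarkerSeries '{self.name}': times/positions length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise GaitgenError(f"MarkerSeries '{self.name}': times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise GaitgenError(f"MarkerSeries '{self.name}': positions must be finite")

    def __len__(self) -> int:
        return len(self.times)


def build_pelvis_frame(rasis, lasis, sacral, world_up=(0.0, 0.0, 1.0)) -> RigidFrame:
    """Construct the pelvis frame {P} from the three pelvis markers.

    Parameters are world-coordinate 3-vectors (cm).  ``world_up`` fixes the
    sign of the inferior z axis and defaults to the laboratory +z.

    Raises
    ------
    GeometryError
        If the three markers are collinear or coincident.
    """
    rasis = np.asarray(rasis, dtype=float)
    lasis = np.asarray(lasis, dtype=float)
    sacral = np.asarray(sacral, dtype=float)
    up = _unit(world_up, "world up")

    y_raw = lasis - rasis
    scale = max(np.linalg.norm(y_raw), np.linalg.norm(sacral - rasis))
    normal = np.cross(y_raw, sacral - rasis)
    if scale == 0.0 or np.linalg.norm(normal) < 1e-9 * scale**2:
        raise GeometryError("pelvis markers are collinear or coincident")

    y = _unit(y_raw, "pelvis y axis")
    z = _unit(normal, "pelvis plane normal")
    if np.dot(z, up) > 0:  # choose the inferior normal
        z = -z
    x = _unit(np.cross(y, z), "pelvis x axis")
    y = np.cross(z, x)  # re-orthogonalize; already unit

    frame = RigidFrame(origin=(rasis + lasis) / 2.0, x_axis=x, y_axis=y, z_axis=z)
    assert np.linalg.det(frame.rotation) > 0
    return frame


def build_hip_frame(pelvis: RigidFrame, hjc_world) -> RigidFrame:
    """The hip frame {H}: pelvis axes translated to the hip joint center."""
    hjc = np.asarray(hjc_world, dtype=float)
    if hjc.shape != (3,) or not np.all(np.isfinite(hjc)):
        raise GaitgenError("hjc_world must be a finite 3-vector")
    return RigidFrame(origin=hjc, x_axis=pelvis.x_axis, y_axis=pelvis.y_axis, z_axis=pelvis.z_axis)


def frame_to_transform(frame: RigidFrame) -> HomTransform:
    """T_WH: columns of the rotation are the frame axes, translation is the origin."""
    return HomTransform(rotation=frame.rotation, translation=frame.origin)


def world_point_to_frame(t: HomTransform, p_world) -> np.ndarray:
    """Express a world point in the transform's frame: R^T (p - translation)."""
    p = np.asarray(p_world, dtype=float)
    return (p - t.translation) @ t.rotation


def _check_common_times(series: list[MarkerSeries]) -> np.ndarray:
    t0 = series[0].times
    for s in series[1:]:
        if s.times.shape != t0.shape or not np.allclose(s.times, t0, atol=1e-9):
            raise AlignmentError(
                f"marker series '{series[0].name}' and '{s.name}' do not share a time base"
            )
    return t0


def acp_in_hip(
    ajc: MarkerSeries,
    rasis: MarkerSeries,
    lasis: MarkerSeries,
    sacral: MarkerSeries,
    hjc: MarkerSeries,
    world_up=(0.0, 0.0, 1.0),
    origin: str = "hip",
) -> MarkerSeries:
    """Ankle center position: the AJC expressed in the hip (or pelvis) frame.

    A pelvis frame is built independently at every sample; the AJC is then
    mapped through the inverse of the sample's world->hip transform.  The
    computation is fully vectorized over samples.

    Parameters
    ----------
    origin:
        ``"hip"`` (default) expresses the ACP about the hip joint center,
        ``"pelvis"`` about the pelvis origin (midpoint of the Asis markers).
    """
    if origin not in ("hip", "pelvis"):
        raise GaitgenError(f"origin must be 'hip' or 'pelvis', got {origin!r}")
    times = _check_common_times([ajc, rasis, lasis, sacral, hjc])

    up = _unit(world_up, "world up")
    ra, la, sa = rasis.positions, lasis.positions, sacral.positions

    y = la - ra
    normal = np.cross(y, sa - ra)
    nn = np.linalg.norm(normal, axis=1)
    scale = np.maximum(np.linalg.norm(y, axis=1), np.linalg.norm(sa - ra, axis=1))
    if np.any(nn < 1e-9 * scale**2):
        raise GeometryError("pelvis markers collinear/coincident at one or more samples")
    y = y / np.linalg.norm(y, axis=1, keepdims=True)
    z = normal / nn[:, None]
    flip = (z @ up) > 0
    z[flip] = -z[flip]
    x = np.cross(y, z)
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    y = np.cross(z, x)

    org = hjc.positions if origin == "hip" else (ra + la) / 2.0
    d = ajc.positions - org
    # R^T d per sample: rotation columns are (x, y, z)
    acp = np.stack([np.sum(d * x, axis=1), np.sum(d * y, axis=1), np.sum(d * z, axis=1)], axis=1)
    return MarkerSeries(name="ACP", times=times, positions=acp)
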