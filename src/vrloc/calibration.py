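"""Virtual-to-real rigid calibration from three tracked reference points.

A virtual environment (VE) rendered on a head-mounted display must stay
spatially aligned with the real environment (RE) it replicates; tracking
losses can silently offset the VE.  The alignment is recovered from three
trackers placed on the ear-level loudspeakers at 0 and +-45 deg azimuth,
whose coordinates are known in both frames, using a three-step rigid
correction:

1. rotate the virtual point set so the normal of its plane matches the
   normal of the real plane;
2. translate so a chosen reference point coincides with its real
   counterpart;
3. rotate about the real normal through the reference point by the angle
   between the in-plane vectors from the reference point to one of the
   remaining points in each frame.

For an exactly rigid correspondence the composed transform maps all three
virtual points onto their real counterparts to numerical precision.  A
residual monitor flags recalibration when any mapped point is more than
2 cm from its true position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import azel_to_direction

__all__ = [
    "TrackerSet",
    "RigidTransform",
    "AlignmentResidual",
    "RECALIBRATION_THRESHOLD_M",
    "default_tracker_geometry",
    "plane_normal",
    "rotation_between",
    "calibrate",
    "alignment_residual",
    "worst_case_rotation_deg",
]

RECALIBRATION_THRESHOLD_M = 0.02

_MIN_TRIANGLE_AREA_M2 = 1e-9


@dataclass(frozen=True)
class TrackerSet:
    """Three non-collinear tracked points (rows of a 3x3 array, meters)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (3, 3):
            raise ValueError(f"expected 3 points x 3 coords, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)
        area = 0.5 * np.linalg.norm(
            np.cross(pts[1] - pts[0], pts[2] - pts[0])
        )
        if area <= _MIN_TRIANGLE_AREA_M2:
            raise ValueError(
                f"tracker points are (near-)collinear: triangle area {area:g} m^2"
            )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if not math.isclose(np.linalg.det(R), 1.0, abs_tol=1e-10):
            raise ValueError("rotation matrix determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AlignmentResidual:
    max_offset: float
    recalibrate: bool


def default_tracker_geometry(radius: float = 2.4) -> TrackerSet:
    """Tracker positions on the ear-level loudspeakers at 0 and +-45 deg."""
    pts = np.stack(
        [radius * azel_to_direction(az, 0.0) for az in (0.0, -45.0, 45.0)]
    )
    return TrackerSet(pts)


def _oriented_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal oriented by vertex order, (p2-p1) x (p3-p1).

    This orientation commutes with any proper rigid transform of the points,
    which is what lets the three-step alignment recover arbitrary rotations;
    a fixed world-axis sign convention would not.
    """
    n = np.cross(points[1] - points[0], points[2] - points[0])
    return n / np.linalg.norm(n)


def plane_normal(trackers: TrackerSet) -> np.ndarray:
    """Unit normal of the plane spanned by the three tracker points.

    The sign ambiguity is resolved toward positive z (then positive x, then
    positive y), a convenient convention for reporting; see
    :func:`calibrate` for the orientation actually used during alignment.
    """
    n = _oriented_normal(trackers.points)
    for comp in (2, 0, 1):
        if abs(n[comp]) > 1e-12:
            return n if n[comp] > 0 else -n
    return n


def rotation_between(u: np.ndarray, v: np.ndarray) -> RigidTransform:
    """Minimal rotation mapping direction ``u`` onto direction ``v``.

    Identity when parallel; for antiparallel inputs, a 180 deg rotation about
    a deterministic perpendicular axis (built from the world axis least
    aligned with ``u``).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("directions must be nonzero")
    u, v = u / nu, v / nv
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-15:
        if c > 0:
            return RigidTransform.identity()
        # antiparallel: rotate 180 deg about a perpendicular axis
        helper = np.eye(3)[int(np.argmin(np.abs(u)))]
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, math.pi)
    axis /= s
    return _axis_angle(axis, math.atan2(s, c))


def _axis_angle(axis: np.ndarray, angle: float) -> RigidTransform:
    """Rodrigues rotation about a unit axis through the origin."""
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    R = np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)
    return RigidTransform(R, np.zeros(3))


def calibrate(
    real: TrackerSet, virtual: TrackerSet, reference_index: int = 1
) -> RigidTransform:
    """Three-step rigid alignment of the virtual frame onto the real frame.

    ``reference_index`` (1-based) selects the tracker used as the positional
    anchor in step 2; step 3 uses the lowest-index non-reference point.
    Returns the transform to apply to virtual coordinates.
    """
    if reference_index not in (1, 2, 3):
        raise ValueError("reference_index must be 1, 2 or 3")
    ref = reference_index - 1
    other = min(i for i in range(3) if i != ref)

    rp = real.points
    vp = virtual.points

    # step 1: align plane normals (vertex-order orientation, see _oriented_normal)
    n_real = _oriented_normal(rp)
    n_virt = _oriented_normal(vp)
    r1 = rotation_between(n_virt, n_real)
    vp1 = r1.apply(vp)

    # step 2: translate the reference point onto its real counterpart
    shift = rp[ref] - vp1[ref]
    vp2 = vp1 + shift

    # step 3: rotate about the real normal through the reference point
    a = vp2[other] - rp[ref]
    b = rp[other] - rp[ref]
    a = a - np.dot(a, n_real) * n_real
    b = b - np.dot(b, n_real) * n_real
    angle = math.atan2(float(np.dot(n_real, np.cross(a, b))), float(np.dot(a, b)))
    r3 = _axis_angle(n_real, angle)

    rotation = r3.rotation @ r1.rotation
    translation = r3.rotation @ (shift - rp[ref]) + rp[ref]
    return RigidTransform(rotation, translation)


def alignment_residual(
    transform: RigidTransform,
    real: TrackerSet,
    virtual: TrackerSet,
    threshold: float = RECALIBRATION_THRESHOLD_M,
) -> AlignmentResidual:
    """Largest mapped-point offset and whether it trips the 2 cm trigger."""
    mapped = transform.apply(virtual.points)
    offsets = np.linalg.norm(mapped - real.points, axis=1)
    max_offset = float(offsets.max())
    return AlignmentResidual(max_offset, max_offset > threshold)


def worst_case_rotation_deg(
    offset: float = RECALIBRATION_THRESHOLD_M, lever: float | None = None
) -> float:
    """Rotation (deg) produced by a positional offset acting on a lever arm.

    A tangential tracker offset of ``offset`` meters at distance ``lever``
    from the rotation pivot corresponds to atan(offset / lever).  The
    geometric model (which point pair pivots, offset direction) is a modelling
    choice, so the lever is configurable; by default it is half the shortest
    inter-tracker chord of the default geometry.
    """
    if lever is None:
        pts = default_tracker_geometry().points
        chords = [
            np.linalg.norm(pts[i] - pts[j])
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        lever = min(chords) / 2.0
    return math.degrees(math.atan2(offset, lever))
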