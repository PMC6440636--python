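"""Loudspeaker-array geometry and angular arithmetic.

Coordinate conventions used throughout the package:

* Azimuth in degrees in (-180, 180], positive to the listener's *right*,
  negative to the left, 0 straight ahead.
* Elevation in degrees in [-90, 90], positive upward.
* The Cartesian listener frame has x pointing forward (toward 0 deg
  azimuth), y to the right and z up, so ``azimuth = atan2(y, x)`` and
  ``elevation = asin(z / r)``.

The experimental array consists of 27 loudspeakers in the frontal
hemisphere at 2.4 m: thirteen at ear level (0 deg elevation) spanning
-90..+90 deg azimuth in 15 deg steps, and seven each at +28 and -28 deg
elevation spanning the same range in 30 deg steps.  Speakers are labelled
with a color per elevation row and a number per azimuth, number 1 at
-90 deg (left); the elevated rows use only the odd numbers so that equal
numbers always mean equal azimuth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SourcePosition",
    "DEFAULT_RADIUS_M",
    "DEFAULT_ELEVATION_COLORS",
    "build_source_array",
    "label_source",
    "array_table",
    "azel_to_direction",
    "direction_to_azel",
    "wrap_azimuth",
    "signed_errors",
    "ray_sphere_intersection",
]

DEFAULT_RADIUS_M = 2.4

#: Elevation row (deg) -> color.  The color/elevation pairing is a rig
#: configuration choice; override via the ``colors`` argument where offered.
DEFAULT_ELEVATION_COLORS = {28.0: "yellow", 0.0: "red", -28.0: "blue"}

_EAR_LEVEL_AZIMUTHS = tuple(float(a) for a in range(-90, 91, 15))
_ELEVATED_AZIMUTHS = tuple(float(a) for a in range(-90, 91, 30))


@dataclass(frozen=True)
class SourcePosition:
    """A loudspeaker direction with its label."""

    azimuth: float
    elevation: float
    radius: float = DEFAULT_RADIUS_M
    color: str | None = None
    number: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not -180.0 <= self.azimuth <= 180.0:
            raise ValueError(f"azimuth out of range: {self.azimuth}")
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation out of range: {self.elevation}")

    @property
    def azel(self) -> tuple[float, float]:
        return (self.azimuth, self.elevation)


def build_source_array(
    radius: float = DEFAULT_RADIUS_M,
    colors: dict[float, str] | None = None,
) -> list[SourcePosition]:
    """Return the 27-speaker frontal array (13 at 0 deg, 7 at each of +-28 deg)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    colors = DEFAULT_ELEVATION_COLORS if colors is None else colors
    sources = []
    for elevation, azimuths in (
        (0.0, _EAR_LEVEL_AZIMUTHS),
        (28.0, _ELEVATED_AZIMUTHS),
        (-28.0, _ELEVATED_AZIMUTHS),
    ):
        for az in azimuths:
            color, number = label_source(az, elevation, colors=colors)
            sources.append(
                SourcePosition(az, elevation, radius, color=color, number=number)
            )
    return sources


def label_source(
    azimuth: float,
    elevation: float,
    colors: dict[float, str] | None = None,
) -> tuple[str, int]:
    """Label an array position: number ``1 + (azimuth + 90) / 15``, color by row.

    Numbers run 1..13 from -90 deg (left) to +90 deg (right); the +-28 deg rows
    hold only odd numbers, so equal numbers share an azimuth across rows.
    """
    colors = DEFAULT_ELEVATION_COLORS if colors is None else colors
    if elevation not in colors:
        raise ValueError(
            f"elevation {elevation} is not an array row (rows: {sorted(colors)})"
        )
    valid = _EAR_LEVEL_AZIMUTHS if elevation == 0.0 else _ELEVATED_AZIMUTHS
    if azimuth not in valid:
        raise ValueError(
            f"azimuth {azimuth} is not an array position at elevation {elevation}"
        )
    number = int(round(1 + (azimuth + 90.0) / 15.0))
    return colors[elevation], number


def array_table(
    radius: float = DEFAULT_RADIUS_M, colors: dict[float, str] | None = None
) -> pd.DataFrame:
    """The array as a table (azimuth_deg, elevation_deg, radius_m, color, number)."""
    rows = [
        {
            "azimuth_deg": s.azimuth,
            "elevation_deg": s.elevation,
            "radius_m": s.radius,
            "color": s.color,
            "number": s.number,
        }
        for s in build_source_array(radius, colors)
    ]
    return pd.DataFrame(rows)


def azel_to_direction(azimuth: float, elevation: float) -> np.ndarray:
    """Unit vector (x forward, y right, z up) for an azimuth/elevation pair."""
    az = math.radians(azimuth)
    el = math.radians(elevation)
    return np.array(
        [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
    )


def direction_to_azel(v: Iterable[float]) -> tuple[float, float]:
    """Azimuth/elevation (deg) of a direction vector; the zero vector is rejected.

    At the poles (|elevation| = 90) azimuth is reported as 0 by convention.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("direction vector must be nonzero and finite")
    x, y, z = v / norm
    azimuth = math.degrees(math.atan2(y, x))
    elevation = math.degrees(math.asin(np.clip(z, -1.0, 1.0)))
    return azimuth, elevation


def wrap_azimuth(angle_deg):
    """Wrap angles to (-180, 180]; exactly -180 maps to +180 (documented tie)."""
    wrapped = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def signed_errors(
    target: SourcePosition | tuple[float, float],
    response_azel: tuple[float, float],
) -> tuple[float, float]:
    """Signed (azimuth, elevation) error in degrees, response minus target.

    Azimuth error is wrapped to (-180, 180] (positive = rightward of the
    target); elevation error is an unwrapped difference (positive = above).
    """
    t_az, t_el = target.azel if isinstance(target, SourcePosition) else target
    r_az, r_el = response_azel
    return wrap_azimuth(r_az - t_az), r_el - t_el


def ray_sphere_intersection(
    origin: Iterable[float],
    direction: Iterable[float],
    radius: float = DEFAULT_RADIUS_M,
    center: Iterable[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Intersection of a pointing ray with the response sphere.

    The pointing direction of a hand-held controller is converted to a
    reported source location by intersecting the ray from the controller tip
    with the sphere of the loudspeaker radius centred on the listener's head.
    Returns the first intersection at positive ray parameter (for an origin
    inside the sphere this is the exit point).
    """
    o = np.asarray(origin, dtype=float) - np.asarray(center, dtype=float)
    d = np.asarray(direction, dtype=float)
    dn = np.linalg.norm(d)
    if dn == 0:
        raise ValueError("ray direction must be nonzero")
    d = d / dn
    b = float(np.dot(o, d))
    c = float(np.dot(o, o) - radius**2)
    disc = b * b - c
    if disc < 0:
        raise ValueError("ray does not intersect the sphere")
    sq = math.sqrt(disc)
    for t in (-b - sq, -b + sq):
        if t > 0:
            return np.asarray(center, dtype=float) + o + t * d
    raise ValueError("sphere is entirely behind the ray origin")
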