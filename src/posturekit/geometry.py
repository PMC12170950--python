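"""Pure posture-angle arithmetic.

All angles cross the API boundary in degrees.  Image coordinates follow the
raster convention (x grows rightward, y grows *downward*); every angle is
computed after converting the vertical displacement to an up-positive frame,
so that anatomy above the vertex yields positive elevation over the
horizontal.  The horizontal reference is the unit vector (1, 0) along the
image x-axis.

Three angle families are covered:

* craniovertebral angle (CA) — elevation of the C7→tragus line over the
  horizontal through C7; low values indicate forward head posture,
* shoulder angle (SA) — elevation of the acromion→C7 line over the
  horizontal through the acromion,
* accelerometric inclination — tilt of a sensor's X-axis relative to the
  horizontal plane, derived from the gravity vector, with the kyphosis
  angle (KA) being the sum of the upper-back (alpha) and mid-back (beta)
  inclinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidSampleError, MalformedDetectionError, UndefinedAngleError

__all__ = [
    "PixelPoint",
    "MarkerDetection",
    "AccelerationSample",
    "InclinationPair",
    "marker_center",
    "craniovertebral_angle",
    "shoulder_angle",
    "tilt_from_acceleration",
    "kyphosis_angle",
]


@dataclass(frozen=True)
class PixelPoint:
    """A 2D image point in pixels (x: column, rightward; y: row, downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite pixel coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class MarkerDetection:
    """One detected square fiducial: dictionary ID plus four corner points.

    Corner order is whatever the detector delivers; the centroid is
    order-invariant so downstream geometry never depends on it.
    """

    marker_id: int
    corners: tuple[PixelPoint, PixelPoint, PixelPoint, PixelPoint]

    def __post_init__(self) -> None:
        if self.marker_id < 0:
            raise MalformedDetectionError(f"negative marker id {self.marker_id}")
        if len(self.corners) != 4:
            raise MalformedDetectionError(
                f"marker {self.marker_id}: expected 4 corners, got {len(self.corners)}"
            )


@dataclass(frozen=True)
class AccelerationSample:
    """A 3-axis accelerometer reading in g-units at time ``t`` seconds."""

    t: float
    ax: float
    ay: float
    az: float

    @property
    def norm(self) -> float:
        return math.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass(frozen=True)
class InclinationPair:
    """Surface inclinations of the two spine-mounted sensors, degrees.

    ``alpha_deg`` is the upper-back sensor (T1/T2), ``beta_deg`` the
    mid-back sensor (T12/L1).  Forward flexion is positive.
    """

    alpha_deg: float
    beta_deg: float


def marker_center(detection: MarkerDetection) -> PixelPoint:
    """Centroid of a detected marker: component-wise mean of its 4 corners."""
    corners: Sequence[PixelPoint] = detection.corners
    if len(corners) != 4:  # defensive: dataclass validates, ad-hoc tuples may not
        raise MalformedDetectionError(
            f"marker {detection.marker_id}: expected 4 corners, got {len(corners)}"
        )
    return PixelPoint(
        x=sum(c.x for c in corners) / 4.0,
        y=sum(c.y for c in corners) / 4.0,
    )


def _elevation_deg(origin: PixelPoint, target: PixelPoint, what: str) -> float:
    """Unsigned angle in [0, 180] between origin→target and the horizontal.

    The vertical displacement is flipped to up-positive before the angle is
    taken, matching the clinical convention of elevation above a horizontal
    reference line drawn through the vertex landmark.
    """
    dx = target.x - origin.x
    dy_up = origin.y - target.y  # image rows grow downward
    if dx == 0.0 and dy_up == 0.0:
        raise UndefinedAngleError(f"{what}: coincident landmark points {origin}")
    return abs(math.degrees(math.atan2(dy_up, dx)))


def craniovertebral_angle(c7: PixelPoint, tragus: PixelPoint) -> float:
    """Craniovertebral angle: elevation of the C7→tragus line, degrees.

    Returns the unsigned angle in [0, 180] between the vector from the C7
    spinous-process marker to the ear-tragus marker and the horizontal
    unit vector (1, 0).  A tragus directly above C7 gives 90.
    """
    return _elevation_deg(c7, tragus, "craniovertebral angle")


def shoulder_angle(acromion: PixelPoint, upper: PixelPoint) -> float:
    """Shoulder angle: elevation of the acromion→upper-landmark line, degrees.

    ``upper`` is the C7 marker under the default convention; callers that
    prefer the acromion→tragus convention pass the tragus point instead.
    Unsigned, in [0, 180], same up-positive frame as the CA.
    """
    return _elevation_deg(acromion, upper, "shoulder angle")


def tilt_from_acceleration(sample: AccelerationSample) -> float:
    """Inclination of the sensor X-axis from the horizontal plane, degrees.

    Computed as ``atan2(ax, sqrt(ay^2 + az^2))``, which is the angle between
    the X-axis and the plane orthogonal to gravity when the sensor is at
    rest.  The atan2 form is invariant to the overall magnitude of the
    acceleration vector, so small calibration errors in ``|a|`` do not bias
    the angle and the expression never leaves its domain.  Range (-90, 90].
    """
    if sample.norm == 0.0:
        raise InvalidSampleError(f"zero-norm acceleration vector at t={sample.t}")
    horiz = math.sqrt(sample.ay**2 + sample.az**2)
    return math.degrees(math.atan2(sample.ax, horiz))


def kyphosis_angle(pair: InclinationPair) -> float:
    """Kyphosis angle: sum of the alpha and beta surface inclinations."""
    return pair.alpha_deg + pair.beta_deg
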