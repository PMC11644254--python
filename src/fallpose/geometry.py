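"""Geometric posture features from BODY_25 keypoints.

Two primitives drive the whole fall classifier:

* the angle between a joint-to-joint segment and the image's vertical
  axis, ``degrees(atan2(A.h - B.h, A.w - B.w) - pi/2)`` wrapped to
  ``(-180, 180]`` — zero for an upright trunk, +/-90 for a body lying
  across the image;
* the height difference ``HD = A.h - B.h`` between two joints — positive
  when A sits below B on screen (image y grows downward).

Both are evaluated for three named segments: trunk (mid-hip -> neck), head
(neck -> nose) and the hip line (left hip -> right hip). Thresholds on
these quantities are expressed as fractions of a per-subject *body scale*
(median trunk length in pixels), which makes one configuration serve
subjects filmed at different distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .pose_io import Body25Index, PoseFrame

__all__ = [
    "Point2D",
    "FrameFeatures",
    "DegenerateGeometryError",
    "segment_vertical_angle",
    "wrap_degrees",
    "height_difference",
    "body_scale",
    "compute_features",
    "DEFAULT_MIN_CONFIDENCE",
    "DEFAULT_BODY_SCALE",
]

DEFAULT_MIN_CONFIDENCE = 0.1
DEFAULT_BODY_SCALE = 80.0


class DegenerateGeometryError(ValueError):
    """Raised when a segment degenerates to a point (no direction defined)."""


@dataclass(frozen=True)
class Point2D:
    """A pixel position: ``w`` horizontal, ``h`` vertical (grows downward)."""

    w: float
    h: float


PointLike = Union[Point2D, Tuple[float, float], Sequence[float]]


def _as_point(p: PointLike) -> Point2D:
    if isinstance(p, Point2D):
        return p
    w, h = p
    return Point2D(float(w), float(h))


def wrap_degrees(deg: float) -> float:
    """Wrap an angle in degrees to the half-open interval ``(-180, 180]``."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def segment_vertical_angle(a: PointLike, b: PointLike) -> float:
    """Angle between segment A->B and the vertical image axis, in degrees.

    Zero when A is directly below B (upright orientation); the sign follows
    the horizontal offset of B relative to A, so a body leaning toward the
    image's right edge yields a positive angle. Result lies in
    ``(-180, 180]``.

    Raises
    ------
    DegenerateGeometryError
        If the two points coincide exactly.
    """
    a, b = _as_point(a), _as_point(b)
    if a.w == b.w and a.h == b.h:
        raise DegenerateGeometryError(f"coincident points {a} define no segment")
    raw = math.degrees(math.atan2(a.h - b.h, a.w - b.w) - math.pi / 2.0)
    return wrap_degrees(raw)


def height_difference(a: PointLike, b: PointLike) -> float:
    """Vertical pixel offset ``A.h - B.h``; positive when A is below B."""
    a, b = _as_point(a), _as_point(b)
    return a.h - b.h


def _valid_point(frame: PoseFrame, index: Body25Index, min_confidence: float) -> Optional[Point2D]:
    kp = frame.keypoint(index)
    if kp.confidence < min_confidence:
        return None
    return Point2D(kp.x, kp.y)


def _mid_hip_point(frame: PoseFrame, min_confidence: float) -> Optional[Point2D]:
    """MID_HIP, reconstructed from the two hips when the derived joint is
    missing but both hips are valid (mirrors the BODY_25 topology, where
    MID_HIP is itself a hip midpoint)."""
    p = _valid_point(frame, Body25Index.MID_HIP, min_confidence)
    if p is not None:
        return p
    left = _valid_point(frame, Body25Index.L_HIP, min_confidence)
    right = _valid_point(frame, Body25Index.R_HIP, min_confidence)
    if left is not None and right is not None:
        return Point2D((left.w + right.w) / 2.0, (left.h + right.h) / 2.0)
    return None


@dataclass(frozen=True)
class FrameFeatures:
    """The per-frame geometric quantities the classifier consumes.

    Angles are degrees in ``(-180, 180]``; height differences are pixels;
    ``body_scale`` is the pixel trunk length the thresholds are relative to.
    Each feature carries its own validity flag: a feature is invalid iff a
    contributing keypoint falls below the confidence floor (or, for angles,
    the segment is degenerate). The numeric value of an invalid feature is
    ``nan`` and must not be read.
    """

    trunk_angle: float
    head_angle: float
    hip_line_angle: float
    trunk_hd: float
    head_hd: float
    body_scale: float
    trunk_angle_valid: bool
    head_angle_valid: bool
    hip_line_angle_valid: bool
    trunk_hd_valid: bool
    head_hd_valid: bool


def _angle_or_invalid(a: Optional[Point2D], b: Optional[Point2D]) -> Tuple[float, bool]:
    if a is None or b is None:
        return math.nan, False
    try:
        return segment_vertical_angle(a, b), True
    except DegenerateGeometryError:
        return math.nan, False


def _hd_or_invalid(a: Optional[Point2D], b: Optional[Point2D]) -> Tuple[float, bool]:
    if a is None or b is None:
        return math.nan, False
    return height_difference(a, b), True


def compute_features(
    frame: PoseFrame,
    scale: float,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> FrameFeatures:
    """Compute all five geometric features for one frame.

    ``scale`` must be a positive body-scale estimate (see :func:`body_scale`);
    it is passed through into the result so downstream rules can form
    distance-invariant ratios. Keypoints below ``min_confidence`` are never
    read: the features they contribute to are flagged invalid instead.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    nose = _valid_point(frame, Body25Index.NOSE, min_confidence)
    neck = _valid_point(frame, Body25Index.NECK, min_confidence)
    mid_hip = _mid_hip_point(frame, min_confidence)
    l_hip = _valid_point(frame, Body25Index.L_HIP, min_confidence)
    r_hip = _valid_point(frame, Body25Index.R_HIP, min_confidence)

    trunk_angle, trunk_angle_valid = _angle_or_invalid(mid_hip, neck)
    head_angle, head_angle_valid = _angle_or_invalid(neck, nose)
    hip_line_angle, hip_line_angle_valid = _angle_or_invalid(l_hip, r_hip)
    trunk_hd, trunk_hd_valid = _hd_or_invalid(mid_hip, neck)
    head_hd, head_hd_valid = _hd_or_invalid(neck, nose)

    return FrameFeatures(
        trunk_angle=trunk_angle,
        head_angle=head_angle,
        hip_line_angle=hip_line_angle,
        trunk_hd=trunk_hd,
        head_hd=head_hd,
        body_scale=float(scale),
        trunk_angle_valid=trunk_angle_valid,
        head_angle_valid=head_angle_valid,
        hip_line_angle_valid=hip_line_angle_valid,
        trunk_hd_valid=trunk_hd_valid,
        head_hd_valid=head_hd_valid,
    )


def body_scale(
    window: Iterable[PoseFrame],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    default_scale: float = DEFAULT_BODY_SCALE,
) -> float:
    """Estimate the subject's body scale (pixels) from a calibration window.

    The estimate is the median trunk length ``|MID_HIP - NECK|`` over frames
    where both endpoints are valid. When no frame qualifies, fall back to
    twice the median hip width ``2 |L_HIP - R_HIP|`` (the trunk is roughly
    twice the pelvis in the adult frame), and finally to ``default_scale``,
    so a positive value is always returned.
    """
    trunk_lengths: list[float] = []
    hip_widths: list[float] = []
    for frame in window:
        neck = _valid_point(frame, Body25Index.NECK, min_confidence)
        mid_hip = _mid_hip_point(frame, min_confidence)
        if neck is not None and mid_hip is not None:
            length = math.hypot(mid_hip.w - neck.w, mid_hip.h - neck.h)
            if length > 0:
                trunk_lengths.append(length)
        l_hip = _valid_point(frame, Body25Index.L_HIP, min_confidence)
        r_hip = _valid_point(frame, Body25Index.R_HIP, min_confidence)
        if l_hip is not None and r_hip is not None:
            width = math.hypot(l_hip.w - r_hip.w, l_hip.h - r_hip.h)
            if width > 0:
                hip_widths.append(width)
    if trunk_lengths:
        return float(np.median(trunk_lengths))
    if hip_widths:
        return float(2.0 * np.median(hip_widths))
    return float(default_scale)
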