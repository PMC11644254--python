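"""Per-frame posture classification into four fall directions.

The classifier is a deterministic rule cascade over the geometric features
of :mod:`fallpose.geometry`. Left/right falls have an unambiguous signature
— the trunk leaning far toward one image edge — and are split by the sign
of the trunk angle. Forward and backward falls share a *collapsed trunk*
signature (the mid-hip-to-neck height difference shrinks as the body
foreshortens toward or away from the camera) and are split by the head:
nose below neck says forward, nose clearly above neck says backward.

Three forward-fall indicator variants are selectable, reflecting how the
criterion degrades under face-keypoint loss:

``I_OPOSE``
    neck-to-nose height difference only (fails when the face is lost,
    e.g. head shadow in dim lighting);
``E_HN_OPOSE``
    waist(mid-hip)-to-neck height difference on a non-lateral trunk
    (works from the back, immune to face loss);
``E_OPOSE``
    the exact disjunction of the two, so frame-for-frame it fires whenever
    either component fires — its forward recall can never be below either
    component's on the same input.

Directions are camera-frame: ``FALL_LEFT`` means toward the image's left
edge, regardless of which way the subject is facing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml

from .geometry import (
    DEFAULT_BODY_SCALE,
    DEFAULT_MIN_CONFIDENCE,
    FrameFeatures,
    body_scale,
    compute_features,
)
from .pose_io import PoseSequence

__all__ = [
    "DetectorMethod",
    "PostureLabel",
    "ClassifierConfig",
    "forward_indicator",
    "classify_frame",
    "classify_sequence",
    "FALL_LABELS",
]


class DetectorMethod(str, Enum):
    """The three forward-fall detection criteria."""

    I_OPOSE = "i_opose"
    E_HN_OPOSE = "e_hn_opose"
    E_OPOSE = "e_opose"


class PostureLabel(str, Enum):
    """Per-frame posture classes: normal, the four fall directions, and an
    abstention label for frames with no usable skeleton evidence."""

    NORMAL = "normal"
    FALL_LEFT = "leftward_fall"
    FALL_RIGHT = "rightward_fall"
    FALL_BACK = "backward_fall"
    FALL_FORWARD = "forward_fall"
    UNKNOWN = "unknown"


#: The four directional fall labels, in enum order.
FALL_LABELS = (
    PostureLabel.FALL_LEFT,
    PostureLabel.FALL_RIGHT,
    PostureLabel.FALL_BACK,
    PostureLabel.FALL_FORWARD,
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the rule cascade.

    All pixel thresholds are expressed as fractions of the per-subject body
    scale so the same configuration serves near and far camera distances.

    Attributes
    ----------
    lying_hd_ratio
        Trunk height-difference ratio below which the trunk counts as
        collapsed (lying). Default 0.35: a trunk foreshortened to about a
        third of its standing extent.
    lateral_angle_deg
        Absolute trunk angle beyond which the lean counts as lateral.
    head_down_angle_deg
        Angular formulation of the head-down cue (|head angle| beyond this
        means nose below neck). Retained for experimentation; the default
        cascade uses the equivalent height-difference form.
    head_hd_ratio
        Head height-difference ratio threshold for the head-down test:
        ``head_hd < head_hd_ratio * scale`` reads as nose at or below the
        neck. Default 0.0, the literal head-below-neck criterion.
    min_confidence
        Keypoint confidence floor; lower detections are treated as missing.
    method
        Which forward-fall indicator variant drives the cascade.
    calibration_frames
        Number of leading frames used to estimate body scale.
    default_scale
        Pixel fallback when no calibration frame carries a usable trunk.
    """

    lying_hd_ratio: float = 0.35
    lateral_angle_deg: float = 45.0
    head_down_angle_deg: float = 90.0
    head_hd_ratio: float = 0.0
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    method: DetectorMethod = DetectorMethod.E_OPOSE
    calibration_frames: int = 10
    default_scale: float = DEFAULT_BODY_SCALE

    def __post_init__(self) -> None:
        if not 0.0 < self.lying_hd_ratio < 1.0:
            raise ValueError(f"lying_hd_ratio must be in (0, 1), got {self.lying_hd_ratio}")
        if not 0.0 < self.lateral_angle_deg < 180.0:
            raise ValueError(f"lateral_angle_deg must be in (0, 180), got {self.lateral_angle_deg}")
        if not 0.0 < self.head_down_angle_deg < 180.0:
            raise ValueError(
                f"head_down_angle_deg must be in (0, 180), got {self.head_down_angle_deg}"
            )
        if self.calibration_frames < 1:
            raise ValueError("calibration_frames must be >= 1")
        if not self.default_scale > 0:
            raise ValueError("default_scale must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ClassifierConfig":
        kwargs = dict(mapping)
        if "method" in kwargs and not isinstance(kwargs["method"], DetectorMethod):
            kwargs["method"] = DetectorMethod(str(kwargs["method"]).lower())
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ClassifierConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(doc)

    def with_method(self, method: DetectorMethod) -> "ClassifierConfig":
        return replace(self, method=method)


def forward_indicator(
    features: FrameFeatures,
    config: ClassifierConfig,
    method: Optional[DetectorMethod] = None,
) -> bool:
    """Evaluate one forward-fall criterion on one frame's features.

    An invalid contributing feature makes its disjunct false — the
    indicator never fabricates evidence from missing keypoints.
    """
    method = config.method if method is None else method
    scale = features.body_scale
    if method is DetectorMethod.I_OPOSE:
        return features.head_hd_valid and features.head_hd < config.head_hd_ratio * scale
    if method is DetectorMethod.E_HN_OPOSE:
        return (
            features.trunk_hd_valid
            and features.trunk_hd < config.lying_hd_ratio * scale
            and features.trunk_angle_valid
            and abs(features.trunk_angle) < config.lateral_angle_deg
        )
    if method is DetectorMethod.E_OPOSE:
        return forward_indicator(features, config, DetectorMethod.I_OPOSE) or forward_indicator(
            features, config, DetectorMethod.E_HN_OPOSE
        )
    raise ValueError(f"unknown detector method {method!r}")


def classify_frame(features: FrameFeatures, config: ClassifierConfig) -> PostureLabel:
    """Classify one frame's posture. Pure function of (features, config).

    Cascade, first match wins:

    1. no usable trunk and no forward evidence -> ``UNKNOWN``;
    2. trunk collapsed-or-lateral leaning far image-right -> ``FALL_RIGHT``;
    3. symmetrically image-left -> ``FALL_LEFT``;
    4. trunk collapsed, non-lateral, nose demonstrably *above* the neck ->
       ``FALL_BACK`` (positive head-up evidence beats the forward
       indicator, whose waist-to-neck variant cannot tell back from front);
    5. forward indicator fires -> ``FALL_FORWARD``;
    6. trunk collapsed (head evidence absent or neutral) -> ``FALL_BACK``;
    7. otherwise ``NORMAL``.
    """
    scale = features.body_scale
    trunk_valid = features.trunk_hd_valid and features.trunk_angle_valid
    forward = forward_indicator(features, config)

    if not trunk_valid:
        return PostureLabel.FALL_FORWARD if forward else PostureLabel.UNKNOWN

    collapsed = features.trunk_hd < config.lying_hd_ratio * scale
    lateral = abs(features.trunk_angle) > config.lateral_angle_deg

    if (collapsed or lateral) and features.trunk_angle >= config.lateral_angle_deg:
        return PostureLabel.FALL_RIGHT
    if (collapsed or lateral) and features.trunk_angle <= -config.lateral_angle_deg:
        return PostureLabel.FALL_LEFT
    if (
        collapsed
        and not lateral
        and features.head_hd_valid
        and features.head_hd > config.head_hd_ratio * scale
    ):
        return PostureLabel.FALL_BACK
    if forward:
        return PostureLabel.FALL_FORWARD
    if collapsed and not lateral:
        return PostureLabel.FALL_BACK
    return PostureLabel.NORMAL


def classify_sequence(
    seq: PoseSequence,
    config: Optional[ClassifierConfig] = None,
) -> list[PostureLabel]:
    """Classify every frame of a sequence.

    Body scale is estimated once from the first ``config.calibration_frames``
    frames (assumed to capture the subject before any fall) and held fixed,
    so the lying phase does not contaminate its own threshold denominator.
    """
    config = config or ClassifierConfig()
    if len(seq) == 0:
        return []
    window = seq.frames[: config.calibration_frames]
    scale = body_scale(
        window,
        min_confidence=config.min_confidence,
        default_scale=config.default_scale,
    )
    return [
        classify_frame(compute_features(frame, scale, config.min_confidence), config)
        for frame in seq.frames
    ]
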