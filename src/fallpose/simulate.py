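"""Seeded generator of labeled BODY_25 fall sequences.

No public dataset of overhead-camera fall footage with BODY_25 annotations
exists at the scale these rules need, so the test substrate is simulated:
an articulated stick figure stands, falls in one of four directions with a
cosine-eased motion profile, and then lies still.

Kinematics, in image coordinates (y grows downward):

* **leftward / rightward falls** are rigid in-plane rotations of the whole
  skeleton about the ankle midpoint, from upright to -/+90 degrees;
* **forward / backward falls** happen out of the image plane, so their 2D
  signature is *foreshortening*: every keypoint's height above the ground
  line compresses progressively to a factor of 0.25. In a forward fall the
  head end additionally descends past the neck (head down, feet up in the
  image); in a backward fall the nose stays above the neck throughout.

Ground-truth labels come from the generator's own kinematic state — never
from the classifier under test: a frame is labeled with the scenario's
fall direction once the generated trunk height-difference ratio drops
below 0.35 or the rigid rotation exceeds 45 degrees; transition frames
before that are labeled NORMAL.

Measurement noise is modeled as i.i.d. Gaussian jitter on coordinates and
per-keypoint-group dropout (confidence forced to zero), with the face
group — nose, eyes, ears — the canonical victim of dim lighting. All
randomness is driven by the scenario seed; identical specs produce
bit-identical sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .classify import FALL_LABELS, PostureLabel
from .pose_io import Body25Index, N_KEYPOINTS, PoseFrame, PoseSequence

__all__ = [
    "ScenarioSpec",
    "LabeledSequence",
    "PROPORTIONS",
    "KEYPOINT_GROUPS",
    "PRESETS",
    "canonical_skeleton",
    "generate_sequence",
    "apply_noise_and_dropout",
    "simulate_scenario",
    "scenario_from_preset",
]

#: Canonical body proportions as fractions of subject height.
PROPORTIONS = {
    "head": 0.12,  # neck -> nose
    "trunk": 0.30,  # mid-hip -> neck
    "thigh": 0.25,
    "shin": 0.25,
    "shoulder_width": 0.25,
    "hip_width": 0.15,
    "ankle_clearance": 0.05,  # ankle height above the ground line
}

#: Keypoint groups addressable by the dropout model.
KEYPOINT_GROUPS: Dict[str, Tuple[Body25Index, ...]] = {
    "face": (
        Body25Index.NOSE,
        Body25Index.R_EYE,
        Body25Index.L_EYE,
        Body25Index.R_EAR,
        Body25Index.L_EAR,
    ),
    "torso": (
        Body25Index.NECK,
        Body25Index.MID_HIP,
        Body25Index.R_HIP,
        Body25Index.L_HIP,
        Body25Index.R_SHOULDER,
        Body25Index.L_SHOULDER,
    ),
    "arms": (
        Body25Index.R_ELBOW,
        Body25Index.R_WRIST,
        Body25Index.L_ELBOW,
        Body25Index.L_WRIST,
    ),
    "legs": (
        Body25Index.R_KNEE,
        Body25Index.R_ANKLE,
        Body25Index.L_KNEE,
        Body25Index.L_ANKLE,
        Body25Index.L_BIG_TOE,
        Body25Index.L_SMALL_TOE,
        Body25Index.L_HEEL,
        Body25Index.R_BIG_TOE,
        Body25Index.R_SMALL_TOE,
        Body25Index.R_HEEL,
    ),
}

_LYING_RATIO = 0.35  # truth criterion on generated trunk_hd / trunk length
_LATERAL_DEG = 45.0  # truth criterion on rigid rotation
_FINAL_COMPRESSION = 0.25  # foreshortening factor at full forward/backward collapse

_DIRECTIONS = {
    "none": None,
    "left": PostureLabel.FALL_LEFT,
    "right": PostureLabel.FALL_RIGHT,
    "back": PostureLabel.FALL_BACK,
    "forward": PostureLabel.FALL_FORWARD,
}


def _resolve_direction(direction) -> Optional[PostureLabel]:
    if direction is None:
        return None
    if isinstance(direction, PostureLabel):
        if direction is PostureLabel.NORMAL:
            return None
        if direction not in FALL_LABELS:
            raise ValueError(f"direction must be a fall label or none, got {direction}")
        return direction
    key = str(direction).lower()
    if key in _DIRECTIONS:
        return _DIRECTIONS[key]
    return _resolve_direction(PostureLabel(key))


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully seeded description of one synthetic sequence.

    ``direction`` is one of the four fall labels, a short alias
    (``"left"``, ``"right"``, ``"back"``, ``"forward"``) or ``"none"`` for
    pure standing. ``subject_height_px`` is the distance proxy: 400 px for
    the near preset, 240 px for far. ``dropout`` maps group names from
    :data:`KEYPOINT_GROUPS` to per-frame missing probabilities.
    """

    direction: str = "none"
    n_frames: int = 100
    fps: float = 10.0
    fall_start_frame: int = 20
    fall_duration_frames: int = 30
    subject_height_px: float = 400.0
    noise_sigma_px: float = 0.0
    dropout: Dict[str, float] = field(default_factory=dict)
    confidence_range: Tuple[float, float] = (0.7, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _resolve_direction(self.direction)  # validates
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.fall_start_frame < 0 or self.fall_duration_frames < 1:
            raise ValueError("fall_start_frame must be >= 0 and fall_duration_frames >= 1")
        if (
            _resolve_direction(self.direction) is not None
            and self.fall_start_frame + self.fall_duration_frames > self.n_frames
        ):
            raise ValueError("fall must fit inside the sequence")
        if not self.subject_height_px > 0:
            raise ValueError("subject_height_px must be positive")
        if self.noise_sigma_px < 0:
            raise ValueError("noise_sigma_px must be >= 0")
        for group, p in self.dropout.items():
            if group not in KEYPOINT_GROUPS:
                raise ValueError(f"unknown keypoint group {group!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability for {group!r} must be in [0, 1]")
        lo, hi = self.confidence_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("confidence_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class LabeledSequence:
    """A pose sequence paired with its per-frame ground-truth labels."""

    sequence: PoseSequence
    truth: list[PostureLabel]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.truth):
            raise ValueError("sequence and truth must have equal length")


def canonical_skeleton(
    height_px: float,
    center_x: float = 320.0,
    ground_y: float = 440.0,
) -> np.ndarray:
    """The upright reference pose: a ``(25, 2)`` array of pixel coordinates.

    Nose directly above neck directly above mid-hip (trunk angle exactly
    zero), hip line horizontal, subject facing the camera so the subject's
    right side sits at the image's left.
    """
    if not height_px > 0:
        raise ValueError("height_px must be positive")
    H = float(height_px)
    cx = float(center_x)

    def at(dx: float, h: float) -> Tuple[float, float]:
        # h is height above the ground line; image y grows downward
        return (cx + dx * H, ground_y - h * H)

    ankle_h = PROPORTIONS["ankle_clearance"]
    knee_h = ankle_h + PROPORTIONS["shin"]
    hip_h = knee_h + PROPORTIONS["thigh"]
    neck_h = hip_h + PROPORTIONS["trunk"]
    nose_h = neck_h + PROPORTIONS["head"]
    half_hip = PROPORTIONS["hip_width"] / 2.0
    half_shoulder = PROPORTIONS["shoulder_width"] / 2.0

    pts = np.zeros((N_KEYPOINTS, 2))
    pts[Body25Index.NOSE] = at(0.0, nose_h)
    pts[Body25Index.NECK] = at(0.0, neck_h)
    pts[Body25Index.R_SHOULDER] = at(-half_shoulder, neck_h)
    pts[Body25Index.R_ELBOW] = at(-half_shoulder, neck_h - 0.15)
    pts[Body25Index.R_WRIST] = at(-half_shoulder, neck_h - 0.30)
    pts[Body25Index.L_SHOULDER] = at(+half_shoulder, neck_h)
    pts[Body25Index.L_ELBOW] = at(+half_shoulder, neck_h - 0.15)
    pts[Body25Index.L_WRIST] = at(+half_shoulder, neck_h - 0.30)
    pts[Body25Index.MID_HIP] = at(0.0, hip_h)
    pts[Body25Index.R_HIP] = at(-half_hip, hip_h)
    pts[Body25Index.R_KNEE] = at(-half_hip, knee_h)
    pts[Body25Index.R_ANKLE] = at(-half_hip, ankle_h)
    pts[Body25Index.L_HIP] = at(+half_hip, hip_h)
    pts[Body25Index.L_KNEE] = at(+half_hip, knee_h)
    pts[Body25Index.L_ANKLE] = at(+half_hip, ankle_h)
    pts[Body25Index.R_EYE] = at(-0.02, nose_h + 0.02)
    pts[Body25Index.L_EYE] = at(+0.02, nose_h + 0.02)
    pts[Body25Index.R_EAR] = at(-0.04, nose_h + 0.01)
    pts[Body25Index.L_EAR] = at(+0.04, nose_h + 0.01)
    pts[Body25Index.L_BIG_TOE] = at(+half_hip + 0.03, 0.01)
    pts[Body25Index.L_SMALL_TOE] = at(+half_hip + 0.05, 0.01)
    pts[Body25Index.L_HEEL] = at(+half_hip, 0.0)
    pts[Body25Index.R_BIG_TOE] = at(-half_hip - 0.03, 0.01)
    pts[Body25Index.R_SMALL_TOE] = at(-half_hip - 0.05, 0.01)
    pts[Body25Index.R_HEEL] = at(-half_hip, 0.0)
    return pts


def _eased_progress(spec: ScenarioSpec, frame_index: int) -> float:
    """Fall progress in [0, 1]: zero while standing, cosine-eased through
    the fall window, one while lying."""
    if frame_index < spec.fall_start_frame:
        return 0.0
    step = frame_index - spec.fall_start_frame + 1
    if step >= spec.fall_duration_frames:
        return 1.0
    u = step / spec.fall_duration_frames
    return (1.0 - math.cos(math.pi * u)) / 2.0


def _rotate_about(pts: np.ndarray, pivot: np.ndarray, theta_deg: float) -> np.ndarray:
    theta = math.radians(theta_deg)
    c, s = math.cos(theta), math.sin(theta)
    offsets = pts - pivot
    rotated = np.empty_like(offsets)
    rotated[:, 0] = offsets[:, 0] * c - offsets[:, 1] * s
    rotated[:, 1] = offsets[:, 0] * s + offsets[:, 1] * c
    return pivot + rotated


def _pose_at(
    spec: ScenarioSpec,
    base: np.ndarray,
    direction: Optional[PostureLabel],
    progress: float,
    ground_y: float,
) -> Tuple[np.ndarray, PostureLabel]:
    """Skeleton coordinates and truth label for one value of fall progress."""
    if direction is None or progress == 0.0:
        return base.copy(), PostureLabel.NORMAL

    if direction in (PostureLabel.FALL_LEFT, PostureLabel.FALL_RIGHT):
        sign = 1.0 if direction is PostureLabel.FALL_RIGHT else -1.0
        theta = sign * 90.0 * progress
        pivot = (base[Body25Index.R_ANKLE] + base[Body25Index.L_ANKLE]) / 2.0
        pts = _rotate_about(base, pivot, theta)
        truth = direction if abs(theta) > _LATERAL_DEG else PostureLabel.NORMAL
        return pts, truth

    # forward/backward: foreshortening toward the ground line
    sf = 1.0 - (1.0 - _FINAL_COMPRESSION) * progress
    pts = base.copy()
    pts[:, 1] = ground_y - (ground_y - base[:, 1]) * sf
    if direction is PostureLabel.FALL_FORWARD:
        # the head end swings past the neck: above it at progress 0,
        # symmetric distance below it at progress 1
        neck_y = pts[Body25Index.NECK, 1]
        for idx in KEYPOINT_GROUPS["face"]:
            delta = base[Body25Index.NECK, 1] - base[idx, 1]  # > 0, head above neck
            pts[idx, 1] = neck_y + delta * sf * (2.0 * progress - 1.0)
    # the compression factor *is* the generated trunk_hd / trunk-length ratio
    truth = direction if sf < _LYING_RATIO else PostureLabel.NORMAL
    return pts, truth


def generate_sequence(spec: ScenarioSpec) -> LabeledSequence:
    """Generate the clean (noise-free, dropout-free) labeled sequence.

    Confidences are drawn uniformly from ``spec.confidence_range`` — real
    detectors never report certainty — from a generator derived from
    ``spec.seed``, so the output is bit-identical across calls.
    """
    rng = np.random.default_rng([spec.seed, 0])
    direction = _resolve_direction(spec.direction)
    ground_y = 440.0
    base = canonical_skeleton(spec.subject_height_px, ground_y=ground_y)

    frames: list[PoseFrame] = []
    truth: list[PostureLabel] = []
    lo, hi = spec.confidence_range
    for i in range(spec.n_frames):
        progress = _eased_progress(spec, i)
        pts, label = _pose_at(spec, base, direction, progress, ground_y)
        conf = rng.uniform(lo, hi, size=N_KEYPOINTS)
        kp = np.column_stack([pts, conf])
        frames.append(PoseFrame(timestamp=i / spec.fps, keypoints=kp))
        truth.append(label)

    metadata = {
        "source": "fallpose-simulator",
        "fps": spec.fps,
        "direction": spec.direction,
        "seed": spec.seed,
        "subject_height_px": spec.subject_height_px,
    }
    return LabeledSequence(
        sequence=PoseSequence(frames=frames, metadata=metadata),
        truth=truth,
    )


def apply_noise_and_dropout(labeled: LabeledSequence, spec: ScenarioSpec) -> LabeledSequence:
    """Corrupt a labeled sequence per the scenario's noise model.

    Per keypoint per frame: with its group's dropout probability the
    keypoint goes missing (confidence 0, coordinates 0 by the upstream
    convention); otherwise independent Gaussian jitter of standard
    deviation ``noise_sigma_px`` is added to both coordinates. Truth labels
    are untouched. The corruption stream is seeded independently of the
    generation stream, both from ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    p = np.zeros(N_KEYPOINTS)
    for group, prob in spec.dropout.items():
        for idx in KEYPOINT_GROUPS[group]:
            p[idx] = prob

    frames: list[PoseFrame] = []
    for frame in labeled.sequence.frames:
        kp = frame.keypoints.copy()
        dropped = rng.uniform(size=N_KEYPOINTS) < p
        jitter = rng.normal(0.0, 1.0, size=(N_KEYPOINTS, 2))
        if spec.noise_sigma_px > 0:
            kp[:, :2] += spec.noise_sigma_px * jitter
        kp[dropped, :] = 0.0
        frames.append(PoseFrame(timestamp=frame.timestamp, keypoints=kp))
    seq = PoseSequence(frames=frames, metadata=dict(labeled.sequence.metadata))
    return LabeledSequence(sequence=seq, truth=list(labeled.truth))


def simulate_scenario(spec: ScenarioSpec) -> LabeledSequence:
    """Generate and corrupt in one step: the full scenario pipeline."""
    return apply_noise_and_dropout(generate_sequence(spec), spec)


#: Named scenario presets. ``near``/``far`` vary the subject's pixel height
#: (camera distance proxy); the lighting presets vary jitter and face
#: dropout — dim lighting is modeled as losing 70% of face keypoints;
#: the background presets only widen the confidence spread, since skeleton
#: input abstracts the background away.
PRESETS: Dict[str, dict] = {
    "clean": {},
    "near": {"subject_height_px": 400.0, "noise_sigma_px": 1.0, "dropout": {"face": 0.1, "arms": 0.05, "legs": 0.05}},
    "far": {"subject_height_px": 240.0, "noise_sigma_px": 1.0, "dropout": {"face": 0.15, "arms": 0.05, "legs": 0.05}},
    "overexposed": {"noise_sigma_px": 1.5, "dropout": {"face": 0.3}},
    "normal_light": {"noise_sigma_px": 1.0, "dropout": {"face": 0.05}},
    "dim": {"noise_sigma_px": 1.5, "dropout": {"face": 0.7}},
    "similar_background": {"noise_sigma_px": 1.0, "confidence_range": (0.5, 1.0)},
    "different_background": {"noise_sigma_px": 1.0, "confidence_range": (0.5, 1.0), "dropout": {"arms": 0.05}},
}


def scenario_from_preset(
    preset: str,
    direction: str = "none",
    seed: int = 0,
    **overrides,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a named preset.

    Raises
    ------
    KeyError
        For an unknown preset name.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return ScenarioSpec(direction=direction, seed=seed, **kwargs)
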