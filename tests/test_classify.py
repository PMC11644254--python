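"""Rule cascade and the three forward-fall detector variants."""

import math

import numpy as np
import pytest

from fallpose import (
    Body25Index,
    ClassifierConfig,
    DetectorMethod,
    FrameFeatures,
    PoseFrame,
    PoseSequence,
    PostureLabel,
    classify_frame,
    classify_sequence,
    forward_indicator,
    scenario_from_preset,
    simulate_scenario,
)


def make_features(
    trunk_angle=0.0,
    head_angle=0.0,
    hip_line_angle=90.0,
    trunk_hd=None,
    head_hd=48.0,
    scale=120.0,
    trunk_valid=True,
    head_valid=True,
    hip_valid=True,
):
    trunk_hd = scale if trunk_hd is None else trunk_hd
    return FrameFeatures(
        trunk_angle=trunk_angle if trunk_valid else math.nan,
        head_angle=head_angle if head_valid else math.nan,
        hip_line_angle=hip_line_angle if hip_valid else math.nan,
        trunk_hd=trunk_hd if trunk_valid else math.nan,
        head_hd=head_hd if head_valid else math.nan,
        body_scale=scale,
        trunk_angle_valid=trunk_valid,
        head_angle_valid=head_valid,
        hip_line_angle_valid=hip_valid,
        trunk_hd_valid=trunk_valid,
        head_hd_valid=head_valid,
    )


CONFIG = ClassifierConfig()


class TestForwardIndicator:
    def test_head_down_frame_fires_neck_nose_criterion(self):
        feats = make_features(head_hd=-20.0, trunk_hd=30.0)
        assert forward_indicator(feats, CONFIG, DetectorMethod.I_OPOSE) is True

    def test_nose_dropped_shifts_detection_to_trunk_criterion(self):
        # same collapsed frame, but the face is lost (dim lighting):
        # the neck-nose variant goes blind, the waist-neck variant still fires,
        # and the disjunctive variant inherits the detection.
        feats = make_features(head_valid=False, trunk_hd=0.1 * 120.0)
        assert forward_indicator(feats, CONFIG, DetectorMethod.I_OPOSE) is False
        assert forward_indicator(feats, CONFIG, DetectorMethod.E_HN_OPOSE) is True
        assert forward_indicator(feats, CONFIG, DetectorMethod.E_OPOSE) is True

    def test_standing_frame_fires_nothing(self):
        feats = make_features()
        for method in DetectorMethod:
            assert forward_indicator(feats, CONFIG, method) is False

    def test_lateral_trunk_blocks_waist_neck_criterion(self):
        feats = make_features(trunk_angle=80.0, trunk_hd=10.0, head_hd=5.0)
        assert forward_indicator(feats, CONFIG, DetectorMethod.E_HN_OPOSE) is False

    def test_disjunction_identity_on_random_features(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            feats = make_features(
                trunk_angle=float(rng.uniform(-180, 180)),
                trunk_hd=float(rng.uniform(-60, 130)),
                head_hd=float(rng.uniform(-60, 60)),
                trunk_valid=bool(rng.random() > 0.2),
                head_valid=bool(rng.random() > 0.2),
            )
            expected = forward_indicator(feats, CONFIG, DetectorMethod.I_OPOSE) or forward_indicator(
                feats, CONFIG, DetectorMethod.E_HN_OPOSE
            )
            assert forward_indicator(feats, CONFIG, DetectorMethod.E_OPOSE) == expected


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "features, expected",
        [
            # collapsed + far right lean
            (make_features(trunk_angle=80.0, trunk_hd=0.1 * 120, head_hd=0.0), PostureLabel.FALL_RIGHT),
            (make_features(trunk_angle=-80.0, trunk_hd=0.1 * 120, head_hd=0.0), PostureLabel.FALL_LEFT),
            # collapsed, near-vertical trunk, nose above neck: a rear fall
            (make_features(trunk_angle=5.0, trunk_hd=0.12 * 120, head_hd=14.0), PostureLabel.FALL_BACK),
            # collapsed, nose below neck: a forward fall
            (make_features(trunk_angle=5.0, trunk_hd=0.12 * 120, head_hd=-14.0), PostureLabel.FALL_FORWARD),
            # upright standing
            (make_features(trunk_angle=0.0, trunk_hd=0.9 * 120), PostureLabel.NORMAL),
            # lateral lean without collapse still reads as a lateral fall
            (make_features(trunk_angle=60.0, trunk_hd=0.6 * 120, head_hd=20.0), PostureLabel.FALL_RIGHT),
            # no evidence at all
            (make_features(trunk_valid=False, head_valid=False, hip_valid=False), PostureLabel.UNKNOWN),
            # trunk lost but the head criterion still fires (forward under occlusion)
            (make_features(trunk_valid=False, head_hd=-20.0), PostureLabel.FALL_FORWARD),
            # collapsed with the face lost: rear fall needs no facial keypoints,
            # but the default disjunctive method claims it forward via the trunk
            (make_features(trunk_angle=0.0, trunk_hd=0.1 * 120, head_valid=False), PostureLabel.FALL_FORWARD),
        ],
    )
    def test_cascade(self, features, expected):
        assert classify_frame(features, CONFIG) is expected

    def test_collapsed_face_lost_is_backward_under_head_only_method(self):
        feats = make_features(trunk_angle=0.0, trunk_hd=0.1 * 120, head_valid=False)
        config = CONFIG.with_method(DetectorMethod.I_OPOSE)
        assert classify_frame(feats, config) is PostureLabel.FALL_BACK

    def test_pure_function(self):
        feats = make_features(trunk_angle=50.0, trunk_hd=30.0)
        assert classify_frame(feats, CONFIG) is classify_frame(feats, CONFIG)


def _reflect(seq: PoseSequence, axis: float = 320.0) -> PoseSequence:
    frames = []
    for frame in seq.frames:
        kp = frame.keypoints.copy()
        present = kp[:, 2] > 0
        kp[present, 0] = 2 * axis - kp[present, 0]
        frames.append(PoseFrame(timestamp=frame.timestamp, keypoints=kp))
    return PoseSequence(frames=frames, metadata=dict(seq.metadata))


_SWAP = {
    PostureLabel.FALL_LEFT: PostureLabel.FALL_RIGHT,
    PostureLabel.FALL_RIGHT: PostureLabel.FALL_LEFT,
}


class TestClassifySequence:
    def test_empty_sequence_yields_empty_labels(self):
        assert classify_sequence(PoseSequence(frames=[])) == []

    def test_standing_frames_are_all_normal(self, clean_sequence):
        labeled = clean_sequence("none", n_frames=5)
        assert classify_sequence(labeled.sequence) == [PostureLabel.NORMAL] * 5

    def test_clean_rightward_fall_pattern(self, clean_sequence):
        labeled = clean_sequence("right")
        labels = classify_sequence(labeled.sequence)
        assert labels[0] is PostureLabel.NORMAL
        assert labels[-1] is PostureLabel.FALL_RIGHT
        # lying phase matches ground truth exactly
        for got, want in zip(labels, labeled.truth):
            if want is not PostureLabel.NORMAL:
                assert got is want

    @pytest.mark.parametrize("method", list(DetectorMethod))
    def test_clean_forward_fall_detected_by_every_method(self, clean_sequence, method):
        labeled = clean_sequence("forward")
        labels = classify_sequence(labeled.sequence, ClassifierConfig(method=method))
        lying = [l for l, t in zip(labels, labeled.truth) if t is PostureLabel.FALL_FORWARD]
        assert lying and all(l is PostureLabel.FALL_FORWARD for l in lying)

    @pytest.mark.parametrize("direction", ["left", "right", "back", "forward"])
    def test_mirror_symmetry_swaps_lateral_labels(self, direction):
        spec = scenario_from_preset("normal_light", direction=direction, seed=23)
        labeled = simulate_scenario(spec)
        original = classify_sequence(labeled.sequence)
        mirrored = classify_sequence(_reflect(labeled.sequence))
        assert mirrored == [_SWAP.get(label, label) for label in original]
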