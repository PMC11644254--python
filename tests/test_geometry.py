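"""Geometric feature primitives: angles, height differences, body scale."""

import math

import numpy as np
import pytest

from fallpose import (
    Body25Index,
    PoseFrame,
    body_scale,
    canonical_skeleton,
    compute_features,
    height_difference,
    segment_vertical_angle,
)
from fallpose.geometry import DegenerateGeometryError, Point2D, wrap_degrees

from conftest import standing_frame


def oracle_vertical_angle(a, b):
    """Independent oracle: magnitude from the dot product of the normalized
    A->B direction with the on-screen 'up' vector, sign from the horizontal
    offset (the 2D cross product with 'up')."""
    dw, dh = b[0] - a[0], b[1] - a[1]
    norm = math.hypot(dw, dh)
    cos_theta = max(-1.0, min(1.0, -dh / norm))  # up on screen is (0, -1)
    magnitude = math.degrees(math.acos(cos_theta))
    if dw > 0:
        return magnitude
    if dw < 0:
        return -magnitude
    return magnitude  # exactly vertical: 0 (B above A) or 180 (B below A)


class TestSegmentVerticalAngle:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((100.0, 150.0), (100.0, 50.0), 0.0),  # upright: A directly below B
            ((150.0, 100.0), (50.0, 100.0), -90.0),  # horizontal, A right of B
            ((50.0, 100.0), (150.0, 100.0), 90.0),  # horizontal, A left of B
            ((0.0, 1.0), (1.0, 0.0), 45.0),  # diagonal up-right
            ((100.0, 50.0), (100.0, 150.0), 180.0),  # inverted: wraps -180 -> +180
        ],
    )
    def test_exact_cases(self, a, b, expected):
        assert segment_vertical_angle(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = tuple(rng.uniform(-500, 500, 2))
            b = tuple(rng.uniform(-500, 500, 2))
            assert segment_vertical_angle(a, b) == pytest.approx(
                oracle_vertical_angle(a, b), abs=1e-9
            )

    def test_mirror_reflection_negates_angle(self):
        rng = np.random.default_rng(7)
        axis = 320.0
        for _ in range(200):
            a = tuple(rng.uniform(0, 640, 2))
            b = tuple(rng.uniform(0, 640, 2))
            angle = segment_vertical_angle(a, b)
            if abs(angle) == 180.0 or angle == 0.0:
                continue
            mirrored = segment_vertical_angle(
                (2 * axis - a[0], a[1]), (2 * axis - b[0], b[1])
            )
            assert mirrored == pytest.approx(-angle, abs=1e-9)

    def test_coincident_points_are_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            segment_vertical_angle((10.0, 20.0), (10.0, 20.0))

    def test_result_always_in_half_open_range(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            a = tuple(rng.integers(-5, 5, 2).astype(float))
            b = tuple(rng.integers(-5, 5, 2).astype(float))
            if a == b:
                continue
            angle = segment_vertical_angle(a, b)
            assert -180.0 < angle <= 180.0

    def test_wrap_degrees_maps_minus_180_to_plus_180(self):
        assert wrap_degrees(-180.0) == 180.0
        assert wrap_degrees(540.0) == 180.0
        assert wrap_degrees(-190.0) == 170.0


class TestHeightDifference:
    def test_basic_arithmetic(self):
        assert height_difference((100.0, 160.0), (100.0, 80.0)) == 80.0
        assert height_difference((5.0, 42.0), (5.0, 42.0)) == 0.0

    def test_antisymmetry_and_translation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = tuple(rng.uniform(-100, 100, 2))
            b = tuple(rng.uniform(-100, 100, 2))
            dx = float(rng.uniform(-50, 50))
            assert height_difference(a, b) == -height_difference(b, a)
            # shifting both points horizontally changes nothing
            assert height_difference((a[0] + dx, a[1]), (b[0] + dx, b[1])) == height_difference(a, b)

    def test_equivariance_under_vertical_scaling(self):
        a, b = (10.0, 30.0), (40.0, 12.0)
        assert height_difference((a[0], 2 * a[1]), (b[0], 2 * b[1])) == 2 * height_difference(a, b)


def _frame_with(points: dict, confidence: float = 0.9) -> PoseFrame:
    kp = np.zeros((25, 3))
    for index, (x, y) in points.items():
        kp[index] = [x, y, confidence]
    return PoseFrame(timestamp=0.0, keypoints=kp)


class TestBodyScale:
    def test_constant_standing_window(self):
        frames = [standing_frame(timestamp=float(i)) for i in range(10)]
        # canonical trunk is 0.30 x height = 120 px at height 400
        assert body_scale(frames) == pytest.approx(120.0)

    def test_even_count_median_is_mean_of_central_pair(self):
        def trunk_frame(length):
            return _frame_with(
                {Body25Index.NECK: (100.0, 100.0), Body25Index.MID_HIP: (100.0, 100.0 + length)}
            )

        frames = [trunk_frame(80.0), trunk_frame(100.0)] * 3
        assert body_scale(frames) == pytest.approx(90.0)

    def test_fallback_to_hip_width_when_neck_always_missing(self):
        frames = [
            _frame_with({Body25Index.L_HIP: (110.0, 160.0), Body25Index.R_HIP: (90.0, 160.0)})
            for _ in range(5)
        ]
        assert body_scale(frames) == pytest.approx(40.0)  # 2 x 20 px hip width

    def test_final_fallback_is_default_scale(self):
        frames = [PoseFrame.empty(float(i)) for i in range(3)]
        assert body_scale(frames, default_scale=77.0) == 77.0


class TestComputeFeatures:
    def test_canonical_standing_skeleton(self):
        feats = compute_features(standing_frame(), scale=120.0)
        assert feats.trunk_angle == pytest.approx(0.0, abs=1e-9)
        assert abs(feats.hip_line_angle) == pytest.approx(90.0, abs=1e-9)
        assert feats.trunk_hd == pytest.approx(120.0)  # trunk length, hip below neck
        assert feats.head_hd == pytest.approx(48.0)  # 0.12 x 400, nose above neck
        assert all(
            [
                feats.trunk_angle_valid,
                feats.head_angle_valid,
                feats.hip_line_angle_valid,
                feats.trunk_hd_valid,
                feats.head_hd_valid,
            ]
        )

    def test_missing_nose_invalidates_only_head_features(self):
        frame = standing_frame()
        frame.keypoints[Body25Index.NOSE] = [0.0, 0.0, 0.0]
        feats = compute_features(frame, scale=120.0)
        assert not feats.head_angle_valid and not feats.head_hd_valid
        assert feats.trunk_angle_valid and feats.trunk_hd_valid

    def test_mid_hip_reconstructed_from_hip_midpoint(self):
        frame = _frame_with(
            {
                Body25Index.NECK: (100.0, 80.0),
                Body25Index.R_HIP: (90.0, 160.0),
                Body25Index.L_HIP: (110.0, 160.0),
            }
        )
        feats = compute_features(frame, scale=80.0)
        assert feats.trunk_hd_valid
        assert feats.trunk_hd == pytest.approx(80.0)  # midpoint (100, 160) vs neck
        assert feats.trunk_angle == pytest.approx(0.0, abs=1e-9)

    def test_low_confidence_keypoint_is_never_read(self):
        frame = standing_frame()
        # a plausible-looking but sub-threshold nose must not leak into features
        frame.keypoints[Body25Index.NOSE] = [1e9, -1e9, 0.05]
        feats = compute_features(frame, scale=120.0, min_confidence=0.1)
        assert not feats.head_hd_valid
        assert math.isnan(feats.head_hd)

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_features(standing_frame(), scale=0.0)
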