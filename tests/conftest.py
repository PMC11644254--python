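import json

import numpy as np
import pytest

from fallpose import (
    ClassifierConfig,
    PoseFrame,
    scenario_from_preset,
    simulate_scenario,
)


@pytest.fixture
def default_config() -> ClassifierConfig:
    return ClassifierConfig()


@pytest.fixture
def clean_sequence():
    """Factory for clean (noise-free, dropout-free) labeled fall sequences."""

    def make(direction: str, seed: int = 0, **overrides):
        spec = scenario_from_preset("clean", direction=direction, seed=seed, **overrides)
        return simulate_scenario(spec)

    return make


@pytest.fixture
def openpose_file(tmp_path):
    """Factory writing an OpenPose-dialect JSON file from per-person flat
    keypoint arrays."""

    def write(name: str, people: list[list[float]]):
        path = tmp_path / name
        doc = {"version": 1.3, "people": [{"pose_keypoints_2d": p} for p in people]}
        path.write_text(json.dumps(doc))
        return path

    return write


def make_person(x: float = 100.0, y: float = 200.0, confidence: float = 0.9) -> list[float]:
    """A flat 75-float OpenPose person with every joint at (x, y)."""
    return [x, y, confidence] * 25


def standing_frame(timestamp: float = 0.0, height: float = 400.0) -> PoseFrame:
    """A fully confident canonical standing frame."""
    from fallpose import canonical_skeleton

    pts = canonical_skeleton(height)
    kp = np.column_stack([pts, np.full(25, 0.9)])
    return PoseFrame(timestamp=timestamp, keypoints=kp)
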