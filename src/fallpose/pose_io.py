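"""Data model and I/O for BODY_25 pose sequences.

The atomic unit is a :class:`PoseFrame`: one timestamped set of 25 keypoints
in image coordinates (origin top-left, ``y`` grows downward), each with a
detection confidence in ``[0, 1]``. A confidence of exactly zero marks a
*missing* keypoint; by the upstream OpenPose convention its coordinates are
stored as zero and carry no meaning.

Two on-disk formats are supported:

* the OpenPose per-frame JSON dialect (one file per frame, top-level
  ``"people"``, each person a flat ``"pose_keypoints_2d"`` array of
  75 floats = 25 x (x, y, confidence));
* the package's own JSONL sequence format: line 1 is a metadata object,
  every following line is ``{"t": <seconds>, "kp": [[x, y, c] x 25]}``.
  JSON float serialization is round-trip exact for IEEE doubles, so
  ``read(write(seq))`` reproduces every field bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Callable, Iterable, Iterator, NamedTuple, Sequence, Union

import numpy as np

__all__ = [
    "N_KEYPOINTS",
    "Body25Index",
    "Keypoint",
    "PoseFrame",
    "PoseSequence",
    "PoseFormatError",
    "read_openpose_json",
    "write_sequence_jsonl",
    "read_sequence_jsonl",
]

N_KEYPOINTS = 25
_FLOATS_PER_PERSON = 3 * N_KEYPOINTS

JSONL_FORMAT_NAME = "fallpose.pose-sequence"
JSONL_FORMAT_VERSION = 1


class PoseFormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


class Body25Index(IntEnum):
    """The 25 keypoint slots of the OpenPose BODY_25 topology.

    Indices follow the upstream output order. ``MID_HIP`` is itself a
    derived joint upstream (midpoint of the two hips), which is why the
    feature extractor can reconstruct it when absent.
    """

    NOSE = 0
    NECK = 1
    R_SHOULDER = 2
    R_ELBOW = 3
    R_WRIST = 4
    L_SHOULDER = 5
    L_ELBOW = 6
    L_WRIST = 7
    MID_HIP = 8
    R_HIP = 9
    R_KNEE = 10
    R_ANKLE = 11
    L_HIP = 12
    L_KNEE = 13
    L_ANKLE = 14
    R_EYE = 15
    L_EYE = 16
    R_EAR = 17
    L_EAR = 18
    L_BIG_TOE = 19
    L_SMALL_TOE = 20
    L_HEEL = 21
    R_BIG_TOE = 22
    R_SMALL_TOE = 23
    R_HEEL = 24


#: Face keypoints — the ones pose estimation loses first in dim lighting.
FACE_KEYPOINTS = (
    Body25Index.NOSE,
    Body25Index.R_EYE,
    Body25Index.L_EYE,
    Body25Index.R_EAR,
    Body25Index.L_EAR,
)


class Keypoint(NamedTuple):
    """A single 2D joint detection: pixel position plus confidence."""

    x: float
    y: float
    confidence: float

    @property
    def missing(self) -> bool:
        """True when the detector produced no usable estimate for this joint."""
        return self.confidence <= 0.0


@dataclass
class PoseFrame:
    """One timestamped BODY_25 skeleton.

    Parameters
    ----------
    timestamp
        Seconds from sequence start; finite and non-negative.
    keypoints
        ``(25, 3)`` float array, columns ``x, y, confidence``.
    """

    timestamp: float
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValueError(f"keypoints must have shape (25, 3), got {kp.shape}")
        if not (math.isfinite(self.timestamp) and self.timestamp >= 0.0):
            raise ValueError(f"timestamp must be finite and >= 0, got {self.timestamp}")
        conf = kp[:, 2]
        if np.any((conf < 0.0) | (conf > 1.0)):
            raise ValueError("keypoint confidences must lie in [0, 1]")
        present = conf > 0.0
        if not np.all(np.isfinite(kp[present, :2])):
            raise ValueError("coordinates of present keypoints must be finite")
        self.keypoints = kp

    def keypoint(self, index: Union[int, Body25Index]) -> Keypoint:
        x, y, c = self.keypoints[int(index)]
        return Keypoint(float(x), float(y), float(c))

    @classmethod
    def empty(cls, timestamp: float) -> "PoseFrame":
        """A frame in which every keypoint is missing (no person detected)."""
        return cls(timestamp=timestamp, keypoints=np.zeros((N_KEYPOINTS, 3)))


@dataclass
class PoseSequence:
    """An ordered run of pose frames with free-form provenance metadata."""

    frames: list[PoseFrame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[PoseFrame]:
        return iter(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)


def _mean_confidence(person: np.ndarray) -> float:
    return float(np.mean(person[:, 2]))


def select_person_max_mean_confidence(people: Sequence[np.ndarray]) -> int:
    """Default multi-person policy: highest mean keypoint confidence, ties
    broken in favour of the first-listed person."""
    best = 0
    best_score = _mean_confidence(people[0])
    for i, person in enumerate(people[1:], start=1):
        score = _mean_confidence(person)
        if score > best_score:
            best, best_score = i, score
    return best


PersonPolicy = Callable[[Sequence[np.ndarray]], int]


def read_openpose_json(
    paths: Iterable[Union[str, Path]],
    fps: float = 10.0,
    person_policy: PersonPolicy = select_person_max_mean_confidence,
) -> PoseSequence:
    """Load a sequence from per-frame OpenPose JSON files.

    Frame order is the order of ``paths``; OpenPose JSON carries no clock, so
    timestamps are synthesized as ``frame_index / fps``. A file with an empty
    ``"people"`` list yields a frame of 25 missing keypoints; a file with
    several people keeps exactly the one chosen by ``person_policy``.

    Raises
    ------
    PoseFormatError
        On malformed JSON, or a keypoint array whose length is not a
        multiple of 75, naming the offending file.
    """
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    frames: list[PoseFrame] = []
    for i, path in enumerate(paths):
        path = Path(path)
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise PoseFormatError(f"{path}: malformed JSON ({exc})") from exc
        people_raw = doc.get("people", [])
        people: list[np.ndarray] = []
        for person in people_raw:
            flat = person.get("pose_keypoints_2d", [])
            if len(flat) == 0 or len(flat) % _FLOATS_PER_PERSON != 0:
                raise PoseFormatError(
                    f"{path}: pose_keypoints_2d has length {len(flat)}, "
                    f"expected a multiple of {_FLOATS_PER_PERSON}"
                )
            people.append(np.asarray(flat[:_FLOATS_PER_PERSON], dtype=float).reshape(N_KEYPOINTS, 3))
        timestamp = i / fps
        if not people:
            frames.append(PoseFrame.empty(timestamp))
        else:
            chosen = people[person_policy(people)]
            frames.append(PoseFrame(timestamp=timestamp, keypoints=chosen))
    return PoseSequence(frames=frames, metadata={"source": "openpose-json", "fps": fps})


def write_sequence_jsonl(seq: PoseSequence, path: Union[str, Path]) -> None:
    """Write a sequence to the package JSONL format (metadata header line,
    then one ``{"t", "kp"}`` object per frame)."""
    path = Path(path)
    header = {
        "format": JSONL_FORMAT_NAME,
        "version": JSONL_FORMAT_VERSION,
        "metadata": seq.metadata,
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for frame in seq.frames:
            record = {"t": frame.timestamp, "kp": frame.keypoints.tolist()}
            fh.write(json.dumps(record) + "\n")


def read_sequence_jsonl(path: Union[str, Path]) -> PoseSequence:
    """Read a sequence written by :func:`write_sequence_jsonl`.

    Raises
    ------
    PoseFormatError
        If the header is absent or the declared format does not match, or a
        frame record violates the schema.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise PoseFormatError(f"{path}: missing JSONL header line")
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise PoseFormatError(f"{path}: malformed header ({exc})") from exc
        if header.get("format") != JSONL_FORMAT_NAME:
            raise PoseFormatError(
                f"{path}: not a {JSONL_FORMAT_NAME} file (format={header.get('format')!r})"
            )
        frames: list[PoseFrame] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                frame = PoseFrame(
                    timestamp=float(record["t"]),
                    keypoints=np.asarray(record["kp"], dtype=float),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise PoseFormatError(f"{path}:{lineno}: bad frame record ({exc})") from exc
            frames.append(frame)
    return PoseSequence(frames=frames, metadata=header.get("metadata", {}))
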