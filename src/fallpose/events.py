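"""Fall-event timeline: debounced onset/offset detection and severity.

Per-frame labels are noisy — pose estimators flicker — so a fall *event*
opens only after ``onset_frames`` consecutive fall-labeled frames and
closes only after ``release_frames`` consecutive normal frames (or at the
end of the sequence). ``UNKNOWN`` frames inside an open event are treated
as continuation: losing the skeleton mid-fall (occlusion, dim lighting)
must not terminate the record.

Severity is graded from how long the fall posture persisted — a proxy for
the subject being unable to get up: events at or beyond
``severe_after_s`` seconds are ``SEVERE``, shorter ones ``MODERATE``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .classify import FALL_LABELS, PostureLabel

__all__ = [
    "SeverityLevel",
    "FallEvent",
    "TrackerConfig",
    "track_events",
    "write_event_log",
    "read_event_log",
    "format_event_table",
]


class SeverityLevel(str, Enum):
    """Two-level fall severity, ordered MODERATE < SEVERE."""

    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class FallEvent:
    """One recorded fall: direction, time span and severity."""

    direction: PostureLabel
    t_start: float
    t_end: float
    duration: float
    severity: SeverityLevel

    def __post_init__(self) -> None:
        if self.direction not in FALL_LABELS:
            raise ValueError(f"event direction must be a fall label, got {self.direction}")
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")


@dataclass(frozen=True)
class TrackerConfig:
    """Debounce counts and the severity breakpoint.

    ``onset_frames`` / ``release_frames`` are consecutive-frame counts;
    ``severe_after_s`` is the duration (seconds) at which a fall is graded
    severe rather than moderate.
    """

    onset_frames: int = 3
    release_frames: int = 5
    severe_after_s: float = 8.0

    def __post_init__(self) -> None:
        if self.onset_frames < 1 or self.release_frames < 1:
            raise ValueError("onset_frames and release_frames must be >= 1")
        if not self.severe_after_s > 0:
            raise ValueError("severe_after_s must be positive")


def _severity(duration: float, config: TrackerConfig) -> SeverityLevel:
    return SeverityLevel.SEVERE if duration >= config.severe_after_s else SeverityLevel.MODERATE


def _modal_direction(votes: Sequence[PostureLabel]) -> PostureLabel:
    counts: dict[PostureLabel, int] = {}
    for label in votes:
        counts[label] = counts.get(label, 0) + 1
    # tie -> earliest-observed label wins (dict preserves insertion order)
    return max(counts, key=counts.get)


def track_events(
    labels: Sequence[PostureLabel],
    timestamps: Sequence[float],
    config: Optional[TrackerConfig] = None,
) -> list[FallEvent]:
    """Collapse a per-frame label stream into non-overlapping fall events.

    An event's ``t_start`` is the timestamp of the first frame of its
    confirming fall run; ``t_end`` is the timestamp of its last fall-labeled
    frame. Direction is the modal fall label over the event's frames.

    Raises
    ------
    ValueError
        If ``labels`` and ``timestamps`` differ in length or timestamps are
        not strictly increasing.
    """
    config = config or TrackerConfig()
    if len(labels) != len(timestamps):
        raise ValueError(
            f"labels ({len(labels)}) and timestamps ({len(timestamps)}) must match in length"
        )
    if any(b <= a for a, b in zip(timestamps, timestamps[1:])):
        raise ValueError("timestamps must be strictly increasing")

    events: list[FallEvent] = []
    open_event = False
    pending_start: Optional[int] = None  # first frame of a candidate onset run
    pending_count = 0
    votes: list[PostureLabel] = []
    start_index = 0
    last_fall_index = 0
    normal_run = 0

    def close() -> None:
        nonlocal open_event, votes
        t_start = float(timestamps[start_index])
        t_end = float(timestamps[last_fall_index])
        duration = t_end - t_start
        events.append(
            FallEvent(
                direction=_modal_direction(votes),
                t_start=t_start,
                t_end=t_end,
                duration=duration,
                severity=_severity(duration, config),
            )
        )
        open_event = False
        votes = []

    for i, label in enumerate(labels):
        is_fall = label in FALL_LABELS
        if not open_event:
            if is_fall:
                if pending_start is None:
                    pending_start = i
                pending_count += 1
                if pending_count >= config.onset_frames:
                    open_event = True
                    start_index = pending_start
                    votes = list(labels[pending_start : i + 1])
                    last_fall_index = i
                    normal_run = 0
                    pending_start, pending_count = None, 0
            else:
                # NORMAL and UNKNOWN both break a candidate onset run
                pending_start, pending_count = None, 0
        else:
            if is_fall:
                votes.append(label)
                last_fall_index = i
                normal_run = 0
            elif label is PostureLabel.NORMAL:
                normal_run += 1
                if normal_run >= config.release_frames:
                    close()
            # UNKNOWN inside an open event: continuation, counters untouched
    if open_event:
        close()
    return events


def write_event_log(
    events: Iterable[FallEvent],
    seq_metadata: Optional[dict],
    path: Union[str, Path],
) -> None:
    """Write events as JSONL, one object per event with a fixed field order
    (``direction, t_start, t_end, duration, severity, source``). Zero events
    produce an empty file body."""
    source = ""
    if seq_metadata:
        source = str(seq_metadata.get("source", ""))
    with Path(path).open("w") as fh:
        for event in events:
            record = {
                "direction": event.direction.value,
                "t_start": event.t_start,
                "t_end": event.t_end,
                "duration": event.duration,
                "severity": event.severity.value,
                "source": source,
            }
            fh.write(json.dumps(record) + "\n")


def read_event_log(path: Union[str, Path]) -> list[FallEvent]:
    """Read an event log written by :func:`write_event_log`."""
    events: list[FallEvent] = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            record = json.loads(line)
            events.append(
                FallEvent(
                    direction=PostureLabel(record["direction"]),
                    t_start=float(record["t_start"]),
                    t_end=float(record["t_end"]),
                    duration=float(record["duration"]),
                    severity=SeverityLevel(record["severity"]),
                )
            )
    return events


def format_event_table(events: Sequence[FallEvent]) -> str:
    """Human-readable table of events (the care record a monitor displays)."""
    if not events:
        return "no fall events detected"
    lines = [f"{'direction':<16}{'start [s]':>10}{'duration [s]':>14}{'severity':>10}"]
    for event in events:
        lines.append(
            f"{event.direction.value:<16}{event.t_start:>10.2f}"
            f"{event.duration:>14.2f}{event.severity.value:>10}"
        )
    return "\n".join(lines)
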