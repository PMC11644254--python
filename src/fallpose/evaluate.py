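"""Accuracy, confusion matrices and the method-comparison benchmark.

Accuracy is the plain fraction of exactly matching labels, ``correct /
total``. Direction accuracy is scored on *lying-phase* frames (ground
truth is a fall label): transition frames, where even a human annotator
hesitates, are excluded unless explicitly requested. An ``UNKNOWN``
prediction always counts as incorrect.

The benchmark harness regenerates seeded scenario batches, classifies them
with each requested forward-fall method, and reports per-(method, preset,
direction) confusion matrices. Because the per-sequence seeds depend only
on (preset, direction, index) — the stated rule is ``base seed + index`` —
every method sees byte-identical corrupted inputs, which is what makes the
disjunctive method's recall dominance a theorem rather than a tendency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Union

import json

import numpy as np
import pandas as pd

from .classify import (
    ClassifierConfig,
    DetectorMethod,
    FALL_LABELS,
    PostureLabel,
    classify_sequence,
)
from .simulate import LabeledSequence, scenario_from_preset, simulate_scenario

__all__ = [
    "EvalReport",
    "accuracy",
    "confusion",
    "evaluate_labeled",
    "run_benchmark",
    "reports_to_dataframe",
    "write_reports",
]

LABEL_ORDER = list(PostureLabel)
_LABEL_POS = {label: i for i, label in enumerate(LABEL_ORDER)}


def accuracy(predicted: Sequence[PostureLabel], truth: Sequence[PostureLabel]) -> float:
    """Fraction of exactly matching labels (an exact rational, as float).

    Raises
    ------
    ValueError
        On empty or length-mismatched inputs.
    """
    if len(predicted) == 0:
        raise ValueError("cannot compute accuracy of empty label lists")
    if len(predicted) != len(truth):
        raise ValueError(
            f"predicted ({len(predicted)}) and truth ({len(truth)}) must match in length"
        )
    correct = sum(p == t for p, t in zip(predicted, truth))
    return float(Fraction(correct, len(predicted)))


@dataclass
class EvalReport:
    """Confusion-matrix evaluation of one (scenario, method) condition.

    ``confusion_matrix`` is a 6x6 count array, rows = truth, columns =
    prediction, both in :class:`PostureLabel` enum order. ``per_class``
    maps each truth label that occurs to its recall; absent classes map to
    ``None``.
    """

    confusion_matrix: np.ndarray
    n_instances: int
    overall_accuracy: float
    per_class: Dict[PostureLabel, Optional[float]]
    scenario: str = ""
    method: str = ""

    def recall(self, label: PostureLabel) -> Optional[float]:
        return self.per_class[label]

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "method": self.method,
            "n_instances": self.n_instances,
            "overall_accuracy": round(self.overall_accuracy, 4),
            "per_class": {
                label.value: (None if v is None else round(v, 4))
                for label, v in self.per_class.items()
            },
            "confusion_matrix": self.confusion_matrix.tolist(),
            "label_order": [label.value for label in LABEL_ORDER],
        }


def confusion(
    predicted: Sequence[PostureLabel],
    truth: Sequence[PostureLabel],
    scenario: str = "",
    method: str = "",
) -> EvalReport:
    """Full 6x6 confusion matrix plus overall and per-class accuracy."""
    overall = accuracy(predicted, truth)  # validates lengths / emptiness
    matrix = np.zeros((len(LABEL_ORDER), len(LABEL_ORDER)), dtype=int)
    for p, t in zip(predicted, truth):
        matrix[_LABEL_POS[t], _LABEL_POS[p]] += 1
    per_class: Dict[PostureLabel, Optional[float]] = {}
    for label in LABEL_ORDER:
        row = matrix[_LABEL_POS[label]]
        total = int(row.sum())
        per_class[label] = None if total == 0 else float(Fraction(int(row[_LABEL_POS[label]]), total))
    return EvalReport(
        confusion_matrix=matrix,
        n_instances=len(predicted),
        overall_accuracy=overall,
        per_class=per_class,
        scenario=scenario,
        method=method,
    )


def evaluate_labeled(
    labeled: LabeledSequence,
    config: Optional[ClassifierConfig] = None,
    include_transition: bool = False,
) -> EvalReport:
    """Classify one labeled sequence and score it against its ground truth.

    By default only lying-phase frames (truth is a fall label) are scored.
    """
    config = config or ClassifierConfig()
    predicted = classify_sequence(labeled.sequence, config)
    pairs = list(zip(predicted, labeled.truth))
    if not include_transition:
        pairs = [(p, t) for p, t in pairs if t in FALL_LABELS]
    if not pairs:
        raise ValueError("no frames to evaluate (no lying-phase frames in truth)")
    pred, truth = zip(*pairs)
    return confusion(pred, truth, method=config.method.value)


DEFAULT_DIRECTIONS = ("left", "right", "back", "forward")


def run_benchmark(
    methods: Sequence[DetectorMethod],
    presets: Sequence[str],
    n_sequences: int,
    seed: int,
    directions: Sequence[str] = DEFAULT_DIRECTIONS,
    config: Optional[ClassifierConfig] = None,
    include_transition: bool = False,
    n_frames: int = 100,
) -> list[EvalReport]:
    """Run the scenario-grid benchmark.

    For every (preset, direction), ``n_sequences`` scenarios are simulated
    with per-sequence seed ``seed + index``, then classified once per
    method; frames are pooled across a condition's sequences into one
    report per (method, preset, direction), with ``scenario`` set to
    ``"<preset>:<direction>"``.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    base_config = config or ClassifierConfig()
    reports: list[EvalReport] = []
    for preset in presets:
        for direction in directions:
            batch = [
                simulate_scenario(
                    scenario_from_preset(preset, direction=direction, seed=seed + k, n_frames=n_frames)
                )
                for k in range(n_sequences)
            ]
            for method in methods:
                method_config = base_config.with_method(method)
                pred_all: list[PostureLabel] = []
                truth_all: list[PostureLabel] = []
                for labeled in batch:
                    predicted = classify_sequence(labeled.sequence, method_config)
                    for p, t in zip(predicted, labeled.truth):
                        if include_transition or t in FALL_LABELS:
                            pred_all.append(p)
                            truth_all.append(t)
                reports.append(
                    confusion(
                        pred_all,
                        truth_all,
                        scenario=f"{preset}:{direction}",
                        method=method.value,
                    )
                )
    return reports


def reports_to_dataframe(reports: Iterable[EvalReport]) -> pd.DataFrame:
    """Flatten reports into one row per report for CSV export."""
    rows = []
    for report in reports:
        row = {
            "scenario": report.scenario,
            "method": report.method,
            "n_instances": report.n_instances,
            "overall_accuracy": round(report.overall_accuracy, 4),
        }
        for label in LABEL_ORDER:
            v = report.per_class[label]
            row[f"recall_{label.value}"] = "" if v is None else round(v, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(
    reports: Sequence[EvalReport],
    csv_path: Optional[Union[str, Path]] = None,
    json_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write benchmark reports as CSV and/or JSON, deterministically."""
    if csv_path is not None:
        reports_to_dataframe(reports).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = [report.to_dict() for report in reports]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
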