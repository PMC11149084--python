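"""Species-set scoring: precision, recall, F1."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True)
class EvaluationResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def normalize_name(name: str) -> str:
    return " ".join(name.casefold().split())


def score_species_sets(
    predicted: Iterable[str], truth: Iterable[str]
) -> EvaluationResult:
    """Score a predicted species set against the ground-truth set.

    Identity is by normalized name (case-folded, whitespace-collapsed).
    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    empty denominators give 0.
    """
    pred = {normalize_name(s) for s in predicted}
    true = {normalize_name(s) for s in truth}
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return EvaluationResult(tp, fp, fn, precision, recall, f1)
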