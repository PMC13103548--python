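"""Segment- and subject-level evaluation.

SZ is the positive class throughout. Subject-level scoring uses the
rare-event rule: a subject counts as correctly recognized only if strictly
more than 95% of their segments are classified correctly (a 5% fault
tolerance motivated by treating larger error bursts as non-random).
Incorrect subjects enter the subject-level confusion matrix under the
flipped label — the paper-style convention that lets a full 2x2 table be
reported from a correctness rule.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .types import LABELS, ParameterError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Fractions in [0, 1]; NaN marks an undefined ratio (zero denominator)."""

    acc: float
    pre: float
    rec: float
    spec: float
    f1: float

    def as_percent(self) -> Dict[str, Optional[float]]:
        """Percentages to one decimal, half-up, matching tabular convention."""
        return {k: percent(getattr(self, k)) for k in ("acc", "pre", "rec", "spec", "f1")}


def percent(frac: float, decimals: int = 1) -> Optional[float]:
    """Fraction -> percentage, half-up rounding. Tables use one decimal;
    subject-level accuracies are conventionally quoted with two."""
    if frac is None or math.isnan(frac):
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(frac * 100)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_counts(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    """Exact tallies with SZ positive."""
    if len(y_true) != len(y_pred):
        raise ParameterError("y_true and y_pred must have equal length")
    bad = {l for l in list(y_true) + list(y_pred) if l not in LABELS}
    if bad:
        raise ParameterError(f"unknown label(s): {sorted(bad)}")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == "SZ":
            if p == "SZ":
                tp += 1
            else:
                fn += 1
        else:
            if p == "SZ":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, specificity, F1 from the 2x2 table."""
    if c.total == 0:
        raise ParameterError("all-zero confusion counts")
    acc = (c.tp + c.tn) / c.total
    pre = _ratio(c.tp, c.tp + c.fp, "precision")
    rec = _ratio(c.tp, c.tp + c.fn, "recall")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    if math.isnan(pre) or math.isnan(rec) or pre + rec == 0:
        warnings.warn("F1 undefined; reporting NaN")
        f1 = float("nan")
    else:
        f1 = 2 * pre * rec / (pre + rec)
    return MetricsReport(acc=acc, pre=pre, rec=rec, spec=spec, f1=f1)


def f1_from_percent(pre_pct: float, rec_pct: float) -> float:
    """Harmonic mean of precision/recall given as percentages; returns %
    rounded to one decimal (the identity used to audit printed tables)."""
    f1 = 2 * pre_pct * rec_pct / (pre_pct + rec_pct)
    return percent(f1 / 100.0)


@dataclass(frozen=True)
class SubjectOutcome:
    subject_id: str
    label: str
    n_segments: int
    n_correct: int
    correct: bool
    assigned_label: str


def subject_level_eval(segment_results: Iterable[Tuple[str, str, str]],
                       threshold: float = 0.95
                       ) -> Tuple[List[SubjectOutcome], ConfusionCounts, float]:
    """Apply the rare-event subject rule to per-segment results.

    ``segment_results`` yields (subject_id, y_true, y_pred) per segment.
    A subject is correct iff fraction correct > threshold (strict: exactly
    95% does not qualify). Returns per-subject outcomes, the subject-level
    confusion (incorrect subjects under the flipped label) and the
    subject-level accuracy fraction.
    """
    per_subject: Dict[str, List[Tuple[str, str]]] = {}
    for sid, yt, yp in segment_results:
        if yt not in LABELS or yp not in LABELS:
            raise ParameterError(f"unknown label for subject {sid}")
        per_subject.setdefault(sid, []).append((yt, yp))
    if not per_subject:
        raise ParameterError("no segment results given")
    outcomes: List[SubjectOutcome] = []
    for sid in sorted(per_subject):
        pairs = per_subject[sid]
        labels = {yt for yt, _ in pairs}
        if len(labels) != 1:
            raise ParameterError(f"subject {sid} has inconsistent true labels")
        label = labels.pop()
        n = len(pairs)
        n_correct = sum(1 for yt, yp in pairs if yt == yp)
        ok = n_correct / n > threshold
        flipped = "HC" if label == "SZ" else "SZ"
        outcomes.append(SubjectOutcome(
            subject_id=sid, label=label, n_segments=n, n_correct=n_correct,
            correct=ok, assigned_label=label if ok else flipped))
    counts = confusion_counts([o.label for o in outcomes],
                              [o.assigned_label for o in outcomes])
    accuracy = sum(o.correct for o in outcomes) / len(outcomes)
    return outcomes, counts, accuracy
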