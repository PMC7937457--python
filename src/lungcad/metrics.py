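"""The five evaluation indicators under the study's label convention.

The *positive* class here is the NORMAL lung image (label 0) — the reverse
of the usual clinical convention.  Concretely: TP counts normal images
predicted normal, FP tumor images predicted normal, TN tumor predicted
tumor, FN normal predicted tumor.  "Sensitivity" is therefore the recall
of the normal class and "specificity" the recall of the tumor class; the
report spells this out in its field metadata so downstream readers cannot
misread the columns.

The F1 score used throughout is the two-term macro form

    F1 = P·R/(P+R) + P′·R′/(P′+R′)

with P, R the normal-class precision/recall and P′, R′ the tumor-class
ones — each term is half that class's conventional F1, so a perfect
classifier scores 1.

``counts_from_rates`` inverts printed (sensitivity, specificity) pairs on
a balanced test set back into integer confusion counts, which is how the
published table rows are verified to be internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

NORMAL, TUMOR = 0, 1

__all__ = [
    "NORMAL",
    "TUMOR",
    "ConfusionCounts",
    "MetricsReport",
    "count_confusion",
    "accuracy",
    "sensitivity_specificity",
    "mcc",
    "f1_score",
    "counts_from_rates",
    "round_half_away",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with NORMAL as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The five indicators; undefined ratios are NaN and named in ``flags``."""

    accuracy: float
    sensitivity: float      # normal-class recall (study convention)
    specificity: float      # tumor-class recall
    mcc: float
    f1: float
    flags: List[str] = field(default_factory=list)

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricsReport":
        sens, spec, flags = _sens_spec_flagged(c)
        m, mflags = _mcc_flagged(c)
        f, fflags = _f1_flagged(c)
        return cls(accuracy=accuracy(c), sensitivity=sens, specificity=spec,
                   mcc=m, f1=f, flags=flags + mflags + fflags)

    def as_row(self, time_s: float = float("nan"), percent: bool = True):
        """Column order of the published tables: time, accuracy, error,
        sensitivity, specificity, MCC, F1 (rates optionally as percent)."""
        scale = 100.0 if percent else 1.0
        return {
            "time_s": time_s,
            "accuracy": self.accuracy * scale,
            "error": (1.0 - self.accuracy) * scale,
            "sensitivity": self.sensitivity * scale,
            "specificity": self.specificity * scale,
            "mcc": self.mcc,
            "f1": self.f1,
        }


def count_confusion(predicted, truth) -> ConfusionCounts:
    """Tally the four cells from parallel label sequences over {0, 1}."""
    predicted = np.asarray(predicted, int)
    truth = np.asarray(truth, int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    valid = np.isin(predicted, (NORMAL, TUMOR)) & np.isin(truth, (NORMAL, TUMOR))
    if not valid.all():
        raise ValueError("labels must be 0 (normal) or 1 (tumor)")
    return ConfusionCounts(
        tp=int(np.sum((truth == NORMAL) & (predicted == NORMAL))),
        fp=int(np.sum((truth == TUMOR) & (predicted == NORMAL))),
        tn=int(np.sum((truth == TUMOR) & (predicted == TUMOR))),
        fn=int(np.sum((truth == NORMAL) & (predicted == TUMOR))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / (TP+TN+FP+FN)."""
    if c.total == 0:
        raise ValueError("cannot compute accuracy of zero counts")
    return (c.tp + c.tn) / c.total


def _sens_spec_flagged(c: ConfusionCounts) -> Tuple[float, float, List[str]]:
    flags = []
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        sens, flags = math.nan, flags + ["sensitivity undefined: no normal cases"]
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        spec = math.nan
        flags = flags + ["specificity undefined: no tumor cases"]
    return sens, spec, flags


def sensitivity_specificity(c: ConfusionCounts) -> Tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); NaN where a class is absent."""
    sens, spec, _ = _sens_spec_flagged(c)
    return sens, spec


def _mcc_flagged(c: ConfusionCounts):
    # python ints: exact products, no overflow for any realistic count
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0, ["mcc marginal zero: reported as 0 (random-prediction reading)"]
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(denom2), []


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (flagged) on a zero marginal."""
    value, _ = _mcc_flagged(c)
    return value


def _f1_flagged(c: ConfusionCounts):
    flags = []

    def term(a, b, what):
        # a = precision-like, b = recall-like; both already checked finite
        if a + b == 0:
            flags.append(f"{what} term undefined (P+R = 0): contributed 0")
            return 0.0
        return a * b / (a + b)

    if c.tp + c.fp > 0 and c.tp + c.fn > 0:
        pos = term(c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn), "normal-class")
    else:
        flags.append("normal-class term undefined: contributed 0")
        pos = 0.0
    if c.fn + c.tn > 0 and c.tn + c.fp > 0:
        neg = term(c.tn / (c.fn + c.tn), c.tn / (c.tn + c.fp), "tumor-class")
    else:
        flags.append("tumor-class term undefined: contributed 0")
        neg = 0.0
    return pos + neg, flags


def f1_score(c: ConfusionCounts) -> float:
    """Two-term macro F1: P·R/(P+R) + P′·R′/(P′+R′); each term ≤ ½."""
    value, _ = _f1_flagged(c)
    return value


def counts_from_rates(sens: float, spec: float, n_pos: int, n_neg: int,
                      tol: float = 1e-9) -> ConfusionCounts:
    """Invert printed (sensitivity, specificity) into confusion counts.

    TP = sens·n_pos and TN = spec·n_neg must be integers up to ``tol``
    (printed rates are exact fractions of the class sizes); otherwise the
    nearest integer is taken.  Used to verify published table rows.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    tp_f, tn_f = sens * n_pos, spec * n_neg
    tp, tn = round(tp_f), round(tn_f)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero, the published tables' formatting."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
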