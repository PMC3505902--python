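"""Confusion-matrix construction and imbalance-aware performance statistics.

The substrate (minority) class is the positive class throughout.  Besides
standard accuracy the report carries the balanced accuracy
``(sensitivity + specificity) / 2``: on strongly imbalanced transporter
data the standard accuracy is dominated by the majority class, and
published model tables in this area typically quote the balanced variant
under the name "Accuracy".  Both are always reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with substrate = positive: tp, fp, tn, fn."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_substrates(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_substrates(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


def confusion(y_true, y_pred, positive: int = 1) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned binary label sequences."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if not y_true:
        raise ValueError("empty label sequences")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class MetricsReport:
    """The six statistics plus balanced accuracy and F-measure.

    Rates (sensitivity, specificity, accuracies) are fractions in [0, 1];
    ``as_percent`` re-expresses them on the percent scale.  Any metric
    whose denominator was zero is reported as 0 and listed in
    ``undefined``.
    """

    sensitivity: float
    specificity: float
    precision: float
    g_mean: float
    mcc: float
    accuracy: float
    accuracy_balanced: float
    f_measure: float
    confusion: ConfusionMatrix | None = None
    undefined: list[str] = field(default_factory=list)

    def as_percent(self) -> dict[str, float]:
        return {
            "sensitivity": 100.0 * self.sensitivity,
            "specificity": 100.0 * self.specificity,
            "accuracy": 100.0 * self.accuracy,
            "accuracy_balanced": 100.0 * self.accuracy_balanced,
        }

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "g_mean": self.g_mean,
            "mcc": self.mcc,
            "accuracy": self.accuracy,
            "accuracy_balanced": self.accuracy_balanced,
            "f_measure": self.f_measure,
            "undefined": list(self.undefined),
        }
        if self.confusion is not None:
            d["confusion"] = {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            }
        return d

    def round_display(self) -> dict[str, float]:
        """Report-table rounding: rates as percent to 2 dp, ratios to 2 dp."""
        return {
            "specificity_pct": round(100.0 * self.specificity, 2),
            "sensitivity_pct": round(100.0 * self.sensitivity, 2),
            "precision": round(self.precision, 2),
            "g_mean": round(self.g_mean, 2),
            "mcc": round(self.mcc, 2),
            "accuracy_pct": round(100.0 * self.accuracy, 2),
            "accuracy_balanced_pct": round(100.0 * self.accuracy_balanced, 2),
        }


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the statistics from a confusion matrix.

    Specificity = TN/(TN+FP); Sensitivity = TP/(TP+FN);
    Precision = TP/(TP+FP); G-mean = sqrt(Sensitivity x Specificity);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    Accuracy = (TN+TP)/n; balanced accuracy = (Sens + Spec)/2.
    Zero denominators yield 0, flagged in ``undefined``.
    """
    und: list[str] = []
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", und)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", und)
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision", und)
    g_mean = math.sqrt(sens * spec)
    mcc_den2 = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if mcc_den2 == 0:
        und.append("mcc")
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(mcc_den2)
    acc = _ratio(cm.tn + cm.tp, cm.n, "accuracy", und)
    bal = (sens + spec) / 2.0
    f_den = prec + sens
    if f_den == 0:
        und.append("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2.0 * prec * sens / f_den
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        g_mean=g_mean,
        mcc=mcc,
        accuracy=acc,
        accuracy_balanced=bal,
        f_measure=f_measure,
        confusion=cm,
        undefined=und,
    )
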