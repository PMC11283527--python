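"""Multiclass confusion matrices and the nine benchmark evaluation metrics.

From a K x K confusion matrix (rows = true class, columns = predicted),
per-class one-vs-rest counts TP/FP/FN/TN are derived and nine metrics are
evaluated per class, then aggregated:

    ACC = (TP+TN)/(TP+FN+FP+TN)     ER  = (FP+FN)/(TP+FN+FP+TN)
    SV  = TP/(TP+FN)                FNR = FN/(FN+TP)
    SP  = TN/(TN+FP)                FPR = FP/(FP+TN)
    PR  = TP/(TP+FP)                NPV = TN/(TN+FN)
    F1S = 2*SV*PR/(SV+PR)

Macro aggregation (unweighted class mean, the default) is symmetric under
class imbalance; micro aggregation (pool counts, then evaluate) is also
available.  Ratios with a zero denominator contribute 0 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METRIC_NAMES",
    "ConfusionMatrix",
    "MetricVector",
    "metrics_from_confusion",
]

#: Column order used everywhere a metric table is emitted.
METRIC_NAMES = ("ACC", "SV", "SP", "PR", "ER", "FPR", "FNR", "NPV", "F1S")


@dataclass
class ConfusionMatrix:
    """K x K counts of (true, predicted) class pairs."""

    counts: np.ndarray
    class_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_ids = [str(c) for c in self.class_ids]
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K with K = len(class_ids)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self, k: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) for class index ``k``."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = int(self.total - tp - fp - fn)
        return tp, fp, fn, tn

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_ids, columns=self.class_ids)


@dataclass
class MetricVector:
    """The nine evaluation metrics, each in [0, 1]."""

    ACC: float
    SV: float
    SP: float
    PR: float
    ER: float
    FPR: float
    FNR: float
    NPV: float
    F1S: float
    #: (class_id, metric) pairs where a zero denominator forced a 0 value.
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _safe_ratio(num: float, den: float, flags: list, cls: str, metric: str) -> float:
    if den == 0:
        flags.append((cls, metric))
        return 0.0
    return num / den


def _binary_metrics(
    tp: int, fp: int, fn: int, tn: int, cls: str, flags: list
) -> dict[str, float]:
    total = tp + fn + fp + tn
    sv = _safe_ratio(tp, tp + fn, flags, cls, "SV")
    pr = _safe_ratio(tp, tp + fp, flags, cls, "PR")
    return {
        "ACC": _safe_ratio(tp + tn, total, flags, cls, "ACC"),
        "SV": sv,
        "SP": _safe_ratio(tn, tn + fp, flags, cls, "SP"),
        "PR": pr,
        "ER": _safe_ratio(fp + fn, total, flags, cls, "ER"),
        "FPR": _safe_ratio(fp, fp + tn, flags, cls, "FPR"),
        "FNR": _safe_ratio(fn, fn + tp, flags, cls, "FNR"),
        "NPV": _safe_ratio(tn, tn + fn, flags, cls, "NPV"),
        "F1S": _safe_ratio(2.0 * sv * pr, sv + pr, flags, cls, "F1S"),
    }


def metrics_from_confusion(
    cm: ConfusionMatrix, average: str = "macro"
) -> MetricVector:
    """Evaluate the nine metrics from a multiclass confusion matrix.

    ``average="macro"`` evaluates the formulas per class one-vs-rest and
    takes the unweighted class mean; ``average="micro"`` pools the binary
    counts over classes first.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix has no observations")
    flags: list[tuple[str, str]] = []
    if average == "macro":
        per_class = [
            _binary_metrics(*cm.binary_counts(k), cm.class_ids[k], flags)
            for k in range(len(cm.class_ids))
        ]
        values = {
            name: float(np.mean([m[name] for m in per_class])) for name in METRIC_NAMES
        }
    elif average == "micro":
        pooled = np.sum(
            [cm.binary_counts(k) for k in range(len(cm.class_ids))], axis=0
        )
        values = _binary_metrics(*(int(v) for v in pooled), "<pooled>", flags)
    else:
        raise ValueError(f"unknown average {average!r}")
    return MetricVector(**values, undefined=flags)
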