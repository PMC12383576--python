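"""Imbalance-aware evaluation and distribution diagnostics.

Sensitivity (minority-class recall) and specificity (majority-class recall)
are the primary axes under extreme class imbalance; the G-mean
sqrt(sensitivity * specificity) summarises them symmetrically, so a
classifier that collapses onto the majority class scores 0 regardless of
accuracy.  Threshold-free ranking quality is reported as AUROC and AUPRC.

The skewness diagnostic uses the population-moment Fisher-Pearson
coefficient g1 = m3 / m2^(3/2); |g1| > 1 is flagged as highly skewed.  The
discretization report contrasts each raw feature's skewness with that of its
interval indices.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

from .data import TabularDataset
from .discretize import FeatureDiscretizer

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "g_mean",
    "metrics_report",
    "roc_pr_points",
    "fisher_pearson_skewness",
    "skewness_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    g_mean: float
    auroc: float
    auprc: float
    threshold: float
    counts: ConfusionCounts
    flags: list

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def g_mean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return float(np.sqrt(sensitivity * specificity))


def metrics_report(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Thresholded confusion metrics plus threshold-free AUROC / AUPRC.

    Precision and F1 with zero predicted positives are reported as 0 with a
    flag; a single-class truth vector flags AUROC/AUPRC as undefined (nan)
    rather than silently reporting 0.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    flags: list[str] = []
    y_pred = (scores > threshold).astype(int)
    c = confusion(y_true, y_pred)
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    if c.tp + c.fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = c.tp / (c.tp + c.fp)
    if precision + sens > 0 and np.isfinite(precision + sens):
        f1 = 2 * precision * sens / (precision + sens)
    else:
        f1 = 0.0
        flags.append("f1_undefined")
    gm = g_mean(sens, spec) if np.isfinite(sens) and np.isfinite(spec) else float("nan")
    if len(np.unique(y_true)) < 2:
        auroc = auprc = float("nan")
        flags.append("single_class_truth")
    else:
        auroc = float(skm.roc_auc_score(y_true, scores))
        auprc = float(skm.average_precision_score(y_true, scores))
    return MetricsReport(
        sensitivity=float(sens),
        specificity=float(spec),
        precision=float(precision),
        f1=float(f1),
        g_mean=gm,
        auroc=auroc,
        auprc=auprc,
        threshold=threshold,
        counts=c,
        flags=flags,
    )


def roc_pr_points(y_true, scores):
    """ROC and precision-recall curve points (ties grouped per threshold).

    Returns ``(roc, pr)`` where roc is a list of (FPR, TPR) and pr a list of
    (recall, precision), each ordered for direct plotting.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("curves require both classes present")
    fpr, tpr, _ = skm.roc_curve(y_true, scores)
    precision, recall, _ = skm.precision_recall_curve(y_true, scores)
    roc = list(zip(fpr.tolist(), tpr.tolist()))
    pr = list(zip(recall.tolist(), precision.tolist()))
    return roc, pr


def fisher_pearson_skewness(x, bias: bool = True, name: str = "x") -> float:
    """Fisher-Pearson moment coefficient of skewness g1 = m3 / m2^1.5.

    ``bias=True`` (default) is the population-moment form with no
    small-sample correction; ``bias=False`` applies the adjusted coefficient.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError(f"skewness of {name!r} needs at least 3 observations")
    if np.var(x) == 0:
        raise ValueError(f"skewness of {name!r} undefined: sample is constant")
    return float(sps.skew(x, bias=bias))


def skewness_report(
    ds: TabularDataset, discretizers: dict[str, FeatureDiscretizer]
) -> list[dict]:
    """Per-feature (raw skewness, interval-index skewness) in feature order.

    Features whose raw or discretized column is constant are flagged and
    their skewness reported as None.
    """
    rows = []
    for name in ds.flagged_features:
        x = ds.X[name].to_numpy(dtype=float)
        entry = {"feature": name, "raw": None, "discretized": None, "flags": []}
        try:
            entry["raw"] = fisher_pearson_skewness(x, name=name)
            entry["highly_skewed_raw"] = abs(entry["raw"]) > 1
        except ValueError:
            entry["flags"].append("constant_raw")
        disc = discretizers.get(name)
        if disc is None:
            entry["flags"].append("no_discretizer")
        else:
            z = disc.assign(x)
            try:
                entry["discretized"] = fisher_pearson_skewness(z, name=name)
            except ValueError:
                entry["flags"].append("constant_indices")
        rows.append(entry)
    return rows
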