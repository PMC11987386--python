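"""Confusion-matrix metrics, ROC/AUC, cross-level aggregation, assay costs.

All metrics derive from the binary confusion counts::

    Acc = (TP+TN)/(TP+FP+FN+TN)      Precision = TP/(TP+FP)
    Recall = TP/(TP+FN)              Specificity = TN/(TN+FP)
    F1 = harmonic mean(Precision, Recall)
    BA = (Recall + Specificity)/2    FPR = FP/(FP+TN)

AUC is the area under the ROC curve by the trapezoidal rule, equal to the
tie-corrected Mann-Whitney probability that a positive outranks a
negative.  Metrics with a zero denominator are reported as ``None`` and
recorded in the report's ``undefined`` set — never silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

from .data_io import BIOMARKERS, CHEAP_ASSAYS, DomainError, normalize_marker_name

__all__ = [
    "MetricsReport",
    "UndefinedMetricError",
    "metrics_from_predictions",
    "aggregate_levels",
    "roc_points",
    "default_cost_table",
    "assay_cost",
]

METRIC_FIELDS = ("acc", "precision", "recall", "f1", "specificity", "balanced_accuracy", "fpr", "auc")


class UndefinedMetricError(ValueError):
    """A requested metric has no defined value on this input."""


@dataclass
class MetricsReport:
    """Confusion counts plus the derived metric set for one scope."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None
    balanced_accuracy: float | None
    fpr: float | None
    auc: float | None
    scope: str = "test"
    undefined: set = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("tp", "fp", "tn", "fn", *METRIC_FIELDS, "scope")}
        d["undefined"] = sorted(self.undefined)
        return d

    def to_series(self) -> pd.Series:
        return pd.Series({k: np.nan if getattr(self, k) is None else getattr(self, k)
                          for k in METRIC_FIELDS})

    def format_percent(self, metric: str) -> str:
        """Render one metric as a percentage at report precision (2 dp)."""
        v = getattr(self, metric)
        return "undefined" if v is None else f"{100 * v:.2f}%"


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics_from_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    y_score: Sequence[float] | None = None,
    scope: str = "test",
) -> MetricsReport:
    """Full metric report from binary labels, predictions and scores.

    ``y_score`` (positive-class probability) is optional; without it AUC
    is reported undefined.  A single-class ``y_true`` with scores raises
    :class:`UndefinedMetricError` (no ROC exists).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DomainError("y_true and y_pred lengths differ")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    fpr = _ratio(fp, fp + tn)
    acc = _ratio(tp + tn, tp + fp + fn + tn)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    ba = None if (recall is None or specificity is None) else (recall + specificity) / 2

    auc = None
    if y_score is not None:
        y_score = np.asarray(y_score, dtype=float)
        if np.unique(y_true).size < 2:
            raise UndefinedMetricError("AUC undefined: y_true contains a single class")
        auc = float(roc_auc_score(y_true, y_score))

    report = MetricsReport(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        acc=acc, precision=precision, recall=recall, f1=f1,
        specificity=specificity, balanced_accuracy=ba, fpr=fpr, auc=auc,
        scope=scope,
    )
    report.undefined = {k for k in METRIC_FIELDS if getattr(report, k) is None}
    return report


def aggregate_levels(
    reports: Iterable[MetricsReport] | pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> MetricsReport | pd.Series:
    """Average metrics across cascade levels.

    The default is the unweighted (macro) arithmetic mean of each metric;
    ``weights`` (e.g. level sample counts) switches to a weighted mean.
    An undefined metric in any input propagates as undefined.

    Accepts either a list of :class:`MetricsReport` (returns an overall
    report with summed confusion counts) or a plain metric DataFrame with
    one row per level (returns the column means as a Series) — the latter
    serves published per-level metric tables directly.
    """
    if isinstance(reports, pd.DataFrame):
        if reports.empty:
            raise DomainError("no reports to aggregate")
        num = reports.select_dtypes("number")
        if weights is None:
            return num.mean()
        w = np.asarray(weights, dtype=float)
        return pd.Series(np.average(num.to_numpy(), axis=0, weights=w), index=num.columns)

    reports = list(reports)
    if not reports:
        raise DomainError("no reports to aggregate")
    w = None if weights is None else np.asarray(weights, dtype=float)
    values: dict[str, float | None] = {}
    undefined: set[str] = set()
    for metric in METRIC_FIELDS:
        vals = [getattr(r, metric) for r in reports]
        if any(v is None for v in vals):
            values[metric] = None
            undefined.add(metric)
        else:
            values[metric] = float(np.average(vals, weights=w))
    out = MetricsReport(
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports), fn=sum(r.fn for r in reports),
        acc=values["acc"], precision=values["precision"], recall=values["recall"],
        f1=values["f1"], specificity=values["specificity"],
        balanced_accuracy=values["balanced_accuracy"], fpr=values["fpr"],
        auc=values["auc"], scope="overall", undefined=undefined,
    )
    return out


def roc_points(y_true: Sequence[int], y_score: Sequence[float]) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) for external plotting."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true, dtype=int), np.asarray(y_score, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# assay cost/time model


def default_cost_table() -> dict[str, tuple[float, float]]:
    """biomarker -> (USD per assay, hours per assay).

    Six routinely ordered clinical assays (AFP, CA19-9, CA-125, CEA,
    Prolactin, CA 15-3) run at ~$2; the specialized remainder of the panel
    at ~$5.5; every assay takes ~2.5 lab hours.
    """
    return {m: (2.0 if m in CHEAP_ASSAYS else 5.5, 2.5) for m in BIOMARKERS}


def assay_cost(
    panel: Iterable[str],
    costs: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Total (USD, hours) to assay a biomarker panel, serial processing.

    Unknown biomarker names raise a lookup error naming the offender.
    """
    costs = default_cost_table() if costs is None else dict(costs)
    total_usd = 0.0
    total_h = 0.0
    for name in panel:
        canon = normalize_marker_name(name)
        if canon not in costs:
            raise LookupError(f"no cost entry for biomarker {name!r}")
        usd, hours = costs[canon]
        if usd < 0 or hours < 0:
            raise DomainError(f"negative cost/hours for {canon!r}")
        total_usd += usd
        total_h += hours
    return total_usd, total_h
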