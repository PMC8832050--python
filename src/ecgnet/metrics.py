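"""Confusion matrices and per-class classification metrics.

Per class ``c`` the one-vs-rest reduction gives TP, FP, TN, FN, from which
the five standard figures follow:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    PRE = TP / (TP + FP)
    SPE = TN / (TN + FP)
    SEN = TP / (TP + FN)
    F1  = 2 * SEN * PRE / (SEN + PRE)

A metric with a zero denominator (e.g. a class absent from the evaluated
set) is reported as ``None`` rather than 0 or 1: tiny classes otherwise
produce misleading percentages.  All arithmetic is kept at full precision;
rounding (two decimals, half-up) happens only at presentation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np

from .io_formats import LabelTaxonomy

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "mislocalization_rate",
    "average_over_folds",
    "percent",
]

METRIC_NAMES = ("acc", "pre", "spe", "sen", "f1")


def percent(value: float | None, decimals: int = 2) -> float | None:
    """Proportion -> percentage, rounded half-up at presentation precision."""
    if value is None:
        return None
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_names = tuple(self.class_names)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for {k} classes")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def one_vs_rest(self, class_index: int):
        """(TP, FP, TN, FN) for one class against all others."""
        c = class_index
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum()) - tp
        fp = int(self.counts[:, c].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, fp, tn, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_names != other.class_names:
            raise ValueError("cannot add confusion matrices over different taxonomies")
        return ConfusionMatrix(self.counts + other.counts, self.class_names)


def confusion(true_labels, pred_labels, taxonomy: LabelTaxonomy) -> ConfusionMatrix:
    """Count (true, predicted) pairs over the taxonomy."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    k = taxonomy.n_classes
    if t.size and (t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k):
        bad = sorted(set(np.concatenate([t, p]).tolist()) - set(range(k)))
        raise ValueError(f"labels {bad} outside taxonomy {taxonomy.classes}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, taxonomy.classes)


@dataclass
class ClassMetrics:
    """One class's metrics as proportions in [0, 1] (None when undefined)."""

    acc: float | None = None
    pre: float | None = None
    spe: float | None = None
    sen: float | None = None
    f1: float | None = None

    def as_percent(self) -> dict:
        return {name.upper(): percent(getattr(self, name)) for name in METRIC_NAMES}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _class_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassMetrics:
    sen = _ratio(tp, tp + fn)
    pre = _ratio(tp, tp + fp)
    if sen is None or pre is None or (sen + pre) == 0:
        f1 = None
    else:
        f1 = 2 * sen * pre / (sen + pre)
    return ClassMetrics(
        acc=_ratio(tp + tn, tp + fp + tn + fn),
        pre=pre,
        spe=_ratio(tn, tn + fp),
        sen=sen,
        f1=f1,
    )


@dataclass
class MetricsReport:
    """Per-class metrics, their unweighted macro average, and overall accuracy."""

    class_names: tuple
    per_class: dict          # name -> ClassMetrics
    macro: ClassMetrics
    overall_accuracy: float | None = None
    support: dict = field(default_factory=dict)  # name -> true-beat count

    def to_dict(self) -> dict:
        return {
            "classes": {name: self.per_class[name].as_percent() for name in self.class_names},
            "macro": self.macro.as_percent(),
            "overall_accuracy": percent(self.overall_accuracy),
            "support": self.support,
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def to_csv(self, path) -> Path:
        """Tabular layout: one row per class, metric columns in percent."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Category", "ACC (%)", "SEN (%)", "SPE (%)",
                             "PRE (%)", "F1-score (%)", "Number of beats"])
            for name in self.class_names:
                m = self.per_class[name].as_percent()
                writer.writerow([name, m["ACC"], m["SEN"], m["SPE"], m["PRE"],
                                 m["F1"], self.support.get(name, "")])
            macro = self.macro.as_percent()
            writer.writerow(["Average", macro["ACC"], macro["SEN"], macro["SPE"],
                             macro["PRE"], macro["F1"], sum(self.support.values())])
        return path


def _macro(per_class: dict, class_names) -> ClassMetrics:
    values = {}
    for name in METRIC_NAMES:
        defined = [getattr(per_class[c], name) for c in class_names
                   if getattr(per_class[c], name) is not None]
        values[name] = float(np.mean(defined)) if defined else None
    return ClassMetrics(**values)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics plus macro averages and overall accuracy."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    support = {}
    for i, name in enumerate(cm.class_names):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        per_class[name] = _class_metrics(tp, fp, tn, fn)
        support[name] = int(cm.counts[i].sum())
    return MetricsReport(
        class_names=cm.class_names,
        per_class=per_class,
        macro=_macro(per_class, cm.class_names),
        overall_accuracy=cm.trace / cm.total,
        support=support,
    )


def mislocalization_rate(cm: ConfusionMatrix, healthy_class: str = "H"):
    """Fraction of diseased beats assigned the wrong non-healthy class.

    Beats whose true class is not ``healthy_class`` count in the denominator;
    the numerator counts those predicted as a *different* non-healthy class
    (missed detections -- diseased beats predicted healthy -- are excluded:
    they are detection errors, not localization errors).
    Returns ``(rate, n_mislocalized, n_diseased)``; rate is None when no
    diseased beats exist.
    """
    if healthy_class not in cm.class_names:
        raise ValueError(f"{healthy_class!r} not in {cm.class_names}")
    h = cm.class_names.index(healthy_class)
    mask = np.ones(cm.n_classes, dtype=bool)
    mask[h] = False
    diseased = cm.counts[mask]
    n_diseased = int(diseased.sum())
    off = diseased[:, mask]
    n_wrong = int(off.sum() - np.trace(off))
    return (_ratio(n_wrong, n_diseased), n_wrong, n_diseased)


def average_over_folds(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted arithmetic mean of per-class metrics across folds.

    A metric undefined in some folds is averaged over the folds where it is
    defined.  Supports are summed so the averaged report still documents how
    many beats each class contributed overall.
    """
    if not reports:
        raise ValueError("need at least one report")
    names = reports[0].class_names
    for r in reports[1:]:
        if r.class_names != names:
            raise ValueError("reports have mismatched taxonomies")
    per_class = {}
    for cname in names:
        values = {}
        for metric in METRIC_NAMES:
            defined = [getattr(r.per_class[cname], metric) for r in reports
                       if getattr(r.per_class[cname], metric) is not None]
            values[metric] = float(np.mean(defined)) if defined else None
        per_class[cname] = ClassMetrics(**values)
    overall = [r.overall_accuracy for r in reports if r.overall_accuracy is not None]
    support = {}
    for cname in names:
        support[cname] = int(sum(r.support.get(cname, 0) for r in reports))
    return MetricsReport(
        class_names=names,
        per_class=per_class,
        macro=_macro(per_class, names),
        overall_accuracy=float(np.mean(overall)) if overall else None,
        support=support,
    )
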