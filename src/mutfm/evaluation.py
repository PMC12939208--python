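"""Multiclass evaluation: confusion matrices, one-vs-rest / one-vs-one ROC,
precision-recall, and percentile-bootstrap confidence intervals.

Per-class metrics follow the one-vs-rest reduction: sensitivity (recall)
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), and F1 as their
harmonic mean.  Macro averages are unweighted means over classes, so they
treat rare and common subtypes equally.  Zero-denominator cases (a class
never predicted, or absent from the truth) are defined as 0 and flagged
rather than propagated as NaN, keeping macro averages defined on small
folds.

Uncertainty on a fixed test set is quantified by the nonparametric
percentile bootstrap: resample the test set with replacement B times,
recompute each metric from the fixed model's predictions, and read the 95%
interval off the empirical 2.5th/97.5th percentiles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "BootstrapResult",
    "UndefinedMetricError",
    "confusion_matrix",
    "per_class_metrics",
    "roc_points",
    "pr_points",
    "ovo_auc",
    "evaluate_probabilities",
    "bootstrap_ci",
    "BOOTSTRAP_METRICS",
]

BOOTSTRAP_METRICS = ("accuracy", "macro_precision", "macro_recall", "macro_f1", "macro_auc_ovr")


class UndefinedMetricError(ValueError):
    """Raised when a metric has no definition on the given inputs
    (e.g. ROC with single-class truth)."""


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts shape {self.counts.shape} != ({c}, {c})")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)
        df.to_csv(path, sep="\t", index_label="true\\pred")


@dataclass
class EvaluationReport:
    """Per-class and macro-averaged classification metrics."""

    class_names: list[str]
    per_class: dict[str, dict[str, float]]
    accuracy: float
    macro: dict[str, float]
    auc_ovr: dict[str, float] = field(default_factory=dict)
    auc_ovo: dict[str, float] = field(default_factory=dict)
    average_precision: dict[str, float] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    @property
    def macro_f1(self) -> float:
        return self.macro["f1"]

    @property
    def macro_auc_ovr(self) -> float:
        vals = [v for v in self.auc_ovr.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def as_flat_dict(self) -> dict[str, float]:
        out = {"accuracy": self.accuracy}
        for k, v in self.macro.items():
            out[f"macro_{k}"] = v
        for c, m in self.per_class.items():
            for k, v in m.items():
                out[f"{c}_{k}"] = v
        for c, v in self.auc_ovr.items():
            out[f"{c}_auc_ovr"] = v
        if self.auc_ovr:
            out["macro_auc_ovr"] = self.macro_auc_ovr
        for pair, v in self.auc_ovo.items():
            out[f"auc_ovo_{pair}"] = v
        for c, v in self.average_precision.items():
            out[f"{c}_ap"] = v
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "class_names": self.class_names,
                    "per_class": self.per_class,
                    "accuracy": self.accuracy,
                    "macro": self.macro,
                    "auc_ovr": self.auc_ovr,
                    "auc_ovo": self.auc_ovo,
                    "average_precision": self.average_precision,
                    "degenerate": self.degenerate,
                },
                indent=2,
            )
        )


@dataclass
class BootstrapResult:
    """Percentile-bootstrap replicates and 95% CI per metric."""

    replicates: dict[str, np.ndarray]
    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_excluded: dict[str, int]
    B: int
    seed: int

    def to_json(self, path: str | Path, include_replicates: bool = False) -> None:
        payload = {
            "B": self.B,
            "seed": self.seed,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_excluded": self.n_excluded,
        }
        if include_replicates:
            payload["replicates"] = {k: list(map(float, v)) for k, v in self.replicates.items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    names = list(class_names)
    idx = {c: i for i, c in enumerate(names)}
    unknown = set(map(str, np.unique(np.concatenate([y_true, y_pred])))) - set(map(str, names))
    if unknown:
        raise ValueError(f"labels outside class_names: {sorted(unknown)}")
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, names)


def per_class_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """One-vs-rest sensitivity/specificity/precision/F1 per class, accuracy,
    and unweighted macro averages (specificity excluded from the macro set)."""
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts
    total = cm.total
    per_class: dict[str, dict[str, float]] = {}
    degenerate: list[str] = []
    for i, name in enumerate(cm.class_names):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp

        def _ratio(num, den, what):
            if den == 0:
                degenerate.append(f"{name}:{what}")
                return 0.0
            return float(num / den)

        sens = _ratio(tp, tp + fn, "sensitivity")
        spec = _ratio(tn, tn + fp, "specificity")
        prec = _ratio(tp, tp + fp, "precision")
        f1 = _ratio(2 * prec * sens, prec + sens, "f1") if (prec + sens) > 0 else 0.0
        if (prec + sens) == 0:
            degenerate.append(f"{name}:f1")
        per_class[name] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
        }
    macro = {
        "precision": float(np.mean([m["precision"] for m in per_class.values()])),
        "recall": float(np.mean([m["sensitivity"] for m in per_class.values()])),
        "f1": float(np.mean([m["f1"] for m in per_class.values()])),
    }
    return EvaluationReport(
        class_names=list(cm.class_names),
        per_class=per_class,
        accuracy=float(np.trace(counts) / total),
        macro=macro,
        degenerate=degenerate,
    )


def roc_points(
    scores: Sequence[float], positives: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR at all score thresholds, ties grouped) and
    trapezoid AUC; equals the normalised Mann-Whitney U statistic."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives)
    npos = int((positives == 1).sum())
    nneg = int((positives == 0).sum())
    if npos == 0 or nneg == 0:
        raise UndefinedMetricError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = roc_curve(positives, scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def pr_points(
    scores: Sequence[float], positives: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Precision-recall curve, step-wise average precision, and the
    prevalence baseline (precision of a random ranking)."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives)
    npos = int((positives == 1).sum())
    if npos == 0:
        raise UndefinedMetricError("PR curve needs at least one positive")
    precision, recall, _ = precision_recall_curve(positives, scores)
    ap = float(average_precision_score(positives, scores))
    baseline = npos / len(positives)
    return recall, precision, ap, float(baseline)


def ovo_auc(
    prob_matrix: np.ndarray,
    y_true: Sequence,
    pair: tuple[str, str],
    class_names: Sequence[str],
    renormalize: bool = True,
) -> float:
    """One-vs-one AUC: restrict to samples of the two classes and rank them
    by the (optionally pairwise-renormalised) probability of the first."""
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    y_true = np.asarray(y_true)
    names = list(class_names)
    a, b = pair
    ia, ib = names.index(a), names.index(b)
    mask = (y_true == a) | (y_true == b)
    if not (y_true == a).any() or not (y_true == b).any():
        raise UndefinedMetricError(f"both classes of pair {pair} must be present")
    pa = prob_matrix[mask, ia]
    if renormalize:
        denom = prob_matrix[mask, ia] + prob_matrix[mask, ib]
        pa = np.divide(pa, denom, out=np.full_like(pa, 0.5), where=denom > 0)
    pos = (y_true[mask] == a).astype(int)
    _, _, aucv = roc_points(pa, pos)
    return aucv


def evaluate_probabilities(
    y_true: Sequence,
    prob_matrix: np.ndarray,
    class_names: Sequence[str],
    include_curves_metrics: bool = True,
) -> EvaluationReport:
    """Full report from predicted class probabilities: confusion-matrix
    metrics plus OvR AUC / average precision per class and OvO AUC per pair.

    Classes absent from ``y_true`` get NaN AUC/AP (excluded from macro AUC).
    """
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    y_true = np.asarray(y_true)
    names = list(class_names)
    if prob_matrix.shape != (len(y_true), len(names)):
        raise ValueError(
            f"prob_matrix shape {prob_matrix.shape} != ({len(y_true)}, {len(names)})"
        )
    y_pred = np.asarray(names, dtype=object)[prob_matrix.argmax(axis=1)]
    report = per_class_metrics(confusion_matrix(y_true, y_pred, names))
    if include_curves_metrics:
        for i, c in enumerate(names):
            pos = (y_true == c).astype(int)
            try:
                _, _, report.auc_ovr[c] = roc_points(prob_matrix[:, i], pos)
            except UndefinedMetricError:
                report.auc_ovr[c] = float("nan")
            try:
                _, _, report.average_precision[c], _ = pr_points(prob_matrix[:, i], pos)
            except UndefinedMetricError:
                report.average_precision[c] = float("nan")
        for a, b in itertools.combinations(names, 2):
            try:
                report.auc_ovo[f"{a}_vs_{b}"] = ovo_auc(prob_matrix, y_true, (a, b), names)
            except UndefinedMetricError:
                report.auc_ovo[f"{a}_vs_{b}"] = float("nan")
    return report


def _replicate_metrics(
    y_true: np.ndarray, prob_matrix: np.ndarray, class_names: list[str]
) -> dict[str, float]:
    rep = evaluate_probabilities(y_true, prob_matrix, class_names)
    missing = [c for c in class_names if not (y_true == c).any()]
    out = {
        "accuracy": rep.accuracy,
        "macro_precision": rep.macro["precision"],
        "macro_recall": rep.macro["recall"],
        "macro_f1": rep.macro["f1"],
        "macro_auc_ovr": rep.macro_auc_ovr,
    }
    if missing:
        # macro metrics over an incomplete class set are not comparable
        for k in ("macro_precision", "macro_recall", "macro_f1", "macro_auc_ovr"):
            out[k] = float("nan")
    return out


def bootstrap_ci(
    y_true: Sequence,
    prob_matrix: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
    metrics: Sequence[str] = BOOTSTRAP_METRICS,
) -> BootstrapResult:
    """Percentile bootstrap of test-set metrics under a fixed model.

    Each replicate resamples the n evaluated samples with replacement
    (predictions are fixed; the model is never re-fit) and recomputes the
    requested metrics.  Replicates where a metric is undefined (a class
    missing from the resample) are excluded from that metric's summary, with
    the exclusion count reported.  The 95% CI uses linear-interpolation
    empirical quantiles at 2.5% / 97.5%.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y_true = np.asarray(y_true)
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    if class_names is None:
        class_names = sorted(map(str, np.unique(y_true)))
    names = list(class_names)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {m: [] for m in metrics}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        vals = _replicate_metrics(y_true[idx], prob_matrix[idx], names)
        for m in metrics:
            reps[m].append(vals[m])
    replicates = {m: np.asarray(v) for m, v in reps.items()}
    mean, lo, hi, excl = {}, {}, {}, {}
    for m, v in replicates.items():
        ok = v[np.isfinite(v)]
        excl[m] = int(len(v) - len(ok))
        if len(ok) == 0:
            mean[m] = lo[m] = hi[m] = float("nan")
        else:
            mean[m] = float(ok.mean())
            lo[m] = float(np.percentile(ok, 2.5))
            hi[m] = float(np.percentile(ok, 97.5))
    return BootstrapResult(
        replicates=replicates,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        n_excluded=excl,
        B=B,
        seed=seed,
    )
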