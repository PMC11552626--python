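"""Threshold-free metrics and Monte Carlo cross-validation aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)


class EvaluationError(ValueError):
    pass


@dataclass
class MetricReport:
    auc: float
    auprc: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class CVSummary:
    per_fold: list[MetricReport]
    mean_auc: float
    sd_auc: float
    mean_auprc: float
    sd_auprc: float
    paired_per_fold: list[MetricReport] | None = None
    mean_auc_paired: float | None = None
    delta_auc: float | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        d = {
            "folds": [r.to_dict() for r in self.per_fold],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_auprc": self.mean_auprc,
            "sd_auprc": self.sd_auprc,
        }
        if self.paired_per_fold is not None:
            d["paired_folds"] = [r.to_dict() for r in self.paired_per_fold]
            d["mean_auc_paired"] = self.mean_auc_paired
            d["delta_auc"] = self.delta_auc
            d["p_value"] = self.p_value
        return d


def compute_metrics(scores, labels) -> MetricReport:
    """AUC (exact Mann-Whitney concordance, ties half credit) and
    step-interpolated AUPRC, plus the ROC / precision-recall point lists."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be 1-D and equally long")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"need both classes: {n_pos} positives, {n_neg} negatives"
        )
    # exact Mann-Whitney concordance via midranks: the numerator
    # (concordant pairs + half the ties) is an exact multiple of 1/2, so the
    # result is bit-identical to direct pair counting
    ranks = stats.rankdata(scores)
    u = float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    auprc = float(average_precision_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return MetricReport(
        auc=auc,
        auprc=auprc,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        pr_points=list(zip(recall.tolist(), precision.tolist())),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def mann_whitney_auc(scores, labels) -> float:
    """Brute-force O(pos x neg) concordance probability; ties count 1/2.

    Reference implementation used for cross-checking :func:`compute_metrics`.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def summarize_cv(
    fold_reports: list[MetricReport],
    paired_reports: list[MetricReport] | None = None,
    *,
    test: str = "t",
) -> CVSummary:
    """Mean/SD over folds; optionally a two-sided paired test on per-fold AUC.

    ``paired_reports`` must come from the same fold seeds as ``fold_reports``.
    SDs are sample standard deviations (ddof=1).  ``test`` is ``"t"`` (paired
    t-test, default) or ``"wilcoxon"``.
    """
    if len(fold_reports) < 2:
        raise EvaluationError("need at least 2 folds to summarize")
    aucs = np.array([r.auc for r in fold_reports])
    auprcs = np.array([r.auprc for r in fold_reports])
    summary = CVSummary(
        per_fold=fold_reports,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)),
        mean_auprc=float(auprcs.mean()),
        sd_auprc=float(auprcs.std(ddof=1)),
    )
    if paired_reports is not None:
        if len(paired_reports) != len(fold_reports):
            raise EvaluationError(
                f"paired fold counts differ: {len(fold_reports)} vs "
                f"{len(paired_reports)}"
            )
        other = np.array([r.auc for r in paired_reports])
        diffs = aucs - other
        if np.allclose(diffs, 0.0):
            p = 1.0  # identical folds: no evidence of a difference
        elif test == "t":
            p = float(stats.ttest_rel(aucs, other).pvalue)
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(aucs, other).pvalue)
        else:
            raise EvaluationError(f"unknown paired test {test!r}")
        summary.paired_per_fold = paired_reports
        summary.mean_auc_paired = float(other.mean())
        summary.delta_auc = float(diffs.mean())
        summary.p_value = p
    return summary
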