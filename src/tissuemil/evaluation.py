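"""Tissue-count-weighted ROC/PR evaluation and fold x seed aggregation.

Slides (bags) contribute to the ROC and PR accumulators in proportion to
their number of segmented tissues, which down-weights inadequate biopsies
that would otherwise add noise.  AUCs from the fold x seed model grid are
averaged with an unbiased standard error; across tasks, ROC-AUCs are pooled
with inverse-variance weighting (precise tasks count more) while PR-AUCs are
pooled with the arithmetic mean.  The optimal operating point of a ROC curve
is its intercept with the maximum iso-accuracy line, i.e. the threshold
maximising weighted accuracy at the pool's prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import validate_weights


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class PrCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auc: float


def _binary_setup(y_true, scores, weights, positive_label):
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if weights is None:
        weights = np.ones_like(scores)
    weights = validate_weights(weights)
    pos = y_true == positive_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    return pos, scores, weights


def weighted_roc(y_true, scores, weights=None, positive_label=1) -> RocCurve:
    """Weighted ROC curve and trapezoidal AUC.

    Each bag contributes its weight to the TPR/FPR accumulators; tied scores
    step simultaneously, which makes the AUC equal to the weighted pairwise
    Mann-Whitney statistic with half-credit for ties.
    """
    pos, scores, weights = _binary_setup(y_true, scores, weights, positive_label)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    wp = np.where(pos[order], weights[order], 0.0)
    wn = np.where(pos[order], 0.0, weights[order])
    # group tied scores into simultaneous steps
    last = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    cum_p = np.cumsum(wp)[last]
    cum_n = np.cumsum(wn)[last]
    Wp, Wn = cum_p[-1], cum_n[-1]
    tpr = np.r_[0.0, cum_p / Wp]
    fpr = np.r_[0.0, cum_n / Wn]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def weighted_pr(y_true, scores, weights=None, positive_label=1) -> PrCurve:
    """Weighted precision-recall curve with step interpolation.

    AUC is the step sum ``sum (R_i - R_{i-1}) * P_i`` (precision held
    constant to the right).  With constant scores this reduces to the
    weighted positive prevalence.
    """
    pos, scores, weights = _binary_setup(y_true, scores, weights, positive_label)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    wp = np.where(pos[order], weights[order], 0.0)
    wn = np.where(pos[order], 0.0, weights[order])
    last = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    cum_p = np.cumsum(wp)[last]
    cum_n = np.cumsum(wn)[last]
    Wp = cum_p[-1]
    if Wp == 0:
        raise ValueError("no positive weight")
    recall = cum_p / Wp
    precision = cum_p / (cum_p + cum_n)
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PrCurve(
        recall=np.r_[0.0, recall],
        precision=np.r_[1.0 if precision.size == 0 else precision[0], precision],
        thresholds=np.r_[np.inf, s[last]],
        auc=auc,
    )


def macro_ovr_auc(y_true, score_matrix, weights=None) -> float:
    """Macro-averaged one-vs-rest weighted ROC-AUC for multi-class scores."""
    y_true = np.asarray(y_true)
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim == 1:
        S = np.column_stack([1.0 - S, S])
    aucs = []
    for c in range(S.shape[1]):
        if (y_true == c).any() and (y_true != c).any():
            aucs.append(weighted_roc((y_true == c).astype(int), S[:, c], weights).auc)
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def auc_mean_se(aucs: Sequence[float]) -> tuple[float, float]:
    """Mean and unbiased standard error of the mean over fold x seed AUCs."""
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 2:
        raise ValueError("need >= 2 model AUCs for a standard error")
    return float(aucs.mean()), float(aucs.std(ddof=1) / np.sqrt(aucs.size))


def combine_tasks(
    task_means: Sequence[float],
    task_ses: Sequence[float] | None = None,
    method: str = "invvar",
) -> tuple[float, float]:
    """Pool per-task AUC means across tasks.

    ``invvar`` weights each task by ``1/se^2`` (pooled se = ``1/sqrt(sum
    se^-2)``), used for ROC-AUCs; ``arithmetic`` is the plain mean with the
    usual SE, used for PR-AUCs.
    """
    means = np.asarray(task_means, dtype=float)
    if means.size == 0:
        raise ValueError("need >= 1 task")
    if method == "arithmetic":
        if means.size == 1:
            return float(means[0]), 0.0
        return float(means.mean()), float(means.std(ddof=1) / np.sqrt(means.size))
    if method != "invvar":
        raise ValueError("method must be 'invvar' or 'arithmetic'")
    if task_ses is None:
        raise ValueError("inverse-variance pooling needs per-task standard errors")
    ses = np.asarray(task_ses, dtype=float)
    if np.any(ses == 0):
        raise ValueError(
            "zero standard error: inverse-variance weights are undefined; "
            "use method='arithmetic'"
        )
    w = 1.0 / ses**2
    return float(np.sum(w * means) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def optimal_threshold(curve: RocCurve, prevalence: float) -> tuple[float, float, float]:
    """Operating point maximising weighted accuracy (iso-accuracy tangent).

    ``accuracy = tpr * pi + (1 - fpr) * (1 - pi)`` at prevalence ``pi``;
    ties break toward the higher TPR.  Returns ``(threshold, tpr, fpr)``.
    """
    if curve.tpr.size == 0:
        raise ValueError("empty curve")
    acc = curve.tpr * prevalence + (1.0 - curve.fpr) * (1.0 - prevalence)
    best = np.lexsort((curve.tpr, acc))[-1]
    return float(curve.thresholds[best]), float(curve.tpr[best]), float(curve.fpr[best])


def bootstrap_bands(
    y_true,
    scores,
    weights=None,
    n_boot: int = 5,
    seed: int = 0,
    grid: np.ndarray | None = None,
    max_retries: int = 50,
) -> dict:
    """Bootstrap ROC band: median curve and min/max range over resamples.

    Bags are resampled with replacement within the test pool; degenerate
    resamples missing a class are redrawn (capped retries).  Curves are
    compared on a common FPR grid.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n = y_true.size
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(seed)
    tprs, aucs = [], []
    for _ in range(n_boot):
        for _retry in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y_true[idx])) > 1:
                break
        else:
            raise RuntimeError("could not draw a resample containing both classes")
        c = weighted_roc(y_true[idx], scores[idx], weights[idx])
        tprs.append(np.interp(grid, c.fpr, c.tpr))
        aucs.append(c.auc)
    tprs = np.vstack(tprs)
    aucs = np.asarray(aucs)
    return {
        "fpr": grid,
        "tpr_median": np.median(tprs, axis=0),
        "tpr_min": tprs.min(axis=0),
        "tpr_max": tprs.max(axis=0),
        "auc_median": float(np.median(aucs)),
        "auc_min": float(aucs.min()),
        "auc_max": float(aucs.max()),
        "aucs": aucs,
    }


@dataclass
class EvaluationReport:
    """Per-task weighted AUC summaries plus the cross-task aggregate."""

    per_task: pd.DataFrame
    roc_auc_pooled: float
    roc_auc_pooled_se: float
    pr_auc_pooled: float
    pr_auc_pooled_se: float
    details: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Evaluation report", "=" * 60]
        for _, r in self.per_task.iterrows():
            lines.append(
                f"{r['task']:<24} ROC {r['roc_auc_mean']:.3f}+/-{r['roc_auc_se']:.3f}"
                f"  PR {r['pr_auc_mean']:.3f}+/-{r['pr_auc_se']:.3f}"
            )
        lines.append("-" * 60)
        lines.append(
            f"{'pooled (invvar ROC)':<24} ROC {self.roc_auc_pooled:.3f}"
            f"+/-{self.roc_auc_pooled_se:.3f}  PR {self.pr_auc_pooled:.3f}"
            f"+/-{self.pr_auc_pooled_se:.3f}"
        )
        return "\n".join(lines)


def report_from_predictions(task_predictions: dict[str, pd.DataFrame]) -> EvaluationReport:
    """Build a report from per-task pooled CV prediction tables.

    Each table needs columns ``label, n_tissues, fold, seed`` and
    ``score_<c>``; per (fold, seed) model the weighted ROC/PR AUCs are
    computed on its out-of-fold bags, then averaged with an unbiased SE, and
    finally pooled across tasks.
    """
    rows = []
    for task, df in task_predictions.items():
        score_cols = sorted(
            (c for c in df.columns if c.startswith("score_")),
            key=lambda c: int(c.split("_")[1]),
        )
        roc_list, pr_list = [], []
        for _, grp in df.groupby(["fold", "seed"]):
            y = grp["label"].to_numpy()
            w = grp["n_tissues"].to_numpy(float)
            S = grp[score_cols].to_numpy(float)
            if len(score_cols) == 2:
                roc_list.append(weighted_roc(y, S[:, 1], w).auc)
                pr_list.append(weighted_pr(y, S[:, 1], w).auc)
            else:
                roc_list.append(macro_ovr_auc(y, S, w))
                prs = [
                    weighted_pr((y == c).astype(int), S[:, c], w).auc
                    for c in range(len(score_cols))
                    if (y == c).any()
                ]
                pr_list.append(float(np.mean(prs)))
        roc_m, roc_se = auc_mean_se(roc_list)
        pr_m, pr_se = auc_mean_se(pr_list)
        rows.append(
            {
                "task": task,
                "n_models": len(roc_list),
                "roc_auc_mean": roc_m,
                "roc_auc_se": roc_se,
                "pr_auc_mean": pr_m,
                "pr_auc_se": pr_se,
            }
        )
    per_task = pd.DataFrame(rows)
    roc_pooled, roc_pooled_se = combine_tasks(
        per_task["roc_auc_mean"], per_task["roc_auc_se"], method="invvar"
    )
    pr_pooled, pr_pooled_se = combine_tasks(per_task["pr_auc_mean"], method="arithmetic")
    return EvaluationReport(
        per_task=per_task,
        roc_auc_pooled=roc_pooled,
        roc_auc_pooled_se=roc_pooled_se,
        pr_auc_pooled=pr_pooled,
        pr_auc_pooled_se=pr_pooled_se,
    )
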