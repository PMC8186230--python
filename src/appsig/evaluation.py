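"""ROC construction, AUC, and bootstrap aggregation of performance.

A sample is called gangrenous when its class probability strictly exceeds the
threshold. Sensitivity is the true-positive rate with respect to GA (class 1),
specificity the true-negative rate. Sweeping the threshold over a grid and
computing the rates per bootstrap iteration on that iteration's out-of-bag
samples gives a mean +/- SE ROC curve, where "SE" is the bootstrap standard
error: the standard deviation of the per-iteration statistic across
iterations (not divided by sqrt(B)).

The headline AUC is the mean of per-iteration out-of-bag AUCs; its SE is
again the across-iteration SD, and two lower 95% confidence limits are
reported — normal approximation (mean - 1.96*SE) and the 2.5th percentile of
the per-iteration AUCs — since either convention is defensible for bootstrap
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from appsig.errors import ValidationError

#: Default probability-threshold grid: 0.05 to 0.95 in steps of 0.05.
DEFAULT_THRESHOLDS = np.round(np.linspace(0.05, 0.95, 19), 10)


def confusion_at_threshold(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) calling GA when probability > threshold."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValidationError("labels must contain both classes")
    pred = probabilities > threshold
    pos, neg = labels == 1, labels == 0
    sensitivity = float(np.sum(pred & pos) / np.sum(pos))
    specificity = float(np.sum(~pred & neg) / np.sum(neg))
    return sensitivity, specificity


def auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a GA sample outscores a PA sample (ties count half).

    Identical to the trapezoidal area under the full-resolution ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n0 == 0 or n1 == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties => half-credit
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass
class ROCPoint:
    threshold: float
    sensitivity_mean: float
    sensitivity_se: float
    specificity_mean: float
    specificity_se: float
    n_iterations: int


@dataclass
class AUCSummary:
    """Bootstrap summary of out-of-bag AUC for one signature size."""

    mean_auc: float
    se_auc: float  # SD of per-iteration AUCs (bootstrap SE)
    cl_lower_normal: float  # mean - 1.96 * SE
    cl_lower_percentile: float  # 2.5th percentile of per-iteration AUCs
    n_iterations: int

    def report_line(self) -> str:
        """The study's reporting style, on the percent scale."""
        return (
            f"AUC was {100 * self.mean_auc:.0f}% "
            f"(SE {100 * self.se_auc:.0f}, CL {100 * self.cl_lower_normal:.1f})"
        )


def aggregate_roc(
    records: Sequence,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    signature_size: int | None = None,
) -> pd.DataFrame:
    """Mean +/- SE sensitivity/specificity across iterations per threshold.

    ``records`` are :class:`~appsig.signature.IterationRecord` objects;
    ``signature_size`` picks which candidate's probabilities to evaluate
    (default: the largest size). SE is the across-iteration SD (ddof=1).
    """
    records = list(records)
    if not records:
        raise ValidationError("no iteration records to aggregate")
    k_max = len(records[0].signatures)
    size = k_max if signature_size is None else int(signature_size)
    if not 1 <= size <= k_max:
        raise ValidationError(f"signature_size must lie in [1, {k_max}]")
    thresholds = np.asarray(list(thresholds), dtype=float)

    rows = []
    for thr in thresholds:
        sens, spec = [], []
        for r in records:
            p = r.validation_probabilities[size - 1]
            if not np.all(np.isfinite(p)):
                continue
            se_, sp_ = confusion_at_threshold(p, r.validation_labels, thr)
            sens.append(se_)
            spec.append(sp_)
        if len(sens) < 2:
            raise ValidationError(
                f"fewer than 2 contributing iterations at threshold {thr:g}"
            )
        sens, spec = np.array(sens), np.array(spec)
        rows.append(
            {
                "threshold": thr,
                "sensitivity_mean": sens.mean(),
                "sensitivity_se": sens.std(ddof=1),
                "specificity_mean": spec.mean(),
                "specificity_se": spec.std(ddof=1),
                "n_iterations": len(sens),
            }
        )
    return pd.DataFrame(rows)


def summarize_auc(records: Sequence, signature_size: int) -> AUCSummary:
    """Aggregate per-iteration out-of-bag AUCs for one candidate size."""
    records = list(records)
    if not records:
        raise ValidationError("no iteration records to summarize")
    aucs = np.array([r.validation_auc[signature_size - 1] for r in records])
    aucs = aucs[np.isfinite(aucs)]
    if aucs.size < 2:
        raise ValidationError("need >= 2 iterations with a validation AUC")
    mean = float(aucs.mean())
    se = float(aucs.std(ddof=1))
    return AUCSummary(
        mean_auc=mean,
        se_auc=se,
        cl_lower_normal=mean - 1.96 * se,
        cl_lower_percentile=float(np.percentile(aucs, 2.5)),
        n_iterations=int(aucs.size),
    )


def mean_roc_auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under the threshold-averaged (mean-point) ROC curve.

    Complements the headline mean-of-AUCs: this is the area under the curve
    drawn through the mean sensitivity/specificity points, closed at (0,0)
    and (1,1) in ROC space.
    """
    fpr = 1.0 - roc["specificity_mean"].to_numpy()
    tpr = roc["sensitivity_mean"].to_numpy()
    order = np.argsort(fpr, kind="stable")
    fpr = np.concatenate(([0.0], fpr[order], [1.0]))
    tpr = np.concatenate(([0.0], tpr[order], [1.0]))
    return float(np.trapezoid(tpr, fpr))


def plot_roc(roc: pd.DataFrame, path, title: str = "Out-of-bag ROC (mean ± SE)") -> None:
    """Write the mean ± SE ROC curve as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    fpr = 1.0 - roc["specificity_mean"]
    ax.errorbar(
        fpr,
        roc["sensitivity_mean"],
        xerr=roc["specificity_se"],
        yerr=roc["sensitivity_se"],
        fmt="o-",
        capsize=2,
        lw=1,
    )
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity (false-positive rate)")
    ax.set_ylabel("sensitivity (true-positive rate)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
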