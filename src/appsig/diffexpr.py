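"""Per-gene Welch's unequal-variance t-test and log2 fold change.

The contrast is gangrenous (class 1) versus phlegmonous (class 0): positive t
and positive log2 fold change mean higher expression in the gangrenous group.
Significance is the raw two-sided p-value against ``alpha`` (default 0.05)
with no multiple-testing correction — that is the faithful analysis mode; an
optional Benjamini–Hochberg column can be added for reference but is never
used by the pipeline's significance flag.

Degenerate genes (both group variances zero) are kept, not dropped: equal
means give t = 0, p = 1; unequal means give p = 0 with an infinite t, so the
output always has one row per input gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from appsig.data_io import LOG2, ClassLabels, ExpressionMatrix
from appsig.errors import ValidationError


def welch_test_arrays(
    group0: np.ndarray, group1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch test along the last axis (rows = genes).

    Returns (t, df, p) with t = (mean1 - mean0)/sqrt(s1^2/n1 + s0^2/n0),
    Welch–Satterthwaite degrees of freedom, and two-sided p from Student's t.
    """
    group0 = np.asarray(group0, dtype=float)
    group1 = np.asarray(group1, dtype=float)
    n0, n1 = group0.shape[-1], group1.shape[-1]
    if n0 < 2 or n1 < 2:
        raise ValidationError("Welch's test needs at least 2 samples per group")
    m0, m1 = group0.mean(axis=-1), group1.mean(axis=-1)
    v0, v1 = group0.var(axis=-1, ddof=1), group1.var(axis=-1, ddof=1)
    a0, a1 = v0 / n0, v1 / n1
    denom_sq = a0 + a1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(denom_sq)
        df = denom_sq**2 / (a0**2 / (n0 - 1) + a1**2 / (n1 - 1))
    degenerate = denom_sq == 0.0
    if np.any(degenerate):
        equal_means = degenerate & (m0 == m1)
        t = np.where(equal_means, 0.0, t)
        signed_inf = np.where(m1 > m0, np.inf, -np.inf)
        t = np.where(degenerate & ~equal_means, signed_inf, t)
        df = np.where(degenerate, float(n0 + n1 - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def welch_test(group0, group1) -> tuple[float, float, float]:
    """Welch's two-sample t-test for a single gene: returns (t, df, p)."""
    t, df, p = welch_test_arrays(np.atleast_1d(group0), np.atleast_1d(group1))
    return float(t), float(df), float(p)


def log2_fold_change(group0, group1) -> float:
    """mean(group1) - mean(group0) of already-log2 values.

    Equals the log2 ratio of geometric means of the linear-scale intensities.
    """
    group0 = np.asarray(group0, dtype=float)
    group1 = np.asarray(group1, dtype=float)
    if group0.size == 0 or group1.size == 0:
        raise ValidationError("log2 fold change needs non-empty groups")
    return float(group1.mean() - group0.mean())


@dataclass
class DifferentialExpressionTable:
    """Per-gene Welch statistics in input gene order, plus the run summary."""

    table: pd.DataFrame  # gene_id, t, df, p, log2fc, significant [, p_bh]
    alpha: float

    @property
    def n_genes(self) -> int:
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.n_significant / self.n_genes

    def summary(self) -> str:
        return (
            f"{self.n_significant} of {self.n_genes} genes significantly "
            f"differentially expressed ({self.percent_significant:.1f}%) at p < {self.alpha:g}"
        )


def run_de(
    matrix: ExpressionMatrix,
    labels: ClassLabels,
    alpha: float = 0.05,
    add_bh: bool = False,
) -> DifferentialExpressionTable:
    """Welch test + log2 fold change for every gene of a log2-scale matrix."""
    if matrix.scale != LOG2:
        raise ValidationError("run_de expects a log2-scale matrix; apply log2_transform first")
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must lie in [0, 1]")
    y = labels.y_for(matrix)
    values = matrix.values.to_numpy(dtype=float)
    g0, g1 = values[:, y == 0], values[:, y == 1]
    t, df, p = welch_test_arrays(g0, g1)
    log2fc = g1.mean(axis=1) - g0.mean(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "t": t,
            "df": df,
            "p": p,
            "log2fc": log2fc,
            "significant": p < alpha,
        }
    )
    if add_bh:
        out["p_bh"] = stats.false_discovery_control(p, method="bh")
    return DifferentialExpressionTable(out, alpha=alpha)
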