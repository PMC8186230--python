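"""Quantile normalization across samples and log2 transformation.

Quantile normalization forces every sample column to share one empirical
distribution: the k-th smallest value of each column is replaced by the mean
of the k-th smallest values across columns. Tied values within a column
receive the mean of the reference values over their tied rank span (the
convention of the canonical microarray implementations), which keeps the
procedure idempotent and rank-preserving.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from appsig.data_io import LINEAR, LOG2, ExpressionMatrix
from appsig.errors import ValidationError


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a 2-D array (rows = genes)."""
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 sample columns")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        # np.unique returns ascending values; equal entries occupy a
        # contiguous span of sorted positions, so reduceat gives the mean
        # reference value over each tie span.
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        span_means = np.add.reduceat(ref, starts) / counts
        out[:, j] = span_means[inverse]
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic cross-sample quantile normalization of a linear-scale matrix.

    After normalization the sorted values of every column are identical, and
    within-column rank order is preserved (ties collapse to a common value).
    """
    if matrix.scale != LINEAR:
        raise ValidationError("quantile normalization expects a linear-scale matrix")
    normalized = quantile_normalize_values(matrix.values.to_numpy(dtype=float))
    return ExpressionMatrix(
        pd.DataFrame(normalized, index=matrix.values.index, columns=matrix.values.columns),
        scale=LINEAR,
    )


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2. No pseudo-count: positivity is a matrix invariant."""
    if matrix.scale == LOG2:
        raise ValidationError("matrix is already on the log2 scale")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        g, s = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"cannot log2-transform non-positive value at gene "
            f"{matrix.values.index[g]!r}, sample {matrix.values.columns[s]!r}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr), index=matrix.values.index, columns=matrix.values.columns),
        scale=LOG2,
    )


def preprocess(matrix: ExpressionMatrix, quantile: bool = True, log2: bool = True) -> ExpressionMatrix:
    """Pipeline preprocessing in the fixed order: quantile-normalize, then log2."""
    out = matrix
    if quantile:
        out = quantile_normalize(out)
    if log2:
        out = log2_transform(out)
    return out
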