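"""Expression matrices, class labels, and their tab-separated on-disk forms.

Matrices are stored genes x samples (the universal expression-matrix
convention); the classifier-facing samples x genes orientation is obtained via
:meth:`ExpressionMatrix.samples_by_genes`. Files are plain TSV: expression
matrices have a ``gene_id`` header column followed by one column per sample,
optionally preceded by ``# scale: log2`` directive lines; label tables have
``sample_id`` and ``class`` columns with class names ``PA`` (phlegmonous,
code 0) and ``GA`` (gangrenous, code 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from appsig.errors import CrossReferenceError, StructuralError, ValidationError

LINEAR = "linear"
LOG2 = "log2"

CLASS_NAMES: Mapping[int, str] = {0: "PA", 1: "GA"}
CLASS_CODES: Mapping[str, int] = {"PA": 0, "GA": 1}


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise StructuralError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A gene x sample intensity matrix.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers as
        columns. Linear-scale intensities must be strictly positive; no
        missing values are accepted (the pipeline never imputes).
    scale
        ``"linear"`` (raw intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale flag: {self.scale!r}")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise StructuralError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.scale == LINEAR and (arr <= 0).any():
            g, s = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                f"non-positive linear intensity at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_by_genes(self) -> pd.DataFrame:
        """Transpose view: n samples x p genes, the classifier orientation."""
        return self.values.T

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise CrossReferenceError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], scale=self.scale)


@dataclass
class ClassLabels:
    """Sample -> binary class mapping; PA (phlegmonous) = 0, GA (gangrenous) = 1."""

    codes: pd.Series  # index: sample_id, values: int {0, 1}
    class_names: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        _check_unique(list(self.codes.index), "sample")
        bad = set(self.codes.unique()) - {0, 1}
        if bad:
            raise ValidationError(f"class codes must be 0/1, got {sorted(bad)}")
        self.codes = self.codes.astype(np.int64)
        counts = self.class_counts()
        for code, n in counts.items():
            if n < 2:
                raise ValidationError(
                    f"class {self.class_names[code]} has {n} sample(s); "
                    "at least 2 per class are required"
                )
        if len(counts) < 2:
            raise ValidationError("both classes must be present")

    def class_counts(self) -> dict[int, int]:
        vc = self.codes.value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.index)

    def y_for(self, matrix: ExpressionMatrix) -> np.ndarray:
        """Label vector aligned to the matrix sample order (errors on gaps)."""
        missing = [s for s in matrix.sample_ids if s not in self.codes.index]
        if missing:
            raise CrossReferenceError(f"matrix samples without labels: {missing[:5]}")
        return self.codes.loc[matrix.sample_ids].to_numpy()

    def check_against(self, matrix: ExpressionMatrix) -> None:
        extra = [s for s in self.codes.index if s not in set(matrix.sample_ids)]
        if extra:
            raise CrossReferenceError(
                f"labeled sample(s) absent from the expression matrix: {extra[:5]}"
            )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    The first row holds sample identifiers (first cell is the gene-id column
    name), each following row one gene. Leading lines starting with ``#`` are
    directives; ``# scale: log2`` marks an already log-transformed matrix.
    """
    path = Path(path)
    scale = LINEAR
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        directive = line[1:].strip()
        if directive.lower().startswith("scale:"):
            scale = directive.split(":", 1)[1].strip().lower()
        body_start += 1
    if body_start >= len(lines):
        raise StructuralError(f"{path}: no data rows")
    raw = pd.read_csv(
        io.StringIO("".join(lines[body_start:])), sep="\t", index_col=0, dtype=str
    )
    raw.index = raw.index.astype(str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & ~raw.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise StructuralError(
            f"{path}: non-numeric cell {raw.iloc[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return ExpressionMatrix(values, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at full float precision (lossless round trip)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if matrix.scale != LINEAR:
            fh.write(f"# scale: {matrix.scale}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def read_labels(path: str | Path, matrix: ExpressionMatrix) -> ClassLabels:
    """Read a two-column ``sample_id<TAB>class`` table; class is PA or GA.

    Every labeled sample must exist in ``matrix`` and each class must have at
    least two samples (Welch's test and logistic fitting need within-group
    variance).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "class"]
    if list(table.columns[:2]) != expected:
        raise StructuralError(f"{path}: expected columns {expected}, got {list(table.columns)}")
    unknown = sorted(set(table["class"]) - set(CLASS_CODES))
    if unknown:
        raise StructuralError(f"{path}: unknown class name(s) {unknown}; expected PA/GA")
    codes = pd.Series(
        [CLASS_CODES[c] for c in table["class"]],
        index=table["sample_id"].astype(str),
        name="class_code",
    )
    labels = ClassLabels(codes)
    labels.check_against(matrix)
    return labels


def write_labels(labels: ClassLabels, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "sample_id": labels.sample_ids,
            "class": [labels.class_names[int(c)] for c in labels.codes],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_table(records, path: str | Path) -> None:
    """Write tabular results as TSV with a header; floats at 6 significant digits.

    ``records`` is a DataFrame or a non-empty list of uniform dicts. An empty
    input is an error: silently producing an empty results file would mask
    upstream failures.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if records and len({tuple(r.keys()) for r in records}) != 1:
            raise ValidationError("records have non-uniform fields")
        frame = pd.DataFrame.from_records(records)
    if frame.empty:
        raise ValidationError("refusing to write an empty results table")
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
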