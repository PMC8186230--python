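"""Bootstrap discovery/validation alternation and biomarker-signature search.

This is the heart of the pipeline. With only 13 + 16 patients, a single
train/test split is too unstable, so the discovery and validation phases
alternate over bootstrap resamples: each iteration draws n samples with
replacement (the discovery multiset), leaving the out-of-bag samples — those
never drawn — as an untouched validation set. Genes are ranked by |Welch t|
computed on the discovery samples only, a nested family of candidate
signatures (top-1, top-2, ..., top-k_max genes) is built, a ridge-logistic
model is fitted per candidate on the discovery samples, and its class
probabilities are scored on both sets. Validation metrics therefore never see
a sample that influenced gene ranking or model fitting.

Aggregating over iterations, the winning signature size maximizes mean
out-of-bag AUC (ties favour the smaller, more parsimonious size), and the
reported signature consists of the genes most frequently ranked into the
top-k* across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from appsig.data_io import LOG2, ClassLabels, ExpressionMatrix
from appsig.diffexpr import welch_test_arrays
from appsig.errors import ValidationError
from appsig.evaluation import auc_concordance
from appsig.model import fit_logistic, predict_proba


@dataclass
class BootstrapSplit:
    """One bootstrap draw: discovery multiset + out-of-bag validation set."""

    iteration_index: int
    discovery_indices: np.ndarray  # size n, drawn with replacement
    validation_indices: np.ndarray  # out-of-bag, each sample once, sorted

    def __post_init__(self) -> None:
        if np.intersect1d(self.discovery_indices, self.validation_indices).size:
            raise ValidationError("validation set overlaps the discovery multiset")


@dataclass(frozen=True)
class Signature:
    """An ordered set of biomarker genes feeding the classifier."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValidationError("a signature needs at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("signature contains duplicate genes")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


@dataclass
class IterationRecord:
    """Per-iteration results for every candidate signature size.

    Arrays are indexed by candidate size - 1. ``validation_auc``/
    ``discovery_auc`` hold NaN for candidates whose fit failed (never silently
    dropped; aggregation counts only finite entries).
    """

    iteration_index: int
    split: BootstrapSplit
    ranked_genes: tuple[str, ...]  # top-k_max genes by discovery |t|
    signatures: list[Signature]
    discovery_auc: np.ndarray
    validation_auc: np.ndarray
    validation_probabilities: list[np.ndarray]  # per size, aligned to split OOB
    validation_labels: np.ndarray = field(default_factory=lambda: np.array([]))


def bootstrap_split(
    n_samples: int,
    labels: ClassLabels | np.ndarray,
    rng: np.random.Generator,
    iteration_index: int = 0,
    max_attempts: int = 1000,
) -> BootstrapSplit:
    """Draw n samples with replacement; the out-of-bag complement validates.

    Redraws (up to ``max_attempts``) until the validation set contains both
    classes and the discovery multiset holds at least two samples of each —
    otherwise the per-iteration Welch ranking and the logistic fit are
    undefined. For n = 29 with 13/16 per class the redraw fires with
    negligible probability, so out-of-bag size statistics are essentially
    those of the unconstrained bootstrap.
    """
    if n_samples < 4:
        raise ValidationError("bootstrap splitting needs at least 4 samples")
    y = labels.codes.to_numpy() if isinstance(labels, ClassLabels) else np.asarray(labels)
    if y.shape[0] != n_samples:
        raise ValidationError("labels do not match n_samples")
    for _ in range(max_attempts):
        discovery = rng.integers(0, n_samples, size=n_samples)
        oob = np.setdiff1d(np.arange(n_samples), discovery)
        if oob.size == 0 or len(np.unique(y[oob])) < 2:
            continue
        if min(np.sum(y[discovery] == 0), np.sum(y[discovery] == 1)) < 2:
            continue
        return BootstrapSplit(iteration_index, discovery, oob)
    raise ValidationError(
        f"could not draw a valid bootstrap split in {max_attempts} attempts; "
        "check the class balance"
    )


def build_candidate_signatures(ranking: Sequence[str], k_max: int) -> list[Signature]:
    """Nested candidates: top-1, top-2, ..., top-k_max genes of the ranking."""
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if k_max > len(ranking):
        raise ValidationError("k_max exceeds the number of ranked genes")
    return [Signature(tuple(ranking[:k])) for k in range(1, k_max + 1)]


def rank_genes_by_welch(
    values: np.ndarray, y: np.ndarray, gene_ids: Sequence[str]
) -> np.ndarray:
    """Indices of genes ordered by decreasing |Welch t| (ties: input order)."""
    t, _, _ = welch_test_arrays(values[:, y == 0], values[:, y == 1])
    order = np.argsort(-np.abs(t), kind="stable")  # stable => smaller gene index wins ties
    return order


def run_discovery_validation(
    matrix: ExpressionMatrix,
    labels: ClassLabels,
    B: int = 1000,
    k_max: int = 10,
    ridge_lambda: float = 1.0,
    seed: int | np.random.Generator = 0,
    ranking: str = "per-iteration",
) -> list[IterationRecord]:
    """Run B bootstrap iterations of discovery-set ranking, fitting, and
    out-of-bag validation.

    Parameters
    ----------
    matrix
        preprocessed (quantile-normalized, log2) expression matrix.
    B
        number of bootstrap iterations; up to a thousand is the faithful
        operating range, and B = 1000 the default.
    k_max
        largest candidate-signature size (nested top-k candidates).
    ranking
        ``"per-iteration"`` (default) recomputes the Welch ranking on each
        discovery multiset, which keeps gene selection inside the resampling
        loop and free of validation leakage. ``"global"`` ranks once on the
        full matrix — a deliberately optimistic comparison mode whose
        validation AUCs are biased upward by selection leakage.
    """
    if matrix.scale != LOG2:
        raise ValidationError("run_discovery_validation expects a log2-scale matrix")
    if B < 1:
        raise ValidationError("B must be >= 1")
    if ranking not in ("per-iteration", "global"):
        raise ValidationError(f"unknown ranking mode: {ranking!r}")
    if k_max < 1 or k_max > matrix.n_genes:
        raise ValidationError("k_max must lie in [1, n_genes]")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float)
    gene_ids = np.array(matrix.gene_ids)
    y = labels.y_for(matrix)
    n = matrix.n_samples
    X_samples = matrix.samples_by_genes()  # samples x genes view

    global_order = None
    if ranking == "global":
        global_order = rank_genes_by_welch(values, y, gene_ids)

    records: list[IterationRecord] = []
    for b in range(1, B + 1):
        split = bootstrap_split(n, y, rng, iteration_index=b)
        disc, val = split.discovery_indices, split.validation_indices
        y_disc, y_val = y[disc], y[val]
        if global_order is None:
            order = rank_genes_by_welch(values[:, disc], y_disc, gene_ids)
        else:
            order = global_order
        top = order[:k_max]
        ranked = tuple(str(g) for g in gene_ids[top])
        signatures = build_candidate_signatures(ranked, k_max)

        disc_auc = np.full(k_max, np.nan)
        val_auc = np.full(k_max, np.nan)
        val_probs: list[np.ndarray] = []
        X_disc_full = X_samples.iloc[disc]
        X_val_full = X_samples.iloc[val]
        for k, sig in enumerate(signatures, start=1):
            cols = list(sig.gene_ids)
            try:
                model = fit_logistic(
                    X_disc_full[cols], y_disc, ridge_lambda=ridge_lambda
                )
                p_disc = predict_proba(model, X_disc_full[cols])
                p_val = predict_proba(model, X_val_full[cols])
            except Exception:  # failed fit: recorded as missing, never dropped
                val_probs.append(np.full(val.size, np.nan))
                continue
            disc_auc[k - 1] = auc_concordance(p_disc, y_disc)
            val_auc[k - 1] = auc_concordance(p_val, y_val)
            val_probs.append(p_val)

        records.append(
            IterationRecord(
                iteration_index=b,
                split=split,
                ranked_genes=ranked,
                signatures=signatures,
                discovery_auc=disc_auc,
                validation_auc=val_auc,
                validation_probabilities=val_probs,
                validation_labels=y_val,
            )
        )
    return records


def per_size_validation_auc(records: Iterable[IterationRecord]) -> pd.DataFrame:
    """Mean out-of-bag AUC per candidate size, with contributing counts."""
    records = list(records)
    if not records:
        raise ValidationError("no iteration records")
    k_max = len(records[0].signatures)
    aucs = np.vstack([r.validation_auc for r in records])
    n_ok = np.sum(np.isfinite(aucs), axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_ok > 0, np.nanmean(aucs, axis=0), np.nan)
    return pd.DataFrame(
        {
            "size": np.arange(1, k_max + 1),
            "mean_validation_auc": means,
            "n_iterations": n_ok,
        }
    )


def gene_selection_frequency(records: Iterable[IterationRecord], k: int) -> pd.Series:
    """How often each gene appears in the per-iteration top-k ranking."""
    counts: dict[str, int] = {}
    n = 0
    for r in records:
        n += 1
        for g in r.ranked_genes[:k]:
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=float) / n
    # ties in frequency break lexicographically by gene id
    return freq.sort_index().sort_values(ascending=False, kind="stable")


def select_best_signature(
    records: Sequence[IterationRecord],
) -> tuple[Signature, dict]:
    """Pick the signature the bootstrap evidence supports best.

    The winning size k* maximizes mean out-of-bag AUC across iterations
    (ties favour the smaller size); the reported signature contains the k*
    genes most frequently ranked into the per-iteration top-k* (frequency
    ties break lexicographically).
    """
    records = list(records)
    if not records:
        raise ValidationError("no iteration records to select from")
    sizes = per_size_validation_auc(records)
    if not np.isfinite(sizes["mean_validation_auc"]).any():
        raise ValidationError("all validation metrics are missing; nothing to select")
    best_k = None
    best_auc = -np.inf
    for _, row in sizes.iterrows():
        auc = row["mean_validation_auc"]
        if np.isfinite(auc) and auc > best_auc:  # strict > keeps the smaller size on ties
            best_auc = float(auc)
            best_k = int(row["size"])
    freq = gene_selection_frequency(records, best_k)
    genes = tuple(freq.index[:best_k])
    summary = {
        "per_size": sizes,
        "gene_frequency": freq,
        "best_size": best_k,
        "best_mean_validation_auc": best_auc,
    }
    return Signature(genes), summary
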