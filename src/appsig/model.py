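"""Ridge-penalized logistic regression fitted by IRLS.

The classifier maps a sample's log2 expression over the signature genes to
p(GA), the probability of gangrenous appendicitis (the clinically dangerous
class). Features are z-scored internally with the fitting data's mean/SD so
the ridge penalty lambda acts comparably on every gene; the standardization
is stored in the model and reapplied verbatim to validation samples, so no
validation information leaks into the fit.

The objective is the penalized log-likelihood

    l(b0, w) - (lambda/2) * ||w||^2

with the intercept unpenalized. With 13 + 16 samples and up to ~10 genes,
complete separation is common; any lambda > 0 keeps the coefficients finite.
Newton/IRLS iterations stop when the largest absolute coefficient change
drops below ``tol`` (default 1e-8) or after ``max_iter`` (default 100)
iterations; the ``converged`` flag records which.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from appsig.errors import SchemaError, ValidationError


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class LogisticModel:
    """Fitted ridge-logistic classifier over one gene signature."""

    intercept: float
    weights: dict[str, float]  # gene_id -> coefficient on the z-scored feature
    ridge_lambda: float
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    converged: bool
    n_iterations: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights)

    def save(self, path: str | Path) -> None:
        """Serialize to a plain-text key:value file."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"intercept\t{self.intercept!r}\n")
            fh.write(f"ridge_lambda\t{self.ridge_lambda!r}\n")
            fh.write(f"converged\t{int(self.converged)}\n")
            fh.write(f"n_iterations\t{self.n_iterations}\n")
            for g in self.gene_ids:
                fh.write(
                    f"gene\t{g}\t{self.weights[g]!r}\t"
                    f"{self.feature_means[g]!r}\t{self.feature_sds[g]!r}\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        scalars: dict[str, str] = {}
        weights: dict[str, float] = {}
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "gene":
                    _, g, w, m, s = parts
                    weights[g], means[g], sds[g] = float(w), float(m), float(s)
                else:
                    scalars[parts[0]] = parts[1]
        return cls(
            intercept=float(scalars["intercept"]),
            weights=weights,
            ridge_lambda=float(scalars["ridge_lambda"]),
            feature_means=means,
            feature_sds=sds,
            converged=bool(int(scalars["converged"])),
            n_iterations=int(scalars["n_iterations"]),
        )


def penalized_loglik(
    intercept: float, w: np.ndarray, Z: np.ndarray, y: np.ndarray, ridge_lambda: float
) -> float:
    """l(b0, w) - (lambda/2)||w||^2 on an already-standardized design Z."""
    eta = intercept + Z @ w
    # log-likelihood: sum y*eta - log(1 + exp(eta)), computed stably
    ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
    return ll - 0.5 * ridge_lambda * float(w @ w)


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    ridge_lambda: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Fit p(GA | signature genes) by IRLS on z-scored features.

    Parameters
    ----------
    X
        samples x signature-genes DataFrame of log2 values (columns are the
        signature's gene identifiers).
    y
        binary labels (0 = PA, 1 = GA); both classes must be present.
    ridge_lambda
        penalty on the squared weights (not the intercept); must be >= 0.

    A zero-variance column cannot be z-scored: its weight is fixed at 0 (with
    a warning) and its stored SD set to 1 so that prediction is well defined.
    """
    if ridge_lambda < 0:
        raise ValidationError("ridge_lambda must be >= 0")
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y disagree on the number of samples")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if len(classes) < 2:
            raise ValidationError("y contains a single class; cannot fit")
        raise ValidationError("y must be coded 0/1")

    gene_ids = [str(c) for c in X.columns]
    raw = X.to_numpy(dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    constant = sds == 0.0
    if constant.any():
        warnings.warn(
            f"zero-variance signature column(s) {list(np.array(gene_ids)[constant])}; "
            "their weights are fixed at 0",
            stacklevel=2,
        )
    sds_safe = np.where(constant, 1.0, sds)
    Z = (raw - means) / sds_safe
    active = ~constant

    n, p = Z.shape
    beta = np.zeros(p + 1)  # [intercept, weights]
    Za = Z[:, active]
    pa = int(active.sum())
    penalty = np.zeros(pa + 1)
    penalty[1:] = ridge_lambda
    design = np.hstack([np.ones((n, 1)), Za])
    beta_a = np.zeros(pa + 1)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = design @ beta_a
        mu = _sigmoid(eta)
        w_irls = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = design.T @ (y - mu) - penalty * beta_a
        hess = (design * w_irls[:, None]).T @ design + np.diag(penalty)
        step = np.linalg.solve(hess, grad)
        beta_a = beta_a + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    beta[0] = beta_a[0]
    beta[1:][active] = beta_a[1:]
    return LogisticModel(
        intercept=float(beta[0]),
        weights={g: float(b) for g, b in zip(gene_ids, beta[1:])},
        ridge_lambda=float(ridge_lambda),
        feature_means={g: float(m) for g, m in zip(gene_ids, means)},
        feature_sds={g: float(s) for g, s in zip(gene_ids, sds_safe)},
        converged=converged,
        n_iterations=n_iter,
    )


def predict_proba(model: LogisticModel, X: pd.DataFrame) -> np.ndarray:
    """p(GA) per sample; X must carry every signature gene as a column."""
    missing = [g for g in model.gene_ids if g not in X.columns]
    if missing:
        raise SchemaError(f"signature gene(s) missing from input: {missing}")
    genes = model.gene_ids
    raw = X[genes].to_numpy(dtype=float)
    means = np.array([model.feature_means[g] for g in genes])
    sds = np.array([model.feature_sds[g] for g in genes])
    w = np.array([model.weights[g] for g in genes])
    eta = model.intercept + ((raw - means) / sds) @ w
    return _sigmoid(eta)
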