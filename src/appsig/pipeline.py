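"""End-to-end orchestration: simulate/load -> preprocess -> DE -> signature
search -> ROC/AUC evaluation, with a reproducibility manifest.

A run is a pure function of its configuration: one global seed is expanded
via ``numpy.random.SeedSequence`` into independent per-stage streams, so e.g.
changing the number of bootstrap iterations does not perturb the synthetic
data. Outputs carry no timestamps — two runs with the same configuration
produce byte-identical artifact files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

import appsig
from appsig.data_io import (
    ClassLabels,
    ExpressionMatrix,
    read_expression_matrix,
    read_labels,
    write_expression_matrix,
    write_labels,
    write_table,
)
from appsig.diffexpr import DifferentialExpressionTable, run_de
from appsig.errors import ValidationError
from appsig.evaluation import (
    DEFAULT_THRESHOLDS,
    AUCSummary,
    aggregate_roc,
    mean_roc_auc,
    summarize_auc,
)
from appsig.preprocess import preprocess
from appsig.signature import (
    IterationRecord,
    Signature,
    run_discovery_validation,
    select_best_signature,
)
from appsig.synthetic import GroundTruth, SyntheticConfig, generate_dataset

ARTIFACTS = (
    "de_table.tsv",
    "iterations.tsv",
    "per_size_auc.tsv",
    "signature.txt",
    "roc.tsv",
    "auc_summary.tsv",
    "manifest.json",
)


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of (file inputs, synthetic) is set."""

    matrix_path: str | None = None
    labels_path: str | None = None
    synthetic: SyntheticConfig | None = None
    quantile: bool = True
    log2: bool = True
    alpha: float = 0.05
    B: int = 1000
    k_max: int = 10
    ridge_lambda: float = 1.0
    thresholds: tuple[float, ...] = tuple(DEFAULT_THRESHOLDS)
    ranking: str = "per-iteration"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        file_mode = self.matrix_path is not None or self.labels_path is not None
        if file_mode and self.synthetic is not None:
            raise ValidationError("give either input files or a synthetic config, not both")
        if file_mode and (self.matrix_path is None or self.labels_path is None):
            raise ValidationError("file input needs both matrix_path and labels_path")
        if not file_mode and self.synthetic is None:
            raise ValidationError("either input files or a synthetic config is required")
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.B < 1 or self.k_max < 1:
            raise ValidationError("B and k_max must be >= 1")
        if self.ridge_lambda < 0:
            raise ValidationError("ridge_lambda must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "matrix_path": self.matrix_path,
            "labels_path": self.labels_path,
            "synthetic": None,
            "quantile": self.quantile,
            "log2": self.log2,
            "alpha": self.alpha,
            "B": self.B,
            "k_max": self.k_max,
            "ridge_lambda": self.ridge_lambda,
            "thresholds": list(self.thresholds),
            "ranking": self.ranking,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            d["synthetic"] = {
                "n_class0": self.synthetic.n_class0,
                "n_class1": self.synthetic.n_class1,
                "n_genes": self.synthetic.n_genes,
                "n_informative": self.synthetic.n_informative,
                "delta_log2": self.synthetic.delta_log2,
                "sigma_log2": self.synthetic.sigma_log2,
                "baseline_log2_range": list(self.synthetic.baseline_log2_range),
                "equicorrelation": self.synthetic.equicorrelation,
            }
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    de: DifferentialExpressionTable
    records: list[IterationRecord]
    signature: Signature
    summary: dict
    roc: pd.DataFrame
    auc: AUCSummary
    truth: GroundTruth | None = None
    manifest: dict = field(default_factory=dict)


def _stage_seeds(seed: int, n: int = 2) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _load_inputs(
    config: RunConfig,
) -> tuple[ExpressionMatrix, ClassLabels, GroundTruth | None]:
    if config.synthetic is not None:
        data_seed, _ = _stage_seeds(config.seed)
        syn = SyntheticConfig(
            **{
                k: getattr(config.synthetic, k)
                for k in (
                    "n_class0",
                    "n_class1",
                    "n_genes",
                    "n_informative",
                    "delta_log2",
                    "sigma_log2",
                    "baseline_log2_range",
                    "equicorrelation",
                )
            },
            seed=data_seed,
        )
        return generate_dataset(syn)
    matrix = read_expression_matrix(config.matrix_path)
    labels = read_labels(config.labels_path, matrix)
    return matrix, labels, None


def iterations_frame(records: Iterable[IterationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for k, sig in enumerate(r.signatures, start=1):
            rows.append(
                {
                    "iteration": r.iteration_index,
                    "size": k,
                    "genes": ",".join(sig.gene_ids),
                    "discovery_auc": r.discovery_auc[k - 1],
                    "validation_auc": r.validation_auc[k - 1],
                    "n_validation": len(r.validation_labels),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in the fixed order and (optionally) write artifacts.

    Stages: load-or-simulate -> quantile normalization -> log2 -> whole-matrix
    differential expression (reporting only; gene ranking for the signature
    search is redone inside each bootstrap iteration) -> bootstrap
    discovery/validation search -> signature selection -> ROC/AUC aggregation
    at the selected size. If ``config.out_dir`` is set, all result tables, the
    signature, and a manifest sufficient for bit-identical re-running are
    written there.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "version": appsig.__version__}
    try:
        result = _run_stages(config, manifest)
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        if out_dir is not None:
            _write_manifest(manifest, out_dir)
        raise
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    return result


def _run_stages(config: RunConfig, manifest: dict) -> PipelineResult:
    matrix, labels, truth = _load_inputs(config)
    manifest["stage"] = "preprocess"
    processed = preprocess(matrix, quantile=config.quantile, log2=config.log2)

    manifest["stage"] = "diffexpr"
    de = run_de(processed, labels, alpha=config.alpha)
    manifest["n_genes"] = de.n_genes
    manifest["n_significant"] = de.n_significant
    manifest["percent_significant"] = round(de.percent_significant, 1)

    manifest["stage"] = "signature_search"
    _, boot_seed = _stage_seeds(config.seed)
    records = run_discovery_validation(
        processed,
        labels,
        B=config.B,
        k_max=config.k_max,
        ridge_lambda=config.ridge_lambda,
        seed=boot_seed,
        ranking=config.ranking,
    )
    n_failed = int(sum(np.isnan(r.validation_auc).any() for r in records))
    manifest["iterations_completed"] = len(records)
    manifest["iterations_with_failed_fit"] = n_failed

    manifest["stage"] = "selection"
    signature, summary = select_best_signature(records)

    manifest["stage"] = "evaluation"
    roc = aggregate_roc(records, config.thresholds, signature_size=summary["best_size"])
    auc = summarize_auc(records, summary["best_size"])

    manifest.update(
        {
            "stage": "done",
            "status": "ok",
            "selected_signature": list(signature.gene_ids),
            "selected_size": summary["best_size"],
            "mean_validation_auc": auc.mean_auc,
            "se_auc": auc.se_auc,
            "cl_lower_normal": auc.cl_lower_normal,
            "cl_lower_percentile": auc.cl_lower_percentile,
            "mean_curve_auc": mean_roc_auc(roc),
        }
    )
    return PipelineResult(
        config=config,
        de=de,
        records=records,
        signature=signature,
        summary=summary,
        roc=roc,
        auc=auc,
        truth=truth,
        manifest=manifest,
    )


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    write_table(result.de.table, out_dir / "de_table.tsv")
    write_table(iterations_frame(result.records), out_dir / "iterations.tsv")
    write_table(result.summary["per_size"], out_dir / "per_size_auc.tsv")
    with open(out_dir / "signature.txt", "w", encoding="utf-8") as fh:
        fh.write("\t".join(result.signature.gene_ids) + "\n")
    write_table(result.roc, out_dir / "roc.tsv")
    a = result.auc
    write_table(
        pd.DataFrame(
            [
                {
                    "mean_auc": a.mean_auc,
                    "se_auc": a.se_auc,
                    "cl_lower_normal": a.cl_lower_normal,
                    "cl_lower_percentile": a.cl_lower_percentile,
                    "mean_curve_auc": mean_roc_auc(result.roc),
                    "n_iterations": a.n_iterations,
                }
            ]
        ),
        out_dir / "auc_summary.tsv",
    )
    _write_manifest(result.manifest, out_dir)


def simulate_to_dir(config: SyntheticConfig, out_dir: str | Path, force: bool = False) -> list[Path]:
    """Write a synthetic dataset (matrix, labels, ground truth) as TSV files."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ValidationError(f"output directory {out_dir} is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, labels, truth = generate_dataset(config)
    paths = [out_dir / "matrix.tsv", out_dir / "labels.tsv", out_dir / "truth.tsv"]
    write_expression_matrix(matrix, paths[0])
    write_labels(labels, paths[1])
    write_table(truth.to_frame(), paths[2])
    return paths


def report(run_dir: str | Path) -> str:
    """Human-readable summary assembled purely from a completed run's files."""
    run_dir = Path(run_dir)
    for name in ("signature.txt", "per_size_auc.tsv", "auc_summary.tsv"):
        if not (run_dir / name).exists():
            raise ValidationError(f"missing run artifact: {run_dir / name}")
    signature = (run_dir / "signature.txt").read_text().strip().split("\t")
    per_size = pd.read_csv(run_dir / "per_size_auc.tsv", sep="\t")
    auc_row = pd.read_csv(run_dir / "auc_summary.tsv", sep="\t").iloc[0]
    lines = [
        f"Selected signature ({len(signature)} genes): {', '.join(signature)}",
        "Mean out-of-bag AUC by signature size:",
    ]
    for _, row in per_size.iterrows():
        lines.append(
            f"  size {int(row['size']):2d}: {row['mean_validation_auc']:.3f} "
            f"({int(row['n_iterations'])} iterations)"
        )
    lines.append(
        f"AUC was {100 * auc_row['mean_auc']:.0f}% (SE {100 * auc_row['se_auc']:.0f}, "
        f"CL {100 * auc_row['cl_lower_normal']:.1f})"
    )
    lines.append(
        f"Percentile lower confidence limit: {100 * auc_row['cl_lower_percentile']:.1f}%"
    )
    return "\n".join(lines)
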