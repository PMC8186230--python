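import numpy as np
import pandas as pd
import pytest

from appsig.data_io import ClassLabels
from appsig.errors import ValidationError
from appsig.preprocess import log2_transform, quantile_normalize
from appsig.signature import (
    Signature,
    bootstrap_split,
    build_candidate_signatures,
    per_size_validation_auc,
    run_discovery_validation,
    select_best_signature,
)
from appsig.synthetic import SyntheticConfig, generate_dataset


def _prepared(n_genes=150, seed=0, **kw):
    matrix, labels, truth = generate_dataset(SyntheticConfig(n_genes=n_genes, seed=seed, **kw))
    return log2_transform(quantile_normalize(matrix)), labels, truth


class TestBootstrapSplit:
    def test_discovery_size_and_oob_disjointness(self, rng):
        y = np.array([0] * 13 + [1] * 16)
        for i in range(50):
            s = bootstrap_split(29, y, rng, iteration_index=i)
            assert len(s.discovery_indices) == 29
            assert np.intersect1d(s.discovery_indices, s.validation_indices).size == 0
            assert set(np.unique(y[s.validation_indices])) == {0, 1}

    def test_mean_oob_size_matches_closed_form(self, rng):
        y = np.array([0] * 13 + [1] * 16)
        sizes = [bootstrap_split(29, y, rng).validation_indices.size for _ in range(4000)]
        expected = 29 * (1 - 1 / 29) ** 29  # ~10.48
        assert np.mean(sizes) == pytest.approx(expected, abs=0.3)

    def test_minimal_two_per_class_design(self, rng):
        y = np.array([0, 0, 1, 1])
        for _ in range(30):
            s = bootstrap_split(4, y, rng)
            assert s.validation_indices.size >= 1
            assert set(np.unique(y[s.validation_indices])) == {0, 1}

    def test_fixed_rng_state_reproduces_split_sequence(self):
        y = np.array([0] * 6 + [1] * 6)
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        for _ in range(10):
            a, b = bootstrap_split(12, y, r1), bootstrap_split(12, y, r2)
            np.testing.assert_array_equal(a.discovery_indices, b.discovery_indices)
            np.testing.assert_array_equal(a.validation_indices, b.validation_indices)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            bootstrap_split(3, np.array([0, 0, 1]), rng)


class TestCandidateSignatures:
    def test_nested_top_k_definition(self):
        sigs = build_candidate_signatures(["g7", "g2", "g9", "g1"], k_max=3)
        assert [s.gene_ids for s in sigs] == [("g7",), ("g7", "g2"), ("g7", "g2", "g9")]

    def test_k_max_one(self):
        assert build_candidate_signatures(["gA", "gB"], 1)[0].gene_ids == ("gA",)

    def test_candidates_distinct_and_nested(self):
        sigs = build_candidate_signatures([f"g{i}" for i in range(8)], 8)
        seen = set()
        for i, s in enumerate(sigs):
            assert s.gene_ids not in seen
            seen.add(s.gene_ids)
            if i:
                assert set(sigs[i - 1].gene_ids) < set(s.gene_ids)

    def test_invalid_k_max(self):
        with pytest.raises(ValidationError):
            build_candidate_signatures(["g1"], 0)

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValidationError):
            Signature(("g1", "g1"))


class TestRunDiscoveryValidation:
    def test_no_leakage_between_discovery_and_validation(self):
        matrix, labels, _ = _prepared(seed=1)
        records = run_discovery_validation(matrix, labels, B=20, k_max=4, seed=3)
        y = labels.y_for(matrix)
        for r in records:
            disc, val = r.split.discovery_indices, r.split.validation_indices
            assert np.intersect1d(disc, val).size == 0
            np.testing.assert_array_equal(r.validation_labels, y[val])
            for p in r.validation_probabilities:
                assert p.shape == (val.size,)

    def test_gene_ranking_ignores_validation_samples(self):
        """Perturbing only out-of-bag sample values leaves the discovery
        ranking of that iteration unchanged."""
        matrix, labels, _ = _prepared(seed=2)
        [rec] = run_discovery_validation(matrix, labels, B=1, k_max=5, seed=7)
        perturbed = matrix.values.copy()
        perturbed.iloc[:, rec.split.validation_indices] += np.linspace(
            0.5, 3.0, rec.split.validation_indices.size
        )
        from appsig.data_io import ExpressionMatrix

        m2 = ExpressionMatrix(perturbed, scale="log2")
        [rec2] = run_discovery_validation(m2, labels, B=1, k_max=5, seed=7)
        assert rec.ranked_genes == rec2.ranked_genes

    def test_deterministic_in_seed(self):
        matrix, labels, _ = _prepared(seed=4)
        r1 = run_discovery_validation(matrix, labels, B=10, k_max=3, seed=9)
        r2 = run_discovery_validation(matrix, labels, B=10, k_max=3, seed=9)
        for a, b in zip(r1, r2):
            assert a.ranked_genes == b.ranked_genes
            np.testing.assert_array_equal(a.validation_auc, b.validation_auc)
            np.testing.assert_array_equal(a.discovery_auc, b.discovery_auc)

    def test_global_ranking_mode_uses_one_ranking(self):
        matrix, labels, _ = _prepared(seed=5)
        records = run_discovery_validation(
            matrix, labels, B=8, k_max=4, seed=11, ranking="global"
        )
        rankings = {r.ranked_genes for r in records}
        assert len(rankings) == 1

    def test_informative_signature_beats_random_genes(self, rng):
        """Mean out-of-bag AUC of the size-4 candidate exceeds that of a
        random 4-gene signature fitted the same way (paired comparison)."""
        from appsig.evaluation import auc_concordance
        from appsig.model import fit_logistic, predict_proba

        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            matrix, labels, truth = _prepared(n_genes=300, seed=seed)
            records = run_discovery_validation(matrix, labels, B=40, k_max=4, seed=seed)
            sel_auc = per_size_validation_auc(records)["mean_validation_auc"].iloc[3]
            X = matrix.samples_by_genes()
            y = labels.y_for(matrix)
            rand_aucs = []
            for r in records:
                genes = list(rng.choice(matrix.gene_ids, size=4, replace=False))
                disc, val = r.split.discovery_indices, r.split.validation_indices
                model = fit_logistic(X[genes].iloc[disc], y[disc])
                rand_aucs.append(auc_concordance(predict_proba(model, X[genes].iloc[val]), y[val]))
            if sel_auc > np.mean(rand_aucs):
                wins += 1
        assert wins == n_seeds


class TestSelectBestSignature:
    def test_dominating_size_wins(self):
        matrix, labels, truth = _prepared(n_genes=400, seed=6, delta_log2=2.5)
        records = run_discovery_validation(matrix, labels, B=60, k_max=6, seed=13)
        sig, summary = select_best_signature(records)
        assert len(sig) == summary["best_size"]
        per_size = summary["per_size"]
        best = per_size["mean_validation_auc"].max()
        assert summary["best_mean_validation_auc"] == pytest.approx(best)

    def test_parsimony_tie_break_prefers_smaller_size(self):
        class _Rec:  # minimal synthetic iteration record
            def __init__(self, ranked):
                self.ranked_genes = ranked
                self.signatures = [
                    Signature(ranked[:1]), Signature(ranked[:2]), Signature(ranked[:3])
                ]
                self.validation_auc = np.array([0.8, 0.8, 0.7])
                self.discovery_auc = np.array([0.9, 0.9, 0.9])

        sig, summary = select_best_signature([_Rec(("gB", "gA", "gC")), _Rec(("gB", "gC", "gA"))])
        assert summary["best_size"] == 1
        assert sig.gene_ids == ("gB",)

    def test_selected_genes_are_planted(self):
        # whichever size wins, the genes it contains should be planted ones
        matrix, labels, truth = _prepared(n_genes=500, seed=8)
        records = run_discovery_validation(matrix, labels, B=80, k_max=8, seed=15)
        sig, summary = select_best_signature(records)
        assert set(sig.gene_ids) <= set(truth.informative_gene_ids)
        assert summary["best_mean_validation_auc"] > 0.9

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            select_best_signature([])
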