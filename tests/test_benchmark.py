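from itertools import permutations

import numpy as np
import pytest

from corrbic.benchmark import (
    Bicluster,
    consensus_score,
    evaluate_collections,
    f1_scores,
    jaccard_index,
    jaccard_matrix,
    match_biclusters,
    roc_from_ranking,
    select_optimum,
)


def bic(genes, samples, label=""):
    return Bicluster(frozenset(genes), frozenset(samples), label)


class TestJaccard:
    def test_identical_is_one(self):
        a = bic("abcd", "wxyz")
        assert jaccard_index(a, a) == 1.0

    def test_disjoint_genes_is_zero(self):
        assert jaccard_index(bic("ab", "wx"), bic("cd", "wx")) == 0.0

    def test_partial_overlap_enumerates_cells(self):
        # two 4x4 biclusters overlapping in a 2x2 block: 4 / (16+16-4) = 1/7
        a = bic("abcd", "stuv")
        b = bic("cdef", "uvwx")
        assert jaccard_index(a, b) == pytest.approx(4 / 28)
        # independent cell-set oracle
        cells_a = {(g, s) for g in a.genes for s in a.samples}
        cells_b = {(g, s) for g in b.genes for s in b.samples}
        assert jaccard_index(a, b) == pytest.approx(len(cells_a & cells_b) / len(cells_a | cells_b))

    def test_empty_bicluster_errors(self):
        with pytest.raises(ValueError):
            jaccard_index(bic("", "ab"), bic("ab", "cd"))


def _random_collection(rng, n, universe_genes, universe_samples):
    out = []
    for i in range(n):
        genes = rng.choice(universe_genes, size=rng.integers(2, 6), replace=False)
        samples = rng.choice(universe_samples, size=rng.integers(2, 6), replace=False)
        out.append(bic(genes, samples, f"b{i}"))
    return out


class TestMatching:
    def test_permuted_collection_identity_total(self, rng):
        genes = [f"g{i}" for i in range(30)]
        samples = [f"s{i}" for i in range(30)]
        known = _random_collection(rng, 4, genes, samples)
        pred = [known[2], known[0], known[3], known[1]]
        matching = match_biclusters(pred, known)
        J = jaccard_matrix(pred, known)
        assert sum(J[i, j] for i, j in matching) == pytest.approx(len(known))

    def test_matches_exhaustive_assignment(self, rng):
        genes = [f"g{i}" for i in range(40)]
        samples = [f"s{i}" for i in range(40)]
        for trial in range(5):
            local = np.random.default_rng(trial)
            pred = _random_collection(local, 3, genes, samples)
            known = _random_collection(local, 3, genes, samples)
            J = jaccard_matrix(pred, known)
            best = max(sum(J[i, p[i]] for i in range(3)) for p in permutations(range(3)))
            matching = match_biclusters(pred, known)
            assert sum(J[i, j] for i, j in matching) == pytest.approx(best, abs=1e-12)

    def test_single_prediction_matches_argmax(self, rng):
        genes = [f"g{i}" for i in range(30)]
        samples = [f"s{i}" for i in range(30)]
        known = _random_collection(rng, 4, genes, samples)
        pred = [known[2]]
        [(i, j)] = match_biclusters(pred, known)
        assert i == 0 and j == 2


class TestConsensus:
    def test_perfect_recovery(self, rng):
        known = _random_collection(rng, 8, [f"g{i}" for i in range(60)], [f"s{i}" for i in range(60)])
        assert consensus_score(known, known) == pytest.approx(1.0)

    def test_six_of_eight(self, rng):
        known = _random_collection(rng, 8, [f"g{i}" for i in range(80)], [f"s{i}" for i in range(80)])
        assert consensus_score(known[:6], known) == pytest.approx(6 / 8)

    def test_spurious_prediction_never_increases(self, rng):
        genes = [f"g{i}" for i in range(50)]
        samples = [f"s{i}" for i in range(50)]
        known = _random_collection(rng, 3, genes, samples)
        pred = list(known)
        base = consensus_score(pred, known)
        spurious = bic(genes[40:45], samples[40:45], "extra")
        assert consensus_score(pred + [spurious], known) <= base + 1e-12

    def test_empty_pred_is_zero(self, rng):
        known = _random_collection(rng, 2, [f"g{i}" for i in range(20)], [f"s{i}" for i in range(20)])
        assert consensus_score([], known) == 0.0

    def test_symmetric_for_equal_sizes(self, rng):
        genes = [f"g{i}" for i in range(40)]
        samples = [f"s{i}" for i in range(40)]
        a = _random_collection(rng, 3, genes, samples)
        b = _random_collection(rng, 3, genes, samples)
        assert consensus_score(a, b) == pytest.approx(consensus_score(b, a), abs=1e-12)


class TestF1:
    def test_perfect_recovery(self, rng):
        known = _random_collection(rng, 4, [f"g{i}" for i in range(40)], [f"s{i}" for i in range(40)])
        rep = f1_scores(match_biclusters(known, known), known, known)
        assert rep.genes_f1 == pytest.approx(1.0)
        assert rep.samples_f1 == pytest.approx(1.0)

    def test_half_recall_full_precision(self):
        known = [bic([f"g{i}" for i in range(10)], ["s1", "s2", "s3"], "k")]
        pred = [bic([f"g{i}" for i in range(5)], ["s1", "s2", "s3"], "p")]
        rep = f1_scores([(0, 0)], pred, known)
        row = rep.per_pair.iloc[0]
        assert row.gene_recall == pytest.approx(0.5)
        assert row.gene_precision == pytest.approx(1.0)
        assert rep.genes_f1 == pytest.approx(2 / 3)
        assert rep.samples_f1 == pytest.approx(1.0)

    def test_unmatched_knowns_count_zero(self, rng):
        known = _random_collection(rng, 4, [f"g{i}" for i in range(60)], [f"s{i}" for i in range(60)])
        pred = known[:2]
        rep = f1_scores(match_biclusters(pred, known), pred, known)
        assert rep.genes_f1 == pytest.approx(2 / 4)
        assert (rep.per_pair.gene_f1 == 0).sum() == 2


class TestRoc:
    def test_perfect_ranking_auc_one(self):
        order = list("abcdefgh")
        _, auc = roc_from_ranking(order, {"a", "b", "c"})
        assert auc == pytest.approx(1.0)

    def test_random_ranking_auc_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(200):
            order = rng.permutation(40)
            _, auc = roc_from_ranking(order.tolist(), set(range(10)))
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_degenerate_known_sets_error(self):
        with pytest.raises(ValueError):
            roc_from_ranking(list("abc"), set())
        with pytest.raises(ValueError):
            roc_from_ranking(list("abc"), {"a", "b", "c"})


class TestSelectOptimum:
    def test_noiseless_recovery_exact(self):
        known = bic([f"g{i}" for i in range(5)], [f"s{j}" for j in range(4)], "k")
        gene_order = [f"g{i}" for i in range(10)]
        sample_order = [f"s{j}" for j in range(8)]
        pred, jac = select_optimum(sample_order, gene_order, known)
        assert jac == pytest.approx(1.0)
        assert pred.genes == known.genes and pred.samples == known.samples

    def test_matches_exhaustive_prefix_scan(self, rng):
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(20)]
        gene_order = list(rng.permutation(genes))
        sample_order = list(rng.permutation(samples))
        known = bic(rng.choice(genes, 7, replace=False), rng.choice(samples, 6, replace=False), "k")
        pred, jac = select_optimum(sample_order, gene_order, known)
        best = max(
            jaccard_index(bic(gene_order[:i], sample_order[:j]), known)
            for i in range(1, 21)
            for j in range(1, 21)
        )
        assert jac == pytest.approx(best, abs=1e-12)

    def test_optimum_at_least_threshold_jaccard(self, rng):
        """Optimum prefix selection can only beat any fixed prefix choice."""
        genes = [f"g{i}" for i in range(15)]
        samples = [f"s{j}" for j in range(15)]
        gene_order = list(rng.permutation(genes))
        sample_order = list(rng.permutation(samples))
        known = bic(rng.choice(genes, 5, replace=False), rng.choice(samples, 5, replace=False), "k")
        _, jac = select_optimum(sample_order, gene_order, known)
        fixed = bic(gene_order[:5], sample_order[:5])
        assert jac >= jaccard_index(fixed, known) - 1e-12


class TestEvaluateCollections:
    def test_report_consistency(self, rng):
        genes = [f"g{i}" for i in range(50)]
        samples = [f"s{i}" for i in range(50)]
        pred = _random_collection(rng, 3, genes, samples)
        known = _random_collection(rng, 5, genes, samples)
        report = evaluate_collections(pred, known)
        assert report.consensus == pytest.approx(consensus_score(pred, known), abs=1e-12)
        assert 0.0 <= report.genes_f1 <= 1.0
        assert 0.0 <= report.samples_f1 <= 1.0
        assert len(report.matching) == min(len(pred), len(known))
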