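import math
from itertools import combinations

import numpy as np
import pytest

from corrbic.extend import (
    CorrelationVector,
    ForkAssignment,
    SampleRanking,
    average_expression_vector,
    classify_forks,
    correlation_vector,
    fork_permutation_test,
    pc1_projection,
    sort_samples,
    threshold_bicluster,
)
from corrbic.search import correlation_score


def pearson(a, b):
    a = a - np.mean(a)
    b = b - np.mean(b)
    return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))


class TestAverageExpressionVector:
    def test_identical_genes_return_profile(self, rng):
        profile = rng.normal(size=6)
        values = np.tile(profile, (8, 1))
        values += rng.normal(scale=1e-12, size=values.shape)  # break exact ties only
        avg, members = average_expression_vector(values, np.arange(8), np.arange(6))
        assert pearson(avg, profile) == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_groups_symmetry(self, rng):
        profile = rng.normal(size=7)
        up = np.outer(np.abs(rng.normal(2, 0.3, size=4)), profile)
        down = np.outer(-np.abs(rng.normal(2, 0.3, size=4)), profile)
        values = np.vstack([up, down])
        avg, members = average_expression_vector(values, np.arange(8), np.arange(7))
        # the other group's genes correlate with the profile at exactly -1
        other = sorted(set(range(8)) - set(members.tolist()))
        for g in other:
            assert pearson(values[g], avg) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_exhaustive_group_scan(self):
        from corrbic.search import gene_correlation_groups

        values = np.random.default_rng(77).normal(size=(30, 9))
        groups = gene_correlation_groups(values, np.arange(30), np.arange(9), n_groups=3)
        best_score, best_members = -np.inf, None
        for g in groups:
            if g.size < 2:
                continue
            profile = values[g].mean(axis=0)
            score = np.mean([abs(pearson(values[i], profile)) for i in g])
            if score > best_score:
                best_score, best_members = score, tuple(g)
        _, members = average_expression_vector(values, np.arange(30), np.arange(9), n_groups=3)
        assert tuple(members) == best_members


class TestCorrelationVector:
    def test_identical_and_negated_genes(self, rng):
        avg = rng.normal(size=8)
        values = np.vstack([avg, -avg, rng.normal(size=(3, 8))])
        cv = correlation_vector(values, avg, np.arange(8))
        assert cv.values[0] == pytest.approx(1.0)
        assert cv.values[1] == pytest.approx(-1.0)

    def test_definitional_oracle(self, rng):
        values = rng.normal(size=(10, 12))
        avg = rng.normal(size=5)
        cv = correlation_vector(values, avg, np.array([1, 3, 5, 7, 9]))
        for g in range(10):
            expected = pearson(values[g, [1, 3, 5, 7, 9]], avg)
            assert cv.values[g] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_gets_zero(self, rng):
        values = rng.normal(size=(4, 6))
        values[2] = 7.0
        cv = correlation_vector(values, rng.normal(size=6), np.arange(6))
        assert cv.values[2] == 0.0

    def test_gene_order_by_absolute_value(self):
        cv = CorrelationVector(np.array([0.5, -0.9, 0.1, 0.9]))
        assert cv.gene_order().tolist() == [1, 3, 0, 2]  # tie 0.9 broken by input order


class TestSortSamples:
    def test_ranking_is_core_when_no_other_samples(self, rng):
        values = rng.normal(size=(5, 4))
        r = sort_samples(values, np.arange(5), np.arange(4))
        assert r.order.tolist() == [0, 1, 2, 3]
        assert r.prefix_scores.size == 1

    def test_prefix_scores_match_direct_recomputation(self, rng):
        values = rng.normal(size=(9, 14))
        r = sort_samples(values, np.arange(9), np.array([2, 5, 8]))
        for j in range(3, 15):
            direct = correlation_score(values, np.arange(9), r.order[:j])
            assert r.prefix_scores[j - 3] == pytest.approx(direct, abs=1e-9)

    def test_greedy_choice_is_argmax(self, rng):
        """The sample ranked k+1 maximizes the score over all candidates."""
        values = rng.normal(size=(7, 12))
        core = np.array([0, 1, 2, 3])
        r = sort_samples(values, np.arange(7), core)
        first_added = r.order[4]
        # compare against scoring every non-core candidate directly
        scores = {
            s: correlation_score(values, np.arange(7), np.append(core, s)) for s in range(4, 12)
        }
        assert scores[first_added] == pytest.approx(max(scores.values()), abs=1e-12)

    def test_duplicate_core_column_outranks_noise(self, rng):
        values = rng.normal(size=(6, 10))
        values[:, 7] = values[:, 0]  # duplicates a core sample's column
        r = sort_samples(values, np.arange(6), np.array([0, 1, 2]))
        dup_score = correlation_score(values, np.arange(6), [0, 1, 2, 7])
        for s in range(3, 10):
            if s != 7:
                assert dup_score >= correlation_score(values, np.arange(6), [0, 1, 2, s]) - 1e-12
        assert r.order[3] == 7

    def test_first_prefix_score_is_core_score(self, rng):
        values = rng.normal(size=(6, 9))
        core = np.array([1, 4, 7])
        r = sort_samples(values, np.arange(6), core)
        assert r.prefix_scores[0] == pytest.approx(correlation_score(values, np.arange(6), core), abs=1e-12)

    def test_max_genes_subsamples_core(self, rng):
        values = rng.normal(size=(20, 12))
        r = sort_samples(values, np.arange(20), np.arange(3), max_genes=5,
                         rng=np.random.default_rng(0))
        assert r.order.size == 12  # still a full permutation


class TestPC1:
    def test_rank_one_data_reproduces_profile(self, rng):
        profile = rng.normal(size=12)
        weights = np.abs(rng.normal(2, 0.5, size=6))
        values = np.outer(weights, profile)
        ranking = SampleRanking(np.arange(12), np.zeros(8), k=5)
        pc1 = pc1_projection(values, np.arange(6), ranking, n_fit=5)
        r = abs(pearson(pc1.values, profile))
        assert r >= 0.999
        assert pc1.explained_ratio == pytest.approx(1.0)

    def test_eigen_oracle(self, rng):
        values = rng.normal(size=(5, 9))
        ranking = SampleRanking(np.arange(9), np.zeros(4), k=6)
        pc1 = pc1_projection(values, np.arange(5), ranking, n_fit=6)
        # independent eigen-decomposition of the gene covariance over the fit samples
        A = values[:, :6]
        Ac = A - A.mean(axis=1, keepdims=True)
        cov = Ac @ Ac.T
        evals, evecs = np.linalg.eigh(cov)
        w = evecs[:, -1]
        expected = (values - A.mean(axis=1, keepdims=True)).T @ w
        r = abs(pearson(pc1.values, expected))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_sign_follows_positive_cv_group(self, rng):
        profile = rng.normal(size=10)
        values = np.vstack(
            [np.outer(np.abs(rng.normal(2, 0.3, 4)), profile),
             np.outer(-np.abs(rng.normal(2, 0.3, 4)), profile)]
        )
        ranking = SampleRanking(np.arange(10), np.zeros(6), k=5)
        cv = CorrelationVector(np.concatenate([np.ones(4), -np.ones(4)]))
        pc1 = pc1_projection(values, np.arange(8), ranking, n_fit=5, cv=cv)
        ref = values[:4, :5].mean(axis=0)
        assert pearson(pc1.values[:5], ref) > 0

    def test_n_fit_too_small(self, rng):
        ranking = SampleRanking(np.arange(6), np.zeros(3), k=4)
        with pytest.raises(ValueError, match="n_fit"):
            pc1_projection(rng.normal(size=(4, 6)), np.arange(4), ranking, n_fit=1)


class TestClassifyForks:
    def _threshold(self, samples):
        from corrbic.extend import ThresholdedBicluster

        return ThresholdedBicluster(np.arange(2), np.asarray(samples), alpha=0.05)

    def test_all_positive_pc1_all_upper(self):
        from corrbic.extend import PC1Vector

        pc1 = PC1Vector(np.array([1.0, 2.0, 3.0, 0.5]), np.arange(2), np.arange(2))
        ranking = SampleRanking(np.arange(4), np.zeros(2), k=3)
        forks = classify_forks(pc1, ranking, self._threshold([0, 1, 2, 3]))
        assert list(forks.labels) == ["upper"] * 4

    def test_signs_and_zero(self):
        from corrbic.extend import PC1Vector

        pc1 = PC1Vector(np.array([1.0, -2.0, 0.0, 4.0]), np.arange(2), np.arange(2))
        ranking = SampleRanking(np.arange(4), np.zeros(2), k=3)
        forks = classify_forks(pc1, ranking, self._threshold([0, 1, 2]))
        assert list(forks.labels) == ["upper", "lower", "unassigned", ""]

    def test_empty_threshold_empty_assignment(self):
        from corrbic.extend import PC1Vector

        pc1 = PC1Vector(np.array([1.0, -1.0, 2.0]), np.arange(2), np.arange(2))
        ranking = SampleRanking(np.arange(3), np.zeros(1), k=3)
        forks = classify_forks(pc1, ranking, self._threshold([]))
        assert list(forks.labels) == ["", "", ""]


class TestThresholdBicluster:
    def _extended(self, dataset):
        matrix = dataset.matrix
        truth = dataset.truth[0]
        genes = matrix.gene_indices(sorted(truth.genes))
        samples = matrix.sample_indices(sorted(truth.samples))
        core_samples = samples[:10]
        ranking = sort_samples(matrix, genes, core_samples)
        avg = matrix.values[np.ix_(genes, core_samples)].mean(axis=0)
        cv = correlation_vector(matrix, avg, core_samples)
        return matrix, genes, ranking, cv, samples

    def test_noiseless_bicluster_recovered_exactly(self, noiseless_dataset):
        matrix, genes, ranking, cv, samples = self._extended(noiseless_dataset)
        thr = threshold_bicluster(matrix, genes, ranking, cv, alpha=0.05)
        assert set(thr.sample_indices.tolist()) == set(samples.tolist())
        # member genes have |CV| = 1 in the noiseless limit, so all of them
        # clear the default gene cutoff
        assert np.all(np.abs(cv.values[genes]) >= 1.0 - 1e-9)
        assert set(genes.tolist()).issubset(set(thr.gene_indices.tolist()))

    def test_alpha_monotonicity(self, noiseless_dataset):
        matrix, genes, ranking, cv, _ = self._extended(noiseless_dataset)
        loose = threshold_bicluster(matrix, genes, ranking, cv, alpha=0.5)
        strict = threshold_bicluster(matrix, genes, ranking, cv, alpha=0.05)
        assert len(loose.sample_indices) >= len(strict.sample_indices)

    def test_alpha_out_of_range(self, noiseless_dataset):
        matrix, genes, ranking, cv, _ = self._extended(noiseless_dataset)
        with pytest.raises(ValueError, match="alpha"):
            threshold_bicluster(matrix, genes, ranking, cv, alpha=1.5)

    def test_pure_noise_calibration(self):
        """Under pure noise the threshold retains more than the k core
        samples in ~alpha of runs (binomial 3-sigma band)."""
        n_reps = 200
        alpha = 0.05
        retained = 0
        for rep in range(n_reps):
            rng = np.random.default_rng(10_000 + rep)
            values = rng.standard_normal((30, 60))
            core_genes = np.arange(12)
            core_samples = rng.choice(60, size=10, replace=False)
            ranking = sort_samples(values, core_genes, core_samples)
            avg = values[np.ix_(core_genes, core_samples)].mean(axis=0)
            cv = correlation_vector(values, avg, core_samples)
            thr = threshold_bicluster(values, core_genes, ranking, cv, alpha=alpha)
            retained += len(thr.sample_indices) > 10
        rate = retained / n_reps
        sd = math.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) <= 3 * sd


class TestForkPermutationTest:
    def _forks(self, labels):
        return ForkAssignment(np.asarray(labels, dtype=object), rank_cutoff=len(labels))

    def test_constant_covariate_p_one(self):
        forks = self._forks(["upper", "upper", "lower", "lower", "upper", "lower"])
        obs, p = fork_permutation_test(np.ones(6), forks, n_perm=500)
        assert obs == 0.0
        assert p == pytest.approx(1.0)

    def test_indicator_covariate_hits_floor(self, rng):
        labels = ["upper"] * 12 + ["lower"] * 12
        values = np.array([1.0] * 12 + [0.0] * 12)
        obs, p = fork_permutation_test(values, self._forks(labels), n_perm=999, rng=rng)
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_exhaustive_enumeration_oracle(self, rng):
        values = np.array([3.1, -0.2, 1.4, 0.7, 2.2, -1.0])
        labels = ["upper", "upper", "upper", "lower", "lower", "lower"]
        obs, p = fork_permutation_test(values, self._forks(labels), n_perm=20)
        # independent enumeration of all C(6,3) = 20 label arrangements
        observed = values[:3].mean() - values[3:].mean()
        count = 0
        for comb in combinations(range(6), 3):
            up = values[list(comb)]
            down = values[[i for i in range(6) if i not in comb]]
            if abs(up.mean() - down.mean()) >= abs(observed) - 1e-12:
                count += 1
        assert obs == pytest.approx(observed)
        assert p == pytest.approx(count / 20.0, abs=1e-12)

    def test_empty_fork_errors(self):
        forks = self._forks(["upper", "upper", "upper"])
        with pytest.raises(ValueError, match="fork"):
            fork_permutation_test(np.ones(3), forks, n_perm=10)
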