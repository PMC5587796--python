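"""Extending a bicluster core to the whole matrix.

Given a refined gene core and its k samples, the bicluster is extended in
four steps:

1. an *average expression vector* — the mean profile, over the core
   samples, of the most internally coherent half of the core genes;
2. a *correlation vector* (CV) — the Pearson correlation of every gene in
   the matrix to that profile over the core samples, the bicluster's
   genome-wide signature;
3. a *sample ranking* — all samples ordered by repeatedly appending the
   sample whose inclusion best preserves the gene core's correlation
   score, with the score of every prefix recorded;
4. a *PC1 projection* — principal component analysis fitted on the
   top-ranked samples, projecting every sample onto the first component;
   plotted against rank this produces the characteristic two-fork pattern
   of anti-correlated expression states.

Thresholding then decides which ranked samples and which genes (by |CV|)
formally belong to the bicluster, and a permutation test compares a
per-sample covariate between the two forks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .search import _as_values, correlation_score, gene_correlation_groups

logger = logging.getLogger(__name__)

try:  # optional compiled kernel for the candidate scan of sort_samples
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=False, fastmath=True)
def _scan_candidates(Cu, iu0, iu1, diagC, S1, V, m):  # pragma: no cover - numba
    """Mean-|r| score for every candidate column in V appended to the
    current sample set, from running sums (see sort_samples)."""
    g, c = V.shape
    n_pairs = iu0.size
    scores = np.empty(c)
    sp = np.empty(g)
    inv = np.empty(g)
    for t in range(c):
        valid = True
        for i in range(g):
            s = S1[i] + V[i, t]
            d = m * (diagC[i] + V[i, t] * V[i, t]) - s * s
            if d <= 0.0:
                valid = False
                break
            sp[i] = s
            inv[i] = 1.0 / np.sqrt(d)
        if not valid:
            scores[t] = -np.inf
            continue
        tot = 0.0
        for p in range(n_pairs):
            i = iu0[p]
            j = iu1[p]
            num = m * (Cu[p] + V[i, t] * V[j, t]) - sp[i] * sp[j]
            r = abs(num) * inv[i] * inv[j]
            if r > 1.0:
                r = 1.0
            tot += r
        scores[t] = (g + 2.0 * tot) / (g * g)
    return scores

__all__ = [
    "CorrelationVector",
    "SampleRanking",
    "PC1Vector",
    "ForkAssignment",
    "ThresholdedBicluster",
    "average_expression_vector",
    "correlation_vector",
    "sort_samples",
    "pc1_projection",
    "classify_forks",
    "threshold_bicluster",
    "fork_permutation_test",
]


@dataclass
class CorrelationVector:
    """Per-gene Pearson correlation with the core's average profile."""

    values: np.ndarray  # one value in [-1, 1] per matrix gene
    core_genes: np.ndarray | None = None
    core_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("a correlation vector is 1-D")

    def gene_order(self) -> np.ndarray:
        """Gene indices by decreasing |CV|, ties broken by input order."""
        return np.argsort(-np.abs(self.values), kind="stable")


@dataclass
class SampleRanking:
    """Permutation of all samples by correlation preservation.

    ``order[:k]`` are the core samples; ``prefix_scores[j - k]`` is the
    correlation score of the gene core over the first j ranked samples.
    """

    order: np.ndarray
    prefix_scores: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.intp)
        self.prefix_scores = np.asarray(self.prefix_scores, dtype=np.float64)
        n = self.order.size
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of all sample indices")
        if self.prefix_scores.size != n - self.k + 1:
            raise ValueError("need one prefix score per prefix length k..n")


@dataclass
class PC1Vector:
    values: np.ndarray  # one PC1 value per sample
    genes: np.ndarray  # genes the PCA was fitted on
    fit_samples: np.ndarray  # samples the PCA was fitted on
    sign_flipped: bool = False
    explained_ratio: float = float("nan")


@dataclass
class ForkAssignment:
    labels: np.ndarray  # per-sample: "upper", "lower", "unassigned", or "" outside
    rank_cutoff: int


@dataclass
class ThresholdedBicluster:
    gene_indices: np.ndarray
    sample_indices: np.ndarray  # a prefix of the ranking
    alpha: float
    null_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# average vector and correlation vector
# ---------------------------------------------------------------------------

def average_expression_vector(
    matrix,
    core_genes,
    core_samples,
    n_groups: int = 2,
    linkage_method: str = "average",
):
    """Mean profile of the most coherent core-gene group over the core samples.

    The core genes are split into ``n_groups`` by the same hierarchical
    clustering used for gene-core refinement; each group's mean expression
    profile is scored by the mean |r| between the profile and its member
    genes, and the best group's profile is returned together with the group
    member gene indices.
    """
    values = _as_values(matrix)
    core_samples = np.asarray(core_samples, dtype=np.intp)
    core_genes = np.asarray(core_genes, dtype=np.intp)
    if core_genes.size <= n_groups:
        # core too small to split meaningfully: average over the whole core
        groups = [core_genes]
    else:
        groups = gene_correlation_groups(matrix, core_genes, core_samples, n_groups, linkage_method)
    best_profile = None
    best_members = None
    best_score = -np.inf
    for members in groups:
        if members.size < 2:
            continue
        sub = values[np.ix_(members, core_samples)]
        profile = sub.mean(axis=0)
        if profile.std() == 0.0:
            continue
        z = (sub - sub.mean(axis=1, keepdims=True))
        norms = np.linalg.norm(z, axis=1)
        pz = profile - profile.mean()
        pnorm = np.linalg.norm(pz)
        r = (z @ pz) / (norms * pnorm)
        score = float(np.abs(r).mean())
        if score > best_score:
            best_score = score
            best_profile = profile
            best_members = members
    if best_profile is None:
        raise ValueError("all gene groups have size 1; cannot build an average vector")
    return best_profile, best_members


def correlation_vector(matrix, avg_vector, core_samples, core_genes=None) -> CorrelationVector:
    """Correlate every matrix gene with the average vector over the core samples.

    Genes constant over the core samples get CV = 0 (logged) so the
    downstream |CV| ordering stays total.
    """
    values = _as_values(matrix)
    core_samples = np.asarray(core_samples, dtype=np.intp)
    avg = np.asarray(avg_vector, dtype=np.float64)
    if avg.size != core_samples.size:
        raise ValueError("avg_vector must be indexed by core_samples")
    sub = values[:, core_samples]
    z = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    pz = avg - avg.mean()
    pnorm = np.linalg.norm(pz)
    if pnorm == 0.0:
        raise ValueError("average vector is constant")
    degenerate = norms == 0.0
    norms[degenerate] = 1.0
    cv = (z @ pz) / (norms * pnorm)
    cv[degenerate] = 0.0
    if degenerate.any():
        logger.info("correlation_vector: %d constant genes set to CV = 0", int(degenerate.sum()))
    np.clip(cv, -1.0, 1.0, out=cv)
    return CorrelationVector(
        cv,
        core_genes=None if core_genes is None else np.asarray(core_genes, dtype=np.intp),
        core_samples=core_samples,
    )


# ---------------------------------------------------------------------------
# sample ranking
# ---------------------------------------------------------------------------

def sort_samples(
    matrix,
    core_genes,
    core_samples,
    max_genes: int | None = None,
    rng: np.random.Generator | None = None,
    chunk_elems: int = 4_000_000,
) -> SampleRanking:
    """Rank all samples by how well they preserve the core's correlation.

    Starting from the core samples, the unranked sample maximizing
    ``correlation_score(core_genes, ranked + candidate)`` is appended until
    every sample is ranked; ties break towards the lower sample index.

    The scan is computed incrementally from running per-gene sums and the
    gene-gene cross-product matrix, so each candidate costs O(G^2) instead
    of a fresh O(G^2 j) correlation.  ``max_genes`` optionally subsamples
    the gene core used for scoring (an analysis-scale control for very
    large cores; the ranking semantics are unchanged).
    """
    values = _as_values(matrix)
    core_genes = np.asarray(core_genes, dtype=np.intp)
    core_samples = np.asarray(core_samples, dtype=np.intp)
    if max_genes is not None and core_genes.size > max_genes:
        rng = rng or np.random.default_rng(0)
        core_genes = np.sort(rng.choice(core_genes, size=max_genes, replace=False))
    k = core_samples.size
    X = values[core_genes].astype(np.float64)
    X = X - X.mean(axis=1, keepdims=True)  # global centring: Pearson-invariant, better conditioned
    g, n = X.shape

    iu0, iu1 = np.triu_indices(g, k=1)
    n_pairs = iu0.size

    order = list(core_samples)
    in_set = np.zeros(n, dtype=bool)
    in_set[core_samples] = True
    S1 = X[:, core_samples].sum(axis=1)
    C = X[:, core_samples] @ X[:, core_samples].T

    prefix_scores = [correlation_score(X, np.arange(g), core_samples)]
    Cu = C[iu0, iu1]
    chunk = max(1, int(chunk_elems // max(n_pairs, 1)))

    for size in range(k, n):
        cand = np.flatnonzero(~in_set)
        m = size + 1
        diagC = np.ascontiguousarray(np.diag(C))
        if _HAVE_NUMBA:
            scores = _scan_candidates(Cu, iu0, iu1, diagC, S1, np.ascontiguousarray(X[:, cand]), float(m))
            best_pos = int(np.argmax(scores))
            best_score = float(scores[best_pos])
            best_sample = int(cand[best_pos]) if np.isfinite(best_score) else -1
        else:
            best_score = -np.inf
            best_sample = -1
            for start in range(0, cand.size, chunk):
                cc = cand[start : start + chunk]
                V = X[:, cc]  # g x c
                Sp = S1[:, None] + V  # g x c
                # per-gene sum of squares terms: d_i = m * (C_ii + v_i^2) - Sp_i^2
                d = m * (diagC[:, None] + V * V) - Sp * Sp
                valid = (d > 0.0).all(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    inv = 1.0 / np.sqrt(np.where(d > 0.0, d, 1.0))
                # pairwise numerators over the upper triangle
                T = m * (Cu[None, :] + (V[iu0] * V[iu1]).T) - (Sp[iu0] * Sp[iu1]).T  # c x P
                absr = np.minimum(np.abs(T) * (inv[iu0] * inv[iu1]).T, 1.0)
                sums = absr.sum(axis=1)
                scores = np.where(valid, (g + 2.0 * sums) / (g * g), -np.inf)
                local_best = int(np.argmax(scores))
                if scores[local_best] > best_score:
                    best_score = float(scores[local_best])
                    best_sample = int(cc[local_best])
        if best_sample < 0:  # every candidate degenerate: fall back to input order
            best_sample = int(cand[0])
            best_score = float("nan")
        v = X[:, best_sample]
        S1 += v
        C += np.outer(v, v)
        Cu = C[iu0, iu1]
        in_set[best_sample] = True
        order.append(best_sample)
        prefix_scores.append(min(best_score, 1.0) if math.isfinite(best_score) else best_score)

    return SampleRanking(np.asarray(order), np.asarray(prefix_scores), k=k)


# ---------------------------------------------------------------------------
# PC1 and forks
# ---------------------------------------------------------------------------

def pc1_projection(
    matrix,
    bicluster_genes,
    ranking: SampleRanking,
    n_fit: int = 10,
    cv: CorrelationVector | None = None,
) -> PC1Vector:
    """Project every sample on the first principal component fitted on the
    ``n_fit`` top-ranked samples over ``bicluster_genes``.

    Genes are centred over the fitting samples.  The sign is fixed so that
    PC1 correlates positively, over the fitting samples, with the mean
    expression of the positive-CV gene group (or of the positive-loading
    genes when no CV is supplied).
    """
    if n_fit < 2:
        raise ValueError("n_fit must be >= 2")
    values = _as_values(matrix)
    genes = np.asarray(bicluster_genes, dtype=np.intp)
    if genes.size == 0:
        raise ValueError("bicluster_genes must be non-empty")
    fit_samples = ranking.order[:n_fit]
    A = values[np.ix_(genes, fit_samples)]  # g x n_fit
    mu = A.mean(axis=1)
    Ac = (A - mu[:, None]).T  # n_fit x g, observations = samples
    _, s, vt = np.linalg.svd(Ac, full_matrices=False)
    w = vt[0]
    total = float((s**2).sum())
    explained = float(s[0] ** 2 / total) if total > 0 else float("nan")

    projections = (values[genes].T - mu) @ w

    if cv is not None:
        pos = genes[cv.values[genes] > 0]
    else:
        pos = genes[w > 0]
    if pos.size == 0:
        pos = genes
    ref = values[np.ix_(pos, fit_samples)].mean(axis=0)
    fit_proj = projections[fit_samples]
    flip = False
    if np.std(ref) > 0 and np.std(fit_proj) > 0:
        if np.corrcoef(fit_proj, ref)[0, 1] < 0:
            flip = True
    elif fit_proj.sum() < 0:
        flip = True
    if flip:
        projections = -projections
        w = -w
    return PC1Vector(projections, genes, fit_samples, sign_flipped=flip, explained_ratio=explained)


def classify_forks(
    pc1: PC1Vector,
    ranking: SampleRanking,
    threshold: ThresholdedBicluster,
    include_all: bool = False,
) -> ForkAssignment:
    """Label thresholded samples upper/lower by the sign of PC1.

    Samples outside the bicluster threshold get an empty label unless
    ``include_all``; PC1 exactly 0 maps to ``unassigned``.
    """
    n = pc1.values.size
    labels = np.full(n, "", dtype=object)
    members = set(threshold.sample_indices.tolist())
    for s in range(n):
        if not include_all and s not in members:
            continue
        v = pc1.values[s]
        labels[s] = "upper" if v > 0 else ("lower" if v < 0 else "unassigned")
    return ForkAssignment(labels, rank_cutoff=len(threshold.sample_indices))


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold_bicluster(
    matrix,
    core_genes,
    ranking: SampleRanking,
    cv: CorrelationVector,
    alpha: float = 0.05,
    gene_cv_cutoff: float = 0.7,
    n_fit: int = 10,
    null: str = "beta",
    n_null: int = 1000,
    rng: np.random.Generator | None = None,
) -> ThresholdedBicluster:
    """Decide which ranked samples and which genes belong to the bicluster.

    Per-sample statistic: f_s, the squared cosine between the sample's
    expression over the gene core (after subtracting the cohort's
    background profile, the mean of the bottom-half-ranked samples) and
    the PC1 axis fitted on the ``n_fit`` top-ranked samples — the fraction
    of the sample's variance explained by the bicluster's rank-1 pattern.
    Centring on the background profile rather than the fitted samples
    matters: gene-mean-centred data leaks a component proportional to the
    pattern into every background sample, and the background profile
    cancels it.  Under independent Gaussian noise f follows a
    Beta(1/2, (G-1)/2) law, so samples are retained walking down the
    ranking while f exceeds the family-wise-alpha cutoff (per-sample level
    1 - (1-alpha)^(1/(N-k))), stopping at the first failure; the first k
    (core) positions are always retained.  Bicluster genes are those with
    |CV| >= ``gene_cv_cutoff``.  (Implied assumption: the bicluster covers
    less than half the cohort, so the bottom half is background.)

    ``null="empirical"`` replaces the Beta law with ``n_null`` Monte Carlo
    draws of random directions (useful when the noise model is in doubt).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    values = _as_values(matrix)
    genes = np.asarray(core_genes, dtype=np.intp)
    g = genes.size
    if g < 2:
        raise ValueError("need at least 2 core genes to threshold")
    n = ranking.order.size
    k = ranking.k
    fit_samples = ranking.order[:n_fit]
    A = values[np.ix_(genes, fit_samples)]
    _, _, vt = np.linalg.svd((A - A.mean(axis=1, keepdims=True)).T, full_matrices=False)
    w = vt[0]

    background = ranking.order[max(k, n // 2):]
    if background.size >= 3:
        mu = values[np.ix_(genes, background)].mean(axis=1)
    else:  # degenerate cohort: fall back to the global gene means
        mu = values[genes].mean(axis=1)

    resid = values[genes] - mu[:, None]  # g x n
    proj = w @ resid
    ss = np.einsum("ij,ij->j", resid, resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ss > 0, proj**2 / ss, 0.0)

    m_tests = max(n - k, 1)
    per_sample = 1.0 - (1.0 - alpha) ** (1.0 / m_tests)
    if null == "beta":
        f_star = float(stats.beta.isf(per_sample, 0.5, (g - 1) / 2.0))
    elif null == "empirical":
        rng = rng or np.random.default_rng(0)
        draws = rng.standard_normal((n_null, g))
        fn = (draws @ w) ** 2 / np.einsum("ij,ij->i", draws, draws)
        f_star = float(np.quantile(fn, 1.0 - per_sample))
    else:
        raise ValueError(f"unknown null {null!r}")

    cutoff = k
    for pos in range(k, n):
        if f[ranking.order[pos]] > f_star:
            cutoff = pos + 1
        else:
            break

    gene_sel = np.flatnonzero(np.abs(cv.values) >= gene_cv_cutoff)
    return ThresholdedBicluster(
        gene_indices=gene_sel,
        sample_indices=ranking.order[:cutoff].copy(),
        alpha=alpha,
        null_summary={
            "method": null,
            "f_star": f_star,
            "per_sample_level": per_sample,
            "n_tests": m_tests,
            "n_core_genes": g,
            "f_values": f,
        },
    )


# ---------------------------------------------------------------------------
# fork association
# ---------------------------------------------------------------------------

def fork_permutation_test(
    values,
    forks: ForkAssignment,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test for a covariate difference between the two forks.

    Observed statistic: mean(upper) - mean(lower) over samples with a
    non-missing covariate.  Fork labels are randomly reassigned (group
    sizes fixed) and the two-sided p-value is the fraction of permutations
    with |difference| >= |observed|.  When the number of distinct label
    arrangements is <= ``n_perm`` all of them are enumerated and the
    p-value is exact; otherwise ``n_perm`` Monte Carlo permutations are
    used with the add-one estimator (b + 1) / (n_perm + 1).
    """
    vals = np.asarray(values, dtype=np.float64)
    labels = np.asarray(forks.labels, dtype=object)
    if vals.size != labels.size:
        raise ValueError("covariate and fork labels must align")
    ok = np.isfinite(vals)
    upper = vals[ok & (labels == "upper")]
    lower = vals[ok & (labels == "lower")]
    if upper.size < 2 or lower.size < 2:
        raise ValueError("each fork needs >= 2 samples with a non-missing covariate")
    observed = float(upper.mean() - lower.mean())
    pooled = np.concatenate([upper, lower])
    n_u = upper.size
    n_tot = pooled.size
    total = math.comb(n_tot, n_u)
    tol = 1e-12 * max(1.0, abs(observed))

    if total <= n_perm:
        count = 0
        tot_sum = pooled.sum()
        for comb in combinations(range(n_tot), n_u):
            up_sum = pooled[list(comb)].sum()
            diff = up_sum / n_u - (tot_sum - up_sum) / (n_tot - n_u)
            if abs(diff) >= abs(observed) - tol:
                count += 1
        return observed, count / total

    rng = rng or np.random.default_rng(0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:n_u].mean() - perm[n_u:].mean()
        if abs(diff) >= abs(observed) - tol:
            count += 1
    return observed, (count + 1) / (n_perm + 1)
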