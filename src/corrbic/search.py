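"""Bicluster correlation score and the stochastic greedy seed search.

The quality metric of a bicluster (gene subset, sample subset) is the mean
of the absolute values of all entries of the gene-gene Pearson correlation
matrix computed across the selected samples, diagonal included.  For G
genes the score therefore lives in [1/G, 1] and equals 1 exactly when every
gene pair is perfectly (anti-)correlated.  Sign is deliberately ignored:
the ideal bicluster mixes up- and down-regulated genes.

A single run starts from a seed gene list (~1000 genes) and k random
samples (default 10) and hill-climbs by randomly swapping one in-set sample
for one out-of-set sample, accepting only strict score increases.  The
tightly correlated gene core is then extracted by hierarchical clustering
of the seed genes over the found samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConstantGeneError",
    "SearchParams",
    "BiclusterCore",
    "correlation_score",
    "find_seed",
    "refine_gene_core",
]


class ConstantGeneError(ValueError):
    """A gene is constant over the selected samples; Pearson r is undefined."""

    def __init__(self, gene: str):
        self.gene = gene
        super().__init__(f"gene {gene!r} is constant over the selected samples")


@dataclass(frozen=True)
class SearchParams:
    """Parameters of one stochastic search run."""

    n_seed_genes: int = 1000
    n_seed_samples: int = 10
    n_iterations: int = 500
    n_gene_groups: int = 8
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_seed_samples < 3:
            raise ValueError("n_seed_samples must be >= 3")
        if self.n_gene_groups < 2:
            raise ValueError("n_gene_groups must be >= 2")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


@dataclass
class BiclusterCore:
    """A (gene set, sample set, score) triple found by one search run."""

    gene_indices: np.ndarray
    sample_indices: np.ndarray
    score: float
    trajectory: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.intp)
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.intp)
        if len(set(self.sample_indices.tolist())) != len(self.sample_indices):
            raise ValueError("sample_indices must be distinct")
        if len(self.sample_indices) < 3:
            raise ValueError("a bicluster core needs at least 3 samples")


def _as_values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)


def _score_submatrix(sub: np.ndarray) -> float:
    """Mean |r| over the full correlation matrix of the rows of ``sub``."""
    centred = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centred, centred))
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise _DegenerateRow(int(bad[0]))
    z = centred / norms[:, None]
    r = z @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    return float(np.abs(r).mean())


class _DegenerateRow(Exception):
    def __init__(self, row: int):
        self.row = row
        super().__init__(row)


def correlation_score(matrix, genes, samples) -> float:
    """Bicluster quality: mean absolute pairwise Pearson r, diagonal included.

    Parameters
    ----------
    matrix : ExpressionMatrix or 2-D array
    genes, samples : index sequences
        At least 2 genes and 3 samples; every listed gene must vary over the
        listed samples (otherwise :class:`ConstantGeneError`).
    """
    values = _as_values(matrix)
    genes = np.asarray(genes, dtype=np.intp)
    samples = np.asarray(samples, dtype=np.intp)
    if genes.size < 2:
        raise ValueError("correlation_score needs at least 2 genes")
    if samples.size < 3:
        raise ValueError("correlation_score needs at least 3 samples")
    sub = values[np.ix_(genes, samples)]
    try:
        return _score_submatrix(sub)
    except _DegenerateRow as exc:
        gene = genes[exc.row]
        name = matrix.gene_ids[gene] if isinstance(matrix, ExpressionMatrix) else str(gene)
        raise ConstantGeneError(name) from None


def find_seed(matrix, seed_genes, params: SearchParams, rng: np.random.Generator) -> BiclusterCore:
    """Greedy hill-climb over sample sets at fixed seed genes.

    Starts from ``params.n_seed_samples`` samples drawn uniformly without
    replacement; each of the ``params.n_iterations`` proposals swaps one
    uniformly chosen in-set sample for one uniformly chosen out-of-set
    sample and is accepted iff the score strictly increases.  A proposal
    whose score is undefined (a constant gene) is rejected.  The trajectory
    of scores after each accepted move (including the initial score) is
    returned on the core and is non-decreasing by construction.
    """
    values = _as_values(matrix)
    seed_genes = np.asarray(seed_genes, dtype=np.intp)
    n_samples = values.shape[1]
    k = params.n_seed_samples
    if n_samples <= k:
        raise ValueError("matrix must have more samples than the seed sample count")
    X = values[seed_genes]

    def score_of(cols: np.ndarray) -> float:
        try:
            return _score_submatrix(X[:, cols])
        except _DegenerateRow:
            return -np.inf

    current = rng.choice(n_samples, size=k, replace=False)
    in_set = np.zeros(n_samples, dtype=bool)
    in_set[current] = True
    current_score = score_of(current)
    trajectory = [current_score]

    out_pool = np.flatnonzero(~in_set)
    for _ in range(params.n_iterations):
        drop_pos = int(rng.integers(k))
        add_pos = int(rng.integers(out_pool.size))
        candidate = current.copy()
        old = candidate[drop_pos]
        new = out_pool[add_pos]
        candidate[drop_pos] = new
        cand_score = score_of(candidate)
        if cand_score > current_score:
            current = candidate
            current_score = cand_score
            out_pool[add_pos] = old
            in_set[old] = False
            in_set[new] = True
            trajectory.append(current_score)

    return BiclusterCore(
        gene_indices=seed_genes.copy(),
        sample_indices=np.sort(current),
        score=current_score,
        trajectory=np.asarray(trajectory),
    )


def gene_correlation_groups(
    matrix,
    genes,
    samples,
    n_groups: int,
    method: str = "average",
) -> list[np.ndarray]:
    """Cut a hierarchical clustering of ``genes`` (distance 1 - Pearson r
    over ``samples``, given linkage) into ``n_groups`` groups.

    Genes constant over the samples are excluded first (logged).  Returns
    absolute matrix gene indices per group, ordered by cluster label.
    """
    values = _as_values(matrix)
    genes = np.asarray(genes, dtype=np.intp)
    samples = np.asarray(samples, dtype=np.intp)
    sub = values[np.ix_(genes, samples)]
    varying = sub.std(axis=1) > 0.0
    if not varying.all():
        logger.info(
            "excluding %d genes constant over the core samples before clustering",
            int((~varying).sum()),
        )
        genes = genes[varying]
        sub = sub[varying]
    if genes.size < 2:
        raise ValueError("fewer than 2 varying genes; nothing to cluster")
    if genes.size <= n_groups:
        return [np.array([g]) for g in genes]
    r = np.corrcoef(sub)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    links = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(links, t=n_groups, criterion="maxclust")
    return [genes[labels == lab] for lab in np.unique(labels)]


def refine_gene_core(
    matrix,
    seed_genes,
    core_samples,
    n_groups: int = 8,
    linkage_method: str = "average",
    min_group_size: int = 2,
) -> np.ndarray:
    """Keep the seed-gene group with the highest correlation score.

    The seed genes are clustered hierarchically into ``n_groups`` groups
    (distance 1 - r over the core samples); each group of size >= 2 is
    scored over the core samples and the member genes of the best-scoring
    group are returned.  Ties break towards the first group in label order.

    ``min_group_size`` softly guards against degenerate winners: the mean
    absolute correlation of a handful of genes is upward biased (two genes
    can reach |r| ~ 1 by chance over ten samples), so groups below the
    minimum are only considered when no larger group exists.
    """
    groups = gene_correlation_groups(matrix, seed_genes, core_samples, n_groups, linkage_method)
    scored: list[tuple[float, int, np.ndarray]] = []
    for pos, members in enumerate(groups):
        if members.size < 2:
            continue  # score undefined for a single gene
        scored.append((correlation_score(matrix, members, core_samples), -pos, members))
    if not scored:
        raise ValueError("all gene groups have size 1; cannot score any group")
    eligible = [t for t in scored if t[2].size >= min_group_size]
    pool = eligible or scored
    return max(pool)[2]
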