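"""Batches of stochastic runs and their consolidation into bicluster groups.

Each stochastic run ends in a different bicluster; runs that found the same
underlying structure have strongly correlated correlation vectors (up to an
arbitrary global sign, because the two anti-correlated forks of a bicluster
are exchangeable).  Runs are therefore clustered on the distance
1 - |r(cv_a, cv_b)| and the number of distinct biclusters is chosen by
maximizing the average silhouette width over the cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples, silhouette_score

from .extend import CorrelationVector, SampleRanking, average_expression_vector, correlation_vector
from .matrix import ExpressionMatrix
from .search import BiclusterCore, SearchParams, find_seed, refine_gene_core

logger = logging.getLogger(__name__)

__all__ = [
    "RunResult",
    "BiclusterGroup",
    "run_batch",
    "cv_distance",
    "silhouette_cluster",
    "group_representative",
]


@dataclass
class RunResult:
    """Everything one stochastic run produced."""

    run_id: int
    rng_seed: int
    params: SearchParams
    seed_genes: np.ndarray
    core: BiclusterCore
    correlation_vector: CorrelationVector
    ranking: SampleRanking | None = None  # filled in at extension time

    def __post_init__(self) -> None:
        self.seed_genes = np.asarray(self.seed_genes, dtype=np.intp)
        if self.ranking is not None:
            k = self.ranking.k
            if set(self.ranking.order[:k].tolist()) != set(self.core.sample_indices.tolist()):
                raise ValueError("core samples must be a prefix of the ranking")


@dataclass
class BiclusterGroup:
    """A consolidated group of runs that found the same bicluster."""

    label: int
    member_runs: list[int]
    representative: np.ndarray  # sign-aligned average CV, one value per gene
    medoid_run: int
    silhouette: dict[int, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_runs)


def _single_run(
    matrix: ExpressionMatrix,
    run_id: int,
    rng_seed: int,
    params: SearchParams,
    seed_genes: np.ndarray | None,
    min_core_genes: int = 8,
) -> RunResult:
    rng = np.random.default_rng(rng_seed)
    if seed_genes is None:
        n = min(params.n_seed_genes, matrix.n_genes)
        seed_genes = np.sort(rng.choice(matrix.n_genes, size=n, replace=False))
    from .search import correlation_score

    seed_core = find_seed(matrix, seed_genes, params, rng)
    refined = refine_gene_core(matrix, seed_genes, seed_core.sample_indices, params.n_gene_groups,
                               min_group_size=min_core_genes)
    core = BiclusterCore(
        refined,
        seed_core.sample_indices,
        score=correlation_score(matrix, refined, seed_core.sample_indices),
        trajectory=seed_core.trajectory,
    )
    avg, _ = average_expression_vector(matrix, refined, core.sample_indices)
    cv = correlation_vector(matrix, avg, core.sample_indices, core_genes=refined)
    return RunResult(run_id, rng_seed, params, seed_genes, core, cv)


def run_batch(
    matrix: ExpressionMatrix,
    seed_gene_spec,
    n_runs: int,
    params: SearchParams,
    root_seed: int,
    out_dir: str | Path | None = None,
) -> list[RunResult]:
    """Run ``n_runs`` independent searches with per-run seeds root_seed + i.

    ``seed_gene_spec`` is ``"random"`` (params.n_seed_genes genes drawn
    without replacement per run) or an explicit sequence of gene ids /
    indices shared by all runs.  With ``out_dir`` each finished run is
    written to ``run_####.json`` and already-present runs are loaded
    instead of recomputed, so an interrupted batch resumes where it
    stopped.  Individual failures are logged and skipped; more than 50%
    failures abort the batch.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    fixed_genes: np.ndarray | None = None
    if not (isinstance(seed_gene_spec, str) and seed_gene_spec == "random"):
        spec = list(seed_gene_spec)
        if spec and isinstance(spec[0], str):
            fixed_genes = matrix.gene_indices(spec)
        else:
            fixed_genes = np.asarray(spec, dtype=np.intp)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    from . import io as _io  # local import: io depends on this module's types

    results: list[RunResult] = []
    failures = 0
    for i in range(n_runs):
        path = None if out_dir is None else out_dir / f"run_{i:04d}.json"
        if path is not None and path.exists():
            results.append(_io.read_run_result(path))
            continue
        try:
            res = _single_run(matrix, i, root_seed + i, params, fixed_genes)
        except Exception:
            failures += 1
            logger.exception("run %d failed; continuing", i)
            continue
        if path is not None:
            _io.write_run_result(res, path)
        results.append(res)
    if failures > n_runs / 2:
        raise RuntimeError(f"{failures} of {n_runs} runs failed")
    return results


def cv_distance(cv_a, cv_b) -> float:
    """1 - |Pearson r| between two correlation vectors (sign is arbitrary)."""
    a = cv_a.values if isinstance(cv_a, CorrelationVector) else np.asarray(cv_a, float)
    b = cv_b.values if isinstance(cv_b, CorrelationVector) else np.asarray(cv_b, float)
    if a.size != b.size:
        raise ValueError("correlation vectors must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("cannot measure distance to a constant correlation vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(1.0 - abs(r), 0.0, 1.0))


def _distance_matrix(cvs) -> np.ndarray:
    arr = np.vstack([cv.values if isinstance(cv, CorrelationVector) else np.asarray(cv) for cv in cvs])
    if (arr.std(axis=1) == 0.0).any():
        raise ValueError("cannot cluster constant correlation vectors")
    r = np.corrcoef(arr)
    d = np.clip(1.0 - np.abs(r), 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def silhouette_cluster(
    cvs,
    k_max: int = 20,
    floor: float = 0.25,
    linkage_method: str = "average",
) -> list[BiclusterGroup]:
    """Consolidate runs into bicluster groups by max-average-silhouette cut.

    Hierarchical clustering (average linkage by default) on the CV distance
    matrix; the cut k in 2..k_max maximizing the average silhouette width
    is chosen (ties towards the smaller k).  If the maximum is below
    ``floor`` all runs form a single group.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n = len(cvs)
    if n < 2:
        raise ValueError("need at least 2 runs to consolidate")
    D = _distance_matrix(cvs)
    links = linkage(squareform(D, checks=False), method=linkage_method)

    best_k = 1
    best_width = -np.inf
    best_labels = np.ones(n, dtype=int)
    widths_per_member: np.ndarray | None = None
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(links, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        width = float(silhouette_score(D, labels, metric="precomputed"))
        if width > best_width:
            best_width = width
            best_k = k
            best_labels = labels
    if best_k > 1 and best_width < floor:
        logger.info("max average silhouette %.3f below floor %.2f: single group", best_width, floor)
        best_k = 1
        best_labels = np.ones(n, dtype=int)
    if best_k > 1:
        widths_per_member = silhouette_samples(D, best_labels, metric="precomputed")

    groups: list[BiclusterGroup] = []
    for lab in np.unique(best_labels):
        members = np.flatnonzero(best_labels == lab)
        rep, medoid = group_representative(members, cvs, D, return_medoid=True)
        sil = {
            int(m): (float(widths_per_member[m]) if widths_per_member is not None else float("nan"))
            for m in members
        }
        groups.append(
            BiclusterGroup(
                label=int(lab),
                member_runs=[int(m) for m in members],
                representative=rep,
                medoid_run=int(medoid),
                silhouette=sil,
            )
        )
    return groups


def group_representative(members, cvs, distances: np.ndarray | None = None, return_medoid: bool = False):
    """Sign-aligned average CV of a group.

    The medoid (minimum summed CV distance, ties towards the first member)
    anchors the sign: each member CV is flipped to correlate positively
    with the medoid before element-wise averaging.
    """
    members = np.asarray(list(members), dtype=np.intp)
    if members.size == 0:
        raise ValueError("empty group")
    arr = np.vstack(
        [cvs[m].values if isinstance(cvs[m], CorrelationVector) else np.asarray(cvs[m]) for m in members]
    )
    if members.size == 1:
        rep = arr[0].copy()
        return (rep, int(members[0])) if return_medoid else rep
    if distances is None:
        sub = _distance_matrix([cvs[m] for m in members])
    else:
        sub = distances[np.ix_(members, members)]
    medoid_pos = int(np.argmin(sub.sum(axis=1)))
    medoid_cv = arr[medoid_pos]
    signs = np.ones(members.size)
    for i in range(members.size):
        r = np.corrcoef(arr[i], medoid_cv)[0, 1]
        if r < 0:
            signs[i] = -1.0
    rep = (signs[:, None] * arr).mean(axis=0)
    return (rep, int(members[medoid_pos])) if return_medoid else rep
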