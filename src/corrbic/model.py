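"""Model/Results facade over the biclustering pipeline.

`CorrelatedBiclustering` is built from an expression matrix (or a pandas
DataFrame); `fit` runs the batch of stochastic searches and the silhouette
consolidation and returns a `BiclusteringResults` carrying the consolidated
groups, per-group diagnostics and a `summary()` table.  Extension of a
group over the whole matrix (ranking, PC1, thresholding) and enrichment of
its correlation vector hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, adjust_pvalues, mann_whitney_enrichment
from .extend import classify_forks, fork_permutation_test
from .matrix import ExpressionMatrix, preprocess
from .multirun import run_batch, silhouette_cluster
from .pipeline import GroupExtension, extend_group
from .search import SearchParams

__all__ = ["CorrelatedBiclustering", "BiclusteringResults"]


class CorrelatedBiclustering:
    """Large correlated-bicluster discovery on a genes x samples matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix or pandas.DataFrame
        Log-scale expression, genes as rows.  Preprocessed on entry
        (constant genes dropped, missing-value genes dropped).
    seed_genes : "random" or sequence of gene ids
        Seed gene source per run; "random" draws ``n_seed_genes`` genes
        without replacement independently for every run.
    params : SearchParams, optional
        Search parameters (seed sizes, iteration budget, gene groups).
    """

    def __init__(self, matrix, seed_genes="random", params: SearchParams | None = None):
        if isinstance(matrix, pd.DataFrame):
            matrix = ExpressionMatrix.from_dataframe(matrix)
        self.matrix = preprocess(matrix)
        self.seed_genes = seed_genes
        self.params = params or SearchParams()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CorrelatedBiclustering":
        return cls(ExpressionMatrix.from_dataframe(df), **kwargs)

    def fit(
        self,
        n_runs: int = 100,
        seed: int = 0,
        k_max: int = 20,
        silhouette_floor: float = 0.25,
        out_dir=None,
    ) -> "BiclusteringResults":
        """Run ``n_runs`` stochastic searches and consolidate them."""
        runs = run_batch(self.matrix, self.seed_genes, n_runs, self.params,
                         root_seed=seed, out_dir=out_dir)
        groups = silhouette_cluster([r.correlation_vector for r in runs],
                                    k_max=k_max, floor=silhouette_floor)
        return BiclusteringResults(self, runs, groups, seed=seed)


class BiclusteringResults:
    """Fitted biclustering: runs, consolidated groups, diagnostics."""

    def __init__(self, model: CorrelatedBiclustering, runs, groups, seed: int):
        self.model = model
        self.runs = runs
        self.groups = groups
        self.seed = seed
        self._extensions: dict[int, GroupExtension] = {}

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def summary(self) -> pd.DataFrame:
        """One row per consolidated group: size, medoid run, its core score,
        mean silhouette width of the members."""
        rows = []
        for g in self.groups:
            medoid = self.runs[g.medoid_run]
            sil = [w for w in g.silhouette.values() if np.isfinite(w)]
            rows.append(
                dict(
                    group=g.label,
                    n_runs=g.size,
                    medoid_run=g.medoid_run,
                    core_score=medoid.core.score,
                    core_genes=len(medoid.core.gene_indices),
                    mean_silhouette=float(np.mean(sil)) if sil else float("nan"),
                )
            )
        return pd.DataFrame(rows).set_index("group")

    def __str__(self) -> str:
        df = self.summary()
        return (
            f"CorrelatedBiclustering results: {len(self.runs)} runs, "
            f"{self.n_groups} consolidated group(s)\n{df.to_string(float_format='%.4f')}"
        )

    # -- per-group analyses ---------------------------------------------
    def extend(self, group: int, alpha: float = 0.05, gene_cv_cutoff: float = 0.7,
               n_fit: int = 10, max_sort_genes: int | None = None) -> GroupExtension:
        """Sample ranking, PC1 projection and thresholding for one group
        (cached per group index)."""
        if group not in self._extensions:
            self._extensions[group] = extend_group(
                self.model.matrix, self.groups[group], self.runs,
                alpha=alpha, gene_cv_cutoff=gene_cv_cutoff, n_fit=n_fit,
                max_sort_genes=max_sort_genes,
            )
        return self._extensions[group]

    def enrich(self, group: int, gene_sets, min_size: int = 5,
               adjust: str = "BH") -> list[EnrichmentResult]:
        """Mann-Whitney enrichment of the group's representative CV."""
        cv = self.groups[group].representative
        res = mann_whitney_enrichment(cv, self.model.matrix.gene_ids, gene_sets, min_size=min_size)
        return adjust_pvalues(res, method=adjust) if res else res

    def fork_test(self, group: int, covariate, n_perm: int = 10_000,
                  rng: np.random.Generator | None = None) -> tuple[float, float]:
        """Permutation test of a per-sample covariate between the two PC1
        forks of a group.  ``covariate`` maps sample id -> value (mapping or
        pandas Series) or is an array aligned with the matrix samples."""
        ext = self.extend(group)
        from .extend import PC1Vector  # local: only the values are needed

        pc1 = PC1Vector(ext.pc1_values, ext.core_genes, ext.ranking.order[:10])
        forks = classify_forks(pc1, ext.ranking, ext.threshold)
        if isinstance(covariate, pd.Series):
            covariate = covariate.to_dict()
        if isinstance(covariate, dict):
            vals = np.array([covariate.get(s, np.nan) for s in self.model.matrix.sample_ids])
        else:
            vals = np.asarray(covariate, dtype=float)
        return fork_permutation_test(vals, forks, n_perm=n_perm, rng=rng)
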