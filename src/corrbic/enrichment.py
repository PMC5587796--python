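"""Rank-based gene-set enrichment on a correlation vector.

For each term the CV values of in-term genes are compared with those of
all other genes in the matrix by a two-sided Mann-Whitney U test: a term
whose genes sit at the top (or bottom) of the CV ranking is enriched, and
the direction (sign of the in-term minus out-of-term median CV) records
whether the term tracks the positively or negatively correlated side of
the bicluster.  Being a rank test, the p-values are invariant to any
strictly monotone transform of the CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .extend import CorrelationVector
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "mann_whitney_enrichment", "adjust_pvalues"]

_ASYMPTOTIC_MIN = 20  # smaller groups use the exact U distribution (no ties)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_in_universe: int
    u_statistic: float
    p_raw: float
    p_adjusted: float | None
    direction: str  # "positive" or "negative"
    median_in: float
    median_out: float


def mann_whitney_enrichment(
    cv,
    gene_ids,
    sets: GeneSetCollection,
    min_size: int = 5,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Mann-Whitney U enrichment of every term against the CV ranking.

    The universe is the genes present in the matrix; term members outside
    it are ignored, terms below ``min_size`` after intersection are dropped
    (logged) and a term covering the whole universe is skipped with a
    warning.  Exact enumeration of the U distribution is used when the
    smaller group has < 20 genes and there are no ties; otherwise the
    normal approximation with tie correction (and continuity correction).
    """
    values = cv.values if isinstance(cv, CorrelationVector) else np.asarray(cv, float)
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != values.size:
        raise ValueError("gene_ids must align with the correlation vector")
    index = {g: i for i, g in enumerate(gene_ids)}

    results: list[EnrichmentResult] = []
    for term in sets:
        in_idx = np.asarray(sorted({index[g] for g in term.genes if g in index}), dtype=np.intp)
        if in_idx.size < min_size:
            logger.info("term %s dropped: %d genes in universe < min_size %d",
                        term.term_id, in_idx.size, min_size)
            continue
        if in_idx.size == values.size:
            logger.warning("term %s covers the whole universe; skipped", term.term_id)
            continue
        mask = np.zeros(values.size, dtype=bool)
        mask[in_idx] = True
        in_vals = values[mask]
        out_vals = values[~mask]
        ties = np.unique(values).size < values.size
        method = (
            "exact" if (min(in_vals.size, out_vals.size) < _ASYMPTOTIC_MIN and not ties) else "asymptotic"
        )
        u, p = mannwhitneyu(in_vals, out_vals, alternative=alternative, method=method)
        med_in = float(np.median(in_vals))
        med_out = float(np.median(out_vals))
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                n_in_universe=int(in_idx.size),
                u_statistic=float(u),
                p_raw=float(min(p, 1.0)),
                p_adjusted=None,
                direction="positive" if med_in >= med_out else "negative",
                median_in=med_in,
                median_out=med_out,
            )
        )
    return results


def adjust_pvalues(results: list[EnrichmentResult], method: str = "BH") -> list[EnrichmentResult]:
    """Fill in multiple-testing adjusted p-values (Benjamini-Hochberg or
    Bonferroni) over all tested terms, in place; returns the list."""
    if not results:
        raise ValueError("no enrichment results to adjust")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    raw = [r.p_raw for r in results]
    _, adj, _, _ = multipletests(raw, method=key)
    for r, p in zip(results, adj):
        r.p_adjusted = float(p)
    return results
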