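"""Scoring predicted bicluster collections against ground truth.

A bicluster is treated as the set of its (gene, sample) cells.  Predicted
and known collections are compared through the pairwise Jaccard matrix,
the Hungarian (Munkres) assignment maximizing the summed Jaccard, the
consensus score (summed matched Jaccard divided by the size of the larger
collection, penalizing a wrong bicluster count), per-pair recall /
precision / F1 computed separately on gene and sample sets, and ROC curves
over the sample ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Bicluster",
    "jaccard_index",
    "jaccard_matrix",
    "match_biclusters",
    "consensus_score",
    "f1_scores",
    "F1Report",
    "roc_from_ranking",
    "select_optimum",
    "evaluate_collections",
    "BenchmarkReport",
]


@dataclass(frozen=True)
class Bicluster:
    """A labelled (gene set, sample set) pair."""

    genes: frozenset
    samples: frozenset
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "samples", frozenset(self.samples))

    @property
    def n_cells(self) -> int:
        return len(self.genes) * len(self.samples)


def jaccard_index(a: Bicluster, b: Bicluster) -> float:
    """Cell-level Jaccard: |A∩B| / |A∪B| over (gene, sample) cells."""
    if a.n_cells == 0 or b.n_cells == 0:
        raise ValueError("Jaccard index of an empty bicluster is undefined")
    inter = len(a.genes & b.genes) * len(a.samples & b.samples)
    union = a.n_cells + b.n_cells - inter
    return inter / union


def jaccard_matrix(pred: list[Bicluster], known: list[Bicluster]) -> np.ndarray:
    J = np.zeros((len(pred), len(known)))
    for i, p in enumerate(pred):
        for j, q in enumerate(known):
            J[i, j] = jaccard_index(p, q)
    return J


def match_biclusters(pred: list[Bicluster], known: list[Bicluster]) -> list[tuple[int, int]]:
    """One-to-one matching maximizing the summed Jaccard (Munkres)."""
    if not pred or not known:
        raise ValueError("both collections must be non-empty")
    J = jaccard_matrix(pred, known)
    rows, cols = linear_sum_assignment(-J)
    return list(zip(rows.tolist(), cols.tolist()))


def consensus_score(pred: list[Bicluster], known: list[Bicluster]) -> float:
    """Summed matched Jaccard divided by the size of the larger collection."""
    if not known:
        raise ValueError("known collection must be non-empty")
    if not pred:
        return 0.0
    J = jaccard_matrix(pred, known)
    rows, cols = linear_sum_assignment(-J)
    return float(J[rows, cols].sum() / max(len(pred), len(known)))


@dataclass
class F1Report:
    genes_f1: float
    samples_f1: float
    per_pair: pd.DataFrame = field(repr=False)


def _set_prf(pred: frozenset, known: frozenset) -> tuple[float, float, float]:
    inter = len(pred & known)
    recall = inter / len(known) if known else 0.0
    precision = inter / len(pred) if pred else 0.0
    f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    return recall, precision, f1


def f1_scores(matching, pred: list[Bicluster], known: list[Bicluster]) -> F1Report:
    """Mean gene-set and sample-set F1 over all known biclusters.

    Recall, precision and F1 are computed per matched pair, separately for
    gene sets and sample sets; a known bicluster without a match
    contributes F1 = 0 to the mean, so finding too few biclusters is
    penalized just as it is in the consensus score.
    """
    rows = []
    matched_known = {}
    for i, j in matching:
        matched_known[j] = i
    for j, kb in enumerate(known):
        if j in matched_known:
            pb = pred[matched_known[j]]
            gr, gp, gf = _set_prf(pb.genes, kb.genes)
            sr, sp, sf = _set_prf(pb.samples, kb.samples)
            rows.append(
                dict(known=kb.label or str(j), pred=pb.label or str(matched_known[j]),
                     gene_recall=gr, gene_precision=gp, gene_f1=gf,
                     sample_recall=sr, sample_precision=sp, sample_f1=sf)
            )
        else:
            rows.append(
                dict(known=kb.label or str(j), pred=None,
                     gene_recall=0.0, gene_precision=0.0, gene_f1=0.0,
                     sample_recall=0.0, sample_precision=0.0, sample_f1=0.0)
            )
    df = pd.DataFrame(rows)
    return F1Report(float(df.gene_f1.mean()), float(df.sample_f1.mean()), df)


def roc_from_ranking(order, known_samples) -> tuple[pd.DataFrame, float]:
    """ROC over prefix lengths of a sample ranking against a known sample set.

    Returns per-prefix (TPR, FPR) points and the trapezoid AUC.  Raises if
    the known set is empty or covers every sample (FPR undefined).
    """
    order = list(order)
    known = set(known_samples)
    if not known:
        raise ValueError("known sample set is empty")
    n = len(order)
    n_pos = len(known)
    n_neg = n - n_pos
    if n_neg == 0:
        raise ValueError("known sample set covers every sample; ROC undefined")
    hits = np.fromiter((1 if s in known else 0 for s in order), dtype=float, count=n)
    tp = np.concatenate([[0.0], np.cumsum(hits)])
    fp = np.concatenate([[0.0], np.cumsum(1.0 - hits)])
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    df = pd.DataFrame({"prefix": np.arange(n + 1), "tpr": tpr, "fpr": fpr})
    return df, auc


def select_optimum(ranked_samples, genes_by_cv, known: Bicluster) -> tuple[Bicluster, float]:
    """Oracle-assisted extent selection: the prefix pair maximizing Jaccard.

    Scans every (gene prefix of the |CV|-ordered gene list, sample prefix
    of the ranking) pair and returns the bicluster maximizing the
    cell-level Jaccard to the known bicluster, with that Jaccard.  Ties
    break towards the shorter gene prefix, then the shorter sample prefix.
    """
    ranked_samples = list(ranked_samples)
    genes_by_cv = list(genes_by_cv)
    kg = known.genes
    ks = known.samples
    cg = np.cumsum([1 if g in kg else 0 for g in genes_by_cv]).astype(float)
    cs = np.cumsum([1 if s in ks else 0 for s in ranked_samples]).astype(float)
    ng = np.arange(1, len(genes_by_cv) + 1, dtype=float)
    ns = np.arange(1, len(ranked_samples) + 1, dtype=float)
    inter = np.outer(cg, cs)
    union = np.outer(ng, ns) + known.n_cells - inter
    jac = inter / union
    flat = int(np.argmax(jac))
    gi, si = divmod(flat, jac.shape[1])
    best = Bicluster(frozenset(genes_by_cv[: gi + 1]), frozenset(ranked_samples[: si + 1]),
                     label="optimum")
    return best, float(jac[gi, si])


@dataclass
class BenchmarkReport:
    jaccard: np.ndarray
    matching: list[tuple[int, int]]
    consensus: float
    genes_f1: float
    samples_f1: float
    per_pair: pd.DataFrame = field(repr=False)


def evaluate_collections(pred: list[Bicluster], known: list[Bicluster]) -> BenchmarkReport:
    """Jaccard matrix + Munkres matching + consensus + F1s in one report."""
    J = jaccard_matrix(pred, known)
    rows, cols = linear_sum_assignment(-J)
    matching = list(zip(rows.tolist(), cols.tolist()))
    consensus = float(J[rows, cols].sum() / max(len(pred), len(known)))
    f1 = f1_scores(matching, pred, known)
    return BenchmarkReport(J, matching, consensus, f1.genes_f1, f1.samples_f1, f1.per_pair)
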