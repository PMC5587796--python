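"""Expression-matrix container and minimal preprocessing.

The package works on a genes x samples matrix of log-scale expression
values.  All correlations downstream are gene-wise, computed across
(subsets of) samples, so the orientation is fixed internally; readers
accept transposed input via a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "preprocess"]


def _find_duplicates(ids) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix with string identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Log-scale expression values (arbitrary units), no missing values
        required at construction; :func:`preprocess` handles NaNs.
    gene_ids, sample_ids : sequences of unique str
        Row / column identifiers, order preserved.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        ng, ns = self.values.shape
        if len(self.gene_ids) != ng or len(self.sample_ids) != ns:
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids / {len(self.sample_ids)} sample ids"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} ids: {', '.join(dups)}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic views ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_indices(self, gene_ids) -> np.ndarray:
        """Positions of ``gene_ids`` in the matrix row order."""
        return np.array([self._gene_index[g] for g in gene_ids], dtype=np.intp)

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def transpose(self) -> "ExpressionMatrix":
        """Swap gene and sample roles."""
        return ExpressionMatrix(self.values.T.copy(), list(self.sample_ids), list(self.gene_ids))

    # -- pandas interop --------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with gene ids as index, sample ids as columns."""
        return cls(df.to_numpy(dtype=np.float64), list(map(str, df.index)), list(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def preprocess(
    matrix: ExpressionMatrix,
    drop_constant: bool = True,
    na_policy: str = "drop_gene",
) -> ExpressionMatrix:
    """Drop unusable genes so every retained gene has finite, varying values.

    ``na_policy`` is either ``"drop_gene"`` (remove genes with any missing
    value, logged) or ``"error"``.  With ``drop_constant`` genes with zero
    variance across samples are removed.  Idempotent.  Raises if nothing
    survives.
    """
    if na_policy not in ("drop_gene", "error"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    values = matrix.values
    keep = np.ones(matrix.n_genes, dtype=bool)

    has_na = ~np.isfinite(values).all(axis=1)
    if has_na.any():
        bad = [matrix.gene_ids[i] for i in np.flatnonzero(has_na)]
        if na_policy == "error":
            raise ValueError(f"missing values in genes: {', '.join(bad[:10])}")
        logger.info("preprocess: dropping %d genes with missing values", len(bad))
        keep &= ~has_na

    if drop_constant:
        with np.errstate(invalid="ignore"):
            const = np.nanmax(values, axis=1) == np.nanmin(values, axis=1)
        const &= keep
        if const.any():
            logger.info(
                "preprocess: dropping %d constant genes (%s%s)",
                int(const.sum()),
                ", ".join(matrix.gene_ids[i] for i in np.flatnonzero(const)[:5]),
                "..." if const.sum() > 5 else "",
            )
            keep &= ~const

    if not keep.any():
        raise ValueError("preprocessing removed every gene")
    if keep.all():
        return matrix
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        values[idx].copy(), [matrix.gene_ids[i] for i in idx], list(matrix.sample_ids)
    )
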