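"""Readers and writers for every external format the pipeline touches.

Expression matrices are tab- or comma-separated text with gene ids in the
first column and sample ids in the header; gene sets use the GMT dialect
(term_id TAB description TAB gene TAB gene ...); covariates are TSV with a
sample_id column plus numeric columns.  Run results round-trip losslessly
through a versioned JSON container.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .extend import CorrelationVector, SampleRanking
from .matrix import ExpressionMatrix, preprocess  # re-export: preprocess is part of the io surface
from .multirun import RunResult
from .search import BiclusterCore, SearchParams

logger = logging.getLogger(__name__)

RUN_RESULT_SCHEMA_VERSION = 1

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "read_gene_sets_gmt",
    "read_covariates",
    "write_run_result",
    "read_run_result",
    "preprocess",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    terms: list[GeneSet]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples matrix from delimited text.

    The first column holds gene ids, the header row sample ids.  The
    delimiter is sniffed from the extension when not given (.csv -> comma,
    otherwise tab).  ``transpose`` swaps the roles after reading.  Errors
    name duplicated ids and the position of any non-numeric cell.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for j in range(raw.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.flatnonzero(np.isnan(col) & ~pd.isna(raw[:, j]) & (raw[:, j] != "nan"))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-numeric value {raw[i, j]!r} at row {gene_ids[i]!r}, column {sample_ids[j]!r}"
            )
        values[:, j] = col
    mat = ExpressionMatrix(values, gene_ids, sample_ids)  # raises on duplicate ids
    return mat.transpose() if transpose else mat


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file; duplicate genes within a term are dropped,
    empty terms are skipped, a line with fewer than 3 fields is an error."""
    terms: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected term, description and >=1 gene")
            term_id, term_name = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if genes:
                terms.append(GeneSet(term_id, term_name, tuple(genes)))
    return GeneSetCollection(terms)


def read_covariates(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a per-sample covariate table (sample_id column + numeric columns)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.map(str)
    return df.apply(pd.to_numeric, errors="coerce")


# ---------------------------------------------------------------------------
# run-result container
# ---------------------------------------------------------------------------

def _array(x) -> list:
    return np.asarray(x).tolist()


def write_run_result(result: RunResult, path: str | Path) -> None:
    doc = {
        "schema_version": RUN_RESULT_SCHEMA_VERSION,
        "run_id": result.run_id,
        "rng_seed": result.rng_seed,
        "params": {
            "n_seed_genes": result.params.n_seed_genes,
            "n_seed_samples": result.params.n_seed_samples,
            "n_iterations": result.params.n_iterations,
            "n_gene_groups": result.params.n_gene_groups,
            "rng_seed": result.params.rng_seed,
        },
        "seed_genes": _array(result.seed_genes),
        "core": {
            "gene_indices": _array(result.core.gene_indices),
            "sample_indices": _array(result.core.sample_indices),
            "score": result.core.score,
            "trajectory": None if result.core.trajectory is None else _array(result.core.trajectory),
        },
        "correlation_vector": {
            "values": _array(result.correlation_vector.values),
            "core_genes": None
            if result.correlation_vector.core_genes is None
            else _array(result.correlation_vector.core_genes),
            "core_samples": None
            if result.correlation_vector.core_samples is None
            else _array(result.correlation_vector.core_samples),
        },
        "ranking": None
        if result.ranking is None
        else {
            "order": _array(result.ranking.order),
            "prefix_scores": _array(result.ranking.prefix_scores),
            "k": result.ranking.k,
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_run_result(path: str | Path) -> RunResult:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    version = doc.get("schema_version")
    if version != RUN_RESULT_SCHEMA_VERSION:
        raise ValueError(
            f"run-result schema version {version!r} unsupported "
            f"(this build reads version {RUN_RESULT_SCHEMA_VERSION})"
        )
    params = SearchParams(**doc["params"])
    core_doc = doc["core"]
    core = BiclusterCore(
        np.asarray(core_doc["gene_indices"], dtype=np.intp),
        np.asarray(core_doc["sample_indices"], dtype=np.intp),
        score=core_doc["score"],
        trajectory=None if core_doc["trajectory"] is None else np.asarray(core_doc["trajectory"]),
    )
    cv_doc = doc["correlation_vector"]
    cv = CorrelationVector(
        np.asarray(cv_doc["values"], dtype=np.float64),
        core_genes=None if cv_doc["core_genes"] is None else np.asarray(cv_doc["core_genes"], dtype=np.intp),
        core_samples=None
        if cv_doc["core_samples"] is None
        else np.asarray(cv_doc["core_samples"], dtype=np.intp),
    )
    ranking = None
    if doc["ranking"] is not None:
        ranking = SampleRanking(
            np.asarray(doc["ranking"]["order"], dtype=np.intp),
            np.asarray(doc["ranking"]["prefix_scores"], dtype=np.float64),
            k=doc["ranking"]["k"],
        )
    return RunResult(doc["run_id"], doc["rng_seed"], params, np.asarray(doc["seed_genes"], dtype=np.intp), core, cv, ranking)
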