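"""Multiplicative-bicluster synthetic data with ground truth attached.

Datasets follow the multiplicative (factor-analysis style) bicluster
model: an implanted bicluster contributes the rank-1 outer product
``lambda z^T`` of a gene-loading vector (nonzero only for member genes,
random sign, magnitude |N(3, 1)|) and a sample-factor vector (nonzero only
for member samples, random sign, magnitude |N(2, 1)|), on top of Gaussian
noise.  Genes are mean-centred afterwards.

The noise field covers every cell: sd ``noise_sd`` on signal cells (member
gene x member sample) and sd ``background_sd`` elsewhere.  With the
defaults (both 1.0) this is a single homogeneous noise field; setting
``noise_sd = 0`` leaves the implanted pattern exact over a unit-variance
background, i.e. an infinite signal-to-noise bicluster, which keeps sample
membership identifiable in the noiseless limit.

The combined benchmark concatenates eight such single-bicluster datasets
(1000 genes each, member biclusters averaging ~500 genes x ~130 samples,
gene-mean-centred per block) along the sample axis into a 1000 x 1059
matrix whose truth sample sets are pairwise disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .benchmark import Bicluster
from .matrix import ExpressionMatrix

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_single",
    "generate_multi",
    "generate_benchmark",
    "generate_variation_suite",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the multiplicative-bicluster generator.

    ``bicluster_genes`` / ``bicluster_samples`` are means; actual member
    counts are drawn from a Poisson around them (bounded to [1, dim])
    unless ``count_jitter`` is off.
    """

    n_genes: int = 1000
    n_samples: int = 1000
    bicluster_genes: int = 500
    bicluster_samples: int = 130
    loading_loc: float = 3.0
    loading_scale: float = 1.0
    factor_loc: float = 2.0
    factor_scale: float = 1.0
    noise_sd: float = 1.0
    background_sd: float = 1.0
    count_jitter: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("matrix dimensions must be >= 2")
        for name in ("bicluster_genes", "bicluster_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bicluster_genes > self.n_genes or self.bicluster_samples > self.n_samples:
            raise ValueError("bicluster dimensions exceed matrix dimensions")
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise sds must be non-negative")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    truth: list[Bicluster]
    config: GeneratorConfig
    meta: dict = field(default_factory=dict)


def _member_count(mean: int, upper: int, jitter: bool, rng: np.random.Generator) -> int:
    if not jitter:
        return min(mean, upper)
    return int(np.clip(rng.poisson(mean), 1, upper))


def _signed_magnitudes(n: int, loc: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    mags = np.abs(rng.normal(loc, scale, size=n))
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs


def _implant(
    values: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    gene_pool: np.ndarray,
    sample_pool: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n_g = _member_count(config.bicluster_genes, gene_pool.size, config.count_jitter, rng)
    n_s = _member_count(config.bicluster_samples, sample_pool.size, config.count_jitter, rng)
    genes = np.sort(rng.choice(gene_pool, size=n_g, replace=False))
    samples = np.sort(rng.choice(sample_pool, size=n_s, replace=False))
    lam = _signed_magnitudes(n_g, config.loading_loc, config.loading_scale, rng)
    z = _signed_magnitudes(n_s, config.factor_loc, config.factor_scale, rng)
    values[np.ix_(genes, samples)] += np.outer(lam, z)
    return genes, samples


def _noise_field(
    config: GeneratorConfig,
    rng: np.random.Generator,
    signal_mask: np.ndarray,
) -> np.ndarray:
    noise = rng.standard_normal(signal_mask.shape)
    sd = np.where(signal_mask, config.noise_sd, config.background_sd)
    return noise * sd


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_single(
    config: GeneratorConfig,
    rng: np.random.Generator,
    gene_ids: list[str] | None = None,
    sample_prefix: str = "S",
    label: str = "B1",
) -> SyntheticDataset:
    """One matrix with a single implanted multiplicative bicluster,
    gene-mean-centred."""
    values = np.zeros((config.n_genes, config.n_samples))
    genes, samples = _implant(
        values, config, rng, np.arange(config.n_genes), np.arange(config.n_samples)
    )
    mask = np.zeros(values.shape, dtype=bool)
    mask[np.ix_(genes, samples)] = True
    values += _noise_field(config, rng, mask)
    values -= values.mean(axis=1, keepdims=True)
    gids = gene_ids or _ids("G", config.n_genes)
    sids = _ids(sample_prefix, config.n_samples)
    truth = [Bicluster(frozenset(gids[i] for i in genes), frozenset(sids[j] for j in samples), label)]
    return SyntheticDataset(ExpressionMatrix(values, gids, sids), truth, config)


def generate_multi(
    config: GeneratorConfig,
    n_biclusters: int,
    rng: np.random.Generator,
    overlap: str = "exclusive",
) -> SyntheticDataset:
    """One matrix with several implanted biclusters sharing the gene pool.

    ``overlap`` controls the sample sets: ``"exclusive"`` partitions the
    samples into disjoint pools, ``"overlapping"`` draws every bicluster's
    samples independently from all samples (shared samples likely).
    """
    if overlap not in ("exclusive", "overlapping"):
        raise ValueError(f"unknown overlap mode {overlap!r}")
    values = np.zeros((config.n_genes, config.n_samples))
    mask = np.zeros(values.shape, dtype=bool)
    gids = _ids("G", config.n_genes)
    sids = _ids("S", config.n_samples)
    truth: list[Bicluster] = []
    if overlap == "exclusive":
        pools = np.array_split(rng.permutation(config.n_samples), n_biclusters)
    else:
        pools = [np.arange(config.n_samples)] * n_biclusters
    for b, pool in enumerate(pools):
        genes, samples = _implant(values, config, rng, np.arange(config.n_genes), np.asarray(pool))
        mask[np.ix_(genes, samples)] = True
        truth.append(
            Bicluster(frozenset(gids[i] for i in genes), frozenset(sids[j] for j in samples), f"B{b + 1}")
        )
    values += _noise_field(config, rng, mask)
    values -= values.mean(axis=1, keepdims=True)
    return SyntheticDataset(ExpressionMatrix(values, gids, sids), truth, config, {"overlap": overlap})


def generate_benchmark(
    rng: np.random.Generator,
    n_biclusters: int = 8,
    n_genes: int = 1000,
    total_samples: int = 1059,
    config: GeneratorConfig | None = None,
) -> SyntheticDataset:
    """The combined benchmark: eight sample-exclusive multiplicative
    biclusters in a 1000 x 1059 matrix.

    Per-bicluster sample-block sizes are multinomial around
    total_samples / n_biclusters; each block is a single-bicluster dataset
    over the shared 1000-gene universe, gene-mean-centred, and the blocks
    are concatenated along the sample axis.
    """
    base = config or GeneratorConfig(n_genes=n_genes)
    block_sizes = rng.multinomial(total_samples, [1.0 / n_biclusters] * n_biclusters)
    while (block_sizes < 2).any():  # degenerate draw; resample
        block_sizes = rng.multinomial(total_samples, [1.0 / n_biclusters] * n_biclusters)
    gids = _ids("G", n_genes)
    blocks = []
    truth: list[Bicluster] = []
    for b, size in enumerate(block_sizes):
        cfg = replace(
            base,
            n_genes=n_genes,
            n_samples=int(size),
            bicluster_samples=min(base.bicluster_samples, int(size)),
        )
        ds = generate_single(cfg, rng, gene_ids=gids, sample_prefix=f"B{b + 1}_S", label=f"B{b + 1}")
        blocks.append(ds.matrix.values)
        truth.append(ds.truth[0])
    values = np.concatenate(blocks, axis=1)
    sids = [s for b, size in enumerate(block_sizes) for s in _ids(f"B{b + 1}_S", int(size))]
    matrix = ExpressionMatrix(values, gids, sids)
    return SyntheticDataset(matrix, truth, base, {"block_sizes": block_sizes.tolist()})


def generate_variation_suite(
    rng: np.random.Generator,
    sizes: tuple[tuple[int, int], ...] = ((600, 100), (300, 50), (150, 25)),
    noise_levels: tuple[float, ...] = (0.0, 3.0, 6.0),
    n_genes: int = 1000,
    n_samples: int = 1000,
    multi_counts: tuple[int, ...] = (2, 4),
) -> list[SyntheticDataset]:
    """The size x noise grid of single-bicluster 1000 x 1000 datasets plus
    multi-bicluster datasets in exclusive and overlapping sample modes.

    ``sizes`` are exact (genes, samples) bicluster extents (no jitter);
    noise levels scale the signal-cell noise against the unit-variance
    background, spanning exact patterns (0) to substantially corrupted
    ones relative to the ~7 sd of a typical signal cell.
    """
    datasets: list[SyntheticDataset] = []
    for genes, samples in sizes:
        for noise in noise_levels:
            cfg = GeneratorConfig(
                n_genes=n_genes,
                n_samples=n_samples,
                bicluster_genes=genes,
                bicluster_samples=samples,
                noise_sd=noise,
                count_jitter=False,
            )
            ds = generate_single(cfg, rng)
            ds.meta.update({"suite": "size_noise", "genes": genes, "samples": samples, "noise": noise})
            datasets.append(ds)
    for count in multi_counts:
        for overlap in ("exclusive", "overlapping"):
            cfg = GeneratorConfig(
                n_genes=n_genes,
                n_samples=n_samples,
                bicluster_genes=300,
                bicluster_samples=max(2, n_samples // (2 * count)),
                count_jitter=False,
            )
            ds = generate_multi(cfg, count, rng, overlap=overlap)
            ds.meta.update({"suite": "multi", "n_biclusters": count, "overlap": overlap})
            datasets.append(ds)
    return datasets
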