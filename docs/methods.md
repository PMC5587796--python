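# Methods

`corrbic` discovers *massive* biclusters — subsets of genes and samples of
an expression matrix in which the genes are strongly mutually correlated —
and provides the synthetic benchmark and scoring machinery used to
characterize the approach. This note records the model, the algorithmic
and numerical choices, and what the synthetic experiments do and do not
demonstrate.

## The quality metric

For a gene subset of size G and a sample subset, the bicluster score is
the mean of the absolute values of all entries of the G x G Pearson
correlation matrix computed across the selected samples, diagonal
included. The score lies in [1/G, 1] (the diagonal contributes G ones)
and equals 1 exactly when every gene pair satisfies |r| = 1. Absolute
values are essential: the target structure mixes up- and down-regulated
gene groups, and anti-correlation is evidence of co-regulation, not
against it. Including the diagonal is a normalization convention only —
for fixed G it is a monotone transform of the off-diagonal mean, so it
never changes which of two sample sets is preferred.

Two biases of this metric matter in practice and are handled explicitly:

* **Small-set inflation.** The expected |r| of independent Gaussian genes
  over n samples is large for small n (≈ 0.26 at n = 10), and the maximum
  over many candidate gene pairs approaches 1. A handful of genes can
  therefore outscore a genuine 100-gene bicluster. The gene-core
  refinement applies a soft minimum winner size (`min_group_size`,
  8 genes in the batch pipeline) so degenerate two-gene "cores" only win
  when nothing larger exists.
* **Low-leverage preference.** When the scored gene set mixes pattern
  genes with background genes, samples that sit near the centroid
  (background samples) disturb the already-established correlations least
  and can be preferred over genuine pattern samples. The extension stage
  therefore ranks samples on the CV-coherent gene set (below), never on a
  mixed core.

## One stochastic run

1. **Seed.** ~1000 seed genes (random, or a user-supplied functional set)
   and k = 10 random samples.
2. **Greedy sample search** (`find_seed`). Each of `n_iterations`
   (default 500) proposals replaces one uniformly chosen in-set sample
   with one uniformly chosen out-of-set sample; the proposal is accepted
   iff the score strictly increases. A proposal that makes a gene
   constant (score undefined) is rejected. The accepted-score trajectory
   is recorded and is non-decreasing by construction. The climb is a
   local search: on the eight-bicluster benchmark it reliably reaches
   states dominated by one implanted bicluster but typically retains 3-5
   samples serving correlations among genes shared between biclusters —
   a real feature of the objective when biclusters share half their
   genes, not a convergence artifact; pushing the budget from 500 to
   1500 iterations does not change it.
3. **Gene-core refinement** (`refine_gene_core`). The seed genes are
   clustered hierarchically (average linkage on the distance 1 − r over
   the 10 found samples, linkage exposed as a parameter), cut into 8
   groups, and the group with the highest score over those samples is
   kept. Genes constant over the core samples are excluded first.
4. **Correlation vector** (`correlation_vector`). The core genes are
   split into 2 groups by the same clustering (2 matches the two-fork
   anti-correlation structure; exposed as a parameter); the group whose
   mean profile best correlates with its own members provides the
   *average expression vector*, and the CV is each matrix gene's Pearson
   correlation with that profile over the 10 core samples. Genes constant
   over the core samples get CV = 0 so the |CV| ordering stays total.

Per-run seeds are `root_seed + run_index`, so a batch is reproducible and
resumable (finished runs are re-read from their JSON files).

## Consolidating runs

A run's CV sign is arbitrary (the two forks are exchangeable), so runs
are compared by the distance 1 − |r(cv_a, cv_b)|. Hierarchical clustering
(average linkage) of all runs is cut at the k in 2..20 maximizing the
average silhouette width; if even the best cut is weaker than 0.25 the
runs form a single group. Each group's representative CV is the
element-wise mean of the member CVs after flipping each to correlate
positively with the group medoid.

## Extending a group

The member run whose CV agrees best (|r|) with the group representative
is the *exemplar*; its 10 samples anchor the extension. (The medoid and
the highest-scoring member are available as alternatives; the raw core
score is not comparable across core sizes, which is why "best score" is
not the default.)

* **Ranking genes.** Genes are ordered by |CV| of the representative.
  The sample ranking is computed over the top genes of this ordering
  (as many as clear the |CV| ≥ 0.7 cutoff, clamped to [8, `max_sort_genes`]):
  gene extension precedes sample ranking, and using CV-coherent genes
  avoids the low-leverage bias described above.
* **Sample ranking** (`sort_samples`). Starting from the exemplar's 10
  samples, the unranked sample maximizing the core score of the ranked
  prefix plus that sample is appended until all samples are ranked; ties
  break towards the lower sample index. The scan is computed
  incrementally from per-gene running sums and the gene-gene
  cross-product matrix (O(G²) per candidate instead of O(G²·j)), with a
  compiled kernel when numba is available and a vectorized numpy fallback;
  both agree with direct rescoring to ~1e-9. `max_sort_genes`
  (150 in the batch pipeline, uncapped in the standalone function)
  bounds the quadratic gene cost on very large cores.
* **PC1** (`pc1_projection`). PCA is fitted on the 10 top-ranked samples
  over the bicluster genes (genes centred over those samples); all
  samples are projected on PC1. The sign is fixed so PC1 correlates
  positively with the mean expression of the positive-CV gene group over
  the fitting samples. Plotted against rank this yields the
  characteristic two-fork pattern; `classify_forks` labels thresholded
  samples upper/lower by the sign of PC1.

## Thresholding

Which ranked samples formally belong to the bicluster is decided by a
per-sample rank-1 agreement test. For sample s let

    f_s = cos²( x̃_s , w )

where w is the PC1 axis fitted on the 10 top-ranked samples over the
core genes and x̃_s is the sample's core-gene expression minus the
*background profile* — the mean profile of the bottom-half-ranked
samples. Centring on the background is essential: gene-mean-centred data
places a component proportional to the pattern into every background
column (the members pulled the gene means), and the background profile
cancels it exactly while leaving members aligned with w.

Under independent Gaussian noise f follows Beta(1/2, (G−1)/2) exactly.
Walking down the ranking, samples are retained while f exceeds the
family-wise cutoff at level alpha (per-sample level
1 − (1−alpha)^(1/(N−k)), alpha = 0.05 by default); the walk stops at the
first failure, and the k core positions are always retained. An
empirical null (`null="empirical"`, `n_null` random directions) replaces
the Beta law when the noise model is in doubt. Bicluster genes are those
with |CV| ≥ 0.7 (exposed).

Properties: with an exact implanted pattern the retained samples equal
the implanted samples; under pure noise the probability of retaining
anything beyond the core is ≈ alpha (verified at ±3 binomial SD over 200
replicates); retention is monotone in alpha. The construction assumes
the bicluster covers less than half the cohort — if it covers more, the
background profile is contaminated and the threshold over-extends.

## Enrichment and fork association

Gene-set enrichment on a CV is a two-sided Mann-Whitney U test of
in-term vs out-of-term CV values per term (universe = genes in the
matrix; terms with fewer than 5 members after intersection dropped). The
exact U distribution is used when the smaller group has < 20 genes and
there are no ties, otherwise the normal approximation with tie and
continuity correction. Direction (positive/negative) is the sign of the
in-term minus out-of-term median. Benjamini-Hochberg (default) or
Bonferroni adjustment is applied across terms.

The fork association test compares a per-sample covariate between the
upper and lower fork: the observed statistic is the difference of means;
labels are randomly reassigned with group sizes fixed. All C(n, n_upper)
assignments are enumerated when they fit in `n_perm` (exact p-value);
otherwise `n_perm` Monte Carlo permutations with the add-one estimator
(b+1)/(n_perm+1), which never returns 0.

## Synthetic data

A dataset is `sum of lambda z^T + noise`, gene-mean-centred: each
implanted bicluster has gene loadings lambda (nonzero only for member
genes; magnitude |N(3,1)|, random signs) and sample factors z (nonzero
only for member samples; magnitude |N(2,1)|, random signs). A typical
signal cell therefore has sd ≈ 7. The Gaussian noise field has sd
`noise_sd` on signal cells and `background_sd` (default 1) elsewhere;
with both at their defaults this is a single homogeneous N(0,1) field.
The split exists because a literally global sd of 0 makes every gene an
affine function of the factor — every sample subset then scores 1.0 and
sample membership is unidentifiable — so "noiseless" here means an exact
implanted pattern over a unit-variance background (infinite SNR), which
keeps the noiseless limiting behaviour testable.

The combined benchmark concatenates eight single-bicluster 1000-gene
datasets along the sample axis to exactly 1000 x 1059: block sizes are
multinomial around 1059/8, member counts Poisson around 500 genes x 130
samples (bounded to the block), each block is gene-mean-centred before
concatenation, and truth sample sets are disjoint by construction. Gene
memberships are drawn independently per block, so two biclusters share
~250 of their ~500 genes — the property that makes the search's
mixed-block local optima genuinely competitive and recovery imperfect,
for this package as for the method it reimplements.

The variation suite provides single-bicluster 1000 x 1000 datasets on the
grid (600 genes x 100 samples, 300 x 50, 150 x 25) x noise sd
(0, 3, 6 — spanning exact patterns to substantial corruption relative to
the ~7 sd of a signal cell), plus multi-bicluster datasets with
exclusive or overlapping sample modes.

What the generator does **not** emulate: heavy-tailed or count noise,
gene-gene correlation outside biclusters, batch structure, or
platform-specific normalization artifacts. Passing the synthetic tests
shows the machinery behaves as designed under the multiplicative model;
it does not certify performance on real microarray or RNA-seq cohorts.

## Benchmark scoring

Biclusters are compared as sets of (gene, sample) cells; the Jaccard
index of two biclusters reduces to
|G_a∩G_b|·|S_a∩S_b| / (|G_a||S_a| + |G_b||S_b| − inter). Cell-level
similarity is used for the assignment because the matching needs a
single number per pair; gene- and sample-level agreement are reported
separately through the F1 table. Predictions are matched one-to-one to
knowns by the Hungarian algorithm maximizing summed Jaccard; the
consensus score divides the matched sum by the size of the larger
collection, penalizing a wrong bicluster count. Mean gene-set and
sample-set F1 are reported over *all* known biclusters with unmatched
knowns scoring 0 (the per-pair table allows recovering a matched-only
mean). Two extent modes are scored: *optimum* (prefixes of the sample
ranking and |CV| gene ordering maximizing Jaccard to the matched known —
an oracle-assisted upper bound) and *threshold* (the package's own
thresholding, blind to truth).

## Problem sizes and determinism

The benchmark study in the acceptance script and test suite uses 100
runs of 500 iterations on the 1000 x 1059 benchmark, ranking capped at
150 genes — about 10 minutes on one core. Calibration tests use 200
replicates on 30 x 60 matrices; the variation study uses 4-16 restarts
per dataset. All randomness flows from `numpy.random.default_rng` roots;
per-run seeds are root + index, so every result in the test suite and
acceptance script is reproducible bit-for-bit at a fixed root seed (the
sort kernel's compiled and numpy paths may differ at ~1e-12, which never
changes a ranking decision in the tested configurations).

## Known limitations

* The greedy climb cannot split samples shared by overlapping biclusters
  (overlapping-sample recovery is poor by design of the objective).
* The threshold assumes the bicluster is a minority of the cohort.
* Silhouette consolidation needs several runs per bicluster to form
  groups; at very low run counts distinct biclusters surface as
  singleton groups.
* The raw core score is not comparable across core sizes; any selection
  across cores of different size must account for the 1/G floor and
  small-set inflation.
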