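# Methods

## Model

Bulk expression of a mixed sample is modelled as a non-negative linear
combination of cell-type mean profiles, `s ≈ M p`, with `p` on the simplex.
The model assumes linear (non-log) expression units throughout: probe
intensities are averaged on the linear scale, quantile normalization and all
solvers operate on linear values, and no automatic log detection is
attempted. Goodness of fit is the Pearson correlation between the
(preprocessed) mixture and its reconstitution `M p̂`, computed in the same
space used for fitting; being a correlation, it is invariant to affine
rescaling of the mixture.

## Basis construction

The basis matrix is built from an annotated sorted-cell compendium in two
stages, after quantile-normalizing the compendium (idempotent if it already
went through `merge_datasets`, which quantile-normalizes each dataset and
the merged matrix):

1. **Cell-type stage.** For each cell type `i` within each lineage `l`
   (lineages are a user-supplied biological grouping; lineages with a single
   member are skipped here with a warning), compute the one-vs-rest Hedges'
   g per gene against the other members of the lineage, then the min-delta
   separation `ΔE_g,i = min_{j≠i} (E_g,i − E_g,j)`: a gene scores high only
   if it separates the target from its *closest* relative. Genes are ranked
   by ΔE (descending; ties broken lexicographically by gene id for
   determinism) and a stepwise search adds one gene at a time, recomputing
   the AUROC of target-vs-rest classification from the prefix score (the
   mean of per-gene z-scores over the comparison population — the simplest
   monotone aggregate, which reduces to the single-gene AUROC at k = 1). The
   chosen signature is the smallest prefix within ε = 0.005 of the maximum
   AUROC over the searched range, raised to at least 5 genes; the search is
   capped at 50 genes (signatures in this domain are small, and the cap
   bounds runtime).
2. **Lineage stage.** All stage-1 genes (from every lineage) are removed
   from the candidate pool — they separate cell types and would confound
   lineage separation — and the same ranking-plus-stepwise procedure is run
   for each lineage against all other samples.

Basis values are the per-cell-type means of the union gene set computed from
the quantile-normalized compendium; per-gene stage provenance is recorded,
and the two stage gene sets are disjoint by construction.
`basis_from_gene_list` re-estimates values for an externally chosen gene
list (the published-gene-set control) with the same mean-from-QN rule.

Numerical details of the effect size: pooled-SD standardized mean difference
with the Hedges–Olkin small-sample correction `J = 1 − 3/(4(n1+n2) − 9)`,
applied always; a zero pooled SD with unequal means returns ±1e6, so perfect
separators outrank all finite effects without producing non-finite
arithmetic; groups need at least 3 samples on each side (the correction is
ill-behaved below that).

## Deconvolution

Four solvers share one preprocessing contract: the mixture dataset is
quantile-normalized once (dataset-level), then each sample vector is
restricted to the basis genes, z-scored by its own mean/SD, and the basis is
z-scored by its matrix-wide mean/SD (global standardization preserves
between-cell-type contrasts; per-column scaling would erase them). Both
steps can be disabled independently.

- `linear`: ordinary least squares (no intercept), negatives clipped to
  zero, renormalized to sum 1.
- `qp`: exact `argmin ‖s − Mp‖²` subject to `p ≥ 0, Σp = 1`, via a small
  active-set method on the KKT system (finite termination; the returned
  point is checked against the KKT conditions at 1e−8).
- `robust`: Huber M-estimation by IRLS (tuning constant 1.345, scale
  re-estimated each iteration as MAD/0.6745, coefficient tolerance 1e−6,
  at most 50 iterations, error on non-convergence), then clip/renormalize.
- `svr`: linear-kernel ν-SVR with C = 1.0 and tolerance 1e−4, fitted for
  ν ∈ {0.25, 0.5, 0.75}; the fit with the smallest reconstruction RMSE
  (raw coefficients plus the model intercept) is kept, then
  clip/renormalize.

**Benchmark regime.** The recovery benchmarks (exact and 5%-noise) evaluate
linear/qp/robust in raw space and SVR with z-scoring. Rescaling was never
part of the native linear/robust/QP formulations, and z-scoring without an
intercept introduces an affine offset outside the span of the basis columns,
which makes sub-1e−6 recovery impossible for an interceptless OLS fit; SVR,
by contrast, is defined on standardized data and carries its own bias term.
In the default pipeline (both steps on) all solvers remain accurate to a few
percent on well-conditioned bases; on a highly collinear basis the z-scored
regime degrades gracefully rather than exactly.

**Fit significance.** The permutation null re-solves the deconvolution
after assigning a uniformly drawn random gene subset of the sample's full
profile (same size as the basis overlap) to the basis gene slots;
`p = (1 + #{null gof ≥ observed})/(n_perm + 1)`. By construction these
p-values are uniform (up to grid discreteness) when the sample itself is
exchangeable noise, which the calibration benchmark verifies by KS test.

## Bias evaluation

**Platform heterogeneity.** The observed statistic is the raw median
absolute deviation (no 1.4826 consistency constant — it is a descriptive
heterogeneity score, not a robust SD estimate) of per-platform median
goodness of fit, pooling methods. The null distribution permutes the
sample→platform assignment (group sizes preserved; all method rows of a
sample move together) and recomputes the statistic; a one-sided upper-tail
Z-test against the permutation moments gives the p-value. A per-sample
variant (median absolute deviation of each sample's gof from the pooled
mean) is available behind `variant="per_sample"`. Measured size at
α = 0.05 is nominal (≈ 0.05 over 200 null replicates) and power against a
τ = 0.5 platform effect is ≈ 1.

**Fisher combination** uses the log-sum rule (χ² = −2Σln p on 2k degrees of
freedom) and assumes independence of the combined tests — approximate when
methods are correlated, as they are here; it is used descriptively.
**Blood-vs-tissue discrimination** scores samples by −log10 of the fit
p-value, blood as the positive class, and reduces to the Mann–Whitney AUROC
(ties count 1/2). **Agreement** pools all (sample, cell type) pairs for the
Pearson correlation and reports RMSE in percentage points (fractions are
converted by ×100).

## Synthetic data

The generator emulates a heterogeneous sorted-cell compendium:

- **Profiles.** A shared log-normal base profile (log-location 5.0, log-SD
  0.7 — a microarray-like dynamic range of ~40–4000 in arbitrary linear
  units) is modulated per cell type by log-normal jitter with log-SD 0.05.
  Cell identity is carried by planted markers: 5 exclusive markers per cell
  type (default) and 5 lineage-shared markers per multi-member lineage, all
  raised by a fold change of 4. The small jitter is deliberate: cell types
  within a lineage differ through their marker programs plus residual
  background modulation, so the planted markers are the genuinely strongest
  separators; with broad background jitter the "markers" would not be the
  signal a selection method ought to find. For a singleton lineage no
  separate lineage markers are planted (its lineage identity *is* its cell
  identity).
- **Hierarchy.** 20 blood cell types in 9 lineages (T, monocytes,
  macrophages, NK, B, myeloid DC, plasmacytoid DC, progenitors,
  granulocytes); the two DC lineages and progenitors are singletons, which
  exercises the stage-1 skip path.
- **Noise.** Additive Gaussian per sample (default SD 10 ≈ 5% of the mean
  signal), truncated at zero to keep values non-negative.
- **Platforms.** Each platform applies a per-gene multiplicative factor
  `exp(N(0, τ²))` shared by all of its samples, optionally on top of a
  manufacturer-family log-factor shared by the platforms of one family
  (off by default), then a per-platform power-law exponent drawn
  log-uniformly in [1/γ, γ] (γ = 1 disables it). Default platform weights
  fall off as 1/(i+1), echoing the dominance of a single vendor in public
  repositories.
- **Disease.** A fixed disease-responsive gene set (default 30% of genes)
  is scaled in diseased samples only. Two factor models: one shared
  program (one factor per gene, all diseased samples alike) and a
  heterogeneous cohort (factors drawn per gene *and* sample). The
  compendium generator uses the heterogeneous model — public disease
  cohorts span many diseases, and a single shared program would imprint
  itself into the mean values of any basis built on the diseased samples,
  which inverts the biology the disease experiment studies.
- **Mixtures** draw `p ~ Dirichlet(α)` (default α = 1) over the true
  profiles plus truncated noise; **out-of-basis samples** draw independent
  log-normal profiles (cell types disjoint from the basis), emulating solid
  tissue whose constituents a blood basis does not contain.

All generators are pure functions of (config, seed).

### What the generator does not emulate

Probe-level microarray artifacts, background correction, RNA-seq count
noise, correlated marker programs across cell types, partially shared
lineage markers, and tissue samples that *partially* overlap blood cell
types. Passing tests therefore demonstrate the correctness and the
directional behavior of the machinery under a controlled linear-mixing
model, not performance on any particular real cohort.

## Experiment scenarios

Desk-scale sizes are deliberate choices to keep replicated experiments
cheap while preserving the mechanisms; all are recorded here as the
package's benchmark definitions.

- **Marker-recovery scenario**: 1500 genes, 10 samples per cell type,
  fold-change 4, platform τ = 0.2 with γ = 1, no disease. Recovery means
  every cell type retains ≥ 80% of its planted markers in the built basis.
- **Platform experiment**: 1200 genes, 20 samples/type, τ = 0.5 at both the
  manufacturer-family and platform level, two manufacturer families, γ = 1
  (an exponent distortion hits every basis alike and only blurs the
  single-vs-multi contrast), platform 0 holding 30% of sorted samples with
  the two families balanced 50/50; 80 mixtures (10 per platform), all four
  methods, MAD test with 200 permutations. The family layer mirrors real
  cohorts, where platforms cluster by manufacturer — and a robust MAD of
  per-platform medians detects exactly that cluster structure rather than a
  single outlying platform.
- **Disease experiment**: 1600 genes with redundant marker pools (20 per
  cell type, 12 per lineage), 16 samples/type, half the sorted samples
  diseased, disease-responsive set = 50% of genes at log-SD 2
  (leukemia-scale remodeling). Redundancy matters: a basis built on
  healthy + diseased cells avoids responsive genes only if enough clean
  markers exist to fill the 5-gene signature minimum. Test cohorts: 20
  blood-analog mixtures and 20 tissue-analog samples per state; diseased
  blood reuses the compendium's responsive gene set (same blood-disease
  biology) while diseased tissue draws its own perturbed set (solid-tumor
  programs differ from blood-disease programs); discrimination uses fit
  p-values at 100 permutations.
- **Concordance experiment**: the built basis versus an alternative matrix
  re-estimated from the same compendium over a partially overlapping gene
  list (two planted markers per cell type plus random filler), all four
  methods, 24 noisy multi-platform mixtures; pairwise Pearson correlations
  of the flattened estimate tables, grouped by same-matrix/different-method,
  different-matrix/same-method, and both-different.

## Known limitations

- **Quantile-normalization tail artifact.** Basis values are means over the
  quantile-normalized compendium. QN maps each sample through its rank onto
  a shared reference; in the sparse upper tail (where fold-4 markers live)
  this introduces a systematic per-entry error of ~4–8% that does not
  average out with more samples. Under the shared-base profile geometry the
  20 basis columns are highly collinear, and that error is comparable to
  the contrast contributed by small proportions: the full
  generate→build→deconvolve loop attains a pooled truth correlation of
  ≈ 0.86–0.97 across seeds (median ≈ 0.93) at 5% noise, while the same loop
  with oracle basis values attains ≥ 0.99. Real signature matrices, with
  fold changes of 10–1000 and near-zero off-target expression, sit far from
  this regime.
- Strict QN idempotence holds for tie-free data; the tie rule (tied entries
  share the mean of the reference values over their rank span) necessarily
  alters the shared multiset when ties exist (for example, zeros introduced
  by noise truncation).
- The Fisher combination treats per-method p-values as independent, which
  they are not; it is reported as a descriptive summary.
- The MAD Z-test relies on approximate normality of the permutation null of
  a median-based statistic; with very few platforms (< 4) its size can
  drift from nominal.
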