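# decomix

Cell-mixture deconvolution for bulk transcriptomics, with an emphasis on the
**basis matrix**: how it is built, and how its construction biases the
proportions you get out.

## The problem

Bulk expression of a mixed-cell sample (blood, PBMC, a biopsy) is modelled as
a linear combination of cell-type-specific profiles:

    s ≈ M · p

where **s** is the mixture expression vector over signature genes, **M** is a
basis (signature) matrix of mean expression per cell type, and **p** is the
vector of cell-type proportions (p ≥ 0, Σp = 1). Deconvolution estimates
**p**. Quality is summarized by the *goodness of fit*, the Pearson
correlation between **s** and the reconstitution **M·p̂**, and its permutation
significance.

Basis matrices built from healthy sorted cells on a single microarray
platform carry technical (platform) and biological (disease) biases into
every downstream estimate, regardless of the solver. `decomix` implements
the full workflow needed to construct low-bias matrices from heterogeneous
sorted-cell compendia and to quantify both biases:

- **`decomix.io_norm`** — expression-matrix I/O, probe→gene collapsing,
  quantile normalization, multi-dataset merging;
- **`decomix.basis`** — hierarchical basis construction: one-vs-rest Hedges'
  g effect sizes per cell type within a lineage, the min-delta separation
  statistic ΔE_g,i = min_j (E_g,i − E_g,j) over competitor cell types j, and
  a stepwise AUROC search for the smallest gene prefix within ε = 0.005 of
  the maximum (≥ 5 genes per signature), run first for cell types within
  lineages, then for lineages with the stage-1 genes excluded;
- **`decomix.deconv`** — four solvers behind one preprocessing contract
  (dataset-level quantile normalization + z-scoring, each optional): OLS,
  exact simplex-constrained least squares, Huber IRLS, and linear-kernel
  ν-SVR over ν ∈ {0.25, 0.5, 0.75};
- **`decomix.evaluate`** — permutation p-values for goodness of fit, the MAD
  platform-heterogeneity Z-test, Fisher's p-value combination,
  blood-vs-tissue discrimination AUROC, and agreement with measured
  proportions (Pearson r, RMSE in percentage points);
- **`decomix.synthetic`** — a generator for multi-platform, multi-disease
  sorted-cell compendia with planted markers, plus Dirichlet mixtures and
  out-of-basis ("tissue") samples, so every claim is testable without
  external data;
- **`decomix.workbench`** — replicated experiments for the three headline
  phenomena: platform bias, disease bias, and matrix-over-method
  concordance.

## Worked example

`examples/02_deconvolve_mixtures.py` builds 30 Dirichlet mixtures of 20
cell-type profiles over 317 genes at 5% additive noise and deconvolves them
against the true reference:

```
30 mixtures x 317 genes at 5% noise

method    pearson r  RMSE (pp)
linear       0.9891       0.67
qp           0.9892       0.67
robust       0.9887       0.68
svr          0.9873       0.73
```

All four solvers recover the known composition almost perfectly (pooled
correlation ≈ 0.99; root-mean-square error < 1 percentage point) — with the
*same* matrix, the choice of method barely matters. The bias experiments
show the converse: `examples/03_platform_bias.py` prints, per replicate, the
cross-platform MAD of median goodness of fit for a basis built from one
platform versus all platforms,

```
median MAD, single-platform basis: 0.127
median MAD, multi-platform basis:  0.035
replicates with MAD(single) > MAD(multi): 100%
```

i.e. the single-platform basis fits its own manufacturer's mixtures well and
the other's poorly, and the heterogeneity score exposes it. The other
examples cover basis construction with planted-marker recovery
(`01_build_basis.py`) and fit-significance/blood-vs-tissue discrimination
(`04_fit_significance_and_agreement.py`).

A thin CLI mirrors the library for shell use:

```bash
decomix simulate --config cfg.json --seed 7 --out-dir sim/
decomix build-basis --compendium sim/compendium.tsv --out basis.tsv
decomix deconvolve --mixtures mix.tsv --basis basis.tsv \
    --methods linear,qp,robust,svr --out results.tsv
decomix evaluate-bias --results results.tsv --annotations ann.tsv --out bias.json
decomix agreement --estimated est.tsv --measured facs.tsv --out agree.json
decomix experiment platform --reps 20 --seed 7 --out report.json
```

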