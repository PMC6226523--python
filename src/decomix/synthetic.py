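"""Synthetic sorted-cell compendia, mixtures, and ground truths.

The generator emulates a heterogeneous multi-platform sorted-leukocyte
compendium: per-cell-type mean expression profiles are a shared log-normal
base profile modulated by per-cell-type jitter, with planted marker genes
(cell-type-specific and lineage-shared) raised by a configurable fold
change.  Samples add truncated Gaussian noise; platform effects apply
per-(platform, gene) multiplicative log-normal factors plus a per-platform
power-law nonlinearity; a disease program scales a shared random gene subset
in diseased samples only.  Mixtures draw Dirichlet proportions over the
cell-type profiles.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_norm import ExpressionMatrix

#: 20 blood cell types grouped into 9 lineages (myeloid/plasmacytoid DCs and
#: progenitors are singleton lineages).
DEFAULT_HIERARCHY: dict[str, str] = {
    "CD4_T": "T",
    "CD8_T": "T",
    "gamma_delta_T": "T",
    "CD14_monocyte": "monocytes",
    "CD16_monocyte": "monocytes",
    "macrophage_M0": "macrophages",
    "macrophage_M1": "macrophages",
    "macrophage_M2": "macrophages",
    "NK_bright": "NK",
    "NK_dim": "NK",
    "naive_B": "B",
    "memory_B": "B",
    "plasma_cell": "B",
    "myeloid_DC": "mDC",
    "plasmacytoid_DC": "pDC",
    "progenitor": "HPC",
    "neutrophil": "granulocytes",
    "eosinophil": "granulocytes",
    "basophil": "granulocytes",
    "mast_cell": "granulocytes",
}


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the synthetic compendium generator.

    Defaults echo a desk-scale analog of a large multi-platform sorted-cell
    compendium: 20 cell types in 9 lineages, a dominant first platform
    (weights ~ 1/(i+1)), mild platform distortions, and a moderate disease
    program affecting a shared gene subset in diseased samples.
    """

    n_genes: int = 5000
    hierarchy: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_HIERARCHY))
    n_samples_per_type: int = 10
    n_markers_per_type: int = 5
    marker_fold_change: float = 4.0
    n_lineage_markers: int = 5  # multi-member lineages only
    base_loc: float = 5.0  # log-normal location of the shared base profile
    base_scale: float = 0.7  # log-normal scale of the shared base profile
    profile_jitter_sd: float = 0.05  # per-(cell type, gene) log-scale jitter
    noise_sd: float = 10.0  # additive linear-scale Gaussian, truncated at 0
    n_platforms: int = 8
    platform_tau: float = 0.3  # per-(platform, gene) log-factor SD
    platform_gamma: float = 1.1  # per-platform exponents drawn in [1/gamma, gamma]
    n_manufacturers: int = 2  # platform families (round-robin assignment)
    manufacturer_tau: float = 0.0  # family-level log-factor SD shared within family
    disease_fraction: float = 0.3  # fraction of sorted samples diseased
    disease_gene_fraction: float = 0.3  # fraction of genes in the disease program
    disease_scale: float = 1.0  # log-SD of per-gene disease factors
    dirichlet_alpha: float | Sequence[float] = 1.0
    platform_weights_custom: tuple | None = None  # overrides the 1/(i+1) default
    n_out_of_basis_types: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_type < 1 or self.n_platforms < 1:
            raise ValueError("all counts must be >= 1")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must exceed 1")
        if self.platform_tau < 0 or self.platform_gamma <= 0:
            raise ValueError("platform_tau >= 0 and platform_gamma > 0 required")
        if not (0 <= self.disease_fraction <= 1 and 0 <= self.disease_gene_fraction <= 1):
            raise ValueError("disease fractions must lie in [0, 1]")
        if self.noise_sd < 0 or self.profile_jitter_sd < 0 or self.disease_scale < 0:
            raise ValueError("dispersion parameters must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        return list(self.hierarchy)

    @property
    def lineages(self) -> list[str]:
        return list(dict.fromkeys(self.hierarchy.values()))

    def platform_weights(self) -> np.ndarray:
        if self.platform_weights_custom is not None:
            w = np.asarray(self.platform_weights_custom, dtype=float)
            if w.size != self.n_platforms or (w < 0).any() or w.sum() <= 0:
                raise ValueError("invalid platform weights")
        else:
            w = 1.0 / (1.0 + np.arange(self.n_platforms))
        return w / w.sum()


@dataclass
class SimTruth:
    """Ground truth for one synthetic scenario."""

    config: SimConfig
    mean_profiles: pd.DataFrame  # genes x cell types (clean, pre-noise)
    markers: dict[str, list]  # cell type -> planted marker genes
    lineage_markers: dict[str, list]  # lineage -> shared marker genes
    platform_factors: pd.DataFrame  # platforms x genes, multiplicative
    platform_exponents: pd.Series  # per-platform power-law exponent
    disease_genes: list  # genes in the disease program
    disease_factors: pd.Series  # per perturbed gene, multiplicative
    seed: int = 0
    mixture_proportions: pd.DataFrame | None = None  # mixtures x cell types


def _platform_names(n: int) -> list[str]:
    return [f"platform_{i}" for i in range(n)]


def _draw_platform_model(cfg: SimConfig, genes, rng) -> tuple[pd.DataFrame, pd.Series]:
    # factor = family (manufacturer) log-factor shared within the family
    # plus a platform-specific log-factor, both zero-mean Gaussian
    names = _platform_names(cfg.n_platforms)
    log_factors = rng.normal(0.0, cfg.platform_tau, size=(cfg.n_platforms, len(genes)))
    if cfg.manufacturer_tau > 0 and cfg.n_manufacturers > 1:
        family = rng.normal(
            0.0, cfg.manufacturer_tau, size=(cfg.n_manufacturers, len(genes))
        )
        for i in range(cfg.n_platforms):
            log_factors[i] += family[i % cfg.n_manufacturers]
    log_g = np.log(cfg.platform_gamma)
    exponents = np.exp(rng.uniform(-log_g, log_g, size=cfg.n_platforms))
    return (
        pd.DataFrame(np.exp(log_factors), index=names, columns=genes),
        pd.Series(exponents, index=names),
    )


def simulate_sorted_compendium(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate an annotated multi-platform sorted-cell compendium.

    Returns the compendium (fully annotated: cell_type, lineage, platform,
    disease_state, tissue_source = blood) and the SimTruth with clean mean
    profiles, the planted marker map, platform factors/exponents, and the
    disease program.  Bit-reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    cell_types = cfg.cell_types
    lineages = cfg.lineages
    members = {lin: [c for c, l in cfg.hierarchy.items() if l == lin] for lin in lineages}
    multi_lineages = [lin for lin in lineages if len(members[lin]) > 1]

    demand = len(cell_types) * cfg.n_markers_per_type + len(multi_lineages) * cfg.n_lineage_markers
    if demand > cfg.n_genes:
        raise ValueError(f"marker demand ({demand}) exceeds n_genes ({cfg.n_genes})")
    genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]

    base = np.exp(rng.normal(cfg.base_loc, cfg.base_scale, size=cfg.n_genes))
    marker_pool = rng.choice(cfg.n_genes, size=demand, replace=False)
    cursor = 0
    markers: dict[str, list] = {}
    for ct in cell_types:
        idx = marker_pool[cursor : cursor + cfg.n_markers_per_type]
        markers[ct] = [genes[i] for i in idx]
        cursor += cfg.n_markers_per_type
    lineage_markers: dict[str, list] = {lin: [] for lin in lineages}
    for lin in multi_lineages:
        idx = marker_pool[cursor : cursor + cfg.n_lineage_markers]
        lineage_markers[lin] = [genes[i] for i in idx]
        cursor += cfg.n_lineage_markers

    gene_pos = {g: i for i, g in enumerate(genes)}
    profiles = np.empty((cfg.n_genes, len(cell_types)))
    for j, ct in enumerate(cell_types):
        jitter = np.exp(rng.normal(0.0, cfg.profile_jitter_sd, size=cfg.n_genes))
        prof = base * jitter
        prof[[gene_pos[g] for g in markers[ct]]] *= cfg.marker_fold_change
        lin = cfg.hierarchy[ct]
        if lineage_markers[lin]:
            prof[[gene_pos[g] for g in lineage_markers[lin]]] *= cfg.marker_fold_change
        profiles[:, j] = prof
    mean_profiles = pd.DataFrame(profiles, index=genes, columns=cell_types)

    # samples
    sample_ids, ann_rows, cols = [], [], []
    for ct in cell_types:
        prof = mean_profiles[ct].to_numpy()
        for r in range(cfg.n_samples_per_type):
            sid = f"{ct}_s{r:02d}"
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes) if cfg.noise_sd > 0 else 0.0
            cols.append(np.clip(prof + noise, 0.0, None))
            sample_ids.append(sid)
            ann_rows.append({"cell_type": ct, "lineage": cfg.hierarchy[ct]})
    expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    ann = pd.DataFrame(ann_rows, index=pd.Index(sample_ids, name="sample_id"))

    # platform assignment and model
    platform_factors, platform_exponents = _draw_platform_model(cfg, genes, rng)
    ann["platform"] = rng.choice(
        _platform_names(cfg.n_platforms), size=len(sample_ids), p=cfg.platform_weights()
    )

    # disease program
    n_disease_genes = int(round(cfg.disease_gene_fraction * cfg.n_genes))
    disease_idx = np.sort(rng.choice(cfg.n_genes, size=n_disease_genes, replace=False))
    disease_genes = [genes[i] for i in disease_idx]
    disease_factors = pd.Series(
        np.exp(rng.normal(0.0, cfg.disease_scale, size=n_disease_genes)), index=disease_genes
    )
    is_disease = rng.random(len(sample_ids)) < cfg.disease_fraction
    ann["disease_state"] = np.where(is_disease, "disease", "healthy")
    ann["tissue_source"] = "blood"

    m = ExpressionMatrix(expr, ann)
    # heterogeneous disease cohort: every diseased sorted sample carries its
    # own factor draw over the shared disease-responsive gene set
    m = apply_disease_effect(
        m,
        pd.Series(is_disease, index=sample_ids),
        f=cfg.disease_gene_fraction,
        scale=cfg.disease_scale,
        seed=int(rng.integers(2**31)),
        genes=disease_genes,
        per_sample=True,
    )
    m = apply_platform_effect(
        m,
        ann["platform"],
        tau=cfg.platform_tau,
        gamma=cfg.platform_gamma,
        seed=0,
        factors=platform_factors,
        exponents=platform_exponents,
    )
    truth = SimTruth(
        config=cfg,
        mean_profiles=mean_profiles,
        markers=markers,
        lineage_markers=lineage_markers,
        platform_factors=platform_factors,
        platform_exponents=platform_exponents,
        disease_genes=disease_genes,
        disease_factors=disease_factors,
        seed=cfg.seed,
    )
    return m, truth


def apply_platform_effect(
    m: ExpressionMatrix,
    assignments,
    tau: float,
    gamma: float,
    seed: int = 0,
    factors: pd.DataFrame | None = None,
    exponents: pd.Series | None = None,
) -> ExpressionMatrix:
    """Apply per-platform distortions: shared per-(platform, gene)
    multiplicative factor exp(N(0, tau^2)), then a per-platform power-law
    ``value -> value**gamma_p``.  tau = 0 with gamma = 1 is the identity.

    Pre-drawn ``factors``/``exponents`` (e.g. from a SimTruth) may be passed
    to reuse one platform model across compendium and mixtures.
    """
    if tau < 0 or gamma <= 0:
        raise ValueError("tau >= 0 and gamma > 0 required")
    assignments = pd.Series(assignments, index=m.sample_ids) if not isinstance(
        assignments, pd.Series
    ) else assignments.reindex(m.sample_ids)
    if assignments.isna().any():
        raise ValueError("platform assignment missing for some samples")
    platforms = sorted(assignments.unique())
    rng = np.random.default_rng(seed)
    if factors is None or exponents is None:
        f = np.exp(rng.normal(0.0, tau, size=(len(platforms), m.n_genes)))
        factors = pd.DataFrame(f, index=platforms, columns=m.expr.index)
        log_g = np.log(gamma)
        exponents = pd.Series(
            np.exp(rng.uniform(-log_g, log_g, size=len(platforms))), index=platforms
        )
    unknown = set(assignments.unique()) - set(factors.index)
    if unknown:
        raise ValueError(f"unknown platform labels: {sorted(unknown)}")
    out = m.values.copy()
    fac = factors[m.expr.index].to_numpy() if list(factors.columns) != m.gene_ids else factors.to_numpy()
    pos = {p: i for i, p in enumerate(factors.index)}
    for j, sid in enumerate(m.sample_ids):
        p = assignments.loc[sid]
        out[:, j] = (out[:, j] * fac[pos[p]]) ** exponents.loc[p]
    expr = pd.DataFrame(out, index=m.expr.index, columns=m.expr.columns)
    ann = m.annotations.copy()
    if len(ann) == 0:
        ann = pd.DataFrame(index=pd.Index(m.sample_ids, name="sample_id"))
    ann["platform"] = assignments.reindex(ann.index)
    return ExpressionMatrix(expr, ann)


def apply_disease_effect(
    m: ExpressionMatrix,
    disease,
    f: float,
    scale: float,
    seed: int = 0,
    genes: Sequence | None = None,
    factors: pd.Series | None = None,
    per_sample: bool = False,
) -> ExpressionMatrix:
    """Scale a shared random fraction ``f`` of genes in diseased samples only.

    The disease-responsive gene set (fraction ``f`` of genes) is shared
    across the scenario (drawn once from ``seed`` unless given).  Factor
    model:

    - ``per_sample=False`` (single shared program): one factor
      exp(N(0, scale^2)) per gene, shared by every diseased sample;
    - ``per_sample=True`` (heterogeneous diseases): factors drawn
      independently per (gene, diseased sample), modelling a cohort in which
      each sample carries its own disease program over the same responsive
      gene set.

    Healthy columns are returned bit-identical.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must lie in [0, 1]")
    disease = pd.Series(disease, index=m.sample_ids) if not isinstance(disease, pd.Series) \
        else disease.reindex(m.sample_ids).fillna(False)
    rng = np.random.default_rng(seed)
    if genes is None:
        n_pert = int(round(f * m.n_genes))
        idx = np.sort(rng.choice(m.n_genes, size=n_pert, replace=False))
        genes = [m.gene_ids[i] for i in idx]
    genes = [g for g in genes if g in m.expr.index]
    out = m.expr.copy()
    if genes:
        mask = disease.to_numpy(dtype=bool)
        block = out.loc[genes].to_numpy()
        if per_sample:
            fac = np.exp(rng.normal(0.0, scale, size=(len(genes), int(mask.sum()))))
            block[:, mask] = block[:, mask] * fac
        else:
            if factors is None:
                factors = pd.Series(
                    np.exp(rng.normal(0.0, scale, size=len(genes))), index=genes
                )
            fac = factors.reindex(genes).to_numpy()
            block[:, mask] = block[:, mask] * fac[:, None]
        out.loc[genes] = block
    return ExpressionMatrix(out, m.annotations.copy())


def simulate_mixtures(
    truth: SimTruth,
    n: int,
    alpha: float | Sequence[float] | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    prefix: str = "mix",
) -> tuple[ExpressionMatrix, SimTruth]:
    """Dirichlet-weighted mixtures of the true cell-type profiles.

    Each mixture draws p ~ Dirichlet(alpha) and sets expression to
    (mean profiles) @ p plus truncated Gaussian noise.  Returns the mixture
    matrix (annotated tissue_source = blood, disease_state = healthy) and a
    truth copy carrying the true proportions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = truth.config
    cell_types = list(truth.mean_profiles.columns)
    if alpha is None:
        alpha = cfg.dirichlet_alpha
    alpha = np.asarray(
        [alpha] * len(cell_types) if np.isscalar(alpha) else list(alpha), dtype=float
    )
    if alpha.size != len(cell_types):
        raise ValueError(
            f"alpha dimension {alpha.size} != number of cell types {len(cell_types)}"
        )
    if noise_sd is None:
        noise_sd = cfg.noise_sd
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(alpha, size=n)
    profiles = truth.mean_profiles.to_numpy()
    expr = profiles @ p.T
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expr = np.clip(expr, 0.0, None)
    ids = [f"{prefix}_{i:04d}" for i in range(n)]
    ann = pd.DataFrame(
        {"tissue_source": "blood", "disease_state": "healthy"},
        index=pd.Index(ids, name="sample_id"),
    )
    m = ExpressionMatrix(
        pd.DataFrame(expr, index=truth.mean_profiles.index, columns=ids), ann
    )
    props = pd.DataFrame(p, index=ids, columns=cell_types)
    updated = dataclasses.replace(truth, mixture_proportions=props)
    return m, updated


def simulate_out_of_basis_samples(
    cfg: SimConfig,
    truth: SimTruth,
    n: int,
    seed: int = 0,
    prefix: str = "tissue",
) -> ExpressionMatrix:
    """Samples from cell types disjoint from the basis ground truth.

    Out-of-basis profiles are drawn from an independent log-normal base (not
    the compendium's shared base), emulating solid-tissue biopsies whose
    constituent cells are absent from a blood basis matrix.  Annotated with
    tissue_source = tissue.
    """
    if cfg.n_out_of_basis_types < 1:
        raise ValueError("no out-of-basis cell types configured")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(truth.mean_profiles.index)
    types = [f"{prefix}_type_{k}" for k in range(cfg.n_out_of_basis_types)]
    profiles = {
        t: np.exp(rng.normal(cfg.base_loc, cfg.base_scale, size=len(genes))) for t in types
    }
    ids, cols, ann_rows = [], [], []
    for i in range(n):
        t = types[i % len(types)]
        noise = rng.normal(0.0, cfg.noise_sd, size=len(genes)) if cfg.noise_sd > 0 else 0.0
        cols.append(np.clip(profiles[t] + noise, 0.0, None))
        ids.append(f"{prefix}_{i:04d}")
        ann_rows.append({"cell_type": t, "tissue_source": "tissue", "disease_state": "healthy"})
    expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
    ann = pd.DataFrame(ann_rows, index=pd.Index(ids, name="sample_id"))
    return ExpressionMatrix(expr, ann)


# -- named scenarios ----------------------------------------------------------

def marker_recovery_config(seed: int = 0, n_genes: int = 1500) -> SimConfig:
    """Low-noise planted-marker scenario: fold-change 4, 10 samples per cell
    type, mild single-exponent platform effect, no disease program."""
    return SimConfig(
        n_genes=n_genes,
        n_samples_per_type=10,
        marker_fold_change=4.0,
        platform_tau=0.2,
        platform_gamma=1.0,
        disease_fraction=0.0,
        disease_gene_fraction=0.0,
        seed=seed,
    )


def recovery_benchmark_truth(seed: int = 0, n_genes: int = 317) -> SimTruth:
    """Clean 20-cell-type truth (317-gene default) for solver recovery
    benchmarks: every gene informative, no platform or disease effects."""
    cfg = SimConfig(
        n_genes=n_genes,
        n_markers_per_type=5,
        n_lineage_markers=5,
        noise_sd=0.0,
        platform_tau=0.0,
        platform_gamma=1.0,
        disease_fraction=0.0,
        disease_gene_fraction=0.0,
        n_samples_per_type=1,
        seed=seed,
    )
    _, truth = simulate_sorted_compendium(cfg)
    return truth


def truth_basis(truth: SimTruth, basis_id: str = "truth") -> "BasisMatrix":
    """BasisMatrix holding the true mean profiles (oracle reference)."""
    from .basis import BasisMatrix

    cfg = truth.config
    return BasisMatrix(
        values=truth.mean_profiles.copy(),
        lineage_of=dict(cfg.hierarchy),
        stage_of={},
        basis_id=basis_id,
    )
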