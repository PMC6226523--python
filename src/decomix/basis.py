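"""Hierarchical basis-matrix construction from sorted-cell compendia.

A basis (signature) matrix holds the mean expression of a small set of
cell-type-discriminative genes for each cell type.  Construction is a
two-stage hierarchical search over an annotated sorted-cell compendium:

1. within each lineage, genes are scored per cell type by a one-vs-rest
   Hedges' g effect size; a min-delta statistic (the smallest margin of the
   target's effect over any competitor cell type in the lineage) ranks genes
   by how cleanly they separate the target from its closest relative; a
   stepwise AUROC search picks the smallest prefix of the ranking that
   classifies the target near-optimally (within epsilon of the maximum,
   at least ``min_genes`` genes);
2. the stage-1 genes are removed from the candidate pool and the same
   ranking-plus-stepwise search is repeated at the lineage level to select
   genes that separate lineages from one another.

The basis values are per-cell-type means of the union gene set computed from
the quantile-normalized compendium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io_norm import ExpressionMatrix, quantile_normalize

#: sentinel effect size for zero pooled variance with unequal means
EFFECT_CAP = 1e6
#: minimum samples per group (cases and controls) for effect-size computation
DEFAULT_MIN_SAMPLES = 3

CELL_TYPE_STAGE = "cell_type_stage"
LINEAGE_STAGE = "lineage_stage"
#: pseudo-lineage label grouping all lineages for the lineage-level comparison
GLOBAL_LINEAGE = "__all__"


def hedges_g(case, control) -> float:
    """Hedges' g standardized mean difference with small-sample correction.

    g = J * (mean(case) - mean(control)) / s_pooled with the Hedges-Olkin
    correction J = 1 - 3 / (4(n1+n2) - 9).  When the pooled SD is zero the
    result is 0 for equal means and +/-EFFECT_CAP otherwise, so perfect
    separators outrank every finite effect without non-finite arithmetic.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 observations per group, got {n1} and {n2}")
    diff = case.mean() - control.mean()
    pooled_var = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0
        return float(np.sign(diff) * EFFECT_CAP)
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(correction * diff / np.sqrt(pooled_var))


def _hedges_g_rows(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized row-wise Hedges' g (rows = genes, columns = samples)."""
    n1, n2 = case.shape[1], control.shape[1]
    diff = case.mean(axis=1) - control.mean(axis=1)
    pooled_var = (
        (n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * control.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = correction * diff / np.sqrt(pooled_var)
    zero_var = pooled_var == 0.0
    g[zero_var] = np.sign(diff[zero_var]) * EFFECT_CAP
    return g


@dataclass
class EffectSizeTable:
    """Per (gene, target, lineage) one-vs-rest effects and min-delta margins.

    ``table`` columns: gene, target, lineage, effect, n_case, n_control and,
    after :func:`delta_effects`, delta.  ``level`` records whether targets are
    cell types or lineages.
    """

    table: pd.DataFrame
    level: str = "cell_type"

    def effects_wide(self, lineage) -> pd.DataFrame:
        """Genes x targets effect matrix for one lineage."""
        sub = self.table[self.table["lineage"] == lineage]
        return sub.pivot(index="gene", columns="target", values="effect")


def one_vs_rest_effects(
    m: ExpressionMatrix,
    level: str = "cell_type",
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> EffectSizeTable:
    """One-vs-rest Hedges' g for every gene and group at the requested level.

    At level ``"cell_type"`` each cell type (cases) is compared against all
    remaining cells *within its lineage* (controls); at level ``"lineage"``
    each lineage is compared against all other samples.  Groups with fewer
    than ``min_samples`` cases or controls are excluded with a warning.
    """
    if level not in ("cell_type", "lineage"):
        raise ValueError(f"level must be cell_type or lineage, got {level!r}")
    labels = m.annotation(level)
    if labels.isna().all():
        raise ValueError(f"no {level} annotations present")
    x = m.values
    genes = m.expr.index
    rows = []
    if level == "cell_type":
        lineages = m.annotation("lineage")
        if lineages.isna().all():
            raise ValueError("cell_type-level effects require lineage annotations")
        pool_iter = [
            (lin, np.asarray(lineages.values == lin)) for lin in pd.unique(lineages.dropna())
        ]
    else:
        pool_iter = [(GLOBAL_LINEAGE, np.ones(m.n_samples, dtype=bool))]
    for pool_label, pool_mask in pool_iter:
        pool_labels = labels.values[pool_mask]
        pool_x = x[:, pool_mask]
        for target in pd.unique(pd.Series(pool_labels).dropna()):
            case_mask = pool_labels == target
            n_case = int(case_mask.sum())
            n_control = int((~case_mask).sum())
            if n_case < min_samples or n_control < min_samples:
                warnings.warn(
                    f"group {target!r} in {pool_label!r} excluded: "
                    f"{n_case} cases / {n_control} controls < min_samples={min_samples}"
                )
                continue
            g = _hedges_g_rows(pool_x[:, case_mask], pool_x[:, ~case_mask])
            rows.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "target": target,
                        "lineage": pool_label,
                        "effect": g,
                        "n_case": n_case,
                        "n_control": n_control,
                    }
                )
            )
    if not rows:
        raise ValueError("no eligible group meets the min_samples requirement")
    return EffectSizeTable(pd.concat(rows, ignore_index=True), level=level)


def delta_effects(t: EffectSizeTable) -> EffectSizeTable:
    """Min-delta separation: delta_gi = min over competitors j of (E_gi - E_gj).

    Competitors are the other targets within the same lineage pool.  Since the
    minimum over j of (E_i - E_j) equals E_i minus the largest competitor
    effect, a high delta marks genes whose effect in the target exceeds even
    its closest relative's.  Lineages with a single target are skipped with a
    warning (delta undefined).
    """
    parts = []
    for lineage, sub in t.table.groupby("lineage", sort=False):
        wide = sub.pivot(index="gene", columns="target", values="effect")
        targets = list(wide.columns)
        if len(targets) < 2:
            warnings.warn(f"lineage {lineage!r} has a single target; delta undefined, skipped")
            continue
        e = wide.to_numpy()
        order = np.argsort(e, axis=1)
        best = e[np.arange(e.shape[0]), order[:, -1]]
        second = e[np.arange(e.shape[0]), order[:, -2]]
        # competitor max: overall max unless the target IS the max, then runner-up
        comp_max = np.where(e == best[:, None], second[:, None], best[:, None])
        delta = pd.DataFrame(e - comp_max, index=wide.index, columns=wide.columns)
        sub = sub.copy()
        sub["delta"] = [
            delta.at[g, tgt] for g, tgt in zip(sub["gene"], sub["target"])
        ]
        parts.append(sub)
    if not parts:
        raise ValueError("no lineage with >=2 targets; delta undefined everywhere")
    return EffectSizeTable(pd.concat(parts, ignore_index=True), level=t.level)


def auroc(scores, labels) -> float:
    """AUROC = Mann-Whitney U / (n_pos * n_neg) with ties counting 1/2."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def _auroc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUROC via the rank-sum identity (average ranks give ties 1/2)."""
    from scipy.stats import rankdata

    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores, axis=1)
    u = ranks[:, labels].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass
class SignatureSet:
    """Result of the stepwise AUROC search for one target."""

    target: str
    level: str
    ranked_genes: list
    auroc_trajectory: list
    chosen_k: int
    flagged: bool = False

    @property
    def genes(self) -> list:
        return self.ranked_genes[: self.chosen_k]


def choose_prefix_length(
    trajectory: Sequence[float], epsilon: float = 0.005, min_genes: int = 5
) -> int:
    """Smallest prefix length whose AUROC is within epsilon of the maximum,
    raised to at least ``min_genes`` (capped at the trajectory length)."""
    traj = np.asarray(trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty AUROC trajectory")
    k = int(np.argmax(traj >= traj.max() - epsilon)) + 1
    return min(max(k, min_genes), traj.size)


def _prefix_scores(x: np.ndarray) -> np.ndarray:
    """Per-sample prefix scores: running mean of per-gene z-scores.

    Genes (rows) are standardized over the comparison population; a sample's
    score for prefix length k is the mean of its first k z-scores.  Constant
    genes contribute 0.  Reduces to a single-gene score at k = 1.
    """
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    k = np.arange(1, x.shape[0] + 1)[:, None]
    return np.cumsum(z, axis=0) / k


def stepwise_select(
    m: ExpressionMatrix,
    target: str,
    ranked: Sequence,
    epsilon: float = 0.005,
    min_genes: int = 5,
    max_genes: int = 50,
    level: str = "cell_type",
    within: Sequence | None = None,
) -> SignatureSet:
    """Stepwise AUROC search over an effect-ranked gene list.

    Genes are added one at a time in ranked order; after each addition the
    AUROC of classifying ``target`` against the rest of the comparison
    population (``within`` sample ids, default all samples) is recomputed
    from the prefix score (mean of per-gene z-scores).  The selected prefix
    is the smallest one within ``epsilon`` of the maximum AUROC, with at
    least ``min_genes`` genes.  Fewer than ``min_genes`` candidates selects
    all of them and flags the signature.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked gene list is empty")
    sub = m if within is None else m.subset_samples(list(within))
    labels = (sub.annotation(level) == target).to_numpy()
    if not labels.any():
        raise ValueError(f"target {target!r} absent from {level} annotations")
    if labels.all():
        raise ValueError(f"target {target!r} covers the whole comparison population")
    flagged = len(ranked) < min_genes
    if flagged:
        warnings.warn(
            f"only {len(ranked)} candidate genes for {target!r} (< min_genes={min_genes}); "
            "selecting all"
        )
    ranked_capped = ranked[: min(max_genes, len(ranked))]
    x = sub.expr.loc[ranked_capped].to_numpy(dtype=float)
    scores = _prefix_scores(x)
    trajectory = _auroc_rows(scores, labels).tolist()
    chosen_k = choose_prefix_length(trajectory, epsilon=epsilon, min_genes=min_genes)
    return SignatureSet(
        target=target,
        level=level,
        ranked_genes=ranked_capped,
        auroc_trajectory=trajectory,
        chosen_k=chosen_k,
        flagged=flagged,
    )


@dataclass
class BasisMatrix:
    """Signature genes x cell types mean-expression reference.

    ``values``: DataFrame indexed by gene id with one column per cell type
    (non-negative, same units as the compendium).  ``lineage_of`` maps each
    cell type to its lineage; ``stage_of`` records per gene whether it was
    selected at the cell-type or the lineage stage; ``signatures`` keeps the
    per-target stepwise-search provenance when available.
    """

    values: pd.DataFrame
    lineage_of: Mapping[str, str]
    stage_of: Mapping[str, str] = field(default_factory=dict)
    signatures: Mapping[str, SignatureSet] = field(default_factory=dict)
    basis_id: str = "basis"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate genes in basis matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("basis values must be non-negative")
        missing = set(self.values.columns) - set(self.lineage_of)
        if missing:
            raise ValueError(f"cell types without a lineage: {sorted(missing)}")
        ct_genes = {g for g, s in self.stage_of.items() if s == CELL_TYPE_STAGE}
        lin_genes = {g for g, s in self.stage_of.items() if s == LINEAGE_STAGE}
        if ct_genes & lin_genes:
            raise ValueError("cell_type-stage and lineage-stage gene sets must be disjoint")

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def cell_types(self) -> list:
        return self.values.columns.tolist()

    def write_tsv(self, path) -> None:
        """Write the matrix (col 1 = gene id, one column per cell type) plus a
        ``<stem>.meta.tsv`` sidecar with lineage map and stage provenance."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        meta = pd.DataFrame(
            {
                "kind": (["lineage"] * len(self.lineage_of)) + (["stage"] * len(self.stage_of)),
                "key": list(self.lineage_of) + list(self.stage_of),
                "value": list(self.lineage_of.values()) + list(self.stage_of.values()),
            }
        )
        meta.to_csv(path.with_name(path.stem + ".meta.tsv"), sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, basis_id: str | None = None) -> "BasisMatrix":
        """Read a basis matrix TSV (published-matrix dialect: gene id column
        plus one column per cell type).  The meta sidecar is optional; without
        it every cell type is assigned its own singleton lineage."""
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        lineage_of: dict = {}
        stage_of: dict = {}
        meta_path = path.with_name(path.stem + ".meta.tsv")
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t", dtype=str)
            lineage_of = dict(meta.loc[meta["kind"] == "lineage", ["key", "value"]].values)
            stage_of = dict(meta.loc[meta["kind"] == "stage", ["key", "value"]].values)
        if not lineage_of:
            lineage_of = {ct: ct for ct in values.columns}
        return cls(values, lineage_of, stage_of, basis_id=basis_id or path.stem)


def _celltype_means(m: ExpressionMatrix, genes: Sequence, cell_types: Sequence) -> pd.DataFrame:
    ct = m.annotation("cell_type")
    cols = {}
    for cell_type in cell_types:
        mask = (ct == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"cell type {cell_type!r} has no samples")
        cols[cell_type] = m.expr.loc[list(genes)].to_numpy()[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def _ranked_genes(sub: pd.DataFrame) -> list:
    """Delta-descending ranking with lexicographic gene-id tie break."""
    s = sub.sort_values(["delta", "gene"], ascending=[False, True], kind="mergesort")
    return s["gene"].tolist()


def build_basis(
    m: ExpressionMatrix,
    hierarchy: Mapping[str, str],
    epsilon: float = 0.005,
    min_genes: int = 5,
    max_genes: int = 50,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    basis_id: str = "basis",
) -> BasisMatrix:
    """Two-stage hierarchical basis construction from a sorted-cell compendium.

    Stage 1 selects, for every cell type within each multi-member lineage, the
    min-delta-ranked stepwise signature separating it from the rest of its
    lineage.  Stage 2 removes all stage-1 genes from the candidate pool and
    repeats the search at the lineage level.  The basis values are the
    per-cell-type means of the union gene set computed from the
    quantile-normalized compendium.
    """
    ct = m.annotation("cell_type")
    observed_types = set(ct.dropna().unique())
    uncovered = observed_types - set(hierarchy)
    if uncovered:
        raise ValueError(f"hierarchy does not cover cell types: {sorted(uncovered)}")
    mq = quantile_normalize(m)
    if "lineage" not in mq.annotations.columns:
        ann = mq.annotations.copy()
        ann["lineage"] = ct.reindex(ann.index).map(hierarchy)
        mq = ExpressionMatrix(mq.expr, ann)
    lineage = mq.annotation("lineage")

    signatures: dict = {}
    stage_of: dict = {}

    # stage 1: cell types within each lineage
    effects = one_vs_rest_effects(mq, level="cell_type", min_samples=min_samples)
    effects = delta_effects(effects)
    for lin, sub in effects.table.groupby("lineage", sort=False):
        member_samples = lineage.index[lineage == lin].tolist()
        for target in sorted(sub["target"].unique()):
            ranked = _ranked_genes(sub[sub["target"] == target])
            sig = stepwise_select(
                mq, target, ranked, epsilon=epsilon, min_genes=min_genes,
                max_genes=max_genes, level="cell_type", within=member_samples,
            )
            signatures[target] = sig
            for g in sig.genes:
                stage_of.setdefault(g, CELL_TYPE_STAGE)

    stage1_genes = set(stage_of)

    # stage 2: lineages against one another, stage-1 genes excluded
    n_lineages = lineage.dropna().nunique()
    if n_lineages < 2:
        warnings.warn("single lineage in compendium; lineage stage skipped")
    else:
        lin_effects = delta_effects(
            one_vs_rest_effects(mq, level="lineage", min_samples=min_samples)
        )
        table2 = lin_effects.table[~lin_effects.table["gene"].isin(stage1_genes)]
        for target in sorted(table2["target"].unique()):
            ranked = _ranked_genes(table2[table2["target"] == target])
            sig = stepwise_select(
                mq, target, ranked, epsilon=epsilon, min_genes=min_genes,
                max_genes=max_genes, level="lineage", within=None,
            )
            signatures[f"lineage:{target}"] = sig
            for g in sig.genes:
                if g not in stage_of:
                    stage_of[g] = LINEAGE_STAGE

    union_genes = sorted(stage_of)
    if not union_genes:
        raise ValueError("no signature genes selected")
    cell_types = sorted(observed_types)
    values = _celltype_means(mq, union_genes, cell_types)
    return BasisMatrix(
        values=values,
        lineage_of={c: hierarchy[c] for c in cell_types},
        stage_of=stage_of,
        signatures=signatures,
        basis_id=basis_id,
    )


def basis_from_gene_list(
    m: ExpressionMatrix,
    genes: Sequence,
    cell_types: Sequence | None = None,
    hierarchy: Mapping[str, str] | None = None,
    basis_id: str = "basis_from_gene_list",
) -> BasisMatrix:
    """Basis matrix from a fixed gene list: per-cell-type means from the
    quantile-normalized compendium, with unspecified stage provenance.

    This is the published-gene-set control: it re-estimates expression values
    for an externally chosen gene list from a different compendium.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in m.expr.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    mq = quantile_normalize(m)
    ct = mq.annotation("cell_type")
    if cell_types is None:
        cell_types = sorted(ct.dropna().unique())
    values = _celltype_means(mq, genes, cell_types)
    if hierarchy is None:
        hierarchy = {c: c for c in cell_types}
    return BasisMatrix(
        values=values,
        lineage_of={c: hierarchy.get(c, c) for c in cell_types},
        stage_of={},
        signatures={},
        basis_id=basis_id,
    )
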