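"""Expression-matrix I/O, probe collapsing, quantile normalization, and merging.

The central container is :class:`ExpressionMatrix`: a genes x samples matrix of
non-negative, linear-scale expression values with a per-sample annotation table
(cell type, lineage, platform, disease state, tissue source).  Multi-dataset
compendia are assembled by quantile-normalizing each dataset, intersecting gene
sets, concatenating samples, and quantile-normalizing the combined matrix so
that every sample shares one empirical distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_FIELDS = ("cell_type", "lineage", "platform", "disease_state", "tissue_source")
DISEASE_STATES = {"healthy", "disease"}
TISSUE_SOURCES = {"blood", "tissue"}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with optional per-sample annotations.

    Parameters
    ----------
    expr
        DataFrame indexed by gene id with one column per sample id.  Values
        must be finite and non-negative (linear scale).
    annotations
        DataFrame indexed by sample id whose columns are a subset of
        ``ANNOTATION_FIELDS``.  Every annotated sample must exist in ``expr``.
    """

    expr: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.expr.columns.has_duplicates:
            dups = self.expr.columns[self.expr.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.expr.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                raise ValueError("expression values must be finite")
            if (values < 0).any():
                raise ValueError("expression values must be non-negative")
        self.expr.index.name = "gene_id"
        self.expr.columns.name = None
        if self.annotations is None:
            self.annotations = pd.DataFrame()
        if len(self.annotations):
            self.annotations.index.name = "sample_id"
        if len(self.annotations):
            unknown = set(self.annotations.index) - set(self.expr.columns)
            if unknown:
                raise ValueError(f"annotated samples absent from matrix: {sorted(unknown)}")
            bad_cols = set(self.annotations.columns) - set(ANNOTATION_FIELDS)
            if bad_cols:
                raise ValueError(f"unknown annotation fields: {sorted(bad_cols)}")
            if "disease_state" in self.annotations:
                vals = set(self.annotations["disease_state"].dropna())
                if not vals <= DISEASE_STATES:
                    raise ValueError(f"disease_state must be in {DISEASE_STATES}, got {vals}")
            if "tissue_source" in self.annotations:
                vals = set(self.annotations["tissue_source"].dropna())
                if not vals <= TISSUE_SOURCES:
                    raise ValueError(f"tissue_source must be in {TISSUE_SOURCES}, got {vals}")
            # align annotation order with the sample order
            self.annotations = self.annotations.reindex(
                [s for s in self.expr.columns if s in self.annotations.index]
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return self.expr.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.expr.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.expr.to_numpy(dtype=float)

    def annotation(self, field_name: str) -> pd.Series:
        """Annotation column reindexed over all samples (NaN where missing)."""
        if field_name not in ANNOTATION_FIELDS:
            raise KeyError(field_name)
        if field_name in self.annotations.columns:
            return self.annotations[field_name].reindex(self.expr.columns)
        return pd.Series(np.nan, index=self.expr.columns, name=field_name)

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.expr.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        ann = self.annotations.loc[self.annotations.index.intersection(sample_ids)]
        return ExpressionMatrix(self.expr[list(sample_ids)].copy(), ann.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.expr.copy(), self.annotations.copy())


@dataclass
class ProbeMap:
    """Mapping from probe id to the set of gene ids it interrogates."""

    mapping: Mapping[str, frozenset]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "ProbeMap":
        out: dict = {}
        for probe, gene in pairs:
            out.setdefault(probe, set()).add(gene)
        return cls({p: frozenset(g) for p, g in out.items()})

    @classmethod
    def read_tsv(cls, path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"probe_id", "gene_id"} <= set(df.columns):
            raise ValueError("probe map requires columns probe_id, gene_id")
        return cls.from_pairs(zip(df["probe_id"], df["gene_id"]))

    @property
    def promiscuous(self) -> set:
        return {p for p, genes in self.mapping.items() if len(genes) > 1}


def _annotation_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".annotations.tsv")


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV (first column gene ids).

    An annotation sidecar ``<stem>.annotations.tsv`` (columns: sample_id plus
    any annotation fields) is loaded automatically when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path.name}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene_pos, col_pos = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[gene_pos, col_pos]!r} at gene "
            f"{df.index[gene_pos]!r}, sample {df.columns[col_pos]!r}"
        )
    ann = pd.DataFrame()
    sidecar = _annotation_sidecar_path(path)
    if sidecar.exists():
        ann = pd.read_csv(sidecar, sep="\t", index_col="sample_id", dtype=str)
    return ExpressionMatrix(numeric.astype(float), ann)


def write_expression(m: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write a matrix (and its annotation sidecar, if any) to TSV/CSV."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if format == "tsv" else ","
    m.expr.to_csv(path, sep=sep, index_label="gene_id")
    if len(m.annotations):
        m.annotations.to_csv(_annotation_sidecar_path(path), sep="\t", index_label="sample_id")


def collapse_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes by averaging same-gene probes.

    Probes mapping to more than one gene (promiscuous) and probes with no
    mapping are dropped; each gene row is the arithmetic mean (linear scale)
    of its retained probe rows.
    """
    promiscuous = pm.promiscuous
    gene_of: dict = {}
    n_unmapped = 0
    for probe in m.gene_ids:
        genes = pm.mapping.get(probe)
        if genes is None or not genes:
            n_unmapped += 1
            continue
        if probe in promiscuous:
            continue
        gene_of[probe] = next(iter(genes))
    n_promiscuous = sum(1 for p in m.gene_ids if p in promiscuous)
    if not gene_of:
        raise ValueError("no probes left after dropping promiscuous/unmapped probes")
    kept = m.expr.loc[list(gene_of)]
    collapsed = kept.groupby(pd.Index([gene_of[p] for p in kept.index], name="gene_id")).mean()
    logger.info(
        "collapse_probes: kept %d probes -> %d genes (dropped %d promiscuous, %d unmapped)",
        len(gene_of), collapsed.shape[0], n_promiscuous, n_unmapped,
    )
    return ExpressionMatrix(collapsed, m.annotations.copy())


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples to a shared empirical distribution.

    The reference distribution is the per-rank mean of the sorted columns.
    Ties within a column receive the mean of the reference values their rank
    span covers, so the operation is deterministic and idempotent.
    """
    if m.n_genes < 1:
        raise ValueError("matrix has no genes")
    if m.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return m.copy()
    x = m.values
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the reference values across tied entries
        uniq, inverse = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inverse, weights=assigned)
            counts = np.bincount(inverse)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    expr = pd.DataFrame(out, index=m.expr.index, columns=m.expr.columns)
    return ExpressionMatrix(expr, m.annotations.copy())


def merge_datasets(ms: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge datasets into one compendium on the shared gene set.

    Each input is quantile-normalized on its own, gene sets are intersected
    (order taken from the first input), samples are concatenated, and the
    combined matrix is quantile-normalized again so all samples share one
    distribution.  Annotations are concatenated (missing fields become NaN).
    """
    if len(ms) < 2:
        raise ValueError("merge_datasets requires at least 2 matrices")
    shared = set(ms[0].gene_ids)
    for m in ms[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise ValueError("empty gene intersection across datasets")
    genes = [g for g in ms[0].gene_ids if g in shared]
    all_samples = [s for m in ms for s in m.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample ids across datasets")
    normalized = [quantile_normalize(m) if m.n_samples > 1 else m for m in ms]
    expr = pd.concat([m.expr.loc[genes] for m in normalized], axis=1)
    ann_parts = [m.annotations for m in ms if len(m.annotations)]
    ann = pd.concat(ann_parts) if ann_parts else pd.DataFrame()
    return quantile_normalize(ExpressionMatrix(expr, ann))
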