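"""Deconvolution quality and bias metrics.

Covers the evaluation suite around the deconvolution core: permutation
significance of goodness of fit, platform-heterogeneity testing (MAD of
per-platform median goodness of fit with a permutation-calibrated Z-test),
Fisher's p-value combination, blood-vs-tissue discrimination AUROC, and
agreement with measured cell proportions (Pearson r and RMSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisMatrix, auroc
from .deconv import DeconvolutionResult, _SOLVERS, _gof, align_and_scale


def gof_significance(
    sample: pd.Series,
    basis: BasisMatrix,
    method: str,
    n_perm: int = 100,
    seed: int = 0,
    rescale: bool = True,
) -> float:
    """Permutation p-value for a sample's goodness of fit.

    The null re-solves the deconvolution after replacing the basis-gene slots
    with a uniformly drawn random gene subset (of the same size) from the
    full sample profile; p = (1 + #{null gof >= observed}) / (n_perm + 1).
    Reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in _SOLVERS:
        raise ValueError(f"unknown method {method!r}")
    s, m, n_used = align_and_scale(sample, basis, rescale=rescale)
    if len(sample) <= n_used:
        raise ValueError(
            f"sample universe ({len(sample)} genes) must exceed the basis gene "
            f"count ({n_used}) to draw permutation nulls"
        )
    solver = _SOLVERS[method]
    observed = _gof(s, m, solver(s, m))
    values = sample.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        draw = values[rng.choice(values.size, size=n_used, replace=False)]
        if rescale:
            sd = draw.std(ddof=1)
            if sd == 0:
                continue
            draw = (draw - draw.mean()) / sd
        try:
            null_gof = _gof(draw, m, solver(draw, m))
        except Exception:
            null_gof = -1.0  # failed null solve counts as no fit
        if null_gof >= observed:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


@dataclass
class HeterogeneityReport:
    """MAD-based platform-heterogeneity test result."""

    platform_medians: dict
    mad_observed: float
    null_mean: float
    null_sd: float
    z: float
    pvalue: float
    n_permutations: int
    seed: int
    variant: str = "platform_median"

    def to_dict(self) -> dict:
        return {
            "platform_medians": dict(self.platform_medians),
            "mad_observed": self.mad_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "pvalue": self.pvalue,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "variant": self.variant,
        }


def _results_to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = []
    for r in results:
        if not isinstance(r, DeconvolutionResult):
            raise TypeError(f"expected DeconvolutionResult rows, got {type(r)}")
        rows.append({"sample_id": r.sample_id, "method": r.method, "gof": r.gof})
    return pd.DataFrame(rows)


def _mad_of_medians(gof: np.ndarray, platform_codes: np.ndarray, n_platforms: int) -> float:
    meds = np.array(
        [np.median(gof[platform_codes == k]) for k in range(n_platforms)]
    )
    return float(np.median(np.abs(meds - np.median(meds))))


def _mad_per_sample(gof: np.ndarray, platform_codes: np.ndarray, n_platforms: int) -> float:
    # per-sample deviations from the platform-pooled mean goodness of fit
    return float(np.median(np.abs(gof - gof.mean())))


def mad_heterogeneity(
    results,
    platforms: Sequence | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    variant: str = "platform_median",
) -> HeterogeneityReport:
    """MAD heterogeneity of goodness of fit across platforms, with Z-test.

    The observed statistic (default variant) is the raw median absolute
    deviation of per-platform median goodness-of-fit values, pooling methods.
    The null distribution is built by permuting the sample-to-platform
    assignment (group sizes preserved; all method rows of a sample move
    together) and recomputing the statistic; the one-sided upper-tail Z-test
    asks whether the observed MAD exceeds the homogeneous expectation.

    ``results`` is a DataFrame with columns sample_id, gof and optionally
    platform (or a list of DeconvolutionResult with ``platforms`` supplied as
    a sample_id -> platform mapping / aligned sequence).
    """
    if variant not in ("platform_median", "per_sample"):
        raise ValueError(f"unknown variant {variant!r}")
    df = _results_to_frame(results).copy()
    if "platform" not in df.columns:
        if platforms is None:
            raise ValueError("platform annotation required")
        if isinstance(platforms, (dict, pd.Series)):
            df["platform"] = df["sample_id"].map(dict(platforms))
        else:
            df["platform"] = list(platforms)
    if df["platform"].isna().any():
        raise ValueError("missing platform annotation for some results")

    sample_platform = df.drop_duplicates("sample_id").set_index("sample_id")["platform"]
    platform_labels = sorted(sample_platform.unique())
    if len(platform_labels) < 2:
        raise ValueError("need >=2 platforms for a heterogeneity test")
    code_of = {p: k for k, p in enumerate(platform_labels)}
    n_platforms = len(platform_labels)

    gof = df["gof"].to_numpy(dtype=float)
    sample_ids = sample_platform.index.to_numpy()
    sample_codes = sample_platform.map(code_of).to_numpy()
    # row -> position of its sample, so permuting samples moves method rows together
    sample_pos = {sid: i for i, sid in enumerate(sample_ids)}
    row_sample = df["sample_id"].map(sample_pos).to_numpy()

    stat = _mad_of_medians if variant == "platform_median" else _mad_per_sample
    observed = stat(gof, sample_codes[row_sample], n_platforms)
    platform_medians = {
        p: float(np.median(gof[sample_codes[row_sample] == code_of[p]]))
        for p in platform_labels
    }

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(sample_codes)
        null[b] = stat(gof, perm[row_sample], n_platforms)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        warnings.warn("degenerate permutation null (sd = 0); pvalue set to 1")
        z, pvalue = 0.0, 1.0
    else:
        z = (observed - null_mean) / null_sd
        pvalue = float(stats.norm.sf(z))
        pvalue = max(pvalue, np.finfo(float).tiny)
    return HeterogeneityReport(
        platform_medians=platform_medians,
        mad_observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        pvalue=pvalue,
        n_permutations=n_perm,
        seed=seed,
        variant=variant,
    )


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's log-sum combination: chi2 = -2 sum ln p, df = 2k."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(chi2, df=2 * p.size))


def separation_auroc(pvalues: Sequence[float], labels: Sequence) -> float:
    """AUROC for distinguishing blood from tissue by fit significance.

    Scores are -log10(p); blood is the positive class.  ``labels`` may be
    booleans (True = blood) or the strings "blood"/"tissue".
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        is_blood = labels == "blood"
    else:
        is_blood = labels.astype(bool)
    p = np.asarray(list(pvalues), dtype=float)
    if (p <= 0).any():
        raise ValueError("p-values must be positive")
    return auroc(-np.log10(p), is_blood)


@dataclass
class AgreementReport:
    """Agreement between estimated and measured proportions (one dataset)."""

    pearson_r: float  # NaN when undefined (zero variance)
    rmse: float  # percentage-point units
    n_pairs: int
    r_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "n_pairs": self.n_pairs,
            "r_undefined": self.r_undefined,
        }


def proportion_agreement(
    estimated: pd.DataFrame,
    measured: pd.DataFrame,
    scale: str = "percent",
) -> AgreementReport:
    """Pooled Pearson r and RMSE between estimated and measured proportions.

    Both tables are samples x cell types on the same scale, declared by
    ``scale``: "fraction" (0-1; converted to percentage points for RMSE) or
    "percent" (0-100, used as is).  Pairs are pooled over all shared
    (sample, cell type) entries.
    """
    if scale not in ("fraction", "percent"):
        raise ValueError(f"scale must be fraction or percent, got {scale!r}")
    cell_types = [c for c in estimated.columns if c in measured.columns]
    if not cell_types:
        raise ValueError("no overlapping cell types")
    samples = [s for s in estimated.index if s in measured.index]
    if not samples:
        raise ValueError("no overlapping samples")
    est = estimated.loc[samples, cell_types].to_numpy(dtype=float).ravel()
    mea = measured.loc[samples, cell_types].to_numpy(dtype=float).ravel()
    if scale == "fraction":
        est, mea = est * 100.0, mea * 100.0
    rmse = float(np.sqrt(np.mean((mea - est) ** 2)))
    undefined = bool(est.std() == 0 or mea.std() == 0)
    if undefined:
        warnings.warn("zero-variance vector; Pearson r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(est, mea)[0])
    return AgreementReport(pearson_r=r, rmse=rmse, n_pairs=est.size, r_undefined=undefined)
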