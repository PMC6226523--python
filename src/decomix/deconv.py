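"""Mixture deconvolution: estimate cell-type proportions from bulk profiles.

Given a basis matrix M (signature genes x cell types) and a mixture
expression vector s, deconvolution solves s ~ M p for the proportion vector
p.  Four interchangeable solvers share one preprocessing contract
(dataset-level quantile normalization plus z-scoring, both optional):

- ``linear``: ordinary least squares, negatives clipped, renormalized;
- ``qp``: exact simplex-constrained least squares (p >= 0, sum p = 1) via an
  active-set solver;
- ``robust``: Huber M-estimation by iteratively reweighted least squares;
- ``svr``: linear-kernel nu-SVR over a nu grid, keeping the fit with the
  smallest reconstruction RMSE.

Goodness of fit is the Pearson correlation between the (scaled) mixture and
its reconstitution M p, computed in the space actually used for fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .basis import BasisMatrix
from .io_norm import ExpressionMatrix, quantile_normalize

METHODS = ("linear", "qp", "robust", "svr")

#: Huber tuning constant (95% efficiency at the normal model)
HUBER_C = 1.345
HUBER_MAX_ITER = 50
HUBER_TOL = 1e-6
SVR_NU_GRID = (0.25, 0.5, 0.75)
SVR_C = 1.0
SVR_TOL = 1e-4
QP_KKT_TOL = 1e-8


class SolverError(RuntimeError):
    pass


def align_and_scale(
    sample: pd.Series, basis: BasisMatrix, rescale: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """Restrict to shared genes and optionally z-score both objects.

    The sample vector is standardized by its own mean/SD over the shared
    genes; the basis matrix by its matrix-wide mean/SD, which preserves
    between-cell-type contrasts.  Quantile normalization of the mixture
    *dataset* is a dataset-level step and lives in :func:`deconvolve_dataset`.

    Returns ``(s, M, n_genes_used)`` with rows in basis gene order.
    """
    shared = [g for g in basis.gene_ids if g in sample.index]
    n_used = len(shared)
    if n_used < 2:
        raise ValueError(f"only {n_used} basis genes found in sample (need >=2)")
    s = sample.loc[shared].to_numpy(dtype=float)
    m = basis.values.loc[shared].to_numpy(dtype=float)
    if rescale:
        sd = s.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance sample vector over shared genes")
        s = (s - s.mean()) / sd
        m = (m - m.mean()) / m.std(ddof=1)
    return s, m, n_used


def _clip_renormalize(beta: np.ndarray, context: str) -> np.ndarray:
    p = np.clip(beta, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise SolverError(f"{context}: all coefficients <= 0")
    return p / total


def solve_linear(s: np.ndarray, m: np.ndarray) -> np.ndarray:
    """OLS coefficients, negatives clipped to zero, renormalized to sum 1."""
    beta, _, rank, _ = np.linalg.lstsq(m, s, rcond=None)
    if rank < m.shape[1]:
        corr = np.corrcoef(m.T)
        pairs = [
            (i, j)
            for i in range(m.shape[1])
            for j in range(i + 1, m.shape[1])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise SolverError(f"basis matrix is rank-deficient (collinear column pairs: {pairs})")
    if (beta <= 0).all():
        raise SolverError("linear solve: all coefficients <= 0")
    return _clip_renormalize(beta, "linear solve")


def solve_qp(s: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Exact argmin ||s - Mp||^2 subject to p >= 0 and sum(p) = 1.

    Active-set method on the KKT system of the equality-constrained problem:
    start with all coordinates free, solve with the sum constraint, clamp the
    most negative coordinate to zero, and repeat; then verify dual
    feasibility, releasing clamped coordinates with negative multipliers.
    Terminates finitely and is checked against the KKT conditions.
    """
    n = m.shape[1]
    q = m.T @ m
    c = m.T @ s
    active: set[int] = set()

    def solve_eq(active_set: frozenset) -> tuple[np.ndarray, float]:
        free = [i for i in range(n) if i not in active_set]
        k = len(free)
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2.0 * q[np.ix_(free, free)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.zeros(k + 1)
        rhs[:k] = 2.0 * c[free]
        rhs[k] = 1.0
        sol = np.linalg.solve(kkt, rhs)
        p = np.zeros(n)
        p[free] = sol[:k]
        return p, sol[k]

    for _ in range(4 * n * n + 10):
        try:
            p, lam = solve_eq(frozenset(active))
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"qp solve failed: singular KKT system ({exc})") from exc
        neg = [i for i in range(n) if i not in active and p[i] < -QP_KKT_TOL]
        if neg:
            active.add(min(neg, key=lambda i: p[i]))
            continue
        p = np.clip(p, 0.0, None)
        # dual feasibility: clamped coordinates need non-negative multipliers
        mu = 2.0 * (q @ p - c) + lam
        release = [i for i in active if mu[i] < -QP_KKT_TOL]
        if release:
            active.remove(min(release, key=lambda i: mu[i]))
            continue
        residual = float(np.linalg.norm(s - m @ p))
        grad_norm = float(np.abs(mu[[i for i in range(n) if i not in active]]).max(initial=0.0))
        if grad_norm > 1e-6 * max(1.0, float(np.abs(c).max())):
            raise SolverError(
                f"qp solve did not reach KKT tolerance (grad={grad_norm:.3g}, "
                f"residual={residual:.3g})"
            )
        return p / p.sum()
    raise SolverError("qp solve: active-set iteration limit exceeded")


def solve_robust(s: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Huber M-estimator via IRLS (c=1.345, MAD scale re-estimated per step).

    Iterates weighted least squares until the coefficient change falls below
    HUBER_TOL (max HUBER_MAX_ITER iterations); negatives clipped, renormalized.
    """
    beta, *_ = np.linalg.lstsq(m, s, rcond=None)
    for _ in range(HUBER_MAX_ITER):
        resid = s - m @ beta
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6744897501960817
        if scale == 0:
            return _clip_renormalize(beta, "robust solve")
        u = resid / scale
        w = np.where(np.abs(u) <= HUBER_C, 1.0, HUBER_C / np.abs(u))
        wm = m * w[:, None]
        beta_new = np.linalg.solve(wm.T @ m, wm.T @ s)
        if np.max(np.abs(beta_new - beta)) < HUBER_TOL:
            return _clip_renormalize(beta_new, "robust solve")
        beta = beta_new
    raise SolverError(
        f"robust solve: IRLS did not converge in {HUBER_MAX_ITER} iterations"
    )


def solve_svr(s: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Linear-kernel nu-SVR over nu in {0.25, 0.5, 0.75}.

    Each fit's reconstruction RMSE (||s - M beta - b|| / sqrt(n), raw
    coefficients plus the model's intercept) is evaluated; the best fit's
    coefficients are clipped and renormalized.
    """
    best = None
    for nu in SVR_NU_GRID:
        model = NuSVR(kernel="linear", nu=nu, C=SVR_C, tol=SVR_TOL)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(m, s)
        beta = model.coef_.ravel()
        rmse = float(np.sqrt(np.mean((s - (m @ beta + model.intercept_[0])) ** 2)))
        if np.clip(beta, 0.0, None).sum() <= 0:
            continue
        if best is None or rmse < best[0]:
            best = (rmse, beta)
    if best is None:
        raise SolverError("svr solve: all nu fits degenerate (no positive coefficients)")
    return _clip_renormalize(best[1], "svr solve")


_SOLVERS = {
    "linear": solve_linear,
    "qp": solve_qp,
    "robust": solve_robust,
    "svr": solve_svr,
}


@dataclass
class DeconvolutionResult:
    """Per-sample deconvolution outcome."""

    sample_id: str
    method: str
    basis_id: str
    proportions: pd.Series  # indexed by cell type, >= 0, sums to 1
    gof: float
    n_genes_used: int
    pvalue: float | None = None

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "method": self.method,
            "basis_id": self.basis_id,
            "gof": self.gof,
            "pvalue": self.pvalue,
            "n_genes_used": self.n_genes_used,
        }
        d.update(self.proportions.to_dict())
        return d


def _gof(s: np.ndarray, m: np.ndarray, p: np.ndarray) -> float:
    recon = m @ p
    if np.std(recon) == 0 or np.std(s) == 0:
        return 0.0
    return float(stats.pearsonr(s, recon)[0])


def deconvolve_sample(
    sample: pd.Series,
    basis: BasisMatrix,
    method: str,
    rescale: bool = True,
    with_pvalue: bool = False,
    n_perm: int = 100,
    seed: int = 0,
    sample_id: str | None = None,
) -> DeconvolutionResult:
    """Deconvolve one mixture profile with the requested solver.

    ``sample`` is a gene-indexed Series (the full profile; only basis genes
    are used for the solve, but the full profile feeds the permutation null
    when ``with_pvalue`` is set).
    """
    if method not in _SOLVERS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    sample_id = sample_id or (sample.name if sample.name is not None else "sample")
    try:
        s, m, n_used = align_and_scale(sample, basis, rescale=rescale)
        p = _SOLVERS[method](s, m)
    except (ValueError, SolverError) as exc:
        raise SolverError(f"sample {sample_id!r}: {exc}") from exc
    gof = _gof(s, m, p)
    pvalue = None
    if with_pvalue:
        from .evaluate import gof_significance

        pvalue = gof_significance(
            sample, basis, method, n_perm=n_perm, seed=seed, rescale=rescale
        )
    return DeconvolutionResult(
        sample_id=str(sample_id),
        method=method,
        basis_id=basis.basis_id,
        proportions=pd.Series(p, index=basis.cell_types),
        gof=gof,
        n_genes_used=n_used,
        pvalue=pvalue,
    )


@dataclass
class DatasetDeconvolution:
    """All per-(sample, method) results for one dataset, failures recorded."""

    results: list[DeconvolutionResult] = field(default_factory=list)
    failures: list[tuple[str, str, str]] = field(default_factory=list)  # (sample, method, error)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def proportions_frame(self, method: str) -> pd.DataFrame:
        """Samples x cell types proportion table for one method."""
        rows = {r.sample_id: r.proportions for r in self.results if r.method == method}
        return pd.DataFrame(rows).T


def deconvolve_dataset(
    m: ExpressionMatrix,
    basis: BasisMatrix,
    methods: Sequence[str],
    qn: bool = True,
    rescale: bool = True,
    with_pvalue: bool = False,
    n_perm: int = 100,
    seed: int = 0,
) -> DatasetDeconvolution:
    """Deconvolve every sample with every method.

    Dataset-level quantile normalization (``qn``) is applied once before the
    per-sample loop.  Per-sample solver failures are recorded, not fatal.
    """
    if not methods:
        raise ValueError("empty method list")
    for method in methods:
        if method not in _SOLVERS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    data = quantile_normalize(m) if (qn and m.n_samples > 1) else m
    out = DatasetDeconvolution()
    for k, sid in enumerate(data.sample_ids):
        profile = data.expr[sid]
        for method in methods:
            try:
                out.results.append(
                    deconvolve_sample(
                        profile, basis, method, rescale=rescale,
                        with_pvalue=with_pvalue, n_perm=n_perm,
                        seed=seed + k, sample_id=sid,
                    )
                )
            except SolverError as exc:
                out.failures.append((str(sid), method, str(exc)))
    return out
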