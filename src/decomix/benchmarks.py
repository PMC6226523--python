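"""Reproducible benchmark runs of the package's core guarantees.

Each function generates its own synthetic inputs from a seed, runs the
method under study, and returns measured quantities (errors, correlations,
rejection rates, recovery fractions).  They are the basis of the acceptance
checks and of ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .basis import build_basis
from .deconv import METHODS, deconvolve_dataset, deconvolve_sample
from .evaluate import gof_significance, mad_heterogeneity
from .io_norm import quantile_normalize
from .synthetic import (
    apply_platform_effect,
    marker_recovery_config,
    recovery_benchmark_truth,
    simulate_mixtures,
    simulate_sorted_compendium,
    truth_basis,
)


def _sub_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([seed, *salt]).generate_state(1)[0] % (2**31))


def recovery_benchmark(
    seed: int, n_mixtures: int = 50, noise_frac: float = 0.0, n_genes: int = 317
) -> dict:
    """Proportion recovery against the oracle basis (true mean profiles).

    Noiseless mixtures probe solver exactness; ``noise_frac`` adds additive
    Gaussian noise as a fraction of the mean basis signal.  linear/qp/robust
    solve in raw space (their native regime); svr in the standardized space
    its algorithm requires.  Returns per-method max abs error, pooled Pearson
    r, RMSE in percentage points, and the minimum goodness of fit.
    """
    truth = recovery_benchmark_truth(seed=_sub_seed(seed, 0), n_genes=n_genes)
    basis = truth_basis(truth)
    m = basis.values.to_numpy()
    noise_sd = noise_frac * m.mean()
    rng = np.random.default_rng(_sub_seed(seed, 1))
    k = m.shape[1]
    true_rows, est_rows = [], {meth: [] for meth in METHODS}
    min_gof = 1.0
    for _ in range(n_mixtures):
        p = rng.dirichlet(np.ones(k))
        true_rows.append(p)
        vals = m @ p
        if noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, noise_sd, m.shape[0]), 0.0, None)
        sample = pd.Series(vals, index=basis.gene_ids)
        for meth in METHODS:
            r = deconvolve_sample(sample, basis, meth, rescale=(meth == "svr"))
            est_rows[meth].append(r.proportions.to_numpy())
            min_gof = min(min_gof, r.gof)
    true = np.array(true_rows)
    out = {"min_gof": float(min_gof)}
    for meth in METHODS:
        est = np.array(est_rows[meth])
        out[meth] = {
            "max_abs_error": float(np.abs(est - true).max()),
            "pearson_r": float(stats.pearsonr(est.ravel(), true.ravel())[0]),
            "rmse_pp": float(np.sqrt(np.mean((100 * est - 100 * true) ** 2))),
        }
    return out


def marker_recovery_benchmark(seed: int, n_seeds: int = 20, n_genes: int = 1500) -> dict:
    """Planted-marker recovery by the two-stage basis build across seeds.

    For each seed: simulate the low-noise planted-marker compendium
    (fold-change 4, 10 samples per cell type), build the basis, and check
    that every cell type recovers >= 80% of its planted markers, every
    signature has >= 5 genes, and the stage gene sets are disjoint.
    """
    n_ok = 0
    recoveries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            cfg = marker_recovery_config(seed=_sub_seed(seed, i), n_genes=n_genes)
            compendium, truth = simulate_sorted_compendium(cfg)
            basis = build_basis(compendium, dict(cfg.hierarchy))
            selected = set(basis.gene_ids)
            per_type = [
                sum(g in selected for g in markers) / len(markers)
                for markers in truth.markers.values()
            ]
            recoveries.append(float(np.mean(per_type)))
            sizes_ok = all(len(s.genes) >= 5 for s in basis.signatures.values())
            stages = pd.Series(basis.stage_of)
            disjoint = not (
                set(stages[stages == "cell_type_stage"].index)
                & set(stages[stages == "lineage_stage"].index)
            )
            if min(per_type) >= 0.8 and sizes_ok and disjoint:
                n_ok += 1
    return {
        "fraction_seeds_ok": n_ok / n_seeds,
        "mean_marker_recovery": float(np.mean(recoveries)),
        "n_seeds": n_seeds,
    }


def _mad_rep_pvalue(truth, basis, rep_seed: int, tau: float,
                    n_platforms: int = 8, per_platform: int = 12,
                    n_perm: int = 300) -> float:
    noise_sd = 0.05 * basis.values.to_numpy().mean()
    n = n_platforms * per_platform
    mix, _ = simulate_mixtures(truth, n, noise_sd=noise_sd, seed=_sub_seed(rep_seed, 0))
    platforms = pd.Series(
        [f"platform_{i % n_platforms}" for i in range(n)], index=mix.sample_ids
    )
    if tau > 0:
        mix = apply_platform_effect(
            mix, platforms, tau=tau, gamma=1.0, seed=_sub_seed(rep_seed, 1)
        )
    run = deconvolve_dataset(mix, basis, ["linear"])
    df = run.to_frame()
    df["platform"] = df["sample_id"].map(platforms)
    report = mad_heterogeneity(
        df[["sample_id", "gof", "platform"]], n_perm=n_perm, seed=_sub_seed(rep_seed, 2)
    )
    return report.pvalue


def mad_calibration_benchmark(
    seed: int, n_null: int = 200, n_power: int = 50, tau: float = 0.5
) -> dict:
    """Size and power of the MAD heterogeneity Z-test at alpha = 0.05.

    Null: mixtures with no platform effect (rejection rate should sit near
    the nominal level).  Power: platform effect of log-SD ``tau`` injected.
    """
    truth = recovery_benchmark_truth(seed=_sub_seed(seed, 10), n_genes=300)
    basis = truth_basis(truth)
    null_p = [
        _mad_rep_pvalue(truth, basis, _sub_seed(seed, 11, i), tau=0.0)
        for i in range(n_null)
    ]
    power_p = [
        _mad_rep_pvalue(truth, basis, _sub_seed(seed, 12, i), tau=tau)
        for i in range(n_power)
    ]
    return {
        "null_rejection_rate": float(np.mean(np.asarray(null_p) < 0.05)),
        "power": float(np.mean(np.asarray(power_p) < 0.05)),
        "n_null": n_null,
        "n_power": n_power,
    }


def gof_calibration_benchmark(
    seed: int, n_samples: int = 100, n_perm: int = 99, n_universe: int = 1000
) -> dict:
    """Uniformity of permutation fit p-values on pure-noise samples (KS test)."""
    truth = recovery_benchmark_truth(seed=_sub_seed(seed, 20), n_genes=150)
    basis = truth_basis(truth)
    rng = np.random.default_rng(_sub_seed(seed, 21))
    ids = list(basis.gene_ids) + [
        f"bg{i}" for i in range(n_universe - len(basis.gene_ids))
    ]
    pvals = []
    for i in range(n_samples):
        sample = pd.Series(np.exp(rng.normal(5, 0.7, n_universe)), index=ids)
        pvals.append(
            gof_significance(
                sample, basis, "linear", n_perm=n_perm, seed=_sub_seed(seed, 22, i)
            )
        )
    ks = stats.kstest(pvals, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_samples": n_samples,
    }


def determinism_check(seed: int) -> dict:
    """Bit-reproducibility of simulators, selection, and permutation tests,
    plus quantile-normalization idempotence."""
    cfg = marker_recovery_config(seed=_sub_seed(seed, 30), n_genes=400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1, t1 = simulate_sorted_compendium(cfg)
        m2, t2 = simulate_sorted_compendium(cfg)
        sim_ok = m1.expr.equals(m2.expr) and t1.mean_profiles.equals(t2.mean_profiles)
        b1 = build_basis(m1, dict(cfg.hierarchy))
        b2 = build_basis(m2, dict(cfg.hierarchy))
        build_ok = b1.values.equals(b2.values) and b1.stage_of == b2.stage_of
        mix, t1 = simulate_mixtures(t1, 6, seed=_sub_seed(seed, 31))
        basis = b1  # built basis: a strict subset of the mixture gene universe
        p1 = gof_significance(
            quantile_normalize(mix).expr.iloc[:, 0], basis, "linear",
            n_perm=40, seed=_sub_seed(seed, 32),
        )
        p2 = gof_significance(
            quantile_normalize(mix).expr.iloc[:, 0], basis, "linear",
            n_perm=40, seed=_sub_seed(seed, 32),
        )
        # idempotence on a continuous (tie-free) matrix; tied values get the
        # mean of their reference span, which intentionally departs from
        # strict idempotence
        from .io_norm import ExpressionMatrix

        qn1 = quantile_normalize(ExpressionMatrix(t1.mean_profiles.copy()))
        qn2 = quantile_normalize(qn1)
        qn_drift = float(np.abs(qn2.values - qn1.values).max())
    return {
        "simulators_bit_reproducible": bool(sim_ok),
        "basis_build_deterministic": bool(build_ok),
        "permutation_test_deterministic": bool(p1 == p2),
        "qn_idempotence_max_drift": qn_drift,
    }
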