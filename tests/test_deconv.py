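"""Solver contracts, shared preprocessing, and dataset-level deconvolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

import decomix as dx
from decomix.deconv import SolverError, _gof

from conftest import make_matrix


def qp_oracle(s, m):
    """Simplex-constrained least squares via scipy SLSQP (independent route)."""
    n = m.shape[1]
    res = minimize(
        lambda p: np.sum((s - m @ p) ** 2),
        np.full(n, 1.0 / n),
        jac=lambda p: 2 * m.T @ (m @ p - s),
        method="SLSQP",
        bounds=[(0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1}],
        options={"maxiter": 300, "ftol": 1e-14},
    )
    return res.x


class TestAlignAndScale:
    def _basis(self):
        values = pd.DataFrame(
            {"X": [1.0, 2.0, 3.0, 4.0, 5.0], "Y": [5.0, 4.0, 3.0, 2.0, 1.0]},
            index=[f"g{i}" for i in range(5)],
        )
        return dx.BasisMatrix(values, {"X": "L", "Y": "L"})

    def test_shared_gene_count(self):
        sample = pd.Series([1.0, 2.0, 3.0], index=["g0", "g2", "g4"])
        _, _, n = dx.align_and_scale(sample, self._basis())
        assert n == 3

    def test_closed_form_zscore(self):
        sample = pd.Series([2.0, 4.0, 6.0, 8.0], index=["g0", "g1", "g2", "g3"])
        s, m, _ = dx.align_and_scale(sample, self._basis())
        x = np.array([2.0, 4.0, 6.0, 8.0])
        np.testing.assert_allclose(s, (x - x.mean()) / x.std(ddof=1), atol=1e-12)
        mm = self._basis().values.iloc[:4].to_numpy()
        np.testing.assert_allclose(m, (mm - mm.mean()) / mm.std(ddof=1), atol=1e-12)

    def test_rescaling_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        x = (x - x.mean()) / x.std(ddof=1)
        values = rng.uniform(1, 2, size=(6, 2))
        values = (values - values.mean()) / values.std(ddof=1)
        basis = dx.BasisMatrix(
            pd.DataFrame(values - values.min(), index=[f"g{i}" for i in range(6)],
                         columns=["X", "Y"]),
            {"X": "L", "Y": "L"},
        )
        # shifting a standardized matrix to non-negative then re-standardizing
        # recovers the same centered values
        sample = pd.Series(x, index=basis.gene_ids)
        s, m, _ = dx.align_and_scale(sample, basis)
        np.testing.assert_allclose(s, x, atol=1e-12)
        np.testing.assert_allclose(
            m, (values - values.mean()) / values.std(ddof=1), atol=1e-12
        )

    def test_too_few_shared_genes(self):
        with pytest.raises(ValueError, match="basis genes"):
            dx.align_and_scale(pd.Series([1.0], index=["g0"]), self._basis())

    def test_zero_variance_sample(self):
        sample = pd.Series(np.ones(5), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="zero-variance"):
            dx.align_and_scale(sample, self._basis())


class TestSolveLinear:
    def test_normal_equations_by_hand(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        s = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(dx.solve_linear(s, m), [1 / 3, 2 / 3], atol=1e-12)

    def test_negative_clipped_then_renormalized(self):
        np.testing.assert_allclose(
            dx.solve_linear(np.array([1.0, -1.0]), np.eye(2)), [1.0, 0.0], atol=1e-12
        )

    def test_exact_recovery_on_simplex(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 10, size=(40, 6))
        p = rng.dirichlet(np.ones(6))
        np.testing.assert_allclose(dx.solve_linear(m @ p, m), p, atol=1e-8)

    def test_rank_deficient_flags_collinearity(self):
        m = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(SolverError, match="rank-deficient"):
            dx.solve_linear(np.arange(5.0), m)

    def test_all_nonpositive_is_error(self):
        with pytest.raises(SolverError, match="<= 0"):
            dx.solve_linear(np.array([-1.0, -2.0]), np.eye(2))


class TestSolveQP:
    def test_interior_optimum(self):
        np.testing.assert_allclose(
            dx.solve_qp(np.array([0.3, 0.7]), np.eye(2)), [0.3, 0.7], atol=1e-10
        )

    def test_boundary_projection_by_hand(self):
        # minimizing (2-p1)^2 + (0-p2)^2 on the simplex hits the vertex [1, 0]
        np.testing.assert_allclose(
            dx.solve_qp(np.array([2.0, 0.0]), np.eye(2)), [1.0, 0.0], atol=1e-10
        )

    def test_exact_recovery_on_simplex(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 10, size=(60, 8))
        p = rng.dirichlet(np.ones(8))
        np.testing.assert_allclose(dx.solve_qp(m @ p, m), p, atol=1e-6)

    def test_matches_slsqp_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            m = rng.normal(size=(30, 5))
            s = rng.normal(size=30)
            ours = dx.solve_qp(s, m)
            ref = qp_oracle(s, m)
            assert np.sum((s - m @ ours) ** 2) <= np.sum((s - m @ ref) ** 2) + 1e-8
            np.testing.assert_allclose(ours, ref, atol=1e-4)


class TestSolveRobust:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0, 10, size=(50, 6))
        p = rng.dirichlet(np.ones(6))
        np.testing.assert_allclose(dx.solve_robust(m @ p, m), p, atol=1e-4)

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 10, size=(60, 5))
        p = rng.dirichlet(np.ones(5))
        s = m @ p
        s[10] += 10 * s.std()  # single gross outlier
        err_robust = np.abs(dx.solve_robust(s, m) - p).max()
        err_ols = np.abs(dx.solve_linear(s, m) - p).max()
        assert err_robust < err_ols

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        m = rng.uniform(0, 5, size=(80, 4))
        p = rng.dirichlet(np.ones(4))
        s = m @ p + rng.standard_t(3, size=80) * 0.3
        ours = dx.solve_robust(s, m)
        fit = sm.RLM(s, m, M=sm.robust.norms.HuberT(t=1.345)).fit()
        ref = np.clip(fit.params, 0, None)
        ref = ref / ref.sum()
        np.testing.assert_allclose(ours, ref, atol=5e-3)

    def test_simplex_contract(self):
        rng = np.random.default_rng(10)
        m = rng.uniform(0, 5, size=(40, 5))
        s = m @ rng.dirichlet(np.ones(5)) + rng.normal(0, 0.5, 40)
        out = dx.solve_robust(s, m)
        assert (out >= 0).all() and out.sum() == pytest.approx(1.0)


class TestSolveSVR:
    def test_recovery_correlation(self, benchmark_basis):
        rng = np.random.default_rng(11)
        values = benchmark_basis.values.to_numpy()
        m = (values - values.mean()) / values.std(ddof=1)
        p = rng.dirichlet(np.ones(m.shape[1]))
        s = m @ p
        s = (s - s.mean()) / s.std(ddof=1)
        out = dx.solve_svr(s, m)
        assert stats.pearsonr(out, p)[0] > 0.99

    def test_grid_choice_minimizes_rmse(self):
        from sklearn.svm import NuSVR

        rng = np.random.default_rng(12)
        m = rng.normal(size=(50, 4))
        s = m @ np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.3, 50)
        ours = dx.solve_svr(s, m)
        best = None
        for nu in (0.25, 0.5, 0.75):
            f = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-4).fit(m, s)
            beta = f.coef_.ravel()
            rmse = np.sqrt(np.mean((s - (m @ beta + f.intercept_[0])) ** 2))
            if np.clip(beta, 0, None).sum() <= 0:
                continue
            if best is None or rmse < best[0]:
                best = (rmse, beta)
        expected = np.clip(best[1], 0, None)
        np.testing.assert_allclose(ours, expected / expected.sum(), atol=1e-12)

    def test_simplex_contract(self):
        rng = np.random.default_rng(13)
        m = rng.normal(size=(40, 5))
        out = dx.solve_svr(m @ rng.dirichlet(np.ones(5)), m)
        assert (out >= 0).all() and out.sum() == pytest.approx(1.0)


class TestDeconvolveSample:
    def test_dispatch_consistency_with_direct_solver(self, benchmark_basis):
        rng = np.random.default_rng(14)
        p = rng.dirichlet(np.ones(len(benchmark_basis.cell_types)))
        sample = pd.Series(
            benchmark_basis.values.to_numpy() @ p, index=benchmark_basis.gene_ids
        )
        result = dx.deconvolve_sample(sample, benchmark_basis, "qp")
        s, m, _ = dx.align_and_scale(sample, benchmark_basis)
        np.testing.assert_allclose(
            result.proportions.to_numpy(), dx.solve_qp(s, m), atol=1e-12
        )
        assert result.n_genes_used == len(benchmark_basis.gene_ids)

    def test_noiseless_gof_near_one(self, benchmark_basis):
        # linear/qp/robust fit in raw space (their native regime), svr in the
        # standardized space its algorithm requires
        rng = np.random.default_rng(15)
        p = rng.dirichlet(np.ones(len(benchmark_basis.cell_types)))
        sample = pd.Series(
            benchmark_basis.values.to_numpy() @ p, index=benchmark_basis.gene_ids
        )
        for method in dx.METHODS:
            r = dx.deconvolve_sample(
                sample, benchmark_basis, method, rescale=(method == "svr")
            )
            assert r.gof >= 0.999

    def test_unknown_method_is_error(self, benchmark_basis):
        sample = pd.Series(np.ones(10), index=benchmark_basis.gene_ids[:10])
        with pytest.raises(ValueError, match="unknown method"):
            dx.deconvolve_sample(sample, benchmark_basis, "pert")

    def test_gof_invariant_to_affine_rescaling(self, benchmark_basis):
        rng = np.random.default_rng(16)
        p = rng.dirichlet(np.ones(len(benchmark_basis.cell_types)))
        m = benchmark_basis.values.to_numpy()
        s = m @ p + rng.normal(0, 5, m.shape[0])
        phat = dx.solve_qp(s, m)
        assert _gof(s, m, phat) == pytest.approx(_gof(3.5 * s + 11, m, phat), abs=1e-12)


class TestDeconvolveDataset:
    def _mixtures(self, basis, n=3, seed=0):
        rng = np.random.default_rng(seed)
        m = basis.values.to_numpy()
        cols = {
            f"mix{i}": m @ rng.dirichlet(np.ones(m.shape[1])) for i in range(n)
        }
        return dx.ExpressionMatrix(pd.DataFrame(cols, index=basis.gene_ids))

    def test_cardinality(self, benchmark_basis):
        run = dx.deconvolve_dataset(
            self._mixtures(benchmark_basis), benchmark_basis, ["linear", "qp"]
        )
        assert len(run.results) == 6 and not run.failures

    def test_empty_method_list_is_error(self, benchmark_basis):
        with pytest.raises(ValueError):
            dx.deconvolve_dataset(self._mixtures(benchmark_basis), benchmark_basis, [])

    def test_failure_isolation(self, benchmark_basis):
        mix = self._mixtures(benchmark_basis, n=3)
        expr = mix.expr.copy()
        expr["mix2"] = 1.0  # zero-variance sample fails align_and_scale
        run = dx.deconvolve_dataset(
            dx.ExpressionMatrix(expr), benchmark_basis, ["linear", "qp"], qn=False
        )
        assert len(run.results) == 4
        assert len(run.failures) == 2
        assert all(f[0] == "mix2" for f in run.failures)

    def test_cross_method_concordance_on_noisy_mixtures(self, separated_basis):
        # same matrix, different methods: estimates strongly correlated
        basis = separated_basis
        rng = np.random.default_rng(21)
        m = basis.values.to_numpy()
        noise = 0.05 * m.mean()
        cols = {
            f"mix{i}": np.clip(
                m @ rng.dirichlet(np.ones(m.shape[1])) + rng.normal(0, noise, m.shape[0]),
                0, None,
            )
            for i in range(12)
        }
        mix = dx.ExpressionMatrix(pd.DataFrame(cols, index=basis.gene_ids))
        run = dx.deconvolve_dataset(mix, basis, list(dx.METHODS))
        frames = {meth: run.proportions_frame(meth) for meth in dx.METHODS}
        rs = []
        methods = list(dx.METHODS)
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a = frames[methods[i]].to_numpy().ravel()
                b = frames[methods[j]].to_numpy().ravel()
                rs.append(stats.pearsonr(a, b)[0])
        assert np.median(rs) > 0.9

    def test_rescaling_changes_little_for_linear_and_robust(self, separated_basis):
        basis = separated_basis
        rng = np.random.default_rng(22)
        m = basis.values.to_numpy()
        noise = 0.05 * m.mean()
        cols = {
            f"mix{i}": np.clip(
                m @ rng.dirichlet(np.ones(m.shape[1])) + rng.normal(0, noise, m.shape[0]),
                0, None,
            )
            for i in range(10)
        }
        mix = dx.ExpressionMatrix(pd.DataFrame(cols, index=basis.gene_ids))
        for method in ("linear", "robust"):
            with_rs = dx.deconvolve_dataset(mix, basis, [method], rescale=True)
            without = dx.deconvolve_dataset(mix, basis, [method], rescale=False)
            a = with_rs.proportions_frame(method).to_numpy().ravel()
            b = without.proportions_frame(method).to_numpy().ravel()
            assert stats.pearsonr(a, b)[0] > 0.95
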