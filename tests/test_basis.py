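"""Effect sizes, min-delta ranking, AUROC, stepwise selection, basis assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import decomix as dx
from decomix.basis import (
    EFFECT_CAP,
    _auroc_rows,
    choose_prefix_length,
    delta_effects,
    one_vs_rest_effects,
)

from conftest import make_matrix


def hedges_oracle(case, control):
    """Independent closed-form computation for cross-checking."""
    case, control = np.asarray(case, float), np.asarray(control, float)
    n1, n2 = len(case), len(control)
    sp = np.sqrt(((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2))
    return (1 - 3 / (4 * (n1 + n2) - 9)) * (case.mean() - control.mean()) / sp


def auroc_oracle(scores, labels):
    """Pair enumeration: wins count 1, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestHedgesG:
    def test_equal_means_zero(self):
        assert dx.hedges_g([5, 5, 5], [5, 5, 5]) == 0.0

    def test_hand_computed_value(self):
        # means 4 vs 2, pooled SD 1, J = 1 - 3/15 = 0.8 -> 1.6
        assert dx.hedges_g([3, 4, 5], [1, 2, 3]) == pytest.approx(1.6, abs=1e-12)

    def test_zero_variance_sentinel(self):
        assert dx.hedges_g([2, 2], [0, 0]) == EFFECT_CAP
        assert dx.hedges_g([0, 0], [2, 2]) == -EFFECT_CAP

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            dx.hedges_g([1], [2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10), st.integers(2, 10),
           st.floats(-5, 5), st.floats(0.1, 4))
    def test_antisymmetry_and_affine_invariance(self, seed, n1, n2, shift, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n1), rng.normal(2, 1, size=n2)
        g = dx.hedges_g(a, b)
        assert dx.hedges_g(b, a) == pytest.approx(-g, rel=1e-10)
        assert dx.hedges_g(a + shift, b + shift) == pytest.approx(g, rel=1e-8, abs=1e-10)
        assert dx.hedges_g(a * scale, b * scale) == pytest.approx(g, rel=1e-8, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(1, 2, size=5)
        assert dx.hedges_g(a, b) == pytest.approx(hedges_oracle(a, b), rel=1e-12)


class TestOneVsRestEffects:
    def test_matches_per_gene_brute_force(self, toy_annotated):
        table = one_vs_rest_effects(toy_annotated, "cell_type").table
        ct = toy_annotated.annotation("cell_type")
        lin = toy_annotated.annotation("lineage")
        for _, row in table.sample(20, random_state=0).iterrows():
            pool = lin == row["lineage"]
            case = toy_annotated.expr.loc[row["gene"], pool & (ct == row["target"])]
            ctrl = toy_annotated.expr.loc[row["gene"], pool & (ct != row["target"])]
            assert row["effect"] == pytest.approx(hedges_oracle(case, ctrl), rel=1e-10)

    def test_lineage_level_controls_span_everything(self, toy_annotated):
        table = one_vs_rest_effects(toy_annotated, "lineage").table
        assert set(table["target"]) == {"L1", "L2"}
        row = table[(table["target"] == "L1") & (table["gene"] == "g0")].iloc[0]
        lin = toy_annotated.annotation("lineage")
        case = toy_annotated.expr.loc["g0", (lin == "L1").to_numpy()]
        ctrl = toy_annotated.expr.loc["g0", (lin != "L1").to_numpy()]
        assert row["effect"] == pytest.approx(hedges_oracle(case, ctrl), rel=1e-10)

    def test_exclusive_gene_has_positive_effect(self):
        vals = np.ones((2, 8))
        vals[0, :4] = 9.0  # gene g0 expressed only in cell type A
        vals += np.arange(8) * 1e-3  # break zero variance
        m = make_matrix(vals, ann={"cell_type": ["A"] * 4 + ["B"] * 4,
                                   "lineage": ["L"] * 8})
        table = one_vs_rest_effects(m, "cell_type").table
        assert table[(table.gene == "g0") & (table.target == "A")]["effect"].iloc[0] > 0

    def test_small_group_excluded_with_warning(self):
        m = make_matrix(np.ones((2, 5)) + np.arange(5) * 0.1,
                        ann={"cell_type": ["A"] * 3 + ["B"] * 2, "lineage": ["L"] * 5})
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError):
                one_vs_rest_effects(m, "cell_type")


class TestDeltaEffects:
    def _table(self, effects: dict) -> "dx.EffectSizeTable":
        rows = [
            {"gene": "g", "target": t, "lineage": "L", "effect": e,
             "n_case": 3, "n_control": 3}
            for t, e in effects.items()
        ]
        return dx.EffectSizeTable(pd.DataFrame(rows))

    def test_two_competitors_enumerated(self):
        out = delta_effects(self._table({"i": 2.0, "j1": 0.5, "j2": -1.0})).table
        d = dict(zip(out["target"], out["delta"]))
        assert d["i"] == pytest.approx(1.5)  # min(2-0.5, 2+1)
        assert d["j1"] == pytest.approx(-1.5)
        assert d["j2"] == pytest.approx(-3.0)

    def test_pairwise_lineage_is_symmetric_difference(self):
        out = delta_effects(self._table({"a": 1.0, "b": 0.25})).table
        d = dict(zip(out["target"], out["delta"]))
        assert d["a"] == pytest.approx(0.75) and d["b"] == pytest.approx(-0.75)

    def test_all_equal_gives_zero(self):
        out = delta_effects(self._table({"a": 1.0, "b": 1.0, "c": 1.0})).table
        assert np.allclose(out["delta"], 0.0)

    def test_singleton_lineage_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="single target"):
            with pytest.raises(ValueError):
                delta_effects(self._table({"only": 1.0}))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 5))
    def test_matches_double_loop_oracle(self, seed, n_targets, n_genes):
        rng = np.random.default_rng(seed)
        rows = [
            {"gene": f"g{g}", "target": f"t{t}", "lineage": "L",
             "effect": float(np.round(rng.normal(), 2)), "n_case": 3, "n_control": 3}
            for g in range(n_genes) for t in range(n_targets)
        ]
        table = pd.DataFrame(rows)
        out = delta_effects(dx.EffectSizeTable(table)).table
        for _, row in out.iterrows():
            competitors = table[(table.gene == row.gene) & (table.target != row.target)]
            expected = min(row.effect - e for e in competitors["effect"])
            assert row.delta == pytest.approx(expected, abs=1e-12)


class TestAuroc:
    def test_perfect_separation(self):
        assert dx.auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_enumerated_value(self):
        assert dx.auroc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert dx.auroc([2, 2, 2, 2], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            dx.auroc([1, 2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 50))
    def test_matches_pair_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert dx.auroc(scores, labels) == pytest.approx(
            auroc_oracle(scores, labels), abs=1e-12
        )
        row = _auroc_rows(scores[None, :], labels)[0]
        assert row == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)


class TestStepwiseSelect:
    def test_minimum_size_rule_dominates(self):
        # 5 perfect markers ranked first: AUROC(1) = 1 but floor is 5 genes
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 2, size=(8, 12))
        vals[:5, :6] += 10.0  # first five genes separate perfectly
        m = make_matrix(vals, ann={"cell_type": ["X"] * 6 + ["Y"] * 6})
        sig = dx.stepwise_select(m, "X", [f"g{i}" for i in range(8)])
        assert sig.chosen_k == 5
        assert sig.auroc_trajectory[0] == 1.0
        assert sig.genes == [f"g{i}" for i in range(5)]

    def test_prefix_rule_on_constructed_trajectory(self):
        traj = [0.90, 0.91, 0.92, 0.93, 0.94, 0.996, 0.99, 0.99, 0.99, 1.0]
        assert choose_prefix_length(traj, epsilon=0.005, min_genes=5) == 6

    def test_prefix_rule_min_genes_floor(self):
        assert choose_prefix_length([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]) == 5
        assert choose_prefix_length([0.6, 0.7, 1.0], min_genes=5) == 3

    def test_fewer_candidates_selects_all_and_flags(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 2, size=(3, 10))
        vals[:, :5] += np.array([[3.0], [2.0], [1.0]])
        m = make_matrix(vals, ann={"cell_type": ["X"] * 5 + ["Y"] * 5})
        with pytest.warns(UserWarning, match="selecting all"):
            sig = dx.stepwise_select(m, "X", ["g0", "g1", "g2"])
        assert sig.flagged and sig.genes == ["g0", "g1", "g2"]

    def test_absent_target_is_error(self):
        m = make_matrix(np.ones((2, 4)), ann={"cell_type": ["X"] * 4})
        with pytest.raises(ValueError, match="covers|absent"):
            dx.stepwise_select(m, "Z", ["g0"])


class TestBuildBasis:
    @pytest.fixture(scope="class")
    def marker_scenario(self):
        from decomix.synthetic import marker_recovery_config

        cfg = marker_recovery_config(seed=5, n_genes=600)
        compendium, truth = dx.simulate_sorted_compendium(cfg)
        basis = dx.build_basis(compendium, dict(cfg.hierarchy))
        return cfg, compendium, truth, basis

    def test_stage_sets_disjoint_and_min_sizes(self, marker_scenario):
        _, _, _, basis = marker_scenario
        stages = pd.Series(basis.stage_of)
        ct_genes = set(stages[stages == "cell_type_stage"].index)
        lin_genes = set(stages[stages == "lineage_stage"].index)
        assert ct_genes and lin_genes and not (ct_genes & lin_genes)
        for sig in basis.signatures.values():
            assert len(sig.genes) >= 5

    def test_assembly_equals_per_type_means(self, marker_scenario):
        cfg, compendium, _, basis = marker_scenario
        mq = dx.quantile_normalize(compendium)
        ct = mq.annotation("cell_type")
        gene, cell_type = basis.gene_ids[0], basis.cell_types[3]
        expected = mq.expr.loc[gene, (ct == cell_type).to_numpy()].mean()
        assert basis.values.loc[gene, cell_type] == pytest.approx(expected, rel=1e-12)

    def test_deterministic(self, marker_scenario):
        cfg, compendium, _, basis = marker_scenario
        again = dx.build_basis(compendium, dict(cfg.hierarchy))
        pd.testing.assert_frame_equal(again.values, basis.values)
        assert again.stage_of == basis.stage_of

    def test_single_lineage_skips_stage_two(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 2, size=(30, 12))
        vals[:5, :6] += 5.0
        vals[5:10, 6:] += 5.0
        m = make_matrix(vals, ann={"cell_type": ["X"] * 6 + ["Y"] * 6,
                                   "lineage": ["L"] * 12})
        with pytest.warns(UserWarning, match="lineage stage skipped"):
            basis = dx.build_basis(m, {"X": "L", "Y": "L"})
        assert set(basis.stage_of.values()) == {"cell_type_stage"}

    def test_round_trip_tsv(self, marker_scenario, tmp_path):
        _, _, _, basis = marker_scenario
        basis.write_tsv(tmp_path / "b.tsv")
        back = dx.BasisMatrix.read_tsv(tmp_path / "b.tsv")
        pd.testing.assert_frame_equal(back.values, basis.values)
        assert dict(back.lineage_of) == dict(basis.lineage_of)
        assert dict(back.stage_of) == dict(basis.stage_of)


class TestBasisFromGeneList:
    def test_hand_computed_group_means(self):
        m = make_matrix([[1.0, 3.0, 10.0, 20.0], [2.0, 2.0, 5.0, 5.0]],
                        genes=["A", "B"],
                        ann={"cell_type": ["X", "X", "Y", "Y"]})
        basis = dx.basis_from_gene_list(m, ["A", "B"])
        mq = dx.quantile_normalize(m)
        assert basis.values.loc["A", "X"] == pytest.approx(
            mq.expr.loc["A", ["s0", "s1"]].mean()
        )
        assert basis.values.shape == (2, 2)

    def test_consistency_with_built_basis(self, benchmark_truth):
        from decomix.synthetic import marker_recovery_config

        cfg = marker_recovery_config(seed=6, n_genes=600)
        compendium, _ = dx.simulate_sorted_compendium(cfg)
        built = dx.build_basis(compendium, dict(cfg.hierarchy))
        relisted = dx.basis_from_gene_list(
            compendium, built.gene_ids, hierarchy=dict(cfg.hierarchy)
        )
        pd.testing.assert_frame_equal(
            relisted.values[built.cell_types], built.values[built.cell_types]
        )

    def test_missing_gene_error_names_it(self):
        m = make_matrix(np.ones((2, 2)), genes=["A", "B"], ann={"cell_type": ["X", "Y"]})
        with pytest.raises(ValueError, match="ZZ"):
            dx.basis_from_gene_list(m, ["A", "ZZ"])
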