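"""Gaussian graphical model estimation, edge tests, centrality, node effects."""

import numpy as np
import pandas as pd
import pytest

from metabrisk import (partial_correlations, edge_tests, betweenness_centrality,
                       node_effect_z, build_network, make_precision_matrix,
                       log_pareto)
from metabrisk.simulate import edges_of

from conftest import exact_covariance_sample
from oracles import brute_force_betweenness, residual_partial_correlation


class TestPartialCorrelations:
    def test_two_variables_equals_pearson(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 2))
        X[:, 1] += 0.5 * X[:, 0]
        pc = partial_correlations(X, shrinkage=0)
        assert pc[0, 1] == pytest.approx(np.corrcoef(X.T)[0, 1], abs=1e-10)

    def test_trivariate_closed_form(self):
        # all marginal correlations 0.5: pcor(1,2|3) = (r12 - r13*r23) /
        # sqrt((1-r13^2)(1-r23^2)) = 0.25/0.75 = 1/3
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        X = exact_covariance_sample(S, 100, np.random.default_rng(1))
        pc = partial_correlations(X, shrinkage=0)
        assert pc[0, 1] == pytest.approx(1 / 3, abs=1e-10)

    def test_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(2)
        omega = make_precision_matrix(6, 0.4, 0.35, seed=3)
        X = rng.multivariate_normal(np.zeros(6), np.linalg.inv(omega), size=200)
        pc = partial_correlations(X, shrinkage=0)
        for i in range(6):
            for j in range(i + 1, 6):
                assert pc[i, j] == pytest.approx(
                    residual_partial_correlation(X, i, j), abs=1e-8)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        pc = partial_correlations(rng.standard_normal((40, 8)))
        assert np.allclose(pc, pc.T)
        assert np.allclose(np.diag(pc), 1.0)
        off = pc[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() <= 1.0

    def test_singular_covariance_instructs_shrinkage(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 20))   # p > n: singular
        with pytest.raises(ValueError, match="shrinkage"):
            partial_correlations(X, shrinkage=0)
        pc = partial_correlations(X, shrinkage="auto")   # works via Ledoit-Wolf
        assert np.isfinite(pc).all()


class TestEdgeTests:
    def test_zero_pcor_p_one(self):
        pc = np.eye(4)
        res = edge_tests(pc, n=100)
        assert (res["p_value"] == 1.0).all()

    def test_fisher_z_hand_example(self):
        # r = 0.442 at n = 132 with 23 variables: z = atanh(0.442) = 0.4749,
        # se = 1/sqrt(132 - 21 - 3) = 0.0962, far beyond p = 0.001
        pc = np.eye(23)
        pc[0, 1] = pc[1, 0] = 0.442
        res = edge_tests(pc, n=132).set_index(["i", "j"])
        row = res.loc[(0, 1)]
        assert row["z"] == pytest.approx(0.4749, abs=1e-3)
        assert row["p_value"] < 0.001
        se = 1 / np.sqrt(132 - 21 - 3)
        assert se == pytest.approx(0.0962, abs=1e-3)

    def test_insufficient_df_raises(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            edge_tests(np.eye(23), n=24)


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness_centrality([(0, 1), (1, 2)], nodes=["A", "B", "C"])
        assert bc["B"] == 1.0 and bc["A"] == 0.0 and bc["C"] == 0.0

    def test_star_graph_closed_form(self):
        k = 6
        edges = [(0, i) for i in range(1, k + 1)]
        bc = betweenness_centrality(edges, nodes=range(k + 1))
        assert bc.iloc[0] == k * (k - 1) / 2
        assert (bc.iloc[1:] == 0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.4]
        bc = betweenness_centrality(edges, nodes=range(n))
        np.testing.assert_allclose(bc.to_numpy(),
                                   brute_force_betweenness(n, edges),
                                   atol=1e-10)


class TestNodeEffects:
    @staticmethod
    def _abundance(case_vals, control_vals, p=1):
        vals = np.column_stack([np.r_[case_vals, control_vals]] * p)
        idx = [f"s{i}" for i in range(vals.shape[0])]
        groups = pd.Series(["case"] * len(case_vals)
                           + ["control"] * len(control_vals), index=idx)
        ab = pd.DataFrame(vals, index=idx,
                          columns=[f"m{j}" for j in range(p)])
        return ab, groups

    def test_identical_groups_zero_z(self):
        vals = np.exp(np.random.default_rng(6).normal(0, 1, 20))
        ab, groups = self._abundance(vals, vals)
        res = node_effect_z(ab, groups)
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["q_value"].iloc[0] == pytest.approx(1.0)

    def test_three_sd_shift_large_z(self):
        rng = np.random.default_rng(7)
        control = np.exp(rng.normal(0, 1, 66))
        case = np.exp(rng.normal(3, 1, 66))
        ab, groups = self._abundance(case, control)
        assert abs(node_effect_z(ab, groups)["z"].iloc[0]) > 5

    def test_zero_variance_flagged(self):
        ab, groups = self._abundance([1.0] * 5, [1.0] * 5)
        res = node_effect_z(ab, groups)
        assert not res["computed"].iloc[0]

    def test_planted_17_of_23_pattern_recovered(self):
        # 17 of 23 metabolites shifted at effect 1.0, n = 66 + 66: the BH
        # q < 0.05 flags recover every planted node with at most one false
        # flag in >= 18/20 replicates.  (Demanding *exactly* the planted set
        # would fight BH by construction: with 17 true effects the step-up
        # threshold leaves roughly a one-in-five chance that one of the six
        # null nodes slips under it.)
        successes = 0
        planted = {f"m{j}" for j in range(17)}
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            logged = rng.standard_normal((132, 23))
            logged[:66, :17] += 1.0
            ab = pd.DataFrame(np.exp(logged), index=[f"s{i}" for i in range(132)],
                              columns=[f"m{j}" for j in range(23)])
            groups = pd.Series(["case"] * 66 + ["control"] * 66, index=ab.index)
            res = node_effect_z(ab, groups)
            flagged = set(res.index[res["significant"]])
            if planted <= flagged and len(flagged - planted) <= 1:
                successes += 1
        assert successes >= 18


class TestBuildNetwork:
    def test_full_model_coherent(self, small_study):
        set1, _, _, truth = small_study
        nodes = truth.network_ids
        ab = set1.abundance[nodes]
        scaled = log_pareto(ab)
        net = build_network(ab, scaled, set1.groups)
        assert net.pcor.shape == (23, 23)
        assert (net.betweenness >= 0).all()
        sig = net.edges[net.edges["significant"]]
        assert (sig["q_value"] < 0.05).all()
        assert net.node_table().shape[0] == 23
        assert (net.node_stats["significant"]
                == (net.node_stats["q_value"] < 0.05)).all()

    def test_graphml_export(self, small_study, tmp_path):
        import networkx as nx
        set1, _, _, truth = small_study
        nodes = truth.network_ids
        ab = set1.abundance[nodes]
        net = build_network(ab, log_pareto(ab), set1.groups)
        net.write_graphml(tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g.number_of_nodes() == 23
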