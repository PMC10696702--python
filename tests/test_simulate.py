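"""Generator correctness: planted precision structure, determinism, effects."""

import numpy as np
import pandas as pd
import pytest

from metabrisk import (SimulationConfig, generate_study, make_precision_matrix,
                       fit_oplsda, log_pareto, qc_filter, replicated_selection)
from metabrisk.containers import FeatureTable, GenotypePanel
from metabrisk.simulate import SyntheticTruth, edges_of


def implied_pcor(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


class TestPrecisionMatrix:
    def test_zero_density_gives_identity(self):
        assert np.array_equal(make_precision_matrix(6, 0.0, 0.4, seed=0), np.eye(6))

    def test_single_edge_closed_form_pcor(self):
        # hand-built precision with one edge at strength 0.4: the implied
        # partial correlation is exactly -omega_01/sqrt(omega_00*omega_11)
        omega = np.eye(3)
        omega[0, 1] = omega[1, 0] = -0.4
        truth = SyntheticTruth([0], [0, 1, 2], omega, edges_of(omega), [0],
                               np.array([0.1]))
        pc = truth.implied_partial_correlations()
        assert pc[0, 1] == pytest.approx(0.4, abs=1e-12)
        assert pc[0, 2] == 0.0

    @pytest.mark.parametrize("p,density,strength", [
        (5, 0.3, 0.4), (23, 0.08, 0.4), (30, 0.5, 0.3), (10, 0.9, 0.45),
    ])
    def test_positive_definite(self, p, density, strength):
        omega = make_precision_matrix(p, density, strength, seed=2)
        assert np.linalg.eigvalsh(omega).min() > 0
        assert np.allclose(omega, omega.T)

    def test_edge_support_matches_edges_of(self):
        omega = make_precision_matrix(12, 0.25, 0.4, seed=3)
        edges = edges_of(omega)
        for i in range(12):
            for j in range(i + 1, 12):
                assert ((i, j) in edges) == (omega[i, j] != 0)

    def test_monte_carlo_partial_correlations_converge(self):
        # sample partial correlations of a large draw approach the values
        # implied by the generating precision matrix
        omega = make_precision_matrix(10, 0.2, 0.4, seed=4)
        sigma = np.linalg.inv(omega)
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal(np.zeros(10), sigma, size=50_000)
        est = implied_pcor(np.linalg.inv(np.cov(X, rowvar=False)))
        assert np.abs(est - implied_pcor(omega)).max() < 0.02

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_precision_matrix(1, 0.1, 0.4)
        with pytest.raises(ValueError):
            make_precision_matrix(5, 1.0, 0.4)
        with pytest.raises(ValueError):
            make_precision_matrix(5, 0.1, 1.0)


class TestGenerateStudy:
    def test_deterministic_under_seed(self, small_config):
        a1, a2, pa, ta = generate_study(small_config)
        b1, b2, pb, tb = generate_study(small_config)
        pd.testing.assert_frame_equal(a1.abundance, b1.abundance)
        pd.testing.assert_frame_equal(a2.abundance, b2.abundance)
        pd.testing.assert_frame_equal(pa.genotypes, pb.genotypes)
        assert np.array_equal(ta.true_precision, tb.true_precision)
        assert ta.biomarker_indices == tb.biomarker_indices

    def test_group_counts_exact(self, small_study, small_config):
        set1, set2, panel, _ = small_study
        cfg = small_config
        assert set1.groups.value_counts().to_dict() == {
            "case": cfg.n_cases_set1, "control": cfg.n_controls_set1}
        assert set2.groups.value_counts().to_dict() == {
            "case": cfg.n_cases_set2, "control": cfg.n_controls_set2}
        assert (panel.samples["cohort"] == "pool").sum() == cfg.n_gwas_pool

    def test_truth_consistency(self, small_study):
        _, _, _, truth = small_study
        assert set(truth.biomarker_indices) <= set(truth.network_indices)
        assert truth.true_edges == edges_of(truth.true_precision)
        assert np.linalg.eigvalsh(truth.true_precision).min() > 0

    def test_infeasible_config_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_features=5)  # network block cannot fit
        with pytest.raises(ValueError):
            SimulationConfig(n_biomarkers=50, n_network=23)

    def test_planted_biomarkers_exceed_null_effect_quantile(self):
        # at effect 1.5 the planted biomarkers' standardized mean difference
        # clears the 95th percentile of non-planted features in >= 18/20 reps
        successes = 0
        for rep in range(20):
            cfg = SimulationConfig(n_features=120, n_identified=60,
                                   n_network=23, n_biomarkers=5,
                                   effect_size=1.5, n_snps=30, n_risk_snps=5,
                                   n_gwas_pool=80, seed=100 + rep)
            set1, _, _, truth = generate_study(cfg)
            logged = np.log(set1.abundance.to_numpy())
            is_case = (set1.groups == "case").to_numpy()
            num = logged[is_case].mean(0) - logged[~is_case].mean(0)
            den = np.sqrt((logged[is_case].var(0, ddof=1)
                           + logged[~is_case].var(0, ddof=1)) / 2)
            smd = np.abs(num / den)
            bio = np.array(truth.biomarker_indices)
            null = np.delete(smd, bio)
            if (smd[bio] > np.quantile(null, 0.95)).all():
                successes += 1
        assert successes >= 18

    def test_null_config_selection_at_chance_level(self):
        # with no planted effect the replicated VIP filter hits planted
        # biomarkers no more often than arbitrary features
        bio_hits, total_rate = 0, []
        for rep in range(20):
            cfg = SimulationConfig(n_features=80, n_identified=40,
                                   n_network=10, n_biomarkers=5,
                                   effect_size=0.0, pcor_strength=0.0,
                                   n_snps=20, n_risk_snps=3, n_gwas_pool=60,
                                   seed=300 + rep)
            set1, set2, _, truth = generate_study(cfg)
            vips = {}
            for name, tab in (("s1", set1), ("s2", set2)):
                X = log_pareto(qc_filter(tab, min_detect=0.0))
                m = fit_oplsda(X.to_numpy(), tab.groups.to_numpy(), n_orth=0)
                vips[name] = pd.Series(m.vip, index=X.columns)
            sel = replicated_selection(vips["s1"], vips["s2"])
            bio_hits += int(sel.loc[[f"F{i+1:05d}" for i in
                                     truth.biomarker_indices],
                                    "selected"].sum())
            total_rate.append(sel["selected"].mean())
        # binomial upper bound at the empirical overall selection rate
        from scipy.stats import binom
        rate = float(np.mean(total_rate))
        assert bio_hits <= binom.ppf(0.999, 20 * 5, max(rate, 1e-9)) + 1

    def test_qc_detection_reflects_identified_status(self, small_study):
        set1, _, _, _ = small_study
        ident = set1.features["identified"].astype(bool)
        assert set1.qc_detection[ident].mean() > 0.95
        assert set1.qc_detection[~ident].mean() < 0.7


class TestRoundTrip:
    def test_feature_table_tsv_round_trip(self, small_study, tmp_path):
        set1 = small_study[0]
        set1.write(tmp_path, "set1")
        back = FeatureTable.read(tmp_path, "set1")
        np.testing.assert_allclose(back.abundance.to_numpy(),
                                   set1.abundance.to_numpy(), rtol=1e-12)
        assert list(back.samples["group"]) == list(set1.samples["group"])
        assert back.qc_replicates.shape == set1.qc_replicates.shape

    def test_genotype_panel_tsv_round_trip(self, small_study, tmp_path):
        panel = small_study[2]
        panel.write(tmp_path, "panel")
        back = GenotypePanel.read(tmp_path, "panel")
        a, b = panel.genotypes.to_numpy(), back.genotypes.to_numpy()
        assert np.array_equal(np.isnan(a), np.isnan(b))
        assert np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)])

    def test_truth_json_round_trip(self, small_study, tmp_path):
        truth = small_study[3]
        truth.write(tmp_path / "truth.json")
        back = SyntheticTruth.read(tmp_path / "truth.json")
        assert back.true_edges == truth.true_edges
        np.testing.assert_allclose(back.true_precision, truth.true_precision)
        assert back.biomarker_indices == truth.biomarker_indices
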