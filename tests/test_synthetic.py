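"""Generator correctness: LD structure, calibration, planted signals, determinism."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sctargetmr import (
    GroundTruth,
    ParameterError,
    ivw,
    ld_from_dosages,
    run_mr,
    screen,
    simulate_ld_genotypes,
    simulate_mr_instruments,
    simulate_phewas_table,
    simulate_sc_counts,
    simulate_two_trait_sumstats,
)
from sctargetmr.synthetic import marginal_linear, marginal_logistic, read_cell_matrix, write_cell_matrix

from conftest import MARKER_SETS, make_gene_names


class TestLDGenotypes:
    def test_decay_zero_gives_independent_variants(self):
        _, ld = simulate_ld_genotypes(5000, 30, decay=0.0, seed=1)
        off = ld.r[~np.eye(30, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.02
        assert np.max(np.abs(off)) < 0.1

    def test_duplicated_column_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=50)
        dosages = np.column_stack([col, col, rng.integers(0, 3, size=50)])
        ld = ld_from_dosages(dosages, ["a", "b", "c"])
        assert ld.r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_correlation_decays_with_distance(self):
        # mean |r| at lag 1 exceeds mean |r| at lag 5, computed from the matrix
        _, ld = simulate_ld_genotypes(2000, 50, decay=0.9, seed=1)
        adj = np.mean([abs(ld.r[i, i + 1]) for i in range(49)])
        lag5 = np.mean([abs(ld.r[i, i + 5]) for i in range(45)])
        assert adj > lag5

    def test_positions_fixed_1kb_spacing(self):
        panel, _ = simulate_ld_genotypes(10, 5, decay=0.5, seed=0)
        assert list(panel.pos) == [1000, 2000, 3000, 4000, 5000]
        assert panel.dosages.shape == (10, 5)
        assert set(np.unique(panel.dosages)) <= {0, 1, 2}

    @pytest.mark.parametrize("kwargs", [
        {"n_individuals": 1, "n_variants": 5, "decay": 0.5},
        {"n_individuals": 10, "n_variants": 5, "decay": 1.0},
        {"n_individuals": 10, "n_variants": 5, "decay": -0.1},
        {"n_individuals": 10, "n_variants": 5, "decay": 0.5, "maf_range": (0.0, 0.5)},
        {"n_individuals": 10, "n_variants": 5, "decay": 0.5, "maf_range": (0.4, 0.2)},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            simulate_ld_genotypes(seed=0, **kwargs)

    def test_bit_reproducible(self):
        p1, l1 = simulate_ld_genotypes(200, 20, decay=0.7, seed=42)
        p2, l2 = simulate_ld_genotypes(200, 20, decay=0.7, seed=42)
        assert np.array_equal(p1.dosages, p2.dosages)
        assert np.array_equal(l1.r, l2.r)


class TestMarginalRegressions:
    """Vectorized per-variant GWAS vs statsmodels on a small fixture."""

    def test_linear_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(200, 4)).astype(float)
        y = 0.3 * G[:, 1] + rng.standard_normal(200)
        beta, se = marginal_linear(G, y)
        for j in range(4):
            fit = sm.OLS(y, sm.add_constant(G[:, j])).fit()
            assert beta[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert se[j] == pytest.approx(fit.bse[1], abs=1e-10)

    def test_logistic_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, size=(500, 3)).astype(float)
        eta = -0.2 + 0.4 * G[:, 0]
        y = (rng.uniform(size=500) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, se = marginal_logistic(G, y)
        for j in range(3):
            fit = sm.Logit(y, sm.add_constant(G[:, j])).fit(disp=0)
            assert beta[j] == pytest.approx(fit.params[1], abs=1e-7)
            assert se[j] == pytest.approx(fit.bse[1], rel=1e-5)


class TestTwoTraitSumstats:
    def test_null_scenario_p_values_calibrated(self):
        panel, _ = simulate_ld_genotypes(4000, 500, decay=0.0, seed=5)
        exp, out, _ = simulate_two_trait_sumstats(panel, "H0", 0.0, 0.0, seed=5)
        for tab in (exp, out):
            assert np.mean(tab["pval"] < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_null_p_values_uniform_ks(self):
        # pooled over two seeds at 1000 independent variants
        pooled = []
        for seed in (0, 1):
            panel, _ = simulate_ld_genotypes(2000, 500, decay=0.0, seed=seed)
            exp, _, _ = simulate_two_trait_sumstats(panel, "H0", 0.0, 0.0, seed=seed)
            pooled.extend(exp["pval"])
        assert stats.kstest(pooled, "uniform").pvalue > 0.01

    def test_h4_causal_variant_attains_min_p(self):
        hits = 0
        for seed in range(50):
            panel, _ = simulate_ld_genotypes(10000, 100, decay=0.9, seed=seed)
            exp, _, truth = simulate_two_trait_sumstats(panel, "H4", 0.5, 0.5, seed=seed)
            hits += exp.loc[exp["pval"].idxmin(), "snp"] == truth.causal_variant_ids["exposure"][0]
        assert hits >= 45  # >= 90% of 50 seeds

    def test_h3_min_p_variants_are_the_planted_pair(self):
        hits = 0
        for seed in range(20):
            panel, _ = simulate_ld_genotypes(10000, 100, decay=0.9, seed=100 + seed)
            exp, out, truth = simulate_two_trait_sumstats(panel, "H3", 0.5, 0.5, seed=seed)
            ok = exp.loc[exp["pval"].idxmin(), "snp"] == truth.causal_variant_ids["exposure"][0]
            ok &= out.loc[out["pval"].idxmin(), "snp"] == truth.causal_variant_ids["outcome"][0]
            hits += ok
        assert hits > 10  # majority of seeds

    def test_scenario_effect_mismatch_rejected(self):
        panel, _ = simulate_ld_genotypes(100, 10, decay=0.5, seed=0)
        with pytest.raises(ParameterError):
            simulate_two_trait_sumstats(panel, "H0", 0.5, 0.0, seed=0)
        with pytest.raises(ParameterError):
            simulate_two_trait_sumstats(panel, "H4", 0.5, 0.0, seed=0)
        with pytest.raises(ParameterError):
            simulate_two_trait_sumstats(panel, "H2", 0.3, 0.3, seed=0)

    def test_case_control_outcome_on_log_odds_scale(self):
        panel, _ = simulate_ld_genotypes(8000, 50, decay=0.5, seed=9)
        _, out, truth = simulate_two_trait_sumstats(
            panel, "H4", 0.5, 0.4, outcome_type="case_control", seed=9)
        causal = truth.causal_variant_ids["outcome"][0]
        row = out[out["snp"] == causal].iloc[0]
        # per-allele log-odds should be positive and within a plausible band
        assert row["beta"] > 0
        assert row["pval"] < 1e-4


class TestMRInstrumentGenerator:
    def test_noise_free_limit_ratios_equal_causal(self):
        hset, _ = simulate_mr_instruments(10, 0.37, exposure_n=10**14,
                                          outcome_n=10**14, seed=0)
        ratios = hset["beta_outcome"] / hset["beta_exposure"]
        assert np.allclose(ratios, 0.37, atol=1e-4)

    def test_null_causal_ivw_covered(self):
        hits = 0
        for seed in range(100):
            hset, _ = simulate_mr_instruments(20, 0.0, seed=seed)
            res = ivw(hset)
            hits += abs(res.beta) <= 2 * res.se
        assert hits >= 93

    def test_single_instrument_dispatches_to_wald(self):
        hset, _ = simulate_mr_instruments(1, 0.2, seed=0)
        assert run_mr(hset).primary.method == "wald_ratio"

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            simulate_mr_instruments(0, 0.4)
        with pytest.raises(ParameterError):
            simulate_mr_instruments(5, 0.4, pleiotropy_sd=-1)


class TestSCCounts:
    def test_marker_elevated_in_own_type(self, planted_sc):
        adata, _ = planted_sc
        X = np.asarray(adata.X.todense(), dtype=float)
        types = adata.obs["true_cell_type"].to_numpy()
        for t, genes in MARKER_SETS.items():
            for g in genes:
                j = list(adata.var_names).index(g)
                own = X[types == t, j].mean()
                other = X[types != t, j].mean()
                assert own > other

    def test_de_gene_outside_gene_list_rejected(self):
        with pytest.raises(ParameterError):
            simulate_sc_counts({"A": 10, "B": 10}, 50,
                               de_genes={"A": [["NOT_A_GENE", 1.0]]}, seed=0)

    def test_lowq_fraction_zero_passes_qc(self):
        from sctargetmr import qc_filter
        adata, _ = simulate_sc_counts({"A": 40, "B": 40}, 300,
                                      lowq_cell_fraction=0.0, seed=3)
        kept = qc_filter(adata, min_genes_per_cell=50)
        assert kept.n_obs == adata.n_obs

    def test_matrix_round_trips_through_mtx(self, planted_sc, tmp_path):
        adata, _ = planted_sc
        write_cell_matrix(adata, tmp_path)
        back = read_cell_matrix(tmp_path)
        assert list(back.var_names) == list(adata.var_names)
        assert list(back.obs_names) == list(adata.obs_names)
        assert (back.X != adata.X).nnz == 0
        assert list(back.obs["condition"]) == list(adata.obs["condition"])

    def test_bit_reproducible(self):
        a1, _ = simulate_sc_counts({"A": 20, "B": 20}, 100, seed=11)
        a2, _ = simulate_sc_counts({"A": 20, "B": 20}, 100, seed=11)
        assert (a1.X != a2.X).nnz == 0


class TestPhewasTable:
    def test_no_planted_screen_empty(self):
        table = simulate_phewas_table(200, background_p_floor=1e-6, seed=0, gene="G")
        assert screen(table, "G", alpha=2e-8).empty

    def test_planted_hit_returned_exactly(self):
        table = simulate_phewas_table(200, planted=[("traitA", 1e-9)], seed=0, gene="G")
        hits = screen(table, "G", alpha=2e-8)
        assert list(hits["trait"]) == ["traitA"]

    def test_boundary_p_excluded(self):
        table = simulate_phewas_table(50, planted=[("traitB", 3e-8)], seed=0, gene="G")
        assert screen(table, "G", alpha=2e-8).empty

    def test_nonpositive_planted_p_rejected(self):
        with pytest.raises(ParameterError):
            simulate_phewas_table(10, planted=[("t", 0.0)], seed=0)


class TestGroundTruth:
    def test_json_round_trip(self, tmp_path):
        truth = GroundTruth(scenario="H4",
                            causal_variant_ids={"exposure": ["rs7"], "outcome": ["rs7"]},
                            causal_effect=-0.5,
                            de_genes={"B": [["SG0001", 1.5]]})
        path = tmp_path / "truth.json"
        truth.to_json(path)
        assert GroundTruth.from_json(path) == truth
        assert json.loads(path.read_text())["scenario"] == "H4"

    @pytest.mark.parametrize("ids", [
        {"exposure": ["rs1"], "outcome": ["rs2"]},   # H4 must share the variant
        {"exposure": [], "outcome": []},             # H4 needs a variant at all
    ])
    def test_h4_invariant_enforced(self, ids):
        with pytest.raises(ParameterError):
            GroundTruth(scenario="H4", causal_variant_ids=ids)

    def test_h3_and_h0_invariants_enforced(self):
        with pytest.raises(ParameterError):
            GroundTruth(scenario="H3",
                        causal_variant_ids={"exposure": ["rs1"], "outcome": ["rs1"]})
        with pytest.raises(ParameterError):
            GroundTruth(scenario="H0", causal_variant_ids={"exposure": ["rs1"], "outcome": []})
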