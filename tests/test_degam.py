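"""Tests for the NB-GAM along lineages and the condition Wald test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import trajdiff as td


def single_lineage_fit(n, rng, t_max=5.0):
    T = rng.uniform(0, t_max, (n, 1))
    W = np.ones((n, 1))
    return td.TrajectoryFit(pseudotimes=T, weights=W, skeleton=None)


class TestAssignCells:
    def test_degenerate_weights_pick_unique_lineage(self):
        W = np.tile([1.0, 0.0], (20, 1))
        fit = td.TrajectoryFit(np.zeros((20, 2)), W, None)
        conds = np.array(["a"] * 20)
        for mode in ("sample", "argmax"):
            asn = td.assign_cells(fit, conds, mode=mode, seed=0)
            assert np.all(asn.lineage == 0)

    def test_sampling_respects_weights(self):
        n = 10_000
        W = np.tile([0.5, 0.5], (n, 1))
        fit = td.TrajectoryFit(np.zeros((n, 2)), W, None)
        asn = td.assign_cells(fit, np.array(["a"] * n), mode="sample", seed=1)
        assert np.mean(asn.lineage == 0) == pytest.approx(0.5, abs=0.02)

    def test_same_seed_reproduces_assignment(self):
        rng = np.random.default_rng(2)
        W = rng.dirichlet([1, 1, 1], size=500)
        fit = td.TrajectoryFit(np.zeros((500, 3)), W, None)
        conds = np.array(["a", "b"] * 250)
        a1 = td.assign_cells(fit, conds, seed=7)
        a2 = td.assign_cells(fit, conds, seed=7)
        assert np.array_equal(a1.lineage, a2.lineage)
        assert np.array_equal(a1.Z(), a2.Z())

    def test_one_hot_layout_blocks(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        fit = td.TrajectoryFit(np.zeros((2, 2)), W, None)
        conds = np.array(["a", "b"])
        Z = td.assign_cells(fit, conds, mode="argmax").Z()
        assert Z.shape == (2, 4)
        assert Z[0, 0] == 1.0 and Z[0].sum() == 1.0  # (l=0, c=a)
        assert Z[1, 3] == 1.0 and Z[1].sum() == 1.0  # (l=1, c=b)


class TestBuildDesign:
    def test_two_conditions_one_lineage_gives_12_smoother_columns(self):
        rng = np.random.default_rng(3)
        fit = single_lineage_fit(200, rng)
        conds = np.array(["a"] * 100 + ["b"] * 100)
        asn = td.assign_cells(fit, conds, mode="argmax")
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=6))
        assert design.X.shape[1] == 12
        # each row is nonzero only within its own condition block
        assert np.all(np.count_nonzero(design.X, axis=1) <= 6)

    def test_constant_basis_reduces_to_intercept_model(self):
        rng = np.random.default_rng(4)
        fit = single_lineage_fit(50, rng)
        conds = np.array(["a"] * 50)
        asn = td.assign_cells(fit, conds, mode="argmax")
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=1))
        assert design.X.shape[1] == 1
        assert np.all(design.X == 1.0)

    def test_empty_block_dropped_and_recorded(self):
        rng = np.random.default_rng(5)
        T = rng.uniform(0, 1, (100, 2))
        W = np.zeros((100, 2))
        W[:, 0] = 1.0  # nobody on lineage 2
        fit = td.TrajectoryFit(T, W, None)
        conds = np.array(["a", "b"] * 50)
        asn = td.assign_cells(fit, conds, mode="argmax")
        with pytest.warns(UserWarning, match="dropped"):
            design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=4))
        assert (1, 0) in design.dropped and (1, 1) in design.dropped
        assert design.X.shape[1] == 8

    def test_covariates_appended_unpenalized(self):
        rng = np.random.default_rng(6)
        fit = single_lineage_fit(80, rng)
        conds = np.array(["a"] * 80)
        asn = td.assign_cells(fit, conds, mode="argmax")
        U = rng.normal(size=(80, 2))
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=4), U=U)
        assert design.X.shape[1] == 6
        assert design.n_covariates == 2
        assert not design.penalized[-2:].any()

    def test_invalid_basis_size_rejected(self):
        with pytest.raises(ValueError, match="K must be"):
            td.SplineBasis(K=3).fit(np.linspace(0, 1, 20))


class TestFitGeneNBGAM:
    def test_intercept_only_recovers_mean_and_dispersion(self):
        rng = np.random.default_rng(7)
        n, mu, phi = 5000, 5.0, 2.0
        fit = single_lineage_fit(n, rng)
        asn = td.assign_cells(fit, np.array(["a"] * n), mode="argmax")
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=1))
        y = rng.negative_binomial(phi, phi / (phi + mu), size=n)
        gf = td.fit_gene_nbgam(y, design)
        assert gf.converged
        assert gf.beta[0] == pytest.approx(np.log(mu), abs=0.05)
        assert gf.phi == pytest.approx(phi, rel=0.2)

    def test_poisson_limit_matches_poisson_glm_oracle(self):
        rng = np.random.default_rng(8)
        n = 3000
        fit = single_lineage_fit(n, rng)
        conds = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        asn = td.assign_cells(fit, conds, mode="argmax")
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=1))
        mu = np.where(conds == "a", 4.0, 9.0)
        y = rng.poisson(mu)
        gf = td.fit_gene_nbgam(y, design)
        X = np.column_stack([np.ones(n), (conds == "b").astype(float)])
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        ours = np.array([gf.beta[0], gf.beta[1]])
        ref = np.array([oracle.params[0], oracle.params[0] + oracle.params[1]])
        assert np.allclose(ours, ref, atol=1e-6)
        assert gf.phi > 20  # dispersion well above the NB-like range

    def test_all_zero_gene_flagged_low_information(self):
        rng = np.random.default_rng(9)
        fit = single_lineage_fit(200, rng)
        asn = td.assign_cells(fit, np.array(["a"] * 200), mode="argmax")
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=4))
        gf = td.fit_gene_nbgam(np.zeros(200, dtype=int), design)
        assert gf.low_information
        assert np.all(np.isfinite(gf.beta))

    def test_offset_shift_moves_intercept_by_log_factor(self):
        rng = np.random.default_rng(10)
        n = 2000
        fit = single_lineage_fit(n, rng)
        asn = td.assign_cells(fit, np.array(["a"] * n), mode="argmax")
        lib = np.full(n, 100.0)
        d1 = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=1), lib_sizes=lib)
        d2 = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=1), lib_sizes=2 * lib)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + 5.0), size=n)
        g1 = td.fit_gene_nbgam(y, d1, phi=2.0)
        g2 = td.fit_gene_nbgam(y, d2, phi=2.0)
        assert g2.beta[0] == pytest.approx(g1.beta[0] - np.log(2.0), abs=1e-6)
        assert np.allclose(g1.mu(d1), g2.mu(d2), rtol=1e-6)

    def test_negative_counts_rejected(self):
        rng = np.random.default_rng(11)
        fit = single_lineage_fit(10, rng)
        asn = td.assign_cells(fit, np.array(["a"] * 10), mode="argmax")
        design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=1))
        with pytest.raises(ValueError):
            td.fit_gene_nbgam(np.array([-1] + [0] * 9), design)


def two_condition_design(rng, n=1200, K=6):
    fit = single_lineage_fit(n, rng)
    conds = np.repeat(["a", "b"], n // 2)
    asn = td.assign_cells(fit, conds, mode="argmax")
    design = td.build_design(fit.pseudotimes, asn, basis=td.SplineBasis(K=K))
    return fit, conds, design


class TestConditionTest:
    def test_swapping_condition_order_leaves_statistic_unchanged(self):
        rng = np.random.default_rng(12)
        fit, conds, design = two_condition_design(rng)
        t = fit.pseudotimes[:, 0]
        mu = np.exp(1.0 + 0.2 * t + 0.6 * (conds == "b"))
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        gf = td.fit_gene_nbgam(y, design)
        tab1 = td.condition_test({"g": gf}, design)

        swapped = np.where(conds == "a", "b", "a")
        asn2 = td.assign_cells(fit, swapped, mode="argmax")
        design2 = td.build_design(fit.pseudotimes, asn2, basis=design.basis)
        gf2 = td.fit_gene_nbgam(y, design2)
        tab2 = td.condition_test({"g": gf2}, design2)
        assert tab1.wald_stat[0] == pytest.approx(tab2.wald_stat[0], rel=1e-6)

    def test_constant_fold_change_zeroed_above_threshold(self):
        rng = np.random.default_rng(13)
        fit, conds, design = two_condition_design(rng)
        t = fit.pseudotimes[:, 0]
        # condition b has exactly 4x the mean: log2 fold change = 2
        mu = np.exp(1.0 + 0.3 * t) * np.where(conds == "b", 4.0, 1.0)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        gf = td.fit_gene_nbgam(y, design)
        t0 = td.condition_test({"g": gf}, design, lfc_threshold=0.0)
        t15 = td.condition_test({"g": gf}, design, lfc_threshold=1.5)
        t3 = td.condition_test({"g": gf}, design, lfc_threshold=3.0)
        assert t0.wald_stat[0] > 0 and t0.p_value[0] < 1e-6
        assert t15.wald_stat[0] > 0  # fitted |log2FC| ~ 2 >= 1.5 everywhere
        assert t3.wald_stat[0] == 0.0 and t3.df[0] == 0  # all rows zeroed

    def test_null_gene_p_values_roughly_uniform(self):
        rng = np.random.default_rng(14)
        fit, conds, design = two_condition_design(rng, n=800)
        t = fit.pseudotimes[:, 0]
        mu = np.exp(1.2 + 0.2 * np.sin(t))
        ps = []
        for _ in range(40):
            y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
            gf = td.fit_gene_nbgam(y, design)
            ps.append(td.condition_test({"g": gf}, design).p_value[0])
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.15
        assert ps.mean() == pytest.approx(0.5, abs=0.2)

    def test_unmapped_lineages_raise(self):
        rng = np.random.default_rng(15)
        T = rng.uniform(0, 1, (100, 2))
        W = np.zeros((100, 2))
        conds = np.repeat(["a", "b"], 50)
        W[:50, 0] = 1.0  # condition a only on lineage 1
        W[50:, 1] = 1.0  # condition b only on lineage 2
        fit = td.TrajectoryFit(T, W, None)
        asn = td.assign_cells(fit, conds, mode="argmax")
        with pytest.warns(UserWarning, match="dropped"):
            design = td.build_design(T, asn, basis=td.SplineBasis(K=4))
        with pytest.raises(ValueError, match="mapped"):
            td.condition_test({}, design)

    def test_non_convergent_or_empty_genes_excluded_with_reason(self):
        rng = np.random.default_rng(16)
        fit, conds, design = two_condition_design(rng, n=400)
        gf_zero = td.fit_gene_nbgam(np.zeros(400, dtype=int), design)
        mu = np.exp(1.0)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu), size=400)
        gf_ok = td.fit_gene_nbgam(y, design)
        tab = td.condition_test({"dead": gf_zero, "live": gf_ok}, design)
        dead = tab.set_index("gene").loc["dead"]
        assert dead.filtered_reason == "low_information"
        assert np.isnan(dead.p_value)
        assert tab.set_index("gene").loc["live", "filtered_reason"] == ""


class TestConditionDEPipeline:
    def test_end_to_end_on_simulated_de_genes(self):
        ds, truth = td.simulate_dataset(
            td.SimSpec(
                topology="linear",
                n_per_condition=400,
                n_genes=60,
                de_frac=0.2,
                multiplier=4.0,
                seed=17,
            )
        )
        fit = td.project_cells(ds, td.fit_skeleton(ds, root="O-M:0"))
        table, meta = td.condition_de(ds, fit, K=6, seed=0)
        assert meta["K"] == 6 and meta["n_tested"] >= 50
        merged = table.set_index("gene")
        hits = {g for g in merged.index[merged.q_value < 0.05]}
        de = {f"gene_{j}" for j in np.flatnonzero(truth.de_genes)}
        # strong 4x effects should be mostly recovered with few false hits
        assert len(hits & de) >= 0.7 * len(de)
        assert len(hits - de) <= 3
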