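"""Residualization, mass-univariate scan, driver attribution, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pewas import OmicsMatrix, PlantedEffect, SimulationConfig, simulate_cohort
from pewas.containers import ConfigurationError
from pewas.pipeline import preprocess_bundle
from pewas.stepwise import (
    StepDefinition,
    bonferroni_threshold,
    default_steps,
    ewas_scan,
    genomic_inflation,
    joint_model_check,
    pc_confounder_check,
    residualize,
    run_stepwise,
    select_cis_snps,
)

from conftest import toy_matrix


def _cov(n, rng=None, **extra):
    rng = rng or np.random.default_rng(0)
    base = {
        "sex": rng.integers(0, 2, n).astype(float),
        "age": rng.uniform(30, 80, n),
        "bmi": rng.normal(27, 4, n),
        "smoking": rng.choice(["never", "former", "current"], n),
        "diabetes": rng.integers(0, 2, n).astype(float),
    }
    base.update(extra)
    return pd.DataFrame(base, index=[f"s{i}" for i in range(n)])


class TestResidualize:
    def test_orthogonal_covariate_leaves_centered_column(self, rng):
        n = 50
        cov = _cov(n, rng)
        # column orthogonal to the design by explicit projection
        x = np.column_stack([np.ones(n), cov["age"].to_numpy()])
        raw = rng.normal(size=n)
        ortho = raw - x @ np.linalg.lstsq(x, raw, rcond=None)[0]
        mat = toy_matrix(ortho[:, None] + 5.0, "standardized")
        mat.data.index = cov.index
        out, dropped = residualize(mat, cov, ["age"])
        assert dropped == []
        centered = (ortho + 5.0) - (ortho + 5.0).mean()
        assert np.allclose(out.values()[:, 0], centered, atol=1e-10)

    def test_exact_linear_function_of_covariate_gives_zero_residual(self, rng):
        cov = _cov(40, rng)
        mat = toy_matrix(2.0 * cov["sex"].to_numpy()[:, None], "standardized")
        mat.data.index = cov.index
        out, _ = residualize(mat, cov, ["sex"])
        assert np.allclose(out.values(), 0.0, atol=1e-10)

    def test_collinear_design_names_offending_columns(self, rng):
        cov = _cov(30, rng)
        cov["age_copy"] = cov["age"]
        mat = toy_matrix(rng.normal(size=(30, 2)), "standardized")
        mat.data.index = cov.index
        with pytest.raises(ConfigurationError, match="age"):
            residualize(mat, cov, ["age", "age_copy"])

    def test_missing_covariate_rows_dropped_and_reported(self, rng):
        cov = _cov(25, rng)
        cov.loc[cov.index[3], "age"] = np.nan
        mat = toy_matrix(rng.normal(size=(25, 2)), "standardized")
        mat.data.index = cov.index
        out, dropped = residualize(mat, cov, ["age"])
        assert dropped == [cov.index[3]]
        assert out.n_samples == 24


class TestEwasScan:
    def test_identical_columns_slope_one_minimal_p(self, rng):
        col = rng.normal(size=60)
        meth = toy_matrix(col[:, None], "standardized", prefix="cg")
        prot = toy_matrix(col[:, None], "standardized", prefix="pr")
        scan = ewas_scan(meth, prot, threshold=0.05)
        rec = scan.records.iloc[0]
        assert rec["beta_hat"] == pytest.approx(1.0, abs=1e-10)
        assert 0 < rec["p"] <= 1e-300

    def test_matches_hand_rolled_normal_equations_on_toy(self, rng):
        # 5 samples x 4 features, one covariate; slopes and p-values agree
        # with an explicit (X'X)^{-1}X'y computation to 1e-9
        n = 5
        cov = _cov(n, rng)
        meth = toy_matrix(rng.normal(size=(n, 4)), "standardized", prefix="cg")
        prot = toy_matrix(rng.normal(size=(n, 4)), "standardized", prefix="pr")
        meth.data.index = prot.data.index = cov.index
        steps = [StepDefinition(0, "initial", ()), StepDefinition(1, "age", ("age",))]
        res = run_stepwise(meth, prot, cov, threshold=1.1, steps=steps)
        scan = res.scans[1]

        c = cov["age"].to_numpy()
        x_cov = np.column_stack([np.ones(n), c])
        proj = lambda v: v - x_cov @ np.linalg.solve(x_cov.T @ x_cov, x_cov.T @ v)
        for i, cpg in enumerate(meth.feature_ids):
            for j, pr in enumerate(prot.feature_ids):
                y = proj(meth.values()[:, i])
                x = proj(prot.values()[:, j])
                xd = np.column_stack([np.ones(n), x])
                beta = np.linalg.solve(xd.T @ xd, xd.T @ y)
                resid = y - xd @ beta
                se = np.sqrt((resid @ resid) / (n - 2) / ((x - x.mean()) @ (x - x.mean())))
                t = beta[1] / se
                p = 2 * stats.t.sf(abs(t), n - 2)
                assert scan.slopes.at[cpg, pr] == pytest.approx(beta[1], abs=1e-9)
                assert scan.p_values.at[cpg, pr] == pytest.approx(p, abs=1e-9)

    def test_planted_direct_pair_recovered_at_desk_bonferroni(self):
        cfg = SimulationConfig(
            n_samples=500,
            n_cpgs=100,
            n_proteins=20,
            planted_effects=[PlantedEffect("cg0000090", "seq_0003", "direct", 0.3)],
            seed=21,
        )
        bundle = simulate_cohort(cfg, "discovery")
        proc = preprocess_bundle(bundle)
        threshold = bonferroni_threshold(0.05, [100, 20])
        scan = ewas_scan(proc.meth, proc.prot, threshold)
        assert ("cg0000090", "seq_0003") in scan.significant_pairs()

    def test_pairs_with_too_few_observations_skipped(self, rng):
        values = rng.normal(size=(6, 2))
        values[2:, 0] = np.nan  # only 2 complete rows for feature 0
        meth = toy_matrix(values, "standardized", prefix="cg")
        prot = toy_matrix(rng.normal(size=(6, 1)), "standardized", prefix="pr")
        scan = ewas_scan(meth, prot, threshold=0.5)
        assert scan.n_skipped == 1
        assert np.isnan(scan.p_values.iloc[0, 0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,counts,expected,rel",
        [
            (0.05, [470_837, 1123], 9.46e-11, 5e-3),
            (0.05, [89, 2251], 2.5e-7, 5e-2),
            (0.05, [1], 0.05, 1e-12),
        ],
    )
    def test_threshold_arithmetic(self, alpha, counts, expected, rel):
        assert bonferroni_threshold(alpha, counts) == pytest.approx(expected, rel=rel)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(1.5, [10])
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(0.05, [0])


def _stepwise_inputs(planted, seed, n_samples=400, n_cpgs=300, n_proteins=30):
    cfg = SimulationConfig(
        n_samples=n_samples,
        n_cpgs=n_cpgs,
        n_proteins=n_proteins,
        planted_effects=planted,
        seed=seed,
    )
    bundle = simulate_cohort(cfg, "discovery")
    proc = preprocess_bundle(bundle)
    threshold = bonferroni_threshold(0.05, [n_cpgs, n_proteins])
    return bundle, proc, threshold


class TestRunStepwise:
    def test_sex_pairs_attributed_and_direct_pairs_survive(self):
        planted = [
            PlantedEffect(f"cg{60 + k:07d}", f"seq_{k:04d}", "sex", 0.5 if k % 2 else -0.5)
            for k in range(5)
        ] + [
            PlantedEffect(f"cg{70 + k:07d}", f"seq_{10 + k:04d}", "direct", 0.5)
            for k in range(5)
        ]
        hits_sex, hits_direct = 0, 0
        for seed in (31, 32):
            bundle, proc, threshold = _stepwise_inputs(planted, seed)
            res = run_stepwise(proc.meth, proc.prot, proc.covariates, threshold=threshold)
            ledger = {
                (r.cpg_id, r.protein_id): r.attributed_driver
                for r in res.dropout_ledger.itertuples()
            }
            finals = set(zip(res.final_set["cpg_id"], res.final_set["protein_id"]))
            hits_sex += sum(
                ledger.get((e.cpg_id, e.protein_id)) == "sex"
                for e in planted
                if e.driver == "sex"
            )
            hits_direct += sum(
                (e.cpg_id, e.protein_id) in finals for e in planted if e.driver == "direct"
            )
        assert hits_sex >= 8  # >= 4/5 per seed
        assert hits_direct >= 8

    def test_zero_effect_covariates_final_equals_step0(self):
        planted = [
            PlantedEffect(f"cg{60 + k:07d}", f"seq_{k:04d}", "direct", 0.6) for k in range(4)
        ]
        bundle, proc, threshold = _stepwise_inputs(planted, 41, n_samples=300)
        res = run_stepwise(proc.meth, proc.prot, proc.covariates, threshold=threshold)
        finals = set(zip(res.final_set["cpg_id"], res.final_set["protein_id"]))
        assert finals == res.step0_pairs()

    def test_ledger_partitions_step0_set(self):
        bundle, proc, threshold = _stepwise_inputs(None, 42, n_samples=300)
        res = run_stepwise(proc.meth, proc.prot, proc.covariates, threshold=threshold)
        ledger_pairs = list(zip(res.dropout_ledger["cpg_id"], res.dropout_ledger["protein_id"]))
        assert len(ledger_pairs) == len(set(ledger_pairs))  # each pair dropped once
        finals = set(zip(res.final_set["cpg_id"], res.final_set["protein_id"]))
        assert finals | set(ledger_pairs) == res.step0_pairs()
        assert finals.isdisjoint(ledger_pairs)


class TestSelectCisSnps:
    def _setup(self, rng, effect=0.45):
        n = 500
        dos_causal = rng.binomial(2, 0.3, n).astype(float)
        dos_null = rng.binomial(2, 0.3, n).astype(float)
        z = (dos_causal - dos_causal.mean()) / dos_causal.std()
        y = np.sqrt(effect) * z + np.sqrt(1 - effect) * rng.normal(size=n)
        feats = toy_matrix(y[:, None], "standardized", prefix="cg")
        genotypes = pd.DataFrame(
            {"snp_c": dos_causal, "snp_n": dos_null}, index=feats.data.index
        )
        positions = pd.DataFrame(
            {"feature_id": ["cg0"], "chromosome": ["1"], "start": [5_000_000], "end": [5_000_000]}
        )
        snp_positions = pd.DataFrame(
            {
                "snp_id": ["snp_c", "snp_n", "snp_far"],
                "chromosome": ["1", "1", "2"],
                "position": [5_400_000, 4_800_000, 5_000_000],
            }
        )
        genotypes["snp_far"] = rng.binomial(2, 0.3, n).astype(float)
        return feats, positions, genotypes, snp_positions

    def test_causal_snp_chosen_over_null(self, rng):
        feats, positions, genotypes, snp_positions = self._setup(rng)
        sel = select_cis_snps(feats, positions, genotypes, snp_positions)
        assert sel["cg0"] == ["snp_c"]

    def test_no_snp_in_window_empty_selection(self, rng):
        feats, positions, genotypes, snp_positions = self._setup(rng)
        positions["chromosome"] = "9"
        sel = select_cis_snps(feats, positions, genotypes, snp_positions)
        assert sel["cg0"] == []

    def test_planted_snp_selected_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            feats, positions, genotypes, snp_positions = self._setup(rng, effect=0.2)
            sel = select_cis_snps(feats, positions, genotypes, snp_positions)
            hits += sel["cg0"] == ["snp_c"]
        assert hits >= 9


class TestGenomicInflation:
    def test_all_half_p_values_give_lambda_one(self):
        assert genomic_inflation(np.full(1000, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_chi2_statistics_inflated_by_two(self, rng):
        chi2 = 2.0 * rng.chisquare(1, size=200_000)
        p = stats.chi2.sf(chi2, 1)
        assert genomic_inflation(p) == pytest.approx(2.0, abs=0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(Exception):
            genomic_inflation([])


class TestPCConfounderCheck:
    def test_planted_global_factor_flagged_far_above_noise(self, rng):
        n, n_cpg, n_prot = 500, 1000, 200
        factor = rng.normal(size=n)
        meth = rng.normal(size=(n, n_cpg))
        prot = rng.normal(size=(n, n_prot))
        prot[:, : int(0.3 * n_prot)] += 1.5 * factor[:, None]  # 30% of proteins
        meth[:, : int(0.01 * n_cpg)] += 1.5 * factor[:, None]  # 1% of CpGs
        report = pc_confounder_check(
            toy_matrix(meth, "residual", prefix="cg"),
            toy_matrix(prot, "residual", prefix="pr"),
        )
        protein_pc1 = report[(report["matrix"] == "protein") & (report["pc"] == 1)].iloc[0]
        assert protein_pc1["flagged"]
        assert protein_pc1["max_r2"] > 0.5  # factor CpGs are strongly explained

        # independent noise: max R^2 stays at the order-statistic null level,
        # far below the planted-factor signal
        noise_report = pc_confounder_check(
            toy_matrix(rng.normal(size=(n, n_cpg)), "residual", prefix="cg"),
            toy_matrix(rng.normal(size=(n, n_prot)), "residual", prefix="pr"),
        )
        assert noise_report["max_r2"].max() < 0.06

    def test_n_pcs_reduced_for_narrow_matrices(self, rng):
        report = pc_confounder_check(
            toy_matrix(rng.normal(size=(30, 4)), "residual", prefix="cg"),
            toy_matrix(rng.normal(size=(30, 5)), "residual", prefix="pr"),
            n_pcs=10,
        )
        assert report[report["matrix"] == "methylation"]["pc"].max() == 4


class TestJointModelCheck:
    def test_orthogonal_covariates_joint_equals_simple_slope(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        base = rng.normal(size=(n, 3))
        design = np.column_stack([np.ones(n), x, y])
        base -= design @ np.linalg.lstsq(design, base, rcond=None)[0]  # orthogonalize
        cov = _cov(n, rng)
        cov["age"], cov["bmi"], cov["diabetes"] = base[:, 0], base[:, 1], base[:, 2]
        meth = toy_matrix(y[:, None], "standardized", prefix="cg")
        prot = toy_matrix(x[:, None], "standardized", prefix="pr")
        meth.data.index = prot.data.index = cov.index
        simple = float(np.polyfit(x, y, 1)[0])
        out = joint_model_check(
            meth, prot, cov, [("cg0", "pr0")], covariate_names=["age", "bmi", "diabetes"],
            stepwise_slopes={("cg0", "pr0"): simple},
        )
        assert out["abs_slope_diff"].iloc[0] < 1e-8

    def test_correlated_covariates_small_slope_shift(self):
        planted = [PlantedEffect("cg0000061", "seq_0001", "direct", 0.5)]
        bundle, proc, threshold = _stepwise_inputs(planted, 52, n_samples=400)
        res = run_stepwise(proc.meth, proc.prot, proc.covariates, threshold=threshold)
        pair = ("cg0000061", "seq_0001")
        step_slope = float(res.scans[-1].slopes.at[pair[0], pair[1]])
        out = joint_model_check(
            proc.meth, proc.prot, proc.covariates, [pair],
            covariate_names=["sex", "cell", "age", "smoking", "bmi", "diabetes"],
            stepwise_slopes={pair: step_slope},
        )
        assert out["abs_slope_diff"].iloc[0] < 0.05

    def test_interaction_driven_pair_detected_by_interaction_terms(self, rng):
        n = 500
        cov = _cov(n, rng)
        sex_z = (cov["sex"] - cov["sex"].mean()) / cov["sex"].std()
        age_z = (cov["age"] - cov["age"].mean()) / cov["age"].std()
        inter = (sex_z * age_z).to_numpy()
        inter = (inter - inter.mean()) / inter.std()
        y = inter + 0.4 * rng.normal(size=n)
        x = inter + 0.4 * rng.normal(size=n)
        meth = toy_matrix(y[:, None], "standardized", prefix="cg")
        prot = toy_matrix(x[:, None], "standardized", prefix="pr")
        meth.data.index = prot.data.index = cov.index
        plain = joint_model_check(
            meth, prot, cov, [("cg0", "pr0")], covariate_names=["sex", "age"]
        )
        with_inter = joint_model_check(
            meth, prot, cov, [("cg0", "pr0")], covariate_names=["sex", "age"],
            include_interactions=True,
        )
        assert plain["joint_p"].iloc[0] < 1e-10  # looks like a pQTM without interactions
        assert with_inter["joint_p"].iloc[0] > 1e-3  # interaction explains it away
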