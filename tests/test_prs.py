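"""PRS construction: pruning, HWE fill, residualization, scan, CV, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rorp_prs import (
    InputError,
    cv_threshold_selection,
    fill_missing_genotypes,
    fit_final_weights,
    ld_prune,
    residualize_rorp,
    score_prs,
    snp_association_scan,
    standardize_prs,
)
from rorp_prs.simulate import GenotypeMatrix

from conftest import make_genotypes, make_pc_covars


def _cand(snps, pub_p):
    return pd.DataFrame({"snp": snps, "pub_p": pub_p})


def _ld(pairs):
    return pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"])


class TestLDPrune:
    def test_correlated_pair_keeps_lower_p(self):
        cand = _cand(["s1", "s2"], [1e-10, 1e-8])
        kept = ld_prune(cand, _ld([("s1", "s2", 0.3)]))
        assert kept["snp"].tolist() == ["s1"]

    def test_below_threshold_pair_both_kept(self):
        cand = _cand(["s1", "s2"], [1e-10, 1e-8])
        kept = ld_prune(cand, _ld([("s1", "s2", 0.1)]))
        assert sorted(kept["snp"]) == ["s1", "s2"]

    def test_greedy_chain(self):
        """A-B and B-C in LD, A-C free, p_A < p_B < p_C: keep {A, C}."""
        cand = _cand(["A", "B", "C"], [1e-12, 1e-10, 1e-8])
        ld = _ld([("A", "B", 0.25), ("B", "C", 0.25), ("A", "C", 0.0)])
        kept = ld_prune(cand, ld)
        assert sorted(kept["snp"]) == ["A", "C"]

    def test_invalid_r2_rejected(self):
        with pytest.raises(InputError):
            ld_prune(_cand(["a", "b"], [0.1, 0.2]), _ld([("a", "b", 1.5)]))

    def test_output_is_maximal(self):
        """Every dropped SNP conflicts with some kept SNP at the threshold."""
        rng = np.random.default_rng(0)
        snps = [f"s{i}" for i in range(30)]
        cand = _cand(snps, rng.uniform(1e-12, 1e-6, 30))
        pairs = []
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.15:
                    pairs.append((snps[i], snps[j], rng.uniform(0, 1)))
        ld = _ld(pairs)
        kept = set(ld_prune(cand, ld)["snp"])
        r2 = {frozenset((a, b)): r for a, b, r in pairs}
        for snp in set(snps) - kept:
            assert any(r2.get(frozenset((snp, k)), 0.0) >= 0.2 for k in kept)
        for a in kept:
            for b in kept:
                if a != b:
                    assert r2.get(frozenset((a, b)), 0.0) < 0.2


class TestFillMissing:
    def test_above_threshold_excluded_and_complete_passthrough(self):
        gm = make_genotypes(200, 3, seed=1)
        dos = gm.dosages.copy()
        dos.iloc[:12, 0] = np.nan  # 6% missing -> excluded
        dos.iloc[:4, 1] = np.nan   # 2% missing -> filled
        masked = GenotypeMatrix(dos, gm.snp_info)
        filled, report = fill_missing_genotypes(masked, seed=0)
        assert "rs0" not in filled.snps and report.loc["rs0", "excluded"]
        assert not filled.dosages.isna().any().any()
        # untouched SNP passes through identically
        pd.testing.assert_series_equal(filled.dosages["rs2"], gm.dosages["rs2"])

    def test_fill_matches_hwe_of_observed_frequency(self):
        gm = make_genotypes(50_000, 1, maf=0.5, seed=2)
        dos = gm.dosages.copy()
        rng = np.random.default_rng(3)
        mask = rng.random(len(dos)) < 0.04
        dos.loc[mask, "rs0"] = np.nan
        p = dos["rs0"].mean() / 2
        filled, _ = fill_missing_genotypes(GenotypeMatrix(dos, gm.snp_info), seed=4)
        fill_vals = filled.dosages.loc[mask, "rs0"]
        counts = fill_vals.value_counts().reindex([0.0, 1.0, 2.0], fill_value=0).to_numpy()
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * counts.sum()
        assert stats.chisquare(counts, f_exp=expected).pvalue > 0.001

    def test_deterministic(self):
        gm = make_genotypes(500, 4, seed=5)
        dos = gm.dosages.copy()
        dos.iloc[::30, :] = np.nan
        masked = GenotypeMatrix(dos, gm.snp_info)
        a, _ = fill_missing_genotypes(masked, seed=9)
        b, _ = fill_missing_genotypes(masked, seed=9)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)


class TestResidualize:
    def test_orthogonal_covariates_return_centered_phenotype(self):
        rng = np.random.default_rng(1)
        n = 500
        cov = make_pc_covars(n, seed=2)
        cov["study"] = "one"
        y = pd.Series(rng.normal(5, 1, n))
        # orthogonalize y against the full design (intercept + PCs) explicitly
        X = np.column_stack([np.ones(n)] + [cov[f"PC{i}"] for i in range(1, 11)])
        y_orth = y.to_numpy() - X @ np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        resid = residualize_rorp(pd.Series(y_orth, index=cov.index), cov)
        assert np.abs(resid.to_numpy() - y_orth).max() < 1e-8

    def test_perfect_linear_fit_gives_zero_residuals(self):
        cov = make_pc_covars(100, seed=3)
        y = pd.Series(3.0 * cov["PC1"].to_numpy(), index=cov.index)
        resid = residualize_rorp(y, cov)
        assert np.abs(resid).max() < 1e-10

    def test_residual_variance_matches_noise(self):
        rng = np.random.default_rng(4)
        cov = make_pc_covars(20_000, seed=4)
        y = pd.Series(2.0 * cov["PC1"] + rng.normal(0, 1, len(cov)), index=cov.index)
        resid = residualize_rorp(y, cov)
        assert abs(resid.var() - 1.0) < 0.05

    def test_rank_deficiency_names_collinear_column(self):
        cov = make_pc_covars(50, seed=5)
        cov["PC10"] = cov["PC1"]  # exact collinearity
        y = pd.Series(np.arange(50.0), index=cov.index)
        with pytest.raises(InputError, match="PC10|PC1"):
            residualize_rorp(y, cov)


class TestScan:
    def test_recovers_simulated_effect(self):
        gm = make_genotypes(2000, 50, seed=6)
        rng = np.random.default_rng(7)
        y = 0.5 * gm.dosages["rs0"] + rng.normal(0, 1, 2000)
        scan = snp_association_scan(pd.Series(y.to_numpy(), index=gm.samples), gm)
        b, se = scan.loc["rs0", "beta"], scan.loc["rs0", "se"]
        assert b - 1.96 * se < 0.5 < b + 1.96 * se

    def test_null_type_one_error_calibrated(self):
        gm = make_genotypes(2000, 226, seed=8)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(0, 1, 2000), index=gm.samples)
        scan = snp_association_scan(y, gm)
        frac = (scan["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 226)

    def test_monomorphic_snp_flagged(self):
        gm = make_genotypes(100, 2, seed=10)
        dos = gm.dosages.copy()
        dos["rs1"] = 0.0
        y = pd.Series(np.random.default_rng(0).normal(0, 1, 100), index=gm.samples)
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = snp_association_scan(y, GenotypeMatrix(dos, gm.snp_info))
        assert scan.loc["rs1", "excluded"] and np.isnan(scan.loc["rs1", "beta"])


class TestWeights:
    def test_single_snp_weight_matches_statsmodels(self):
        import statsmodels.api as sm

        gm = make_genotypes(400, 3, seed=11)
        cov = make_pc_covars(400, seed=12, index=gm.samples)
        rng = np.random.default_rng(13)
        y = pd.Series(
            0.3 * gm.dosages["rs1"] + cov["PC2"] + rng.normal(0, 1, 400),
            index=gm.samples,
        )
        w = fit_final_weights(y, cov, gm, ["rs0", "rs1", "rs2"])
        X = sm.add_constant(
            pd.concat([gm.dosages[["rs1"]], cov], axis=1).astype(float)
        )
        fit = sm.OLS(y, X).fit()
        row = w.set_index("snp").loc["rs1"]
        assert row["beta"] == pytest.approx(fit.params["rs1"], abs=1e-10)
        assert row["se"] == pytest.approx(fit.bse["rs1"], rel=1e-8)
        assert row["p"] == pytest.approx(fit.pvalues["rs1"], rel=1e-6)

    def test_adjustment_reduces_confounding_bias(self):
        """When PC1 drives both dosage structure and the phenotype, the
        covariate-adjusted weight is closer to truth than the crude scan."""
        rng = np.random.default_rng(14)
        n = 4000
        pc1 = rng.normal(0, 1, n)
        dos = rng.binomial(2, np.clip(0.3 + 0.1 * np.tanh(pc1), 0.05, 0.95)).astype(float)
        idx = pd.Index([f"S{i}" for i in range(n)], name="sample")
        gm = GenotypeMatrix(
            pd.DataFrame({"rs0": dos}, index=idx),
            pd.DataFrame(
                {"effect_allele": ["A"], "other_allele": ["G"], "maf_true": [0.3], "pub_p": [1e-9]},
                index=pd.Index(["rs0"], name="snp"),
            ),
        )
        cov = make_pc_covars(n, seed=15, index=idx)
        cov["PC1"] = pc1
        true_beta = 0.2
        y = pd.Series(true_beta * dos + 0.8 * pc1 + rng.normal(0, 1, n), index=idx)
        crude = snp_association_scan(y - y.mean(), gm).loc["rs0", "beta"]
        adjusted = fit_final_weights(y, cov, gm, ["rs0"])["beta"].iloc[0]
        assert abs(adjusted - true_beta) < abs(crude - true_beta)

    def test_null_snp_weight_ci_covers_zero(self):
        gm = make_genotypes(5000, 1, seed=16)
        cov = make_pc_covars(5000, seed=17, index=gm.samples)
        y = pd.Series(np.random.default_rng(18).normal(0, 1, 5000), index=gm.samples)
        w = fit_final_weights(y, cov, gm, ["rs0"]).iloc[0]
        assert w["beta"] - 1.96 * w["se"] < 0 < w["beta"] + 1.96 * w["se"]


class TestCV:
    def _setup(self, n, n_causal, beta, seed):
        gm = make_genotypes(n, 60, seed=seed)
        rng = np.random.default_rng(seed + 1)
        y = rng.normal(0, 1, n)
        if n_causal:
            y = y + gm.dosages.iloc[:, :n_causal].to_numpy() @ np.full(n_causal, beta)
        cov = make_pc_covars(n, seed=seed + 2, index=gm.samples)
        cand = pd.DataFrame({"snp": list(gm.snps), "pub_p": 1e-9})
        return pd.Series(y, index=gm.samples), cov, gm, cand

    def test_deterministic(self):
        y, cov, gm, cand = self._setup(600, 5, 0.2, 20)
        a = cv_threshold_selection(y, cov, gm, cand, repeats=3, seed=5)
        b = cv_threshold_selection(y, cov, gm, cand, repeats=3, seed=5)
        assert a.selected_threshold == b.selected_threshold
        np.testing.assert_array_equal(a.fold_r2, b.fold_r2)
        assert a.selected_snps == b.selected_snps

    def test_cv_r2_below_in_sample_r2_on_null(self):
        """Held-out r2 must not inherit the in-sample optimism (leakage guard)."""
        y, cov, gm, cand = self._setup(1000, 0, 0.0, 30)
        cv = cv_threshold_selection(y, cov, gm, cand, repeats=3, seed=6)
        sel = int(np.argmax(cv.mean_r2))
        assert cv.mean_r2[sel] < cv.in_sample_r2

    def test_empty_grid_rejected(self):
        y, cov, gm, cand = self._setup(200, 0, 0.0, 40)
        with pytest.raises(InputError):
            cv_threshold_selection(y, cov, gm, cand, grid=np.array([]), seed=0)


class TestScorePRS:
    def _weights(self, snps, betas):
        return pd.DataFrame(
            {"snp": snps, "effect_allele": "A", "beta": betas, "p": 0.01}
        )

    def test_hand_computed_sums(self):
        idx = pd.Index(["s1"], name="sample")
        dos = pd.DataFrame({"a": [2.0], "b": [1.0], "c": [0.0]}, index=idx)
        w = self._weights(["a", "b", "c"], [0.1, -0.2, 0.05])
        scores, coverage = score_prs(dos, w)
        assert scores.iloc[0] == pytest.approx(0.0)
        assert coverage == 1.0
        single, cov1 = score_prs(dos[["a"]], self._weights(["a"], [0.2]))
        assert single.iloc[0] == pytest.approx(0.4)

    def test_zero_weights_zero_scores(self):
        gm = make_genotypes(50, 3, seed=21)
        scores, _ = score_prs(gm, self._weights(list(gm.snps), [0.0, 0.0, 0.0]))
        assert (scores == 0).all()

    def test_additive_over_disjoint_snp_sets(self):
        gm = make_genotypes(100, 6, seed=22)
        snps = list(gm.snps)
        rng = np.random.default_rng(23)
        betas = rng.normal(0, 0.2, 6)
        full, _ = score_prs(gm, self._weights(snps, betas))
        a, _ = score_prs(gm, self._weights(snps[:3], betas[:3]))
        b, _ = score_prs(gm, self._weights(snps[3:], betas[3:]))
        assert np.allclose(full, a + b)

    def test_missing_snps_dropped_with_coverage(self):
        gm = make_genotypes(20, 2, seed=24)
        w = self._weights(["rs0", "rs1", "absent1", "absent2"], [0.1, 0.2, 0.3, 0.4])
        _, coverage = score_prs(gm, w)
        assert coverage == pytest.approx(0.5)

    def test_zero_overlap_is_an_error(self):
        gm = make_genotypes(20, 2, seed=25)
        with pytest.raises(InputError, match="no weight SNPs"):
            score_prs(gm, self._weights(["x"], [0.1]))


class TestStandardize:
    def test_zscore_moments_and_affine_invariance(self):
        rng = np.random.default_rng(26)
        x = pd.Series(rng.normal(10, 3, 500))
        z = standardize_prs(x)
        assert abs(z.mean()) < 1e-12 and abs(np.std(z) - 1) < 1e-12
        z2 = standardize_prs(7.0 * x - 3.0)
        assert np.allclose(z, z2)

    def test_log_zscore_normalizes_lognormal(self):
        rng = np.random.default_rng(27)
        x = pd.Series(np.exp(rng.normal(0, 1, 500)))
        z = standardize_prs(x, mode="log-zscore")
        assert stats.shapiro(z).pvalue > 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            standardize_prs(pd.Series([1.0]))
        with pytest.raises(InputError):
            standardize_prs(pd.Series([2.0, 2.0, 2.0]))
        with pytest.raises(InputError):
            standardize_prs(pd.Series([-1.0, 2.0]), mode="log-zscore")


def test_end_to_end_recovery_beats_half_oracle(small_cohort):
    """The built PRS recovers at least half the oracle r2 against the true
    genetic value on a development-scale cohort."""
    from rorp_prs import score_expression

    cohort = small_cohort
    scored = score_expression(
        cohort.expression, cohort.truth.samples["er_status"], cohort.centroids,
        probe_map=cohort.probe_map, n_reps=200, seed=3,
    )
    filled, _ = fill_missing_genotypes(cohort.genotypes, seed=4)
    cand = cohort.genotypes.candidates()
    cand = cand[cand["snp"].isin(filled.snps)]
    cand = ld_prune(cand, cohort.ld)
    cov = cohort.clinical[[f"PC{i}" for i in range(1, 11)] + ["study"]]
    cv = cv_threshold_selection(scored["rorp"], cov, filled, cand, repeats=3, seed=5)
    w = fit_final_weights(scored["rorp"], cov, filled, cv.selected_snps)
    prs, _ = score_prs(filled, w)
    gv = cohort.truth.samples["genetic_value"]
    r2_prs = np.corrcoef(prs, gv)[0, 1] ** 2
    oracle = cohort.truth.snp_effects
    # oracle PRS: score with the true per-dosage effects on the latent scale
    true_w = pd.DataFrame(
        {
            "snp": oracle.index,
            "effect_allele": "A",
            "beta": (oracle["subtype_weight"] + oracle["prolif_weight"]).to_numpy(),
        }
    )
    oracle_prs, _ = score_prs(cohort.genotypes_complete, true_w)
    r2_oracle = np.corrcoef(oracle_prs, gv)[0, 1] ** 2
    assert r2_prs > 0.5 * r2_oracle
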