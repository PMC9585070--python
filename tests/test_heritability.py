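import numpy as np
import pandas as pd
import pytest

from helpers import bh_stepup
from pamscape import heritability as h2
from pamscape import simulate as sim


def _annots(m, cas_frac=0.1):
    cas = np.zeros(m, dtype=np.int8)
    cas[: int(m * cas_frac)] = 1
    return pd.DataFrame({"base": np.ones(m, dtype=np.int8), "cas": cas})


class TestLDScores:
    def test_window_zero_keeps_own_term_only(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(50, 20))
        A = _annots(20, 0.5)
        L = h2.compute_ld_scores(X, np.arange(20.0), A, window_cm=0.0)
        assert np.allclose(L["base"], 1.0)
        assert np.allclose(L["cas"], A["cas"])

    def test_perfect_ld_unadjusted(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=100)
        X = np.stack([col, col], axis=1)
        L = h2.compute_ld_scores(
            X, np.array([0.0, 0.1]), _annots(2, 1.0), window_cm=1.0, adjusted=False
        )
        assert np.allclose(L["base"], 2.0)

    def test_independent_snps_adjusted_mean_near_one(self):
        """The n-adjusted estimator removes the 1/n inflation: for
        unlinked SNPs the LD score averages to its own term."""
        spec = sim.SimSpec(n=120, m=400, block_size=1, rho=0.0, seed=7, cm_per_mb=1e6)
        X, panel = sim.generate_genotypes(spec)
        A = pd.DataFrame({"base": np.ones(400, dtype=np.int8)})
        L = h2.compute_ld_scores(X, panel["cm"].to_numpy(), A, window_cm=np.inf)
        raw = h2.compute_ld_scores(
            X, panel["cm"].to_numpy(), A, window_cm=np.inf, adjusted=False
        )
        assert abs(L["base"].mean() - 1.0) < 0.2
        assert raw["base"].mean() > L["base"].mean() + 1.0  # 1/n bias accumulates

    def test_sub_annotation_bounded_by_base_unadjusted(self):
        # with the raw (non-negative) r2 estimator, an annotation's score
        # can never exceed the all-SNPs score; the bias-adjusted estimator
        # may break this through negative terms, so it is not asserted there
        spec = sim.SimSpec(n=80, m=300, block_size=20, rho=0.6, seed=8)
        X, panel = sim.generate_genotypes(spec)
        A = _annots(300, 0.3)
        L = h2.compute_ld_scores(X, panel["cm"].to_numpy(), A, window_cm=1.0,
                                 adjusted=False)
        assert (L["cas"] <= L["base"] + 1e-9).all()

    def test_monomorphic_excluded_with_warning(self):
        X = np.ones((30, 3))
        X[:, 1] = np.arange(30) % 2
        X[:, 2] = np.arange(30) % 3
        with pytest.warns(UserWarning, match="monomorphic"):
            L = h2.compute_ld_scores(
                X, np.array([0.0, 0.01, 0.02]), pd.DataFrame({"base": [1, 1, 1]})
            )
        assert np.isnan(L["base"].iloc[0])
        assert np.isfinite(L["base"].iloc[1:]).all()


class TestStratifiedRegression:
    def _ldscores(self, m, seed=0):
        rng = np.random.default_rng(seed)
        base = 1.0 + rng.gamma(2.0, 4.0, size=m)
        cas = base * (np.arange(m) < m // 10)
        return pd.DataFrame({"base": base, "cas": cas})

    def test_noiseless_identification(self):
        m, n = 5000, 10_000
        L = self._ldscores(m)
        tau = np.array([3e-5, 8e-5])
        chi2 = 1.0 + n * L.to_numpy() @ tau
        fit = h2.stratified_regression(chi2, L, n, weights="none")
        assert np.allclose(fit.tau.to_numpy(), tau, rtol=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_null_trait_recovers_intercept_one(self):
        rng = np.random.default_rng(3)
        m = 8000
        L = self._ldscores(m, seed=4)
        chi2 = rng.chisquare(1, size=m)
        fit = h2.stratified_regression(chi2, L, 10_000.0)
        assert fit.intercept == pytest.approx(1.0, abs=0.1)
        assert abs(fit.tau["base"]) * 10_000 * L["base"].mean() * m < 0.5 * m  # tiny signal

    def test_duplicated_annotation_rejected(self):
        L = self._ldscores(100)
        L["dup"] = L["base"]
        with pytest.raises(ValueError, match="collinear"):
            h2.stratified_regression(np.ones(100), L, 1000.0)

    def test_explicit_weights_validated(self):
        L = self._ldscores(50)
        with pytest.raises(ValueError):
            h2.stratified_regression(np.ones(50), L, 100.0, weights=np.zeros(50))


class TestPartition:
    def test_all_snps_annotation_enrichment_one(self):
        A = pd.DataFrame({"base": np.ones(100, dtype=np.int8)})
        out = h2.partition_and_enrich(np.array([1e-4]), A)
        assert out.loc["base", "enrichment"] == pytest.approx(1.0)

    def test_share_arithmetic(self):
        # h2 share 0.35 on a 10% annotation -> enrichment 3.5
        A = _annots(1000, 0.1)
        tau_base = 0.65 / 900
        tau_cas = 0.35 / 100 - tau_base
        out = h2.partition_and_enrich(np.array([tau_base, tau_cas]), A)
        assert out.loc["cas", "h2_share"] == pytest.approx(0.35)
        assert out.loc["cas", "enrichment"] == pytest.approx(3.5)

    def test_empty_annotation_rejected(self):
        A = pd.DataFrame({"base": np.ones(10, dtype=np.int8), "empty": np.zeros(10, dtype=np.int8)})
        with pytest.raises(ValueError, match="empty"):
            h2.partition_and_enrich(np.array([1e-4, 0.0]), A)

    def test_disjoint_partition_telescopes_to_one(self):
        """Enrichments of a disjoint cover, weighted by SNP share, sum to 1."""
        rng = np.random.default_rng(9)
        m = 300
        labels = rng.integers(0, 3, size=m)
        A = pd.DataFrame({f"g{i}": (labels == i).astype(np.int8) for i in range(3)})
        out = h2.partition_and_enrich(np.array([1e-5, 5e-5, 9e-5]), A)
        total = (out["enrichment"] * out["snp_share"]).sum()
        assert total == pytest.approx(1.0)


class TestJackknife:
    def test_sample_mean_closed_form(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        n = len(x)
        deletes = np.array([(x.sum() - xi) / (n - 1) for xi in x])
        se = h2.jackknife_se(deletes[:, None])[0]
        assert se == pytest.approx(x.std(ddof=1) / np.sqrt(n))

    def test_constant_estimates_zero_se(self):
        assert h2.jackknife_se(np.full((10, 2), 3.3)).tolist() == [0.0, 0.0]

    def test_wls_delete_blocks_match_direct_refit(self):
        rng = np.random.default_rng(12)
        m = 200
        L = pd.DataFrame({"base": 1 + rng.gamma(2, 2, m)})
        chi2 = 1 + 500 * L["base"] * 2e-4 + rng.normal(0, 0.5, m)
        fit = h2.stratified_regression(chi2.to_numpy(), L, 500.0, weights="none")
        dels = h2.delete_block_estimates(fit, n_blocks=4)
        # refit by hand with block 0 removed
        keep = np.ones(m, bool)
        keep[:50] = False
        direct, *_ = np.linalg.lstsq(fit.design[keep], fit.y[keep], rcond=None)
        assert np.allclose(dels[0], direct)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            h2._block_bounds(100, 1)

    def test_wald_p_of_zero_estimate_is_one(self):
        assert h2.wald_p(np.array([0.0]), np.array([0.5]))[0] == 1.0


class TestBHFDR:
    def test_stepup_example(self):
        flags = h2.bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_none_significant(self):
        assert not h2.bh_fdr(np.ones(5)).any()

    def test_single_p(self):
        assert h2.bh_fdr(np.array([0.04]), q=0.05)[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            h2.bh_fdr(np.array([0.5, 1.2]))

    def test_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(rng.integers(1, 20))
            assert (h2.bh_fdr(p, 0.05) == bh_stepup(p, 0.05)).all()


class TestEndToEnd:
    def test_planted_enrichment_recovered_single_replicate(self):
        spec = sim.SimSpec(n=150, m=4000, block_size=25, rho=0.7, seed=21,
                           cm_per_mb=20.0, length=2_000_000)
        X, panel = sim.generate_genotypes(spec)
        A = _annots(4000, 0.1)
        L = h2.compute_ld_scores(X, panel["cm"].to_numpy(), A, window_cm=1.0)
        ss, tau = sim.simulate_sumstats(
            panel, A, n_gwas=40_000, target_enrichment={"cas": 3.5},
            mode="model", ldscores=L, seed=22,
        )
        res = h2.enrichment_analysis(ss["Z"].to_numpy() ** 2, L, A, 40_000, n_blocks=100)
        est, se = res.loc["cas", "enrichment"], res.loc["cas", "enrichment_se"]
        assert abs(est - 3.5) < 3 * se
        assert res.loc["cas", "enrichment_p"] < 0.05

    def test_genotype_level_chi2_matches_model_mean(self):
        spec = sim.SimSpec(n=800, m=1500, block_size=10, rho=0.5, seed=31, cm_per_mb=50.0)
        X, panel = sim.generate_genotypes(spec)
        A = _annots(1500, 0.2)
        L = h2.compute_ld_scores(X, panel["cm"].to_numpy(), A, window_cm=1.0)
        ss, tau = sim.simulate_sumstats(
            panel, A, n_gwas=0, tau={"base": 0.3 / 1500, "cas": 0.3 / 1500},
            mode="genotype", genotypes=X, seed=32,
        )
        predicted = 1.0 + ss["N"].iloc[0] * (L.to_numpy() @ tau.to_numpy())
        observed = ss["Z"].to_numpy() ** 2
        # means agree within Monte-Carlo error of a chi-square sample
        assert observed.mean() == pytest.approx(predicted.mean(), rel=0.15)
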