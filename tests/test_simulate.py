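import numpy as np
import pandas as pd
import pytest

from pamscape import landscape as ls
from pamscape import simulate as sim
from pamscape.overlap import fisher_or


class TestGenerateGenome:
    def test_block_gc_concentrates_near_target(self):
        spec = sim.GenomeSpec(
            chrom_lengths={"1": 100_000}, gc_blocks=(("1", 20_000, 70_000, 0.8),), seed=3
        )
        seq = sim.generate_genome(spec)["1"]
        block = seq[20_000:70_000]
        gc = (block.count("G") + block.count("C")) / len(block)
        assert 0.78 <= gc <= 0.82

    def test_n_run_placed_exactly(self, toy_genome_spec):
        seq = sim.generate_genome(toy_genome_spec)["2"]
        assert set(seq[:10_000]) == {"N"}
        assert "N" not in seq[10_000:]

    def test_planted_motifs_present_at_density(self):
        spec = sim.GenomeSpec(
            chrom_lengths={"1": 50_000},
            background_gc=0.0,  # A/T background cannot produce GGCG by chance
            motif_blocks=(("GGCG", "1", 0, 50_000, 0.002),),
            seed=4,
        )
        seq = sim.generate_genome(spec)["1"]
        n_hits = len({off for off, s in ls.match_positions(seq, "GGCG", "forward")})
        assert 60 <= n_hits <= 140  # Poisson(100) concentration

    def test_n_wins_over_motif_with_warning(self):
        spec = sim.GenomeSpec(
            chrom_lengths={"1": 1000},
            motif_blocks=(("GGCG", "1", 0, 1000, 0.05),),
            n_runs=(("1", 0, 1000),),
            seed=5,
        )
        with pytest.warns(UserWarning, match="overwrites"):
            seq = sim.generate_genome(spec)["1"]
        assert set(seq) == {"N"}

    def test_seed_determinism(self, toy_genome_spec):
        assert sim.generate_genome(toy_genome_spec) == sim.generate_genome(toy_genome_spec)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            sim.GenomeSpec(chrom_lengths={"1": 100}, gc_blocks=(("1", 0, 200, 0.5),))


class TestGenerateGenotypes:
    def test_independent_snps_r2_near_1_over_n(self):
        spec = sim.SimSpec(n=100, m=200, block_size=1, rho=0.0, seed=6)
        X, _ = sim.generate_genotypes(spec)
        Xs = (X - X.mean(0)) / X.std(0)
        C = (Xs.T @ Xs / 100) ** 2
        off = C[~np.eye(200, dtype=bool)]
        assert off.mean() == pytest.approx(1 / 100, rel=0.3)

    def test_block_structure_in_r2(self):
        spec = sim.SimSpec(n=200, m=100, block_size=20, rho=0.9, seed=7)
        X, _ = sim.generate_genotypes(spec)
        Xs = (X - X.mean(0)) / X.std(0)
        C = (Xs.T @ Xs / 200) ** 2
        within = C[:20, :20][~np.eye(20, dtype=bool)].mean()
        between = C[:20, 20:40].mean()
        assert within > 5 * between

    def test_panel_is_sorted_with_cm_map(self):
        X, panel = sim.generate_genotypes(sim.SimSpec(n=10, m=50, seed=8, cm_per_mb=2.0))
        assert (np.diff(panel["pos"]) > 0).all()
        assert np.allclose(panel["cm"], panel["pos"] / 1e6 * 2.0)
        assert X.shape == (10, 50)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            sim.SimSpec(n=10, m=10, rho=1.0)

    def test_seed_determinism(self):
        spec = sim.SimSpec(n=20, m=30, seed=9)
        X1, p1 = sim.generate_genotypes(spec)
        X2, p2 = sim.generate_genotypes(spec)
        assert (X1 == X2).all() and p1.equals(p2)


class TestSimulateSumstats:
    def _setup(self, m=2000, seed=10):
        rng = np.random.default_rng(seed)
        panel = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(m)], "chrom": "1",
             "pos": np.arange(1, m + 1), "a1": "A", "a2": "G",
             "maf": 0.3, "cm": np.arange(m) * 1e-3}
        )
        A = pd.DataFrame(
            {"base": np.ones(m, dtype=np.int8),
             "cas": (np.arange(m) < m // 10).astype(np.int8)}
        )
        L = pd.DataFrame({"base": 1 + rng.gamma(2, 3, m)})
        L["cas"] = L["base"] * A["cas"]
        return panel, A, L

    def test_null_mean_chi2_near_one(self):
        panel, A, L = self._setup()
        ss, tau = sim.simulate_sumstats(panel, A, n_gwas=10_000, mode="model",
                                        ldscores=L, seed=11)
        assert (tau == 0).all()
        assert (ss["Z"] ** 2).mean() == pytest.approx(1.0, abs=0.1)

    def test_target_enrichment_realizes_h2_share(self):
        panel, A, L = self._setup()
        _, tau = sim.simulate_sumstats(
            panel, A, n_gwas=10_000, target_enrichment={"cas": 3.5}, h2=0.4,
            mode="model", ldscores=L, seed=12,
        )
        per_snp = A.to_numpy(float) @ tau.to_numpy()
        share = per_snp[A["cas"] == 1].sum() / per_snp.sum()
        assert share == pytest.approx(0.35)
        assert per_snp.sum() == pytest.approx(0.4)

    def test_tau_and_enrichment_mutually_exclusive(self):
        panel, A, L = self._setup(m=100)
        with pytest.raises(ValueError, match="not both"):
            sim.simulate_sumstats(panel, A, n_gwas=100, tau={"base": 1e-4},
                                  target_enrichment={"cas": 2.0}, ldscores=L)

    def test_overcommitted_enrichment_rejected(self):
        panel, A, L = self._setup(m=100)
        with pytest.raises(ValueError, match="more than 100%"):
            sim.simulate_sumstats(panel, A, n_gwas=100,
                                  target_enrichment={"cas": 15.0}, ldscores=L)

    def test_seed_determinism(self):
        panel, A, L = self._setup(m=500)
        ss1, _ = sim.simulate_sumstats(panel, A, 1000, mode="model", ldscores=L, seed=13)
        ss2, _ = sim.simulate_sumstats(panel, A, 1000, mode="model", ldscores=L, seed=13)
        assert ss1.equals(ss2)


class TestFunctionalAnnotations:
    def test_zero_slope_independent_of_gc(self):
        rng = np.random.default_rng(14)
        gc = rng.random(30_000)
        annots = sim.generate_functional_annotations(gc, {"f": 0.0}, prevalence=0.2, seed=15)
        gc_top = (gc > np.quantile(gc, 0.8)).astype(int)
        res = fisher_or(annots["f"].to_numpy(), gc_top)
        assert abs(res.log_or) < 0.12
        assert res.p > 0.001

    def test_positive_slope_couples_to_gc(self):
        rng = np.random.default_rng(16)
        gc = rng.random(30_000)
        annots = sim.generate_functional_annotations(gc, {"f": 2.0}, prevalence=0.2, seed=17)
        gc_top = (gc > np.quantile(gc, 0.8)).astype(int)
        res = fisher_or(annots["f"].to_numpy(), gc_top)
        assert res.log_or > 0.5 and res.p < 1e-10

    def test_prevalence_approximate(self):
        gc = np.random.default_rng(18).random(50_000)
        annots = sim.generate_functional_annotations(gc, {"f": 0.0}, prevalence=0.1, seed=19)
        assert annots["f"].mean() == pytest.approx(0.1, abs=0.01)

    def test_seed_determinism(self):
        gc = np.linspace(0, 1, 1000)
        a1 = sim.generate_functional_annotations(gc, {"f": 1.0}, seed=20)
        a2 = sim.generate_functional_annotations(gc, {"f": 1.0}, seed=20)
        assert a1.equals(a2)


class TestOffTargetSites:
    def test_zero_coupling_uniform(self, toy_concat, toy_plan):
        counts = np.zeros(len(toy_plan))
        sites = sim.generate_offtarget_sites(toy_concat, toy_plan, counts,
                                             coupling=0.0, n_sites=2000, seed=21)
        occupancy = sites["segment"].value_counts()
        assert len(occupancy) > 25  # nearly every segment hit
        assert occupancy.max() < 2000 * 0.1

    def test_all_zero_counts_with_coupling_warns(self, toy_concat, toy_plan):
        with pytest.warns(UserWarning, match="uniform"):
            sim.generate_offtarget_sites(toy_concat, toy_plan,
                                         np.zeros(len(toy_plan)), coupling=1.0,
                                         n_sites=10, seed=22)

    def test_positions_fall_inside_their_segment(self, toy_concat, toy_plan):
        counts = np.arange(1, len(toy_plan) + 1, dtype=float)
        sites = sim.generate_offtarget_sites(toy_concat, toy_plan, counts,
                                             coupling=1.0, n_sites=500, seed=23)
        for _, row in sites.iterrows():
            cpos = toy_concat.to_concat(row["chrom"], row["pos"] - 1)
            s, e = toy_plan[row["segment"]]
            assert s <= cpos < e

    def test_seed_determinism(self, toy_concat, toy_plan):
        counts = np.ones(len(toy_plan))
        s1 = sim.generate_offtarget_sites(toy_concat, toy_plan, counts, n_sites=50, seed=24)
        s2 = sim.generate_offtarget_sites(toy_concat, toy_plan, counts, n_sites=50, seed=24)
        assert s1.equals(s2)
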