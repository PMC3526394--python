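"""Cross simulator: determinism, Mendelian structure, Haldane calibration."""

import math

import numpy as np
import pytest

from bsamap import (
    RelocatedBlock,
    SimConfig,
    haldane_theta,
    join_pools,
    place_markers,
    read_pileup,
    run_simulation,
    sequence_pool,
    simulate_cross,
    simulate_dataset,
    simulate_gametes,
)
from bsamap.simulate import assembly_coordinates, assembly_scaffold_lengths


class TestHaldane:
    def test_zero_distance_never_switches(self):
        assert haldane_theta(0, 1.2) == 0.0

    def test_infinite_distance_half(self):
        assert haldane_theta(1e12, 1.2) == pytest.approx(0.5)

    def test_one_centimorgan_closed_form(self):
        # 1 cM -> theta = (1 - e^-0.02)/2
        d_bp = 1e6 / 1.2  # one cM at 1.2 cM/Mb
        assert haldane_theta(d_bp, 1.2) == pytest.approx((1 - math.exp(-0.02)) / 2)
        assert haldane_theta(d_bp, 1.2) == pytest.approx(0.00990, abs=1e-5)


class TestPlaceMarkers:
    def test_expected_marker_count(self, rng):
        cfg = SimConfig(scaffolds={"s01": 1_000_000}, causal=("s01", 500_000),
                        snp_spacing_bp=10_000)
        df = place_markers(cfg, rng)
        assert 60 <= len(df) <= 140  # Poisson around 100

    def test_causal_always_a_marker(self, rng):
        cfg = SimConfig(scaffolds={"s01": 50_000}, causal=("s01", 42_000),
                        snp_spacing_bp=200_000)
        df = place_markers(cfg, rng)
        assert ((df["chrom"] == "s01") & (df["pos"] == 42_000)).any()

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=7)
        a = place_markers(cfg, np.random.default_rng(7))
        b = place_markers(cfg, np.random.default_rng(7))
        assert a.equals(b)

    def test_alleles_distinct(self, rng):
        df = place_markers(SimConfig(), rng)
        assert (df["n_allele"] != df["map_allele"]).all()

    def test_positions_sorted_within_scaffold(self, rng):
        df = place_markers(SimConfig(), rng)
        for _, grp in df.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_analytic_expectations(self, rng):
        df = place_markers(SimConfig(causal=("s01", 1_000_000)), rng)
        causal = df[(df["chrom"] == "s01") & (df["pos"] == 1_000_000)].iloc[0]
        assert causal["exp_mut_n_freq"] == pytest.approx(1.0)
        assert causal["exp_wt_n_freq"] == pytest.approx(1 / 3)
        unlinked = df[df["chrom"] == "s02"]
        assert (unlinked["exp_mut_n_freq"] == 0.5).all()
        assert (unlinked["exp_wt_n_freq"] == 0.5).all()


class TestGametes:
    def test_zero_separation_never_switches(self, rng):
        g = simulate_gametes(np.array([100, 100 + 0]), 1.2, rng, 500)
        assert (g[:, 0] == g[:, 1]).all()

    def test_conditional_recombination_matches_theta(self):
        rng = np.random.default_rng(99)
        pos = np.array([1, 1_000_001])
        g = simulate_gametes(pos, 1.2, rng, 200_000)
        cond = g[g[:, 0] == 0]
        theta = haldane_theta(1_000_000, 1.2)
        se = math.sqrt(theta * (1 - theta) / len(cond))
        assert abs(cond[:, 1].mean() - theta) < 3 * se

    def test_empty_and_single_marker(self, rng):
        assert simulate_gametes(np.array([]), 1.2, rng, 5).shape == (5, 0)
        assert simulate_gametes(np.array([10]), 1.2, rng, 5).shape == (5, 1)


class TestCross:
    def test_every_mutant_embryo_n_hom_at_causal(self, small_config, small_dataset):
        truth, _, _ = small_dataset
        ci = truth.causal_index
        assert (truth.mut_genotypes[:, :, ci] == 0).all()

    def test_no_wildtype_embryo_n_hom_at_causal(self, small_dataset):
        truth, _, _ = small_dataset
        ci = truth.causal_index
        assert not ((truth.wt_genotypes[:, :, ci] == 0).all(axis=1)).any()

    def test_pool_sizes(self, small_config, small_dataset):
        truth, _, _ = small_dataset
        assert truth.mut_genotypes.shape[0] == small_config.n_mut_embryos
        assert truth.wt_genotypes.shape[0] == small_config.n_wt_embryos

    def test_wt_pool_n_freq_near_one_third_at_causal(self):
        """Phenotype-sorted WT bulks are 2:1 het:mapcross-hom at the causal
        locus, so the N allele sits at expected frequency 1/3 there."""
        freqs = []
        n_chrom = 0
        for seed in range(50, 60):
            cfg = SimConfig(scaffolds={"s01": 200_000}, causal=("s01", 100_000),
                            snp_spacing_bp=50_000, n_mut_embryos=5,
                            n_wt_embryos=40, seed=seed)
            rng = np.random.default_rng(cfg.seed)
            truth = simulate_cross(cfg, rng, place_markers(cfg, rng))
            freqs.append(truth.pool_n_freq("wt")[truth.causal_index])
            n_chrom += 2 * cfg.n_wt_embryos
        mean = np.mean(freqs)
        se = math.sqrt((1 / 3) * (2 / 3) / n_chrom)
        assert abs(mean - 1 / 3) < 3 * se

    def test_rejection_budget_error(self):
        cfg = SimConfig(n_mut_embryos=50, n_wt_embryos=50, max_rejection_draws=10)
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError, match="rejection budget"):
            simulate_cross(cfg, rng, place_markers(cfg, rng))


class TestSequencing:
    def test_counts_sum_to_drawn_depth(self, small_dataset):
        _, wt, mut = small_dataset
        for site in wt + mut:
            assert sum(site.counts.values()) == site.depth_reported
            assert site.skipped == 0

    def test_error_free_fixed_pool_is_monomorphic(self):
        cfg = SimConfig(scaffolds={"s01": 100_000}, causal=("s01", 50_000),
                        snp_spacing_bp=10_000, n_mut_embryos=10, n_wt_embryos=10,
                        error_rate=0.0, seed=4)
        truth, _, mut = simulate_dataset(cfg)
        ci = truth.causal_index
        causal_site = next(
            s for s in mut if s.pos == truth.markers["pos"].iloc[ci]
        )
        n_allele = truth.markers["n_allele"].iloc[ci]
        assert causal_site.counts[n_allele] == causal_site.depth_reported

    def test_mean_depth_matches_poisson_mean(self):
        cfg = SimConfig(scaffolds={"s01": 3_000_000}, causal=("s01", 1_500_000),
                        snp_spacing_bp=300, n_mut_embryos=5, n_wt_embryos=5,
                        depth_mean=30.0, seed=8)
        _, wt, _ = simulate_dataset(cfg)
        assert len(wt) > 8_000
        mean = np.mean([s.depth_reported for s in wt])
        assert abs(mean - 30.0) / 30.0 < 0.05

    def test_high_error_flattens_major_fraction(self):
        def mean_maf(err):
            cfg = SimConfig(scaffolds={"s01": 500_000}, causal=("s01", 250_000),
                            snp_spacing_bp=5_000, n_mut_embryos=10, n_wt_embryos=10,
                            error_rate=err, seed=9)
            _, _, mut = simulate_dataset(cfg)
            return np.mean([max(s.counts.values()) / s.depth for s in mut if s.depth])

        assert mean_maf(0.5) < mean_maf(0.0)


class TestRunSimulation:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(scaffolds={"s01": 300_000, "s02": 300_000},
                        causal=("s01", 150_000), snp_spacing_bp=20_000,
                        n_mut_embryos=10, n_wt_embryos=10, seed=3)
        p1 = run_simulation(cfg, tmp_path / "a", gzip_output=False)
        p2 = run_simulation(cfg, tmp_path / "b", gzip_output=False)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_output_parses_and_joins_without_loss(self, tmp_path):
        cfg = SimConfig(scaffolds={"s01": 300_000}, causal=("s01", 150_000),
                        snp_spacing_bp=10_000, n_mut_embryos=10, n_wt_embryos=10,
                        seed=5)
        paths = run_simulation(cfg, tmp_path, gzip_output=True)
        wt = list(read_pileup(str(paths["wt_pileup"])))
        mut = list(read_pileup(str(paths["mut_pileup"])))
        joined = list(join_pools(iter(wt), iter(mut)))
        assert len(joined) == len(wt) == len(mut)


class TestMisassemblyFixture:
    def test_relocated_markers_change_coordinates_only(self, rng):
        block = RelocatedBlock("s01", 1, 500_000, "s05")
        cfg = SimConfig(relocate_block=block, seed=2)
        markers = place_markers(cfg, rng)
        asm = assembly_coordinates(markers, cfg)
        moved = asm[asm["chrom"] != asm["asm_chrom"]]
        assert (moved["chrom"] == "s01").all()
        assert (moved["asm_chrom"] == "s05").all()
        assert (moved["pos"] <= 500_000).all()
        assert (moved["asm_pos"] > cfg.scaffolds["s05"]).all()
        lengths = assembly_scaffold_lengths(cfg)
        assert lengths["s05"] == cfg.scaffolds["s05"] + 500_000
        untouched = asm[asm["chrom"] != "s01"]
        assert (untouched["pos"] == untouched["asm_pos"]).all()
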