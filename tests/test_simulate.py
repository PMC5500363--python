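"""Tests of the synthetic cross, coverage and expression generators."""

import numpy as np
import pandas as pd
import pytest

from bsakit import (
    CrossConfig,
    DepthModel,
    GenomeSpec,
    assign_phenotypes,
    simulate_coverage,
    simulate_expression,
    simulate_meiosis,
    simulate_parent_sites,
    simulate_pool_reads,
)
from bsakit.simulate import (
    INTERMEDIATE,
    RESISTANT_EVOLVED,
    RESISTANT_PARENTAL,
    SENSITIVE,
    simulate_parent_counts,
)


class TestParentSites:
    def test_single_site_forced_allocation(self, single_chromosome):
        sites = simulate_parent_sites(1, single_chromosome, seed=0)
        assert len(sites) == 1
        assert sites["chrom"].iloc[0] == "chr1"
        assert 1 <= sites["pos"].iloc[0] <= 1000

    def test_counts_proportional_to_length(self):
        genome = GenomeSpec()
        n = 18_000
        sites = simulate_parent_sites(n, genome, seed=1)
        counts = sites.groupby("chrom", sort=False).size()
        total = genome.total_length
        for chrom, length in genome.chromosomes:
            p = length / total
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[chrom] - n * p) < 3 * sigma, chrom

    def test_sorted_unique_within_bounds(self, tiny_genome):
        sites = simulate_parent_sites(500, tiny_genome, seed=3)
        for chrom, sub in sites.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            assert (np.diff(pos) > 0).all()
            assert pos.min() >= 1 and pos.max() <= tiny_genome.length_of(chrom)

    def test_infeasible_density_raises(self, single_chromosome):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_parent_sites(2000, single_chromosome, seed=0)

    def test_seed_reproducibility(self, tiny_genome):
        a = simulate_parent_sites(200, tiny_genome, seed=5)
        b = simulate_parent_sites(200, tiny_genome, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestMeiosis:
    def test_zero_recombination_gives_whole_chromosome_haplotypes(self, single_chromosome):
        sites = simulate_parent_sites(20, single_chromosome, seed=1)
        cross = CrossConfig(
            n_segregants=50, qtl_major=("chr1", 500), qtl_minor=("chr1", 900), seed=2
        )
        segs = simulate_meiosis(sites, cross, single_chromosome)
        row_means = segs.genotypes.mean(axis=1)
        assert set(np.round(row_means, 6)) <= {0.0, 1.0}

    def test_haldane_recombinant_fraction(self):
        # two markers 50 cM apart: c = (1 - exp(-1)) / 2 ~ 0.3161
        genome = GenomeSpec(
            chromosomes=(("chr1", 200_000),), recombination_rate=1.0  # 1 cM/kb
        )
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [50_000, 100_000],
             "ref": ["A", "A"], "alt": ["T", "T"]}
        )
        cross = CrossConfig(
            n_segregants=10_000, qtl_major=("chr1", 1), qtl_minor=("chr1", 2), seed=7
        )
        segs = simulate_meiosis(sites, cross, genome)
        recomb = (segs.genotypes[:, 0] != segs.genotypes[:, 1]).mean()
        expected = (1 - np.exp(-1)) / 2
        assert abs(recomb - expected) < 0.01

    def test_marginal_allele_frequency_is_half(self, tiny_genome):
        sites = simulate_parent_sites(50, tiny_genome, seed=4)
        cross = CrossConfig(
            n_segregants=2000, qtl_major=("chrA", 1), qtl_minor=("chrB", 1), seed=4
        )
        segs = simulate_meiosis(sites, cross, tiny_genome)
        freqs = segs.genotypes.mean(axis=0)
        sigma = 0.5 / np.sqrt(cross.n_segregants)
        assert (np.abs(freqs - 0.5) < 3 * sigma + 1e-9).mean() > 0.97

    def test_haplotype_blocks_piecewise_constant(self, tiny_genome):
        # with a short genome the number of switches along a chromosome is
        # bounded by the Poisson crossover count, far below the site count
        sites = simulate_parent_sites(300, tiny_genome, seed=9)
        cross = CrossConfig(
            n_segregants=30, qtl_major=("chrA", 1), qtl_minor=("chrB", 1), seed=9
        )
        segs = simulate_meiosis(sites, cross, tiny_genome)
        for chrom in tiny_genome.names:
            idx = np.flatnonzero(segs.sites["chrom"].to_numpy() == chrom)
            sub = segs.genotypes[:, idx]
            switches = (np.diff(sub, axis=1) != 0).sum(axis=1)
            assert switches.max() <= 12  # ~0.35-2.1 cM chromosomes


class TestPhenotypes:
    @pytest.fixture
    def cross_genome(self):
        return GenomeSpec(chromosomes=(("chrA", 500_000), ("chrB", 500_000)))

    def test_two_locus_mendelian_fractions(self, cross_genome):
        sites = simulate_parent_sites(40, cross_genome, seed=1)
        cross = CrossConfig(
            n_segregants=8000,
            qtl_major=("chrA", 250_000),
            qtl_minor=("chrB", 250_000),
            intermediate_fraction=0.0,
            seed=1,
        )
        segs = assign_phenotypes(simulate_meiosis(sites, cross, cross_genome), cross)
        frac = pd.Series(segs.phenotypes).value_counts(normalize=True)
        assert abs(frac[SENSITIVE] - 0.5) < 0.02
        assert abs(frac[RESISTANT_PARENTAL] - 0.25) < 0.02
        assert abs(frac[RESISTANT_EVOLVED] - 0.25) < 0.02
        assert INTERMEDIATE not in frac

    def test_observed_study_configuration_is_realizable(self):
        # 69 segregants, intermediate_fraction 0.4: some seed yields the
        # observed 37 Sensitive / 9 / 9 / 14 Intermediate split
        genome = GenomeSpec()
        target = {SENSITIVE: 37, RESISTANT_PARENTAL: 9, RESISTANT_EVOLVED: 9, INTERMEDIATE: 14}
        sites = simulate_parent_sites(500, genome, seed=0)
        for seed in range(400):
            cross = CrossConfig(seed=seed)
            segs = assign_phenotypes(simulate_meiosis(sites, cross, genome), cross)
            counts = pd.Series(segs.phenotypes).value_counts().to_dict()
            if counts == target:
                return
        pytest.fail("observed 37/9/9/14 configuration never realized in 400 seeds")

    def test_all_reference_at_major_locus_means_all_sensitive(self, cross_genome):
        sites = simulate_parent_sites(40, cross_genome, seed=2)
        cross = CrossConfig(
            n_segregants=100, qtl_major=("chrA", 250_000), qtl_minor=("chrB", 250_000), seed=2
        )
        segs = simulate_meiosis(sites, cross, cross_genome)
        segs.genotypes[:, :] = 0
        segs = assign_phenotypes(segs, cross)
        assert (segs.phenotypes == SENSITIVE).all()

    def test_qtl_off_genome_raises(self, cross_genome):
        sites = simulate_parent_sites(40, cross_genome, seed=3)
        cross = CrossConfig(
            n_segregants=10, qtl_major=("chrA", 999_999_999), qtl_minor=("chrB", 1), seed=3
        )
        with pytest.raises(ValueError, match="outside"):
            simulate_meiosis(sites, cross, cross_genome)


class TestPoolReads:
    @pytest.fixture
    def labeled_cross(self, tiny_genome):
        sites = simulate_parent_sites(200, tiny_genome, seed=6)
        cross = CrossConfig(
            n_segregants=60,
            qtl_major=("chrC", 300_000),
            qtl_minor=("chrB", 150_000),
            intermediate_fraction=0.0,
            seed=6,
        )
        return assign_phenotypes(simulate_meiosis(sites, cross, tiny_genome), cross), cross

    def test_full_selection_no_error_gives_pure_reads(self, labeled_cross):
        segs, cross = labeled_cross
        segs.genotypes[:, :] = 1
        segs.phenotypes[:] = RESISTANT_EVOLVED
        counts = simulate_pool_reads(segs, RESISTANT_EVOLVED, DepthModel(50, 0.0, seed=1))
        assert (counts["ref_depth"] == 0).all()

    def test_mean_alternate_fraction_near_half(self):
        genome = GenomeSpec(chromosomes=(("chr1", 10_000_000),))
        sites = simulate_parent_sites(10_000, genome, seed=3)
        cross = CrossConfig(
            n_segregants=2, qtl_major=("chr1", 1), qtl_minor=("chr1", 2), seed=3
        )
        segs = simulate_meiosis(sites, cross, genome)
        segs.genotypes[0, :] = 0
        segs.genotypes[1, :] = 1  # pool frequency exactly 0.5 everywhere
        segs.phenotypes = np.array([SENSITIVE, SENSITIVE])
        counts = simulate_pool_reads(segs, SENSITIVE, DepthModel(80, 0.0, seed=3))
        frac = counts["alt_depth"].sum() / (counts["ref_depth"] + counts["alt_depth"]).sum()
        assert abs(frac - 0.5) < 0.01

    def test_sensitive_pool_fixed_reference_at_major_locus(self, labeled_cross):
        segs, cross = labeled_cross
        eps = 0.002
        counts = simulate_pool_reads(segs, SENSITIVE, DepthModel(2000, eps, seed=2))
        sites = segs.sites
        on = (sites["chrom"] == cross.qtl_major[0]).to_numpy()
        i = np.abs(sites["pos"].to_numpy()[on] - cross.qtl_major[1]).argmin()
        row = counts[on].iloc[i]
        frac = row["alt_depth"] / (row["ref_depth"] + row["alt_depth"])
        assert frac == pytest.approx(eps, abs=0.005)

    def test_empty_pool_raises(self, labeled_cross):
        segs, _ = labeled_cross
        segs.phenotypes[:] = SENSITIVE
        with pytest.raises(ValueError, match="empty"):
            simulate_pool_reads(segs, RESISTANT_EVOLVED, DepthModel(50, seed=1))

    def test_linked_marker_frequency_follows_haldane(self):
        # pool selected on the major locus: expected alt frequency at distance
        # d Morgans is 1 - c(d) with c = (1 - exp(-2d)) / 2
        genome = GenomeSpec(chromosomes=(("chr1", 1_000_000),), recombination_rate=0.35)
        positions = np.array([500_000, 550_000, 650_000, 800_000])
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "ref": "A", "alt": "T"}
        )
        cross = CrossConfig(
            n_segregants=10_000,
            qtl_major=("chr1", 500_000),
            qtl_minor=("chr1", 1),
            intermediate_fraction=0.0,
            seed=13,
        )
        segs = simulate_meiosis(sites, cross, genome)
        selected = segs.genotypes[:, 0] == 1
        freqs = segs.genotypes[selected].mean(axis=0)
        d = np.abs(positions - 500_000) / 1000 * 0.35 / 100  # Morgans
        expected = 1 - (1 - np.exp(-2 * d)) / 2
        assert np.abs(freqs - expected).max() < 0.02


class TestCoverage:
    def test_diploid_mean_matches_depth(self, tiny_genome):
        w = simulate_coverage(tiny_genome, mean_depth=60, window=1000, seed=1)
        assert w["mean_depth"].mean() == pytest.approx(60, rel=0.02)

    def test_trisomic_chromosome_scales_mean(self, tiny_genome):
        w = simulate_coverage(tiny_genome, {"chrA": 3}, window=1000, mean_depth=100, seed=2)
        chra = w.loc[w["chrom"] == "chrA", "mean_depth"]
        rest = w.loc[w["chrom"] != "chrA", "mean_depth"]
        assert chra.mean() == pytest.approx(150, rel=0.02)
        assert rest.mean() == pytest.approx(100, rel=0.02)

    def test_windows_tile_chromosomes(self, tiny_genome):
        w = simulate_coverage(tiny_genome, window=1000, seed=0)
        for chrom, length in tiny_genome.chromosomes:
            sub = w[w["chrom"] == chrom]
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1] + 1).all()

    def test_window_larger_than_smallest_chromosome_raises(self, tiny_genome):
        with pytest.raises(ValueError, match="smallest"):
            simulate_coverage(tiny_genome, window=200_000, seed=0)

    def test_invalid_copy_numbers_raise(self, tiny_genome):
        with pytest.raises(ValueError, match="unknown chromosome"):
            simulate_coverage(tiny_genome, {"chrZ": 3}, seed=0)
        with pytest.raises(ValueError, match=">= 1"):
            simulate_coverage(tiny_genome, {"chrA": 0}, seed=0)


class TestExpression:
    def test_no_dosage_no_dispersion_balanced(self):
        counts, ann = simulate_expression(n_genes=2000, dispersion=0.0, seed=1)
        ratio = counts["evolved_1"].sum() / counts["parent_1"].sum()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_dosage_shifts_mean_log2_fc(self):
        counts, ann = simulate_expression(
            n_genes=4000, dosage={"chrI": 1.5}, dispersion=0.0, seed=2
        )
        on = ann["chrom"] == "chrI"
        fc = np.log2(counts["evolved_1"] + 0.5) - np.log2(counts["parent_1"] + 0.5)
        assert fc[on].mean() == pytest.approx(np.log2(1.5), abs=0.05)
        assert abs(fc[~on].mean()) < 0.05

    def test_replicate_structure_default(self):
        counts, _ = simulate_expression(n_genes=10, seed=0)
        assert list(counts.columns) == ["parent_1", "parent_2", "parent_3", "evolved_1"]

    def test_unknown_dosage_chromosome_raises(self):
        with pytest.raises(ValueError, match="dosage"):
            simulate_expression(n_genes=10, dosage={"chrZZ": 2.0}, seed=0)

    def test_explicit_gene_map_respected(self):
        gene_map = {"g1": "chrI", "g2": "chrII"}
        counts, ann = simulate_expression(gene_chromosomes=gene_map, seed=0)
        assert dict(ann["chrom"]) == gene_map


def test_all_generators_bit_reproducible(tiny_genome):
    sites = simulate_parent_sites(100, tiny_genome, seed=42)
    cross = CrossConfig(
        n_segregants=30, qtl_major=("chrC", 100_000), qtl_minor=("chrB", 100_000), seed=42
    )
    run = []
    for _ in range(2):
        segs = assign_phenotypes(simulate_meiosis(sites, cross, tiny_genome), cross)
        pool = simulate_pool_reads(segs, SENSITIVE, DepthModel(50, seed=42))
        parent = simulate_parent_counts(sites, DepthModel(100, seed=42))
        cov = simulate_coverage(tiny_genome, {"chrA": 3}, window=500, seed=42)
        expr, _ = simulate_expression(n_genes=50, dispersion=0.1, seed=42)
        run.append((segs.genotypes.copy(), pool, parent, cov, expr))
    assert (run[0][0] == run[1][0]).all()
    for a, b in zip(run[0][1:], run[1][1:]):
        pd.testing.assert_frame_equal(a, b)
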