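import numpy as np
import pytest
from scipy import stats

from f2impute import (
    make_genome_map,
    medaka_cross_design,
    meiosis,
    simulate_cohort,
    simulate_cross,
    simulate_founders,
    simulate_reads,
)
from f2impute.simdata import CrossDesign


class TestGenomeMap:
    def test_positions_sorted_and_in_range(self):
        gm = make_genome_map(2, 5_000_000, 2000, 2.0, seed=1)
        assert gm.n_sites == 4000
        for ci in range(2):
            p = gm.pos[gm.chrom_sites(ci)]
            assert np.all(np.diff(p) > 0)
            assert p[0] >= 1 and p[-1] <= 5_000_000

    def test_seeded_determinism(self):
        a = make_genome_map(1, 5_000_000, 2000, 2.0, seed=1)
        b = make_genome_map(1, 5_000_000, 2000, 2.0, seed=1)
        assert np.array_equal(a.pos, b.pos)

    def test_more_sites_than_bases_rejected(self):
        with pytest.raises(ValueError):
            make_genome_map(1, 100, 200, 2.0, seed=1)


class TestFounders:
    def test_zero_residual_het_is_fully_homozygous(self):
        gm = make_genome_map(1, 1_000_000, 500, 2.0, seed=2)
        panel = simulate_founders(gm, 4, residual_het=0.0, seed=3)
        assert np.array_equal(panel.haplotypes[:, 0, :], panel.haplotypes[:, 1, :])

    def test_residual_het_fraction_within_binomial_error(self):
        gm = make_genome_map(1, 1_000_000, 2000, 2.0, seed=2)
        het = 0.01
        panel = simulate_founders(gm, 8, residual_het=het, seed=3)
        frac = (panel.haplotypes[:, 0, :] != panel.haplotypes[:, 1, :]).mean()
        n = 8 * 2000
        assert abs(frac - het) < 3 * np.sqrt(het * (1 - het) / n)

    def test_every_site_polymorphic_across_panel(self):
        gm = make_genome_map(1, 1_000_000, 1000, 2.0, seed=4)
        for n_lines in (2, 8):
            panel = simulate_founders(gm, n_lines, residual_het=0.0, seed=5)
            flat = panel.haplotypes.reshape(-1, gm.n_sites)
            assert np.all(flat.min(axis=0) == 0)
            assert np.all(flat.max(axis=0) == 1)

    def test_single_line_rejected(self):
        gm = make_genome_map(1, 1_000_000, 100, 2.0, seed=4)
        with pytest.raises(ValueError):
            simulate_founders(gm, 1, seed=1)


class TestMeiosis:
    def test_identical_parents_give_identical_gamete(self):
        gm = make_genome_map(1, 5_000_000, 500, 2.0, seed=6)
        h = np.random.default_rng(0).integers(0, 2, gm.n_sites).astype(np.int8)
        assert np.array_equal(meiosis(h, h, gm, seed=1), h)

    def test_zero_rate_gives_whole_parental_haplotype(self):
        gm = make_genome_map(1, 5_000_000, 500, 0.0, seed=6)
        rng = np.random.default_rng(1)
        ha = np.zeros(gm.n_sites, dtype=np.int8)
        hb = np.ones(gm.n_sites, dtype=np.int8)
        for s in range(10):
            g = meiosis(ha, hb, gm, seed=s)
            assert g.min() == g.max()  # all from one parent

    def test_crossover_count_matches_poisson_rate(self):
        # expected 2 cM/Mb * 5 Mb / 100 = 0.1 crossovers per gamete
        gm = make_genome_map(1, 5_000_000, 200, 2.0, seed=7)
        ha = np.zeros(gm.n_sites, dtype=np.int8)
        hb = np.ones(gm.n_sites, dtype=np.int8)
        rng = np.random.default_rng(8)
        n = 10_000
        switches = np.empty(n)
        for i in range(n):
            g = meiosis(ha, hb, gm, rng)
            switches[i] = np.count_nonzero(np.diff(g))
        lam = 2.0 * 5.0 / 100.0
        assert abs(switches.mean() - lam) < 3 * np.sqrt(lam / n)


class TestCross:
    def test_obligate_f1_heterozygote(self):
        gm = make_genome_map(1, 2_000_000, 400, 2.0, seed=9)
        panel = simulate_founders(gm, 2, residual_het=0.0, seed=10, line_ids=("A", "B"))
        design = CrossDesign(crosses=(("A", "B", 50),))
        cohort = simulate_cross(panel, design, gm, seed=11)
        diff = np.flatnonzero(panel.consensus("A") != panel.consensus("B"))
        f1 = [i for i, s in enumerate(cohort.samples) if s.generation == "F1"]
        assert np.all(cohort.truth_genotypes[np.ix_(f1, diff)] == 1)

    def test_f2_segregation_is_mendelian(self):
        gm = make_genome_map(1, 2_000_000, 200, 2.0, seed=9)
        panel = simulate_founders(gm, 2, residual_het=0.0, seed=10, line_ids=("A", "B"))
        design = CrossDesign(crosses=(("A", "B", 400),))
        cohort = simulate_cross(panel, design, gm, seed=12)
        diff = np.flatnonzero(panel.consensus("A") != panel.consensus("B"))
        f2 = [i for i, s in enumerate(cohort.samples) if s.generation == "F2"]
        site = diff[len(diff) // 2]
        g = cohort.truth_genotypes[f2, site]
        counts = np.bincount(g, minlength=3)
        p = stats.chisquare(counts, f_exp=len(f2) * np.array([0.25, 0.5, 0.25])).pvalue
        assert p > 0.001

    def test_f2_allele_frequency_near_half(self):
        gm = make_genome_map(1, 2_000_000, 300, 2.0, seed=9)
        panel = simulate_founders(gm, 2, residual_het=0.0, seed=10, line_ids=("A", "B"))
        design = CrossDesign(crosses=(("A", "B", 400),))
        cohort = simulate_cross(panel, design, gm, seed=13)
        diff = np.flatnonzero(panel.consensus("A") != panel.consensus("B"))
        f2 = [i for i, s in enumerate(cohort.samples) if s.generation == "F2"]
        af = cohort.truth_genotypes[np.ix_(f2, diff)].mean(axis=0) / 2.0
        sd = np.sqrt(0.25 / (2 * len(f2)))
        assert np.all(np.abs(af - 0.5) < 4 * sd)

    def test_default_truth_plan_yields_twelve_truth_samples(self):
        design = medaka_cross_design()
        gm = make_genome_map(1, 1_000_000, 50, 2.0, seed=14)
        panel = simulate_founders(gm, 8, residual_het=0.0, seed=15, line_ids=design.lines)
        cohort = simulate_cross(panel, design, gm, seed=16)
        assert int(cohort.truth_mask.sum()) == 12
        f1_truth = [s for s in cohort.samples if s.is_truth and s.generation == "F1"]
        f2_truth = [s for s in cohort.samples if s.is_truth and s.generation == "F2"]
        assert len(f1_truth) == 10 and len(f2_truth) == 2

    def test_f2_label_switch_rate_reflects_meiosis(self):
        # line-of-origin labels switch only at the F2-forming meiosis, so the
        # expected switch count per F2 haplotype is exp_rate * L_Mb / 100
        design = CrossDesign(crosses=(("A", "B", 300),))
        gm = make_genome_map(1, 5_000_000, 500, 2.0, seed=17)
        panel = simulate_founders(gm, 2, residual_het=0.0, seed=18, line_ids=("A", "B"))
        cohort = simulate_cross(panel, design, gm, seed=19, keep_origins=True)
        f2 = [i for i, s in enumerate(cohort.samples) if s.generation == "F2"]
        orig = cohort.haplotype_origins[f2]  # (n, 2, T)
        switches = (np.diff(orig, axis=2) != 0).sum(axis=2).ravel()
        lam = 2.0 * 5.0 / 100.0
        assert abs(switches.mean() - lam) < 3 * np.sqrt(lam / switches.size)

    def test_unknown_line_rejected(self):
        gm = make_genome_map(1, 1_000_000, 50, 2.0, seed=14)
        panel = simulate_founders(gm, 2, seed=15, line_ids=("A", "B"))
        with pytest.raises(ValueError):
            simulate_cross(panel, CrossDesign(crosses=(("A", "C", 5),)), gm, seed=1)


@pytest.fixture(scope="module")
def cohort():
    design = CrossDesign(crosses=(("A", "B", 50),))
    gm = make_genome_map(1, 2_000_000, 300, 2.0, seed=20)
    panel = simulate_founders(gm, 2, residual_het=0.0, seed=21, line_ids=("A", "B"))
    return simulate_cross(panel, design, gm, seed=22)


class TestReads:

    def test_zero_depth_gives_no_reads(self, cohort):
        c = simulate_reads(cohort, mean_depth=0.0, base_error=0.01, seed=1, truth_depth=0.0)
        assert c.ref_counts.sum() == 0 and c.alt_counts.sum() == 0

    def test_no_error_homalt_gives_no_ref_reads(self, cohort):
        c = simulate_reads(cohort, mean_depth=2.0, base_error=0.0, seed=2, fixed_depth=True)
        hom_alt = c.truth_genotypes == 2
        assert c.ref_counts[hom_alt].sum() == 0

    def test_realized_depth_matches_poisson_mean(self, cohort):
        c = simulate_reads(cohort, mean_depth=1.0, base_error=0.01, seed=3, fixed_depth=True)
        low = ~c.truth_mask
        total = (c.ref_counts[low] + c.alt_counts[low]).astype(float)
        n = total.size
        assert abs(total.mean() - 1.0) < 3 * np.sqrt(1.0 / n)

    def test_seeded_reproducibility(self, cohort):
        a = simulate_reads(cohort, 1.0, 0.01, seed=9)
        b = simulate_reads(cohort, 1.0, 0.01, seed=9)
        assert np.array_equal(a.ref_counts, b.ref_counts)
        assert np.array_equal(a.alt_counts, b.alt_counts)


def test_simulate_cohort_end_to_end_reproducible():
    design = CrossDesign(crosses=(("A", "B", 20),))
    _, a = simulate_cohort(design=design, n_sites=100, seed=42)
    _, b = simulate_cohort(design=design, n_sites=100, seed=42)
    assert np.array_equal(a.truth_genotypes, b.truth_genotypes)
    assert np.array_equal(a.alt_counts, b.alt_counts)
    assert a.sample_ids == b.sample_ids
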