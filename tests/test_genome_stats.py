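"""Genotype-statistics tests: ROH scanning, inbreeding, diversity, F_ST, HWE."""

import itertools

import numpy as np
import pytest

from imcoal.coalsim import GenotypePanel, plant_roh_panel, simulate_genotype_panel
from imcoal.genome_stats import (
    GENOME_LENGTH_BP,
    RohParams,
    RohSegment,
    detect_roh,
    f_is,
    f_roh,
    hwe_exact_excess_p,
    hwe_het_filter,
    nucleotide_diversity,
    sample_heterozygosity,
    weighted_fst,
)


def make_panel(positions, genotypes, chrom="chr1", region="R"):
    """Single-sample panel from explicit positions and genotype codes."""
    g = np.asarray(genotypes, dtype=np.int8)[:, None]
    return GenotypePanel(
        samples=["s1"], regions=np.array([region]),
        chroms=np.array([chrom] * len(positions), dtype=object),
        positions=np.asarray(positions, dtype=np.int64), genotypes=g)


def brute_force_roh(panel, params):
    """Independent reference: direct enumeration of windows and runs."""
    segments = []
    for chrom in dict.fromkeys(panel.chroms):
        idx = np.flatnonzero(panel.chroms == chrom)
        pos = panel.positions[idx]
        for si, sample in enumerate(panel.samples):
            gt = panel.genotypes[idx, si]
            n = len(gt)
            W = params.window_snps
            # window homozygosity flags by direct counting
            win_ok = []
            for start in range(n - W + 1):
                w = gt[start:start + W]
                win_ok.append(
                    int(np.sum(w == 1)) <= params.max_het_per_window
                    and int(np.sum(w == -1)) <= params.max_missing_per_window)
            # per-SNP hit rates by direct scan over overlapping windows
            cand = []
            for i in range(n):
                hom = tot = 0
                for start in range(max(0, i - W + 1),
                                   min(i, n - W) + 1):
                    tot += 1
                    hom += win_ok[start]
                cand.append(tot > 0 and hom / tot >= params.hit_threshold)
            # runs of candidates, split at large gaps
            i = 0
            while i < n:
                if not cand[i]:
                    i += 1
                    continue
                j = i
                while (j + 1 < n and cand[j + 1]
                       and pos[j + 1] - pos[j] <= params.max_gap_kb * 1000):
                    j += 1
                length = int(pos[j] - pos[i] + 1)
                n_snps = j - i + 1
                if (length >= params.min_length_kb * 1000
                        and n_snps >= params.min_snps
                        and length / n_snps
                        <= params.max_inverse_density_kb_per_snp * 1000):
                    segments.append((sample, str(chrom), int(pos[i]),
                                     int(pos[j]), n_snps))
                i = j + 1
    return segments


class TestDetectRoh:
    def test_homozygous_run_detected(self):
        # 40 consecutive homozygous SNPs spanning ~80 kb at 2 kb spacing
        pos = np.arange(40) * 2000 + 10_000
        panel = make_panel(pos, np.zeros(40))
        segs = detect_roh(panel)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end) == (10_000, 10_000 + 39 * 2000)
        assert seg.n_snps == 40 and seg.n_het == 0

    def test_two_hets_per_window_blocks_detection(self):
        pos = np.arange(40) * 2000 + 10_000
        gt = np.zeros(40)
        gt[10] = gt[12] = 1  # every window covering the run holds 2 hets
        panel = make_panel(pos, gt)
        assert detect_roh(panel) == []

    def test_large_gap_splits_run(self):
        # two 70-SNP homozygous stretches separated by a 600 kb gap
        pos = np.concatenate([np.arange(70) * 2000 + 10_000,
                              np.arange(70) * 2000 + 760_000])
        panel = make_panel(pos, np.zeros(140))
        segs = detect_roh(panel)
        assert len(segs) == 2
        assert segs[0].end < 200_000 < 760_000 <= segs[1].start

    def test_density_requirement(self):
        # 35 SNPs over 7 Mb: 200 kb/SNP, far sparser than 100 kb/SNP
        pos = np.arange(35) * 200_000 + 1
        panel = make_panel(pos, np.zeros(35))
        assert detect_roh(panel) == []

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            make_panel([100, 50, 200], [0, 0, 0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reference(self, seed):
        """Optimized scan equals direct enumeration, segment for segment."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 400))
        pos = np.sort(rng.choice(int(rng.uniform(1e5, 5e6)), size=n,
                                 replace=False)) + 1
        p_het = float(rng.uniform(0.0, 0.2))
        gt = rng.choice([0, 1, 2, -1], size=n,
                        p=[0.55, p_het, 0.2, 0.25 - p_het])
        panel = make_panel(pos, gt)
        params = RohParams()
        got = [(s.sample, s.chrom, s.start, s.end, s.n_snps)
               for s in detect_roh(panel, params)]
        assert got == brute_force_roh(panel, params)


class TestFroh:
    def test_ten_percent(self):
        segs = [RohSegment("s", "c", 1, 21_929_137, 700, 0)]
        assert f_roh(segs)["s"] == pytest.approx(0.100, abs=5e-8)

    def test_no_segments(self):
        assert f_roh([]) == {}

    def test_full_genome(self):
        segs = [RohSegment("s", "c", 1, GENOME_LENGTH_BP, 1000, 0)]
        assert f_roh(segs)["s"] == pytest.approx(1.0)


class TestFis:
    def test_all_heterozygous_approaches_minus_one(self):
        g = np.ones((500, 10), dtype=np.int8)
        panel = GenotypePanel(
            samples=[f"s{i}" for i in range(10)],
            regions=np.array(["R"] * 10),
            chroms=np.array(["c"] * 500, dtype=object),
            positions=np.arange(1, 501), genotypes=g)
        per_sample, med = f_is(panel, "R")
        assert med < -0.9

    def test_fully_homozygous_at_half_frequency(self):
        g = np.tile(np.array([0, 2, 0, 2, 0, 2], dtype=np.int8), (400, 1))
        panel = GenotypePanel(
            samples=[f"s{i}" for i in range(6)],
            regions=np.array(["R"] * 6),
            chroms=np.array(["c"] * 400, dtype=object),
            positions=np.arange(1, 401), genotypes=g)
        _, med = f_is(panel, "R")
        assert med == pytest.approx(1.0)

    def test_random_mating_panel_near_zero(self):
        panel = simulate_genotype_panel(
            {"R": {"n_samples": 20, "fst": 0.0, "selfing_f": 0.0}},
            n_sites=10_000, chrom_lengths={"c": 50_000_000}, seed=11)
        _, med = f_is(panel, "R")
        assert abs(med) < 0.02

    def test_small_region_rejected(self):
        panel = simulate_genotype_panel(
            {"R": {"n_samples": 3, "fst": 0.0, "selfing_f": 0.0}},
            n_sites=50, chrom_lengths={"c": 1_000_000}, seed=1)
        with pytest.raises(ValueError, match="four samples"):
            f_is(panel, "R")


class TestNucleotideDiversity:
    def test_fixed_site_contributes_zero(self):
        g = np.full((1, 5), 2, dtype=np.int8)
        panel = GenotypePanel(["a", "b", "c", "d", "e"], np.array(["R"] * 5),
                              np.array(["c"], dtype=object), np.array([10]), g)
        assert nucleotide_diversity(panel, "R") == 0.0

    def test_single_half_frequency_site(self):
        g = np.ones((1, 5), dtype=np.int8)  # p = 0.5, 10 haplotypes
        panel = GenotypePanel(["a", "b", "c", "d", "e"], np.array(["R"] * 5),
                              np.array(["c"], dtype=object), np.array([10]), g)
        pi = nucleotide_diversity(panel, "R", n_callable=1000)
        assert pi == pytest.approx(2 * 0.25 * 10 / 9 / 1000, rel=1e-12)

    def test_matches_brute_force_pairwise_differences(self):
        """pi equals the mean over haplotype pairs of per-site differences."""
        rng = np.random.default_rng(5)
        n_sites, n_samp = 100, 6
        g = rng.integers(0, 3, size=(n_sites, n_samp)).astype(np.int8)
        panel = GenotypePanel([f"s{i}" for i in range(n_samp)],
                              np.array(["R"] * n_samp),
                              np.array(["c"] * n_sites, dtype=object),
                              np.arange(1, n_sites + 1), g)
        # brute force: expand to haplotypes (genotype k -> k alt alleles,
        # allele identity within a diploid is exchangeable for freq-based pi)
        total = 0.0
        for k in range(n_sites):
            alleles = np.concatenate([[1] * int(d) + [0] * (2 - int(d))
                                      for d in g[k]])
            diffs = [a != b for a, b in itertools.combinations(alleles, 2)]
            total += np.mean(diffs)
        expected = total / n_sites
        assert nucleotide_diversity(panel, "R") == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_invariant_to_selfing(self):
        """pi uses allele frequencies only, so selfing leaves it unchanged."""
        common = dict(n_sites=4000, chrom_lengths={"c": 20_000_000}, seed=42)
        p0 = simulate_genotype_panel(
            {"R": {"n_samples": 30, "fst": 0.0, "selfing_f": 0.0}}, **common)
        p9 = simulate_genotype_panel(
            {"R": {"n_samples": 30, "fst": 0.0, "selfing_f": 0.9}}, **common)
        pi0 = nucleotide_diversity(p0, "R")
        pi9 = nucleotide_diversity(p9, "R")
        assert pi9 == pytest.approx(pi0, rel=0.05)


class TestWeightedFst:
    def _two_region_panel(self, ga, gb):
        na, nb = ga.shape[1], gb.shape[1]
        g = np.concatenate([ga, gb], axis=1).astype(np.int8)
        return GenotypePanel(
            samples=[f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)],
            regions=np.array(["A"] * na + ["B"] * nb),
            chroms=np.array(["c"] * g.shape[0], dtype=object),
            positions=np.arange(1, g.shape[0] + 1), genotypes=g)

    def test_fixed_difference_gives_one(self):
        ga = np.zeros((50, 6))
        gb = np.full((50, 6), 2)
        assert weighted_fst(self._two_region_panel(ga, gb), "A", "B") == \
            pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, size=(5000, 40))
        theta = weighted_fst(self._two_region_panel(g[:, :20], g[:, 20:]),
                             "A", "B")
        assert abs(theta) < 0.01

    def test_balding_nichols_recovery(self):
        panel = simulate_genotype_panel(
            {"A": {"n_samples": 15, "fst": 0.2, "selfing_f": 0.0},
             "B": {"n_samples": 15, "fst": 0.2, "selfing_f": 0.0}},
            n_sites=10_000, chrom_lengths={"c": 50_000_000}, seed=7)
        theta = weighted_fst(panel, "A", "B")
        assert theta == pytest.approx(0.2, abs=0.02)

    def test_invariant_to_site_order_and_allele_swap(self):
        rng = np.random.default_rng(9)
        ga = rng.binomial(2, 0.3, size=(300, 8))
        gb = rng.binomial(2, 0.6, size=(300, 8))
        panel = self._two_region_panel(ga, gb)
        theta = weighted_fst(panel, "A", "B")
        perm = rng.permutation(300)
        shuffled = GenotypePanel(
            panel.samples, panel.regions,
            panel.chroms, np.arange(1, 301),
            panel.genotypes[perm])
        assert weighted_fst(shuffled, "A", "B") == pytest.approx(theta,
                                                                 rel=1e-12)
        swapped = GenotypePanel(
            panel.samples, panel.regions, panel.chroms, panel.positions,
            np.where(panel.genotypes >= 0, 2 - panel.genotypes, -1))
        assert weighted_fst(swapped, "A", "B") == pytest.approx(theta,
                                                                rel=1e-12)

    def test_subsample_is_seeded(self):
        panel = simulate_genotype_panel(
            {"A": {"n_samples": 10, "fst": 0.1, "selfing_f": 0.0},
             "B": {"n_samples": 10, "fst": 0.1, "selfing_f": 0.0}},
            n_sites=500, chrom_lengths={"c": 5_000_000}, seed=3)
        t1 = weighted_fst(panel, "A", "B", subsample_n=5, seed=1)
        t2 = weighted_fst(panel, "A", "B", subsample_n=5, seed=1)
        assert t1 == t2


def brute_force_hwe_excess_p(n_het, n_alt, n_dip):
    """Sum P over all genotype assignments conditional on allele count.

    Conditional on the allele count, every assignment's probability is
    proportional to 2^(number of heterozygotes); enumerate all 3^n genotype
    vectors and sum those at least as heterozygous as observed.
    """
    num = den = 0.0
    for combo in itertools.product((0, 1, 2), repeat=n_dip):
        if sum(combo) != n_alt:
            continue
        w = 2.0 ** sum(1 for c in combo if c == 1)
        den += w
        if sum(1 for c in combo if c == 1) >= n_het:
            num += w
    return num / den


class TestHweFilter:
    def test_ten_all_het_removed(self):
        p = hwe_exact_excess_p(10, 10, 10)
        assert p == pytest.approx(1024 / 184756, rel=1e-12)
        assert p < 0.01

    def test_five_all_het_retained(self):
        p = hwe_exact_excess_p(5, 5, 5)
        assert p == pytest.approx(32 / 252, rel=1e-12)
        assert p > 0.01

    @pytest.mark.parametrize("n_dip", [2, 3, 5, 7])
    def test_matches_brute_force_enumeration(self, n_dip):
        for n_alt in range(2 * n_dip + 1):
            h_min = n_alt % 2
            h_max = min(n_alt, 2 * n_dip - n_alt)
            for n_het in range(h_min, h_max + 1, 2):
                got = hwe_exact_excess_p(n_het, n_alt, n_dip)
                want = brute_force_hwe_excess_p(n_het, n_alt, n_dip)
                assert got == pytest.approx(want, rel=1e-10), \
                    (n_dip, n_alt, n_het)

    def test_homozygote_excess_never_removes(self):
        # all-homozygous site at p = 0.5: maximal homozygote excess
        g = np.array([[0, 0, 0, 0, 0, 2, 2, 2, 2, 2]] * 3, dtype=np.int8)
        panel = GenotypePanel([f"s{i}" for i in range(10)],
                              np.array(["R"] * 10),
                              np.array(["c"] * 3, dtype=object),
                              np.arange(1, 4), g)
        retained, pvals = hwe_het_filter(panel)
        assert retained.all()
        assert np.all(pvals["R"] == 1.0)

    def test_removal_in_any_region(self):
        # region A in HWE; region B all-heterozygous (10 diploids)
        rng = np.random.default_rng(4)
        ga = rng.binomial(2, 0.5, size=(2, 10)).astype(np.int8)
        gb = np.ones((2, 10), dtype=np.int8)
        panel = GenotypePanel(
            [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
            np.array(["A"] * 10 + ["B"] * 10),
            np.array(["c"] * 2, dtype=object), np.arange(1, 3),
            np.concatenate([ga, gb], axis=1))
        retained, _ = hwe_het_filter(panel)
        assert not retained.any()


class TestSampleHeterozygosity:
    def test_extremes(self):
        g = np.array([[1, 0], [1, 2], [1, 0]], dtype=np.int8)
        panel = GenotypePanel(["het", "hom"], np.array(["R", "R"]),
                              np.array(["c"] * 3, dtype=object),
                              np.arange(1, 4), g)
        het = sample_heterozygosity(panel)
        assert het["het"] == 1.0 and het["hom"] == 0.0

    def test_selfing_half(self):
        panel = simulate_genotype_panel(
            {"R": {"n_samples": 10, "fst": 0.0, "selfing_f": 0.5}},
            n_sites=20_000, chrom_lengths={"c": 50_000_000}, seed=8)
        het = np.mean(list(sample_heterozygosity(panel).values()))
        # expected het = E[2pq] * (1 - F); p ~ U(0.05, 0.95)
        p = panel.truth["ancestral_freq"]
        expect = float(np.mean(2 * p * (1 - p))) * 0.5
        assert het == pytest.approx(expect, rel=0.05)


class TestRohRecovery:
    def test_planted_segments_recovered(self):
        """Base-level precision/recall >= 0.9 on planted 250-500 kb ROH."""
        truth = {
            "s1": [("chr1", 1_000_001, 1_300_000),
                   ("chr1", 3_000_001, 3_500_000)],
            "s2": [("chr1", 2_000_001, 2_250_000)],
        }
        panel = plant_roh_panel(truth, {"chr1": 5_000_000},
                                snp_spacing_bp=5_000, seed=21)
        segs = detect_roh(panel)
        for sample, true_segs in truth.items():
            mask_true = np.zeros(5_000_001, dtype=bool)
            for _, a, b in true_segs:
                mask_true[a:b + 1] = True
            mask_called = np.zeros(5_000_001, dtype=bool)
            for s in segs:
                if s.sample == sample:
                    mask_called[s.start:s.end + 1] = True
            tp = np.sum(mask_true & mask_called)
            precision = tp / max(mask_called.sum(), 1)
            recall = tp / mask_true.sum()
            assert precision >= 0.9 and recall >= 0.9, (sample, precision,
                                                        recall)
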