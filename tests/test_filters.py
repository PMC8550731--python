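"""Filter cascade, ascertainment and polarization tests, checked against
independent brute-force implementations on toy and randomized matrices."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gt, make_ped, f2_sex_ped
from oracles import brute_force_cascade, hwe_exact_distribution

from sexscan.core import read_vcf, MISSING
from sexscan.filters import (FilterConfig, EmptyTableError, apply_filter_cascade,
                             mask_low_depth, filter_sites_individuals,
                             depth_iqr_site_filter, maf_filter, hwe_filter,
                             hwe_exact_p, select_f0_diagnostic_sites,
                             infer_f1_het_sites_by_af,
                             polarization_orientation, polarize)


class TestMaskLowDepth:
    def test_boundary_strict_less_than(self):
        gt = make_gt([[1, 1]], depth=[[9, 10]])
        out = mask_low_depth(gt, 10)
        assert out.gt[0, 0] == MISSING and out.gt[0, 1] == 1

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
            d = rng.integers(0, 30, size=(8, 6))
            out = mask_low_depth(make_gt(g, depth=d), 10)
            expect = np.where(d < 10, MISSING, g)
            assert np.array_equal(out.gt, expect)


class TestSiteIndividualFilters:
    def test_site_mostly_missing_removed(self):
        g = [[-1, -1, -1, 1], [0, 1, 2, 1]]
        out = filter_sites_individuals(make_gt(g), FilterConfig(maf_min=0.0))
        assert out.n_sites == 1

    def test_individual_mean_depth_boundary(self):
        g = np.ones((4, 2), dtype=np.int8)
        g[:, 1] = [0, 1, 2, 1]
        d = np.full((4, 2), 30)
        d[:, 0] = 11  # mean 11.9 < 12 -> removed; use 11 to be unambiguous
        out = filter_sites_individuals(make_gt(g, depth=d), FilterConfig(maf_min=0.0))
        assert out.n_samples == 1

    def test_everything_filtered_raises(self):
        g = np.full((3, 3), MISSING, dtype=np.int8)
        with pytest.raises(EmptyTableError):
            filter_sites_individuals(make_gt(g), FilterConfig())

    def test_cascade_equals_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            n_s = rng.integers(4, 16)
            n_i = rng.integers(4, 12)
            g = rng.integers(0, 3, size=(n_s, n_i)).astype(np.int8)
            g[rng.random((n_s, n_i)) < 0.2] = MISSING
            d = rng.integers(0, 40, size=(n_s, n_i))
            gt = make_gt(g, depth=d)
            sites, inds, _ = brute_force_cascade(g, d)
            try:
                out = apply_filter_cascade(gt, FilterConfig())
            except EmptyTableError:
                assert len(sites) == 0 or len(inds) == 0
                continue
            got_sites = [int(m.split("_")[1]) // 1000 - 1 for m in out.markers["marker_id"]]
            got_inds = [int(s[1:]) for s in out.samples]
            assert got_sites == sites, f"trial {trial}"
            assert got_inds == inds, f"trial {trial}"

    def test_cascade_idempotent(self, xy_cross):
        _, gt, _, _ = xy_cross
        once = apply_filter_cascade(gt)
        twice = apply_filter_cascade(once)
        assert np.array_equal(once.gt, twice.gt)
        assert once.samples == twice.samples


class TestDepthIQR:
    def test_uniform_depth_all_kept(self):
        gt = make_gt(np.ones((6, 4), dtype=np.int8), depth=np.full((6, 4), 20))
        assert depth_iqr_site_filter(gt, 1.5).n_sites == 6

    def test_extreme_site_removed(self):
        d = np.full((6, 4), 20)
        d[2] = 200
        gt = make_gt(np.ones((6, 4), dtype=np.int8), depth=d)
        out = depth_iqr_site_filter(gt, 1.5)
        assert out.n_sites == 5
        assert "chr01_3000" not in set(out.markers["marker_id"])

    def test_infinite_mult_keeps_all(self):
        d = np.full((6, 4), 20)
        d[2] = 200
        gt = make_gt(np.ones((6, 4), dtype=np.int8), depth=d)
        assert depth_iqr_site_filter(gt, np.inf).n_sites == 6

    def test_too_few_sites_warns_and_passes(self):
        gt = make_gt(np.ones((3, 4), dtype=np.int8))
        with pytest.warns(UserWarning):
            out = depth_iqr_site_filter(gt, 1.5)
        assert out.n_sites == 3


class TestMafHwe:
    def test_maf_boundary(self):
        # 1000 alleles: 49 alt -> maf 0.049 removed; 50 alt -> 0.05 kept
        def site(n_alt):
            g = np.zeros(500, dtype=np.int8)
            g[:n_alt] = 1
            return g

        gt = make_gt(np.vstack([site(49), site(50)]))
        out = maf_filter(gt, 0.05)
        assert out.n_sites == 1

    def test_hwe_matches_factorial_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n0, nh, n2 = rng.integers(0, 15, size=3)
            if n0 + nh + n2 == 0:
                continue
            assert hwe_exact_p(int(nh), int(n0), int(n2)) == pytest.approx(
                hwe_exact_distribution(int(nh), int(n0), int(n2)), rel=1e-9)

    def test_all_heterozygotes_removed(self):
        g = np.vstack([
            np.ones(20, dtype=np.int8),                      # 20 hets: exact P < 0.1
            np.array([0] * 5 + [1] * 10 + [2] * 5, np.int8),  # HWE proportions: kept
        ])
        samples, ped = f2_sex_ped(10, 10)
        gt = make_gt(g, samples=samples)
        out = hwe_filter(gt, 0.1, ped)
        assert out.n_sites == 1
        assert hwe_exact_p(20, 0, 0) < 0.1


class TestDiagnosticAscertainment:
    def _toy(self):
        # columns: F0_GM, F0_GF, F1a, F1b, two F2
        g = np.array([
            [0, 2, 1, 1, 0, 2],   # diagnostic, F1 het
            [0, 0, 0, 0, 0, 0],   # founders identical
            [0, 2, 1, 0, 1, 1],   # one F1 hom
            [0, 2, 1, -1, 1, 1],  # missing F1
            [2, 0, 1, 1, 2, 0],   # diagnostic, flipped orientation
        ], dtype=np.int8)
        samples = ["F0_GM", "F0_GF", "F1a", "F1b", "F2a", "F2b"]
        ped = make_ped(samples,
                       generation=["F0", "F0", "F1", "F1", "F2", "F2"],
                       sex=["F", "M", "F", "M", "M", "F"],
                       species=["A", "B", "-", "-", "-", "-"])
        return make_gt(g, samples=samples), ped

    def test_selection_rules(self):
        gt, ped = self._toy()
        got = select_f0_diagnostic_sites(gt, ped, require_f1_het=True)
        assert got.tolist() == [0, 4]
        got2 = select_f0_diagnostic_sites(gt, ped, require_f1_het=False)
        assert got2.tolist() == [0, 2, 3, 4]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        samples = ["F0_GM", "F0_GF", "F1a", "F1b", "F2a"]
        ped = make_ped(samples, generation=["F0", "F0", "F1", "F1", "F2"],
                       sex=["F", "M", "F", "M", "M"], species=["A", "B", "-", "-", "-"])
        for _ in range(100):
            g = rng.integers(-1, 3, size=(12, 5)).astype(np.int8)
            gt = make_gt(g, samples=samples)
            got = select_f0_diagnostic_sites(gt, ped, require_f1_het=True).tolist()
            expect = [i for i in range(12)
                      if {g[i, 0], g[i, 1]} == {0, 2} and g[i, 2] == g[i, 3] == 1]
            assert got == expect

    def test_no_f0_errors(self):
        samples, ped = f2_sex_ped(2, 2)
        gt = make_gt(np.zeros((3, 4), dtype=np.int8), samples=samples)
        with pytest.raises(ValueError):
            select_f0_diagnostic_sites(gt, ped)

    def test_polarization_involution(self):
        """Swapping the two founders maps coded genotypes g -> 2 - g (missing fixed)."""
        gt, ped = self._toy()
        orient = polarization_orientation(gt, ped)
        pol = polarize(gt, orient)
        swapped = ped.df.copy()
        swapped.loc[swapped["sample_id"] == "F0_GM", ["sex", "species"]] = ["M", "B"]
        swapped.loc[swapped["sample_id"] == "F0_GF", ["sex", "species"]] = ["F", "A"]
        from sexscan.core import PedigreeTable
        orient2 = polarization_orientation(gt, PedigreeTable(swapped))
        pol2 = polarize(gt, orient2)
        diag = [0, 4]  # orientation only differs at diagnostic sites
        for i in diag:
            a, b = pol.gt[i], pol2.gt[i]
            nm = a != MISSING
            assert np.array_equal(b[nm], 2 - a[nm])


class TestF1HetByAF:
    def test_mean_of_sex_frequencies_semantics(self):
        # site 0: af 0.5 in both sexes -> kept
        # site 1: af 0.3 males / 0.7 females -> mean 0.5 -> kept
        # site 2: af 0.2 / 0.2 -> rejected
        males = np.array([[1] * 10, [0] * 7 + [2] * 3, [0] * 6 + [1] * 4], np.int8)
        females = np.array([[1] * 10, [2] * 7 + [0] * 3, [0] * 6 + [1] * 4], np.int8)
        g = np.hstack([males, females])
        samples, ped = f2_sex_ped(10, 10)
        gt = make_gt(g, samples=samples)
        got = infer_f1_het_sites_by_af(gt, ped, (0.45, 0.55), het_excess_max=1.0)
        assert got.tolist() == [0, 1]

    def test_paralog_filter_removes_het_excess(self):
        g = np.vstack([
            np.ones(20, dtype=np.int8),                       # 100% het: removed
            np.array([0] * 5 + [1] * 10 + [2] * 5, np.int8),  # 50% het: kept
        ])
        samples, ped = f2_sex_ped(10, 10)
        gt = make_gt(g, samples=samples)
        got = infer_f1_het_sites_by_af(gt, ped, (0.45, 0.55), het_excess_max=0.75)
        assert got.tolist() == [1]

    def test_one_sex_missing_errors(self):
        samples, ped = f2_sex_ped(4, 0)
        gt = make_gt(np.ones((2, 4), dtype=np.int8), samples=samples)
        with pytest.raises(ValueError):
            infer_f1_het_sites_by_af(gt, ped)

    def test_recovers_simulated_f1_het_sites(self):
        """Sensitivity for true F1-het (diagnostic) sites matches the exact
        binomial band probability: the mean-of-sex allele frequency at a true
        F1-het site is a convolution of two scaled binomials, and the AF-band
        filter keeps the site when it falls in [0.45, 0.55]."""
        from scipy.stats import binom
        from sexscan.simulate import CrossConfig, simulate_f2

        cfg = CrossConfig(n_chromosomes=22, n_markers=2000, n_f2=186,
                          depth_mean=20.0, missing_rate=0.0,
                          genotype_error_rate=0.0, sd_system="XY",
                          sd_chromosome=0, seed=31)
        gt, ped, truth = simulate_f2(cfg)
        got = set(infer_f1_het_sites_by_af(gt, ped).tolist())
        true_sites = set(np.flatnonzero(truth.sites["diagnostic"].values).tolist())
        sens = len(got & true_sites) / len(true_sites)

        # oracle: P(0.45 <= (S_m/2n_m + S_f/2n_f)/2 <= 0.55), S ~ Bin(2n, 1/2)
        n_m, n_f = len(ped.f2_males()), len(ped.f2_females())
        sm = np.arange(2 * n_m + 1)
        sf = np.arange(2 * n_f + 1)
        grid = (sm[:, None] / (2 * n_m) + sf[None, :] / (2 * n_f)) / 2
        pm = binom.pmf(sm, 2 * n_m, 0.5)[:, None] * binom.pmf(sf, 2 * n_f, 0.5)[None, :]
        expect = pm[(grid >= 0.45) & (grid <= 0.55)].sum()
        assert expect > 0.9  # at the mapping-cohort size the filter is sensitive
        # sites share the cohort, so allow for their correlation
        assert abs(sens - expect) < 0.1


class TestVcfIO:
    def test_round_trip(self, tmp_path, zw_cross):
        _, gt, ped, _ = zw_cross
        path = tmp_path / "x.vcf"
        gt.write_vcf(path)
        back = read_vcf(path, ped)
        assert back.samples == gt.samples
        assert np.array_equal(back.gt, gt.gt)
        assert np.array_equal(back.depth, gt.depth)
        assert back.markers["bp"].tolist() == gt.markers["bp"].tolist()

    def test_triallelic_dropped(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\n"
            "chr1\t100\ta\tA\tT\t.\t.\t.\tGT:DP\t0/1:20\t0/0:20\n"
            "chr1\t200\tb\tA\tT,G\t.\t.\t.\tGT:DP\t0/1:20\t0/2:20\n"
            "chr1\t300\tc\tAT\tA\t.\t.\t.\tGT:DP\t0/1:20\t0/0:20\n"
        )
        got = read_vcf(vcf)
        assert got.n_sites == 1
        assert got.markers["bp"].tolist() == [100]

    def test_unknown_sample_rejected(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tGHOST\n"
            "chr1\t100\ta\tA\tT\t.\t.\t.\tGT\t0/1\n"
        )
        ped = make_ped(["S0"])
        with pytest.raises(ValueError, match="GHOST"):
            read_vcf(vcf, ped)
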