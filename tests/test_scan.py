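"""Association scan: ANOVA/LOD/PVE formulas vs statsmodels, the intercross
HMM vs exact chain enumeration, binary interval mapping, permutation
thresholds, credible intervals, binomial sex-ratio test and cM->bp splines."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gt, f2_sex_ped
from oracles import anova_f_oracle, bayes_interval_oracle

from sexscan.core import MISSING
from sexscan.maps import kosambi_r
from sexscan.scan import (anova_lod, lod_from_f, pve_from_lod, bonferroni,
                          conditional_genotype_probs, interval_scan_binary,
                          _binary_model_lod, genome_scan_binary, LinkageMap,
                          permutation_threshold, bayes_interval,
                          binomial_sex_ratio_test, cm_bp_interpolate,
                          marker_regression_scan)


class TestAnovaLod:
    def test_worked_pve_example(self):
        """PVE from LOD 21.58 at n = 186 is 41.39% to two decimals."""
        assert round(float(pve_from_lod(21.58, 186)), 2) == 41.39

    def test_pve_identities(self):
        assert pve_from_lod(0.0, 100) == 0.0
        lods = np.linspace(0, 30, 50)
        pves = pve_from_lod(lods, 150)
        assert np.all(np.diff(pves) > 0)
        assert np.all(pves < 100)

    def test_eight_individual_toy_matches_textbook_sums(self):
        g = np.array([0, 0, 1, 1, 1, 2, 2, 2])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        F, df, n, lod, pve, p = anova_lod(g, y)
        # hand computation: group means 0, 2/3, 2/3; grand mean 1/2
        ssb = 2 * (0 - 0.5) ** 2 + 3 * (2 / 3 - 0.5) ** 2 + 3 * (2 / 3 - 0.5) ** 2
        ssw = sum(float(((y[g == c] - y[g == c].mean()) ** 2).sum()) for c in (0, 1, 2))
        F_hand = (ssb / 2) / (ssw / 5)
        assert F == pytest.approx(F_hand)
        assert df == 2 and n == 8
        assert lod == pytest.approx((8 / 2) * np.log10(F_hand * 2 / 5 + 1))

    def test_matches_statsmodels_on_random_toys(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(200):
            n = rng.integers(8, 30)
            g = rng.integers(0, 3, size=n)
            g[rng.random(n) < 0.1] = MISSING
            y = rng.integers(0, 2, size=n).astype(float)
            oracle = anova_f_oracle(g, y)
            F, df, n_used, lod, pve, p = anova_lod(g, y)
            if oracle is None:
                assert lod == 0.0
                continue
            if not np.isfinite(F):
                continue  # perfect separation: statsmodels F is unstable there
            assert F == pytest.approx(oracle[0], rel=1e-6, abs=1e-9)
            assert df == oracle[1]
            checked += 1
        assert checked > 100

    def test_constant_genotype_degenerate(self):
        F, df, n, lod, pve, p = anova_lod(np.ones(10, dtype=int), np.arange(10) % 2)
        assert lod == 0.0 and np.isnan(F)


class TestBonferroni:
    def test_examples_and_cap(self):
        assert bonferroni(np.array([0.01] + [1.0] * 9))[0] == pytest.approx(0.1)
        assert bonferroni(np.array([0.2] + [1.0] * 9))[0] == 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.random(50)
        _, adj, _, _ = multipletests(p, method="bonferroni")
        assert np.allclose(bonferroni(p), adj)


class TestGenotypeHMM:
    def test_observed_marker_has_probability_one_without_error(self):
        g = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
        pos, is_marker, probs = conditional_genotype_probs(g, [0.0, 10.0],
                                                          error_rate=0.0)
        for k in np.flatnonzero(is_marker):
            j = 0 if pos[k] == 0 else 1
            for i in range(3):
                assert probs[k, i, g[j, i]] == pytest.approx(1.0, abs=1e-9)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        g = rng.integers(-1, 3, size=(8, 5)).astype(np.int8)
        _, _, probs = conditional_genotype_probs(g, np.linspace(0, 35, 8))
        assert np.allclose(probs.sum(axis=2), 1.0)

    def test_missing_middle_marker_matches_exact_chain_enumeration(self):
        """Three markers 1 cM apart, middle missing: posterior at the middle
        equals brute-force enumeration over all 27 state paths."""
        e = 0.05
        g = np.array([[0], [MISSING], [0]], dtype=np.int8)
        cm = np.array([0.0, 1.0, 2.0])
        pos, is_marker, probs = conditional_genotype_probs(
            g, cm, step_cM=1.0, error_rate=e, map_function_name="kosambi")

        r = float(kosambi_r(1.0))
        s = 1 - r

        def trans(a, b):
            T = np.array([[s * s, 2 * s * r, r * r],
                          [s * r, s * s + r * r, s * r],
                          [r * r, 2 * s * r, s * s]])
            return T[a, b]

        def emit(obs, true):
            if obs == MISSING:
                return 1.0
            return 1 - e if obs == true else e / 2

        prior = [0.25, 0.5, 0.25]
        joint = np.zeros(3)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    joint[b] += (prior[a] * emit(0, a) * trans(a, b) * emit(MISSING, b)
                                 * trans(b, c) * emit(0, c))
        joint /= joint.sum()
        k_mid = int(np.flatnonzero(np.isclose(pos, 1.0))[0])
        assert np.allclose(probs[k_mid, 0], joint, atol=1e-12)
        assert joint[0] > 0.95  # flanked by identical homozygotes -> near 1

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError):
            conditional_genotype_probs(np.zeros((2, 1), np.int8), [5.0, 1.0])


class TestIntervalScan:
    def test_null_genotype_column_lod_near_zero(self):
        rng = np.random.default_rng(4)
        probs = np.tile(np.array([0.25, 0.5, 0.25]), (5, 40, 1))
        y = rng.integers(0, 2, 40).astype(float)
        lod = interval_scan_binary(probs, y)
        assert np.all(lod < 0.05)

    def test_agrees_with_direct_fit_at_informative_markers(self):
        """With error rate ~ 0 and full data, the interval LOD at a marker
        equals the direct binary-model likelihood ratio on observed genotypes."""
        rng = np.random.default_rng(9)
        n = 120
        g = rng.integers(0, 3, size=n)
        y = (rng.random(n) < np.where(g == 2, 0.8, 0.3)).astype(float)
        pos, is_marker, probs = conditional_genotype_probs(
            g.reshape(1, -1).astype(np.int8), [0.0], error_rate=1e-12)
        lod = interval_scan_binary(probs, y)

        def direct_binary_lod():
            p0 = y.mean()
            ll0 = (y * np.log(p0) + (1 - y) * np.log(1 - p0)).sum()
            ll1 = 0.0
            for c in (0, 1, 2):
                yc = y[g == c]
                pc = min(max(yc.mean(), 1e-12), 1 - 1e-12)
                ll1 += (yc * np.log(pc) + (1 - yc) * np.log(1 - pc)).sum()
            return (ll1 - ll0) / np.log(10)

        assert lod[0] == pytest.approx(direct_binary_lod(), abs=1e-3)

    def test_complete_separation_capped_and_flagged(self):
        g = np.array([0] * 20 + [2] * 20, dtype=np.int8)
        y = np.array([0.0] * 20 + [1.0] * 20)
        _, _, probs = conditional_genotype_probs(g.reshape(1, -1), [0.0],
                                                error_rate=1e-12)
        lod, sep = _binary_model_lod(probs, y)
        assert sep[0]
        assert lod[0] <= 50.0

    def test_peak_on_true_chromosome(self, xy_cross):
        cfg, gt, ped, truth = xy_cross
        diag = np.flatnonzero(truth.sites["diagnostic"].values)
        map_df = truth.sites.iloc[diag][["chrom", "marker_id", "bp", "cM"]]
        scan = genome_scan_binary(gt, LinkageMap(map_df.reset_index(drop=True)), ped)
        peak = scan.loc[scan["lod"].idxmax()]
        assert peak["chrom"] == cfg.chrom_name(cfg.sd_chromosome)
        lo, hi = bayes_interval(scan, peak["chrom"])
        assert lo <= cfg.sd_position_cM <= hi


class TestPermutationThreshold:
    @pytest.fixture(scope="class")
    def small_cross(self):
        from sexscan.simulate import CrossConfig, simulate_f2
        cfg = CrossConfig(n_chromosomes=2, chrom_lengths_bp=10_000_000,
                          chrom_lengths_cM=30.0, n_markers=60, n_f2=60,
                          diagnostic_rate=1.0, sd_system="none",
                          missing_rate=0.0, genotype_error_rate=0.0, seed=23)
        gt, ped, truth = simulate_f2(cfg)
        lmap = LinkageMap(truth.sites[["chrom", "marker_id", "bp", "cM"]],
                          step_cM=5.0)
        return gt, ped, lmap

    def test_monotone_and_reproducible(self, small_cross):
        gt, ped, lmap = small_cross
        thr = permutation_threshold(gt, lmap, ped, n_perm=60, seed=5)
        thr2 = permutation_threshold(gt, lmap, ped, n_perm=60, seed=5)
        assert thr == thr2
        assert thr[0.05] >= thr[0.1]

    def test_null_scan_rarely_exceeds_threshold(self, small_cross):
        """~5% of null scans exceed the alpha = 0.05 threshold."""
        gt, ped, lmap = small_cross
        thr = permutation_threshold(gt, lmap, ped, n_perm=200, seed=1)
        rng = np.random.default_rng(12)
        exceed = 0
        n_rep = 60
        for _ in range(n_rep):
            ped_null = ped.df.copy()
            f2 = ped_null["generation"] == "F2"
            ped_null.loc[f2, "sex"] = rng.permutation(ped_null.loc[f2, "sex"].values)
            from sexscan.core import PedigreeTable
            scan = genome_scan_binary(gt, lmap, PedigreeTable(ped_null))
            exceed += scan["lod"].max() > thr[0.05]
        assert exceed / n_rep < 0.15  # ~5% with Monte-Carlo slack


class TestBayesInterval:
    def _scan(self, lods, cm=None):
        cm = cm if cm is not None else np.arange(len(lods), dtype=float)
        return pd.DataFrame({"chrom": "chr01", "cM": cm, "lod": lods,
                             "is_pseudomarker": [False] * len(lods)})

    def test_sharp_peak_near_zero_width(self):
        lods = np.zeros(50)
        lods[25] = 20.0
        lo, hi = bayes_interval(self._scan(lods), "chr01")
        assert hi - lo <= 2.0

    def test_flat_lod_spans_nearly_whole_chromosome(self):
        lo, hi = bayes_interval(self._scan(np.ones(30)), "chr01")
        assert hi - lo == 28  # 29 of 30 uniform positions hold >= 95% mass

    def test_two_peak_profile_matches_direct_mass_summation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lods = rng.random(40) * 3
            lods[10] += rng.random() * 4
            lods[30] += rng.random() * 4
            lo_idx, hi_idx = bayes_interval_oracle(lods, 0.95)
            lo, hi = bayes_interval(self._scan(lods), "chr01", 0.95)
            assert (int(lo), int(hi)) == (lo_idx, hi_idx)


class TestSexRatio:
    def test_paper_scale_counts_significant(self):
        assert binomial_sex_ratio_test(51, 102) < 0.001

    def test_balanced_is_one(self):
        assert binomial_sex_ratio_test(5, 5) == pytest.approx(1.0)

    def test_two_vs_eight_enumeration(self):
        # sum of P(X=k) over outcomes with P <= P(X=2), X ~ Bin(10, 1/2)
        assert binomial_sex_ratio_test(2, 8) == pytest.approx(0.109375)


class TestCmBpSpline:
    def test_linear_map_predicts_on_line(self):
        cm = np.linspace(0, 50, 30)
        bp = cm * 1e5 + 1
        map_df = pd.DataFrame({"chrom": "chr01", "cM": cm, "bp": bp})
        pred = cm_bp_interpolate(map_df)["chr01"]
        x = np.array([5.0, 17.3, 42.0])
        assert np.allclose(pred(x), x * 1e5 + 1, rtol=1e-3)

    def test_interior_predictions_within_bp_range(self):
        rng = np.random.default_rng(8)
        cm = np.sort(rng.random(25) * 60)
        bp = np.sort(rng.integers(1, 30_000_000, size=25))
        map_df = pd.DataFrame({"chrom": "c", "cM": cm, "bp": bp})
        pred = cm_bp_interpolate(map_df)["c"]
        x = np.linspace(cm.min(), cm.max(), 100)
        v = pred(x)
        assert v.min() >= bp.min() and v.max() <= bp.max()
        assert np.all(np.diff(v[np.argsort(x)]) >= 0)

    def test_noisy_map_rmse_below_noise_sd(self):
        rng = np.random.default_rng(21)
        cm = np.linspace(0, 60, 80)
        curve = 1e5 * cm + 2e3 * cm ** 2
        noise_sd = 2e5
        bp = curve + rng.normal(0, noise_sd, size=len(cm))
        map_df = pd.DataFrame({"chrom": "c", "cM": cm, "bp": np.sort(bp)})
        pred = cm_bp_interpolate(map_df)["c"]
        rmse = np.sqrt(np.mean((pred(cm) - curve) ** 2))
        assert rmse < noise_sd


class TestMarkerScanIntegration:
    def test_family_covariate_runs_and_flags_peak(self, zw_cross):
        cfg, gt, ped, truth = zw_cross
        from sexscan.filters import apply_filter_cascade
        filt = apply_filter_cascade(gt)
        out = marker_regression_scan(filt, ped, family_covariate=True)
        peak = out.loc[out["lod"].idxmax()]
        assert peak["chrom"] == cfg.chrom_name(cfg.sd_chromosome)
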