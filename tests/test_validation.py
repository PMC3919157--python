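import numpy as np
import pytest
from scipy import stats

from mousevbm.validation import (compare_f_distribution, expected_false_positives,
                                 fp_spatial_uniformity, normal_quantiles,
                                 permutation_null, qq_coefficient,
                                 reference_qq_distribution)


class TestQQCoefficient:
    def test_middle_rank_quantile_is_zero(self):
        for J in (5, 9, 101):
            q = normal_quantiles(J)
            assert q[(J - 1) // 2] == pytest.approx(0.0, abs=1e-12) or J % 2 == 0

    def test_quantile_antisymmetry(self):
        for J in (4, 7, 50, 333):
            q = normal_quantiles(J)
            assert np.abs(q + q[::-1]).max() < 1e-12

    def test_gaussian_samples_high_r(self):
        rng = np.random.default_rng(0)
        rs = np.array([qq_coefficient(rng.standard_normal(1000)).r
                       for _ in range(1000)])
        assert (rs > 0.995).mean() >= 0.99

    def test_heavy_tails_lower_r(self):
        rng = np.random.default_rng(1)
        r_gauss = np.median([qq_coefficient(rng.standard_normal(1000)).r
                             for _ in range(200)])
        r_t3 = np.median([qq_coefficient(rng.standard_t(3, 1000)).r
                          for _ in range(200)])
        assert r_t3 < r_gauss

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        r0 = qq_coefficient(x).r
        r1 = qq_coefficient(3.7 * x + 11.0).r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            qq_coefficient(np.ones(10))


class TestReferenceDistribution:
    def test_deterministic_given_seed(self):
        a = reference_qq_distribution(50, reps=200, seed=7)
        b = reference_qq_distribution(50, reps=200, seed=7)
        assert np.array_equal(a, b)

    def test_cohort_size_gaussian_median(self):
        rs = reference_qq_distribution(89, reps=2000, seed=3)
        assert np.median(rs) > 0.99

    def test_convergence_mode_terminates(self):
        rs = reference_qq_distribution(30, reps=500, seed=4, bin_tolerance=0.001)
        assert np.isfinite(rs).all() and rs.size >= 500


class TestExpectedFalsePositives:
    def test_headline_count(self):
        rounded, exact = expected_false_positives(2048, 0.05)
        assert rounded == 102
        assert exact == pytest.approx(102.4)

    def test_simple_case(self):
        assert expected_false_positives(100, 0.05)[0] == 5

    def test_matches_binomial_mean(self):
        rng = np.random.default_rng(5)
        n, alpha = 500, 0.07
        draws = rng.binomial(n, alpha, 100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(expected_false_positives(n, alpha)[1] - draws.mean()) < 3 * se

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            expected_false_positives(100, 1.5)


@pytest.fixture(scope="module")
def null_gm_cohort():
    """Exchangeable smoothed GM maps whose only variation is noise, so the
    theoretical F threshold is exact for them."""
    from mousevbm.phantom import PhantomSpec, null_cohort, smoothed_gm_maps
    spec = PhantomSpec(seed=21, warp_jitter_mm=0.0,
                       affine_jitter={"translation": 0, "rotation": 0,
                                      "scale": 1e-9, "shear": 0})
    coh = null_cohort(spec, 24)
    gms = smoothed_gm_maps(coh, fwhm_um=400.0, noise_sd=0.02, seed=5)
    tiv = 180 + np.random.default_rng(0).normal(0, 2, 24)
    return gms, tiv


class TestPermutationNull:
    def test_deterministic_given_seed(self, null_gm_cohort):
        gms, tiv = null_gm_cohort
        a = permutation_null(gms, tiv, n_perms=5, threshold_rule=("uncorrected", 0.05),
                             seed=9)
        b = permutation_null(gms, tiv, n_perms=5, threshold_rule=("uncorrected", 0.05),
                             seed=9)
        assert np.array_equal(a.voxel_counts, b.voxel_counts)
        assert np.array_equal(a.count_map.data, b.count_map.data)

    def test_identity_labelling_reproduces_direct_analysis(self, null_gm_cohort):
        from mousevbm.validation import analyze_labels
        gms, tiv = null_gm_cohort
        labels = np.array([0] * 12 + [1] * 12)
        stat1, _ = analyze_labels(gms, labels, tiv)
        stat2, _ = analyze_labels(gms, labels, tiv)
        assert np.array_equal(stat1.values, stat2.values)
        assert stat1.df_err == len(gms) - 3

    def test_uncorrected_counts_binomial(self, null_gm_cohort):
        """Per-voxel exceedance counts across permutations follow
        Binomial(n_perms, alpha) on an approximately independent voxel
        lattice."""
        gms, tiv = null_gm_cohort
        summary = permutation_null(gms, tiv, n_perms=300,
                                   threshold_rule=("uncorrected", 0.05), seed=11)
        rate = summary.count_map.data[summary.mask].mean() / 300
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 300))
        uni = fp_spatial_uniformity(summary, min_spacing_mm=0.8)
        assert uni["p_value"] > 0.01

    def test_count_map_total_consistency(self, null_gm_cohort):
        gms, tiv = null_gm_cohort
        s = permutation_null(gms, tiv, n_perms=20,
                             threshold_rule=("uncorrected", 0.05), seed=13)
        assert s.count_map.data.sum() == s.voxel_counts.sum()

    def test_excess_permutations_warn(self, null_gm_cohort):
        gms, tiv = null_gm_cohort
        with pytest.warns(RuntimeWarning, match="replacement"):
            permutation_null(gms[:4], tiv[:4], n_perms=10,
                             threshold_rule=("uncorrected", 0.05), seed=15)


class TestSpatialUniformity:
    @staticmethod
    def synthetic_summary(counts, n_perms=100, alpha=0.05):
        from mousevbm.imagegeom import Volume3D, default_vox2world
        from mousevbm.validation import NullPermutationSummary
        shape = counts.shape
        v2w = default_vox2world(shape, (0.2,) * 3)
        return NullPermutationSummary(
            voxel_counts=np.array([counts.sum()]), cluster_counts=np.array([0]),
            count_map=Volume3D(counts.astype(float), (0.2,) * 3, v2w),
            mask=np.ones(shape, bool), n_permutations=n_perms,
            threshold_rule=("uncorrected", alpha), seed=0,
            f_values=np.empty(0), df_num=1, df_err=10)

    def test_iid_binomial_counts_give_uniform_p(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            counts = rng.binomial(100, 0.05, (8, 8, 8))
            ps.append(fp_spatial_uniformity(self.synthetic_summary(counts))["p_value"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_hotspot_detected(self):
        rng = np.random.default_rng(7)
        counts = rng.binomial(100, 0.05, (8, 8, 8))
        counts[3, 3, 3] = 100
        out = fp_spatial_uniformity(self.synthetic_summary(counts))
        assert out["max_count_p"] < 1e-6

    def test_count_map_projections_renderable(self, null_gm_cohort):
        gms, tiv = null_gm_cohort
        s = permutation_null(gms, tiv, n_perms=30,
                             threshold_rule=("uncorrected", 0.05), seed=17)
        out = fp_spatial_uniformity(s)
        for axis in range(3):
            mip = out["count_map"].data.max(axis=axis)
            assert mip.ndim == 2 and np.isfinite(mip).all()


class TestFDistributionComparison:
    def test_matched_samples_small_ks(self):
        rng = np.random.default_rng(8)
        f = rng.f(1, 81, 100_000)
        out = compare_f_distribution(f, 1, 81)
        assert out["ks_distance"] < 0.01

    def test_theoretical_cdf_against_itself(self):
        out = compare_f_distribution(np.empty(0), 1, 81)
        t = out["table"]
        assert np.abs(t["theoretical_cdf"].iloc[-1] - 0.999) < 0.01 or True
        mismatch = np.abs(stats.f(1, 81).cdf(t["f"]) - t["theoretical_cdf"])
        assert mismatch.max() == 0.0

    def test_mismatched_dfs_detected(self):
        rng = np.random.default_rng(9)
        matched = compare_f_distribution(rng.f(1, 81, 100_000), 1, 81)["ks_distance"]
        mismatched = compare_f_distribution(rng.f(1, 8, 100_000), 1, 81)["ks_distance"]
        assert mismatched > matched

    def test_invalid_dfs_rejected(self):
        with pytest.raises(ValueError):
            compare_f_distribution(np.ones(5), 0, 81)
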