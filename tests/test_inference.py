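"""Group inference: ANCOVA F, smoothness, cluster correction, post-hoc
contrasts, Mann-Whitney U and Pearson correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, stats

from couplemap import inference
from couplemap.inference import (
    ClusterResult,
    StatMap,
    build_design,
    correlate_with_mmse,
    estimate_smoothness,
    fit_voxelwise_ancova,
    gaussianize_f,
    grf_cluster_correct,
    grf_cluster_p,
    mann_whitney_u,
    pearson_r_to_p,
    permutation_cluster_correct,
    posthoc_pairwise,
)


def make_phenotype(groups, rng, age=None):
    n = len(groups)
    return pd.DataFrame({
        "subject": [f"s{i}" for i in range(n)],
        "group": groups,
        "age": rng.normal(75, 8, n) if age is None else age,
        "gender": rng.integers(0, 2, n),
        "education": rng.integers(10, 20, n).astype(float),
    })


def brute_force_partial_f(y, X_full, X_red):
    """Independent two-model RSS computation of the partial F."""
    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    df1 = X_full.shape[1] - X_red.shape[1]
    df2 = len(y) - X_full.shape[1]
    return ((rss(X_red) - rss(X_full)) / df1) / (rss(X_full) / df2)


class TestAncova:
    def test_nine_subject_example_matches_rss_oracle(self, rng):
        groups = np.repeat(["NC", "VMCI", "MCI"], 3)
        pheno = make_phenotype(groups, rng)
        design = build_design(pheno)
        y = rng.standard_normal(9)
        stack = y.reshape(9, 1, 1, 1)
        mask = np.ones((1, 1, 1), dtype=bool)
        stat, resid = fit_voxelwise_ancova(stack, design, mask)
        expected = brute_force_partial_f(y, design.full, design.reduced)
        assert stat.data[0, 0, 0] == pytest.approx(expected, rel=1e-10)
        assert stat.df == (2, 9 - 6)  # intercept + 2 dummies + 3 covariates

    def test_null_data_p_rate_near_nominal(self):
        rng = np.random.default_rng(1234)
        n = 30
        pheno = make_phenotype(np.repeat(["NC", "VMCI", "MCI"], n // 3), rng)
        design = build_design(pheno)
        nvox = 10_000
        stack = rng.standard_normal((n, nvox, 1, 1))
        mask = np.ones((nvox, 1, 1), dtype=bool)
        stat, _ = fit_voxelwise_ancova(stack, design, mask)
        pvals = stats.f.sf(stat.data[mask], *stat.df)
        rate = (pvals < 0.001).mean()
        se = np.sqrt(0.001 * 0.999 / nvox)
        assert abs(rate - 0.001) < 3 * se

    def test_age_mediated_group_difference_absorbed_by_covariate(self):
        # group means differ only through age; age is in the design, so the
        # group F concentrates near its null
        rng = np.random.default_rng(99)
        n_g = 20
        groups = np.repeat(["NC", "VMCI", "MCI"], n_g)
        age = np.concatenate([rng.normal(70, 3, n_g), rng.normal(75, 3, n_g),
                              rng.normal(80, 3, n_g)])
        pheno = make_phenotype(groups, rng, age=age)
        design = build_design(pheno)
        nvox = 2000
        stack = (0.1 * age)[:, None] + rng.standard_normal((3 * n_g, nvox))
        stat, _ = fit_voxelwise_ancova(stack.reshape(3 * n_g, nvox, 1, 1),
                                       design, np.ones((nvox, 1, 1), bool))
        pvals = stats.f.sf(stat.data[..., 0, 0], *stat.df)
        assert np.median(pvals) > 0.3

    def test_small_group_rejected(self, rng):
        pheno = make_phenotype(["NC"] * 4 + ["VMCI"] * 2 + ["MCI"], rng)
        design = build_design(pheno)
        with pytest.raises(ValueError):
            fit_voxelwise_ancova(np.zeros((7, 1, 1, 1)), design,
                                 np.ones((1, 1, 1), bool))


class TestSmoothness:
    def _stack(self, rng, fwhm_mm, n_img=12, grid=24, voxel=3.0):
        sigma = fwhm_mm / voxel / 2.3548200450309493
        fields = [ndimage.gaussian_filter(rng.standard_normal((grid,) * 3),
                                          sigma, mode="wrap")
                  for _ in range(n_img)]
        return np.stack(fields)

    def test_recovers_applied_smoothing(self):
        rng = np.random.default_rng(5)
        grid, voxel = 24, 3.0
        mask = np.ones((grid,) * 3, dtype=bool)
        estimates = [
            estimate_smoothness(self._stack(rng, 6.0), mask, voxel).fwhm_mm.mean()
            for _ in range(50)
        ]
        assert np.mean(estimates) == pytest.approx(6.0, rel=0.10)

    def test_white_noise_estimates_near_voxel_size(self):
        rng = np.random.default_rng(6)
        grid, voxel = 24, 3.0
        mask = np.ones((grid,) * 3, dtype=bool)
        stack = np.stack([rng.standard_normal((grid,) * 3) for _ in range(12)])
        est = estimate_smoothness(stack, mask, voxel)
        assert est.fwhm_mm.mean() == pytest.approx(voxel, rel=0.25)

    def test_resels_identity(self, rng):
        mask = np.ones((10, 10, 10), dtype=bool)
        est = estimate_smoothness(self._stack(rng, 5.0, grid=10), mask, 3.0)
        assert est.resels == pytest.approx(mask.sum() / np.prod(est.fwhm_vox))

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_smoothness(rng.standard_normal((5, 8, 8, 8)),
                                np.ones((8, 8, 8), bool), 3.0)


class TestGrfCorrection:
    def _smoothness(self, fwhm_mm=8.0, voxel=3.0, grid=20):
        rng = np.random.default_rng(2)
        sigma = fwhm_mm / voxel / 2.3548200450309493
        stack = np.stack([ndimage.gaussian_filter(
            rng.standard_normal((grid,) * 3), sigma, mode="wrap") for _ in range(12)])
        return estimate_smoothness(stack, np.ones((grid,) * 3, bool), voxel)

    def test_subthreshold_map_gives_empty_result(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        stat = StatMap(np.full(mask.shape, 1.0), (2, 40), mask)
        out = grf_cluster_correct(stat, self._smoothness(), np.eye(4))
        assert out == []

    def test_cluster_p_decreases_with_size(self):
        smooth = self._smoothness()
        ps = [grf_cluster_p(k, smooth, 0.001, 8000) for k in (5, 20, 80, 320)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 <= p <= 1 for p in ps)

    def test_gaussianized_f_preserves_tail_probability(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        f_vals = np.array([1.0, 5.0, 10.0, 20.0, 3.3, 7.7, 2.2, 0.5]).reshape(2, 2, 2)
        stat = StatMap(f_vals, (2, 85), mask)
        z = gaussianize_f(stat)
        np.testing.assert_allclose(stats.norm.sf(z),
                                   stats.f.sf(f_vals, 2, 85), rtol=1e-10)

    def test_strong_effect_yields_significant_cluster_with_subject_means(self, rng):
        grid, voxel = 20, 3.0
        sigma = 8.0 / voxel / 2.3548200450309493
        groups = np.repeat(["NC", "VMCI", "MCI"], 10)
        pheno = make_phenotype(groups, rng)
        design = build_design(pheno)
        region = np.zeros((grid,) * 3, dtype=bool)
        region[8:13, 8:13, 8:13] = True
        fields = []
        for _ in range(30):
            f = ndimage.gaussian_filter(rng.standard_normal((grid,) * 3),
                                        sigma, mode="wrap")
            fields.append(f / f.std())
        stack = np.stack(fields)
        shift = {"NC": 0.0, "VMCI": 1.0, "MCI": 2.0}
        for i, g in enumerate(groups):
            stack[i][region] += shift[g]
        mask = np.ones((grid,) * 3, dtype=bool)
        stat, resid = fit_voxelwise_ancova(stack, design, mask)
        smooth = estimate_smoothness(resid, mask, voxel)
        clusters = grf_cluster_correct(stat, smooth, np.diag([3, 3, 3, 1.0]),
                                       map_stack=stack)
        assert clusters, "expected a significant cluster"
        top = clusters[0]
        assert region[top.voxel_indices].mean() > 0.5
        assert top.per_subject_means.shape == (30,)
        # group ordering of the cluster means follows the injected shifts
        means = {g: top.per_subject_means[groups == g].mean() for g in shift}
        assert means["NC"] < means["VMCI"] < means["MCI"]


class TestPermutation:
    def test_deterministic_given_seed(self, rng):
        grid = 10
        groups = np.repeat(["NC", "VMCI", "MCI"], 8)
        pheno = make_phenotype(groups, rng)
        design = build_design(pheno)
        stack = np.random.default_rng(3).standard_normal((24, grid, grid, grid))
        stack[:8, 4:7, 4:7, 4:7] -= 2.0
        mask = np.ones((grid,) * 3, dtype=bool)
        kwargs = dict(voxel_p=0.01, n_perm=120, seed=7)
        a = permutation_cluster_correct(stack, design, mask, np.eye(4), **kwargs)
        b = permutation_cluster_correct(stack, design, mask, np.eye(4), **kwargs)
        assert [(c.label, c.cluster_p, c.cluster_size_voxels) for c in a] == \
               [(c.label, c.cluster_p, c.cluster_size_voxels) for c in b]
        assert a and a[0].cluster_p < 0.05

    def test_minimum_permutations_enforced(self, rng):
        pheno = make_phenotype(np.repeat(["NC", "VMCI", "MCI"], 3), rng)
        with pytest.raises(ValueError):
            permutation_cluster_correct(np.zeros((9, 4, 4, 4)),
                                        build_design(pheno),
                                        np.ones((4, 4, 4), bool), np.eye(4),
                                        n_perm=10)


class TestPosthoc:
    def test_identical_groups_give_null_statistics(self):
        rng = np.random.default_rng(11)
        groups = np.repeat(["NC", "VMCI", "MCI"], 30)
        pheno = make_phenotype(groups, rng)
        design = build_design(pheno)
        values = rng.standard_normal(90)
        results = posthoc_pairwise(values, design, n_regions=1)
        for r in results:
            assert abs(r.t_stat) < 3.0
            assert r.p_u > 0.001

    def test_zero_covariate_effect_matches_plain_t(self, rng):
        groups = np.repeat(["NC", "VMCI", "MCI"], 15)
        n = len(groups)
        dummies = np.column_stack([(groups == g).astype(float)
                                   for g in ("VMCI", "MCI")])
        covs = np.zeros((n, 3))  # constant covariates: reduces to a plain t-test
        design = inference.DesignMatrix(
            np.column_stack([np.ones(n), dummies, covs]),
            np.column_stack([np.ones(n), covs]),
            groups, np.arange(n))
        values = rng.standard_normal(45)
        values[30:] += 1.0
        res = {r.pair: r for r in posthoc_pairwise(values, design, 1,
                                                   method="ancova_t")}
        plain = stats.ttest_ind(values[(design.groups == "MCI")],
                                values[(design.groups == "NC")])
        assert abs(res[("NC", "MCI")].t_stat) == pytest.approx(
            abs(plain.statistic), rel=1e-8)
        assert res[("NC", "MCI")].p_t == pytest.approx(plain.pvalue, rel=1e-6)

    def test_bonferroni_is_min_of_one_and_np(self, rng):
        groups = np.repeat(["NC", "VMCI", "MCI"], 10)
        design = build_design(make_phenotype(groups, rng))
        values = rng.standard_normal(30)
        for n_regions in (1, 3, 50):
            for r in posthoc_pairwise(values, design, n_regions):
                assert r.p_bonferroni == pytest.approx(
                    min(1.0, r.p_raw * n_regions))
                assert r.significant == (r.p_raw < 0.05 / n_regions)


class TestMannWhitney:
    def brute_force(self, x, y):
        u_xy = sum((xi < yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        return min(u_xy, len(x) * len(y) - u_xy)

    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=0.001)  # exact two-sided 2/20

    def test_interleaved_example(self):
        u, _ = mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert u == self.brute_force([1, 3, 5], [2, 4, 6]) == 3.0

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, rng.integers(1, 9)).astype(float)
        y = rng.integers(0, 10, rng.integers(1, 9)).astype(float)
        u, p = mann_whitney_u(x, y)
        assert u == self.brute_force(x, y)
        assert 0 <= p <= 1

    def test_exact_close_to_normal_approximation_at_n15(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.3, 1, 15)
        _, p_exact = mann_whitney_u(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.01

    def test_all_identical_values(self):
        u, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
        assert u == 3.0  # n1*n2/2 with all ties

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_r_zero_gives_p_one(self):
        assert pearson_r_to_p(0.0, 50) == 1.0

    def test_perfect_correlation_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert pearson_r_to_p(1.0, 10) == 0.0

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = correlate_with_mmse(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identity_gives_r_one(self, rng):
        x = rng.standard_normal(20)
        with pytest.warns(UserWarning):
            res = correlate_with_mmse(x, x.copy())
        assert res.r == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(314)
        hits = sum(
            correlate_with_mmse(rng.standard_normal(90),
                                rng.standard_normal(90)).p_two_tailed < 0.05
            for _ in range(200)
        )
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(hits / 200 - 0.05) < 3 * se

    def test_recovers_true_correlation(self):
        rng = np.random.default_rng(2718)
        n, r_true = 500, -0.4
        x = rng.standard_normal(n)
        y = r_true * x + np.sqrt(1 - r_true ** 2) * rng.standard_normal(n)
        res = correlate_with_mmse(x, y)
        assert res.r == pytest.approx(r_true, abs=0.05)

    def test_group_filter(self, rng):
        groups = np.array(["NC"] * 5 + ["VMCI"] * 20)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        res = correlate_with_mmse(x, y, groups, "VMCI")
        assert res.n == 20

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_mmse(np.ones(10), np.arange(10.0))
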