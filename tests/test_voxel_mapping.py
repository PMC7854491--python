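import numpy as np
import pytest

from connectotier.lesion_tier import BinaryMask
from connectotier.stats import rank_sum_test
from connectotier.voxel_mapping import (
    dichotomise,
    fit_svr_sgd,
    fit_voxelwise_svr,
    stack_masks,
    subgroup_probability_map,
    svr_objective,
    voxelwise_group_test,
)

from oracles import svr_optimal_objective

AFF = np.eye(4)


def mask_of(grid):
    return BinaryMask(grid=np.asarray(grid, bool), affine=AFF,
                      voxel_volume=0.001)


def random_stack(rng, n_subj=12, shape=(10, 10, 10), rate=0.25):
    icv = np.zeros(shape, bool)
    icv[2:8, 2:8, 2:8] = True
    masks = [mask_of(icv & (rng.random(shape) < rate)) for _ in range(n_subj)]
    return stack_masks(masks, mask_of(icv)), masks, mask_of(icv)


class TestStackMasks:
    def test_crop_box_is_icv_bounding_box(self):
        icv = np.zeros((8, 8, 8), bool)
        icv[2:6, 2:6, 2:6] = True
        stack = stack_masks([mask_of(np.zeros((8, 8, 8)))], mask_of(icv))
        assert stack.crop_box == ((2, 6), (2, 6), (2, 6))

    def test_all_zero_masks(self):
        icv = np.zeros((6, 6, 6), bool)
        icv[1:5, 1:5, 1:5] = True
        stack = stack_masks([mask_of(np.zeros((6, 6, 6)))] * 3, mask_of(icv))
        assert stack.data.shape == (3, 64)
        assert stack.data.sum() == 0

    def test_unstack_round_trip(self, rng):
        stack, masks, _ = random_stack(rng)
        for i, m in enumerate(masks):
            np.testing.assert_array_equal(stack.unstack(i), m.grid)

    def test_grid_mismatch_and_empty_icv(self, rng):
        with pytest.raises(ValueError, match="shape"):
            stack_masks([mask_of(np.zeros((4, 4, 4)))],
                        mask_of(np.ones((5, 5, 5))))
        with pytest.raises(ValueError, match="empty ICV"):
            stack_masks([mask_of(np.zeros((4, 4, 4)))],
                        mask_of(np.zeros((4, 4, 4))))


class TestSubgroupProbabilityMap:
    def test_single_subject_is_its_mask(self, rng):
        stack, masks, _ = random_stack(rng)
        np.testing.assert_array_equal(
            subgroup_probability_map(stack, [0]) > 0.5, masks[0].grid)

    def test_two_of_three(self):
        icv = np.zeros((5, 5, 5), bool)
        icv[1:4, 1:4, 1:4] = True
        on = np.zeros((5, 5, 5), bool)
        on[2, 2, 2] = True
        stack = stack_masks([mask_of(on), mask_of(on),
                             mask_of(np.zeros((5, 5, 5)))], mask_of(icv))
        pm = subgroup_probability_map(stack, [0, 1, 2])
        assert pm[2, 2, 2] == pytest.approx(2 / 3)

    def test_complement_additivity(self, rng):
        stack, _, _ = random_stack(rng, n_subj=9)
        sub_a = np.arange(4)
        sub_b = np.arange(4, 9)
        total = 9 * subgroup_probability_map(stack, np.arange(9))
        parts = (4 * subgroup_probability_map(stack, sub_a)
                 + 5 * subgroup_probability_map(stack, sub_b))
        np.testing.assert_allclose(total, parts, atol=1e-12)

    def test_empty_subgroup_rejected(self, rng):
        stack, _, _ = random_stack(rng)
        with pytest.raises(ValueError):
            subgroup_probability_map(stack, [])


class TestDichotomise:
    def test_median_split(self):
        assert dichotomise([1, 2, 3, 4]).tolist() == \
            ["low", "low", "high", "high"]

    def test_boundary_to_lower(self):
        assert dichotomise([1, 1, 1, 2]).tolist() == \
            ["low", "low", "low", "high"]

    def test_quartiles_of_one_to_eight(self):
        labels = dichotomise(np.arange(1, 9), "quartiles")
        assert labels.tolist() == ["q1", "q1", "q2", "q2",
                                   "q3", "q3", "q4", "q4"]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomise([2, 2, 2, 2])


class TestVoxelwiseGroupTest:
    def test_identical_groups_no_rejections(self, rng):
        stack, _, _ = random_stack(rng, n_subj=10)
        half = stack.data[:5]
        stack2 = type(stack)(
            data=np.vstack([half, half]), crop_box=stack.crop_box,
            grid_shape=stack.grid_shape, affine=stack.affine)
        maps = voxelwise_group_test(stack2, ["a"] * 5 + ["b"] * 5)
        assert not maps.passed.any()

    def test_planted_voxel_survives_among_nulls(self):
        rng = np.random.default_rng(7)
        n = 20
        shape = (7, 7, 7)
        icv = np.ones(shape, bool)
        masks = []
        for s in range(n):
            g = rng.random(shape) < 0.5
            g[0, 0, 0] = s < 10  # on in all of group A, off in all of B
            masks.append(mask_of(g))
        stack = stack_masks(masks, mask_of(icv))
        maps = voxelwise_group_test(stack, ["a"] * 10 + ["b"] * 10)
        assert maps.n_tested >= 100
        assert maps.passed[0, 0, 0]
        # the planted voxel attains the smallest p in the map
        assert maps.p[0, 0, 0] == np.nanmin(maps.p)

    def test_row_permutation_invariance(self, rng):
        stack, _, _ = random_stack(rng, n_subj=10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        stack_p = type(stack)(
            data=stack.data[perm], crop_box=stack.crop_box,
            grid_shape=stack.grid_shape, affine=stack.affine)
        m1 = voxelwise_group_test(stack, labels)
        m2 = voxelwise_group_test(stack_p, labels[perm])
        np.testing.assert_allclose(m1.p, m2.p, equal_nan=True)

    def test_constant_voxels_outside_fdr_family(self, rng):
        stack, _, _ = random_stack(rng)
        maps = voxelwise_group_test(stack, ["a"] * 6 + ["b"] * 6)
        total = stack.data.sum(axis=0)
        n_varying = int(((total > 0) & (total < 12)).sum())
        assert maps.n_tested == n_varying
        box = tuple(slice(a, b) for a, b in stack.crop_box)
        assert np.isnan(maps.p[box]).sum() == stack.data.shape[1] - n_varying

    def test_matches_stats_module_per_voxel(self, rng):
        stack, _, _ = random_stack(rng, n_subj=11)
        labels = np.array(["a"] * 5 + ["b"] * 6)
        maps = voxelwise_group_test(stack, labels)
        box = tuple(slice(a, b) for a, b in stack.crop_box)
        p_box = maps.p[box].ravel()
        for j in rng.choice(stack.data.shape[1], size=25, replace=False):
            col = stack.data[:, j].astype(float)
            if col.min() == col.max():
                assert np.isnan(p_box[j])
                continue
            expected = rank_sum_test(col[labels == "a"], col[labels == "b"])
            assert p_box[j] == pytest.approx(expected.p_value)

    def test_kruskal_mode_with_quartile_groups(self, rng):
        stack, _, _ = random_stack(rng, n_subj=16)
        labels = dichotomise(rng.normal(size=16), "quartiles")
        maps = voxelwise_group_test(stack, labels, test="kruskal")
        assert maps.method == "kruskal"
        assert maps.n_tested > 0

    def test_group_size_checks(self, rng):
        stack, _, _ = random_stack(rng, n_subj=6)
        with pytest.raises(ValueError, match="two groups"):
            voxelwise_group_test(stack, ["a"] * 6)
        with pytest.raises(ValueError, match="at least 2"):
            voxelwise_group_test(stack, ["a"] * 5 + ["b"])


class TestSvrFit:
    def make_instance(self, seed, n=20, p=30):
        rng = np.random.default_rng(seed)
        X = (rng.random((n, p)) < 0.3).astype(float)
        X = np.hstack([X, rng.standard_normal((n, 2))])
        beta = np.zeros(p + 2)
        beta[:5] = rng.normal(0, 1, 5)
        y = X @ beta + rng.normal(0, 0.5, n)
        q75, q25 = np.percentile(y, [75, 25])
        return X, y, (q75 - q25) / 13.49

    def test_objective_matches_convex_oracle(self):
        lam = 1 / 47
        for seed in (0, 1, 2):
            X, y, eps = self.make_instance(seed)
            fit = fit_svr_sgd(X, y, lam, eps, seed=seed, n_epochs=20000)
            opt = svr_optimal_objective(X, y, lam, eps)
            assert fit.objective >= opt - 1e-9
            assert fit.objective - opt < 1e-4

    def test_trace_decreases_and_converges(self):
        X, y, eps = self.make_instance(5)
        fit = fit_svr_sgd(X, y, 1 / 47, eps, seed=5, n_epochs=20000)
        trace = np.array(fit.trace)
        assert trace[-1] <= trace[0]
        # averaged-iterate objective is monotone within a small tolerance
        assert (np.diff(trace[1:]) <= 1e-4 * np.abs(trace[1:-1]) + 1e-12).all()
        assert fit.converged

    def test_deterministic_given_seed(self):
        X, y, eps = self.make_instance(3)
        f1 = fit_svr_sgd(X, y, 1 / 47, eps, seed=11, n_epochs=200)
        f2 = fit_svr_sgd(X, y, 1 / 47, eps, seed=11, n_epochs=200)
        np.testing.assert_array_equal(f1.w, f2.w)
        assert f1.intercept == f2.intercept


class TestFitVoxelwiseSvr:
    def small_cohort(self, seed=0, n=14, shape=(8, 8, 8)):
        rng = np.random.default_rng(seed)
        icv = np.ones(shape, bool)
        z = rng.standard_normal(n)
        masks = []
        for s in range(n):
            g = rng.random(shape) < 0.15
            # planted 2x2x2 cluster tracks the indicator
            g[3:5, 3:5, 3:5] = rng.random((2, 2, 2)) < 1 / (1 + np.exp(-2 * z[s]))
            masks.append(mask_of(g))
        stack = stack_masks(masks, mask_of(icv))
        cov = np.column_stack([rng.normal(50, 10, n),
                               (rng.random(n) < 0.5).astype(float)])
        return stack, z, cov

    def test_ridge_shrinkage_limit(self):
        stack, z, cov = self.small_cohort()
        small = fit_voxelwise_svr(stack, z, cov, lam=1 / 47, seed=1,
                                  n_epochs=150)
        huge = fit_voxelwise_svr(stack, z, cov, lam=1e6, seed=1, n_epochs=150)
        assert np.nanmax(np.abs(huge.b_map)) < \
            1e-3 * np.nanmax(np.abs(small.b_map))

    def test_constant_voxels_get_zero_b(self):
        stack, z, cov = self.small_cohort()
        svr = fit_voxelwise_svr(stack, z, cov, seed=0, n_epochs=50)
        box = tuple(slice(a, b) for a, b in stack.crop_box)
        b_box = svr.b_map[box].ravel()
        total = stack.data.sum(axis=0)
        constant = (total == 0) | (total == stack.n_subjects)
        assert (b_box[constant] == 0).all()

    def test_covariate_coefficients_reported(self):
        stack, z, cov = self.small_cohort()
        svr = fit_voxelwise_svr(stack, z, cov, seed=0, n_epochs=50)
        assert set(svr.covariate_coefs) == {"age", "sex"}

    def test_degenerate_outcomes_rejected(self):
        stack, z, cov = self.small_cohort()
        with pytest.raises(ValueError, match="constant outcome"):
            fit_voxelwise_svr(stack, np.ones(stack.n_subjects), cov, seed=0)
        bad = z.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_voxelwise_svr(stack, bad, cov, seed=0)
        with pytest.raises(ValueError, match="lambda"):
            fit_voxelwise_svr(stack, z, cov, lam=0.0, seed=0)

    def test_epsilon_auto_is_iqr_scaled(self):
        stack, z, cov = self.small_cohort()
        svr = fit_voxelwise_svr(stack, z, cov, seed=0, n_epochs=20)
        q75, q25 = np.percentile(z, [75, 25])
        assert svr.epsilon == pytest.approx((q75 - q25) / 13.49)

    def test_planted_cluster_attains_high_b(self):
        stack, z, cov = self.small_cohort(seed=4)
        svr = fit_voxelwise_svr(stack, z, cov, seed=4, n_epochs=300)
        cluster = np.zeros((8, 8, 8), bool)
        cluster[3:5, 3:5, 3:5] = True
        b = svr.b_map
        nz = b[np.isfinite(b) & (b != 0)]
        thr = np.quantile(np.abs(nz), 0.9)
        assert np.mean(np.abs(b[cluster]) >= thr) >= 0.75
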