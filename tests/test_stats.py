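import itertools

import numpy as np
import pandas as pd
import pytest

from scnkit import auc_over_densities, cohens_d, fdr_bh, permute_global
from scnkit.covariates import ResidualTable
from scnkit.errors import ParameterError
from scnkit.network import DensityGrid
from scnkit.stats import permute_nodal, permute_robustness


def residual_table(X, group):
    return ResidualTable(
        subject_id=[f"s{i}" for i in range(X.shape[0])],
        group=np.asarray(group, dtype=object),
        residuals=np.asarray(X, dtype=float),
        region_labels=[f"r{j}" for j in range(X.shape[1])],
        covariates=(),
        scope="pooled",
        model_info=pd.DataFrame(),
    )


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d(1.0, 0.2, 1.0, 0.3).cohens_d == 0.0

    def test_pooled_sd_formula(self):
        es = cohens_d(0.0, 1.0, 1.0, 1.0)
        assert es.cohens_d == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ParameterError):
            cohens_d(1.0, 0.0, 2.0, 0.0)


class TestFdrBH:
    def test_all_ones_reject_nothing(self):
        assert not fdr_bh(np.ones(10)).any()

    def test_all_tiny_reject_everything(self):
        assert fdr_bh(np.full(10, 0.001)).all()

    def test_step_up_thresholds_by_hand(self):
        # thresholds q*k/m = 0.0125, 0.025, 0.0375, 0.05:
        # p3=0.04 > 0.0375 and p4=0.8, so exactly the first two reject
        mask = fdr_bh([0.01, 0.02, 0.04, 0.8], q=0.05)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_rejections_subset_of_uncorrected_and_monotone_in_q(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 40) ** 2
        for q in (0.01, 0.05, 0.2):
            mask = fdr_bh(p, q=q)
            assert np.all(~mask | (p < q))  # BH rejects only p below q
        m1 = fdr_bh(p, q=0.05)
        m2 = fdr_bh(p, q=0.10)
        assert np.all(~m1 | m2)  # step-up mask grows with q


class TestAucOverDensities:
    def test_constant_curve_is_rectangle(self):
        grid = DensityGrid(0.22, 0.50, 0.02)
        assert auc_over_densities(np.full(15, 3.0), grid) == pytest.approx(0.28 * 3)

    def test_two_point_trapezoid(self):
        grid = DensityGrid(0.22, 0.50, 0.28)
        assert auc_over_densities([1.0, 2.0], grid) == pytest.approx(0.42)

    def test_linearity(self):
        grid = DensityGrid(0.22, 0.50, 0.02)
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 15))
        lhs = auc_over_densities(2.5 * x - 1.2 * y, grid)
        rhs = 2.5 * auc_over_densities(x, grid) - 1.2 * auc_over_densities(y, grid)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            auc_over_densities([1.0, 2.0], DensityGrid(0.22, 0.5, 0.02))


def correlated_residuals(rng, n, p):
    """Residual-like data with a shared latent factor, so most pairwise
    correlations are positive and every density stays feasible."""
    latent = rng.standard_normal((n, 1))
    return 0.8 * latent + 0.6 * rng.standard_normal((n, p))


def duplicated_group_table(n=8, p=12, seed=0):
    """Group b is an exact copy of group a's residuals."""
    rng = np.random.default_rng(seed)
    Xa = correlated_residuals(rng, n, p)
    X = np.vstack([Xa, Xa])
    group = ["a"] * n + ["b"] * n
    return residual_table(X, group)


class TestPermuteGlobal:
    def test_identical_groups_give_zero_diff_and_p_one(self):
        res = duplicated_group_table()
        grid = DensityGrid(0.3, 0.5, 0.1)
        r = permute_global(res, "cp", grid, n_perm=30, seed=1)
        assert r.observed_auc_diff == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        # 3 + 3 subjects: only C(6,3) = 20 label assignments exist, so the
        # permutation p can be computed exactly and compared
        # seed chosen so every label split keeps density 0.5 feasible
        rng = np.random.default_rng(2)
        X = correlated_residuals(rng, 6, 8)
        res = residual_table(X, ["a"] * 3 + ["b"] * 3)
        grid = DensityGrid(0.3, 0.5, 0.1)

        from scnkit.network import (adjacency_from_ranking, edge_ranking,
                                    positive_part, target_edge_count)
        from scnkit.metrics import clustering_mean

        def stat(mask_a):
            vals = []
            for m in (mask_a, ~mask_a):
                r = positive_part(np.corrcoef(X[m], rowvar=False))
                iu, ju, _ = edge_ranking(r)
                curve = [
                    clustering_mean(
                        adjacency_from_ranking(iu, ju, target_edge_count(d, 8), 8)
                    )
                    for d in grid.densities
                ]
                vals.append(np.trapezoid(curve, grid.densities))
            return vals[1] - vals[0]

        obs_mask = np.array([True] * 3 + [False] * 3)
        observed = stat(obs_mask)
        null = []
        for combo in itertools.combinations(range(6), 3):
            m = np.zeros(6, dtype=bool)
            m[list(combo)] = True
            null.append(stat(m))
        exact_p = (np.sum(np.abs(null) >= abs(observed)) + 1) / (len(null) + 1)

        r = permute_global(res, "cp", grid, n_perm=2000, seed=3)
        assert r.observed_auc_diff == pytest.approx(observed, abs=1e-12)
        assert r.p_value == pytest.approx(exact_p, abs=0.02)

    def test_multiple_metrics_share_permutations(self):
        res = duplicated_group_table(seed=2)
        grid = DensityGrid(0.3, 0.5, 0.1)
        out = permute_global(res, ["cp", "t"], grid, n_perm=10, seed=4)
        assert set(out) == {"cp", "t"}
        assert out["cp"].n_perm == out["t"].n_perm == 10

    def test_unknown_metric_rejected(self):
        res = duplicated_group_table()
        with pytest.raises(ParameterError):
            permute_global(res, "pagerank", DensityGrid(0.3, 0.5, 0.1), n_perm=5)


class TestPermuteNodal:
    def test_identical_groups_nothing_survives_fdr(self):
        res = duplicated_group_table(seed=3)
        out = permute_nodal(res, 0.4, n_perm=50, seed=1)
        assert not out.degree_sig_fdr.any()
        assert not out.betweenness_sig_fdr.any()
        assert np.all(out.degree_diff == 0)

    def test_masks_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        X = correlated_residuals(rng, 20, 15)
        res = residual_table(X, ["a"] * 10 + ["b"] * 10)
        o1 = permute_nodal(res, 0.4, n_perm=100, seed=5)
        o2 = permute_nodal(res, 0.4, n_perm=100, seed=5)
        np.testing.assert_array_equal(o1.degree_p, o2.degree_p)
        np.testing.assert_array_equal(o1.degree_sig_unc, o2.degree_sig_unc)

    def test_fdr_mask_subset_of_uncorrected(self):
        rng = np.random.default_rng(8)
        X = correlated_residuals(rng, 16, 12)
        res = residual_table(X, ["a"] * 8 + ["b"] * 8)
        out = permute_nodal(res, 0.4, n_perm=100, seed=2)
        assert np.all(~out.degree_sig_fdr | out.degree_sig_unc)
        assert np.all(~out.betweenness_sig_fdr | out.betweenness_sig_unc)


class TestPermuteRobustness:
    def test_identical_groups_p_is_one(self):
        res = duplicated_group_table(seed=4)
        out = permute_robustness(res, mode="targeted", density=0.4,
                                 n_perm=30, seed=1)
        assert out.observed_auc_diff == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == 1.0

    def test_random_mode_auc_stable_in_rep_count(self):
        rng = np.random.default_rng(9)
        X = correlated_residuals(rng, 20, 15)
        res = residual_table(X, ["a"] * 10 + ["b"] * 10)
        o_small = permute_robustness(res, "random", 0.4, n_perm=1,
                                     n_reps=100, seed=3)
        o_big = permute_robustness(res, "random", 0.4, n_perm=1,
                                   n_reps=1000, seed=4)
        assert o_small.observed_auc_diff == pytest.approx(
            o_big.observed_auc_diff, abs=0.02
        )
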