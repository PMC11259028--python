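import numpy as np
import pytest

from scnkit import CovarianceMatrix, find_min_density, threshold_at_density
from scnkit.covariates import ResidualTable
from scnkit.errors import DegenerateRegionError, InfeasibleDensityError
from scnkit.network import (
    DensityGrid,
    binarize_grid,
    correlation_matrix,
    target_edge_count,
)

import pandas as pd


def residual_table(X, group=None):
    n = X.shape[0]
    if group is None:
        group = np.array(["a"] * n, dtype=object)
        group[n // 2:] = "b"
    return ResidualTable(
        subject_id=[f"s{i}" for i in range(n)],
        group=group,
        residuals=np.asarray(X, dtype=float),
        region_labels=[f"r{j}" for j in range(X.shape[1])],
        covariates=(),
        scope="pooled",
        model_info=pd.DataFrame(),
    )


def cov_from_weights(w):
    """CovarianceMatrix from a dict {(i, j): weight} on n nodes."""
    n = max(max(e) for e in w) + 1
    r = np.zeros((n, n))
    for (i, j), v in w.items():
        r[i, j] = r[j, i] = v
    return CovarianceMatrix(r=r, group="g", n_subjects=10,
                            region_labels=[f"r{k}" for k in range(n)])


# the 4-node ranked-weight worked example
FOUR_NODE = cov_from_weights(
    {(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7, (0, 3): 0.6, (1, 3): 0.5, (2, 3): 0.4}
)


class TestCorrelationMatrix:
    def test_perfect_positive_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = residual_table(np.column_stack([x, 2 * x]),
                             group=np.array(["a"] * 5, dtype=object))
        cov = correlation_matrix(res, "a")
        assert cov.r[0, 1] == pytest.approx(1.0)
        assert cov.r[0, 0] == 0.0  # diagonal reset

    def test_negative_correlation_zeroed(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = residual_table(np.column_stack([x, -x]),
                             group=np.array(["a"] * 5, dtype=object))
        cov = correlation_matrix(res, "a")
        assert cov.r[0, 1] == 0.0

    def test_pearson_value_matches_direct_formula(self):
        x = np.array([1.0, 2, 3])
        y = np.array([1.0, 2, 4])
        res = residual_table(np.column_stack([x, y]),
                             group=np.array(["a"] * 3, dtype=object))
        cov = correlation_matrix(res, "a")
        # two-pass Pearson computed by hand
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(0.9819805061)
        assert cov.r[0, 1] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_region_named(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        res = residual_table(X, group=np.array(["a"] * 5, dtype=object))
        with pytest.raises(DegenerateRegionError, match="r1"):
            correlation_matrix(res, "a")

    def test_entries_match_two_pass_computation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 6))
        res = residual_table(X, group=np.array(["a"] * 12, dtype=object))
        cov = correlation_matrix(res, "a")
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc**2).sum(axis=0))
        expect = (Xc.T @ Xc) / np.outer(denom, denom)
        expect = np.clip(expect, 0, None)
        np.fill_diagonal(expect, 0)
        np.testing.assert_allclose(cov.r, expect, atol=1e-12)


class TestThreshold:
    def test_half_density_keeps_top_three_pairs(self):
        net = threshold_at_density(FOUR_NODE, 0.5)
        assert set(net.edge_list()) == {(0, 1), (0, 2), (1, 2)}
        assert net.degrees()[3] == 0  # weakest node left isolated

    def test_full_density_keeps_all_pairs(self):
        net = threshold_at_density(FOUR_NODE, 1.0)
        assert net.n_edges == 6

    def test_infeasible_density_reports_max(self):
        cov = cov_from_weights({(0, 1): 0.5, (2, 3): 0.4})
        with pytest.raises(InfeasibleDensityError) as exc:
            threshold_at_density(cov, 0.9)  # needs 5 edges, only 2 positive
        assert exc.value.max_density == pytest.approx(2 / 6)

    def test_exact_edge_count_and_density_within_one_edge(self):
        rng = np.random.default_rng(1)
        r = np.abs(rng.standard_normal((20, 20)))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        cov = CovarianceMatrix(r=r, group="g", n_subjects=9,
                               region_labels=[f"r{k}" for k in range(20)])
        m = 20 * 19 // 2
        for d in (0.1, 0.25, 0.333, 0.5):
            net = threshold_at_density(cov, d)
            assert net.n_edges == target_edge_count(d, 20)
            assert abs(net.density - d) <= 1.0 / m

    def test_edge_sets_nested_across_densities(self):
        rng = np.random.default_rng(2)
        # include ties so the deterministic tie rule is exercised
        r = rng.choice([0.1, 0.2, 0.3, 0.4], size=(12, 12))
        r = np.triu(r, 1)
        r = r + r.T
        cov = CovarianceMatrix(r=r, group="g", n_subjects=9,
                               region_labels=[f"r{k}" for k in range(12)])
        prev = set()
        for d in np.arange(0.05, 1.0001, 0.05):
            cur = set(threshold_at_density(cov, float(d)).edge_list())
            assert prev <= cur
            prev = cur

    def test_grid_binarization_matches_single_thresholds(self):
        nets = binarize_grid(FOUR_NODE, [0.5, 1.0])
        assert set(nets[0].edge_list()) == {(0, 1), (0, 2), (1, 2)}
        assert nets[1].n_edges == 6


class TestFindMinDensity:
    def test_four_node_example_by_exhaustive_scan(self):
        # independent oracle: try every grid density in order, threshold,
        # and check degrees directly
        def scan(cov, step):
            d = step
            while d <= 1.0 + 1e-9:
                net = threshold_at_density(cov, min(d, 1.0))
                if net.degrees().min() > 0:
                    return round(d, 10)
                d = round(d + step, 10)

        expected = scan(FOUR_NODE, 0.01)
        got = find_min_density(FOUR_NODE, FOUR_NODE, grid_step=0.01)
        assert got == expected == 0.59  # 4th-ranked edge attaches node 3

    def test_two_node_single_edge(self):
        cov = cov_from_weights({(0, 1): 0.5})
        assert find_min_density(cov, cov, grid_step=0.01) == 0.50

    def test_uses_worst_group(self):
        # group B needs more edges than group A to attach its last node
        cov_a = cov_from_weights({(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7,
                                  (0, 3): 0.6, (1, 3): 0.5, (2, 3): 0.4})
        cov_b = cov_from_weights({(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7,
                                  (2, 3): 0.1})
        d = find_min_density(cov_a, cov_b, grid_step=0.01)
        net_b = threshold_at_density(cov_b, d)
        assert net_b.degrees().min() > 0

    def test_isolated_forever_raises(self):
        from scnkit.errors import NoFeasibleDensityError
        cov = cov_from_weights({(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7,
                                (0, 3): 0.0})  # node 3 never connects
        with pytest.raises(NoFeasibleDensityError):
            find_min_density(cov, cov, grid_step=0.01)


class TestDensityGrid:
    def test_reference_grid_has_fifteen_points(self):
        grid = DensityGrid(0.22, 0.50, 0.02)
        assert len(grid) == 15
        assert grid.densities[0] == 0.22
        assert grid.densities[-1] == 0.50

    def test_rejects_bad_bounds(self):
        with pytest.raises(ValueError):
            DensityGrid(0.5, 0.2, 0.02)
        with pytest.raises(ValueError):
            DensityGrid(0.0, 0.5, 0.02)
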