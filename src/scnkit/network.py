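"""Covariance-network construction and density thresholding.

For each group, residual volumes are correlated region-by-region across
subjects (Pearson), the diagonal and all negative entries are set to zero,
and the matrix is binarized at a target connection density D = E / (N(N-1)/2)
by keeping the top-ranked correlations.  Rank-based selection (rather than an
absolute r cutoff) guarantees that both groups' graphs have exactly the same
number of edges at every density, which is what makes the group comparison
fair.

The selected edge sets are nested across densities: the graph at density
d1 <= d2 is a subgraph of the graph at d2, because edges are always taken
in the same deterministic order (decreasing weight, ties broken by node
index pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRegionError,
    InfeasibleDensityError,
    NoFeasibleDensityError,
)


@dataclass
class CovarianceMatrix:
    """Nonnegative Pearson correlation matrix for one group.

    ``r`` is symmetric with zero diagonal; negative correlations have been
    set to zero so only positive covariance contributes edges.
    """

    r: np.ndarray
    group: object
    n_subjects: int
    region_labels: list[str]

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.region_labels, columns=self.region_labels)


@dataclass
class BinaryNetwork:
    """Undirected, simple binary graph as a hollow symmetric 0/1 matrix."""

    a: np.ndarray
    node_labels: list[str]
    density_target: float | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a)
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(self.a != self.a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.a) != 0):
            raise ValueError("adjacency must be hollow (zero diagonal)")
        if not set(np.unique(self.a)) <= {0, 1}:
            raise ValueError("adjacency must be binary")
        self.a = self.a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(np.int64)

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.a, 1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass
class DensityGrid:
    """Inclusive arithmetic grid of densities, d_min to d_max by step."""

    d_min: float
    d_max: float
    step: float = 0.02

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max <= 1):
            raise ValueError("require 0 < d_min <= d_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def densities(self) -> np.ndarray:
        k = int(round((self.d_max - self.d_min) / self.step))
        return np.round(self.d_min + self.step * np.arange(k + 1), 10)

    def __len__(self) -> int:
        return len(self.densities)


def target_edge_count(d: float, n_nodes: int) -> int:
    """Edge count nearest to d * N(N-1)/2; exact halves round up."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(d * m + 0.5))


def correlation_matrix(res, group) -> CovarianceMatrix:
    """Pearson-correlate residual volumes across one group's subjects.

    The diagonal and every negative correlation are reset to zero.
    Requires at least 3 subjects in the group and nonzero variance in
    every region.
    """
    mask = res.group_mask(group)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"group {group!r} has {n} subjects; need >= 3")
    X = res.residuals[mask]
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateRegionError(
            f"region {res.region_labels[dead[0]]!r} has zero variance in group {group!r}"
        )
    r = np.corrcoef(X, rowvar=False)
    r = positive_part(r)
    return CovarianceMatrix(
        r=r, group=group, n_subjects=n, region_labels=list(res.region_labels)
    )


def positive_part(r: np.ndarray) -> np.ndarray:
    """Zero the diagonal and clip negative correlations to zero."""
    r = np.array(r, dtype=float, copy=True)
    np.fill_diagonal(r, 0.0)
    np.clip(r, 0.0, None, out=r)
    return r


def edge_ranking(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Rank node pairs by decreasing weight; ties break by (i, j) index.

    Returns the (i, j) upper-triangle indices in selection order and the
    number of strictly positive pairs.  Taking the first E pairs of this
    ranking yields the density-E/M graph; the nesting of edge sets across
    densities follows from the fixed order.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = r[iu, ju]
    order = np.lexsort((ju, iu, -w))
    n_pos = int((w > 0).sum())
    return iu[order], ju[order], n_pos


def adjacency_from_ranking(
    iu: np.ndarray, ju: np.ndarray, n_edges: int, n_nodes: int
) -> np.ndarray:
    a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    a[iu[:n_edges], ju[:n_edges]] = 1
    a |= a.T
    return a


def threshold_at_density(cov: CovarianceMatrix, d: float) -> BinaryNetwork:
    """Binarize a covariance matrix at density ``d`` by top-ranked selection.

    The E* = round(d * N(N-1)/2) largest-weight pairs become edges, so the
    realized edge count always equals the target exactly.
    """
    if not (0 < d <= 1):
        raise ValueError(f"density must be in (0, 1], got {d}")
    n = cov.n_regions
    e_star = target_edge_count(d, n)
    iu, ju, n_pos = edge_ranking(cov.r)
    if e_star > n_pos:
        m = n * (n - 1) // 2
        raise InfeasibleDensityError(
            f"density {d} needs {e_star} edges but only {n_pos} positive "
            f"correlations exist (max achievable density {n_pos / m:.4f})",
            max_density=n_pos / m,
        )
    return BinaryNetwork(
        a=adjacency_from_ranking(iu, ju, e_star, n),
        node_labels=list(cov.region_labels),
        density_target=float(d),
    )


def _min_covering_edges(iu: np.ndarray, ju: np.ndarray, n_nodes: int) -> int | None:
    """Smallest prefix of the ranking whose edges touch every node."""
    seen = np.zeros(n_nodes, dtype=bool)
    covered = 0
    for k in range(len(iu)):
        for v in (iu[k], ju[k]):
            if not seen[v]:
                seen[v] = True
                covered += 1
        if covered == n_nodes:
            return k + 1
    return None


def find_min_density(
    cov_a: CovarianceMatrix,
    cov_b: CovarianceMatrix,
    grid_step: float = 0.01,
    d_cap: float = 1.0,
) -> float:
    """Smallest grid density at which neither group's graph has an isolated node.

    Scans the grid ``grid_step, 2*grid_step, ...`` up to ``d_cap`` in
    ascending order and returns the first density whose thresholded graphs
    leave no degree-0 node in either group.  Because edge sets are nested
    across densities, this is equivalent to finding the smallest grid
    density whose target edge count reaches each group's minimal covering
    prefix.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not (0 < d_cap <= 1):
        raise ValueError("d_cap must be in (0, 1]")
    n = cov_a.n_regions
    if cov_b.n_regions != n:
        raise ValueError("covariance matrices differ in size")
    need = []
    for cov in (cov_a, cov_b):
        iu, ju, n_pos = edge_ranking(cov.r)
        e_cov = _min_covering_edges(iu[:n_pos], ju[:n_pos], n)
        if e_cov is None:
            raise NoFeasibleDensityError(
                f"group {cov.group!r}: some node has no positive correlation; "
                "isolated nodes cannot be avoided at any density"
            )
        need.append((e_cov, n_pos))
    e_need = max(e for e, _ in need)
    e_max = min(p for _, p in need)
    k = 1
    while True:
        d = round(k * grid_step, 10)
        if d > d_cap:
            raise NoFeasibleDensityError(
                f"no grid density <= {d_cap} frees both groups of isolated nodes "
                f"(need {e_need} edges, positive-correlation cap {e_max})"
            )
        e_star = target_edge_count(d, n)
        if e_star >= e_need and e_star <= e_max:
            return d
        k += 1


def binarize_grid(cov: CovarianceMatrix, densities) -> list[BinaryNetwork]:
    """Threshold one covariance matrix at every density (shared ranking)."""
    n = cov.n_regions
    iu, ju, n_pos = edge_ranking(cov.r)
    nets = []
    for d in densities:
        e_star = target_edge_count(float(d), n)
        if e_star > n_pos:
            m = n * (n - 1) // 2
            raise InfeasibleDensityError(
                f"density {d} infeasible for group {cov.group!r} "
                f"(max {n_pos / m:.4f})",
                max_density=n_pos / m,
            )
        nets.append(
            BinaryNetwork(
                a=adjacency_from_ranking(iu, ju, e_star, n),
                node_labels=list(cov.region_labels),
                density_target=float(d),
            )
        )
    return nets
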