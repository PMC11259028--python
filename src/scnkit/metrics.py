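"""Global and nodal graph-theory metrics for binary networks.

Global measures
---------------
cp    mean nodal clustering coefficient (triangles over possible triangles)
lp    characteristic path length: mean shortest-path length over reachable
      unordered pairs (unreachable pairs are excluded and counted)
t     transitivity: 3 * triangles / connected triples
eg    global efficiency: mean of 1/d(i,j) over all unordered pairs
eloc  local efficiency: mean over nodes of the global efficiency of the
      subgraph induced on each node's neighbors
gamma, lam, sigma
      cp and lp normalized by their means over degree-preserving rewired
      reference graphs, and their ratio sigma = gamma / lam (the
      small-world coefficient; sigma > 1 with lam ~ 1 is the small-world
      signature)

Nodal measures are degree and raw betweenness (shortest-path pair counts,
fractionally split among tied shortest paths, no normalization).

All computations are dense-matrix based: triangle counts come from
diag(A^3), distances from breadth-first search (scipy.sparse.csgraph), and
betweenness and degree-preserving rewiring are delegated to igraph.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import NormalizationDegenerateError, UndefinedMetricsError
from .network import BinaryNetwork

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("cp", "lp", "t", "eg", "eloc", "gamma", "lam", "sigma")
PLAIN_METRIC_NAMES = ("cp", "lp", "t", "eg", "eloc")
NORMALIZED_METRIC_NAMES = ("gamma", "lam", "sigma")


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    t: float
    eg: float
    eloc: float
    density: float | None = None
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None
    n_unreachable_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (*GLOBAL_METRIC_NAMES, "density", "n_unreachable_pairs")
        }


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    node_labels: list[str]


# ---------------------------------------------------------------------------
# dense-array primitives (hot path for permutation loops)


def triangle_counts(a: np.ndarray) -> np.ndarray:
    """Triangles incident at each node: diag(A^3) / 2."""
    af = a.astype(float)
    return ((af @ af) * af).sum(axis=1) / 2.0


def clustering_mean(a: np.ndarray) -> float:
    """Mean nodal clustering; nodes with degree < 2 contribute 0."""
    k = a.sum(axis=1).astype(float)
    tri = triangle_counts(a)
    denom = k * (k - 1) / 2.0
    c = np.divide(tri, denom, out=np.zeros_like(tri), where=denom > 0)
    return float(c.mean())


def transitivity(a: np.ndarray) -> float:
    """3 * #triangles / #connected triples; 0 when there are no triples."""
    k = a.sum(axis=1).astype(float)
    triples = (k * (k - 1)).sum() / 2.0
    if triples == 0:
        return 0.0
    n_triangles = triangle_counts(a).sum() / 3.0
    return float(3.0 * n_triangles / triples)


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def path_length_and_efficiency(a: np.ndarray) -> tuple[float, float, int]:
    """(lp over reachable pairs, eg over all pairs, #unreachable pairs)."""
    n = a.shape[0]
    d = _distance_matrix(a)
    iu = np.triu_indices(n, 1)
    dv = d[iu]
    finite = np.isfinite(dv)
    n_unreach = int((~finite).sum())
    lp = float(dv[finite].mean()) if finite.any() else float("inf")
    inv = np.zeros_like(dv)
    inv[finite] = 1.0 / dv[finite]
    eg = float(inv.mean()) if dv.size else 0.0
    return lp, eg, n_unreach


def global_efficiency(a: np.ndarray) -> float:
    return path_length_and_efficiency(a)[1]


def local_efficiency(a: np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    n = a.shape[0]
    vals = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(a[v])
        if nb.size >= 2:
            vals[v] = global_efficiency(a[np.ix_(nb, nb)])
    return float(vals.mean())


# ---------------------------------------------------------------------------
# public operations


def global_metrics(net: BinaryNetwork) -> GlobalMetrics:
    """All plain global measures of a binary network (gamma/lam/sigma unset)."""
    a = np.asarray(net.a)
    if net.n_edges == 0:
        raise UndefinedMetricsError("global metrics are undefined for an empty graph")
    lp, eg, n_unreach = path_length_and_efficiency(a)
    if n_unreach:
        logger.info(
            "graph is disconnected: %d unreachable pairs excluded from lp", n_unreach
        )
    return GlobalMetrics(
        cp=clustering_mean(a),
        lp=lp,
        t=transitivity(a),
        eg=eg,
        eloc=local_efficiency(a),
        density=net.density,
        n_unreachable_pairs=n_unreach,
    )


def to_igraph(net_or_a) -> ig.Graph:
    a = net_or_a.a if isinstance(net_or_a, BinaryNetwork) else np.asarray(net_or_a)
    i, j = np.nonzero(np.triu(a, 1))
    return ig.Graph(n=a.shape[0], edges=list(zip(i.tolist(), j.tolist())))


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    """Per-node degree and raw betweenness (unordered-pair counts)."""
    g = to_igraph(net)
    bet = np.asarray(g.betweenness(directed=False), dtype=float)
    return NodalMetrics(
        degree=net.degrees(), betweenness=bet, node_labels=list(net.node_labels)
    )


def rewire_adjacency(
    a: np.ndarray, n_swaps_per_edge: int = 10, seed: int | None = None
) -> np.ndarray:
    """Degree-preserving rewiring of an adjacency matrix.

    Runs ``n_swaps_per_edge * E`` double-edge-swap attempts; attempts that
    would create a self-loop or multi-edge are discarded, so every node
    keeps its exact degree and the result stays simple.  Graphs with no
    valid swap (stars, complete graphs) come back unchanged.
    """
    g = to_igraph(a)
    e = g.ecount()
    if e >= 2 and n_swaps_per_edge > 0:
        random.seed(seed)
        g.rewire(n=n_swaps_per_edge * e, mode="simple")
    out = np.zeros_like(np.asarray(a), dtype=np.int8)
    el = np.asarray(g.get_edgelist(), dtype=np.int64)
    if el.size:
        out[el[:, 0], el[:, 1]] = 1
        out |= out.T
    return out


def random_reference(
    net: BinaryNetwork, n_swaps_per_edge: int = 10, seed: int | None = None
) -> BinaryNetwork:
    """A degree-matched random (rewired) reference graph; seeded, simple."""
    out = rewire_adjacency(net.a, n_swaps_per_edge, seed)
    if n_swaps_per_edge > 0 and np.array_equal(out, np.asarray(net.a)):
        logger.warning(
            "rewiring left the graph unchanged (no valid double-edge swap "
            "exists, or all attempts failed); returning the input topology"
        )
    return BinaryNetwork(
        a=out, node_labels=list(net.node_labels), density_target=net.density_target
    )


def reference_mean_stats(
    g: ig.Graph,
    n_random: int,
    n_swaps_per_edge: int,
    seeds,
    need_lp: bool = True,
) -> tuple[float, float]:
    """Mean clustering and path length over degree-preserving rewired copies.

    ``seeds`` is an iterable of per-reference integer seeds.  The rewired
    copies stay inside igraph (its mean local clustering with zero-fill
    for degree < 2 and its reachable-pair average path length agree with
    this module's dense implementations to machine precision), which keeps
    permutation-test null loops fast.
    """
    e = g.ecount()
    cps, lps = [], []
    for _, s in zip(range(n_random), seeds):
        h = g.copy()
        if e >= 2 and n_swaps_per_edge > 0:
            random.seed(int(s))
            h.rewire(n=n_swaps_per_edge * e, mode="simple")
        cps.append(h.transitivity_avglocal_undirected(mode="zero"))
        lps.append(h.average_path_length(unconn=True) if need_lp else 1.0)
    return float(np.mean(cps)), float(np.mean(lps))


def _reference_means(
    a: np.ndarray, n_random: int, n_swaps_per_edge: int, seed: int | None
) -> tuple[float, float]:
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_random)]
    return reference_mean_stats(to_igraph(a), n_random, n_swaps_per_edge, seeds)


def normalized_metrics(
    net: BinaryNetwork,
    n_random: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
) -> GlobalMetrics:
    """Global metrics with gamma, lambda and sigma set.

    gamma = cp / <cp over rewired references>, lam = lp / <lp over
    references>, sigma = gamma / lam.  ``n_swaps_per_edge=0`` makes every
    reference the graph itself, so all three normalize to exactly 1.
    """
    if net.n_edges < 2:
        raise UndefinedMetricsError("normalization needs at least 2 edges")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    gm = global_metrics(net)
    cp_r, lp_r = _reference_means(np.asarray(net.a), n_random, n_swaps_per_edge, seed)
    if cp_r == 0 or lp_r == 0 or not np.isfinite(lp_r):
        raise NormalizationDegenerateError(
            f"degenerate reference means (cp={cp_r}, lp={lp_r})"
        )
    gm.gamma = gm.cp / cp_r
    gm.lam = gm.lp / lp_r
    gm.sigma = gm.gamma / gm.lam
    return gm
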