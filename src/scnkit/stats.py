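"""Permutation-based group inference, effect sizes and FDR correction.

Group differences in network organization cannot be tested subject-by-
subject, because each group contributes a single covariance network.  The
standard solution is label permutation: subjects' group labels are
reshuffled (group sizes preserved), both covariance networks are rebuilt
from the residual volumes, thresholded at every density, and the metric of
interest recomputed — yielding a null distribution for the observed
group difference.  The headline statistic is the difference in the area
under the metric-vs-density curve (AUC), a threshold-free summary; the
two-tailed Monte-Carlo p-value uses the +1 correction so it is never
exactly zero.

Residualization happens once, before permutation: covariate adjustment is
label-blind, so permuting labels after it leaves the null exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .covariates import ResidualTable
from .errors import ParameterError
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NORMALIZED_METRIC_NAMES,
    clustering_mean,
    local_efficiency,
    path_length_and_efficiency,
    reference_mean_stats,
    to_igraph,
    transitivity,
)
from .network import (
    BinaryNetwork,
    DensityGrid,
    adjacency_from_ranking,
    edge_ranking,
    positive_part,
    target_edge_count,
)
from .robustness import (
    RobustnessCurve,
    random_failure,
    robustness_auc,
    targeted_attack,
)


@dataclass
class EffectSize:
    """Pooled-SD standardized mean difference (Cohen's d, equal-n form)."""

    cohens_d: float
    m1: float
    s1: float
    m2: float
    s2: float
    n1: int | None = None
    n2: int | None = None


@dataclass
class PermutationResult:
    """Observed group difference with its permutation null.

    ``observed_diff`` is the per-density difference curve (group_b -
    group_a); ``observed_auc_diff`` its AUC; ``p_value`` the two-tailed
    Monte-Carlo p for the AUC difference; ``ci_band`` the per-density
    2.5/97.5 percentiles of the null difference curves.
    """

    metric_name: str
    densities: np.ndarray
    curve_a: np.ndarray
    curve_b: np.ndarray
    observed_diff: np.ndarray
    observed_auc_diff: float
    null_auc_diffs: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    ci_band: np.ndarray


@dataclass
class NodalPermutationResult:
    """Per-node degree/betweenness group differences at a single density."""

    node_labels: list[str]
    density: float
    degree_diff: np.ndarray
    betweenness_diff: np.ndarray
    degree_p: np.ndarray
    betweenness_p: np.ndarray
    degree_sig_unc: np.ndarray
    degree_sig_fdr: np.ndarray
    betweenness_sig_unc: np.ndarray
    betweenness_sig_fdr: np.ndarray
    n_perm: int
    seed: int | None


@dataclass
class RobustnessPermutationResult:
    """Group difference in robustness AUC at one density, with per-step flags."""

    mode: str
    density: float
    curve_a: RobustnessCurve
    curve_b: RobustnessCurve
    observed_auc_diff: float
    null_auc_diffs: np.ndarray
    p_value: float
    step_diff: np.ndarray
    step_band: np.ndarray
    step_significant: np.ndarray
    n_perm: int
    seed: int | None


# ---------------------------------------------------------------------------
# scalar helpers


def cohens_d(m1, s1, m2, s2, n1=None, n2=None) -> EffectSize:
    """d = |m2 - m1| / sqrt((s1^2 + s2^2) / 2)."""
    if s1 < 0 or s2 < 0:
        raise ParameterError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        raise ParameterError("both standard deviations are zero; d is undefined")
    d = abs(m2 - m1) / np.sqrt((s1**2 + s2**2) / 2.0)
    return EffectSize(cohens_d=float(d), m1=m1, s1=s1, m2=m2, s2=s2, n1=n1, n2=n2)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def auc_over_densities(values, grid: DensityGrid) -> float:
    """Trapezoidal integral of a metric curve over the density grid."""
    values = np.asarray(values, dtype=float)
    dens = grid.densities
    if values.shape[0] != dens.shape[0]:
        raise ParameterError(
            f"{values.shape[0]} values for {dens.shape[0]} grid densities"
        )
    if not np.all(np.isfinite(values)):
        raise ParameterError("metric values must be finite")
    return float(np.trapezoid(values, dens))


def _perm_p(null: np.ndarray, observed: float) -> float:
    return float((np.sum(np.abs(null) >= abs(observed)) + 1) / (null.size + 1))


# ---------------------------------------------------------------------------
# permutation engine


def _metric_value(a: np.ndarray, name: str, ref_stats=None) -> float:
    if name == "cp":
        return clustering_mean(a)
    if name == "t":
        return transitivity(a)
    if name == "lp":
        return path_length_and_efficiency(a)[0]
    if name == "eg":
        return path_length_and_efficiency(a)[1]
    if name == "eloc":
        return local_efficiency(a)
    if name in NORMALIZED_METRIC_NAMES:
        cp_r, lp_r = ref_stats
        if name == "gamma":
            return clustering_mean(a) / cp_r
        lam = path_length_and_efficiency(a)[0] / lp_r
        if name == "lam":
            return lam
        return (clustering_mean(a) / cp_r) / lam  # sigma
    raise ParameterError(f"unknown metric {name!r}")


def _group_curves(
    X: np.ndarray,
    mask: np.ndarray,
    densities: np.ndarray,
    metric_names: tuple[str, ...],
    n_random_refs: int,
    n_swaps_per_edge: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Metric curves over densities for one group of residual rows."""
    need_refs = any(m in NORMALIZED_METRIC_NAMES for m in metric_names)
    need_lp_refs = any(m in ("lam", "sigma") for m in metric_names)
    r = positive_part(np.corrcoef(X[mask], rowvar=False))
    n = r.shape[0]
    iu, ju, n_pos = edge_ranking(r)
    out = {m: np.empty(len(densities)) for m in metric_names}
    for k, d in enumerate(densities):
        e_star = target_edge_count(float(d), n)
        if e_star > n_pos:
            raise ParameterError(
                f"density {d} infeasible under permutation "
                f"(needs {e_star} edges, {n_pos} positive correlations)"
            )
        a = adjacency_from_ranking(iu, ju, e_star, n)
        ref_stats = None
        if need_refs:
            seeds = rng.integers(2**31, size=n_random_refs)
            ref_stats = reference_mean_stats(
                to_igraph(a), n_random_refs, n_swaps_per_edge, seeds,
                need_lp=need_lp_refs,
            )
        for m in metric_names:
            out[m][k] = _metric_value(a, m, ref_stats)
    return out


def _resolve_masks(res: ResidualTable):
    ga, gb = res.group_labels
    mask_a = res.group_mask(ga)
    mask_b = res.group_mask(gb)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ParameterError("both groups need >= 3 subjects for correlation")
    return ga, gb, np.asarray(mask_a), np.asarray(mask_b)


def _permuted_masks(rng: np.random.Generator, n: int, n_a: int):
    perm = rng.permutation(n)
    mask_a = np.zeros(n, dtype=bool)
    mask_a[perm[:n_a]] = True
    return mask_a, ~mask_a


def permute_global(
    res: ResidualTable,
    metric,
    grid: DensityGrid,
    n_perm: int = 1000,
    n_random_refs: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
):
    """Label-permutation test of per-density metric curves and their AUC.

    ``metric`` may be one name or a sequence of names from
    ``cp, lp, t, eg, eloc, gamma, lam, sigma``; with a sequence, all
    metrics share the same permutations and a dict of results is returned.
    The difference convention is group_b - group_a with groups in sorted
    label order.
    """
    single = isinstance(metric, str)
    names = (metric,) if single else tuple(metric)
    for m in names:
        if m not in GLOBAL_METRIC_NAMES:
            raise ParameterError(f"unknown metric {m!r}")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    ga, gb, mask_a, mask_b = _resolve_masks(res)
    dens = grid.densities
    rng = np.random.default_rng(seed)
    X = res.residuals

    obs_a = _group_curves(X, mask_a, dens, names, n_random_refs, n_swaps_per_edge, rng)
    obs_b = _group_curves(X, mask_b, dens, names, n_random_refs, n_swaps_per_edge, rng)

    null_auc = {m: np.empty(n_perm) for m in names}
    null_curves = {m: np.empty((n_perm, len(dens))) for m in names}
    n_a = int(mask_a.sum())
    for p in range(n_perm):
        pa, pb = _permuted_masks(rng, res.n_subjects, n_a)
        ca = _group_curves(X, pa, dens, names, n_random_refs, n_swaps_per_edge, rng)
        cb = _group_curves(X, pb, dens, names, n_random_refs, n_swaps_per_edge, rng)
        for m in names:
            diff = cb[m] - ca[m]
            null_curves[m][p] = diff
            null_auc[m][p] = np.trapezoid(diff, dens)

    out = {}
    for m in names:
        diff = obs_b[m] - obs_a[m]
        auc_diff = float(np.trapezoid(diff, dens))
        out[m] = PermutationResult(
            metric_name=m,
            densities=dens,
            curve_a=obs_a[m],
            curve_b=obs_b[m],
            observed_diff=diff,
            observed_auc_diff=auc_diff,
            null_auc_diffs=null_auc[m],
            p_value=_perm_p(null_auc[m], auc_diff),
            n_perm=n_perm,
            seed=seed,
            ci_band=np.percentile(null_curves[m], [2.5, 97.5], axis=0),
        )
    return out[metric] if single else out


def _nodal_stats(X, mask, d, n):
    r = positive_part(np.corrcoef(X[mask], rowvar=False))
    iu, ju, n_pos = edge_ranking(r)
    e_star = target_edge_count(d, n)
    if e_star > n_pos:
        raise ParameterError(f"density {d} infeasible under permutation")
    a = adjacency_from_ranking(iu, ju, e_star, n)
    deg = a.sum(axis=1).astype(float)
    bet = np.asarray(to_igraph(a).betweenness(directed=False), dtype=float)
    return deg, bet


def permute_nodal(
    res: ResidualTable,
    density: float,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
) -> NodalPermutationResult:
    """Per-node permutation test of degree and betweenness at one density.

    Returns per-node two-tailed p-values plus uncorrected (p < alpha) and
    Benjamini-Hochberg FDR (level q) significance masks.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    ga, gb, mask_a, mask_b = _resolve_masks(res)
    n = res.n_regions
    rng = np.random.default_rng(seed)
    X = res.residuals

    deg_a, bet_a = _nodal_stats(X, mask_a, density, n)
    deg_b, bet_b = _nodal_stats(X, mask_b, density, n)
    obs_deg = deg_b - deg_a
    obs_bet = bet_b - bet_a

    exc_deg = np.zeros(n)
    exc_bet = np.zeros(n)
    n_a = int(mask_a.sum())
    for _ in range(n_perm):
        pa, pb = _permuted_masks(rng, res.n_subjects, n_a)
        dga, bta = _nodal_stats(X, pa, density, n)
        dgb, btb = _nodal_stats(X, pb, density, n)
        exc_deg += np.abs(dgb - dga) >= np.abs(obs_deg)
        exc_bet += np.abs(btb - bta) >= np.abs(obs_bet)
    p_deg = (exc_deg + 1) / (n_perm + 1)
    p_bet = (exc_bet + 1) / (n_perm + 1)

    return NodalPermutationResult(
        node_labels=list(res.region_labels),
        density=float(density),
        degree_diff=obs_deg,
        betweenness_diff=obs_bet,
        degree_p=p_deg,
        betweenness_p=p_bet,
        degree_sig_unc=p_deg < alpha,
        degree_sig_fdr=fdr_bh(p_deg, q),
        betweenness_sig_unc=p_bet < alpha,
        betweenness_sig_fdr=fdr_bh(p_bet, q),
        n_perm=n_perm,
        seed=seed,
    )


def _network_at(X, mask, d, n, labels):
    r = positive_part(np.corrcoef(X[mask], rowvar=False))
    iu, ju, n_pos = edge_ranking(r)
    e_star = target_edge_count(d, n)
    if e_star > n_pos:
        raise ParameterError(f"density {d} infeasible under permutation")
    return BinaryNetwork(
        a=adjacency_from_ranking(iu, ju, e_star, n), node_labels=labels
    )


def permute_robustness(
    res: ResidualTable,
    mode: str = "targeted",
    density: float = 0.22,
    n_perm: int = 1000,
    n_reps: int = 1000,
    seed: int | None = None,
) -> RobustnessPermutationResult:
    """Permutation test of the group difference in robustness AUC.

    ``mode`` is ``targeted`` (deterministic hub-first deletion) or
    ``random`` (mean over ``n_reps`` random deletion orders).  Per-step
    LCC differences are flagged against the null 95% band.
    """
    if mode not in ("targeted", "random"):
        raise ParameterError(f"mode must be 'targeted' or 'random', got {mode!r}")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    ga, gb, mask_a, mask_b = _resolve_masks(res)
    n = res.n_regions
    labels = list(res.region_labels)
    rng = np.random.default_rng(seed)
    X = res.residuals

    def curve_for(mask):
        net = _network_at(X, mask, density, n, labels)
        if mode == "targeted":
            return targeted_attack(net)
        return random_failure(net, n_reps=n_reps, seed=int(rng.integers(2**31)))

    ca = curve_for(mask_a)
    cb = curve_for(mask_b)
    obs_auc = robustness_auc(cb) - robustness_auc(ca)
    obs_step = cb.lcc_fraction - ca.lcc_fraction

    null_auc = np.empty(n_perm)
    null_step = np.empty((n_perm, n + 1))
    n_a = int(mask_a.sum())
    for p in range(n_perm):
        pa, pb = _permuted_masks(rng, res.n_subjects, n_a)
        na_c = curve_for(pa)
        nb_c = curve_for(pb)
        null_auc[p] = robustness_auc(nb_c) - robustness_auc(na_c)
        null_step[p] = nb_c.lcc_fraction - na_c.lcc_fraction

    band = np.percentile(null_step, [2.5, 97.5], axis=0)
    return RobustnessPermutationResult(
        mode=mode,
        density=float(density),
        curve_a=ca,
        curve_b=cb,
        observed_auc_diff=float(obs_auc),
        null_auc_diffs=null_auc,
        p_value=_perm_p(null_auc, obs_auc),
        step_diff=obs_step,
        step_band=band,
        step_significant=(obs_step < band[0]) | (obs_step > band[1]),
        n_perm=n_perm,
        seed=seed,
    )
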