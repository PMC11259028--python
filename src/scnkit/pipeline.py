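"""End-to-end pipeline: config, orchestration, artifact writing.

``run`` executes the full analysis from a resolved :class:`RunConfig`:
residualization -> per-group covariance matrices -> minimum-density
selection -> density-sweep global metrics (plain and normalized) -> nodal
metrics at the minimum density -> degree-distribution fits -> robustness
simulation -> permutation inference, writing CSV/JSON artifacts and a
machine-readable ``report.json`` that echoes the full configuration,
seeds and package versions for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import RegionalVolumeTable, read_cohort, write_adjacency
from .covariates import DEFAULT_COVARIATES, residualize, write_residuals
from .degree_dist import cumulative_degree_distribution, fit_truncated_power_law
from .errors import InsufficientSupportError
from .metrics import (
    GLOBAL_METRIC_NAMES,
    global_metrics,
    nodal_metrics,
    normalized_metrics,
)
from .network import DensityGrid, binarize_grid, correlation_matrix, find_min_density
from .robustness import random_failure, robustness_auc, targeted_attack
from .stats import (
    cohens_d,
    permute_global,
    permute_nodal,
    permute_robustness,
)
from .synthetic import SyntheticSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved pipeline configuration; every field except ``input`` has a default."""

    input: str | None = None
    schema: dict = field(default_factory=dict)
    sex_codes: tuple[str, str] = ("0", "1")
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    scope: str = "pooled"
    density_min: object = "auto"  # "auto" or a float
    density_max: float = 0.5
    density_step: float = 0.02
    density_scan_step: float = 0.01
    n_random_refs: int = 20
    n_swaps_per_edge: int = 10
    n_perm: int = 1000
    robustness_reps: int = 1000
    permutation_metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES
    fdr_q: float = 0.05
    seed: int = 0
    outdir: str = "scn_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        dens = raw.pop("density", None)
        if dens:
            raw.setdefault("density_min", dens.get("min", "auto"))
            raw.setdefault("density_max", dens.get("max", 0.5))
            raw.setdefault("density_step", dens.get("step", 0.02))
            raw.setdefault("density_scan_step", dens.get("scan_step", 0.01))
        for key in ("covariates", "permutation_metrics", "sex_codes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run(config: RunConfig, table: RegionalVolumeTable | None = None) -> dict:
    """Execute the full SCN analysis; returns the report dict.

    ``table`` may be passed directly (e.g. a synthetic cohort); otherwise
    ``config.input`` is read from disk.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    rng = np.random.default_rng(config.seed)

    if table is None:
        if config.input is None:
            raise ValueError("config.input is required when no table is passed")
        logger.info("reading cohort from %s", config.input)
        table = read_cohort(config.input, schema=config.schema or None,
                            sex_codes=config.sex_codes)
    ga, gb = table.group_labels
    logger.info(
        "cohort: %d subjects (%s=%d, %s=%d), %d regions",
        table.n_subjects, ga, int(table.group_mask(ga).sum()),
        gb, int(table.group_mask(gb).sum()), table.n_regions,
    )

    # 1. residualize covariates
    res = residualize(table, config.covariates, config.scope)
    write_residuals(res, outdir / "residuals.csv")

    # 2. per-group covariance matrices
    covs = {g: correlation_matrix(res, g) for g in (ga, gb)}
    for g, cov in covs.items():
        cov.to_frame().to_csv(outdir / f"correlation_{g}.csv")

    # 3. density grid (auto minimum = first isolated-node-free grid density)
    if config.density_min == "auto":
        d_min = find_min_density(
            covs[ga], covs[gb],
            grid_step=config.density_scan_step, d_cap=config.density_max,
        )
        logger.info("auto minimum density: %.4f", d_min)
    else:
        d_min = float(config.density_min)
    grid = DensityGrid(d_min, config.density_max, config.density_step)
    densities = grid.densities

    # 4. density sweep: plain + normalized global metrics per group
    report_metrics = {}
    nets_at_dmin = {}
    for g in (ga, gb):
        nets = binarize_grid(covs[g], densities)
        nets_at_dmin[g] = nets[0]
        rows = []
        for net in nets:
            s = int(rng.integers(2**31))
            gm = normalized_metrics(
                net, n_random=config.n_random_refs,
                n_swaps_per_edge=config.n_swaps_per_edge, seed=s,
            )
            rows.append(gm.as_dict())
        df = pd.DataFrame(rows).set_index("density")
        df.to_csv(outdir / f"global_metrics_{g}.csv")
        report_metrics[str(g)] = df.reset_index().to_dict(orient="list")

    # per-metric Cohen's d across the density points, as a curve-level summary
    effect_sizes = {}
    for m in GLOBAL_METRIC_NAMES:
        va = np.asarray(report_metrics[str(ga)][m], dtype=float)
        vb = np.asarray(report_metrics[str(gb)][m], dtype=float)
        if va.std(ddof=1) > 0 or vb.std(ddof=1) > 0:
            es = cohens_d(va.mean(), va.std(ddof=1), vb.mean(), vb.std(ddof=1),
                          len(va), len(vb))
            effect_sizes[m] = dataclasses.asdict(es)

    # 5. nodal metrics at minimum density
    nodal = {}
    for g in (ga, gb):
        nm = nodal_metrics(nets_at_dmin[g])
        pd.DataFrame(
            {"region": nm.node_labels, "degree": nm.degree,
             "betweenness": nm.betweenness}
        ).to_csv(outdir / f"nodal_metrics_{g}.csv", index=False)
        write_adjacency(nets_at_dmin[g], outdir / f"network_dmin_{g}.tsv")
        nodal[str(g)] = {"degree": nm.degree, "betweenness": nm.betweenness}

    # 6. degree-distribution fits at minimum density
    fits = {}
    for g in (ga, gb):
        dist = cumulative_degree_distribution(nets_at_dmin[g])
        pd.DataFrame({"degree": dist.d, "p_cum": dist.p_cum}).to_csv(
            outdir / f"degree_distribution_{g}.csv", index=False
        )
        try:
            fit = fit_truncated_power_law(dist)
            fits[str(g)] = {"e": fit.e, "dc": fit.dc, "r2": fit.r2,
                            "scale": fit.scale, "density": float(densities[0])}
        except InsufficientSupportError as exc:
            logger.warning("degree fit skipped for group %s: %s", g, exc)
            fits[str(g)] = None

    # 7. robustness curves at minimum density
    robust = {}
    for g in (ga, gb):
        tc = targeted_attack(nets_at_dmin[g])
        rc = random_failure(nets_at_dmin[g], n_reps=config.robustness_reps,
                            seed=int(rng.integers(2**31)))
        pd.DataFrame(
            {"n_removed": tc.n_removed, "lcc_targeted": tc.lcc_size,
             "lcc_random_mean": rc.lcc_size, "lcc_random_sd": rc.lcc_sd}
        ).to_csv(outdir / f"robustness_{g}.csv", index=False)
        robust[str(g)] = {
            "auc_targeted": robustness_auc(tc),
            "auc_random": robustness_auc(rc),
        }

    # 8. permutation inference
    logger.info("permutation tests: %d permutations", config.n_perm)
    perm_global = permute_global(
        res, list(config.permutation_metrics), grid,
        n_perm=config.n_perm, n_random_refs=config.n_random_refs,
        n_swaps_per_edge=config.n_swaps_per_edge,
        seed=int(rng.integers(2**31)),
    )
    perm_summary = {
        m: {
            "observed_auc_diff": r.observed_auc_diff,
            "p_value": r.p_value,
            "curve_a": r.curve_a, "curve_b": r.curve_b,
            "observed_diff": r.observed_diff, "ci_band": r.ci_band,
        }
        for m, r in perm_global.items()
    }

    pn = permute_nodal(res, float(densities[0]), n_perm=config.n_perm,
                       seed=int(rng.integers(2**31)), q=config.fdr_q)
    pd.DataFrame(
        {"region": pn.node_labels,
         "degree_diff": pn.degree_diff, "betweenness_diff": pn.betweenness_diff,
         "degree_p": pn.degree_p, "betweenness_p": pn.betweenness_p,
         "degree_sig_unc": pn.degree_sig_unc, "degree_sig_fdr": pn.degree_sig_fdr,
         "betweenness_sig_unc": pn.betweenness_sig_unc,
         "betweenness_sig_fdr": pn.betweenness_sig_fdr}
    ).to_csv(outdir / "nodal_permutation.csv", index=False)

    perm_rob = {}
    for mode in ("targeted", "random"):
        pr = permute_robustness(
            res, mode=mode, density=float(densities[0]),
            n_perm=config.n_perm, n_reps=config.robustness_reps,
            seed=int(rng.integers(2**31)),
        )
        perm_rob[mode] = {
            "observed_auc_diff": pr.observed_auc_diff,
            "p_value": pr.p_value,
            "n_steps_significant": int(pr.step_significant.sum()),
        }

    report = {
        "scnkit_version": __version__,
        "config": config.to_dict(),
        "groups": {"a": str(ga), "b": str(gb),
                   "n_a": int(table.group_mask(ga).sum()),
                   "n_b": int(table.group_mask(gb).sum())},
        "n_regions": table.n_regions,
        "density": {"min": float(densities[0]), "max": float(densities[-1]),
                    "step": config.density_step, "n_points": len(densities)},
        "global_metrics": report_metrics,
        "effect_sizes": effect_sizes,
        "degree_fits": fits,
        "robustness": robust,
        "permutation": {
            "global": perm_summary,
            "nodal": {
                "density": pn.density,
                "n_degree_sig_unc": int(pn.degree_sig_unc.sum()),
                "n_degree_sig_fdr": int(pn.degree_sig_fdr.sum()),
                "n_betweenness_sig_unc": int(pn.betweenness_sig_unc.sum()),
                "n_betweenness_sig_fdr": int(pn.betweenness_sig_fdr.sum()),
            },
            "robustness": perm_rob,
        },
        "runtime_seconds": round(time.time() - t0, 2),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
    logger.info("report written to %s", outdir / "report.json")
    return report


def simulate(spec: SyntheticSpec | dict | None, out_path) -> RegionalVolumeTable:
    """Generate a synthetic cohort and write it as CSV."""
    from .cohort_io import write_cohort

    if spec is None:
        spec = SyntheticSpec()
    elif isinstance(spec, dict):
        spec = SyntheticSpec.from_dict(spec)
    table = generate_cohort(spec)
    write_cohort(table, out_path)
    return table


def _setup_logging(logfile: Path) -> None:
    root = logging.getLogger("scnkit")
    root.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == logfile.resolve()
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        root.addHandler(fh)
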