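"""Covariate removal by per-region linear regression.

Each region's volumes are regressed on an intercept plus the nuisance
covariates (age, sex, total intracranial volume by default); the residuals
— the "corrected" gray matter volumes — are what the covariance network is
built from.  The intercept is always included so residuals are centered,
which makes the later Pearson correlations equal correlations of
standardized scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import RegionalVolumeTable
from .errors import InsufficientDataError, SingularDesignError

DEFAULT_COVARIATES = ("age", "sex", "tiv")


@dataclass
class ResidualTable:
    """Corrected GM volumes (regression residuals) per subject and region.

    Subject and region ordering are identical to the input cohort table.
    ``model_info`` holds the fitted coefficients: rows indexed by region
    (pooled scope) or by (group, region) (per-group scope), columns
    ``intercept`` plus the covariate names.
    """

    subject_id: list[str]
    group: np.ndarray
    residuals: np.ndarray
    region_labels: list[str]
    covariates: tuple[str, ...]
    scope: str
    model_info: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_regions(self) -> int:
        return self.residuals.shape[1]

    @property
    def group_labels(self) -> tuple:
        return tuple(sorted(set(self.group)))

    def group_mask(self, label) -> np.ndarray:
        return self.group == label

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_id, "group": self.group})
        res = pd.DataFrame(self.residuals, columns=self.region_labels, index=df.index)
        return pd.concat([df, res], axis=1)


def _check_design(X: np.ndarray, names: tuple[str, ...], where: str) -> None:
    n, p = X.shape
    if n < p:
        raise InsufficientDataError(
            f"{where}: {n} subjects < {p} regression parameters"
        )
    # name the offending covariate when one is constant within scope
    for k, name in enumerate(names, start=1):
        if np.ptp(X[:, k]) == 0:
            raise SingularDesignError(
                f"{where}: covariate {name!r} is constant within the fitting scope"
            )
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(
            f"{where}: design matrix (intercept + {list(names)}) is rank deficient "
            "(collinear covariates)"
        )


def _ols_residuals(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta, beta


def residualize(
    table: RegionalVolumeTable,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    scope: str = "pooled",
) -> ResidualTable:
    """Remove linear covariate effects from every region's volumes.

    Parameters
    ----------
    table
        Validated cohort table.
    covariates
        Covariate names among ``age, sex, tiv``; may be empty, in which
        case the regression is intercept-only (mean-centering).
    scope
        ``"pooled"`` (default) fits one model over all subjects;
        ``"per-group"`` fits within each group separately.

    Returns
    -------
    ResidualTable
        Residuals in the input subject/region order, with fitted
        coefficients in ``model_info``.
    """
    if scope not in ("pooled", "per-group"):
        raise ValueError(f"scope must be 'pooled' or 'per-group', got {scope!r}")
    covariates = tuple(covariates)
    C = table.covariate_matrix(covariates) if covariates else np.empty((table.n_subjects, 0))
    coef_names = ["intercept", *covariates]

    resid = np.empty_like(table.volumes)
    if scope == "pooled":
        X = np.column_stack([np.ones(table.n_subjects), C])
        _check_design(X, covariates, "pooled fit")
        resid[:], beta = _ols_residuals(X, table.volumes)
        info = pd.DataFrame(beta.T, index=table.region_labels, columns=coef_names)
    else:
        frames = []
        for g in table.group_labels:
            m = table.group_mask(g)
            X = np.column_stack([np.ones(int(m.sum())), C[m]])
            _check_design(X, covariates, f"group {g!r} fit")
            resid[m], beta = _ols_residuals(X, table.volumes[m])
            frames.append(
                pd.DataFrame(
                    beta.T,
                    index=pd.MultiIndex.from_product([[g], table.region_labels]),
                    columns=coef_names,
                )
            )
        info = pd.concat(frames)

    return ResidualTable(
        subject_id=list(table.subject_id),
        group=table.group.copy(),
        residuals=resid,
        region_labels=list(table.region_labels),
        covariates=covariates,
        scope=scope,
        model_info=info,
    )


def write_residuals(res: ResidualTable, path) -> None:
    """Write the residual table as CSV mirroring the cohort layout."""
    res.to_frame().to_csv(path, index=False)
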