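"""Cumulative degree distribution and truncated power-law fitting.

Brain covariance networks typically show a degree distribution that follows
a power law only up to an exponential cutoff,

    P(d) ~ d**(e - 1) * exp(-d / dc),

where ``e`` is the scaling exponent and ``dc`` the cutoff degree beyond
which high-degree probability decays exponentially (so the network has a
broad but not scale-free hub structure).  The fit is performed on the
empirical *cumulative* distribution P(k >= d) — more stable than the raw
histogram on small node sets — in log-log space.

In log10 space the model is linear in (log10 scale, e - 1, 1/dc):

    log10 P = log10 s + (e - 1) * log10 d - d / (dc * ln 10)

so the least-squares optimum is found exactly by linear algebra.  If the
unconstrained optimum would put the cutoff at a negative value (data with
no exponential decay), the fit falls back to bounded nonlinear least
squares started from a fixed grid of (e, dc) values; either path is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    EmptyDistributionError,
    FitFailureError,
    InsufficientSupportError,
)
from .network import BinaryNetwork

LN10 = np.log(10.0)

#: deterministic starting grid for the constrained fallback fit
_START_E = (1.1, 1.5, 2.0, 3.0)
_START_DC = (2.0, 5.0, 10.0, 20.0, 40.0)


@dataclass
class DegreeDistribution:
    """Empirical cumulative degree distribution P(k >= d).

    ``d`` holds the sorted distinct positive degrees; ``p_cum[m]`` is the
    fraction of connected (positive-degree) nodes with degree >= d[m], so
    p_cum starts at 1 and is non-increasing.
    """

    d: np.ndarray
    p_cum: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.p_cum = np.asarray(self.p_cum, dtype=float)


@dataclass
class PowerLawFit:
    """Fitted exponentially truncated power law for a cumulative distribution."""

    e: float
    dc: float
    r2: float
    scale: float

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.scale * d ** (self.e - 1.0) * np.exp(-d / self.dc)


def model_cumulative(d, e: float, dc: float, scale: float = 1.0) -> np.ndarray:
    """Evaluate scale * d**(e-1) * exp(-d/dc)."""
    d = np.asarray(d, dtype=float)
    return scale * d ** (e - 1.0) * np.exp(-d / dc)


def cumulative_degree_distribution(net: BinaryNetwork) -> DegreeDistribution:
    """P(k >= d) over the network's connected nodes at each distinct degree."""
    deg = net.degrees()
    pos = deg[deg > 0]
    if pos.size == 0:
        raise EmptyDistributionError("every node has degree 0")
    values = np.unique(pos).astype(float)
    # survival fraction among positive-degree nodes, so p_cum[0] == 1
    p = np.array([(pos >= v).mean() for v in values])
    return DegreeDistribution(d=values, p_cum=p)


def fit_truncated_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Least-squares truncated power-law fit in log-log space.

    Returns the exponent ``e``, cutoff ``dc > 0``, multiplicative ``scale``
    and the coefficient of determination R^2 of log10 p_cum.  Requires at
    least 4 distinct degree values.
    """
    d = dist.d
    y = np.log10(dist.p_cum)
    if d.size < 4:
        raise InsufficientSupportError(
            f"need >= 4 distinct degree values, got {d.size}"
        )
    if np.any(dist.p_cum <= 0):
        raise ValueError("p_cum values must be positive")

    # linear solve: y = c0 + (e-1)*log10(d) - b*d with b = 1/(dc*ln10)
    X = np.column_stack([np.ones_like(d), np.log10(d), -d])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c0, a, b = coef
    if b > 0:
        e, dc, scale = a + 1.0, 1.0 / (b * LN10), 10.0**c0
        yhat = X @ coef
    else:
        e, dc, scale, yhat = _constrained_fit(d, y)

    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(e=float(e), dc=float(dc), r2=r2, scale=float(scale))


def _constrained_fit(d, y):
    """Bounded nonlinear fit with dc > 0, multi-started from a fixed grid."""
    logd = np.log10(d)

    def resid(theta):
        c0, e, dc = theta
        return c0 + (e - 1.0) * logd - d / (dc * LN10) - y

    best = None
    for e0 in _START_E:
        for dc0 in _START_DC:
            try:
                sol = least_squares(
                    resid,
                    x0=[y[0], e0, dc0],
                    bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitFailureError("truncated power-law fit failed from every start")
    c0, e, dc = best.x
    return e, dc, 10.0**c0, resid(best.x) + y
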