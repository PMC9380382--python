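"""Closed-form weighted-means representation of the step-adjusted estimator.

For the canonical two-period design (arms 0 = control, 1 = early treatment,
2 = late treatment; ``n[2, 1] = 0``), the least-squares estimate of theta_2
from the all-arm step-adjustment model can be written as a weighted sum of
the six cell means:

    theta2~ = (ybar22 - ybar02) + rho * [(ybar11 - ybar01) - (ybar12 - ybar02)]

where ``rho`` is the weight placed on the non-concurrent-control information,

    rho = (1/n02) / (1/n01 + 1/n11 + 1/n02 + 1/n12).

Equivalently, theta2~ = ybar22 - y02~, where the model-based period-2 control
estimate

    y02~ = (1 - rho) * ybar02 + rho * [ybar01 + (ybar12 - ybar11)]

shrinks towards the period-1 controls shifted by the time trend learned from
arm 1, and satisfies  1 - Var(y02~) / Var(ybar02) = rho:  rho is exactly the
fractional variance reduction bought by the non-concurrent controls.  With
equal control/arm-1 cells (n01 = n11, n02 = n12) this reduces to
rho = (1/2) * n01 / (n01 + n02) < 1/2.

The module also provides the analytic power calculators used to calibrate
simulation scenarios (noncentral-t for the pooled t-test, normal
approximation for the two-proportion z-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .design import TrialDesign

__all__ = [
    "rho",
    "weights",
    "WeightMatrix",
    "theta2_weighted",
    "control_estimate_period2",
    "variance_reduction",
    "power_pooled",
]


def _cells(n) -> np.ndarray:
    """Coerce a 3x2 count matrix (or TrialDesign) for the two-period design."""
    if isinstance(n, TrialDesign):
        n = n.n
    n = np.asarray(n)
    if n.shape != (3, 2):
        raise ValueError("expected a 3 x 2 count matrix (arms 0,1,2 x periods 1,2)")
    if n[2, 0] != 0:
        raise ValueError("the late arm must have n[2, 1] = 0 in the two-period design")
    return n.astype(float)


def rho(n01: int, n11: int, n02: int, n12: int) -> float:
    """Weight of the non-concurrent controls in the step-adjusted estimator.

    Parameters are the control/arm-1 cell counts: ``n01``/``n11`` in period 1
    and ``n02``/``n12`` in period 2.  All must be >= 1 (the weighted-means
    representation is undefined for empty cells).  The returned value lies in
    (0, 1); it tends to 0 as ``n02`` grows and to 1 as the other three grow.
    """
    counts = (n01, n11, n02, n12)
    if any(c < 1 for c in counts):
        raise ValueError("all four control/arm-1 cell counts must be >= 1")
    inv = [1.0 / c for c in counts]
    return inv[2] / sum(inv)


def variance_reduction(n01: int, n11: int, n02: int, n12: int) -> float:
    """Fractional variance reduction of y02~ versus ybar02; equals ``rho``."""
    return rho(n01, n11, n02, n12)


@dataclass(frozen=True)
class WeightMatrix:
    """Cell-mean weights of the step-adjusted theta_2 estimator (3 arms x 2 periods)."""

    w: np.ndarray
    rho: float
    n: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))


def weights(n) -> WeightMatrix:
    """Weight matrix ``w[k, s]`` such that theta2^ = sum w[k, s] * ybar[k, s].

    ``n`` is the 3 x 2 cell-count matrix (or a canonical TrialDesign).  The
    weights satisfy: sum w = 0, w[2, 2] = 1, w[2, 1] = 0, and the pattern
    ``(-rho, -(1-rho) | +rho, -rho | 0, +1)``.
    """
    cells = _cells(n)
    r = rho(cells[0, 0], cells[1, 0], cells[0, 1], cells[1, 1])
    w = np.array([[-r, -(1.0 - r)], [r, -r], [0.0, 1.0]])
    return WeightMatrix(w=w, rho=r, n=cells)


def theta2_weighted(ybar, n) -> float:
    """theta_2 estimate from cell means: matches the all-arm step-model OLS fit.

    ``ybar`` is a 3 x 2 matrix of cell means (the entry for arm 2 / period 1
    may be NaN); ``n`` the matching cell counts.
    """
    wm = weights(n)
    ybar = np.asarray(ybar, dtype=float)
    if ybar.shape != (3, 2):
        raise ValueError("expected a 3 x 2 matrix of cell means")
    used = wm.w != 0
    if np.isnan(ybar[used]).any():
        raise ValueError("missing cell mean in a cell with non-zero weight")
    return float(np.sum(wm.w[used] * ybar[used]))


def control_estimate_period2(ybar, n) -> float:
    """Model-based period-2 control estimate y02~ (so theta2~ = ybar22 - y02~)."""
    wm = weights(n)
    ybar = np.asarray(ybar, dtype=float)
    if ybar.shape != (3, 2):
        raise ValueError("expected a 3 x 2 matrix of cell means")
    need = np.zeros_like(wm.w, dtype=bool)
    need[0, :] = need[1, :] = True
    if np.isnan(ybar[need]).any():
        raise ValueError("missing control/arm-1 cell mean")
    r = wm.rho
    return float((1.0 - r) * ybar[0, 1] + r * (ybar[0, 0] + ybar[1, 1] - ybar[1, 0]))


# ---------------------------------------------------------------------------
# analytic power (scenario calibration)
# ---------------------------------------------------------------------------

def _power_t(n0: int, n1: int, delta: float, sigma: float, alpha: float) -> float:
    df = n0 + n1 - 2
    ncp = delta / (sigma * np.sqrt(1.0 / n0 + 1.0 / n1))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def _power_z(n0: int, n1: int, p0: float, odds_ratio: float, alpha: float,
             pooled_variance: bool) -> float:
    p1 = float(expit(logit(p0) + np.log(odds_ratio)))
    delta = p1 - p0
    zcrit = stats.norm.ppf(1.0 - alpha)
    se_alt = np.sqrt(p0 * (1 - p0) / n0 + p1 * (1 - p1) / n1)
    if pooled_variance:
        pbar = (n0 * p0 + n1 * p1) / (n0 + n1)
        se_null = np.sqrt(pbar * (1 - pbar) * (1.0 / n0 + 1.0 / n1))
    else:
        se_null = se_alt
    return float(stats.norm.sf((zcrit * se_null - delta) / se_alt))


def power_pooled(endpoint: str, n_per_group, *, delta: float | None = None,
                 sigma: float | None = None, p0: float | None = None,
                 odds_ratio: float | None = None, alpha: float = 0.025,
                 pooled_variance: bool = False) -> float:
    """Analytic one-sided power of the two-sample comparison.

    Continuous endpoints: exact noncentral-t power of the pooled-SD t-test for
    a mean difference ``delta`` with residual SD ``sigma``.  Binary endpoints:
    normal-approximation power of the two-proportion z-test for control rate
    ``p0`` versus ``odds_ratio``; variance under the null is unpooled by
    default (``pooled_variance=True`` switches to the pooled-p̄ form — both
    land within a fraction of a point of each other at trial-sized n).

    ``n_per_group`` is an int (both groups) or a ``(n0, n1)`` pair.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if np.isscalar(n_per_group):
        n0 = n1 = int(n_per_group)
    else:
        n0, n1 = (int(v) for v in n_per_group)
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 patients per group")
    if endpoint == "continuous":
        if delta is None or sigma is None or sigma <= 0:
            raise ValueError("continuous power needs delta and sigma > 0")
        return _power_t(n0, n1, delta, sigma, alpha)
    if endpoint == "binary":
        if p0 is None or not 0 < p0 < 1:
            raise ValueError("binary power needs p0 in (0, 1)")
        if odds_ratio is None or odds_ratio <= 0:
            raise ValueError("binary power needs a positive odds ratio")
        return _power_z(n0, n1, p0, odds_ratio, alpha, pooled_variance)
    raise ValueError(f"unknown endpoint {endpoint!r}")
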