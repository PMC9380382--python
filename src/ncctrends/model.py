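"""Analysis models for treatment-control comparisons under time trends.

The tested hypothesis is one-sided, H02: theta_2 <= 0, for the newest arm
(larger outcomes are better).  Eight analysis methods are supported, named by
which data they use and how they adjust for time:

=============== ==============================================================
``ALLTC-step``   all arms, common step time effect ``nu * I(j > N1)``
``ALLTCI-step``  all arms, step effect plus arm-1 x period interaction
``TC-step``      control + tested arm only, step time effect
``ALLTC-linear`` all arms, linear time effect ``gamma * j``
``ALLTCI-linear``all arms, linear effect plus arm-1 x time interaction
``TC-linear``    control + tested arm only, linear time effect
``pooled``       tested arm vs *all* controls, no time adjustment
``separate``     tested arm vs concurrent controls only, no time adjustment
=============== ==============================================================

Continuous endpoints are fitted by ordinary least squares with the classical
covariance and a t-test on the residual degrees of freedom (``pooled`` and
``separate`` then coincide with the equal-variance two-sample t-test; a Welch
variant is available via ``welch=True``).  Binary endpoints are fitted by
maximum-likelihood logistic regression (Newton/IRLS, score tolerance 1e-8,
at most 50 iterations) with a Wald z-test; non-convergence or separation is
flagged, never reported as a silent estimate.

The module follows the statsmodels idiom: build a :class:`PlatformTrialModel`
from a dataset, call :meth:`~PlatformTrialModel.fit`, read estimates and the
one-sided test off the returned :class:`PlatformTrialResults`.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "METHODS",
    "PlatformTrialModel",
    "PlatformTrialResults",
    "fit_model",
    "one_sided_p",
    "normalize_method",
]

METHODS = (
    "ALLTC-step",
    "ALLTCI-step",
    "TC-step",
    "ALLTC-linear",
    "ALLTCI-linear",
    "TC-linear",
    "pooled",
    "separate",
)

_CANON = {re.sub(r"[^a-z]", "", m.lower()): m for m in METHODS}

_IRLS_TOL = 1e-8
_IRLS_MAXITER = 50
# Linear predictors beyond this magnitude indicate (quasi-)separation: the
# likelihood is maximised at infinity and Wald inference is meaningless.
_SEPARATION_ETA = 20.0


def normalize_method(method: str) -> str:
    """Map spelling variants (``ALLTC_step``, ``alltc step`` ...) to canonical names."""
    key = re.sub(r"[^a-z]", "", str(method).lower())
    try:
        return _CANON[key]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None


def one_sided_p(estimate: float, se: float, df: float | None = None) -> float:
    """Upper-tail p-value for H0: effect <= 0 (larger is better).

    Uses Student's t with ``df`` degrees of freedom when given, the standard
    normal otherwise.
    """
    if not se > 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    return float(stats.t.sf(z, df)) if df is not None else float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# core fitting (shared by the Model class and the simulation engine)
# ---------------------------------------------------------------------------

def _build_design(method, arm, period, j, target):
    """Subset mask, design matrix and coefficient names for one method."""
    if method in ("TC-step", "TC-linear", "pooled", "separate"):
        mask = (arm == 0) | (arm == target)
        if method == "separate":
            concurrent = np.unique(period[arm == target])
            mask &= np.isin(period, concurrent)
    else:
        mask = np.ones(arm.size, dtype=bool)
    a, p_, jj = arm[mask], period[mask], j[mask]

    names = ["eta0"]
    cols = [np.ones(a.size)]
    exp_arms = [int(v) for v in np.unique(a) if v != 0]
    for v in exp_arms:
        cols.append((a == v).astype(float))
        names.append(f"theta{v}")
    periods_here = [int(v) for v in np.unique(p_)]
    if method in ("ALLTC-step", "ALLTCI-step", "TC-step"):
        for s in periods_here[1:]:
            cols.append((p_ == s).astype(float))
            names.append(f"nu{s}")
    elif method in ("ALLTC-linear", "ALLTCI-linear", "TC-linear"):
        cols.append(jj.astype(float))
        names.append("gamma")
    if method == "ALLTCI-step":
        for v in exp_arms:
            if v == target:
                continue
            for s in periods_here[1:]:
                col = ((a == v) & (p_ == s)).astype(float)
                if col.any():
                    cols.append(col)
                    names.append(f"eta{v}_p{s}")
    elif method == "ALLTCI-linear":
        for v in exp_arms:
            if v == target:
                continue
            cols.append(jj * (a == v))
            names.append(f"eta{v}")
    return mask, np.column_stack(cols), names


def _ols(X, y, k2, alpha):
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("singular design matrix (empty or collinear cells)")
    resid = y - X @ beta
    scale = float(resid @ resid) / df
    cov = scale * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    stat = beta[k2] / bse[k2]
    pval = float(stats.t.sf(stat, df))
    return dict(
        params=beta, bse=bse, k2=k2, statistic=float(stat), pvalue=pval,
        reject=pval <= alpha, df_resid=df, scale=scale, converged=True,
        n_iter=0, nobs=n,
    )


def _logit(X, y, k2, alpha):
    n, k = X.shape
    beta = np.zeros(k)
    ybar = float(np.clip(y.mean(), 1e-8, 1 - 1e-8))
    beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    n_iter = 0
    eta = X @ beta
    for n_iter in range(1, _IRLS_MAXITER + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < _IRLS_TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        try:
            step = np.linalg.solve((X * w[:, None]).T @ X, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = X @ beta
        if not np.all(np.isfinite(beta)):
            break
    if converged and np.max(np.abs(eta)) > _SEPARATION_ETA:
        converged = False  # separation: MLE at infinity
    if not converged:
        nan = np.full(k, np.nan)
        return dict(
            params=nan, bse=nan, k2=k2, statistic=np.nan, pvalue=np.nan,
            reject=False, df_resid=None, scale=np.nan, converged=False,
            n_iter=n_iter, nobs=n,
        )
    mu = expit(eta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    bse = np.sqrt(np.diag(cov))
    stat = beta[k2] / bse[k2]
    pval = float(stats.norm.sf(stat))
    return dict(
        params=beta, bse=bse, k2=k2, statistic=float(stat), pvalue=pval,
        reject=pval <= alpha, df_resid=None, scale=np.nan, converged=True,
        n_iter=n_iter, nobs=n,
    )


def _welch(arm, y, mask, target, alpha):
    y0 = y[mask & (arm == 0)]
    y1 = y[mask & (arm == target)]
    n0, n1 = y0.size, y1.size
    if min(n0, n1) < 2:
        raise ValueError("Welch test needs at least two observations per group")
    v0, v1 = y0.var(ddof=1) / n0, y1.var(ddof=1) / n1
    diff = y1.mean() - y0.mean()
    se = np.sqrt(v0 + v1)
    df = (v0 + v1) ** 2 / (v0**2 / (n0 - 1) + v1**2 / (n1 - 1))
    stat = diff / se
    pval = float(stats.t.sf(stat, df))
    return dict(
        params=np.array([y0.mean(), diff]),
        bse=np.array([np.sqrt(y0.var(ddof=1) / n0), se]),
        k2=1, statistic=float(stat), pvalue=pval, reject=pval <= alpha,
        df_resid=float(df), scale=np.nan, converged=True, n_iter=0,
        nobs=n0 + n1,
    ), ["eta0", f"theta{target}"]


def _fit_core(arm, period, j, y, method, endpoint, alpha=0.025, target=None, welch=False):
    """Fit one method on raw arrays; returns a plain dict (engine fast path)."""
    method = normalize_method(method)
    arm = np.asarray(arm)
    period = np.asarray(period)
    j = np.asarray(j, dtype=float)
    y = np.asarray(y, dtype=float)
    if target is None:
        target = int(arm.max())
    if target == 0 or not (arm == target).any():
        raise ValueError(f"tested arm {target} absent from data")
    if not (arm == 0).any():
        raise ValueError("control arm (0) absent from data")

    if endpoint == "continuous" and welch and method in ("pooled", "separate"):
        mask = (arm == 0) | (arm == target)
        if method == "separate":
            concurrent = np.unique(period[arm == target])
            mask &= np.isin(period, concurrent)
        core, names = _welch(arm, y, mask, target, alpha)
        core["names"] = names
        core["method"] = method
        return core

    mask, X, names = _build_design(method, arm, period, j, target)
    k2 = names.index(f"theta{target}")
    fit = _ols if endpoint == "continuous" else _logit
    core = fit(X, y[mask], k2, alpha)
    core["names"] = names
    core["method"] = method
    return core


# ---------------------------------------------------------------------------
# public Model / Results objects
# ---------------------------------------------------------------------------

class PlatformTrialModel:
    """A treatment-vs-control analysis of one platform-trial dataset.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per patient with columns ``arm``, ``period``, ``y``; an
        enrolment-index column ``j`` is used by the linear-time methods
        (defaulting to row order if absent).
    method : str
        One of :data:`METHODS` (underscore spellings are accepted).
    endpoint : {"continuous", "binary"}, optional
        Inferred from the outcomes if omitted (binary iff all values in {0,1}).
    alpha : float
        One-sided significance level, in (0, 0.5); default 0.025.
    target_arm : int, optional
        Arm whose effect is tested; defaults to the highest arm label.
    welch : bool
        Use the Welch (unequal-variance) t-test for ``pooled``/``separate``
        continuous comparisons instead of the pooled-SD test.
    """

    def __init__(self, data: pd.DataFrame, method: str = "ALLTC-step",
                 endpoint: str | None = None, alpha: float = 0.025,
                 target_arm: int | None = None, welch: bool = False):
        missing = [c for c in ("arm", "period", "y") if c not in data.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns {missing}")
        if not 0 < alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        self.data = data
        self.method = normalize_method(method)
        self.alpha = float(alpha)
        self.welch = bool(welch)
        y = np.asarray(data["y"], dtype=float)
        if endpoint is None:
            endpoint = data.attrs.get("endpoint") or (
                "binary" if np.isin(y, (0.0, 1.0)).all() else "continuous"
            )
        if endpoint not in ("continuous", "binary"):
            raise ValueError(f"unknown endpoint {endpoint!r}")
        self.endpoint = endpoint
        self._arm = np.asarray(data["arm"], dtype=np.int64)
        self._period = np.asarray(data["period"], dtype=np.int64)
        self._j = (np.asarray(data["j"], dtype=float) if "j" in data.columns
                   else np.arange(1.0, len(data) + 1.0))
        self._y = y
        self.target_arm = int(self._arm.max()) if target_arm is None else int(target_arm)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PlatformTrialModel":
        from .datagen import read_dataset

        return cls(read_dataset(path), **kwargs)

    def fit(self) -> "PlatformTrialResults":
        core = _fit_core(
            self._arm, self._period, self._j, self._y,
            self.method, self.endpoint, alpha=self.alpha,
            target=self.target_arm, welch=self.welch,
        )
        return PlatformTrialResults(self, core)


class PlatformTrialResults:
    """Estimates, uncertainties and the one-sided test for a fitted model.

    Attributes
    ----------
    params, bse : pandas.Series
        Coefficient estimates and standard errors (NaN if not converged).
    effect, se : float
        The tested arm's effect estimate and its standard error.
    statistic, pvalue : float
        One-sided t (continuous) or Wald z (binary) statistic and upper-tail
        p-value for H0: effect <= 0.
    reject : bool
        ``pvalue <= alpha`` (False when not converged).
    converged : bool
        Always True for least squares; for logistic fits, whether Newton
        reached the score tolerance without signs of separation.
    df_resid : float or None
        Residual degrees of freedom (None for Wald-z inference).
    scale : float
        Residual variance estimate (continuous endpoints).
    """

    def __init__(self, model: PlatformTrialModel, core: dict):
        self.model = model
        self.method = core["method"]
        self.endpoint = model.endpoint
        self.alpha = model.alpha
        self.target_arm = model.target_arm
        self.params = pd.Series(core["params"], index=core["names"])
        self.bse = pd.Series(core["bse"], index=core["names"])
        self._k2 = core["k2"]
        self.effect = float(core["params"][self._k2])
        self.se = float(core["bse"][self._k2])
        self.statistic = core["statistic"]
        self.pvalue = core["pvalue"]
        self.reject = bool(core["reject"])
        self.df_resid = core["df_resid"]
        self.scale = core["scale"]
        self.converged = bool(core["converged"])
        self.n_iter = core["n_iter"]
        self.nobs = core["nobs"]

    def to_record(self) -> dict:
        """Flat record for tabulation/serialisation."""
        return {
            "method": self.method,
            "estimate": self.effect,
            "se": self.se,
            "p": self.pvalue,
            "reject": self.reject,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Platform trial treatment-effect analysis",
            "=" * 56,
            f"method:    {self.method:<18} endpoint: {self.endpoint}",
            f"nobs:      {self.nobs:<18} tested arm: {self.target_arm}",
            f"test:      one-sided H0: theta{self.target_arm} <= 0 at alpha = {self.alpha}",
        ]
        if not self.converged:
            lines.append("FIT DID NOT CONVERGE (possible separation); no estimates reported")
            return "\n".join(lines)
        lines.append("-" * 56)
        lines.append(f"{'coef':<10}{'estimate':>12}{'std err':>12}")
        for name in self.params.index:
            lines.append(f"{name:<10}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        lines.append("-" * 56)
        df_txt = "inf" if self.df_resid is None else f"{self.df_resid:g}"
        lines.append(
            f"theta{self.target_arm} = {self.effect:.4f} (SE {self.se:.4f}), "
            f"stat = {self.statistic:.3f} (df {df_txt}), one-sided p = {self.pvalue:.4f}"
        )
        lines.append(f"reject H0: {self.reject}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PlatformTrialResults {self.method} effect={self.effect:.4g} "
                f"p={self.pvalue:.4g}>")


def fit_model(data: pd.DataFrame, method: str = "ALLTC-step", **kwargs) -> PlatformTrialResults:
    """Convenience wrapper: ``PlatformTrialModel(data, method, ...).fit()``."""
    return PlatformTrialModel(data, method=method, **kwargs).fit()
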