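"""Simulation of complete platform-trial datasets.

Outcomes are generated from the additive model on the link scale

    g(E(Y_j)) = eta0 + sum_k theta_k * I(k_j = k) + f_{k_j}(t_j)

with the identity link and i.i.d. N(0, sigma^2) residuals for continuous
endpoints, and the logit link with Bernoulli outcomes for binary endpoints.
Treatment effects are mean differences (continuous) or odds ratios (binary,
converted to log-odds internally).  Allocation comes from
:mod:`ncctrends.design`; trends from :mod:`ncctrends.trends`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import TrialDesign, allocate
from .trends import TrendSpec, _base

__all__ = [
    "ScenarioSpec",
    "simulate_trial",
    "expected_cell_means",
    "write_dataset",
    "read_dataset",
]

DATA_COLUMNS = ("j", "t", "arm", "period", "y")


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to simulate one trial: design, trend, effects, noise.

    Parameters
    ----------
    design : TrialDesign
    trend : TrendSpec
    endpoint : {"continuous", "binary"}
    eta0 : float
        Control-arm response in period 1 (continuous endpoints; mean outcome).
    effects : tuple of float
        Mean differences vs control for arms 1..K-1 (continuous endpoints).
    sigma : float
        Residual standard deviation (continuous endpoints; must be > 0).
    p0 : float
        Control response rate in period 1 (binary endpoints; in (0, 1)).
    odds_ratios : tuple of float
        Treatment odds ratios vs control for arms 1..K-1 (binary endpoints).
    allocation : {"block", "simple"}
    block_sizes : int or per-period sequence (block allocation only)
    unconditional : bool
        Use unconditional Bernoulli assignment for ``allocation="simple"``.
    """

    design: TrialDesign
    trend: TrendSpec
    endpoint: str = "continuous"
    eta0: float = 0.0
    effects: Sequence[float] = (0.25, 0.25)
    sigma: float = 1.0
    p0: float | None = None
    odds_ratios: Sequence[float] | None = None
    allocation: str = "block"
    block_sizes: int | Sequence[int] | None = (4, 12)
    unconditional: bool = False

    def __post_init__(self) -> None:
        if self.endpoint not in ("continuous", "binary"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        n_exp = self.design.n_arms - 1
        if self.endpoint == "continuous":
            if self.sigma <= 0:
                raise ValueError("sigma must be positive for continuous endpoints")
            object.__setattr__(self, "effects", tuple(float(v) for v in self.effects))
            if len(self.effects) != n_exp:
                raise ValueError(f"expected {n_exp} treatment effects, got {len(self.effects)}")
        else:
            if self.p0 is None or not 0 < self.p0 < 1:
                raise ValueError("binary endpoints need a control rate p0 in (0, 1)")
            if self.odds_ratios is None:
                raise ValueError("binary endpoints need odds_ratios for each treatment arm")
            ors = tuple(float(v) for v in self.odds_ratios)
            if len(ors) != n_exp:
                raise ValueError(f"expected {n_exp} odds ratios, got {len(ors)}")
            if any(v <= 0 for v in ors):
                raise ValueError("odds ratios must be positive")
            object.__setattr__(self, "odds_ratios", ors)
        if isinstance(self.block_sizes, list):
            object.__setattr__(self, "block_sizes", tuple(self.block_sizes))

    # --- link-scale parameters ---------------------------------------------
    @property
    def eta0_link(self) -> float:
        """Control response in period 1 on the model (link) scale."""
        return float(logit(self.p0)) if self.endpoint == "binary" else float(self.eta0)

    @property
    def theta_link(self) -> np.ndarray:
        """Treatment effects on the link scale, indexed by arm (arm 0 -> 0)."""
        if self.endpoint == "binary":
            eff = np.log(self.odds_ratios)
        else:
            eff = np.asarray(self.effects, dtype=float)
        return np.concatenate([[0.0], eff])

    @property
    def target_arm(self) -> int:
        """The newest (highest-index) arm, whose effect is under test."""
        return self.design.n_arms - 1

    @property
    def theta_true(self) -> float:
        return float(self.theta_link[self.target_arm])


def _linear_predictor(scenario: ScenarioSpec, arm: np.ndarray, t: np.ndarray,
                      base: np.ndarray | None = None) -> np.ndarray:
    design = scenario.design
    if base is None:
        base = _base(scenario.trend, t, design.N, design.N1)
    lam = scenario.trend.lam_vector(design.n_arms)
    return scenario.eta0_link + scenario.theta_link[arm] + lam[arm] * base


def _simulate_arrays(scenario: ScenarioSpec, rng: np.random.Generator,
                     base: np.ndarray | None = None):
    """Fast path: simulate one trial, returning (t, arm, period, y) arrays.

    ``base`` may carry the precomputed trend shape for fixed entry times
    (it is identical across replicates in that case).
    """
    design = scenario.design
    alloc = allocate(
        design,
        method=scenario.allocation,
        block_sizes=scenario.block_sizes,
        seed=rng,
        unconditional=scenario.unconditional,
    )
    N = design.N
    if scenario.trend.entry_times == "random":
        t = np.sort(rng.uniform(1.0, N, N))
        base = None  # depends on the drawn times
    else:
        t = np.arange(1, N + 1, dtype=float)
    lp = _linear_predictor(scenario, alloc.arms, t, base)
    if scenario.endpoint == "continuous":
        y = lp + scenario.sigma * rng.standard_normal(N)
    else:
        y = (rng.random(N) < expit(lp)).astype(float)
    return t, alloc.arms, alloc.periods, y


def simulate_trial(scenario: ScenarioSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Simulate one complete trial dataset.

    Returns a DataFrame with columns ``j, t, arm, period, y`` (one row per
    patient, enrolment order); ``df.attrs`` records the endpoint and seed.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, arm, period, y = _simulate_arrays(scenario, rng)
    df = pd.DataFrame(
        {"j": np.arange(1, scenario.design.N + 1), "t": t, "arm": arm, "period": period, "y": y}
    )
    df.attrs["endpoint"] = scenario.endpoint
    if not isinstance(seed, np.random.Generator):
        df.attrs["seed"] = seed
    return df


def expected_cell_means(scenario: ScenarioSpec) -> pd.DataFrame:
    """Expected outcome (mean or response rate) per arm x period.

    For the step trend these are the exact cell means; for linear and
    inverse-U trends each cell is the within-period average of the mean
    function over the period's patient indices (with fixed entry times
    ``t_j = j``).  Cells the design never fills are NaN.
    """
    design = scenario.design
    t = np.arange(1, design.N + 1, dtype=float)
    base = _base(scenario.trend, t, design.N, design.N1)
    lam = scenario.trend.lam_vector(design.n_arms)
    bounds = np.concatenate([[0], design.boundaries])
    out = np.full((design.n_arms, design.n_periods), np.nan)
    for s in range(design.n_periods):
        seg = base[bounds[s]: bounds[s + 1]]
        for k in range(design.n_arms):
            if design.n[k, s] == 0:
                continue
            lp = scenario.eta0_link + scenario.theta_link[k] + lam[k] * seg
            mean = expit(lp) if scenario.endpoint == "binary" else lp
            out[k, s] = mean.mean()
    return pd.DataFrame(
        out,
        index=pd.Index(range(design.n_arms), name="arm"),
        columns=pd.Index(range(1, design.n_periods + 1), name="period"),
    )


def write_dataset(df: pd.DataFrame, path, endpoint: str | None = None) -> None:
    """Write a trial dataset as CSV with a small ``#``-comment metadata block."""
    endpoint = endpoint or df.attrs.get("endpoint")
    with open(path, "w") as fh:
        if endpoint:
            fh.write(f"# endpoint: {endpoint}\n")
        if "seed" in df.attrs:
            fh.write(f"# seed: {df.attrs['seed']}\n")
        df.to_csv(fh, index=False, columns=[c for c in DATA_COLUMNS if c in df.columns])


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset written by :func:`write_dataset` (metadata into ``attrs``)."""
    meta = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        if ":" in line:
            key, val = line.lstrip("# ").split(":", 1)
            meta[key.strip()] = val.strip()
    df = pd.read_csv(io.StringIO(text), comment="#")
    missing = [c for c in ("arm", "period", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns {missing}")
    if "endpoint" in meta:
        df.attrs["endpoint"] = meta["endpoint"]
    return df
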