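"""Replicate simulations and operating characteristics.

For each replicate a full trial dataset is simulated and *every* requested
analysis method is fitted to that same dataset (a paired design: method
comparisons share the Monte-Carlo noise).  Aggregated per method:

- rejection rate of the one-sided test of H02 and its Monte-Carlo SE,
- bias ``E[theta2^] - theta2`` and RMSE of the effect estimate,
- mean reported standard error,
- replicate counts requested / converged (non-converged logistic fits are
  excluded from the aggregates and counted).

Replicate ``r`` draws from an independent RNG stream keyed by
``(base_seed, r)`` (numpy ``SeedSequence`` spawn keys), so runs are
deterministic and independent of execution order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from .datagen import ScenarioSpec, _simulate_arrays
from .model import _fit_core, normalize_method
from .trends import _base

__all__ = [
    "OperatingCharacteristics",
    "run_scenario",
    "run_grid",
    "lambda1_for_period2_level",
]

logger = logging.getLogger("ncctrends")

OC_COLUMNS = (
    "scenario_id", "endpoint", "pattern", "lambda0", "lambda1", "lambda2",
    "hypothesis", "method", "n_reps", "n_converged", "reject_rate",
    "reject_mcse", "bias", "rmse", "mean_se", "theta2_true", "seed",
)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated simulation results for one (scenario, method) pair."""

    scenario_id: str
    method: str
    n_reps: int
    n_converged: int
    reject_rate: float
    reject_mcse: float
    bias: float
    rmse: float
    mean_se: float
    theta2_true: float
    base_seed: int

    @property
    def hypothesis(self) -> str:
        return "H0" if self.theta2_true == 0 else "H1"


def _replicate_rng(base_seed: int, seed_path: tuple, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(*seed_path, r)))


def run_scenario(
    scenario: ScenarioSpec,
    methods: Sequence[str],
    n_reps: int,
    base_seed: int,
    alpha: float = 0.025,
    scenario_id: str = "s0",
    seed_path: tuple = (),
    return_replicates: bool = False,
):
    """Simulate ``n_reps`` trials and aggregate operating characteristics.

    Returns a DataFrame with one row per method (columns :data:`OC_COLUMNS`,
    minus the grid-only ones filled from the scenario).  With
    ``return_replicates=True`` also returns the per-replicate fit table.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    methods = [normalize_method(m) for m in methods]
    if not methods:
        raise ValueError("no analysis methods given")
    design = scenario.design
    target = scenario.target_arm
    if target == 0:
        raise ValueError("the design has no experimental arm to test")

    # trend shape is replicate-invariant under fixed entry times
    base = None
    if scenario.trend.entry_times == "fixed":
        t = np.arange(1, design.N + 1, dtype=float)
        base = _base(scenario.trend, t, design.N, design.N1)

    est = {m: np.empty(n_reps) for m in methods}
    ses = {m: np.empty(n_reps) for m in methods}
    rej = {m: np.zeros(n_reps, dtype=bool) for m in methods}
    conv = {m: np.zeros(n_reps, dtype=bool) for m in methods}

    for r in range(n_reps):
        rng = _replicate_rng(base_seed, seed_path, r)
        t, arm, period, y = _simulate_arrays(scenario, rng, base=base)
        j = np.arange(1.0, design.N + 1.0)
        for m in methods:
            core = _fit_core(arm, period, j, y, m, scenario.endpoint,
                             alpha=alpha, target=target)
            est[m][r] = core["params"][core["k2"]]
            ses[m][r] = core["bse"][core["k2"]]
            rej[m][r] = core["reject"]
            conv[m][r] = core["converged"]

    theta_true = scenario.theta_true
    rows = []
    for m in methods:
        ok = conv[m]
        n_ok = int(ok.sum())
        if n_ok:
            p_hat = float(rej[m][ok].mean())
            mcse = float(np.sqrt(p_hat * (1.0 - p_hat) / n_ok))
            err = est[m][ok] - theta_true
            bias = float(err.mean())
            rmse = float(np.sqrt(np.mean(err**2)))
            mean_se = float(ses[m][ok].mean())
        else:
            p_hat = mcse = bias = rmse = mean_se = float("nan")
        rows.append(OperatingCharacteristics(
            scenario_id=scenario_id, method=m, n_reps=n_reps, n_converged=n_ok,
            reject_rate=p_hat, reject_mcse=mcse, bias=bias, rmse=rmse,
            mean_se=mean_se, theta2_true=theta_true, base_seed=base_seed,
        ))
    oc = _to_frame(rows, scenario)
    if not return_replicates:
        return oc
    reps = pd.DataFrame({
        "rep": np.repeat(np.arange(n_reps), len(methods)),
        "method": np.tile(methods, n_reps),
        "estimate": np.column_stack([est[m] for m in methods]).ravel(),
        "se": np.column_stack([ses[m] for m in methods]).ravel(),
        "reject": np.column_stack([rej[m] for m in methods]).ravel(),
        "converged": np.column_stack([conv[m] for m in methods]).ravel(),
    })
    return oc, reps


def _to_frame(rows: Sequence[OperatingCharacteristics], scenario: ScenarioSpec) -> pd.DataFrame:
    lam = [scenario.trend.lam_for(k) if k < scenario.design.n_arms else np.nan
           for k in range(3)]
    return pd.DataFrame([
        {
            "scenario_id": oc.scenario_id,
            "endpoint": scenario.endpoint,
            "pattern": scenario.trend.pattern,
            "lambda0": lam[0], "lambda1": lam[1], "lambda2": lam[2],
            "hypothesis": oc.hypothesis,
            "method": oc.method,
            "n_reps": oc.n_reps,
            "n_converged": oc.n_converged,
            "reject_rate": oc.reject_rate,
            "reject_mcse": oc.reject_mcse,
            "bias": oc.bias,
            "rmse": oc.rmse,
            "mean_se": oc.mean_se,
            "theta2_true": oc.theta2_true,
            "seed": oc.base_seed,
        }
        for oc in rows
    ], columns=list(OC_COLUMNS))


# ---------------------------------------------------------------------------
# scenario grids
# ---------------------------------------------------------------------------

_GRID_KEYS = ("pattern", "lambda0", "lambda1", "lambda2", "lam", "Np", "hypothesis")


def _apply_combo(base: ScenarioSpec, combo: Mapping) -> ScenarioSpec:
    trend = base.trend
    trend_changes = {}
    if "pattern" in combo:
        trend_changes["pattern"] = combo["pattern"]
    if "Np" in combo:
        trend_changes["Np"] = combo["Np"]
    if "lam" in combo:
        trend_changes["lam"] = float(combo["lam"])
    per_arm = {k: f"lambda{k}" for k in range(base.design.n_arms)}
    if any(name in combo for name in per_arm.values()):
        lam = {k: trend.lam_for(k) for k in range(base.design.n_arms)}
        if "lam" in combo:
            lam = {k: float(combo["lam"]) for k in lam}
        for k, name in per_arm.items():
            if name in combo:
                lam[k] = float(combo[name])
        trend_changes["lam"] = lam
    if trend_changes:
        trend = replace(trend, **trend_changes)
    scenario = replace(base, trend=trend) if trend_changes else base
    if "hypothesis" in combo:
        hyp = combo["hypothesis"]
        if hyp not in ("H0", "H1"):
            raise ValueError("hypothesis must be 'H0' or 'H1'")
        if hyp == "H0":
            if scenario.endpoint == "continuous":
                eff = list(scenario.effects)
                eff[-1] = 0.0
                scenario = replace(scenario, effects=tuple(eff))
            else:
                ors = list(scenario.odds_ratios)
                ors[-1] = 1.0
                scenario = replace(scenario, odds_ratios=tuple(ors))
        # "H1" keeps the base scenario's (alternative) effect
    return scenario


def run_grid(
    base: ScenarioSpec,
    grid: Mapping[str, Sequence],
    methods: Sequence[str],
    n_reps: int,
    base_seed: int,
    alpha: float = 0.025,
) -> pd.DataFrame:
    """Run a Cartesian scenario sweep; one OC row per (scenario, method).

    ``grid`` maps sweep keys (``pattern``, ``lambda0/1/2``, ``lam``, ``Np``,
    ``hypothesis``) to lists of values.  Scenario ``i`` uses replicate streams
    keyed by ``(base_seed, i, r)``, so the full table is reproducible and any
    subset can be re-run in isolation.
    """
    if not grid:
        raise ValueError("empty scenario grid")
    for key in grid:
        if key not in _GRID_KEYS:
            raise ValueError(f"unknown grid key {key!r}; valid keys: {_GRID_KEYS}")
    keys = [k for k in _GRID_KEYS if k in grid]
    values = [list(grid[k]) for k in keys]
    if any(len(v) == 0 for v in values):
        raise ValueError("empty scenario grid")
    combos = list(itertools.product(*values))
    logger.info("running scenario grid: %d scenarios x %d methods x %d replicates",
                len(combos), len(methods), n_reps)
    frames = []
    for i, combo_vals in enumerate(combos):
        combo = dict(zip(keys, combo_vals))
        scenario = _apply_combo(base, combo)
        oc = run_scenario(
            scenario, methods, n_reps, base_seed,
            alpha=alpha, scenario_id=f"g{i:03d}", seed_path=(i,),
        )
        if "hypothesis" in combo:
            oc["hypothesis"] = combo["hypothesis"]
        frames.append(oc)
    return pd.concat(frames, ignore_index=True)


def lambda1_for_period2_level(level: float, scenario: ScenarioSpec) -> float:
    """Arm-1 trend strength implied by a target arm-1 period-2 mean/rate.

    Scenario sweeps are often expressed as "the arm-1 response in period 2
    equals X" (step trends).  On the model scale that pins down
    ``lambda1 = X - eta0 - theta1`` for continuous endpoints and
    ``lambda1 = logit(X) - logit(p0) - log(OR1)`` for binary ones.
    """
    if scenario.endpoint == "continuous":
        return float(level - scenario.eta0 - scenario.effects[0])
    return float(logit(level) - logit(scenario.p0) - np.log(scenario.odds_ratios[0]))
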