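"""YAML run configurations: parsing, validation and resolution to objects.

A run configuration fully determines a simulation run (design, randomisation,
trend, effects, endpoint, methods, replicate count, seed), e.g.::

    design:
      n: [[125, 125], [125, 125], [0, 250]]
    randomisation:
      method: block
      block_sizes: [4, 12]
    trend:
      pattern: step
      lambda: 0.15            # scalar, per-arm list, or {arm: value} map
      # Np: "N1+N2/2"         # inverse-U turning point
    endpoint: continuous
    effects:
      eta0: 0.0
      theta: [0.25, 0.25]     # binary endpoints instead use p0 / odds_ratios
    sigma: 1.0
    methods: [ALLTC-step, ALLTCI-step, pooled, separate]
    alpha: 0.025
    n_reps: 10000
    seed: 42
    # grid:                   # optional scenario sweep (Cartesian product)
    #   lambda1: [0.0, 0.05, 0.1, 0.15, 0.2]
    #   hypothesis: [H0, H1]

Validation errors name the offending key (``trend.pattern: ...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .datagen import ScenarioSpec
from .design import make_design
from .model import normalize_method
from .trends import TrendSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "build_run_config"]


class ConfigError(ValueError):
    """A configuration problem, with the offending key in the message."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a YAML mapping")
    return cfg


def _require(cfg: dict, key: str, where: str = ""):
    if key not in cfg or cfg[key] is None:
        full = f"{where}.{key}" if where else key
        raise ConfigError(f"{full}: required key is missing")
    return cfg[key]


@dataclass
class RunConfig:
    """A fully resolved run: scenario, methods, sizes, seed and the raw dict."""

    scenario: ScenarioSpec
    methods: list
    n_reps: int
    seed: int
    alpha: float
    grid: dict | None
    raw: dict = field(repr=False, default_factory=dict)

    def to_yaml(self) -> str:
        """Serialise the resolved configuration (round-trips losslessly)."""
        return yaml.safe_dump(self.raw, sort_keys=False)


def build_run_config(cfg: dict, *, reps: int | None = None,
                     seed: int | None = None) -> RunConfig:
    """Validate a config dict and resolve it into a :class:`RunConfig`.

    ``reps`` and ``seed`` are command-line overrides; the resolved values are
    written back into the stored raw dict so the output copy reproduces the
    run exactly.
    """
    design_cfg = _require(cfg, "design")
    try:
        design = make_design(_require(design_cfg, "n", "design"))
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"design.n: {exc}") from None

    trend_cfg = _require(cfg, "trend")
    pattern = _require(trend_cfg, "pattern", "trend")
    lam = trend_cfg.get("lambda", trend_cfg.get("lam", 0.0))
    try:
        trend = TrendSpec(
            pattern=pattern,
            lam=lam,
            Np=trend_cfg.get("Np"),
            entry_times=trend_cfg.get("entry_times", "fixed"),
            continuous_inverse_u=bool(trend_cfg.get("continuous_inverse_u", False)),
        )
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"trend: {exc}") from None

    endpoint = _require(cfg, "endpoint")
    if endpoint not in ("continuous", "binary"):
        raise ConfigError(f"endpoint: must be 'continuous' or 'binary', got {endpoint!r}")

    rand_cfg = cfg.get("randomisation", {}) or {}
    method = rand_cfg.get("method", "block")
    if method not in ("block", "simple"):
        raise ConfigError(f"randomisation.method: unknown method {method!r}")
    block_sizes = rand_cfg.get("block_sizes")
    if method == "block" and block_sizes is None:
        raise ConfigError("randomisation.block_sizes: required for block randomisation")

    eff_cfg = cfg.get("effects", {}) or {}
    kwargs = dict(
        design=design, trend=trend, endpoint=endpoint,
        allocation=method, block_sizes=block_sizes,
        unconditional=bool(rand_cfg.get("unconditional", False)),
    )
    try:
        if endpoint == "continuous":
            kwargs["eta0"] = float(eff_cfg.get("eta0", 0.0))
            kwargs["effects"] = tuple(_require(eff_cfg, "theta", "effects"))
            kwargs["sigma"] = float(cfg.get("sigma", 1.0))
        else:
            kwargs["p0"] = float(_require(eff_cfg, "p0", "effects"))
            kwargs["odds_ratios"] = tuple(_require(eff_cfg, "odds_ratios", "effects"))
        scenario = ScenarioSpec(**kwargs)
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"effects: {exc}") from None

    try:
        methods = [normalize_method(m) for m in cfg.get("methods", ["ALLTC-step"])]
    except ValueError as exc:
        raise ConfigError(f"methods: {exc}") from None

    alpha = float(cfg.get("alpha", 0.025))
    if not 0 < alpha < 0.5:
        raise ConfigError("alpha: must be in (0, 0.5)")
    n_reps = int(reps if reps is not None else cfg.get("n_reps", 10000))
    if n_reps < 1:
        raise ConfigError("n_reps: must be >= 1")
    seed_val = seed if seed is not None else cfg.get("seed")
    if seed_val is None:
        raise ConfigError("seed: required key is missing (or pass --seed)")

    grid = cfg.get("grid")
    if grid is not None and (not isinstance(grid, dict) or not grid):
        raise ConfigError("grid: must be a non-empty mapping of sweep keys to lists")

    raw = dict(cfg)
    raw["n_reps"] = n_reps
    raw["seed"] = int(seed_val)
    raw["alpha"] = alpha
    return RunConfig(scenario=scenario, methods=methods, n_reps=n_reps,
                     seed=int(seed_val), alpha=alpha, grid=grid, raw=raw)
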