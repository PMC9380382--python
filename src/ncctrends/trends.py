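"""Time-trend functions f(t) added on the model (link) scale.

Outcomes in a platform trial can drift over calendar time — changes in
standard of care, population drift, seasonal effects.  Such drift is emulated
here by adding an arm-specific trend ``f_k(t)`` to the linear predictor,
with patient index as the time axis (one patient per time unit).  Three
patterns are supported, each with strength ``lambda_k`` (outcome units for
continuous endpoints, log-odds for binary):

- ``linear``:      ``lambda_k * (t - 1) / (N - 1)``
- ``step``:        ``lambda_k * I(t > N1)``
- ``inverse_u``:   ``lambda_k * (t - 1) / (N - 1) * (I(t <= Np) - I(t > Np))``

The inverse-U formula flips sign at the turning point ``Np`` and is therefore
discontinuous there; that discontinuous form is the default, a continuous
"tent" variant is available behind ``continuous_inverse_u=True`` for
sensitivity checks.  Negative ``lambda_k`` turns the inverse-U into a U shape.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = ["TrendSpec", "trend_value", "trend_profile", "PATTERNS"]

PATTERNS = ("linear", "step", "inverse_u")

#: Symbolic turning points resolved against the design: half of period 1,
#: the period boundary, or half-way through period 2.
_NP_SYMBOLS = ("N1/2", "N1", "N1+N2/2")


@dataclass(frozen=True)
class TrendSpec:
    """Trend pattern, per-arm strengths and (for the inverse-U) turning point.

    Parameters
    ----------
    pattern : {"linear", "step", "inverse_u"}
    lam : float, sequence or mapping arm -> float
        Trend strength per arm on the model scale.  A scalar applies the same
        strength to every arm (the equal-trends setting).
    Np : int or {"N1/2", "N1", "N1+N2/2"}, optional
        Turning point for the inverse-U pattern; defaults to ``"N1+N2/2"``.
    entry_times : {"fixed", "random"}
        ``"fixed"`` uses ``t_j = j``; ``"random"`` substitutes N sorted
        Uniform(1, N) draws for the enrolment times.
    continuous_inverse_u : bool
        Replace the discontinuous sign flip by a continuous tent shape
        peaking at ``Np`` (never the default).
    """

    pattern: str
    lam: float | Sequence[float] | Mapping[int, float] = 0.0
    Np: int | str | None = None
    entry_times: str = "fixed"
    continuous_inverse_u: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown trend pattern {self.pattern!r}; choose from {PATTERNS}")
        if self.entry_times not in ("fixed", "random"):
            raise ValueError("entry_times must be 'fixed' or 'random'")
        if isinstance(self.Np, str) and self.Np not in _NP_SYMBOLS:
            raise ValueError(f"symbolic turning point must be one of {_NP_SYMBOLS}")
        if isinstance(self.lam, list):
            object.__setattr__(self, "lam", tuple(self.lam))
        elif isinstance(self.lam, dict):
            object.__setattr__(self, "lam", tuple(sorted(self.lam.items())))

    def lam_for(self, arm: int) -> float:
        lam = self.lam
        if isinstance(lam, tuple) and lam and isinstance(lam[0], tuple):
            lam = dict(lam)  # was a mapping
        if isinstance(lam, Mapping) or isinstance(lam, dict):
            try:
                return float(lam[arm])
            except KeyError:
                raise KeyError(f"no trend strength given for arm {arm}") from None
        if isinstance(lam, (tuple, list)):
            return float(lam[arm])
        return float(lam)

    def lam_vector(self, n_arms: int) -> np.ndarray:
        return np.array([self.lam_for(k) for k in range(n_arms)])

    def turning_point(self, N1: int, N2: int) -> int:
        """Resolve ``Np`` against period sizes; integer division for halves."""
        Np = self.Np if self.Np is not None else "N1+N2/2"
        if isinstance(Np, str):
            Np = {"N1/2": N1 // 2, "N1": N1, "N1+N2/2": N1 + N2 // 2}[Np]
        Np = int(Np)
        if not 1 <= Np <= N1 + N2:
            raise ValueError(f"turning point {Np} outside 1..{N1 + N2}")
        return Np


def _base(spec: TrendSpec, t: np.ndarray, N: int, N1: int) -> np.ndarray:
    """Pattern shape without the strength factor, evaluated at times ``t``."""
    t = np.asarray(t, dtype=float)
    if spec.pattern == "step":
        return (t > N1).astype(float)
    if N < 2:
        raise ValueError("linear and inverse-U trends need N >= 2")
    ramp = (t - 1.0) / (N - 1.0)
    if spec.pattern == "linear":
        return ramp
    Np = spec.turning_point(N1, N - N1)
    if spec.continuous_inverse_u:
        return ((Np - 1.0) - np.abs(t - Np)) / (N - 1.0)
    return ramp * np.where(t <= Np, 1.0, -1.0)


def trend_value(spec: TrendSpec, arm: int, j, N: int, N1: int):
    """Evaluate ``f(t_j)`` for one arm at patient index (or time) ``j``.

    ``j`` may be a scalar or an array; values must lie in ``[1, N]``.
    """
    j_arr = np.asarray(j, dtype=float)
    if (j_arr < 1).any() or (j_arr > N).any():
        raise ValueError(f"patient index {j} outside 1..{N}")
    out = spec.lam_for(arm) * _base(spec, j_arr, N, N1)
    return out if out.ndim else float(out)


def trend_profile(spec: TrendSpec, design) -> np.ndarray:
    """Trend values per arm for every patient index, shape (n_arms, N)."""
    t = np.arange(1, design.N + 1, dtype=float)
    base = _base(spec, t, design.N, design.N1)
    return spec.lam_vector(design.n_arms)[:, None] * base[None, :]
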