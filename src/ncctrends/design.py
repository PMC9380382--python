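"""Trial designs and patient-to-arm randomisation for multi-period platform trials.

A platform trial recruits patients sequentially while experimental arms enter
(or leave) the platform; all arms share a common control.  A *period* is a
maximal span of enrolment during which the set of recruiting arms does not
change.  A design is summarised by the matrix of target cell counts
``n[k, s]`` for arm ``k`` (0 = control) and period ``s``.  In the canonical
two-period design a second experimental arm joins after ``N1`` patients, so
``n[2, 0] = 0``: controls recruited in period 1 are *non-concurrent* with
respect to arm 2, controls in period 2 are *concurrent*.

Patient index ``j`` is 1-based and doubles as enrolment time (one patient per
time unit); patient ``j`` belongs to period 1 iff ``j <= N1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TrialDesign", "AllocationSequence", "make_design", "allocate"]


@dataclass(frozen=True, eq=False)
class TrialDesign:
    """Target per-arm-per-period sample sizes ``n[k, s]``.

    Parameters
    ----------
    n : array-like of int, shape (n_arms, n_periods)
        Cell counts; row 0 is the control arm.  Validated on construction:
        counts are non-negative integers, every period recruits at least one
        control patient, and the set of recruiting arms changes between
        adjacent periods (otherwise they would be a single period — in
        particular, a late-entering arm must have zero counts before its
        entry, e.g. ``n[2, 0] = 0`` in the two-period design).
    """

    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if n.ndim != 2:
            raise ValueError("design matrix must be 2-d (arms x periods)")
        if n.size == 0:
            raise ValueError("design matrix must have at least one arm and one period")
        if not np.issubdtype(n.dtype, np.integer):
            if not np.all(np.equal(np.mod(n, 1), 0)):
                raise ValueError("cell counts must be integers")
        n = n.astype(np.int64)
        if (n < 0).any():
            raise ValueError("cell counts must be non-negative")
        sizes = n.sum(axis=0)
        if (sizes == 0).any():
            s = int(np.flatnonzero(sizes == 0)[0]) + 1
            raise ValueError(f"period {s} recruits no patients")
        if (n[0] < 1).any():
            s = int(np.flatnonzero(n[0] < 1)[0]) + 1
            raise ValueError(f"control arm must recruit in every period (period {s} has none)")
        for s in range(1, n.shape[1]):
            if np.array_equal(n[:, s] > 0, n[:, s - 1] > 0):
                raise ValueError(
                    f"periods {s} and {s + 1} have the same set of recruiting arms; "
                    "periods are defined by arms entering or leaving, so a late arm "
                    "must have zero counts before its entry (e.g. n[2, 0] = 0)"
                )
        object.__setattr__(self, "n", n)

    # --- derived quantities -------------------------------------------------
    @property
    def n_arms(self) -> int:
        return self.n.shape[0]

    @property
    def n_periods(self) -> int:
        return self.n.shape[1]

    @property
    def period_sizes(self) -> np.ndarray:
        """Total patients per period, ``N_s``."""
        return self.n.sum(axis=0)

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative patient-index cut points; entry ``s-1`` is the last index of period ``s``."""
        return np.cumsum(self.period_sizes)

    @property
    def N(self) -> int:
        return int(self.period_sizes.sum())

    @property
    def N1(self) -> int:
        """Size of period 1 (patients ``1..N1``)."""
        return int(self.period_sizes[0])

    @property
    def N2(self) -> int:
        """Patients recruited after period 1 (``N - N1``)."""
        return self.N - self.N1

    def period_of(self, j):
        """Period (1-based) of patient index ``j`` (1-based); ``j <= N1`` is period 1."""
        j = np.asarray(j)
        if (j < 1).any() or (j > self.N).any():
            raise ValueError(f"patient index out of range 1..{self.N}")
        out = np.searchsorted(self.boundaries, j, side="left") + 1
        return out if out.ndim else int(out)

    def arms_in_period(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.n[:, s - 1] > 0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TrialDesign(n={self.n.tolist()}, N={self.N})"


def make_design(n: Sequence[Sequence[int]]) -> TrialDesign:
    """Validate an arm x period count matrix and return a :class:`TrialDesign`."""
    return TrialDesign(np.asarray(n))


@dataclass(frozen=True, eq=False)
class AllocationSequence:
    """An ordered assignment of patients ``j = 1..N`` to arms."""

    arms: np.ndarray
    periods: np.ndarray
    method: str
    block_sizes: tuple | None
    n_arms: int
    seed: object = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.arms.size

    def counts(self) -> np.ndarray:
        """Realised per-arm-per-period counts (same shape as the design matrix)."""
        n_periods = int(self.periods.max())
        out = np.zeros((self.n_arms, n_periods), dtype=np.int64)
        for s in range(1, n_periods + 1):
            sel = self.arms[self.periods == s]
            out[:, s - 1] = np.bincount(sel, minlength=self.n_arms)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"j": np.arange(1, len(self) + 1), "period": self.periods, "arm": self.arms}
        )


def _block_period(counts: np.ndarray, block_size: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """Permuted-block labels for one period; the final block is truncated.

    Each full block is a uniformly random permutation of the per-block arm
    composition ``counts * block_size / sum(counts)``; the residual labels
    needed to hit the cell counts exactly form a final, truncated block drawn
    as a random permutation of that residual multiset.
    """
    total = int(counts.sum())
    if block_size < 1:
        raise ValueError(f"block size must be positive (period {s})")
    comp, rem = np.divmod(counts * block_size, total)
    if rem.any():
        raise ValueError(
            f"block size {block_size} incompatible with period {s} allocation ratio "
            f"{counts.tolist()}: per-block composition must be integral"
        )
    n_full = total // block_size
    parts = []
    if n_full:
        labels = np.repeat(np.arange(counts.size), comp)
        tiled = np.tile(labels, (n_full, 1))
        order = np.argsort(rng.random((n_full, block_size)), axis=1)
        parts.append(np.take_along_axis(tiled, order, axis=1).ravel())
    residual = counts - n_full * comp
    if residual.any():
        parts.append(rng.permutation(np.repeat(np.arange(counts.size), residual)))
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def allocate(
    design: TrialDesign,
    method: str = "block",
    block_sizes: int | Sequence[int] | None = None,
    seed: int | np.random.Generator | None = None,
    unconditional: bool = False,
) -> AllocationSequence:
    """Generate a patient-to-arm allocation sequence.

    Parameters
    ----------
    design : TrialDesign
    method : {"block", "simple"}
        ``"block"``: permuted-block randomisation within each period, block
        composition proportional to the period's allocation ratio, final block
        truncated so realised counts equal the design exactly.
        ``"simple"``: random allocation *conditional on the final counts* — a
        uniformly random permutation of the period's arm-label multiset, so the
        cell counts are again exact.  Set ``unconditional=True`` for i.i.d.
        Bernoulli assignment with probabilities ``n[k, s] / N_s`` (realised
        counts then vary; the closed-form estimator algebra assumes fixed
        counts, so this mode exists for sensitivity illustrations only).
    block_sizes : int or sequence of int per period
        Required for ``method="block"``.  Must make the per-block composition
        integral (e.g. a multiple of 4 for 1:1 and of 12 for 2:1:1 allocation).
    seed : int or numpy Generator
        Required; allocations must be reproducible.

    Returns
    -------
    AllocationSequence
    """
    if seed is None:
        raise ValueError("seed is required: allocation sequences must be reproducible")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method not in ("block", "simple"):
        raise ValueError(f"unknown randomisation method {method!r}")

    parts = []
    if method == "block":
        if block_sizes is None:
            raise ValueError("block_sizes is required for block randomisation")
        if np.isscalar(block_sizes):
            bs_list = [int(block_sizes)] * design.n_periods
        else:
            bs_list = [int(b) for b in block_sizes]
            if len(bs_list) != design.n_periods:
                raise ValueError(
                    f"expected {design.n_periods} block sizes, got {len(bs_list)}"
                )
        for s in range(design.n_periods):
            parts.append(_block_period(design.n[:, s], bs_list[s], s + 1, rng))
        block_sizes_out: tuple | None = tuple(bs_list)
    else:
        block_sizes_out = None
        for s in range(design.n_periods):
            counts = design.n[:, s]
            if unconditional:
                total = int(counts.sum())
                parts.append(rng.choice(counts.size, size=total, p=counts / total))
            else:
                parts.append(rng.permutation(np.repeat(np.arange(counts.size), counts)))

    arms = np.concatenate(parts).astype(np.int64)
    periods = np.repeat(np.arange(1, design.n_periods + 1), design.period_sizes)
    return AllocationSequence(
        arms=arms,
        periods=periods,
        method=method,
        block_sizes=block_sizes_out,
        n_arms=design.n_arms,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )
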