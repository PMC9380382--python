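"""Operating-characteristic curves (rejection rate vs trend strength)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_rejection_curves"]


def plot_rejection_curves(oc: pd.DataFrame, x: str = "lambda1",
                          value: str = "reject_rate", alpha: float = 0.025,
                          ax=None):
    """Plot one ``value`` vs ``x`` curve per analysis method.

    ``oc`` is a long-format operating-characteristics table as produced by
    :func:`ncctrends.run_grid`.  A horizontal reference line marks the nominal
    one-sided level ``alpha`` when plotting rejection rates.
    """
    import matplotlib.pyplot as plt

    for col in (x, value, "method"):
        if col not in oc.columns:
            raise ValueError(f"results table has no column {col!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for method, sub in oc.groupby("method"):
        sub = sub.sort_values(x)
        ax.plot(sub[x], sub[value], marker="o", label=method)
    if value == "reject_rate" and alpha is not None:
        ax.axhline(alpha, color="grey", linestyle=":", linewidth=1,
                   label=f"nominal {alpha:g}")
    ax.set_xlabel(x)
    ax.set_ylabel(value)
    ax.legend(fontsize="small")
    return ax
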