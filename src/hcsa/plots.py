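"""Summary figures: group scatter with median/CI bars and before-after plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_stats import median_with_ci


def scatter_with_median_ci(df: pd.DataFrame, metric: str, ax=None):
    """Per-group scatter of one metric with median and 95% CI bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = list(dict.fromkeys(df["group"]))
    rng = np.random.default_rng(0)  # jitter for display only
    for i, g in enumerate(groups):
        y = df.loc[df["group"] == g, metric].to_numpy(dtype=float)
        x = i + rng.uniform(-0.12, 0.12, size=len(y))
        ax.plot(x, y, "o", ms=4, alpha=0.6)
        med, lo, hi = median_with_ci(y)
        ax.hlines(med, i - 0.25, i + 0.25, color="k", lw=2)
        ax.vlines(i, lo, hi, color="k", lw=1.2)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(metric)
    return ax


def before_after(df: pd.DataFrame, col_ed: str, col_es: str, ax=None):
    """Paired ED->ES lines per embryo with group means +/- SEM columns."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ed = df[col_ed].to_numpy(dtype=float)
    es = df[col_es].to_numpy(dtype=float)
    for e, s in zip(ed, es):
        ax.plot([0, 1], [e, s], "-", color="0.6", lw=0.8)
    for i, v in enumerate((ed, es)):
        mean, sem = v.mean(), v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        ax.errorbar([i + 0.15], [mean], yerr=[sem], fmt="s", color="red", capsize=4)
    ax.set_xticks([0, 1], [col_ed, col_es])
    return ax
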