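"""Minimal plot helpers: rg heatmap, MR forest plot, leave-one-out plot."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_rg_heatmap(square: pd.DataFrame, ax=None):
    """Heatmap of a square genetic-correlation matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(square.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(square.columns)), square.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(square.index)), square.index)
    ax.figure.colorbar(im, ax=ax, label="rg")
    return ax


def plot_forest(estimates: pd.DataFrame, ax=None, beta_col: str = "beta",
                se_col: str = "se", label_col: str = "method"):
    """Forest plot of MR estimates with 95% CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.5 * len(estimates) + 1))
    y = np.arange(len(estimates))[::-1]
    beta = estimates[beta_col].to_numpy()
    half = 1.96 * estimates[se_col].to_numpy()
    ax.errorbar(beta, y, xerr=half, fmt="o", color="k", capsize=3)
    ax.axvline(0.0, ls="--", color="grey")
    ax.set_yticks(y, estimates[label_col])
    ax.set_xlabel("causal estimate (beta)")
    return ax


def plot_loo(loo_table: pd.DataFrame, ax=None):
    """Leave-one-out IVW estimates, one row per left-out variant."""
    return plot_forest(loo_table, ax=ax, label_col="snp_left_out")
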