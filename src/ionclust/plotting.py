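"""Matplotlib renderings of population distributions and PCA modes.

Bar charts of the mean number of ions per cluster-size class with
maximum-error bars, paired-system difference panels, and per-size
eigenvector compositions for the leading fluctuation modes.
"""
from __future__ import annotations

import numpy as np

from .pca import PCAResult
from .populations import PopulationDifference, PopulationSummary


def plot_summary(summary: PopulationSummary, ax=None, label: str | None = None):
    """Bar chart of ions per size class with maximum-error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sizes = np.arange(1, summary.s_max + 1)
    ax.bar(sizes, summary.counts, yerr=summary.counts_max_error, capsize=3,
           label=label)
    ax.set_xlabel("cluster size")
    ax.set_ylabel("ions in size class")
    ax.set_xticks(sizes)
    if label:
        ax.legend()
    return ax


def plot_difference(diff: PopulationDifference, ax=None):
    """Bar chart of count differences between two systems, with uncertainties."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sizes = np.arange(1, diff.delta.size + 1)
    colors = ["tab:red" if s else "tab:gray" for s in diff.significant]
    ax.bar(sizes, diff.delta_counts, yerr=diff.uncertainty_counts, capsize=3,
           color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("cluster size")
    ax.set_ylabel("difference in ions per class")
    ax.set_xticks(sizes)
    return ax


def plot_modes(result: PCAResult, k: int = 2, ax=None):
    """Grouped bars of the per-size composition of the first ``k`` eigenvectors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sizes = np.arange(1, result.s_max + 1)
    width = 0.8 / k
    for i in range(k):
        frac = result.variance_fractions[i]
        ax.bar(sizes + (i - (k - 1) / 2) * width, result.eigenvectors[:, i],
               width=width, label=f"mode {i + 1} ({100 * frac:.0f}% var)")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("cluster size")
    ax.set_ylabel("eigenvector component")
    ax.set_xticks(sizes)
    ax.legend()
    return ax
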