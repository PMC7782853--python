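"""Diagnostic plots for networks and candidate rankings."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_candidate_scatter", "plot_degree_distribution", "plot_keystoneness"]


def plot_candidate_scatter(candidates, fisher_p_max: float = 0.05, ax=None):
    """BiBC vs −log10 Fisher p scatter with improver/worsener highlighting.

    The horizontal line marks the significance gate; labelled candidates are
    drawn in color with their node ids annotated.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"improver": "tab:blue", "worsener": "tab:red", "none": "0.6"}
    for c in candidates:
        ax.scatter(c.bibc, c.diff_significance, c=colors[c.label], s=18, zorder=3)
        if c.label != "none":
            ax.annotate(str(c.node_id), (c.bibc, c.diff_significance), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.axhline(-np.log10(fisher_p_max), color="green", lw=0.8, ls="--")
    ax.set_xlabel("BiBC")
    ax.set_ylabel("-log10 Fisher p (ileal WD vs ND)")
    return ax


def plot_degree_distribution(graph, ax=None):
    """Log-log degree-frequency plot with the descriptive power-law fit."""
    import matplotlib.pyplot as plt

    from .netanalysis import fit_power_law

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    degrees = [d for _, d in graph.degree() if d > 0]
    uniq, counts = np.unique(degrees, return_counts=True)
    ax.scatter(uniq, counts, s=20, color="k", zorder=3)
    try:
        slope, r2 = fit_power_law(degrees)
        xs = np.linspace(np.log10(uniq.min()), np.log10(uniq.max()), 50)
        intercept = np.log10(counts[0]) - slope * np.log10(uniq[0])
        ax.plot(10**xs, 10 ** (slope * xs + intercept), color="tab:blue", lw=1,
                label=f"slope {slope:.2f}, r² {r2:.2f}")
        ax.legend(fontsize=8)
    except ValueError:
        pass
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("degree")
    ax.set_ylabel("frequency")
    return ax


def plot_keystoneness(scores, top_n: int = 15, ax=None):
    """Horizontal bar chart of the top scaled keystoneness scores."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    top = scores.sort_values(ascending=False).head(top_n)[::-1]
    ax.barh(range(len(top)), top.to_numpy(), color="tab:green")
    ax.set_yticks(range(len(top)), top.index)
    ax.set_xlabel("scaled keystoneness")
    ax.set_xlim(0, 1)
    return ax
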