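"""Count-table filtering and normalization.

The 16S processing chain used throughout: retain abundant features up to a
cumulative-abundance threshold, normalize counts by cumulative sum scaling
(CSS), optionally rescale by per-sample DNA quantity, then quantile
normalization across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceTable

__all__ = [
    "filter_cumulative_abundance",
    "css_normalize",
    "quantile_normalize",
    "scale_by_dna_quantity",
    "relative_abundance",
    "preprocess_chain",
]


def filter_cumulative_abundance(table: AbundanceTable, threshold: float = 0.99) -> AbundanceTable:
    """Keep the most abundant features reaching ``threshold`` cumulative share.

    Features are ranked by total abundance over all samples (descending,
    ties broken by feature id so the result is deterministic) and the
    shortest prefix whose cumulative share of total abundance is at least
    ``threshold`` is retained. With the default 0.99 this drops features
    contributing to the last 1% of reads — i.e. roughly the <0.01%-abundance
    tail.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    totals = table.data.sum(axis=1)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("table has no signal (all-zero)")
    order = sorted(table.data.index, key=lambda f: (-totals[f], str(f)))
    cum = np.cumsum([totals[f] for f in order]) / grand
    n_keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    kept = [f for f in table.data.index if f in set(order[:n_keep])]
    return table.copy_with(
        table.data.loc[kept], note=f"filter_cumulative_abundance(threshold={threshold})"
    )


def _css_scaling_factor(column: np.ndarray, percentile: float) -> float:
    """Sum of counts up to the lower empirical ``percentile`` of nonzero counts."""
    nz = np.sort(column[column > 0])
    if nz.size == 0:
        raise ValueError("all-zero sample cannot be CSS-normalized")
    # inclusive lower empirical quantile: the ceil(p*m)-th smallest nonzero
    idx = int(np.ceil(percentile * nz.size)) - 1
    idx = max(idx, 0)
    q = nz[idx]
    return float(column[column <= q].sum())


def css_normalize(table: AbundanceTable, percentile: float = 0.5, scale: float = 1000.0) -> AbundanceTable:
    """Cumulative sum scaling normalization.

    Each sample j is divided by s_j, the sum of its counts that do not
    exceed the ``percentile``-th (lower, inclusive) quantile of its nonzero
    counts, then multiplied by ``scale``. Dividing by a low-quantile partial
    sum rather than the total makes the factor robust to a few dominant
    features.
    """
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    values = table.data.to_numpy(dtype=float)
    factors = np.array([_css_scaling_factor(values[:, j], percentile) for j in range(values.shape[1])])
    out = pd.DataFrame(values / factors * scale, index=table.data.index, columns=table.data.columns)
    return table.copy_with(out, note=f"css_normalize(percentile={percentile}, scale={scale})")


def quantile_normalize(table: AbundanceTable) -> AbundanceTable:
    """Force every sample to share the same value distribution.

    Values in each sample are replaced by the across-sample mean of the
    order statistics at the same rank; tied values receive the mean of the
    reference values over their tied rank block.
    """
    values = table.data.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values not allowed")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # tied input values receive the mean reference value of their block
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    result = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return table.copy_with(result, note="quantile_normalize()")


def scale_by_dna_quantity(table: AbundanceTable, dna_quantity: pd.Series | None = None) -> AbundanceTable:
    """Rescale each sample by its DNA quantity relative to the cohort median.

    Interprets "accounting for DNA quantity" as per-sample multiplicative
    scaling by ``dna_j / median(dna)``; this is an interpretation knob, see
    the methods note.
    """
    dna = dna_quantity if dna_quantity is not None else table.dna_quantity
    if dna is None:
        raise ValueError("no DNA quantities supplied")
    dna = dna.loc[list(table.data.columns)]
    if dna.isna().any() or (dna <= 0).any():
        raise ValueError("DNA quantity must be positive for every sample")
    factors = dna / float(dna.median())
    out = table.data * factors
    return table.copy_with(out, note="scale_by_dna_quantity()")


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample to sum to 1."""
    sums = table.data.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("all-zero sample in relative_abundance")
    return table.copy_with(table.data / sums, note="relative_abundance()")


def preprocess_chain(
    table: AbundanceTable,
    filter_threshold: float = 0.99,
    css_percentile: float = 0.5,
    css_scale: float = 1000.0,
    dna_quantity: pd.Series | None = None,
    dna_before_quantile: bool = True,
    quantile: bool = True,
) -> AbundanceTable:
    """Full normalization chain: filter → CSS → (DNA scaling) → quantile.

    Whether DNA scaling precedes quantile normalization is configurable
    (``dna_before_quantile``); the applied order is recorded in the table's
    provenance log.
    """
    out = filter_cumulative_abundance(table, filter_threshold)
    out = css_normalize(out, percentile=css_percentile, scale=css_scale)
    dna = dna_quantity if dna_quantity is not None else table.dna_quantity
    if dna is not None and dna_before_quantile:
        out = scale_by_dna_quantity(out, dna)
    if quantile:
        out = quantile_normalize(out)
    if dna is not None and not dna_before_quantile:
        out = scale_by_dna_quantity(out, dna)
    return out
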