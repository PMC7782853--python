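"""Network interrogation: BiBC, degree, power-law check, candidate ranking.

Bipartite betweenness centrality (BiBC) measures how often a node lies on
shortest paths between two disjoint node sets — here microbes on one side
and host phenotypes (or another omic layer) on the other. High-BiBC nodes
are the bottlenecks through which the microbiota communicates with host
physiology, and combined with the direction of diet-induced abundance
change they nominate "improver" (high BiBC, depleted under western diet)
and "worsener" (high BiBC, enriched) candidates.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiBCResult",
    "CandidateRanking",
    "bipartite_betweenness_centrality",
    "degree",
    "fit_power_law",
    "rank_candidates",
    "combined_degree_bibc_score",
]


@dataclass
class BiBCResult:
    node_id: object
    bibc: float
    set_a_size: int
    set_b_size: int
    normalization: str = "raw"  # "raw" | "pairnormalized"


@dataclass
class CandidateRanking:
    node_id: object
    bibc: float
    diff_significance: float  # -log10 Fisher p of the abundance change
    direction: str  # "decreased" | "increased" | "none"
    label: str  # "improver" | "worsener" | "none"


def _single_source_shortest_paths(adjacency: dict, s):
    """BFS from s: visit order, predecessor lists and path counts sigma."""
    sigma = {v: 0.0 for v in adjacency}
    dist = {v: -1 for v in adjacency}
    preds = {v: [] for v in adjacency}
    sigma[s] = 1.0
    dist[s] = 0
    order = []
    queue = deque([s])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in adjacency[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, preds, sigma


def bipartite_betweenness_centrality(
    graph, set_a, set_b, normalization: str = "raw"
) -> list:
    """BiBC of every node: summed shortest-path fractions over A×B pairs.

    For each pair (s, t) with s in ``set_a`` and t in ``set_b`` and each
    node v not in {s, t}, the contribution is σ_st(v)/σ_st, the fraction of
    shortest s–t paths through v (standard fractional path counting);
    disconnected pairs contribute nothing. Paths are unweighted. With
    ``normalization="pairnormalized"`` the sum is divided by |A|·|B|.

    Implemented as Brandes' accumulation restricted to sources in A and
    targets in B; an exhaustive path-enumeration oracle checks it in tests.
    """
    set_a, set_b = set(set_a), set(set_b)
    if set_a & set_b:
        raise ValueError("set_a and set_b must be disjoint")
    nodes = list(graph.nodes)
    missing = (set_a | set_b) - set(nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(map(str, missing))}")
    adjacency = {v: list(graph.neighbors(v)) for v in nodes}
    score = {v: 0.0 for v in nodes}

    for s in set_a:
        order, preds, sigma = _single_source_shortest_paths(adjacency, s)
        delta = {v: 0.0 for v in nodes}
        for w in reversed(order):
            coeff = (1.0 if (w in set_b and w != s) else 0.0) + delta[w]
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * coeff
        # delta[v] sums sigma_st(v)/sigma_st over targets t in B with v
        # interior to the s-t paths; endpoints never credit themselves
        for v in nodes:
            if v != s:
                score[v] += delta[v]
    denom = len(set_a) * len(set_b) if normalization == "pairnormalized" else 1.0
    if normalization not in ("raw", "pairnormalized"):
        raise ValueError("normalization must be 'raw' or 'pairnormalized'")
    return [
        BiBCResult(
            node_id=v,
            bibc=score[v] / denom if denom else 0.0,
            set_a_size=len(set_a),
            set_b_size=len(set_b),
            normalization=normalization,
        )
        for v in nodes
    ]


def degree(graph) -> dict:
    """Node degree (immediate-neighbor count)."""
    return {v: int(d) for v, d in graph.degree()}


def fit_power_law(degrees) -> tuple:
    """Descriptive log-log OLS fit of the degree distribution.

    Frequencies of each positive degree value are regressed as
    log10(frequency) on log10(degree); returns ``(slope, r2)``. This mirrors
    the straight-line-on-log-axes check, not a maximum-likelihood tail
    estimator.
    """
    vals = np.asarray([d for d in degrees if d > 0], dtype=float)
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct positive degrees")
    res = stats.linregress(np.log10(uniq), np.log10(counts))
    return float(res.slope), float(res.rvalue**2)


def rank_candidates(
    bibc_results,
    diff_results,
    top_n: int = 10,
    fisher_p_max: float = 0.05,
) -> list:
    """Label high-BiBC nodes with significant abundance change.

    Candidates are nodes among the ``top_n`` by BiBC whose diet-induced
    abundance change is significant (combined Fisher p < ``fisher_p_max``):
    decreased under western diet → "improver", increased → "worsener".
    Output is sorted by BiBC descending and carries the scatter coordinates
    (BiBC, −log10 Fisher p).
    """
    diff_by_id = {r.feature_id: r for r in diff_results}
    ranked = sorted(bibc_results, key=lambda r: (-r.bibc, str(r.node_id)))
    top_ids = {r.node_id for r in ranked[:top_n]}
    out = []
    for r in ranked:
        diff = diff_by_id.get(r.node_id)
        if diff is None or not np.isfinite(diff.fisher_p):
            sig, direction = 0.0, "none"
        else:
            sig = float(-np.log10(max(diff.fisher_p, np.finfo(float).tiny)))
            direction = (
                "decreased" if diff.direction < 0 else "increased" if diff.direction > 0 else "none"
            )
        label = "none"
        if (
            r.node_id in top_ids
            and r.bibc > 0
            and diff is not None
            and np.isfinite(diff.fisher_p)
            and diff.fisher_p < fisher_p_max
            and direction != "none"
        ):
            label = "improver" if direction == "decreased" else "worsener"
        out.append(
            CandidateRanking(
                node_id=r.node_id,
                bibc=r.bibc,
                diff_significance=sig,
                direction=direction,
                label=label,
            )
        )
    return out


def combined_degree_bibc_score(graph, set_a, set_b) -> dict:
    """Mean of within-network percentile ranks of degree and BiBC.

    A scale-free combination: 1.0 means top-ranked on both properties.
    Invariant to monotone rescaling of either input.
    """
    deg = degree(graph)
    bibc = {r.node_id: r.bibc for r in bipartite_betweenness_centrality(graph, set_a, set_b)}
    nodes = list(graph.nodes)
    deg_rank = pd.Series({v: deg[v] for v in nodes}).rank(pct=True)
    bibc_rank = pd.Series({v: bibc[v] for v in nodes}).rank(pct=True)
    return {v: float((deg_rank[v] + bibc_rank[v]) / 2.0) for v in nodes}
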