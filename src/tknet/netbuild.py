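"""Transkingdom and multi-omic correlation-network construction.

Edges are Spearman correlations computed within each group of each
replicate experiment and meta-analysed across datasets: retained edges must
have a reproducible sign, pass per-dataset and Fisher-combined p
thresholds, survive BH-FDR applied separately within each edge class, and
satisfy the causality-concordance principle — the correlation sign must
equal the product of the two partners' fold-change directions between
conditions. Cross-omic edges additionally go through a 2-of-3 voting
meta-analysis across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .metastats import bh_fdr, fisher_combine, spearman_matrix

__all__ = [
    "CorrelationRecord",
    "OmicsNetwork",
    "pairwise_spearman_by_group",
    "select_consistent_edges",
    "causality_filter",
    "fold_change_direction",
    "voting_meta",
    "build_tk_network",
    "build_multiomic_network",
]

# default per-class BH-FDR ceilings for the transkingdom network
TK_FDR_DEFAULTS = {
    "within-phenotype": 0.10,
    "within-otu": 0.10,
    "otu-phenotype": 0.10,
}


@dataclass
class CorrelationRecord:
    """One candidate edge: per-dataset Spearman evidence plus meta statistics."""

    node_a: object
    node_b: object
    edge_class: str
    per_dataset_rho: list = field(default_factory=list)
    per_dataset_p: list = field(default_factory=list)
    per_dataset_n: list = field(default_factory=list)
    dataset_names: list = field(default_factory=list)
    fisher_p: float = np.nan
    fdr_q: float = np.nan
    constant_flag: bool = False

    @property
    def sign(self) -> int:
        """Common correlation sign, 0 when inconsistent across datasets."""
        signs = {int(np.sign(r)) for r in self.per_dataset_rho if np.isfinite(r) and r != 0}
        return signs.pop() if len(signs) == 1 else 0

    @property
    def sign_consistent(self) -> bool:
        return self.sign != 0


def pairwise_spearman_by_group(
    tables: dict,
    node_types: dict | None = None,
    min_samples: int = 4,
) -> list:
    """Spearman rho/p for every node pair, per dataset.

    Parameters
    ----------
    tables : dict
        dataset name → features × samples DataFrame (all nodes stacked:
        OTUs, phenotypes, genes ...). Each dataset is typically one group of
        one experiment — groups are never pooled before meta-analysis.
    node_types : dict, optional
        node id → type label used to classify edges (e.g. "microbe",
        "phenotype"); edge classes are "within-<type>" or "<ta>-<tb>"
        with types in sorted order.

    Returns
    -------
    list of CorrelationRecord covering pairs present in every dataset.
    """
    names = sorted(tables)
    if not names:
        raise ValueError("no datasets")
    common = None
    for name in names:
        feats = list(tables[name].index)
        common = feats if common is None else [f for f in common if f in set(feats)]
    if len(common) < 2:
        raise ValueError("fewer than two shared features across datasets")

    per_ds = {}
    for name in names:
        df = tables[name].loc[common]
        if df.shape[1] < min_samples:
            raise ValueError(f"dataset {name!r} has fewer than {min_samples} samples")
        rho, p = spearman_matrix(df.to_numpy(dtype=float).T)
        per_ds[name] = (rho, p, df.shape[1])

    def edge_class(a, b):
        if node_types is None:
            return "all"
        ta, tb = node_types.get(a, "unknown"), node_types.get(b, "unknown")
        if ta == tb:
            return f"within-{ta}"
        return "-".join(sorted((ta, tb)))

    records = []
    n_feat = len(common)
    for i in range(n_feat):
        for j in range(i + 1, n_feat):
            rec = CorrelationRecord(
                node_a=common[i], node_b=common[j], edge_class=edge_class(common[i], common[j])
            )
            for name in names:
                rho, p, n = per_ds[name]
                rec.per_dataset_rho.append(float(rho[i, j]))
                rec.per_dataset_p.append(float(p[i, j]))
                rec.per_dataset_n.append(int(n))
                rec.dataset_names.append(name)
                if not np.isfinite(rho[i, j]):
                    rec.constant_flag = True
            records.append(rec)
    return records


def _fdr_within_classes(records, fdr_max):
    """BH-FDR on Fisher p, separately per edge class; returns survivors."""
    out = []
    by_class = {}
    for rec in records:
        by_class.setdefault(rec.edge_class, []).append(rec)
    for cls, recs in by_class.items():
        qvals = bh_fdr([r.fisher_p for r in recs])
        limit = fdr_max[cls] if isinstance(fdr_max, dict) else fdr_max
        for rec, q in zip(recs, qvals):
            rec.fdr_q = float(q)
            if q < limit:
                out.append(rec)
    return out


def select_consistent_edges(
    records,
    per_dataset_p_max: float = 0.30,
    fisher_max: float = 0.05,
    fdr_max=0.10,
) -> list:
    """Reproducibility filter for candidate edges.

    Keeps records whose correlation sign agrees across all datasets, whose
    two-sided p value is below ``per_dataset_p_max`` in every dataset, whose
    Fisher-combined p is below ``fisher_max``, and which survive BH-FDR
    (applied separately within each edge class; ``fdr_max`` may be a dict
    keyed by class).
    """
    survivors = []
    for rec in records:
        if rec.constant_flag or not rec.sign_consistent:
            continue
        if any(not np.isfinite(p) or p >= per_dataset_p_max for p in rec.per_dataset_p):
            continue
        rec.fisher_p = fisher_combine(np.clip(rec.per_dataset_p, np.finfo(float).tiny, 1.0))
        if rec.fisher_p >= fisher_max:
            continue
        survivors.append(rec)
    return _fdr_within_classes(survivors, fdr_max)


def fold_change_direction(fc) -> int | None:
    """Direction of a fold-change ratio: −1 below 1, +1 above, 0 at 1.

    Ratios of 0 (feature absent under treatment) and +inf (absent in
    control) carry a well-defined direction; NaN/missing does not.
    """
    if fc is None:
        return None
    fc = float(fc)
    if np.isnan(fc) or fc < 0:
        return None
    if fc == 0.0:
        return -1
    if np.isinf(fc):
        return 1
    return int(np.sign(np.log(fc)))


def causality_filter(records, fold_changes: dict) -> list:
    """Keep edges concordant with both partners' fold-change directions.

    An edge passes when sign(correlation) equals sign(log FC_a) ×
    sign(log FC_b) — e.g. two partners both increased under the condition
    must be positively correlated. ``fold_changes`` maps node id to a
    fold-change ratio (direction taken as up for >1, down for <1). Records
    with a missing fold change are excluded with a warning.
    """
    out = []
    for rec in records:
        dir_a = fold_change_direction(fold_changes.get(rec.node_a))
        dir_b = fold_change_direction(fold_changes.get(rec.node_b))
        if dir_a is None or dir_b is None:
            warnings.warn(
                f"edge ({rec.node_a}, {rec.node_b}) dropped: missing fold change",
                stacklevel=2,
            )
            continue
        if dir_a == 0 or dir_b == 0:
            continue
        if rec.sign == dir_a * dir_b:
            out.append(rec)
    return out


def voting_meta(records, p_max: float = 0.10) -> list:
    """Three-dataset voting meta-analysis for cross-omic edges.

    A pair is shortlisted when the correlation sign agrees and p < ``p_max``
    in at least two of the exactly-three datasets. If the third dataset's p
    is over the threshold, the pair is retained and the third dataset is
    dropped from the Fisher combination; if the third dataset is under the
    threshold but its sign disagrees, the pair is removed entirely (all
    three under threshold with one discordant sign is a contradiction, not
    missing evidence). Returns the retained records with ``fisher_p``
    computed over the voting datasets and the dropped dataset removed from
    the record.
    """
    out = []
    for rec in records:
        if len(rec.per_dataset_p) != 3:
            raise ValueError("voting_meta requires exactly 3 datasets per record")
        if rec.constant_flag:
            continue
        p = np.asarray(rec.per_dataset_p, dtype=float)
        signs = np.sign(rec.per_dataset_rho).astype(int)
        under = p < p_max
        candidate_votes = [
            (i, j)
            for i in range(3)
            for j in range(i + 1, 3)
            if under[i] and under[j] and signs[i] == signs[j] != 0
        ]
        if not candidate_votes:
            continue
        if under.all():
            # all three datasets vote: signs must agree unanimously
            if signs[0] == signs[1] == signs[2] != 0:
                rec.fisher_p = fisher_combine(np.clip(p, np.finfo(float).tiny, 1.0))
                out.append(rec)
            continue
        i, j = candidate_votes[0]
        k = 3 - i - j
        # third dataset over threshold: retained, excluded from Fisher
        rec.fisher_p = fisher_combine(np.clip(p[[i, j]], np.finfo(float).tiny, 1.0))
        rec.per_dataset_rho = [rec.per_dataset_rho[i], rec.per_dataset_rho[j]]
        rec.per_dataset_p = [float(p[i]), float(p[j])]
        rec.per_dataset_n = [rec.per_dataset_n[i], rec.per_dataset_n[j]]
        rec.dataset_names = [rec.dataset_names[i], rec.dataset_names[j]]
        out.append(rec)
    return out


class OmicsNetwork:
    """Typed, signed, simple undirected correlation network.

    Thin wrapper around :class:`networkx.Graph`; node attributes carry the
    omic type, fold change and significance flags, edge attributes carry the
    full correlation provenance of the surviving record.
    """

    def __init__(self):
        self.graph = nx.Graph()

    def add_node(self, node_id, node_type: str, **attrs):
        self.graph.add_node(node_id, node_type=node_type, **attrs)

    def add_edge_record(self, rec: CorrelationRecord):
        if rec.node_a == rec.node_b:
            raise ValueError("self-loops are not allowed")
        for n in (rec.node_a, rec.node_b):
            if n not in self.graph:
                raise ValueError(f"endpoint {n!r} not registered as a node")
        self.graph.add_edge(
            rec.node_a,
            rec.node_b,
            sign=rec.sign,
            edge_class=rec.edge_class,
            rho=list(rec.per_dataset_rho),
            p=list(rec.per_dataset_p),
            fisher_p=rec.fisher_p,
            fdr_q=rec.fdr_q,
            datasets=list(rec.dataset_names),
        )

    def nodes_of_type(self, node_type: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("node_type") == node_type]

    # -- audit ------------------------------------------------------------
    def audit(self, thresholds: dict, fold_changes: dict | None = None) -> pd.DataFrame:
        """Re-check every retained edge against its class thresholds.

        ``thresholds`` maps edge class → dict with any of ``per_dataset_p``,
        ``fisher_p``, ``fdr`` ceilings and a ``causality`` flag (the
        concordance rule applies only to the classes whose retention rule
        includes it). Returns one row per edge with pass booleans; the
        network is valid when ``all_ok`` holds everywhere.
        """
        rows = []
        for a, b, d in self.graph.edges(data=True):
            th = thresholds.get(d["edge_class"], {})
            ok_sign = len({int(np.sign(r)) for r in d["rho"] if r != 0}) == 1
            ok_p = all(p < th["per_dataset_p"] for p in d["p"]) if "per_dataset_p" in th else True
            ok_fisher = d["fisher_p"] < th["fisher_p"] if "fisher_p" in th else True
            ok_fdr = d["fdr_q"] < th["fdr"] if "fdr" in th else True
            ok_caus = True
            if th.get("causality") and fold_changes is not None:
                da = fold_change_direction(fold_changes.get(a))
                db = fold_change_direction(fold_changes.get(b))
                if da is not None and db is not None:
                    ok_caus = d["sign"] == da * db
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "edge_class": d["edge_class"],
                    "sign_ok": ok_sign,
                    "per_dataset_p_ok": ok_p,
                    "fisher_ok": ok_fisher,
                    "fdr_ok": ok_fdr,
                    "causality_ok": ok_caus,
                    "all_ok": ok_sign and ok_p and ok_fisher and ok_fdr and ok_caus,
                }
            )
        return pd.DataFrame(rows)

    # -- I/O --------------------------------------------------------------
    def write_graphml(self, path):
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):  # graphml cannot store lists
            d["rho"] = ",".join(f"{x:.6g}" for x in d["rho"])
            d["p"] = ",".join(f"{x:.6g}" for x in d["p"])
            d["datasets"] = ",".join(map(str, d["datasets"]))
        nx.write_graphml(g, path)

    def to_frames(self) -> tuple:
        nodes = pd.DataFrame(
            [{"node_id": n, **d} for n, d in self.graph.nodes(data=True)]
        )
        edges = pd.DataFrame(
            [
                {
                    "node_a": a,
                    "node_b": b,
                    "sign": d["sign"],
                    "edge_class": d["edge_class"],
                    "rho": ";".join(f"{x:.6g}" for x in d["rho"]),
                    "p": ";".join(f"{x:.6g}" for x in d["p"]),
                    "fisher_p": d["fisher_p"],
                    "fdr_q": d["fdr_q"],
                }
                for a, b, d in self.graph.edges(data=True)
            ]
        )
        return nodes, edges

    def write_csvs(self, nodes_path, edges_path):
        nodes, edges = self.to_frames()
        nodes.to_csv(nodes_path, index=False)
        edges.to_csv(edges_path, index=False)


def build_tk_network(
    wd_tables: dict,
    otu_ids,
    phenotype_ids,
    ileal_diff_results,
    fold_changes: dict,
    per_dataset_p_max: float = 0.30,
    fisher_max: float = 0.05,
    fdr_max: dict | None = None,
    ileal_fisher_max: float = 0.05,
) -> OmicsNetwork:
    """Assemble the transkingdom (microbe + phenotype) network.

    Parameters
    ----------
    wd_tables : dict
        (experiment, compartment) → stacked OTU+phenotype features ×
        samples DataFrame for the western-diet group. Compartments are
        "stool4", "stool8" and "ileum8"; two experiments are expected.
    ileal_diff_results : list of MetaTestResult
        Ileum-8wk WD-vs-ND differential abundance results; an OTU needs a
        combined Fisher p below ``ileal_fisher_max`` there before it may
        carry any edge to a phenotype.
    fold_changes : dict
        node id → WD/ND fold-change ratio, for the causality filter and the
        node annotations.

    Notes
    -----
    Within-phenotype and within-OTU edges are established on the stool-4wk
    WD groups of the two experiments (sign-consistent, per-dataset p, Fisher
    and within-class FDR). Microbe-phenotype edges additionally require the
    ileal significance gate, a consistent correlation sign across all
    2 experiments × 3 WD compartments, the same numeric thresholds on the
    stool-4wk datasets, and causality concordance (which, given the sign
    consistency, is a single product-of-directions check per edge).
    """
    fdr_max = dict(TK_FDR_DEFAULTS) if fdr_max is None else fdr_max
    node_types = {**{o: "microbe" for o in otu_ids}, **{p: "phenotype" for p in phenotype_ids}}
    experiments = sorted({e for (e, _) in wd_tables})
    compartments = sorted({c for (_, c) in wd_tables})
    if "stool4" not in compartments:
        raise ValueError("stool4 WD tables are required")

    stool4 = {e: wd_tables[(e, "stool4")] for e in experiments}
    records = pairwise_spearman_by_group(stool4, node_types=node_types)
    for rec in records:  # normalize the cross-type class name
        if rec.edge_class == "microbe-phenotype":
            rec.edge_class = "otu-phenotype"
        elif rec.edge_class == "within-microbe":
            rec.edge_class = "within-otu"
    selected = select_consistent_edges(
        records, per_dataset_p_max=per_dataset_p_max, fisher_max=fisher_max, fdr_max=fdr_max
    )

    # ileal-significance gate for any microbe-phenotype edge
    ileal_ok = {
        r.feature_id
        for r in ileal_diff_results
        if np.isfinite(r.fisher_p) and r.fisher_p < ileal_fisher_max
    }
    ileal_p = {r.feature_id: r.fisher_p for r in ileal_diff_results}

    # sign consistency across every WD group (2 experiments x 3 compartments)
    all_groups = {f"{e}:{c}": wd_tables[(e, c)] for (e, c) in wd_tables}
    all_records = pairwise_spearman_by_group(all_groups, node_types=node_types)
    all_sign = {}
    for rec in all_records:
        key = frozenset((rec.node_a, rec.node_b))
        all_sign[key] = rec.sign if not rec.constant_flag else 0

    final = []
    for rec in selected:
        if rec.edge_class != "otu-phenotype":
            final.append(rec)
            continue
        microbe = rec.node_a if node_types[rec.node_a] == "microbe" else rec.node_b
        if microbe not in ileal_ok:
            continue
        if all_sign.get(frozenset((rec.node_a, rec.node_b)), 0) != rec.sign:
            continue
        final.append(rec)
    # causality concordance in the WD-vs-ND comparison
    cross = [r for r in final if r.edge_class == "otu-phenotype"]
    within = [r for r in final if r.edge_class != "otu-phenotype"]
    cross = causality_filter(cross, fold_changes)

    net = OmicsNetwork()
    for rec in within + cross:
        for n in (rec.node_a, rec.node_b):
            if n not in net.graph:
                net.add_node(
                    n,
                    node_types[n],
                    fold_change=float(fold_changes.get(n, np.nan)),
                    ileal_fisher_p=float(ileal_p.get(n, np.nan)),
                    ileal_significant=bool(n in ileal_ok),
                )
        net.add_edge_record(rec)
    return net


def build_multiomic_network(
    gene_tables: dict,
    lipid_tables: dict,
    cross_tables: dict,
    node_types: dict,
    fold_changes: dict,
    phenotype_network: OmicsNetwork | None = None,
    gene_rules: dict | None = None,
    lipid_rules: dict | None = None,
    cross_rules: dict | None = None,
) -> OmicsNetwork:
    """Assemble the gene + lipid + phenotype multi-omic network.

    Gene-gene edges come from the two treatment-group datasets
    (sign-consistent, per-group p < 30%, Fisher < 5%, FDR 5%, causality);
    lipid-lipid edges from three datasets (sign-consistent, Fisher < 5%,
    FDR 10%, causality); cross-omic edges from three datasets via the voting
    meta-analysis (p < 10% in ≥2, see :func:`voting_meta`) followed by
    FDR < 10% and causality. The phenotype subnetwork, when given, is
    imported unchanged from the transkingdom network.
    """
    gene_rules = gene_rules or {"per_dataset_p": 0.30, "fisher_p": 0.05, "fdr": 0.05}
    lipid_rules = lipid_rules or {"per_dataset_p": 1.0, "fisher_p": 0.05, "fdr": 0.10}
    cross_rules = cross_rules or {"vote_p": 0.10, "fdr": 0.10}

    gene_recs = pairwise_spearman_by_group(gene_tables, node_types=node_types)
    gene_recs = [r for r in gene_recs if r.edge_class == "within-gene"]
    gene_edges = select_consistent_edges(
        gene_recs,
        per_dataset_p_max=gene_rules["per_dataset_p"],
        fisher_max=gene_rules["fisher_p"],
        fdr_max=gene_rules["fdr"],
    )
    gene_edges = causality_filter(gene_edges, fold_changes)

    lipid_recs = pairwise_spearman_by_group(lipid_tables, node_types=node_types)
    lipid_recs = [r for r in lipid_recs if r.edge_class == "within-lipid"]
    lipid_edges = select_consistent_edges(
        lipid_recs,
        per_dataset_p_max=lipid_rules["per_dataset_p"],
        fisher_max=lipid_rules["fisher_p"],
        fdr_max=lipid_rules["fdr"],
    )
    lipid_edges = causality_filter(lipid_edges, fold_changes)

    cross_recs = pairwise_spearman_by_group(cross_tables, node_types=node_types)
    cross_recs = [r for r in cross_recs if r.edge_class not in ("within-gene", "within-lipid")]
    voted = voting_meta(cross_recs, p_max=cross_rules["vote_p"])
    voted = _fdr_within_classes(voted, cross_rules["fdr"])
    cross_edges = causality_filter(voted, fold_changes)

    net = OmicsNetwork()
    for rec in gene_edges + lipid_edges + cross_edges:
        for n in (rec.node_a, rec.node_b):
            if n not in net.graph:
                net.add_node(n, node_types.get(n, "unknown"), fold_change=float(fold_changes.get(n, np.nan)))
        net.add_edge_record(rec)
    if phenotype_network is not None:
        for n, d in phenotype_network.graph.nodes(data=True):
            if d.get("node_type") == "phenotype" and n not in net.graph:
                net.graph.add_node(n, **d)
        for a, b, d in phenotype_network.graph.edges(data=True):
            if d.get("edge_class") == "within-phenotype":
                net.graph.add_edge(a, b, **d)
    return net
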