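"""End-to-end analysis orchestration.

High-level functions chain the stages — simulate → preprocess → diffstats →
transkingdom network → BiBC/candidates → keystoneness → multi-omic network —
on in-memory objects; :func:`run_pipeline` drives them from a validated
YAML-style config and writes per-stage outputs plus a reproducibility
manifest (parameters, seed, checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .keystone import (
    KeystonenessModel,
    keystone_features,
    simulate_keystone_training_data,
)
from .metastats import mann_whitney_meta, meta_results_to_frame
from .netanalysis import (
    bipartite_betweenness_centrality,
    combined_degree_bibc_score,
    fit_power_law,
    rank_candidates,
)
from .netbuild import build_multiomic_network, build_tk_network
from .preprocess import preprocess_chain
from .synthetic import StudyConfig, SyntheticStudy, generate_metabolome, generate_multiomic_layers, generate_study

__all__ = [
    "DEFAULT_PHENOTYPES",
    "preprocess_study",
    "ileal_differential",
    "study_fold_changes",
    "stack_wd_tables",
    "run_tk_analysis",
    "run_keystone_analysis",
    "run_multiomic_analysis",
    "RunConfig",
    "run_pipeline",
]

DEFAULT_PHENOTYPES = (
    "fasting_glucose",
    "fasting_insulin",
    "gtt_120",
    "gtt_auc",
    "epididymal_fat",
    "body_weight",
)


def preprocess_study(
    study: SyntheticStudy,
    filter_threshold: float = 0.99,
    css_percentile: float = 0.5,
    quantile: bool = True,
) -> dict:
    """Normalize every (experiment, compartment) OTU table.

    The cumulative-abundance filter is applied across all samples of an
    experiment (compartments stacked), then each compartment table is
    CSS- and quantile-normalized separately.
    """
    experiments = sorted({e for (e, _) in study.otu_tables})
    out = {}
    for exp in experiments:
        comp_tables = {c: t for (e, c), t in study.otu_tables.items() if e == exp}
        stacked = pd.concat([t.data for t in comp_tables.values()], axis=1)
        totals = stacked.sum(axis=1)
        grand = float(totals.sum())
        order = sorted(stacked.index, key=lambda f: (-totals[f], str(f)))
        cum = np.cumsum([totals[f] for f in order]) / grand
        n_keep = int(np.searchsorted(cum, filter_threshold - 1e-12) + 1)
        kept = set(order[:n_keep])
        for comp, tab in comp_tables.items():
            sub = tab.copy_with(tab.data.loc[[f for f in tab.data.index if f in kept]])
            out[(exp, comp)] = preprocess_chain(
                sub, filter_threshold=1.0, css_percentile=css_percentile, quantile=quantile
            )
    return out


def ileal_differential(tables: dict, groups=("ND", "WD"), rules=None) -> list:
    """WD-vs-ND differential abundance in ileum at 8 weeks, meta over experiments."""
    ileal = {e: t for (e, c), t in tables.items() if c == "ileum8"}
    if not ileal:
        raise ValueError("no ileum8 tables present")
    return mann_whitney_meta(ileal, groups[0], groups[1], rules=rules)


def study_fold_changes(study: SyntheticStudy, tables: dict, phenotypes=DEFAULT_PHENOTYPES) -> dict:
    """WD/ND fold-change ratios (group medians) for OTUs and phenotypes."""
    fc = {}
    ileal = {e: t for (e, c), t in tables.items() if c == "ileum8"}
    feats = None
    for t in ileal.values():
        ids = list(t.data.index)
        feats = ids if feats is None else [f for f in feats if f in set(ids)]
    for feat in feats or []:
        wd, nd = [], []
        for t in ileal.values():
            wd.extend(t.samples_in(group="WD").data.loc[feat])
            nd.extend(t.samples_in(group="ND").data.loc[feat])
        med_nd, med_wd = float(np.median(nd)), float(np.median(wd))
        fc[feat] = np.inf if med_nd == 0 and med_wd > 0 else (
            np.nan if med_nd == 0 else med_wd / med_nd
        )
    meta = study.metadata
    for p in phenotypes:
        wd = study.phenotypes.loc[meta["group"] == "WD", p]
        nd = study.phenotypes.loc[meta["group"] == "ND", p]
        fc[p] = float(np.median(wd) / np.median(nd))
    return fc


def stack_wd_tables(study: SyntheticStudy, tables: dict, phenotypes=DEFAULT_PHENOTYPES) -> dict:
    """Per (experiment, compartment): WD-group OTU + phenotype stacked matrix."""
    out = {}
    for (exp, comp), tab in tables.items():
        sub = tab.samples_in(group="WD")
        mice = [s.rsplit("_", 1)[0] for s in sub.sample_ids]
        ph = study.phenotypes.loc[mice, list(phenotypes)].T.copy()
        ph.columns = sub.sample_ids
        out[(exp, comp)] = pd.concat([sub.data, ph])
    return out


def run_tk_analysis(
    study: SyntheticStudy,
    phenotypes=DEFAULT_PHENOTYPES,
    preprocess: bool = True,
    top_n: int = 10,
    diff_rules: dict | None = None,
    **tk_kwargs,
) -> dict:
    """Full transkingdom stage: preprocess → diffstats → network → BiBC.

    Returns a dict with the normalized tables, differential results, the
    network, per-node BiBC, candidate labels and (when the degree spectrum
    allows) the power-law fit of the degree distribution.
    """
    tables = preprocess_study(study) if preprocess else study.otu_tables
    diff = ileal_differential(tables, rules=diff_rules)
    fc = study_fold_changes(study, tables, phenotypes)
    wd = stack_wd_tables(study, tables, phenotypes)
    otu_ids = sorted({f for (e, c), t in tables.items() for f in t.data.index})
    net = build_tk_network(wd, otu_ids, list(phenotypes), diff, fc, **tk_kwargs)
    microbes = net.nodes_of_type("microbe")
    phen_nodes = net.nodes_of_type("phenotype")
    bibc = bipartite_betweenness_centrality(net.graph, microbes, phen_nodes)
    microbe_bibc = [r for r in bibc if r.node_id in set(microbes)]
    candidates = rank_candidates(microbe_bibc, diff, top_n=top_n)
    degrees = [d for _, d in net.graph.degree()]
    try:
        power_law = fit_power_law(degrees)
    except ValueError:
        power_law = None
    return {
        "tables": tables,
        "diff": diff,
        "fold_changes": fc,
        "network": net,
        "bibc": bibc,
        "microbe_bibc": microbe_bibc,
        "candidates": candidates,
        "power_law": power_law,
    }


def run_keystone_analysis(
    tk: dict,
    n_models: int = 20,
    n_samples: int = 30,
    n_iter: int = 50,
    seed: int = 0,
    target: str = "scaled_keystoneness",
) -> dict:
    """Train the keystoneness predictor on gLV simulations and apply it.

    The six node features are computed for the study's microbes from their
    western-diet abundance samples (all compartments pooled per microbe
    sample-wise), then scored with the linear model trained on simulated
    communities. Returns the fit results and per-OTU scaled keystoneness.
    """
    training = simulate_keystone_training_data(
        n_models=n_models, n_samples=n_samples, n_iter=n_iter, seed=seed
    )
    results = KeystonenessModel.from_dataframe(training, target=target).fit(seed=seed)

    tables = tk["tables"]
    wd_cols = []
    for (exp, comp), tab in tables.items():
        sub = tab.samples_in(group="WD")
        wd_cols.append(sub.data)
    common = None
    for d in wd_cols:
        ids = list(d.index)
        common = ids if common is None else [f for f in common if f in set(ids)]
    stacked = pd.concat([d.loc[common] for d in wd_cols], axis=1)
    feats = keystone_features(stacked.T)
    usable = feats.loc[~feats["constant"]]
    scores = results.predict_scaled(usable) if len(usable) > 1 else np.array([])
    keystoneness = pd.Series(scores, index=usable.index, name="scaled_keystoneness")
    return {
        "training": training,
        "results": results,
        "features": feats,
        "otu_keystoneness": keystoneness,
    }


def run_multiomic_analysis(
    study: SyntheticStudy,
    phenotype_network=None,
    phenotypes=DEFAULT_PHENOTYPES,
    **net_kwargs,
) -> dict:
    """Multi-omic stage on the gene/lipid layers of a ≥3-experiment study.

    The western-diet group of each experiment is one dataset: gene-gene
    edges use the first two, lipid-lipid and cross-omic edges use three
    (the voting meta-analysis requires exactly 3).
    """
    if study.gene_table is None or study.lipid_table is None:
        raise ValueError("study has no gene/lipid layers; run generate_multiomic_layers")
    meta = study.metadata
    experiments = sorted(meta["experiment"].unique())
    if len(experiments) < 3:
        raise ValueError("multi-omic voting needs three experiments/datasets")

    def dataset(exp):
        mice = meta.index[(meta["experiment"] == exp) & (meta["group"] == "WD")]
        genes = study.gene_table.data[list(mice)]
        lipids = study.lipid_table.data[list(mice)]
        phen = study.phenotypes.loc[list(mice), list(phenotypes)].T
        return pd.concat([genes, lipids, phen])

    gene_tables = {e: dataset(e).loc[study.gene_table.feature_ids] for e in experiments[:2]}
    lipid_tables = {e: dataset(e).loc[study.lipid_table.feature_ids] for e in experiments[:3]}
    cross_tables = {e: dataset(e) for e in experiments[:3]}

    node_types = {g: "gene" for g in study.gene_table.feature_ids}
    node_types.update({l: "lipid" for l in study.lipid_table.feature_ids})
    node_types.update({p: "phenotype" for p in phenotypes})

    fc = {}
    for layer in (study.gene_table, study.lipid_table):
        wd_mask = meta["group"] == "WD"
        for feat in layer.feature_ids:
            wd = layer.data.loc[feat, meta.index[wd_mask]]
            nd = layer.data.loc[feat, meta.index[~wd_mask]]
            med_nd = float(np.median(nd))
            fc[feat] = np.nan if med_nd == 0 else float(np.median(wd)) / med_nd
    for p in phenotypes:
        wd = study.phenotypes.loc[meta["group"] == "WD", p]
        nd = study.phenotypes.loc[meta["group"] != "WD", p]
        fc[p] = float(np.median(wd) / np.median(nd))

    net = build_multiomic_network(
        gene_tables,
        lipid_tables,
        cross_tables,
        node_types,
        fc,
        phenotype_network=phenotype_network,
        **net_kwargs,
    )
    genes = net.nodes_of_type("gene")
    others = net.nodes_of_type("lipid") + net.nodes_of_type("phenotype")
    combined = (
        combined_degree_bibc_score(net.graph, genes, others) if genes and others else {}
    )
    return {"network": net, "fold_changes": fc, "combined_score": combined}


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "diffstats", "tknet", "bibc", "keystone", "multiomic")

_KNOWN_KEYS = {
    "stages": None,
    "outdir": None,
    "seed": None,
    "simulate": {
        "n_experiments", "n_per_group", "n_otus", "seq_depth", "n_genes",
        "n_lipids", "n_metabolites", "planted_diet_log_shift", "use_glv_base",
    },
    "preprocess": {"filter_threshold", "css_percentile", "quantile"},
    "diffstats": {"per_exp_p", "fisher_p", "fdr"},
    "tknet": {"per_dataset_p_max", "fisher_max", "ileal_fisher_max"},
    "bibc": {"top_n", "normalization"},
    "keystone": {"n_models", "n_samples", "n_iter"},
    "multiomic": set(),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    stages: list = field(default_factory=lambda: list(STAGES))
    outdir: str = "tknet_run"
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        unknown = set(raw) - set(_KNOWN_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = {}
        for stage, allowed in _KNOWN_KEYS.items():
            if allowed is None or stage not in raw:
                continue
            block = dict(raw[stage] or {})
            bad = set(block) - allowed
            if bad:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(bad)}")
            params[stage] = block
        stages = list(raw.get("stages", STAGES))
        bad_stages = set(stages) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        return cls(
            stages=stages,
            outdir=str(raw.get("outdir", "tknet_run")),
            seed=int(raw.get("seed", 0)),
            params=params,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "parameters": config.params,
    }
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            outputs = _run_stage(stage, config, state, outdir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage: str, config: RunConfig, state: dict, outdir: Path) -> dict:
    p = config.params.get(stage, {})
    outputs = {}
    if stage == "simulate":
        sim = {k: v for k, v in p.items() if k in (
            "n_experiments", "n_per_group", "n_otus", "seq_depth",
            "planted_diet_log_shift", "use_glv_base")}
        study = generate_study(StudyConfig(seed=config.seed, **sim))
        generate_multiomic_layers(
            study, n_genes=p.get("n_genes", 60), n_lipids=p.get("n_lipids", 20)
        )
        study.metabolite_table = generate_metabolome(
            study.config, n_metabolites=p.get("n_metabolites", 50)
        )
        study.write(outdir / "simulated")
        state["study"] = study
        outputs = {
            f.name: f for f in sorted((outdir / "simulated").glob("*")) if f.is_file()
        }
    elif stage == "preprocess":
        tables = preprocess_study(state["study"], **p)
        state["tables"] = tables
        for (exp, comp), tab in tables.items():
            path = outdir / f"normalized_{exp}_{comp}.tsv"
            tab.to_tsv(path)
            outputs[path.name] = path
    elif stage == "diffstats":
        tables = state.get("tables") or preprocess_study(state["study"])
        state["tables"] = tables
        rules = {k: v for k, v in p.items()} or None
        diff = ileal_differential(tables, rules=rules)
        state["diff"] = diff
        path = outdir / "ileal_differential.csv"
        meta_results_to_frame(diff).to_csv(path, index=False)
        outputs[path.name] = path
    elif stage == "tknet":
        study = state["study"]
        tk = run_tk_analysis(study, preprocess=False if "tables" not in state else True, **p)
        if "tables" in state:
            tk["tables"] = state["tables"]
        state["tk"] = tk
        nodes_path, edges_path = outdir / "tk_nodes.csv", outdir / "tk_edges.csv"
        tk["network"].write_csvs(nodes_path, edges_path)
        gml = outdir / "tk_network.graphml"
        tk["network"].write_graphml(gml)
        outputs = {x.name: x for x in (nodes_path, edges_path, gml)}
    elif stage == "bibc":
        tk = state["tk"]
        path = outdir / "bibc_candidates.csv"
        pd.DataFrame(
            [
                {
                    "node_id": c.node_id,
                    "bibc": c.bibc,
                    "neg_log10_fisher_p": c.diff_significance,
                    "direction": c.direction,
                    "label": c.label,
                }
                for c in tk["candidates"]
            ]
        ).to_csv(path, index=False)
        outputs[path.name] = path
    elif stage == "keystone":
        tk = state["tk"]
        ks = run_keystone_analysis(tk, seed=config.seed, **p)
        state["keystone"] = ks
        path = outdir / "otu_keystoneness.csv"
        ks["otu_keystoneness"].to_csv(path)
        model_path = outdir / "keystone_model.json"
        model_path.write_text(json.dumps(ks["results"].to_dict(), indent=2))
        outputs = {path.name: path, model_path.name: model_path}
    elif stage == "multiomic":
        study = state["study"]
        if study.config.n_experiments >= 3:
            mo = run_multiomic_analysis(
                study, phenotype_network=state.get("tk", {}).get("network")
            )
            nodes_path, edges_path = outdir / "multiomic_nodes.csv", outdir / "multiomic_edges.csv"
            mo["network"].write_csvs(nodes_path, edges_path)
            outputs = {nodes_path.name: nodes_path, edges_path.name: edges_path}
        else:  # voting needs 3 datasets; record the skip explicitly
            path = outdir / "multiomic_skipped.txt"
            path.write_text("multiomic stage needs n_experiments >= 3\n")
            outputs[path.name] = path
    return outputs
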