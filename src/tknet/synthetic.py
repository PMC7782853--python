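"""Synthetic study generator with planted ground truth.

Emulates the structure of a two-experiment diet study: {normal diet,
western diet} × n mice per group, with OTU count tables from three gut
compartments (stool at 4 and 8 weeks, ileum at 8 weeks), a metabolic
phenotype panel per mouse (fasting glucose/insulin, a glucose-tolerance
curve, adiposity, body weight), liver gene-expression and lipid layers
driven by a latent liver-health factor, and pooled-serum metabolite tables.

Ground truth is planted so every downstream stage is testable: designated
"improver" OTUs are depleted under western diet and causally lower the
glucose phenotypes (and "worseners" the reverse), designated keystone OTUs
carry strong community interactions in the underlying gLV model, and a
configurable subset of genes couples directly to a phenotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable
from .glv import make_hub_model, simulate_to_steady_state
from .metastats import gtt_auc, homa_b, homa_ir

__all__ = [
    "StudyConfig",
    "PlantedTruth",
    "SyntheticStudy",
    "generate_study",
    "generate_metabolome",
    "generate_multiomic_layers",
]

COMPARTMENTS = ("stool4", "stool8", "ileum8")
GTT_TIMES = (0, 15, 30, 60, 120)

# baseline (normal-diet) phenotype means: fasting glucose mg/dL, fasting
# insulin uU/mL, GTT glucose at 0/15/30/60/120 min, epididymal fat g, body
# weight g — ballpark values for chow-fed male C57BL/6 mice
BASELINE_PHENOTYPES = {
    "fasting_glucose": 150.0,
    "fasting_insulin": 1.5,
    "gtt_0": 150.0,
    "gtt_15": 320.0,
    "gtt_30": 300.0,
    "gtt_60": 240.0,
    "gtt_120": 180.0,
    "epididymal_fat": 0.35,
    "body_weight": 27.0,
}

DEFAULT_DIET_EFFECTS = {
    "fasting_glucose": 25.0,
    "fasting_insulin": 1.0,
    "gtt_0": 25.0,
    "gtt_15": 60.0,
    "gtt_30": 80.0,
    "gtt_60": 80.0,
    "gtt_120": 60.0,
    "epididymal_fat": 0.45,
    "body_weight": 6.0,
}

DEFAULT_NOISE_SD = {
    "fasting_glucose": 8.0,
    "fasting_insulin": 0.25,
    "gtt_0": 8.0,
    "gtt_15": 15.0,
    "gtt_30": 15.0,
    "gtt_60": 12.0,
    "gtt_120": 8.0,
    "epididymal_fat": 0.08,
    "body_weight": 1.2,
}


@dataclass
class StudyConfig:
    """Study design and planted effect sizes; the seed fixes everything."""

    # two replicate experiments; the default group size is set by the
    # correlation stage, whose printed p/FDR thresholds are unattainable at
    # very small n (the minimum two-sided Spearman p at n=5 is 0.017, too
    # coarse to clear a 10% BH-FDR over hundreds of candidate pairs)
    n_experiments: int = 2
    n_per_group: int = 24
    groups: tuple = ("ND", "WD")
    compartments: tuple = COMPARTMENTS
    n_otus: int = 40
    seq_depth: int = 50_000
    # (otu_index, phenotype, effect per unit log relative abundance).
    # OTU indices are abundance ranks of the baseline profile (0 = most
    # abundant): the improver sits among the dominant taxa (its WD depletion
    # is compositionally benign) while the worsener is mid-rank so its WD
    # bloom neither distorts the rest of the community nor saturates its
    # own within-sample rank under quantile normalization.
    planted_improvers: list = field(
        default_factory=lambda: [
            (2, "gtt_120", -35.0),
            (2, "gtt_60", -45.0),
            (2, "fasting_glucose", -12.0),
        ]
    )
    planted_worseners: list = field(
        default_factory=lambda: [
            (20, "gtt_120", 35.0),
            (20, "gtt_30", 45.0),
            (20, "fasting_insulin", 0.5),
        ]
    )
    diet_effects: dict = field(default_factory=lambda: dict(DEFAULT_DIET_EFFECTS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    # log-scale western-diet shift applied to planted OTUs (improvers down,
    # worseners up) in every compartment
    planted_diet_log_shift: float = 2.0
    # per-mouse biological variability of OTU log abundances: latent
    # community factors induce OTU-OTU co-variation (without them the
    # microbe co-occurrence subgraph is empty and no microbe-phenotype path
    # exists), plus an idiosyncratic component shared across compartments
    # and a compartment-specific one
    n_otu_factors: int = 3
    otu_factor_sd: float = 0.6
    otu_idio_sd: float = 0.5
    otu_compartment_sd: float = 0.3
    use_glv_base: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.seq_depth <= 0:
            raise ValueError("seq_depth must be positive")
        for otu, phen, eff in self.planted_improvers + self.planted_worseners:
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
            if not 0 <= otu < self.n_otus:
                raise ValueError(f"planted effect on unknown OTU index {otu}")
            if phen not in BASELINE_PHENOTYPES:
                raise ValueError(f"unknown phenotype {phen!r}")

    @property
    def causal_effects(self) -> list:
        return [(o, p, e) for (o, p, e) in self.planted_improvers] + [
            (o, p, e) for (o, p, e) in self.planted_worseners
        ]


@dataclass
class PlantedTruth:
    """What was planted: causal OTUs, keystone OTUs, the latent health factor."""

    causal_otus: dict  # otu id -> list of (phenotype, effect)
    improver_otus: list
    worsener_otus: list
    keystone_otus: list
    latent_health: pd.Series  # per-mouse scalar driving gene/lipid layers

    def to_json(self, path):
        payload = {
            "causal_otus": {str(k): v for k, v in self.causal_otus.items()},
            "improver_otus": self.improver_otus,
            "worsener_otus": self.worsener_otus,
            "keystone_otus": self.keystone_otus,
            "latent_health": {k: float(v) for k, v in self.latent_health.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SyntheticStudy:
    config: StudyConfig
    otu_tables: dict  # (experiment, compartment) -> AbundanceTable (counts)
    phenotypes: pd.DataFrame  # per-mouse panel incl. derived HOMA/AUC
    metadata: pd.DataFrame  # per-mouse experiment/group
    truth: PlantedTruth
    gene_table: AbundanceTable | None = None
    lipid_table: AbundanceTable | None = None
    metabolite_table: AbundanceTable | None = None

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (exp, comp), tab in self.otu_tables.items():
            tab.to_tsv(outdir / f"otu_{exp}_{comp}.tsv")
        self.phenotypes.to_csv(outdir / "phenotypes.csv")
        meta = self.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(outdir / "metadata.csv")
        if self.gene_table is not None:
            self.gene_table.to_tsv(outdir / "genes.tsv")
        if self.lipid_table is not None:
            self.lipid_table.to_tsv(outdir / "lipids.tsv")
        if self.metabolite_table is not None:
            self.metabolite_table.to_tsv(outdir / "metabolites.tsv")
        self.truth.to_json(outdir / "truth.json")


def _base_abundance_profile(config: StudyConfig, rng) -> tuple:
    """Long-tailed baseline relative abundances, and the keystone ids.

    By default the profile is a gLV steady state of a community with an
    engineered strongly-interacting hub, so keystone ground truth is
    meaningful; a plain lognormal fallback exists for speed.
    """
    S = config.n_otus
    if config.use_glv_base:
        model = make_hub_model(S=S, rng=rng, hub_strength=0.008)
        x0 = rng.uniform(0.2, 1.0, size=S) * model.K
        x, ok, bad = simulate_to_steady_state(model.r, model.K, model.A, x0)
        if not ok or bad:  # pragma: no cover - hub model is stable by design
            raise RuntimeError("baseline community failed to converge")
        base = np.maximum(x, 1e-3)
        keystones = [0]
    else:
        base = rng.lognormal(mean=0.0, sigma=1.5, size=S)
        keystones = []
    # relabel species by descending baseline abundance so that OTU indices
    # are abundance ranks (planted indices then have guaranteed read mass)
    order = np.argsort(-base, kind="stable")
    base = base[order]
    rank_of = np.empty(S, dtype=int)
    rank_of[order] = np.arange(S)
    keystones = [int(rank_of[k]) for k in keystones]
    base = base / base.sum()
    return base, keystones


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the full synthetic study from a config (seed-deterministic).

    OTU relative abundances start from a common long-tailed baseline
    profile (gLV steady state), receive per-mouse lognormal biological
    variation (one component shared across compartments, one
    compartment-specific), and planted OTUs are shifted down (improvers) or
    up (worseners) on the log scale in western-diet mice. Counts are
    multinomial at the configured sequencing depth. Phenotypes are baseline
    + diet effect + Σ effect × log relative abundance of the causal OTU
    (ileal, standardized) + Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    base, keystones = _base_abundance_profile(config, rng)
    S = config.n_otus
    otu_ids = [f"OTU{i:03d}" for i in range(S)]

    mice = []
    metadata_rows = []
    for e in range(1, config.n_experiments + 1):
        for group in config.groups:
            for m in range(1, config.n_per_group + 1):
                mouse_id = f"exp{e}_{group}_m{m}"
                mice.append((mouse_id, f"exp{e}", group))
                metadata_rows.append(
                    {"sample_id": mouse_id, "experiment": f"exp{e}", "group": group}
                )
    metadata = pd.DataFrame(metadata_rows).set_index("sample_id")

    # per-mouse log-scale biological variation, shared across compartments:
    # latent community factors (OTU-OTU co-variation) + idiosyncratic noise
    factor_loadings = rng.normal(0.0, config.otu_factor_sd, size=(S, config.n_otu_factors))
    factor_scores = rng.normal(0.0, 1.0, size=(len(mice), config.n_otu_factors))
    shared = factor_scores @ factor_loadings.T + rng.normal(
        0.0, config.otu_idio_sd, size=(len(mice), S)
    )
    # total shared-component SD per OTU, for standardizing causal effects
    shared_sd = np.sqrt((factor_loadings**2).sum(axis=1) + config.otu_idio_sd**2)

    causal = {}
    for otu, phen, eff in config.causal_effects:
        causal.setdefault(otu, []).append((phen, float(eff)))
    improvers = sorted({o for (o, _, _) in config.planted_improvers})
    worseners = sorted({o for (o, _, _) in config.planted_worseners})

    otu_tables = {}
    log_rel_ileum = {}
    for comp in config.compartments:
        cols = {}
        for mi, (mouse_id, exp, group) in enumerate(mice):
            logab = np.log(base) + shared[mi] + rng.normal(
                0.0, config.otu_compartment_sd, size=S
            )
            if group == config.groups[1]:  # western diet
                for o in improvers:
                    logab[o] -= config.planted_diet_log_shift
                for o in worseners:
                    logab[o] += config.planted_diet_log_shift
            rel = np.exp(logab)
            rel = rel / rel.sum()
            counts = rng.multinomial(config.seq_depth, rel)
            cols[mouse_id] = counts
            if comp == "ileum8":
                log_rel_ileum[mouse_id] = np.log(np.maximum(rel, 1e-12))
        frame = pd.DataFrame(cols, index=otu_ids)
        for e in range(1, config.n_experiments + 1):
            exp = f"exp{e}"
            sub_cols = [m for (m, ex, _) in mice if ex == exp]
            meta = metadata.loc[sub_cols].copy()
            meta["compartment"] = comp
            meta["timepoint"] = "4wk" if comp == "stool4" else "8wk"
            meta.index = [f"{c}_{comp}" for c in sub_cols]
            data = frame[sub_cols].copy()
            data.columns = list(meta.index)
            otu_tables[(exp, comp)] = AbundanceTable(data=data, metadata=meta)

    # phenotypes: baseline + diet + causal OTU contributions + noise
    phen_names = list(BASELINE_PHENOTYPES)
    phen_rows = {}
    for mi, (mouse_id, exp, group) in enumerate(mice):
        row = {}
        for phen in phen_names:
            value = BASELINE_PHENOTYPES[phen]
            if group == config.groups[1]:
                value += config.diet_effects.get(phen, 0.0)
            for otu, effects in causal.items():
                for p_name, eff in effects:
                    if p_name == phen:
                        # standardized log abundance so the stated effect is
                        # "per unit log-abundance"
                        z = (
                            log_rel_ileum[mouse_id][otu] - np.log(base[otu])
                        ) / max(shared_sd[otu], 1e-9)
                        value += eff * z
            value += rng.normal(0.0, config.noise_sd.get(phen, 0.0))
            row[phen] = max(value, 1.0)
        phen_rows[mouse_id] = row
    phenotypes = pd.DataFrame(phen_rows).T
    phenotypes["gtt_auc"] = [
        gtt_auc([phenotypes.loc[m, f"gtt_{t}"] for t in GTT_TIMES], GTT_TIMES)
        for m in phenotypes.index
    ]
    phenotypes["homa_ir"] = [
        homa_ir(g, i)
        for g, i in zip(phenotypes["fasting_glucose"], phenotypes["fasting_insulin"])
    ]
    phenotypes["homa_b"] = [
        homa_b(g, i) if g > 63 else np.nan
        for g, i in zip(phenotypes["fasting_glucose"], phenotypes["fasting_insulin"])
    ]

    # latent liver-health factor: high metabolic burden = low health
    burden = (
        phenotypes["gtt_120"] - phenotypes["gtt_120"].mean()
    ) / phenotypes["gtt_120"].std(ddof=0)
    latent_health = -burden + rng.normal(0.0, 0.3, size=len(burden))
    latent_health = pd.Series(latent_health.to_numpy(), index=phenotypes.index)

    truth = PlantedTruth(
        causal_otus={otu_ids[o]: effs for o, effs in causal.items()},
        improver_otus=[otu_ids[o] for o in improvers],
        worsener_otus=[otu_ids[o] for o in worseners],
        keystone_otus=[otu_ids[k] for k in keystones],
        latent_health=latent_health,
    )
    return SyntheticStudy(
        config=config,
        otu_tables=otu_tables,
        phenotypes=phenotypes,
        metadata=metadata,
        truth=truth,
    )


def generate_metabolome(
    config: StudyConfig,
    n_metabolites: int = 133,
    zero_fraction: float = 0.1,
    tech_sd: float = 0.135,
    planted_log2_effect: float = 0.0,
    n_planted: int = 0,
    seed: int | None = None,
) -> AbundanceTable:
    """Pooled-serum metabolite intensities: one pool per group per experiment.

    Intensities are lognormal per metabolite with multiplicative technical
    noise of relative SD ``tech_sd``/1.02 (the internal-standard scale);
    entries are zeroed independently with probability ``zero_fraction``
    (so ⌊zero_fraction·n⌋ zeros per sample on average). The first
    ``n_planted`` metabolites get a ``planted_log2_effect`` shift in the
    treated/second group's pools.
    """
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    met_ids = [f"MET{i:03d}" for i in range(n_metabolites)]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_metabolites)
    cols = {}
    meta_rows = []
    rel_sd = tech_sd / 1.02
    for e in range(1, config.n_experiments + 1):
        for group in config.groups:
            pool_id = f"exp{e}_{group}_pool"
            vals = base.copy()
            if group == config.groups[1] and n_planted:
                vals[:n_planted] *= 2.0 ** planted_log2_effect
            if rel_sd > 0:
                sigma2 = np.log(1 + rel_sd**2)
                # multiplicative noise with unit mean and relative SD rel_sd
                vals = vals * rng.lognormal(
                    mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n_metabolites
                )
            if zero_fraction > 0:
                vals[rng.random(n_metabolites) < zero_fraction] = 0.0
            cols[pool_id] = vals
            meta_rows.append(
                {
                    "sample_id": pool_id,
                    "experiment": f"exp{e}",
                    "group": group,
                    "compartment": "serum",
                    "timepoint": "8wk",
                }
            )
    data = pd.DataFrame(cols, index=met_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return AbundanceTable(data=data, metadata=metadata)


def generate_multiomic_layers(
    study: SyntheticStudy,
    n_genes: int = 150,
    n_lipids: int = 30,
    loading_sd: float = 1.0,
    noise_sd: float = 1.0,
    n_coupled_genes: int = 2,
    coupled_phenotype: str = "gtt_120",
    coupling_strength: float = 1.5,
    seed: int | None = None,
) -> tuple:
    """Gene and lipid layers driven by the latent liver-health factor.

    Each feature is ``loading × latent_health + noise`` with loadings drawn
    N(0, ``loading_sd``²); with ``loading_sd=0`` the layers are pure noise
    (a null configuration for FDR calibration). The first
    ``n_coupled_genes`` genes additionally couple directly to the
    standardized ``coupled_phenotype`` (planted high-BiBC genes). Values are
    shifted to be non-negative expression-like intensities.
    """
    rng = np.random.default_rng(study.config.seed + 1 if seed is None else seed)
    h = study.truth.latent_health
    mice = list(h.index)
    phen = study.phenotypes.loc[mice, coupled_phenotype]
    phen_z = (phen - phen.mean()) / phen.std(ddof=0)

    def layer(n_features, prefix):
        loadings = rng.normal(0.0, loading_sd, size=n_features)
        vals = np.outer(loadings, h.to_numpy()) + rng.normal(
            0.0, noise_sd, size=(n_features, len(mice))
        )
        return loadings, vals

    g_load, g_vals = layer(n_genes, "G")
    for gi in range(min(n_coupled_genes, n_genes)):
        g_vals[gi] += coupling_strength * phen_z.to_numpy()
    l_load, l_vals = layer(n_lipids, "L")

    offset_g = g_vals.min() if g_vals.size else 0.0
    offset_l = l_vals.min() if l_vals.size else 0.0
    gene_ids = [f"GENE{i:03d}" for i in range(n_genes)]
    lipid_ids = [f"LIPID{i:03d}" for i in range(n_lipids)]
    meta = study.metadata.loc[mice].copy()
    meta["compartment"] = "liver"
    meta["timepoint"] = "8wk"
    gene_table = AbundanceTable(
        data=pd.DataFrame(g_vals - offset_g + 1.0, index=gene_ids, columns=mice),
        metadata=meta,
    )
    lipid_table = AbundanceTable(
        data=pd.DataFrame(l_vals - offset_l + 1.0, index=lipid_ids, columns=mice),
        metadata=meta.copy(),
    )
    study.gene_table = gene_table
    study.lipid_table = lipid_table
    return gene_table, lipid_table
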