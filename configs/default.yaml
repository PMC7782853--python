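# Default end-to-end pipeline configuration.
# Every numeric rule threshold used by the analysis appears here by name so
# the full rule set is visible in one file.

seed: 0
outdir: tknet_run
stages: [simulate, preprocess, diffstats, tknet, bibc, keystone, multiomic]

simulate:
  n_experiments: 3        # >=3 enables the multi-omic voting stage
  n_per_group: 24
  n_otus: 40
  seq_depth: 50000
  n_genes: 60
  n_lipids: 20
  n_metabolites: 50

preprocess:
  filter_threshold: 0.99  # cumulative-abundance feature retention
  css_percentile: 0.5     # CSS scaling quantile (lower, inclusive)
  quantile: true          # quantile normalization after CSS

diffstats:                # diet differential rule set
  per_exp_p: 0.20         # two-tail Mann-Whitney p per experiment
  fisher_p: 0.05          # combined Fisher p across experiments
  fdr: 0.10               # BH-FDR across features

tknet:                    # transkingdom edge retention
  per_dataset_p_max: 0.30 # correlation p within each experiment
  fisher_max: 0.05        # combined Fisher p
  ileal_fisher_max: 0.05  # ileal-significance gate for microbe-phenotype edges
  # within-class BH-FDR ceilings default to 10% per edge class
  # (within-phenotype, within-otu, otu-phenotype)

bibc:
  top_n: 10               # candidate pool size by BiBC rank
  normalization: raw      # or pairnormalized (divide by |A|x|B|)

keystone:                 # gLV training-simulation size
  n_models: 20
  n_samples: 30
  n_iter: 50
  # feature network: Spearman edges at BH-adjusted p < 0.05;
  # train/test split 70/30 by community model

multiomic: {}
  # gene subnetwork: per-group p < 0.30, Fisher < 0.05, FDR < 0.05, causality
  # lipid subnetwork: Fisher < 0.05, FDR < 0.10, causality
  # cross-omic: voting p < 0.10 in >=2 of 3 datasets, FDR < 0.10, causality
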