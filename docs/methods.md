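# Methods

This note records the models, rules and numerical choices behind `tknet`,
and what the synthetic-data experiments do and do not demonstrate.

## Normalization chain for count tables

OTU count tables pass through, in order:

1. **Cumulative-abundance filter** (default 0.99): features ranked by total
   abundance across all samples of an experiment; the shortest prefix
   reaching 99% of total reads is retained (ties broken by feature id).
   This removes the ~<0.01%-abundance tail.
2. **Cumulative sum scaling (CSS)**: each sample is divided by the sum of
   its counts up to the 0.5 quantile of its nonzero counts, times 1000.
   The quantile is the *inclusive lower empirical quantile* — for nonzero
   counts (1,2,3,4) the 0.5-quantile is 2 and the scaling sum is 3. The
   adaptive quantile selection of the original CSS method is replaced by a
   fixed default with a knob, keeping the stage auditable.
3. **DNA-quantity scaling** (optional): per-sample multiplication by
   `dna_j / median(dna)`. "Accounting for DNA quantity" is interpreted as
   this multiplicative correction; whether it runs before or after quantile
   normalization is configurable, and the applied order is recorded in the
   table's provenance log.
4. **Quantile normalization**: each sample's values are replaced by the
   across-sample means of order statistics at the same rank; ties receive
   the mean over their tied block. Idempotent by construction.

Quantile normalization equalizes within-sample distributions, so a feature
that is always, say, the second most abundant in every sample becomes
nearly constant across samples. This matters for generator design (below).

## Meta-analysis statistics

- **Differential abundance** (diet comparisons): two-tailed Mann-Whitney U
  per experiment (exact null for per-group n ≤ 8 without ties, normal
  approximation with tie correction otherwise), Fisher's method across
  experiments (χ² with 2k df) *only* when per-experiment directions agree,
  then Benjamini-Hochberg FDR across features. Default rule set:
  per-experiment p < 0.2, combined p < 0.05, FDR < 10%. Fold changes are
  ratios of group medians.
- **Differential expression** (supplementation comparisons): Welch t per
  treatment-vs-control comparison (pooled-variance optional), same-direction
  requirement across treatments, Fisher < 5%, FDR < 10%, per-comparison
  p < 5%.
- **Metabolites**: zeros are imputed per metabolite as
  `max(min nonzero − 3×0.135, ε)`; 0.135 is the technical SD on the
  internal-standard intensity scale (standard mean 1.02). The pooled-serum
  test is a one-sample two-sided t of log2 treated/control ratios against 0
  with BH-FDR; a one-sided option exists for pre-directed hypotheses.
- **Human-cohort correlation**: Spearman rho with a one-tailed p in a
  supplied expected direction, after excluding samples below a
  reads-per-million floor.

## Network construction rules

Spearman correlations are computed within each group of each experiment;
groups are never pooled across experiments before meta-analysis. All p
values for correlations use the t approximation with n−2 df; constant
features are flagged and cannot form edges.

**Transkingdom (microbe + phenotype) network.** Within-phenotype and
within-OTU edges: sign-consistent across the two stool-4wk western-diet
datasets, per-dataset p < 30%, Fisher < 5%, BH-FDR < 10% computed
*separately per edge class*. Microbe-phenotype edges additionally require:
(a) the microbe's ileal 8-wk diet change significant at combined Fisher
p < 0.05; (b) a consistent correlation sign across all six western-diet
datasets (2 experiments × 3 compartments); (c) causality concordance —
sign(correlation) = sign(log FC of partner 1) × sign(log FC of partner 2)
in the diet comparison. The numeric thresholds for the microbe-phenotype
class reuse the within-class values, since only the qualitative conditions
are prescribed for that class; this is exposed in configuration. Because
the sign is consistent across compartments, one concordance check per edge
is equivalent to checking it in each compartment.

**Multi-omic network.** Gene-gene edges from two treatment datasets
(per-dataset p < 30%, Fisher < 5%, FDR 5%, causality); lipid-lipid edges
from three datasets (sign-consistent, Fisher < 5%, FDR 10%, causality);
cross-omic edges from three datasets via the voting rule — shortlist when
the sign agrees and p < 10% in at least two datasets; if the third dataset
is over the threshold it is dropped from the Fisher combination; if it is
under the threshold with a discordant sign the pair is removed entirely —
followed by FDR < 10% and causality. An `audit()` pass re-checks every
retained edge against its class thresholds (causality applies only to the
classes whose retention rule includes it).

**BiBC.** Bipartite betweenness centrality of node v for sets A, B:
Σ over pairs (s∈A, t∈B) of σ_st(v)/σ_st, with σ the number of unweighted
shortest paths and fractional counting over ties (standard betweenness
semantics); disconnected pairs contribute 0; v never scores pairs in which
it is an endpoint. Implemented as Brandes accumulation restricted to B as
targets; tests check exhaustive path enumeration on the full connected
graph atlas up to 7 nodes plus random 8-node graphs. Correlation magnitude
is deliberately not used as a path weight. Candidate labels: among the
top-10 BiBC microbes (with positive BiBC), significant ileal change with
decreased abundance under western diet → "improver"; increased →
"worsener". The degree/BiBC combined score is the mean of the two
within-network percentile ranks — scale-free and invariant to monotone
rescaling.

The power-law check on the degree distribution is a descriptive OLS of
log10 frequency on log10 degree, reproducing the straight-line-on-log-axes
semantics, not a maximum-likelihood tail estimate.

## Generalized Lotka-Volterra simulation

Dynamics: `dx_i/dt = r_i x_i (1 − x_i/K_i) + x_i Σ_{j≠i} A_ij x_j` —
logistic self-limitation with explicit carrying capacity plus additive
pairwise interactions, zero diagonal. A "seqtime-style" parameterization
(self-limitation inside A) is not used; the explicit-K form keeps r and K
independently interpretable over their sampled ranges.

Model ensembles draw, per community model: species count n ∈ [10, 100],
pool similarity s ∈ [0.4, 0.95] (pool size P = n(1+s)/(2s), which makes the
expected Jaccard overlap of two random n-subsets equal s), interaction
connectivity c ∈ [0.005, 0.7], negative-edge percentage ∈ [0, 100], growth
rates r ∈ (0, 1] (floored at 0.05) and carrying capacities K ∈ (0, 100]
(floored at 1) — the floors avoid degenerate timescales and capacities —
and a topology, uniform-random or Klemm-Eguíluz with equal probability.
The Klemm-Eguíluz generator grows from an m₀-clique of active nodes with
inverse-degree deactivation and rewiring probability μ = 0.1; m₀ is derived
from the target connectivity (m₀ ≈ c(S−1)/2).

Interaction magnitudes are uniform on (0, a_max] with a_max set so the
expected interaction pressure on a species is half its mean self-limitation
slope (`interaction_gamma = 0.5`): strong enough that removals propagate,
weak enough that most random communities stabilize. Stronger coupling
regimes (γ = 1, 2) destabilize the ensembles and were rejected.

**Integration.** A batched, clipped forward-Euler fixed-point solver
advances thousands of initial conditions simultaneously (dt = 0.2,
t_max = 400, convergence when max|dx/dt| < 10⁻⁴·max x per column, species
below 10⁻⁴ clamped extinct, divergent columns flagged and discarded).
Fixed points of the discretized map are equilibria of the ODE, so the step
size affects only the transient; steady states are verified in tests
against closed forms (logistic, 2-species interior equilibrium) and against
an adaptive high-order ODE solver on random communities. The batched form
is what makes the removal experiment (every species × 50 initial
conditions in one matrix) tractable on one CPU.

**Keystoneness.** For each species of a converged reference community:
pin it at zero (an absorbing state), re-integrate from a fresh uniform
random initial condition, and take the Canberra distance
Σ|x−y|/(x+y) (0/0 := 0) between the original and post-removal steady
states over the *surviving* species' coordinates; average over the
iterations (the removed species' own coordinate is excluded so the score
measures impact on others; an inclusive mode exists behind a flag). The
random initial conditions are the source of stochasticity across
iterations. Raw scores are min-max scaled to [0, 1] within each evaluated
community.

**The keystoneness regression target is the scaled score.** Raw mean
Canberra distances grow with community size, so pooling communities of
10–100 species puts most of the variance in a scale component that node
features cannot (and should not) explain; out-of-community skill on the raw
target is near zero. The scaled score is the quantity the pipeline
ultimately reports for real communities as well, so the model is trained on
it.

**Features and model.** Per species, from the steady-state abundance
samples: mean relative abundance; and from a Spearman co-occurrence network
(edges at BH-adjusted p < 0.05): sum of |rho| over incident edges, degree,
relative closeness centrality (within-component closeness with
Wasserman-Faust scaling by component size; 0 for isolated nodes),
unnormalized betweenness centrality, and eccentricity within the component
(isolated nodes take the sentinel N). OLS with intercept on a 70/30
train/test split that assigns *whole community models* to one side, so the
reported skill is out-of-community. Test skill is the adjusted R² of the
linear fit of true on predicted keystoneness
(1 − (1−R²)(n−1)/(n−2)). At the scaled-down ensemble size used here —
50 models × 30 samples × 50 removal iterations, versus 542 × 100 × 1000 in
the full design — the multi-seed mean lands around 0.24–0.30 (individual
splits range roughly 0.05–0.47), below the full-size figure of ~0.42. Two
scale effects drive the gap: co-occurrence features estimated from 30
samples instead of 100 are substantially noisier, and with whole community
models assigned to one side of the split, ~35 training communities carry
the six coefficients. Doubling the ensemble to 100 models moves the mean
only from ≈0.24 to ≈0.26 at twice the runtime, so the smaller size is
kept.

## Synthetic study generator

The generator emulates a two-experiment diet study: {normal, western}
diet × 24 mice per group per experiment, OTU counts for stool-4wk,
stool-8wk and ileum-8wk, a phenotype panel (fasting glucose and insulin,
GTT glucose at 0/15/30/60/120 min with trapezoidal AUC, HOMA-IR, HOMA-B,
epididymal fat, body weight), gene/lipid layers and pooled-serum
metabolites (one pool per group per experiment; lognormal intensities with
multiplicative technical noise of relative SD 0.135/1.02 and configurable
zero fraction).

Key design choices, all made for recoverability of planted truth and
documented as such:

- **Baseline community**: a gLV steady state with an engineered
  strongly-interacting hub (so keystone ground truth is meaningful; a plain
  lognormal fallback exists). Species are relabelled by descending baseline
  abundance, so OTU indices are abundance ranks and planted indices always
  carry read mass through the 99% filter.
- **OTU co-variation**: per-mouse log abundances carry three latent
  community factors (loading SD 0.6) plus idiosyncratic (SD 0.5, shared
  across compartments) and compartment-specific (SD 0.3) noise. The factors
  are essential: with independent per-OTU noise the microbe co-occurrence
  subgraph is empty and no microbe-phenotype path exists, making every BiBC
  exactly zero.
- **Planted causal OTUs**: the improver sits at abundance rank 2 (its
  western-diet depletion, e⁻² ≈ 0.14×, is compositionally benign) and the
  worsener at rank 20 (its e² bloom neither distorts the rest of the
  community nor pins its own within-sample rank, which quantile
  normalization would otherwise flatten). Each drives three phenotypes with
  effects of roughly 35–45 mg/dL (or 0.5 µU/mL insulin) per standardized
  log-abundance unit, against phenotype noise SDs of 8–15.
- **Group size**: 24 mice per group per experiment. The husbandry design
  being emulated uses ~5 per group, but the correlation stage of the
  original analysis pooled 35 western-diet mice per experiment, and the
  printed thresholds are unattainable at n=5: the smallest achievable
  two-sided Spearman p at n=5 is ≈0.017, while surviving a 10% BH-FDR over
  ~240 candidate microbe-phenotype pairs needs combined p ≲ 0.002.
- **Phenotype model**: baseline + diet shift + Σ effect × standardized log
  ileal relative abundance of each causal OTU + Gaussian noise — linear in
  log abundance, the simplest structure satisfying the sign-concordance
  assumptions the causality filter tests.
- **Counts**: multinomial at fixed depth 50,000 (a Dirichlet-multinomial
  overdispersion knob is deliberately out of scope); gene/lipid layers are
  `loading × latent health + noise` with the latent health factor defined
  as the negated standardized 120-min glucose plus noise.

What passing tests show: the pipeline recovers *planted* signal of the
stated effect sizes under the stated noise at these sample sizes, and its
false-discovery behaviour under the null matches its configured budgets.
What they do not show: performance on real 16S data with compositional
artifacts, sequencing batch effects, sparsity and taxon correlations
unlike the factor model — none of which the generator emulates (read-level
simulation, PCR/chimera artifacts and within-mouse longitudinal
autocorrelation are explicit non-goals).

## Degenerate inputs and conventions

- All-tied group comparisons: p = 1, direction 0, flagged.
- Sign-inconsistent records: Fisher p undefined (NaN), excluded from FDR.
- Fold-change ratios of 0 and ∞ carry direction (−/+); NaN excludes the
  edge with a warning.
- Prediction min-max scaling of a constant or singleton set returns 0.5
  with a warning.
- p values of exactly 0 are floored at the smallest positive float before
  Fisher combination.
- Seeds: every stochastic routine takes a seed or Generator; a pipeline run
  is reproducible byte-for-byte from its config and seed (checksums in the
  run manifest).

## Scaled problem sizes

Defaults used by the test suite and the acceptance script: 50 gLV models ×
30 samples × 50 removal iterations × 5 seeds for the keystoneness study;
20 seeds for planted-truth recovery; 100 null replicates for FDR
calibration; 10–20 seeds elsewhere. These sizes were chosen so the full
suite completes on a single CPU while keeping Monte-Carlo standard errors
well inside the asserted margins.
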