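"""Keystoneness prediction from correlation-network node features.

Ground-truth keystoneness (mean Canberra impact of a species' removal, from
:mod:`tknet.glv`) is regressed on six per-species features computed from the
community abundance samples: mean relative abundance plus five node
parameters of a Spearman co-occurrence network — sum of absolute correlation
strength, degree, relative closeness centrality, betweenness centrality and
eccentricity. The model is exposed statsmodels-style:
``KeystonenessModel(...).fit()`` returns a :class:`KeystonenessResults`
carrying coefficients, uncertainties, the held-out test skill (adjusted R²
between true and predicted keystoneness) and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glv import (
    random_glv_model,
    sample_community,
    scale_keystoneness,
    true_keystoneness,
)
from .metastats import bh_fdr, spearman_matrix

__all__ = [
    "FEATURE_NAMES",
    "keystone_features",
    "adjusted_r2",
    "KeystonenessModel",
    "KeystonenessResults",
    "train_keystone_model",
    "predict_and_scale",
    "simulate_keystone_training_data",
]

FEATURE_NAMES = (
    "mean_rel_abundance",
    "abs_corr_strength",
    "degree",
    "closeness",
    "betweenness",
    "eccentricity",
)


def network_node_metrics(G: nx.Graph) -> tuple:
    """Degree, relative closeness, betweenness and eccentricity per node.

    Conventions: closeness is within-component, scaled by component size
    (Wasserman-Faust correction; 0 for isolated nodes); betweenness is
    unnormalized; eccentricity is within-component, with isolated nodes
    assigned the sentinel N (the node count, exceeding any attainable
    within-component value). Nodes must be labelled 0..N−1.
    """
    n = G.number_of_nodes()
    degree = np.array([G.degree[i] for i in range(n)], dtype=float)
    closeness = np.array([nx.closeness_centrality(G, u=i, wf_improved=True) for i in range(n)])
    betweenness_map = nx.betweenness_centrality(G, normalized=False)
    betweenness = np.array([betweenness_map[i] for i in range(n)])
    eccentricity = np.full(n, float(n))  # sentinel for isolated nodes
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        ecc = nx.eccentricity(G.subgraph(comp))
        for node, e in ecc.items():
            eccentricity[node] = float(e)
    return degree, closeness, betweenness, eccentricity


def keystone_features(
    samples: pd.DataFrame, spearman_p_max: float = 0.05, adjust_p: bool = True
) -> pd.DataFrame:
    """Per-species features from a samples × species abundance matrix.

    A Spearman co-occurrence network is built over species (edges where the
    BH-adjusted correlation p value is below ``spearman_p_max``); each
    species then gets: mean relative abundance across samples, the sum of
    |rho| over its retained edges, degree, relative closeness centrality
    (within-component closeness scaled by component size), betweenness
    centrality (unnormalized), and eccentricity within its component.
    Isolated nodes get closeness 0 and the sentinel eccentricity N (one more
    than any attainable within-component value). Constant species are
    flagged in the ``constant`` column and can join no edge.
    """
    if samples.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    species = list(samples.columns)
    n_sp = len(species)
    X = samples.to_numpy(dtype=float)
    row_sums = X.sum(axis=1, keepdims=True)
    rel = np.divide(X, row_sums, out=np.zeros_like(X), where=row_sums > 0)
    mean_rel = rel.mean(axis=0)
    constant = np.array([np.all(X[:, j] == X[0, j]) for j in range(n_sp)])

    rho, pval = spearman_matrix(X)
    iu = np.triu_indices(n_sp, k=1)
    p_flat = pval[iu]
    valid = np.isfinite(p_flat)
    q_flat = np.full_like(p_flat, np.nan)
    if valid.any():
        q_flat[valid] = bh_fdr(p_flat[valid]) if adjust_p else p_flat[valid]

    G = nx.Graph()
    G.add_nodes_from(range(n_sp))
    for (i, j, q) in zip(iu[0], iu[1], q_flat):
        if np.isfinite(q) and q < spearman_p_max and not (constant[i] or constant[j]):
            G.add_edge(int(i), int(j), rho=float(rho[i, j]))

    abs_strength = np.zeros(n_sp)
    for i, j, data in G.edges(data=True):
        abs_strength[i] += abs(data["rho"])
        abs_strength[j] += abs(data["rho"])

    degree, closeness, betweenness, eccentricity = network_node_metrics(G)

    return pd.DataFrame(
        {
            "species": species,
            "mean_rel_abundance": mean_rel,
            "abs_corr_strength": abs_strength,
            "degree": degree,
            "closeness": closeness,
            "betweenness": betweenness,
            "eccentricity": eccentricity,
            "constant": constant,
        }
    ).set_index("species")


def adjusted_r2(y, yhat, n_predictors: int = 1) -> float:
    """Adjusted R² between observed and predicted values.

    R² is that of the linear fit of ``y`` on ``yhat`` (squared Pearson
    correlation for the default single predictor), adjusted as
    1 − (1 − R²)(n − 1)/(n − p − 1).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if n <= n_predictors + 1:
        raise ValueError("need n > n_predictors + 1")
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


class KeystonenessModel:
    """Linear keystoneness predictor over the six node features.

    Parameters
    ----------
    endog : array-like
        Ground-truth keystoneness per (model, species) row.
    exog : DataFrame
        Feature matrix with the six columns in :data:`FEATURE_NAMES`
        (an intercept is added internally).
    groups : array-like, optional
        Community-model identifier per row; the train/test split assigns
        whole models to one side so that test skill is out-of-community.
    """

    def __init__(self, endog, exog: pd.DataFrame, groups=None):
        exog = pd.DataFrame(exog)
        missing = [c for c in FEATURE_NAMES if c not in exog.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        self.exog = exog[list(FEATURE_NAMES)].astype(float)
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.size != len(self.exog):
            raise ValueError("endog/exog length mismatch")
        self.groups = None if groups is None else np.asarray(groups)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str = "keystoneness",
        groups: str | None = "model_id",
    ) -> "KeystonenessModel":
        g = df[groups].to_numpy() if groups is not None and groups in df.columns else None
        return cls(endog=df[target], exog=df, groups=g)

    def fit(self, test_fraction: float = 0.3, seed: int = 0) -> "KeystonenessResults":
        """OLS fit on a train split; skill evaluated on the held-out split."""
        if not 0 < test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        n = self.endog.size
        rng = np.random.default_rng(seed)
        if self.groups is not None:
            uniq = np.unique(self.groups)
            shuffled = rng.permutation(uniq)
            n_test = max(1, int(round(test_fraction * uniq.size)))
            test_groups = set(shuffled[:n_test].tolist())
            test_mask = np.array([g in test_groups for g in self.groups])
        else:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[rng.permutation(n)[: max(1, int(round(test_fraction * n)))]] = True
        train_mask = ~test_mask

        X = sm.add_constant(self.exog.to_numpy(), has_constant="add")
        if np.linalg.matrix_rank(X[train_mask]) < X.shape[1]:
            corr = np.corrcoef(self.exog.to_numpy()[train_mask].T)
            pairs = [
                (FEATURE_NAMES[i], FEATURE_NAMES[j])
                for i in range(len(FEATURE_NAMES))
                for j in range(i + 1, len(FEATURE_NAMES))
                if abs(corr[i, j]) > 0.999
            ]
            raise ValueError(f"rank-deficient design; collinear features: {pairs}")
        res = sm.OLS(self.endog[train_mask], X[train_mask]).fit()
        yhat_test = res.predict(X[test_mask])
        return KeystonenessResults(
            model=self,
            sm_results=res,
            train_mask=train_mask,
            test_mask=test_mask,
            yhat_test=yhat_test,
            seed=seed,
            test_fraction=test_fraction,
        )


@dataclass
class KeystonenessResults:
    """Fit results: coefficients, uncertainties and held-out skill."""

    model: KeystonenessModel
    sm_results: object
    train_mask: np.ndarray
    test_mask: np.ndarray
    yhat_test: np.ndarray
    seed: int
    test_fraction: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.sm_results.params, index=("const",) + FEATURE_NAMES)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.sm_results.bse, index=("const",) + FEATURE_NAMES)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.sm_results.pvalues, index=("const",) + FEATURE_NAMES)

    @property
    def adjusted_r2_test(self) -> float:
        return adjusted_r2(self.model.endog[self.test_mask], self.yhat_test)

    @property
    def r2_train(self) -> float:
        return float(self.sm_results.rsquared)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(
            pd.DataFrame(features)[list(FEATURE_NAMES)].to_numpy(dtype=float),
            has_constant="add",
        )
        return np.asarray(self.sm_results.predict(X))

    def predict_scaled(self, features: pd.DataFrame) -> np.ndarray:
        return predict_and_scale(self, features)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "test_fraction": self.test_fraction,
            "seed": int(self.seed),
            "n_train": int(self.train_mask.sum()),
            "n_test": int(self.test_mask.sum()),
            "r2_train": self.r2_train,
            "adjusted_r2_test": self.adjusted_r2_test,
        }

    def summary(self) -> str:
        lines = [
            "Keystoneness linear model (OLS)",
            "=" * 64,
            f"{'':22s}{'coef':>12s}{'std err':>12s}{'P>|t|':>12s}",
        ]
        for name in ("const",) + FEATURE_NAMES:
            lines.append(
                f"{name:22s}{self.params[name]:12.4f}{self.bse[name]:12.4f}"
                f"{self.pvalues[name]:12.4g}"
            )
        lines += [
            "-" * 64,
            f"n_train = {int(self.train_mask.sum())}, n_test = {int(self.test_mask.sum())}",
            f"train R2 = {self.r2_train:.4f}",
            f"test adjusted R2 (true vs predicted) = {self.adjusted_r2_test:.4f}",
        ]
        return "\n".join(lines)


def train_keystone_model(
    features: pd.DataFrame,
    keystoneness,
    test_fraction: float = 0.3,
    seed: int = 0,
    groups=None,
) -> KeystonenessResults:
    """Functional wrapper: fit the 6-feature linear keystoneness model."""
    model = KeystonenessModel(endog=keystoneness, exog=features, groups=groups)
    return model.fit(test_fraction=test_fraction, seed=seed)


def predict_and_scale(results: KeystonenessResults, features: pd.DataFrame) -> np.ndarray:
    """Linear prediction followed by min-max scaling onto [0, 1].

    Scaling removes the negative values the unconstrained linear model can
    produce. Degenerate single-node or constant predictions map to 0.5.
    """
    pred = results.predict(features)
    if pred.size == 1 or float(pred.max()) == float(pred.min()):
        import warnings

        warnings.warn("degenerate prediction set; returning 0.5", stacklevel=2)
        return np.full(pred.shape, 0.5)
    return (pred - pred.min()) / (pred.max() - pred.min())


def simulate_keystone_training_data(
    n_models: int = 50,
    n_samples: int = 30,
    n_iter: int = 50,
    seed: int = 0,
    spearman_p_max: float = 0.05,
    adjust_p: bool = True,
    progress: bool = False,
    **model_kwargs,
) -> pd.DataFrame:
    """Generate the keystoneness training table from gLV simulations.

    For each of ``n_models`` community models drawn from the study parameter
    ranges: integrate ``n_samples`` random sub-communities to steady state
    (the abundance samples), compute the six per-species features from
    them, pick a reference community and measure every member's true
    keystoneness with ``n_iter`` removal iterations. Rows are
    (model, species) pairs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    made = 0
    attempts = 0
    while made < n_models and attempts < 4 * n_models:
        attempts += 1
        model, n_species = random_glv_model(rng, **model_kwargs)
        try:
            reference = sample_community(model, n_species, rng)
            sample_vectors = []
            for _ in range(n_samples):
                s = sample_community(model, n_species, rng)
                sample_vectors.append(s.pool_vector(model.S))
        except RuntimeError:
            continue  # unstable parameter draw; try another model
        samples = pd.DataFrame(sample_vectors, columns=range(model.S))
        feats = keystone_features(samples, spearman_p_max=spearman_p_max, adjust_p=adjust_p)
        records = scale_keystoneness(true_keystoneness(model, reference, n_iter=n_iter, rng=rng))
        for rec in records:
            if not np.isfinite(rec.keystoneness):
                continue
            f = feats.loc[rec.species_id]
            rows.append(
                {
                    "model_id": made,
                    "species_id": rec.species_id,
                    "keystoneness": rec.keystoneness,
                    "scaled_keystoneness": rec.scaled_keystoneness,
                    **{name: float(f[name]) for name in FEATURE_NAMES},
                }
            )
        made += 1
        if progress and made % 10 == 0:
            print(f"  simulated {made}/{n_models} community models")
    if made < n_models:
        raise RuntimeError("too many unstable models; loosen parameter ranges")
    return pd.DataFrame(rows)
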