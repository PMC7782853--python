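"""Phenotype derivations and two-experiment meta-analysis statistics.

Covers the homeostatic-model indices (HOMA-IR, HOMA-B), glucose-tolerance
AUC, Fisher's method for combining per-experiment p values, Benjamini–
Hochberg FDR, the Mann–Whitney and Welch-t meta-analysis rule sets used to
call differential features across replicate experiments, metabolite
zero-imputation and pooled-serum ratio tests, and the filtered Spearman
BMI correlation used on human cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable

__all__ = [
    "homa_ir",
    "homa_b",
    "gtt_auc",
    "fisher_combine",
    "bh_fdr",
    "MetaTestResult",
    "mann_whitney_meta",
    "ttest_meta",
    "impute_metabolite_zeros",
    "metabolite_ratio_test",
    "bmi_correlation",
    "meta_results_to_frame",
    "spearman_matrix",
]

# Mann-Whitney: exact null distribution is used up to this per-group size
EXACT_MW_MAX_N = 8


def spearman_matrix(X: np.ndarray):
    """All-pairs Spearman rho and two-sided p over the columns of ``X``.

    Rank-transforms each column (average ranks on ties) and correlates the
    ranks; p values use the usual t approximation with n−2 degrees of
    freedom. Constant columns yield NaN rho/p rather than poisoning the
    whole matrix. Returns ``(rho, p)`` square arrays.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isposinf(tstat) | np.isneginf(tstat)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    return rho, p


def homa_ir(glucose_mgdl: float, insulin_uUml: float) -> float:
    """Homeostatic model assessment of insulin resistance.

    HOMA-IR = glucose [mg/dL] × insulin [µU/mL] / 405.
    """
    if glucose_mgdl < 0 or insulin_uUml < 0:
        raise ValueError("glucose and insulin must be non-negative")
    return glucose_mgdl * insulin_uUml / 405.0


def homa_b(glucose_mgdl: float, insulin_uUml: float) -> float:
    """Homeostatic model assessment of beta-cell function, in percent.

    HOMA-B = 360 × insulin [µU/mL] / (glucose [mg/dL] − 63) %. Undefined
    for glucose ≤ 63 mg/dL (hypoglycemic input).
    """
    if insulin_uUml < 0:
        raise ValueError("insulin must be non-negative")
    if glucose_mgdl <= 63:
        raise ValueError("HOMA-B undefined for fasting glucose <= 63 mg/dL")
    return 360.0 * insulin_uUml / (glucose_mgdl - 63.0)


def gtt_auc(glucose, times_min=(0, 15, 30, 60, 120)) -> float:
    """Trapezoidal area under the glucose-tolerance curve (mg/dL·min)."""
    times = np.asarray(times_min, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if times.shape != glucose.shape:
        raise ValueError("times and glucose must have the same length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(glucose, times))


def fisher_combine(pvals) -> float:
    """Fisher's method: combined p from X² = −2Σln p ~ χ²(2k)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]; floor zeros at machine epsilon first")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MetaTestResult:
    """Per-feature outcome of a multi-experiment differential test."""

    feature_id: str
    per_experiment_p: list
    per_experiment_direction: list  # +1 / -1 / 0 per experiment
    fisher_p: float  # NaN when directions inconsistent
    fdr_q: float
    fold_change: float  # ratio of group medians (B / A)
    direction_consistent: bool = True
    passes: dict = field(default_factory=dict)

    @property
    def direction(self) -> int:
        """Overall sign of change (B vs A); 0 if inconsistent/flat."""
        if not self.direction_consistent:
            return 0
        nonzero = [d for d in self.per_experiment_direction if d != 0]
        return nonzero[0] if nonzero else 0


def meta_results_to_frame(results) -> pd.DataFrame:
    """Stable-column CSV-ready view of a list of MetaTestResult."""
    rows = []
    for r in results:
        row = {
            "feature_id": r.feature_id,
            "fisher_p": r.fisher_p,
            "fdr_q": r.fdr_q,
            "fold_change": r.fold_change,
            "direction": r.direction,
            "direction_consistent": r.direction_consistent,
        }
        for i, (p, d) in enumerate(zip(r.per_experiment_p, r.per_experiment_direction), 1):
            row[f"p_exp{i}"] = p
            row[f"dir_exp{i}"] = d
        for name, ok in r.passes.items():
            row[f"pass_{name}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def _median_ratio(b: np.ndarray, a: np.ndarray) -> float:
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a == 0:
        return np.inf if med_b > 0 else np.nan
    return med_b / med_a


def _apply_meta_rules(results, rules, per_exp_key):
    """Shared tail of both meta tests: Fisher combine + BH-FDR + rule flags."""
    defined = [r for r in results if r.direction_consistent]
    if defined:
        qvals = bh_fdr([r.fisher_p for r in defined])
        for r, q in zip(defined, qvals):
            r.fdr_q = float(q)
    for r in results:
        per_exp_ok = all(p < rules[per_exp_key] for p in r.per_experiment_p)
        r.passes[per_exp_key] = per_exp_ok
        r.passes["direction"] = r.direction_consistent and r.direction != 0
        r.passes["fisher_p"] = r.direction_consistent and r.fisher_p < rules["fisher_p"]
        r.passes["fdr"] = r.direction_consistent and r.fdr_q < rules["fdr"]
        r.passes["all"] = all(
            r.passes[k] for k in (per_exp_key, "direction", "fisher_p", "fdr")
        )
    return results


def mann_whitney_meta(
    tables: dict,
    group_a: str,
    group_b: str,
    rules: dict | None = None,
    group_column: str = "group",
) -> list:
    """Differential-abundance meta-analysis across replicate experiments.

    For each feature: a two-tailed Mann–Whitney U test B-vs-A per
    experiment (exact null for per-group n ≤ 8 without ties, normal
    approximation with tie correction otherwise), Fisher combination over
    experiments when the per-experiment directions agree, then BH-FDR over
    features. The default rule set (per-experiment p < 0.2, Fisher p < 0.05,
    FDR < 10%) is the one used to call diet-changed features.

    Parameters
    ----------
    tables : dict
        experiment name → AbundanceTable (with group metadata) or a
        features × samples DataFrame paired via metadata.
    """
    rules = dict(rules or {"per_exp_p": 0.2, "fisher_p": 0.05, "fdr": 0.10})
    experiments = sorted(tables)
    features = None
    for exp in experiments:
        idx = list(tables[exp].data.index)
        features = idx if features is None else [f for f in features if f in set(idx)]

    results = []
    for feat in features:
        pvals, dirs, pooled_a, pooled_b = [], [], [], []
        for exp in experiments:
            tab = tables[exp]
            meta = tab.metadata
            a_ids = [s for s in tab.sample_ids if meta.loc[s, group_column] == group_a]
            b_ids = [s for s in tab.sample_ids if meta.loc[s, group_column] == group_b]
            if len(a_ids) < 2 or len(b_ids) < 2:
                raise ValueError(f"need >=2 samples per group in experiment {exp}")
            a = tab.data.loc[feat, a_ids].to_numpy(dtype=float)
            b = tab.data.loc[feat, b_ids].to_numpy(dtype=float)
            pooled_a.append(a)
            pooled_b.append(b)
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                pvals.append(1.0)  # degenerate all-tied groups
                dirs.append(0)
                continue
            method = (
                "exact"
                if max(len(a), len(b)) <= EXACT_MW_MAX_N
                and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
                else "asymptotic"
            )
            res = stats.mannwhitneyu(b, a, alternative="two-sided", method=method)
            pvals.append(float(res.pvalue))
            dirs.append(int(np.sign(np.median(b) - np.median(a))))
        nonzero = [d for d in dirs if d != 0]
        consistent = len(nonzero) > 0 and all(d == nonzero[0] for d in nonzero)
        fisher_p = fisher_combine(np.clip(pvals, np.finfo(float).tiny, 1.0)) if consistent else np.nan
        results.append(
            MetaTestResult(
                feature_id=feat,
                per_experiment_p=pvals,
                per_experiment_direction=dirs,
                fisher_p=fisher_p,
                fdr_q=np.nan,
                fold_change=_median_ratio(np.concatenate(pooled_b), np.concatenate(pooled_a)),
                direction_consistent=consistent,
            )
        )
    return _apply_meta_rules(results, rules, "per_exp_p")


def ttest_meta(
    tables: dict,
    control: str,
    treatments: list,
    rules: dict | None = None,
    group_column: str = "group",
    welch: bool = True,
) -> list:
    """Same-direction differential expression across treatment groups.

    For each feature, a two-sided t test (Welch by default) of each
    treatment against the control; a feature is meta-significant when it
    passes the per-comparison p threshold in every treatment, changes in
    the same direction in all of them, the Fisher-combined p passes, and
    BH-FDR over features passes. Default rules: per-comparison p < 0.05,
    Fisher p < 0.05, FDR < 10%.
    """
    rules_in = dict(rules or {})
    rules = {
        "per_group_p": rules_in.get("per_group_p", 0.05),
        "fisher_p": rules_in.get("fisher_p", 0.05),
        "fdr": rules_in.get("fdr", 0.10),
    }
    comparisons = sorted(tables)
    features = None
    for key in comparisons:
        idx = list(tables[key].data.index)
        features = idx if features is None else [f for f in features if f in set(idx)]

    results = []
    for feat in features:
        pvals, dirs, pooled_c, pooled_t = [], [], [], []
        for key in comparisons:
            tab = tables[key]
            meta = tab.metadata
            c_ids = [s for s in tab.sample_ids if meta.loc[s, group_column] == control]
            # each table contributes one treatment-vs-control comparison per
            # treatment group found in it
            t_groups = [g for g in treatments if (meta.loc[tab.sample_ids, group_column] == g).any()]
            for tg in t_groups:
                t_ids = [s for s in tab.sample_ids if meta.loc[s, group_column] == tg]
                if len(c_ids) < 2 or len(t_ids) < 2:
                    raise ValueError("need >=2 samples per group")
                c = tab.data.loc[feat, c_ids].to_numpy(dtype=float)
                t = tab.data.loc[feat, t_ids].to_numpy(dtype=float)
                pooled_c.append(c)
                pooled_t.append(t)
                if np.std(c) == 0 and np.std(t) == 0:
                    pvals.append(1.0)
                    dirs.append(int(np.sign(np.mean(t) - np.mean(c))))
                    continue
                res = stats.ttest_ind(t, c, equal_var=not welch)
                pvals.append(float(res.pvalue))
                dirs.append(int(np.sign(np.mean(t) - np.mean(c))))
        nonzero = [d for d in dirs if d != 0]
        consistent = len(nonzero) == len(dirs) and len(set(nonzero)) == 1
        fisher_p = fisher_combine(np.clip(pvals, np.finfo(float).tiny, 1.0)) if consistent else np.nan
        results.append(
            MetaTestResult(
                feature_id=feat,
                per_experiment_p=pvals,
                per_experiment_direction=dirs,
                fisher_p=fisher_p,
                fdr_q=np.nan,
                fold_change=_median_ratio(np.concatenate(pooled_t), np.concatenate(pooled_c)),
                direction_consistent=consistent,
            )
        )
    return _apply_meta_rules(results, rules, "per_group_p")


def impute_metabolite_zeros(
    table: AbundanceTable, tech_sd: float = 0.135, floor: float = 1e-6
) -> AbundanceTable:
    """Replace zero intensities by a just-below-detection value.

    Per metabolite, zeros become ``max(min nonzero level − 3·tech_sd,
    floor)``. The default technical SD of 0.135 is on the normalized
    intensity scale anchored by an internal standard at mean 1.02.
    """
    if tech_sd < 0:
        raise ValueError("tech_sd must be non-negative")
    values = table.data.to_numpy(dtype=float).copy()
    flagged = []
    for i, feat in enumerate(table.data.index):
        row = values[i]
        nz = row[row > 0]
        if nz.size == 0:
            values[i] = floor
            flagged.append(feat)
            continue
        imputed = max(float(nz.min()) - 3.0 * tech_sd, floor)
        values[i][row == 0] = imputed
    out = table.copy_with(
        pd.DataFrame(values, index=table.data.index, columns=table.data.columns),
        note=f"impute_metabolite_zeros(tech_sd={tech_sd})",
    )
    out.provenance.append(f"all-zero metabolites floored: {flagged}")
    return out


def metabolite_ratio_test(ratios: pd.DataFrame) -> pd.DataFrame:
    """One-sample t test of log2 treated/control pool ratios against 0.

    ``ratios`` is metabolites × pools of treated/control intensity ratios.
    Returns per-metabolite mean log2 ratio, two-sided p, BH-FDR q, and a
    degeneracy flag for zero-variance rows (p undefined).
    """
    if ratios.shape[1] < 2:
        raise ValueError("need >=2 pool ratios per metabolite")
    log2r = np.log2(ratios.to_numpy(dtype=float))
    means = log2r.mean(axis=1)
    pvals = np.full(len(ratios), np.nan)
    degenerate = np.zeros(len(ratios), dtype=bool)
    for i in range(len(ratios)):
        row = log2r[i]
        if np.std(row, ddof=1) == 0:
            degenerate[i] = True
            continue
        pvals[i] = float(stats.ttest_1samp(row, 0.0).pvalue)
    qvals = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        qvals[ok] = bh_fdr(pvals[ok])
    return pd.DataFrame(
        {
            "metabolite": ratios.index,
            "mean_log2_ratio": means,
            "p": pvals,
            "fdr_q": qvals,
            "degenerate": degenerate,
        }
    ).set_index("metabolite")


def bmi_correlation(
    abundance_rpm: pd.Series,
    bmi: pd.Series,
    min_rpm: float,
    expected_direction: int = -1,
):
    """Spearman correlation of a taxon with BMI after a reads-per-million gate.

    Samples with abundance ≤ ``min_rpm`` are excluded (outlier/absence
    guard), then Spearman rho and a one-tailed p in the supplied expected
    direction are computed. Returns ``(rho, one_tail_p, n_used)``.
    """
    if min_rpm < 0:
        raise ValueError("min_rpm must be non-negative")
    if expected_direction not in (-1, 1):
        raise ValueError("expected_direction must be -1 or +1")
    common = abundance_rpm.index.intersection(bmi.index)
    x = abundance_rpm.loc[common]
    keep = x > min_rpm
    x = x[keep]
    y = bmi.loc[x.index]
    n_used = int(len(x))
    if n_used < 4:
        raise ValueError("fewer than 4 samples after filtering")
    rho, p_two = stats.spearmanr(x, y)
    if np.sign(rho) == expected_direction:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    return float(rho), float(p_one), n_used
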