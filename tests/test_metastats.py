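import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tknet.containers import AbundanceTable
from tknet.metastats import (
    bh_fdr,
    bmi_correlation,
    fisher_combine,
    gtt_auc,
    homa_b,
    homa_ir,
    impute_metabolite_zeros,
    mann_whitney_meta,
    metabolite_ratio_test,
    spearman_matrix,
    ttest_meta,
)


class TestHomaIndices:
    @pytest.mark.parametrize(
        "glucose,insulin,expected",
        [(100.0, 10.0, 1000.0 / 405.0), (0.0, 5.0, 0.0), (405.0, 1.0, 1.0)],
    )
    def test_homa_ir(self, glucose, insulin, expected):
        assert homa_ir(glucose, insulin) == pytest.approx(expected)

    def test_homa_ir_rejects_negative(self):
        with pytest.raises(ValueError):
            homa_ir(-1.0, 5.0)

    def test_homa_b_values_and_domain(self):
        assert homa_b(100.0, 10.0) == pytest.approx(3600.0 / 37.0)  # 97.297...%
        big = homa_b(63.0001, 1.0)
        assert np.isfinite(big) and big > 1e5
        with pytest.raises(ValueError):
            homa_b(63.0, 1.0)


class TestGttAuc:
    def test_constant_curve_is_a_rectangle(self):
        assert gtt_auc([100] * 5) == pytest.approx(12000.0)

    def test_zero_curve(self):
        assert gtt_auc([0, 0, 0, 0, 0]) == 0.0

    def test_hand_trapezoid_sum(self):
        # (100+200)/2*15 + (200+150)/2*15 + (150+120)/2*30 + (120+100)/2*60
        assert gtt_auc([100, 200, 150, 120, 100]) == pytest.approx(15525.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gtt_auc([100, 200], times_min=[0, 15, 30])


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_two_halves(self):
        # chi2 survival of -2*2*ln(0.5) = 2.7726 at 4 df
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    def test_single_p_identity(self):
        assert fisher_combine([0.137]) == pytest.approx(0.137, rel=1e-10)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    def test_concordant_meta_gains_power(self):
        for p in (0.01, 0.05, 0.1, 0.2):
            for k in (2, 3, 4):
                assert fisher_combine([p] * k) <= p


class TestBhFdr:
    def test_equal_p_pass_through(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_equivariance_and_monotonicity(self, rng):
        p = rng.random(25)
        q = bh_fdr(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def two_experiment_tables(values_by_exp, group_pattern):
    tables = {}
    for exp, values in values_by_exp.items():
        values = np.atleast_2d(np.asarray(values, dtype=float))
        cols = [f"{exp}_s{j}" for j in range(values.shape[1])]
        meta = pd.DataFrame({"group": group_pattern}, index=cols)
        tables[exp] = AbundanceTable(
            data=pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])], columns=cols),
            metadata=meta,
        )
    return tables


class TestMannWhitneyMeta:
    def test_identical_groups_fail_per_experiment_rule(self):
        tabs = two_experiment_tables(
            {"e1": [[1, 2, 3, 1, 2, 3]], "e2": [[4, 5, 6, 4, 5, 6]]},
            ["A", "A", "A", "B", "B", "B"],
        )
        res = mann_whitney_meta(tabs, "A", "B")[0]
        assert not res.passes["per_exp_p"]

    def test_fully_separated_groups_exact_p(self):
        a, b = [1, 2, 3, 4, 5], [10, 11, 12, 13, 14]
        tabs = two_experiment_tables({"e1": [a + b]}, ["A"] * 5 + ["B"] * 5)
        res = mann_whitney_meta(tabs, "A", "B")[0]
        # exact two-tailed p for complete separation at n=5 vs 5: 2/252
        assert res.per_experiment_p[0] == pytest.approx(2.0 / 252.0)
        assert res.direction == 1

    def test_opposite_directions_flagged_inconsistent(self):
        up = [1, 2, 3, 10, 11, 12]
        down = [10, 11, 12, 1, 2, 3]
        tabs = two_experiment_tables({"e1": [up], "e2": [down]}, ["A"] * 3 + ["B"] * 3)
        res = mann_whitney_meta(tabs, "A", "B")[0]
        assert not res.direction_consistent
        assert np.isnan(res.fisher_p)
        assert not res.passes["all"]

    def test_fold_change_is_median_ratio(self):
        tabs = two_experiment_tables({"e1": [[2, 2, 2, 6, 6, 6]]}, ["A"] * 3 + ["B"] * 3)
        res = mann_whitney_meta(tabs, "A", "B")[0]
        assert res.fold_change == pytest.approx(3.0)


class TestTtestMeta:
    def make_tables(self, shift_by_group, n=5, n_features=1, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        groups, cols, data = [], [], []
        for g, shift in shift_by_group.items():
            for j in range(n):
                groups.append(g)
                cols.append(f"{g}_{j}")
                data.append(np.maximum(rng.normal(20.0 + shift, noise, size=n_features), 0.0))
        frame = pd.DataFrame(np.array(data).T, index=[f"g{i}" for i in range(n_features)], columns=cols)
        meta = pd.DataFrame({"group": groups}, index=cols)
        return {"d1": AbundanceTable(data=frame, metadata=meta)}

    def test_planted_shift_passes_rules_in_most_replicates(self):
        hits = 0
        for seed in range(20):
            tabs = self.make_tables({"WD": 0.0, "LG": 3.0, "LJ": 3.0}, seed=seed)
            res = ttest_meta(tabs, "WD", ["LG", "LJ"])[0]
            hits += res.passes["all"]
        assert hits >= 18  # 3-sigma shift in both treatments, n=5

    def test_null_features_pass_at_most_fdr_rate(self):
        passes, total = 0, 0
        for seed in range(30):
            tabs = self.make_tables({"WD": 0.0, "LG": 0.0, "LJ": 0.0}, n_features=10, seed=seed)
            for res in ttest_meta(tabs, "WD", ["LG", "LJ"]):
                passes += res.passes["all"]
                total += 1
        assert passes / total <= 0.10

    def test_opposite_treatment_shifts_excluded(self):
        tabs = self.make_tables({"WD": 0.0, "LG": 4.0, "LJ": -4.0}, seed=1)
        res = ttest_meta(tabs, "WD", ["LG", "LJ"])[0]
        assert not res.direction_consistent
        assert not res.passes["all"]


class TestMetaboliteHandling:
    def test_zero_imputation_with_printed_constants(self):
        data = pd.DataFrame(
            [[1.0, 0.0, 2.0]], index=["m1"], columns=["p1", "p2", "p3"]
        )
        out = impute_metabolite_zeros(AbundanceTable(data=data), tech_sd=0.135)
        assert out.data.loc["m1", "p2"] == pytest.approx(1.0 - 3 * 0.135)  # 0.595

    def test_zero_tech_sd_imputes_the_minimum(self):
        data = pd.DataFrame([[0.0, 2.0, 5.0]], index=["m1"], columns=list("abc"))
        out = impute_metabolite_zeros(AbundanceTable(data=data), tech_sd=0.0)
        assert out.data.loc["m1", "a"] == pytest.approx(2.0)

    def test_no_zeros_leaves_table_unchanged(self, rng):
        data = pd.DataFrame(rng.random((5, 4)) + 0.5)
        data.index = [f"m{i}" for i in range(5)]
        out = impute_metabolite_zeros(AbundanceTable(data=data))
        np.testing.assert_allclose(out.data.to_numpy(), data.to_numpy())

    def test_ratio_test_matches_t_distribution_oracle(self):
        ratios = pd.DataFrame([[2.0, 4.0, 2.0, 4.0]], index=["m1"])
        res = metabolite_ratio_test(ratios)
        t = 1.5 / (np.std([1, 2, 1, 2], ddof=1) / 2.0)
        assert t == pytest.approx(5.196, abs=1e-3)
        assert res.loc["m1", "p"] == pytest.approx(2 * stats.t.sf(t, df=3), rel=1e-6)
        assert res.loc["m1", "p"] == pytest.approx(0.0138, abs=2e-3)

    def test_degenerate_unit_ratios_flagged(self):
        res = metabolite_ratio_test(pd.DataFrame([[1.0, 1.0, 1.0]], index=["m1"]))
        assert bool(res.loc["m1", "degenerate"])
        assert np.isnan(res.loc["m1", "p"])

    def test_rescaling_shifts_mean_log2(self):
        base = pd.DataFrame([[2.0, 3.0, 4.0]], index=["m1"])
        shifted = metabolite_ratio_test(base * 4.0)
        plain = metabolite_ratio_test(base)
        assert shifted.loc["m1", "mean_log2_ratio"] - plain.loc["m1", "mean_log2_ratio"] == pytest.approx(2.0)


class TestBmiCorrelation:
    def test_low_abundance_samples_excluded(self):
        ab = pd.Series([5.0, 20, 30, 40, 50, 60], index=list("abcdef"))
        bmi = pd.Series([30.0, 31, 32, 33, 34, 35], index=list("abcdef"))
        rho, p, n = bmi_correlation(ab, bmi, min_rpm=10, expected_direction=1)
        assert n == 5

    def test_perfect_monotone_decrease(self):
        ab = pd.Series([100.0, 80, 60, 40, 20], index=list("abcde"))
        bmi = pd.Series([25.0, 27, 30, 33, 36], index=list("abcde"))
        rho, p, n = bmi_correlation(ab, bmi, min_rpm=10, expected_direction=-1)
        assert rho == pytest.approx(-1.0)
        assert p < 0.01

    def test_one_tail_p_is_calibrated_under_null(self, rng):
        pvals = []
        for _ in range(300):
            ab = pd.Series(rng.random(12) * 100 + 20, index=range(12))
            bmi = pd.Series(rng.random(12) * 10 + 25, index=range(12))
            pvals.append(bmi_correlation(ab, bmi, min_rpm=0, expected_direction=-1)[1])
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.08)
        assert np.mean(np.array(pvals) < 0.1) == pytest.approx(0.1, abs=0.07)


class TestSpearmanMatrix:
    def test_matches_scipy_on_clean_data(self, rng):
        X = rng.random((15, 6))
        rho, p = spearman_matrix(X)
        want_rho, want_p = stats.spearmanr(X)
        np.testing.assert_allclose(rho, want_rho, atol=1e-12)
        np.testing.assert_allclose(p, want_p, atol=1e-10)

    def test_constant_column_isolated_not_poisoning(self, rng):
        X = rng.random((15, 4))
        X[:, 1] = 3.0
        rho, p = spearman_matrix(X)
        assert np.isnan(rho[0, 1]) and np.isnan(p[0, 1])
        assert np.isfinite(rho[0, 2]) and np.isfinite(p[0, 2])
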