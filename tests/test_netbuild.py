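import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tknet.metastats import fisher_combine
from tknet.netbuild import (
    CorrelationRecord,
    causality_filter,
    fold_change_direction,
    pairwise_spearman_by_group,
    select_consistent_edges,
    voting_meta,
)


def record(rhos, ps, edge_class="within-otu", a="x", b="y"):
    return CorrelationRecord(
        node_a=a,
        node_b=b,
        edge_class=edge_class,
        per_dataset_rho=list(rhos),
        per_dataset_p=list(ps),
        per_dataset_n=[10] * len(rhos),
        dataset_names=[f"d{i}" for i in range(len(rhos))],
    )


class TestPairwiseSpearman:
    def make_tables(self, rng, n=8):
        x = rng.random(n)
        data = pd.DataFrame(
            {f"s{j}": None for j in range(n)}, index=["a", "b", "c"], dtype=float
        )
        data.loc["a"] = x
        data.loc["b"] = x * 2 + 1  # identical ranks
        data.loc["c"] = -x  # anti-monotone
        return {"d1": data, "d2": data + rng.normal(0, 1e-9, data.shape)}

    def test_identical_and_antimonotone_pairs(self, rng):
        recs = pairwise_spearman_by_group(self.make_tables(rng))
        by_pair = {(r.node_a, r.node_b): r for r in recs}
        ab = by_pair[("a", "b")]
        ac = by_pair[("a", "c")]
        assert ab.per_dataset_rho[0] == pytest.approx(1.0)
        assert ab.per_dataset_p[0] < 1e-6
        assert ac.per_dataset_rho[0] == pytest.approx(-1.0)

    def test_six_point_pair_matches_rank_formula_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        tables = {"d": pd.DataFrame([x, y], index=["a", "b"], columns=[f"s{j}" for j in range(6)])}
        rec = pairwise_spearman_by_group(tables)[0]
        # oracle: Pearson correlation of average ranks (tie-corrected)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert rec.per_dataset_rho[0] == pytest.approx(want)

    def test_constant_feature_flagged(self, rng):
        tables = {
            "d": pd.DataFrame(
                [[1.0, 1, 1, 1, 1], [1, 2, 3, 4, 5]], index=["a", "b"], columns=list("vwxyz")
            )
        }
        rec = pairwise_spearman_by_group(tables)[0]
        assert rec.constant_flag

    def test_too_few_samples_rejected(self):
        tables = {"d": pd.DataFrame([[1.0, 2, 3], [3, 2, 1]], index=["a", "b"])}
        with pytest.raises(ValueError):
            pairwise_spearman_by_group(tables)


class TestSelectConsistentEdges:
    def test_sign_inconsistent_dropped(self):
        out = select_consistent_edges([record([0.8, -0.2], [0.01, 0.02])])
        assert out == []

    def test_survivor_carries_fisher_p(self):
        rec = record([0.8, 0.7], [0.01, 0.02])
        out = select_consistent_edges([rec])
        assert len(out) == 1
        assert out[0].fisher_p == pytest.approx(0.00191, abs=2e-4)
        assert out[0].fdr_q <= 0.10

    def test_per_dataset_threshold_gate(self):
        out = select_consistent_edges([record([0.5, 0.9], [0.35, 0.01])])
        assert out == []

    def test_fdr_is_per_class(self):
        # many weak within-otu records dilute that class only
        weak = [record([0.5, 0.5], [0.25, 0.25], a=f"x{i}", b=f"y{i}") for i in range(30)]
        strong_a = record([0.9, 0.9], [0.001, 0.001], edge_class="within-phenotype", a="p", b="q")
        out = select_consistent_edges(weak + [strong_a], fdr_max=0.10)
        assert any(r.edge_class == "within-phenotype" for r in out)

    def test_edge_counts_monotone_in_stringency(self, rng):
        recs = [
            record([rng.uniform(0.2, 0.9)] * 2, list(rng.uniform(0.001, 0.4, 2)), a=f"a{i}", b=f"b{i}")
            for i in range(50)
        ]
        import copy

        loose = select_consistent_edges(copy.deepcopy(recs), per_dataset_p_max=0.4, fisher_max=0.2, fdr_max=0.5)
        tight = select_consistent_edges(copy.deepcopy(recs), per_dataset_p_max=0.2, fisher_max=0.05, fdr_max=0.1)
        assert len(tight) <= len(loose)


class TestCausalityFilter:
    @pytest.mark.parametrize(
        "fc_a,fc_b,rho,kept",
        [
            (2.0, 3.0, 0.8, True),  # both up, positive correlation
            (2.0, 0.5, 0.8, False),  # discordant
            (0.5, 0.25, 0.8, True),  # both down: (-)(-) = +
            (0.5, 0.25, -0.8, False),
        ],
    )
    def test_concordance_rule(self, fc_a, fc_b, rho, kept):
        rec = record([rho, rho], [0.01, 0.01], a="a", b="b")
        out = causality_filter([rec], {"a": fc_a, "b": fc_b})
        assert (len(out) == 1) is kept

    def test_flipping_both_fold_changes_is_stable(self, rng):
        recs = [record([s * 0.7] * 2, [0.01, 0.01], a="a", b="b") for s in (1, -1)]
        kept1 = {id(r) for r in causality_filter(list(recs), {"a": 2.0, "b": 0.5})}
        kept2 = {id(r) for r in causality_filter(list(recs), {"a": 0.5, "b": 2.0})}
        assert kept1 == kept2

    def test_missing_fold_change_warns_and_drops(self):
        rec = record([0.7, 0.7], [0.01, 0.01], a="a", b="b")
        with pytest.warns(UserWarning):
            out = causality_filter([rec], {"a": 2.0})
        assert out == []

    def test_extreme_ratios_have_directions(self):
        assert fold_change_direction(0.0) == -1
        assert fold_change_direction(np.inf) == 1
        assert fold_change_direction(1.0) == 0
        assert fold_change_direction(np.nan) is None


class TestVotingMeta:
    def test_two_votes_third_over_threshold_kept_without_third(self):
        rec = record([0.5, 0.6, 0.1], [0.05, 0.08, 0.50])
        out = voting_meta([rec])
        assert len(out) == 1
        assert out[0].fisher_p == pytest.approx(fisher_combine([0.05, 0.08]))
        assert len(out[0].per_dataset_p) == 2

    def test_all_under_threshold_with_discordant_sign_removed(self):
        rec = record([0.5, 0.6, -0.4], [0.05, 0.08, 0.04])
        assert voting_meta([rec]) == []

    def test_single_vote_not_shortlisted(self):
        rec = record([0.5, 0.6, 0.4], [0.50, 0.60, 0.04])
        assert voting_meta([rec]) == []

    def test_unanimous_votes_fisher_over_all_three(self):
        rec = record([0.5, 0.6, 0.4], [0.05, 0.08, 0.04])
        out = voting_meta([rec])
        assert len(out) == 1
        assert out[0].fisher_p == pytest.approx(fisher_combine([0.05, 0.08, 0.04]))

    def test_full_truth_table_of_sign_p_configurations(self):
        # enumerate sign patterns x under/over-threshold patterns and check
        # the three quoted branches exhaustively
        p_lo, p_hi = 0.05, 0.5
        for signs in [(1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1), (1, -1, -1)]:
            for unders in [(1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 0, 0)]:
                ps = [p_lo if u else p_hi for u in unders]
                rhos = [0.5 * s for s in signs]
                out = voting_meta([record(rhos, ps)])
                votes = [
                    (i, j)
                    for i in range(3)
                    for j in range(i + 1, 3)
                    if unders[i] and unders[j] and signs[i] == signs[j]
                ]
                if not votes:
                    expect = 0
                elif all(unders):
                    expect = 1 if len(set(signs)) == 1 else 0
                else:
                    expect = 1
                assert len(out) == expect, (signs, unders)

    def test_requires_exactly_three_datasets(self):
        with pytest.raises(ValueError):
            voting_meta([record([0.5, 0.5], [0.05, 0.05])])
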