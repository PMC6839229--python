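"""The Lamda3 measure, wcs, and rule ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rulomics import (
    Rule,
    RuleMetrics,
    apriori_frequent_itemsets,
    correlation_pvalue,
    generate_rules,
    lamda3_score,
    partition_samples,
    rank_rules,
    rank_weights,
    score_rules,
    wcs_score,
)
from rulomics.lamda3 import MIN_PARTITION, P_FLOOR

from oracles import lamda3_reference


def rule(a, c):
    return Rule((a,), (c,), RuleMetrics(0.5, 1.0, 1.0))


class TestPartitionSamples:
    def test_toy_pair_partition(self, toy_binary):
        part = partition_samples("NEK2", "CDKN3", toy_binary)
        assert part.both_one == (
            "TCGA-2H-A9GF-01", "TCGA-2H-A9GH-01", "TCGA-2H-A9GI-01",
        )
        assert part.both_zero == ("TCGA-2H-A9GG-01", "TCGA-2H-A9GJ-01")
        assert part.inconsistent == ()

    def test_partition_covers_all_samples_disjointly(self, toy_binary):
        for a in toy_binary.columns:
            for c in toy_binary.columns:
                if a == c:
                    continue
                p = partition_samples(a, c, toy_binary)
                groups = [set(p.both_one), set(p.inconsistent), set(p.both_zero)]
                assert set().union(*groups) == set(toy_binary.index)
                assert sum(len(g) for g in groups) == len(toy_binary)

    def test_all_ones_pair(self):
        B = pd.DataFrame({"a": [1, 1, 1], "b": [1, 1, 1]}, index=list("xyz"))
        p = partition_samples("a", "b", B)
        assert p.both_one == ("x", "y", "z")
        assert p.inconsistent == () and p.both_zero == ()

    def test_complementary_pair_is_all_inconsistent(self):
        B = pd.DataFrame({"a": [1, 0, 1], "b": [0, 1, 0]}, index=list("xyz"))
        p = partition_samples("a", "b", B)
        assert set(p.inconsistent) == {"x", "y", "z"}

    def test_unknown_gene_rejected(self, toy_binary):
        with pytest.raises(KeyError, match="nope"):
            partition_samples("NEK2", "nope", toy_binary)


class TestCorrelationPvalue:
    def test_perfect_correlation_hits_floor(self):
        p = correlation_pvalue([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert p == P_FLOOR

    def test_short_vectors_return_one(self):
        assert correlation_pvalue([1, 2], [3, 4]) == 1.0
        assert correlation_pvalue([], []) == 1.0

    def test_constant_vector_returns_one(self):
        assert correlation_pvalue([1, 1, 1, 1], [1, 2, 3, 4]) == 1.0

    def test_matches_closed_form_t_test(self):
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5], dtype=float)
        r = np.corrcoef(x, y)[0, 1]
        t = r * math.sqrt((len(x) - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), len(x) - 2)
        assert correlation_pvalue(x, y) == pytest.approx(expected, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            correlation_pvalue([1, 2, 3], [1, 2])

    def test_spearman_on_monotone_data(self):
        x = np.arange(10.0)
        assert correlation_pvalue(x, np.exp(x), "spearman") < 1e-6


def _planted_matrix(seed=0, m=60, n_noise=4, r=0.95):
    """A and C share a latent factor; the rest is independent noise."""
    rng = np.random.default_rng(seed)
    dys = np.zeros(m)
    dys[rng.choice(m, m // 2, replace=False)] = 1
    factor = rng.standard_normal(m) + 3.0 * dys
    s = math.sqrt((1 - r) / r)
    cols = {
        "A": factor + s * rng.standard_normal(m),
        "C": factor + s * rng.standard_normal(m),
    }
    for j in range(n_noise):
        cols[f"N{j}"] = rng.standard_normal(m)
    M = pd.DataFrame(cols, index=[f"s{i}" for i in range(m)])
    B = pd.DataFrame(0, index=M.index, columns=M.columns)
    B.loc[dys == 1, "A"] = 1
    B.loc[dys == 1, "C"] = 1
    return M, B


class TestLamda3Score:
    def test_numerator_equals_denominator_gives_one(self):
        # background genes are exact copies of C, so the median background
        # p-value equals the pair p-value in both partitions
        rng = np.random.default_rng(4)
        m = 40
        a = rng.standard_normal(m)
        c = 0.8 * a + 0.2 * rng.standard_normal(m)
        M = pd.DataFrame(
            {"A": a, "C": c, "g1": c, "g2": c, "g3": c, "g4": c},
            index=[f"s{i}" for i in range(m)],
        )
        B = pd.DataFrame(0, index=M.index, columns=M.columns)
        B.iloc[: m // 2] = 1
        out = lamda3_score(rule("A", "C"), M, B)
        assert out.value == pytest.approx(1.0)
        assert out.p2_bg == pytest.approx(out.p2_ac)

    def test_planted_pair_outranks_noise_rules(self):
        M, B = _planted_matrix(seed=9)
        genes = list(M.columns)
        scores = {}
        for a in genes:
            for c in genes:
                if a != c:
                    scores[(a, c)] = lamda3_score(rule(a, c), M, B).value
        assert scores[("A", "C")] is not None and scores[("A", "C")] > 1
        best = max(
            (v for v in scores.values() if v is not None), default=None
        )
        assert scores[("A", "C")] == best

    def test_toy_matrix_degenerate_partition_is_na(
        self, toy_continuous, toy_binary
    ):
        # both_zero has 2 samples < MIN_PARTITION
        out = lamda3_score(rule("NEK2", "CDKN3"), toy_continuous, toy_binary)
        assert out.value is None
        assert len(partition_samples("NEK2", "CDKN3", toy_binary).both_zero) \
            < MIN_PARTITION

    def test_matches_independent_transcription(self, random_matrix_pair):
        for seed in range(20):
            M, B = random_matrix_pair(seed)
            genes = list(M.columns)
            for a, c in [(genes[i], genes[j]) for i in range(4) for j in range(4)
                         if i != j]:
                got = lamda3_score(rule(a, c), M, B).value
                ref = lamda3_reference(a, c, M, B)
                if ref is None:
                    assert got is None
                else:
                    assert got == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_sample_order(self, random_matrix_pair):
        M, B = random_matrix_pair(77)
        perm = np.random.default_rng(0).permutation(len(M))
        a = lamda3_score(rule("g00", "g01"), M, B).value
        b = lamda3_score(rule("g00", "g01"), M.iloc[perm], B.iloc[perm]).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_pearson_scale_invariance(self, random_matrix_pair):
        M, B = random_matrix_pair(13)
        scaled = M * np.linspace(0.5, 40, M.shape[1])
        a = lamda3_score(rule("g00", "g01"), M, B).value
        b = lamda3_score(rule("g00", "g01"), scaled, B).value
        assert a == pytest.approx(b, abs=1e-9)

    def test_multi_gene_lhs_uses_lower_median_pair(self, random_matrix_pair):
        M, B = random_matrix_pair(21, m=40, n=6)
        r = Rule(("g00", "g01"), ("g02",), RuleMetrics(0.5, 1.0, 1.0))
        out = lamda3_score(r, M, B)
        pair_values = [
            lamda3_score(rule(a, "g02"), M, B).value for a in ("g00", "g01")
        ]
        defined = sorted(v for v in pair_values if v is not None)
        if defined:
            assert out.value == pytest.approx(defined[(len(defined) - 1) // 2])
            assert out.pair[0] in ("g00", "g01")
        else:
            assert out.value is None

    def test_misaligned_matrices_rejected(self, random_matrix_pair):
        M, B = random_matrix_pair(1)
        with pytest.raises(Exception, match="sample IDs"):
            lamda3_score(rule("g00", "g01"), M, B.iloc[::-1])


class TestWcs:
    def test_unit_weights_reduce_to_support(self, toy_binary):
        its = apriori_frequent_itemsets(toy_binary, 0.6)
        for r in generate_rules(its, toy_binary, 0.8, 1):
            assert wcs_score(r, toy_binary) == pytest.approx(r.metrics.support)

    def test_hand_computed_weighted_case(self, toy_binary):
        r = rule("NEK2", "CDKN3")
        w = {"NEK2": 1.0, "CDKN3": 0.5}
        assert wcs_score(r, toy_binary, w) == pytest.approx(0.6 * 0.75)

    def test_zero_support_rule_scores_zero(self, toy_binary):
        # TPX2 and CKS1B never co-occur in the toy matrix
        assert wcs_score(rule("TPX2", "CKS1B"), toy_binary) == pytest.approx(0.2)
        B = toy_binary.copy()
        B["CKS1B"] = 0
        assert wcs_score(rule("TPX2", "CKS1B"), B) == 0.0

    def test_missing_weight_rejected(self, toy_binary):
        with pytest.raises(KeyError, match="CDKN3"):
            wcs_score(rule("NEK2", "CDKN3"), toy_binary, {"NEK2": 1.0})

    def test_rank_weights_mapping(self):
        w = rank_weights(["top", "mid", "last"])
        assert w == {"top": 1.0, "mid": 2 / 3, "last": 1 / 3}


class TestRankRules:
    def test_toy_rules_ranked_by_support_with_tie_break(self, toy_binary):
        its = apriori_frequent_itemsets(toy_binary, 0.6)
        rules = generate_rules(its, toy_binary, 0.8, 1)
        ranked = rank_rules(rules, "support", top_k=20)
        assert len(ranked) == 9
        keys = [
            (-r.metrics.lift, -r.metrics.support, r.lhs, r.rhs) for r in ranked
        ]
        assert keys == sorted(keys)

    def test_na_values_rank_last(self):
        rs = [
            rule("a", "b").with_metrics(lamda3=2.0),
            rule("c", "d").with_metrics(lamda3=None),
            rule("e", "f").with_metrics(lamda3=1.1),
        ]
        top = rank_rules(rs, "lamda3", top_k=2)
        assert [r.metrics.lamda3 for r in top] == [2.0, 1.1]

    def test_top_one(self):
        rs = [rule("a", "b").with_metrics(lamda3=0.5),
              rule("c", "d").with_metrics(lamda3=3.0)]
        assert rank_rules(rs, "lamda3", 1)[0].lhs == ("c",)

    def test_score_rules_fills_metrics(self, random_matrix_pair):
        M, B = random_matrix_pair(3, m=40, n=5)
        its = apriori_frequent_itemsets(B, 0.2)
        rules = generate_rules(its, B, 0.5, 1)
        scored = score_rules(rules, M, B)
        assert len(scored) == len(rules)
        for r in scored:
            assert r.metrics.wcs == pytest.approx(r.metrics.support)
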