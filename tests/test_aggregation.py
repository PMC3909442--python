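"""Concordance statistic, permutation/exact nulls, and the aggregation test."""

import math
from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famagg import (
    FamilialAggregation,
    FamilyTable,
    concordance_statistic,
    empirical_pvalue,
    exact_null,
    permutation_null,
    run_aggregation_test,
)
from famagg.aggregation import n_distinct_arrangements


def brute_force_null(labels, sizes):
    """Oracle: full enumeration over ordered permutations of the labels."""
    tally = Counter()
    n = 0
    for arr in set(permutations(labels)):
        stat, i = 0, 0
        for k in sizes:
            fam = arr[i : i + k]
            i += k
            if max(Counter(fam).values()) >= 2:
                stat += 1
        tally[stat] += 1
        n += 1
    return {s: c / n for s, c in tally.items()}


class TestConcordanceStatistic:
    def test_discovery_families_have_eight_concordant(self, table3):
        families, labels = table3
        assert concordance_statistic(families, labels) == 8

    def test_confirmation_two_case_families(self, table4):
        families, labels = table4
        two_case = FamilyTable({f: s for f, s in families if f in ("L101", "L414", "L505")})
        assert concordance_statistic(two_case, labels) == 3

    def test_confirmation_all_families_counts_the_normal_like_pair(self, table4):
        # the trio with two Normal-like tumors is concordant by definition
        families, labels = table4
        assert concordance_statistic(families, labels) == 4

    def test_singleton_families_never_contribute(self):
        fams = FamilyTable({"a": ["s1"], "b": ["s2"], "c": ["s3"]})
        labels = {"s1": "X", "s2": "X", "s3": "X"}
        assert concordance_statistic(fams, labels) == 0

    def test_missing_label_names_the_sample(self):
        fams = FamilyTable({"a": ["s1", "s2"]})
        with pytest.raises(ValueError, match="s2"):
            concordance_statistic(fams, {"s1": "X"})

    @given(st.permutations(["Basal-like", "LumA", "LumA", "LumB", "LumB", "LumB"]))
    @settings(deadline=None, max_examples=25)
    def test_relabeling_families_and_subtypes_is_invariant(self, labs):
        fams = FamilyTable({"f1": ["a", "b"], "f2": ["c", "d"], "f3": ["e", "g"]})
        labels = dict(zip("abcdeg", labs))
        stat = concordance_statistic(fams, labels)
        # bijective rename of subtypes and permuted family ids
        rename = {"Basal-like": "z1", "LumA": "z2", "LumB": "z3"}
        fams2 = FamilyTable({"f3": ["a", "b"], "f1": ["c", "d"], "f2": ["e", "g"]})
        labels2 = {s: rename[v] for s, v in labels.items()}
        assert concordance_statistic(fams2, labels2) == stat


class TestFamilyTable:
    def test_duplicate_sample_across_families_rejected(self):
        with pytest.raises(ValueError, match="more than one family"):
            FamilyTable({"a": ["s1"], "b": ["s1"]})

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            FamilyTable({"a": []})


class TestExactNull:
    def test_toy_pair_concordance_is_one_third(self):
        null = exact_null(list("AABB"), [2, 2])
        assert dict(zip(null.support, null.mass)) == pytest.approx({0: 2 / 3, 2: 1 / 3})

    def test_all_singletons_is_point_mass_at_zero(self):
        null = exact_null(list("ABCD"), [1, 1, 1, 1])
        assert null.support == (0,) and null.mass == (1.0,)

    def test_identical_labels_forced_to_maximum(self):
        null = exact_null(["X"] * 4, [2, 2])
        assert null.support == (2,) and null.mass == (1.0,)

    @pytest.mark.parametrize(
        "labels,sizes",
        [
            (list("AABBC"), [2, 3]),
            (list("AAABBC"), [2, 2, 2]),
            (list("ABCDAB"), [1, 2, 3]),
        ],
    )
    def test_matches_full_enumeration(self, labels, sizes):
        expected = brute_force_null(labels, sizes)
        null = exact_null(labels, sizes)
        got = dict(zip(null.support, null.mass))
        assert set(got) == set(expected)
        for s, p in expected.items():
            assert got[s] == pytest.approx(p, abs=1e-12)

    def test_confirmation_table_null_matches_enumeration_oracle(self, table4):
        # frozen from an independent full enumeration over all 831,600
        # distinct arrangements of the 12-label multiset into sizes 2,2,2,3,3
        families, labels = table4
        model = FamilialAggregation(families, labels)
        null = model.null_distribution(method="exact")
        frozen = {
            0: 0.16173160173160173,
            1: 0.4024242424242424,
            2: 0.3189033189033189,
            3: 0.10002886002886002,
            4: 0.015786435786435786,
            5: 0.0011255411255411255,
        }
        got = dict(zip(null.support, null.mass))
        assert got == pytest.approx(frozen, abs=1e-12)

    def test_budget_exceeded_suggests_monte_carlo(self, table3):
        families, labels = table3
        model = FamilialAggregation(families, labels)
        # 23 labels with counts (3,2,9,8,1): ~1.5e11 distinct arrangements
        with pytest.raises(ValueError, match="Monte Carlo"):
            model.null_distribution(method="exact")

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels supplied"):
            exact_null(list("AAB"), [2, 2])


class TestPermutationNull:
    def test_point_mass_when_all_labels_identical(self):
        null = permutation_null(["X"] * 4, [2, 2], n_replicates=500, seed=3)
        assert null.support == (2,) and null.mass == (1.0,)

    def test_toy_pair_frequencies_within_monte_carlo_error(self):
        null = permutation_null(list("AABB"), [2, 2], n_replicates=100_000, seed=11)
        got = dict(zip(null.support, null.mass))
        se = math.sqrt((1 / 3) * (2 / 3) / 100_000)
        assert got[2] == pytest.approx(1 / 3, abs=3 * se)
        assert got[0] == pytest.approx(2 / 3, abs=3 * se)

    def test_reproducible_given_seed(self):
        a = permutation_null(list("AABBCC"), [2, 2, 2], n_replicates=2000, seed=5)
        b = permutation_null(list("AABBCC"), [2, 2, 2], n_replicates=2000, seed=5)
        assert a == b

    def test_agrees_with_exact_null_within_three_standard_errors(self, table4):
        families, labels = table4
        model = FamilialAggregation(families, labels)
        exact = model.null_distribution(method="exact")
        mc = model.null_distribution(n_replicates=100_000, seed=2)
        exact_mass = dict(zip(exact.support, exact.mass))
        mc_mass = dict(zip(mc.support, mc.mass))
        for s, p in exact_mass.items():
            se = math.sqrt(p * (1 - p) / 100_000)
            assert mc_mass.get(s, 0.0) == pytest.approx(p, abs=max(3 * se, 1e-12)), s

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="labels supplied"):
            permutation_null(list("AAB"), [2, 2], n_replicates=10, seed=0)


class TestEmpiricalPvalue:
    def test_observed_zero_gives_one(self):
        null = exact_null(list("AABB"), [2, 2])
        assert empirical_pvalue(null, 0) == 1.0

    def test_toy_observed_two_gives_one_third(self):
        null = exact_null(list("AABB"), [2, 2])
        assert empirical_pvalue(null, 2) == pytest.approx(1 / 3)

    def test_observed_beyond_support_gives_zero(self):
        null = exact_null(list("AABB"), [2, 2])
        assert empirical_pvalue(null, 3) == 0.0

    def test_add_one_convention_is_opt_in(self):
        null = permutation_null(list("AABB"), [2, 2], n_replicates=1000, seed=0)
        plain = empirical_pvalue(null, 2)
        shifted = empirical_pvalue(null, 2, add_one=True)
        assert shifted == pytest.approx((round(plain * 1000) + 1) / 1001)

    def test_add_one_rejected_for_exact_null(self):
        null = exact_null(list("AABB"), [2, 2])
        with pytest.raises(ValueError, match="Monte-Carlo"):
            empirical_pvalue(null, 2, add_one=True)


class TestAggregationModel:
    def test_discovery_pvalue_near_headline(self, table3):
        families, labels = table3
        res = FamilialAggregation(families, labels).fit(n_replicates=100_000, seed=1)
        assert res.observed_statistic == 8
        assert 0.001 <= res.p_value <= 0.003

    def test_confirmation_pvalue_exact(self, table4):
        families, labels = table4
        res = FamilialAggregation(families, labels).fit(method="exact")
        assert res.observed_statistic == 4
        assert res.p_value == pytest.approx(0.016912, abs=1e-5)

    def test_adding_singleton_families_changes_nothing(self, table3):
        families, labels = table3
        base = run_aggregation_test(families, labels, n_replicates=5000, seed=9)
        extended = dict(families.members)
        extended.update({f"solo{i}": (f"x{i}",) for i in range(5)})
        labels2 = dict(labels, **{f"x{i}": "LumA" for i in range(5)})
        again = run_aggregation_test(FamilyTable(extended), labels2,
                                     n_replicates=5000, seed=9)
        assert again.observed_statistic == base.observed_statistic
        assert again.p_value == base.p_value
        assert again.null == base.null

    def test_all_samples_policy_uses_every_family(self, table3):
        families, labels = table3
        extended = dict(families.members)
        extended["solo"] = ("x0",)
        labels2 = dict(labels, x0="LumA")
        model = FamilialAggregation(FamilyTable(extended), labels2,
                                    pool_policy="all_samples")
        res = model.fit(n_replicates=2000, seed=0)
        assert len(res.family_sizes) == 12
        assert sum(res.family_sizes) == 24

    def test_no_multicase_family_is_an_error(self):
        fams = FamilyTable({"a": ["s1"], "b": ["s2"]})
        with pytest.raises(ValueError, match="two or more"):
            FamilialAggregation(fams, {"s1": "X", "s2": "Y"})

    def test_report_records_provenance(self, table4):
        families, labels = table4
        res = FamilialAggregation(families, labels).fit(n_replicates=3000, seed=42)
        d = res.as_dict()
        assert d["seed"] == 42
        assert d["n_replicates"] == 3000
        assert d["pool_policy"] == "multicase_only"
        assert sum(d["null"]["mass"]) == pytest.approx(1.0)

    def test_summary_mentions_observed_and_p(self, table4):
        families, labels = table4
        res = FamilialAggregation(families, labels).fit(method="exact")
        text = res.summary()
        assert "4" in text and "0.0169" in text


def test_arrangement_count_is_multinomial():
    assert n_distinct_arrangements([2, 2]) == 6
    assert n_distinct_arrangements([4, 1, 3, 2, 2]) == 831_600
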