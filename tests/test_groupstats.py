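"""Histology test batteries: Grubbs, Kruskal-Wallis + Dunn, pairwise tests,
Ward dendrograms — each checked against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from camfate.errors import InsufficientDataError
from camfate.groupstats import (
    grubbs_critical_value,
    grubbs_screen,
    kruskal_dunn,
    pairwise_tests,
    ward_profile_dendrogram,
)
from camfate.multitest import holm, stars


class TestGrubbs:
    def test_extreme_value_removed(self):
        kept, removed = grubbs_screen([1.0, 1.1, 0.9, 1.05, 8.0])
        assert removed.tolist() == [8.0]
        assert sorted(kept.tolist()) == [0.9, 1.0, 1.05, 1.1]

    def test_g_statistic_vs_t_quantile_critical_value(self):
        # oracle: recompute G and the critical value from first principles
        x = np.array([1.0, 1.1, 0.9, 1.05, 8.0])
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        n = x.size
        t = sps.t.ppf(1 - 0.05 / (2 * n), n - 2)
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert g > crit  # hence removal
        assert grubbs_critical_value(n, 0.05) == pytest.approx(crit)

    def test_tight_cluster_unchanged(self):
        values = [1.0, 1.05, 0.95, 1.02, 0.98]
        kept, removed = grubbs_screen(values)
        assert removed.size == 0
        assert kept.tolist() == values

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            grubbs_screen([1.0, 2.0])

    def test_screen_is_iterative(self):
        # two separated outliers, removed one at a time
        kept, removed = grubbs_screen([1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 30.0, 60.0])
        assert sorted(removed.tolist()) == [30.0, 60.0]
        assert kept.size == 6


class TestKruskalDunn:
    def test_identical_observations_yield_null_result(self):
        overall, pairwise = kruskal_dunn({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        assert overall.statistic == 0.0
        assert overall.p_raw == 1.0
        assert all(r.p_adj == pytest.approx(1.0) for r in pairwise)

    def test_h_statistic_matches_rank_sum_oracle(self):
        # untied groups {1,2,3},{4,5,6},{7,8,9}: ranks are the values, so
        # H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1) = 7.2 exactly
        overall, _ = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        rank_sums = [6.0, 15.0, 24.0]
        h_oracle = 12.0 / (9 * 10) * sum(r**2 / 3 for r in rank_sums) - 3 * 10
        assert h_oracle == pytest.approx(7.2)
        assert overall.statistic == pytest.approx(h_oracle)
        assert overall.p_raw == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_dunn_z_matches_hand_computation(self):
        # same fixture: mean ranks 2, 5, 8; no ties so the tie term vanishes
        _, pairwise = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        denom = np.sqrt((9 * 10 / 12.0) * (1 / 3 + 1 / 3))
        by_pair = {r.comparison: r for r in pairwise}
        assert by_pair[("a", "b")].statistic == pytest.approx((2 - 5) / denom)
        assert by_pair[("a", "c")].statistic == pytest.approx((2 - 8) / denom)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i, 1, 6) for i, k in enumerate("abcd")}
        _, pairwise = kruskal_dunn(groups)
        assert all(r.p_adj >= r.p_raw for r in pairwise)


class TestPairwiseTests:
    def test_exact_mann_whitney_on_fully_separated_triples(self):
        results = pairwise_tests(
            {"ref": [4.0, 5.0, 6.0], "g": [1.0, 2.0, 3.0]},
            method="mwu_vs_reference",
            reference="ref",
        )
        (r,) = results
        assert r.statistic == 0.0  # U of the non-reference group
        assert r.p_raw == pytest.approx(0.1)  # 2/20 arrangements by enumeration

    def test_group_identical_to_reference_is_not_significant(self):
        results = pairwise_tests(
            {"ref": [1.0, 2.0, 3.0, 4.0], "g": [1.0, 2.0, 3.0, 4.0]},
            method="mwu_vs_reference",
            reference="ref",
        )
        assert results[0].p_raw > 0.9

    def test_one_result_per_non_reference_group(self):
        groups = {k: [1.0, 2.0, 3.0] for k in "abcde"}
        results = pairwise_tests(groups, method="mwu_vs_reference", reference="a")
        assert len(results) == 4
        assert all(r.comparison[1] == "a" for r in results)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            pairwise_tests({"a": [1.0, 2.0]}, method="mwu_vs_reference", reference="zz")

    def test_welch_battery_covers_all_pairs_with_holm(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 1, 5) for i, k in enumerate("abcd")}
        results = pairwise_tests(groups, method="t_all_pairs")
        assert len(results) == 6
        assert all(r.adjustment == "holm" for r in results)
        assert all(r.p_adj >= r.p_raw for r in results)
        # spot-check one pair against scipy's Welch test directly
        r_ab = next(r for r in results if r.comparison == ("a", "b"))
        oracle = sps.ttest_ind(groups["a"], groups["b"], equal_var=False)
        assert r_ab.p_raw == pytest.approx(oracle.pvalue)

    @given(st.permutations(["a", "b", "c"]))
    def test_results_invariant_under_group_order(self, order):
        base = {"a": [1.0, 5.0, 3.0], "b": [2.0, 8.0, 4.0], "c": [9.0, 7.0, 6.0]}
        reference = {r.comparison: r.p_raw for r in pairwise_tests(base)}
        shuffled = pairwise_tests({k: base[k] for k in order})
        for r in shuffled:
            key = r.comparison if r.comparison in reference else r.comparison[::-1]
            assert r.p_raw == pytest.approx(reference[key])

    @given(
        x=st.lists(st.integers(-50, 50), min_size=4, max_size=8, unique=True),
        y=st.lists(st.integers(-50, 50), min_size=4, max_size=8, unique=True),
    )
    def test_rank_tests_invariant_under_monotone_transform(self, x, y):
        # integer inputs keep exp(v/50) strictly monotone in floating point
        groups = {"ref": [float(v) for v in y], "g": [float(v) for v in x]}
        transformed = {k: np.exp(np.asarray(v) / 50.0) for k, v in groups.items()}
        p_before = pairwise_tests(groups, "mwu_vs_reference", reference="ref")[0].p_raw
        p_after = pairwise_tests(transformed, "mwu_vs_reference", reference="ref")[0].p_raw
        assert p_before == pytest.approx(p_after)


class TestHolm:
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_holm_matches_step_down_reference(self, p_values):
        adjusted = holm(p_values)
        # independent step-down reference: running max of (m - i) * p_(i)
        p = np.asarray(p_values)
        order = np.argsort(p)
        m = p.size
        running, ref_sorted = 0.0, []
        for i, idx in enumerate(order):
            running = max(running, (m - i) * p[idx])
            ref_sorted.append(min(1.0, running))
        reference = np.empty(m)
        reference[order] = ref_sorted
        assert np.allclose(adjusted, reference)
        assert np.all(adjusted <= 1.0)
        assert np.all(adjusted >= p)

    def test_star_thresholds(self):
        assert stars(0.0005) == "***"
        assert stars(0.004) == "**"
        assert stars(0.04) == "*"
        assert stars(0.2) == "ns"


def _ward_oracle(profiles: np.ndarray, labels: list[str]):
    """Greedy Ward agglomeration recomputed from scratch each step.

    Merge cost between clusters A, B is sqrt(2 |A||B| / (|A|+|B|)) * ||mean_A
    - mean_B||, the scipy height convention for Ward linkage.
    """
    clusters = [(frozenset([lab]), profiles[i]) for i, lab in enumerate(labels)]
    merges = []
    while len(clusters) > 1:
        best = None
        for (i, (a, ma)), (j, (b, mb)) in itertools.combinations(enumerate(clusters), 2):
            cost = np.sqrt(2 * len(a) * len(b) / (len(a) + len(b))) * np.linalg.norm(ma - mb)
            if best is None or cost < best[0]:
                best = (cost, i, j)
        cost, i, j = best
        (a, ma), (b, mb) = clusters[i], clusters[j]
        merged = a | b
        mean = (len(a) * ma + len(b) * mb) / len(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, mean))
        merges.append((merged, cost))
    return merges


def _merges_from_linkage(dendrogram):
    n = len(dendrogram.labels)
    members = {i: frozenset([dendrogram.labels[i]]) for i in range(n)}
    merges = []
    for step, (a, b, height, _) in enumerate(dendrogram.merges):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append((merged, height))
    return merges


class TestWardDendrogram:
    def test_identical_rows_merge_first_at_height_zero(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], index=["a", "b", "c"]
        )
        dendrogram = ward_profile_dendrogram(profiles)
        first = _merges_from_linkage(dendrogram)[0]
        assert first[0] == frozenset({"a", "b"})
        assert first[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_rows_give_single_merge(self):
        profiles = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        dendrogram = ward_profile_dendrogram(profiles)
        assert dendrogram.merges.shape == (1, 4)
        assert dendrogram.heights[0] == pytest.approx(5.0)

    def test_four_profiles_match_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(4, 3))
        profiles = pd.DataFrame(values, index=list("abcd"))
        dendrogram = ward_profile_dendrogram(profiles)
        got = _merges_from_linkage(dendrogram)
        expected = _ward_oracle(values, list("abcd"))
        for (set_got, h_got), (set_exp, h_exp) in zip(got, expected):
            assert set_got == set_exp
            assert h_got == pytest.approx(h_exp)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(13)
        profiles = pd.DataFrame(rng.normal(size=(6, 4)))
        heights = ward_profile_dendrogram(profiles).heights
        assert np.all(np.diff(heights) >= -1e-12)

    def test_missing_entries_rejected(self):
        profiles = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            ward_profile_dendrogram(profiles)
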