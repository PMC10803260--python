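"""Histology-quantification test batteries and profile dendrograms.

The in situ quantifications (cells per mm of leptomeninges, percent
double-positive cells per compartment, marker regulation in donor- vs
host-derived cells) are small per-patient samples compared across groups.
This module bundles the standard battery applied to them:

* iterative two-sided Grubbs screening of outliers within a group,
* Kruskal–Wallis followed by Dunn's pairwise z-tests with Holm–Bonferroni
  adjustment,
* pairwise Mann–Whitney U-tests against a reference group (exact for small
  untied samples) or Welch t-tests over all pairs with Holm adjustment,
* Ward minimum-variance dendrograms of mean marker-expression profiles.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .errors import InsufficientDataError
from .multitest import holm, stars

__all__ = [
    "TestResult",
    "grubbs_screen",
    "grubbs_critical_value",
    "kruskal_dunn",
    "pairwise_tests",
    "WardDendrogram",
    "ward_profile_dendrogram",
]


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: groups, statistic, raw/adjusted p, stars."""

    comparison: tuple[str, ...]
    statistic: float
    p_raw: float
    p_adj: float
    method: str
    adjustment: str
    stars: str


def _results_with_adjustment(
    comparisons: list[tuple[str, ...]],
    statistics: list[float],
    p_raws: list[float],
    method: str,
    adjustment: str,
) -> list[TestResult]:
    if adjustment == "holm":
        p_adjs = holm(p_raws)
    elif adjustment == "none":
        p_adjs = np.asarray(p_raws, dtype=float)
    else:
        raise ValueError(f"adjustment: expected 'none' or 'holm', got {adjustment!r}")
    return [
        TestResult(
            comparison=cmp,
            statistic=float(stat),
            p_raw=float(p),
            p_adj=float(pa),
            method=method,
            adjustment=adjustment,
            stars=stars(float(pa)),
        )
        for cmp, stat, p, pa in zip(comparisons, statistics, p_raws, p_adjs)
    ]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile formula."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier screen.

    The most extreme value (largest |x - mean| / sd) is removed whenever its
    G statistic exceeds the two-sided critical value at ``alpha``; the test
    repeats on the remainder until no rejection (or fewer than 3 values
    remain). Returns ``(kept, removed)`` arrays in original order of
    appearance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"Grubbs's test needs n >= 3, got {x.size}")
    kept = list(x)
    removed: list[float] = []
    while len(kept) >= 3:
        arr = np.asarray(kept)
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(arr - arr.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        if g > grubbs_critical_value(len(kept), alpha):
            removed.append(kept.pop(idx))
        else:
            break
    return np.asarray(kept), np.asarray(removed)


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal–Wallis omnibus test plus Dunn pairwise z-tests (Holm-adjusted).

    Dunn's z for groups i, j uses mean pooled ranks with the tie correction

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where ``T`` is the sum of ``t^3 - t`` over tied values. All pairs are
    adjusted together with Holm–Bonferroni. If every observation is
    identical, the omnibus result is H = 0, p = 1 and no pair rejects.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(labels) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs >= 2 groups")
    if any(s.size < 1 for s in samples):
        raise InsufficientDataError("every group needs >= 1 observation")
    pooled = np.concatenate(samples)
    if pooled.size < 3:
        raise InsufficientDataError("Kruskal-Wallis needs >= 3 observations in total")

    if np.all(pooled == pooled[0]):
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = stats.kruskal(*samples)
    overall = TestResult(
        comparison=tuple(labels),
        statistic=float(h_stat),
        p_raw=float(p_omni),
        p_adj=float(p_omni),
        method="kruskal-wallis",
        adjustment="none",
        stars=stars(float(p_omni)),
    )

    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        start += s.size
    tie = _tie_term(pooled)
    var_factor = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))

    comparisons, zs, p_raws = [], [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        denom = np.sqrt(var_factor * (1.0 / samples[i].size + 1.0 / samples[j].size))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        comparisons.append((labels[i], labels[j]))
        zs.append(z)
        p_raws.append(float(2 * stats.norm.sf(abs(z))))
    pairwise = _results_with_adjustment(comparisons, zs, p_raws, "dunn", "holm")
    return overall, pairwise


def pairwise_tests(
    groups: Mapping[str, Sequence[float]],
    method: str = "t_all_pairs",
    reference: "str | None" = None,
    adjustment: "str | None" = None,
) -> list[TestResult]:
    """Pairwise group comparisons in either of the two study designs.

    ``mwu_vs_reference`` — two-sided Mann–Whitney U of every non-reference
    group against ``reference`` (exact null distribution when the combined
    sample is small and untied, tie-corrected normal approximation
    otherwise); unadjusted by default.

    ``t_all_pairs`` — Welch (unequal-variance) two-sided t-tests over all
    group pairs; Holm–Bonferroni adjusted by default.
    """
    labels = list(groups)
    samples = {g: np.asarray(groups[g], dtype=float) for g in labels}

    if method == "mwu_vs_reference":
        if reference is None or reference not in samples:
            raise ValueError(f"reference group {reference!r} not present in groups")
        adjustment = adjustment or "none"
        ref = samples[reference]
        comparisons, stats_list, p_raws = [], [], []
        for g in labels:
            if g == reference:
                continue
            x = samples[g]
            combined = np.concatenate([x, ref])
            exact = combined.size <= 12 and np.unique(combined).size == combined.size
            res = stats.mannwhitneyu(
                x, ref, alternative="two-sided", method="exact" if exact else "asymptotic"
            )
            comparisons.append((g, reference))
            stats_list.append(float(res.statistic))
            p_raws.append(float(res.pvalue))
        return _results_with_adjustment(
            comparisons, stats_list, p_raws, "mann-whitney", adjustment
        )

    if method == "t_all_pairs":
        adjustment = adjustment or "holm"
        if any(s.size < 2 for s in samples.values()):
            raise InsufficientDataError("t-tests need >= 2 observations per group")
        comparisons, stats_list, p_raws = [], [], []
        for a, b in itertools.combinations(labels, 2):
            res = stats.ttest_ind(samples[a], samples[b], equal_var=False)
            comparisons.append((a, b))
            stats_list.append(float(res.statistic))
            p_raws.append(float(res.pvalue))
        return _results_with_adjustment(
            comparisons, stats_list, p_raws, "welch-t", adjustment
        )

    raise ValueError(f"method: expected 'mwu_vs_reference' or 't_all_pairs', got {method!r}")


def results_frame(results: "Sequence[TestResult]") -> pd.DataFrame:
    """Tidy DataFrame view of a list of :class:`TestResult`."""
    return pd.DataFrame(
        [
            {
                "comparison": " vs ".join(r.comparison),
                "method": r.method,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "adjustment": r.adjustment,
                "stars": r.stars,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class WardDendrogram:
    """Ward merge tree over labelled profiles (scipy linkage encoding)."""

    labels: tuple[str, ...]
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def ward_profile_dendrogram(mean_profiles: pd.DataFrame) -> WardDendrogram:
    """Hierarchical clustering of mean expression profiles (Ward / Euclidean).

    ``mean_profiles`` is a groups x markers matrix of mean expressions, one
    row per cell type or compartment. Missing entries are rejected — no
    imputation. Heights are non-decreasing along the merge sequence (a Ward
    guarantee).
    """
    if mean_profiles.shape[0] < 2:
        raise InsufficientDataError("dendrogram needs >= 2 profiles")
    values = mean_profiles.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("mean_profiles contains missing entries; no imputation is done")
    merges = linkage(values, method="ward")
    return WardDendrogram(labels=tuple(str(i) for i in mean_profiles.index), merges=merges)
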