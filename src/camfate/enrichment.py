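"""Cluster-composition enrichment by one-sided hypergeometric tests.

Given a clusters x conditions cell-count table, each (cluster, condition)
pair is tested for over-representation: with N cells in total, K of the
condition, and a cluster of size n containing k condition cells, the
upper-tail probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

is computed by exact tail summation in log space (no normal approximation,
so small clusters are handled correctly). The Benjamini–Hochberg step-up
correction is applied across the full cluster x condition family, and
significance stars follow the usual 0.05 / 0.01 / 0.001 thresholds on the
adjusted p. A Marimekko-ready summary (per-cluster condition proportions
with widths proportional to cluster size) accompanies the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .multitest import benjamini_hochberg, stars

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "hypergeom_enrichment",
    "HypergeomEnrichment",
    "marimekko_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One (cluster, condition) enrichment test."""

    cluster: str
    condition: str
    k: int  # condition cells in the cluster
    n: int  # cluster size
    K: int  # condition total
    N: int  # grand total
    p_raw: float
    p_adj: float
    stars: str


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space.

    By the upper-tail definition, P(X >= 0) = 1; values of ``k`` at or below
    the distribution's lower support bound likewise give exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    support_lo = max(0, n + K - N)
    support_hi = min(n, K)
    if k <= support_lo:
        return 1.0
    if k > support_hi:
        return 0.0
    ks = np.arange(k, support_hi + 1)
    log_p = logsumexp(stats.hypergeom.logpmf(ks, N, K, n))
    return float(min(1.0, np.exp(log_p)))


def _lower_tail(N: int, K: int, n: int, k: int) -> float:
    support_hi = min(n, K)
    if k >= support_hi:
        return 1.0
    ks = np.arange(max(0, n + K - N), k + 1)
    return float(min(1.0, np.exp(logsumexp(stats.hypergeom.logpmf(ks, N, K, n)))))


def _validate_table(table: pd.DataFrame) -> np.ndarray:
    counts = table.to_numpy()
    if counts.size == 0:
        raise ValueError("composition table is empty")
    if np.isnan(counts.astype(float)).any() or (counts < 0).any():
        raise ValueError("composition table must contain non-negative counts")
    if not np.allclose(counts, np.round(counts.astype(float))):
        raise ValueError("composition table must contain integer counts")
    counts = counts.astype(np.int64)
    if counts.sum() == 0:
        raise ValueError("composition table has no cells")
    return counts


def hypergeom_enrichment(
    table: pd.DataFrame, alpha: float = 0.05, depletion: bool = False
) -> list[EnrichmentResult]:
    """Test every (cluster, condition) pair of a composition table.

    ``table`` is a clusters x conditions DataFrame of non-negative integer
    counts. One-sided enrichment (upper tail) by default; ``depletion=True``
    switches to the lower tail. BH adjustment spans the entire cluster x
    condition family.
    """
    counts = _validate_table(table)
    N = int(counts.sum())
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)

    records = []
    for i, cluster in enumerate(table.index):
        for j, condition in enumerate(table.columns):
            k, n, K = int(counts[i, j]), int(row_totals[i]), int(col_totals[j])
            tail = _lower_tail if depletion else hypergeom_upper_tail
            records.append((str(cluster), str(condition), k, n, K, tail(N, K, n, k)))

    p_adj = benjamini_hochberg([r[5] for r in records])
    return [
        EnrichmentResult(
            cluster=cl,
            condition=co,
            k=k,
            n=n,
            K=K,
            N=N,
            p_raw=p,
            p_adj=float(pa),
            stars=stars(float(pa)),
        )
        for (cl, co, k, n, K, p), pa in zip(records, p_adj)
    ]


def enrichment_frame(results: "list[EnrichmentResult]") -> pd.DataFrame:
    """Tidy DataFrame view of enrichment results."""
    return pd.DataFrame([r.__dict__ for r in results])


def marimekko_table(table: pd.DataFrame) -> pd.DataFrame:
    """Marimekko-ready long table of condition proportions and cluster widths.

    Each row carries the proportion of a cluster's cells belonging to a
    condition and the cluster's width (its share of all cells), so a mosaic
    chart can be drawn directly.
    """
    counts = _validate_table(table).astype(float)
    n_total = counts.sum()
    widths = counts.sum(axis=1) / n_total
    rows = []
    for i, cluster in enumerate(table.index):
        row_total = counts[i].sum()
        for j, condition in enumerate(table.columns):
            proportion = counts[i, j] / row_total if row_total > 0 else 0.0
            rows.append(
                {
                    "cluster": str(cluster),
                    "condition": str(condition),
                    "proportion": proportion,
                    "cluster_width": float(widths[i]),
                }
            )
    return pd.DataFrame(rows)


class HypergeomEnrichment(BaseEstimator):
    """Estimator wrapper for the enrichment family.

    Attributes after ``fit``:

    results_ : list of :class:`EnrichmentResult`
    frame_ : tidy DataFrame of the same results
    marimekko_ : Marimekko-ready proportions table
    """

    def __init__(self, alpha: float = 0.05, depletion: bool = False):
        self.alpha = alpha
        self.depletion = depletion

    def fit(self, table: pd.DataFrame, y=None) -> "HypergeomEnrichment":
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha: must lie in (0, 1), got {self.alpha}")
        self.results_ = hypergeom_enrichment(table, alpha=self.alpha, depletion=self.depletion)
        self.frame_ = enrichment_frame(self.results_)
        self.marimekko_ = marimekko_table(table)
        return self
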