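"""Multiple-testing adjustments and significance stars.

Thin wrappers over :func:`statsmodels.stats.multitest.multipletests` so that
every module in the package applies identical conventions: Holm step-down for
pairwise post-hoc batteries, Benjamini–Hochberg step-up for the enrichment
family, and the usual ``*``/``**``/``***`` star thresholds at 0.05 / 0.01 /
0.001.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values (never below the raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stars(p: float) -> str:
    """Significance label for a (possibly adjusted) p-value.

    ``***`` for p < 0.001, ``**`` for p < 0.01, ``*`` for p < 0.05, else ``ns``.
    """
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"
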