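"""Statistical utilities shared by the cohort-level analyses.

Thin, explicit wrappers over scipy/statsmodels: Benjamini-Hochberg (FDR)
and Hochberg (FWER) step-up adjustments, the two-tailed Fisher exact test,
and the two-tailed Mann-Whitney U comparison (exact for small samples,
normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UsageError


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hochberg_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Hochberg step-up adjusted p-values (FWER)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="simes-hochberg")[1]


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-tailed Fisher exact test on a 2x2 count table.

    Returns (odds_ratio, p_value). Negative cells are a usage error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise UsageError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise UsageError("2x2 table cells must be non-negative")
    odds_ratio, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds_ratio), float(p)


def enrichment_fisher(
    tables: Sequence[Sequence[Sequence[int]]],
) -> tuple[list[float], list[float], np.ndarray]:
    """Batched two-tailed Fisher exact tests with Hochberg correction.

    Returns (odds_ratios, raw_p, adjusted_p) across the batch.
    """
    odds, raw = [], []
    for t in tables:
        o, p = fisher_exact_2x2(t)
        odds.append(o)
        raw.append(p)
    return odds, raw, hochberg_adjust(raw)


def group_comparison(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max_n: int = 8,
) -> float:
    """Two-tailed Mann-Whitney U p-value comparing two groups.

    Uses the exact null distribution when both groups have at most
    exact_max_n observations and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UsageError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
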