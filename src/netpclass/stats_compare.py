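"""Pairwise statistical comparison of classification approaches.

For every ordered pair of methods, their per-PSN-set accuracies are
compared with a one-sided Wilcoxon signed-rank test ("is method i superior
to method j?"); the full collection of pairwise p-values is adjusted with
Benjamini-Hochberg false discovery rate control.  Cell (i, j) of the
resulting matrix is the q-value for i being superior to j; q < 0.05 is the
conventional significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_THRESHOLD = 0.05

#: Largest sample size for which the exact null distribution is used.
EXACT_N_MAX = 25


def wilcoxon_signed_rank(a, b, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for paired vectors.

    Zero differences are dropped (classical convention); the exact null
    distribution is used for n <= 25 remaining pairs, the normal
    approximation with continuity correction beyond that.  All-zero
    differences give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; no evidence either way")
        return 1.0
    method = "exact" if len(nonzero) <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(nonzero, alternative=alternative, zero_method="wilcox",
                         correction=True, method=method)
    return float(res.pvalue)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in the p ordering)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return q


@dataclass
class ComparisonMatrix:
    """Pairwise superiority q-values plus the raw ingredients."""

    methods: list
    q_values: pd.DataFrame
    p_values: pd.DataFrame
    accuracies: pd.DataFrame

    def significant(self, threshold: float = SIGNIFICANCE_THRESHOLD) -> pd.DataFrame:
        return self.q_values < threshold


def compare_methods(accuracy_table: pd.DataFrame) -> ComparisonMatrix:
    """All-pairs one-sided comparisons with a single FDR batch.

    Parameters
    ----------
    accuracy_table : DataFrame
        Rows = methods, columns = PSN sets, entries = accuracy on that set.
    """
    methods = list(accuracy_table.index)
    if len(methods) < 2 or accuracy_table.shape[1] < 2:
        raise ValueError("need >= 2 methods and >= 2 PSN sets")
    pairs = [(i, j) for i in methods for j in methods if i != j]
    raw = np.array([
        wilcoxon_signed_rank(accuracy_table.loc[i].to_numpy(),
                             accuracy_table.loc[j].to_numpy())
        for i, j in pairs
    ])
    q = fdr_adjust(raw)
    p_mat = pd.DataFrame(np.nan, index=methods, columns=methods)
    q_mat = pd.DataFrame(np.nan, index=methods, columns=methods)
    for (i, j), pv, qv in zip(pairs, raw, q):
        p_mat.loc[i, j] = pv
        q_mat.loc[i, j] = qv
    return ComparisonMatrix(methods, q_mat, p_mat, accuracy_table.copy())
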