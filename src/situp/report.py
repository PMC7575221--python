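"""Cohort tables and nonparametric group comparisons.

Continuous variables are compared with the two-sample Wilcoxon rank-sum test
(2 groups) or the Kruskal-Wallis test (3+ groups), categorical variables
with the Pearson chi-square test or Fisher's exact test (2x2); all tests are
two-sided.  The standard scipy.stats implementations stand behind this
surface; rank-sum p-values are exact (permutation) for small untied samples
and tie-corrected asymptotic otherwise.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["prevalence_table", "compare_groups", "test_association"]

logger = logging.getLogger(__name__)


def prevalence_table(records: pd.DataFrame, group_by: str,
                     flag_col: str = "oh", digits: int = 0) -> pd.DataFrame:
    """Per-stratum OH prevalence: n, n_oh, percent, plus a totals row.

    ``records`` needs the ``group_by`` column and a boolean ``flag_col``.
    Strata with n = 0 report NaN percent.
    """
    for col in (group_by, flag_col):
        if col not in records.columns:
            raise ValueError(f"records table missing column {col!r}")
    rows = []
    for stratum, grp in records.groupby(group_by, dropna=False, observed=True):
        n = len(grp)
        n_oh = int(grp[flag_col].sum())
        pct = round(100.0 * n_oh / n, digits) if n else np.nan
        rows.append({group_by: stratum, "n": n, "n_oh": n_oh, "percent": pct})
    n_tot = len(records)
    n_oh_tot = int(records[flag_col].sum())
    rows.append({
        group_by: "all", "n": n_tot, "n_oh": n_oh_tot,
        "percent": round(100.0 * n_oh_tot / n_tot, digits) if n_tot else np.nan,
    })
    return pd.DataFrame(rows)


def compare_groups(groups: list[np.ndarray] | dict, method: str = "auto"
                   ) -> tuple[float, float]:
    """(statistic, two-sided p) comparing >= 2 groups of a continuous variable.

    method 'rank_sum' (exactly 2 groups) uses the Mann-Whitney/Wilcoxon
    rank-sum test; 'kruskal_wallis' (2+ groups) the Kruskal-Wallis H test;
    'auto' picks by group count.  All-identical values return p = 1 with a
    warning instead of failing.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    if method == "auto":
        method = "rank_sum" if len(groups) == 2 else "kruskal_wallis"
    if method not in ("rank_sum", "kruskal_wallis"):
        raise ValueError(f"unknown method {method!r}")
    if method == "rank_sum" and len(groups) != 2:
        raise ValueError("rank_sum requires exactly 2 groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        logger.warning("all values identical across groups; p = 1")
        return 0.0, 1.0
    if method == "rank_sum":
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="auto")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def test_association(table: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """(statistic, two-sided p) for association in a contingency table.

    'chi_square': Pearson chi-square without continuity correction.
    'fisher_exact' (2x2 only): hypergeometric enumeration summing all tables
    with probability <= the observed one.  'auto' uses Fisher for 2x2 tables
    with any expected count < 5, chi-square otherwise.  Tables with a zero
    row/column margin are rejected.
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("contingency table must be a 2-D array of non-negative counts")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    if method == "auto":
        if t.shape == (2, 2):
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            method = "fisher_exact" if (expected < 5).any() else "chi_square"
        else:
            method = "chi_square"
    if method == "fisher_exact":
        if t.shape != (2, 2):
            raise ValueError("fisher_exact requires a 2x2 table")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return float(odds), float(p)
    if method == "chi_square":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.chi2_contingency(t, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
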