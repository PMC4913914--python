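"""Cohort characterization tables: group summaries and simple tests.

Reproduces the descriptive table of a two-group clinical cohort: per-group
mean +/- SD for continuous variables (with a two-sample t-test, Welch by
default) and counts/percentages for categorical variables (with a
chi-square test, Yates-corrected for 2x2 tables).  Summary-statistic
t-tests are provided so printed tables (mean, SD, n per group) can be
re-tested without the raw data.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize", "ttest_summary", "chisq_categorical"]

logger = logging.getLogger(__name__)


def ttest_summary(
    m1: float, sd1: float, n1: int,
    m2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Returns ``(t, df, p)``; identical to a raw-data test on any dataset
    having these summaries.  ``variant`` is "welch" (unequal variances,
    Welch-Satterthwaite df) or "pooled".  Both SDs zero follows the
    degenerate conventions: equal means give p = 1, unequal p = 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if sd1 == 0.0 and sd2 == 0.0:
        df = float(n1 + n2 - 2)
        if m1 == m2:
            return 0.0, df, 1.0
        logger.info("ttest_summary: zero variance with unequal means")
        return math.copysign(math.inf, m1 - m2), df, 0.0
    if variant == "welch":
        se1, se2 = sd1**2 / n1, sd2**2 / n2
        t = (m1 - m2) / math.sqrt(se1 + se2)
        df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), min(p, 1.0)


def chisq_categorical(
    counts: np.ndarray, yates: bool = True
) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 contingency table.

    ``counts`` holds non-negative integer cell counts; Yates continuity
    correction is applied by default (it is what matches hand-tabulated
    clinical reports).  Returns ``(chi2, p)`` with df = 1.
    """
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {tab.shape}")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    total = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    diff = np.abs(tab - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def summarize(
    sheet: pd.DataFrame,
    variables: list[str],
    group_key: str = "group",
) -> pd.DataFrame:
    """Per-group descriptive statistics with a between-group test.

    Continuous variables get per-group mean and sample SD (n-1) plus a
    Welch t-test; categorical variables get per-category counts and
    percentages plus a chi-square test (Yates for 2x2).  Single-sample
    groups report SD as missing.  Returns one row per variable (per
    category for categoricals).
    """
    groups = sheet[group_key]
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups, found {levels}")
    rows = []
    for var in variables:
        if var not in sheet.columns:
            raise ValueError(f"variable {var!r} not in sheet")
        col = sheet[var]
        if col.isna().all():
            raise ValueError(f"variable {var!r} is entirely missing")
        if pd.api.types.is_numeric_dtype(col):
            cells: dict[str, float | str] = {"variable": var, "kind": "continuous"}
            per_group = []
            for lev in levels:
                vals = col[groups == lev].dropna()
                mean = vals.mean()
                sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
                if len(vals) <= 1:
                    logger.info("summarize: %s group %s has n<=1, SD undefined",
                                var, lev)
                cells[f"n_{lev}"] = len(vals)
                cells[f"mean_{lev}"] = mean
                cells[f"sd_{lev}"] = sd
                per_group.append(vals)
            if all(len(v) >= 2 for v in per_group):
                t, _, p = ttest_summary(
                    per_group[0].mean(), per_group[0].std(ddof=1), len(per_group[0]),
                    per_group[1].mean(), per_group[1].std(ddof=1), len(per_group[1]),
                )
                cells["stat"] = t
                cells["p"] = p
            else:
                cells["stat"] = np.nan
                cells["p"] = np.nan
            rows.append(cells)
        else:
            cats = sorted(col.dropna().unique())
            table = np.array(
                [[int(((col == c) & (groups == lev)).sum()) for c in cats]
                 for lev in levels]
            )
            if table.shape == (2, 2) and (table.sum(axis=0) > 0).all():
                chi2, p = chisq_categorical(table)
            elif table.shape[1] >= 2:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)[:4]
            else:
                chi2, p = np.nan, np.nan
            for ci, cat in enumerate(cats):
                cells = {"variable": f"{var}={cat}", "kind": "categorical"}
                for li, lev in enumerate(levels):
                    n_lev = int((groups == lev).sum())
                    cells[f"n_{lev}"] = int(table[li, ci])
                    cells[f"pct_{lev}"] = 100.0 * table[li, ci] / n_lev
                cells["stat"] = chi2
                cells["p"] = p
                rows.append(cells)
    return pd.DataFrame(rows)
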