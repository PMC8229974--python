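"""Association statistics: Spearman correlation on log-scale methylation,
Mann-Whitney group comparison, Fisher's exact and chi-square tests.

Percent methylation spans orders of magnitude, so correlations are
computed on log10 percent with a small floor (default 0.1%) that keeps
zeros finite; Spearman is rank-based, hence the floor only affects values
at or below it.  The squared Spearman rho is reported as R^2, matching
the convention of reporting "R^2 and p-value in Spearman's rank
correlation".  All tests are two-sided; no multiple-testing correction is
applied (none is part of the procedure being implemented).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phenotype import classify_methylation, MethylationCategory

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "log10_percent",
    "spearman",
    "mann_whitney",
    "fisher_exact",
    "chi_square",
    "associate_panel",
]

DEFAULT_LOG_FLOOR = 0.1  # percent; below ~1/coverage percents are noise


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def log10_percent(pct, floor: float = DEFAULT_LOG_FLOOR):
    """log10 of percent methylation with values floored at ``floor``."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    arr = np.asarray(pct, float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percent methylation must lie in [0, 100]")
    out = np.log10(np.maximum(arr, floor))
    return float(out) if np.isscalar(pct) or arr.ndim == 0 else out


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks; p from the
    t-distribution approximation; r_squared = rho**2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), r_squared=float(rho) ** 2,
                             p_value=float(p), n=len(x))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> GroupTestResult:
    """Two-sided Mann-Whitney U (U reported for group_a).

    Exact enumeration for small tie-free samples (n1+n2 <= 10), otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                           n1=len(a), n2=len(b))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (sum of hypergeometric
    probabilities <= that of the observed table)."""
    t = np.asarray(table, int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 integer table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero margin")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; df=(r-1)(c-1)."""
    t = np.asarray(table, float)
    if t.ndim != 2 or min(t.shape) < 2 or np.any(t < 0):
        raise ValueError("need a non-negative table of at least 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def associate_panel(panel: pd.DataFrame, floor: float = DEFAULT_LOG_FLOOR) -> pd.DataFrame:
    """Association report for a cell-line panel table.

    Expects columns dr4_pct, dr5_pct, expr_dr4, expr_dr5, rfi_dr4,
    rfi_dr5, inhibition_pct.  Emits a tidy table with one row per
    comparison: Spearman of log10 methylation against expression, RFI and
    inhibition per receptor, plus Mann-Whitney comparisons of inhibition
    between methylation-category groups.
    """
    rows = []
    for gene in ("dr4", "dr5"):
        meth = log10_percent(panel[f"{gene}_pct"].to_numpy(), floor)
        for label, col in (("expression", f"expr_{gene}"),
                           ("rfi", f"rfi_{gene}"),
                           ("inhibition", "inhibition_pct")):
            r = spearman(meth, panel[col].to_numpy())
            rows.append({"comparison": f"{gene}_methylation_vs_{label}",
                         "test": "spearman", "n": r.n, "rho": r.rho,
                         "r_squared": r.r_squared, "statistic": np.nan,
                         "p_value": r.p_value})

    calls = [classify_methylation(d4, d5)
             for d4, d5 in zip(panel.dr4_pct, panel.dr5_pct)]
    cats = pd.Series([c.category.value for c in calls], index=panel.index)
    high = pd.Series([c.highly_methylated for c in calls], index=panel.index)
    inh = panel.inhibition_pct

    unmeth_like = cats.isin([MethylationCategory.UNMETHYLATED.value,
                             MethylationCategory.DR4_PREF_UNMETH.value])
    meth_cat = cats == MethylationCategory.METHYLATED.value
    groupings = [
        ("inhibition_unmethylated_vs_methylated", unmeth_like, meth_cat),
        ("inhibition_highly_methylated_vs_rest", high, ~high),
    ]
    for label, mask_a, mask_b in groupings:
        a, b = inh[mask_a], inh[mask_b]
        if len(a) >= 2 and len(b) >= 2:
            r = mann_whitney(a, b)
            rows.append({"comparison": label, "test": "mann_whitney",
                         "n": r.n1 + r.n2, "rho": np.nan, "r_squared": np.nan,
                         "statistic": r.statistic, "p_value": r.p_value})
    return pd.DataFrame(rows)
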