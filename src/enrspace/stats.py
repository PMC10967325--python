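"""Non-parametric group comparison machinery.

Descriptor distributions in bioactivity datasets are heavy-tailed and
multimodal, so comparisons run through rank tests: Kruskal-Wallis across the
four enzyme datasets, Mann-Whitney U for pairwise follow-ups, with
Holm-Bonferroni control of the family-wise error rate.  Normality tests
(Kolmogorov-Smirnov against a fitted normal and D'Agostino-Pearson) are
computed for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "normality_tests",
    "kruskal_wallis",
    "mann_whitney",
    "holm_bonferroni",
    "pearson_correlation",
    "descriptor_comparison_table",
]

ALPHA = 0.05

#: Descriptors compared between groups by default.
DEFAULT_COMPARISON_PANEL = (
    "BertzCT", "fragCpx", "LogS", "apol", "RotBFrac", "SlogP", "TPSA", "AMW",
)


class StatsError(ValueError):
    pass


class DegenerateDataError(StatsError):
    pass


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: Optional[float] = None
    reject: Optional[bool] = None
    name: str = ""

    def decide(self, alpha: float = ALPHA) -> "TestResult":
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        self.reject = bool(p < alpha)
        return self


def _clean(values) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(arr)):
        raise StatsError("non-finite values in input")
    return arr


def normality_tests(values: Sequence[float]) -> tuple[TestResult, TestResult]:
    """Kolmogorov-Smirnov (vs fitted normal) and D'Agostino-Pearson tests."""
    arr = _clean(values)
    if arr.size < 20:
        raise StatsError(f"normality testing needs >= 20 values, got {arr.size}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant vector has no normality to test")
    ks = sps.kstest(arr, "norm", args=(arr.mean(), sd))
    dp = sps.normaltest(arr)
    return (
        TestResult(float(ks.statistic), float(ks.pvalue), name="kolmogorov_smirnov"),
        TestResult(float(dp.statistic), float(dp.pvalue), name="dagostino_pearson"),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p with k-1 df."""
    arrays = [_clean(g) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise StatsError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size < 2:
        raise DegenerateDataError("all values identical")
    res = sps.kruskal(*arrays)
    return TestResult(float(res.statistic), float(res.pvalue), name="kruskal_wallis")


def mann_whitney(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U.

    Exact null distribution when both groups have <= 8 observations and no
    ties; normal approximation with tie correction otherwise.
    """
    xa, xb = _clean(a), _clean(b)
    if xa.size == 0 or xb.size == 0:
        raise StatsError("both groups must be non-empty")
    ties = np.unique(np.concatenate([xa, xb])).size < xa.size + xb.size
    method = "exact" if (xa.size <= 8 and xb.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), name="mann_whitney")


def holm_bonferroni(p_values: Sequence[float], alpha: float = ALPHA) -> list[TestResult]:
    """Holm step-down adjustment; results align with the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return [
        TestResult(float(p[i]), float(p[i]), p_adjusted=float(p_adj[i]),
                   reject=bool(reject[i]), name="holm")
        for i in range(p.size)
    ]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided t-distribution p-value."""
    xa, ya = _clean(x), _clean(y)
    if xa.size != ya.size or xa.size < 3:
        raise StatsError("need matched samples of size >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise DegenerateDataError("zero variance in correlation input")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


def descriptor_comparison_table(
    table: pd.DataFrame,
    descriptors: Sequence[str] = DEFAULT_COMPARISON_PANEL,
    group_col: str = "enzyme",
    class_col: str = "activity_class",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-descriptor active-vs-inactive Mann-Whitney tests within each group,
    preceded by a Kruskal-Wallis screen across groups, Holm-adjusted as one
    family per analysis table.

    Returns a tidy frame: descriptor, comparison, statistic, p_raw,
    p_adjusted, reject.
    """
    rows = []
    groups = sorted(table[group_col].dropna().unique())
    for desc in descriptors:
        if desc not in table.columns:
            continue
        series = [table.loc[table[group_col] == g, desc].dropna().values for g in groups]
        series = [s for s in series if len(s) > 0]
        if len(series) >= 3:
            try:
                kw = kruskal_wallis(series)
                rows.append((desc, "across_enzymes", kw.statistic, kw.p_value))
            except DegenerateDataError:
                pass
        for g in groups:
            sub = table[table[group_col] == g]
            act = sub.loc[sub[class_col] == "active", desc].dropna().values
            inact = sub.loc[sub[class_col] == "inactive", desc].dropna().values
            if len(act) == 0 or len(inact) == 0:
                continue
            try:
                mw = mann_whitney(act, inact)
            except StatsError:
                continue
            rows.append((desc, f"{g}:active_vs_inactive", mw.statistic, mw.p_value))
    frame = pd.DataFrame(rows, columns=["descriptor", "comparison", "statistic", "p_raw"])
    if len(frame):
        adj = holm_bonferroni(frame["p_raw"].tolist(), alpha=alpha)
        frame["p_adjusted"] = [t.p_adjusted for t in adj]
        frame["reject"] = [t.reject for t in adj]
    else:
        frame["p_adjusted"] = []
        frame["reject"] = []
    return frame
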