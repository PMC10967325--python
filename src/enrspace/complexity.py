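"""Molecular complexity vs activity.

BertzCT graph complexity per enzyme dataset and activity class, an
active-vs-inactive rank comparison, and the Pearson correlation between
complexity and pIC50 within each class.  All statistics delegate to
:mod:`enrspace.stats` so there is exactly one implementation of each test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import stats as st

__all__ = ["ComplexitySummary", "complexity_report"]


@dataclass
class ComplexitySummary:
    group_stats: pd.DataFrame  # enzyme x class: n, mean, median BertzCT
    comparisons: pd.DataFrame  # Mann-Whitney active vs inactive per enzyme
    correlations: dict = field(default_factory=dict)  # class -> (r, p) | None


def complexity_report(
    table: pd.DataFrame,
    value_col: str = "BertzCT",
    activity_col: str = "pic50",
    aggregate: str = "mean",
) -> ComplexitySummary:
    """Summarize complexity per (enzyme, activity class).

    ``table`` needs columns enzyme, activity_class, ``value_col`` and
    ``activity_col``.  Dataset-level figures use ``aggregate`` (mean by
    default; median available).  Degenerate groups (empty, or zero
    variance for the correlation) are flagged as absent (None).
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    rows = []
    for (enzyme, cls), sub in table.groupby(["enzyme", "activity_class"]):
        vals = sub[value_col].dropna()
        rows.append(
            {
                "enzyme": enzyme,
                "activity_class": cls,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else None,
                "median": float(vals.median()) if len(vals) else None,
            }
        )
    group_stats = pd.DataFrame(rows)

    comp_rows = []
    for enzyme, sub in table.groupby("enzyme"):
        act = sub.loc[sub["activity_class"] == "active", value_col].dropna().values
        inact = sub.loc[sub["activity_class"] == "inactive", value_col].dropna().values
        if len(act) == 0 or len(inact) == 0:
            comp_rows.append({"enzyme": enzyme, "statistic": None, "p_value": None})
            continue
        try:
            res = st.mann_whitney(act, inact)
            comp_rows.append(
                {"enzyme": enzyme, "statistic": res.statistic, "p_value": res.p_value}
            )
        except st.StatsError:
            comp_rows.append({"enzyme": enzyme, "statistic": None, "p_value": None})
    comparisons = pd.DataFrame(comp_rows)

    correlations: dict[str, Optional[tuple[float, float]]] = {}
    for cls, sub in table.groupby("activity_class"):
        x = sub[value_col].dropna()
        sub = sub.loc[x.index]
        try:
            correlations[cls] = st.pearson_correlation(
                sub[value_col].values, sub[activity_col].values
            )
        except st.StatsError:
            correlations[cls] = None
    return ComplexitySummary(
        group_stats=group_stats, comparisons=comparisons, correlations=correlations
    )
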