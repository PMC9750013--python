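"""Descriptive surfaces: support CDFs, central tendencies, prioritization
shares, and the fair-share benchmark arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import PRIORITY_LEVELS

#: named grouping rules for support curves: label function plus the closed
#: set of expected group labels.  "costs" contrasts scenarios with both risk
#: conditions active against scenarios with neither (mixed cells with
#: exactly one active are excluded); "multilateralism" contrasts any
#: international deal against no deal.
GROUPINGS: dict[str, tuple[Callable[[pd.DataFrame], pd.Series], tuple[str, ...]]] = {
    "costs": (
        lambda df: pd.Series(
            np.select(
                [(df["trade"] == 1) & (df["risk"] == 1),
                 (df["trade"] == 0) & (df["risk"] == 0)],
                ["high costs", "low costs"],
                default=None,
            ),
            index=df.index, dtype=object,
        ),
        ("high costs", "low costs"),
    ),
    "multilateralism": (
        lambda df: pd.Series(
            np.where(df["deal"] != 0, "high multilateralism", "low multilateralism"),
            index=df.index,
        ),
        ("high multilateralism", "low multilateralism"),
    ),
}


def support_cdf(
    data: pd.DataFrame,
    grouping_rule: str | Callable[[pd.DataFrame], pd.Series] = "costs",
    thresholds: np.ndarray | None = None,
    outcome: str = "cash",
) -> pd.DataFrame:
    """Empirical CDF of stated support per scenario grouping.

    Parameters
    ----------
    data
        Responses merged with their vignette conditions: needs the outcome
        column plus ``trade``, ``risk``, ``deal`` for the named groupings.
    grouping_rule
        A key of :data:`GROUPINGS` or a callable mapping the data frame to a
        series of group labels (None/NaN rows are excluded) — the generic
        group-by hook for custom subgroup curves.
    thresholds
        Ascending grid; defaults to the sorted unique outcome values pooled
        across groups.

    Returns a tidy frame (group, threshold, share, n).  For named groupings
    an empty expected group is kept with NaN shares and n = 0 rather than
    silently dropped.
    """
    if isinstance(grouping_rule, str):
        rule, expected = GROUPINGS[grouping_rule]
    else:
        rule, expected = grouping_rule, None
    labels = rule(data)
    y = data[outcome].to_numpy(dtype=float)

    if thresholds is None:
        thresholds = np.unique(y)
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        if np.any(np.diff(thresholds) < 0):
            raise ValueError("thresholds must be sorted ascending")

    observed = list(pd.unique(labels.dropna()))
    groups = list(expected) if expected is not None else observed
    rows = []
    for grp in groups:
        vals = np.sort(y[(labels == grp).to_numpy()])
        n = len(vals)
        if n == 0:
            share = np.full(len(thresholds), np.nan)
        else:
            share = np.searchsorted(vals, thresholds, side="right") / n
        for t, s in zip(thresholds, share):
            rows.append({"group": grp, "threshold": float(t), "share": s, "n": n})
    return pd.DataFrame(rows, columns=["group", "threshold", "share", "n"])


def summarize_central(
    responses: pd.DataFrame, outcome_cols: tuple[str, ...] = ("cash", "doses")
) -> pd.DataFrame:
    """Sample median and mean per outcome column, units preserved."""
    if len(responses) == 0:
        raise ValueError("responses table is empty")
    cols = [c for c in outcome_cols if c in responses.columns]
    if not cols:
        raise ValueError(f"none of {outcome_cols} present in responses")
    return pd.DataFrame(
        {
            "median": [float(responses[c].median()) for c in cols],
            "mean": [float(responses[c].mean()) for c in cols],
        },
        index=pd.Index(cols, name="outcome"),
    )


def priorities_shares(table: pd.DataFrame) -> tuple[float, float]:
    """(share equal-or-higher, share strictly higher) of the distant
    beneficiary's priority."""
    resp = table["priority"]
    unknown = set(resp.unique()) - set(PRIORITY_LEVELS)
    if unknown:
        raise ValueError(f"unknown priority categories: {sorted(unknown)}")
    n = len(resp)
    if n == 0:
        raise ValueError("priority table is empty")
    share_gt = float((resp == "higher").sum() / n)
    share_geq = share_gt + float((resp == "equal").sum() / n)
    return share_geq, share_gt


@dataclass(frozen=True)
class FairShare:
    """Benchmark contribution: a donor-share fraction of a total cost."""

    exact: float
    presented: int  # rounded to the nearest billion for reporting


def fair_share(total_cost: float, donor_share: float) -> FairShare:
    """Donor-share fraction of a total global cost, in billion EUR."""
    if total_cost < 0:
        raise ValueError("total_cost must be >= 0")
    if not 0 <= donor_share <= 1:
        raise ValueError("donor_share must be in [0, 1]")
    exact = total_cost * donor_share
    return FairShare(exact=exact, presented=int(round(exact)))
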