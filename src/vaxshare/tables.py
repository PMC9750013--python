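"""Shared estimate-table construction.

All inference output in this package uses one tidy shape: columns
``term, estimate, std.error, statistic, p.value, conf.low, conf.high``.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ESTIMATE_COLUMNS = (
    "term", "estimate", "std.error", "statistic", "p.value", "conf.low", "conf.high",
)


def make_estimate_table(
    terms: Sequence[str],
    estimates: Sequence[float],
    std_errors: Sequence[float],
    level: float = 0.95,
    df: float | None = None,
) -> pd.DataFrame:
    """Build a tidy inference table from estimates and standard errors.

    Statistics are estimate / std.error; p-values are two-sided from the
    normal reference, or from Student's t with ``df`` degrees of freedom if
    given.  Confidence bounds are Wald-type at ``level``.  Rows with a
    non-finite or non-positive standard error get NaN inference columns
    (the estimate is kept).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(std_errors, dtype=float)
    if not (len(terms) == est.size == se.size):
        raise ValueError("terms, estimates and std_errors must have equal length")

    ok = np.isfinite(se) & (se > 0)
    stat = np.full_like(est, np.nan)
    stat[ok] = est[ok] / se[ok]
    if df is None:
        crit = stats.norm.ppf(0.5 + level / 2.0)
        pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    else:
        crit = stats.t.ppf(0.5 + level / 2.0, df)
        pval = np.where(ok, 2.0 * stats.t.sf(np.abs(stat), df), np.nan)
    lo = np.where(ok, est - crit * se, np.nan)
    hi = np.where(ok, est + crit * se, np.nan)
    return pd.DataFrame(
        {
            "term": list(terms),
            "estimate": est,
            "std.error": np.where(ok, se, np.nan),
            "statistic": stat,
            "p.value": pval,
            "conf.low": lo,
            "conf.high": hi,
        }
    )
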