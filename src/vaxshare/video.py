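"""Average treatment effects of the information video (two-arm experiment).

One observation per respondent, so a heteroskedasticity-robust difference in
means (equivalently OLS of the outcome on the treatment indicator with HC2
errors) is the default; no clustering is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import make_estimate_table

OUTCOMES = ("attitude", "donation")


def _outcome_vector(table: pd.DataFrame, outcome_name: str) -> tuple[np.ndarray, str]:
    if outcome_name == "attitude":
        return table["attitude"].to_numpy(dtype=float), "attitude (scale units)"
    if outcome_name == "donation":
        # report on the 0-100 percent-of-endowment scale
        if "donation_share" in table.columns:
            share = table["donation_share"].to_numpy(dtype=float)
        else:
            share = table["donation_points"].to_numpy(dtype=float) / 50.0
        return 100.0 * share, "donation (% of endowment)"
    raise ValueError(f"outcome_name must be one of {OUTCOMES}, got {outcome_name!r}")


def estimate_ate(
    table: pd.DataFrame, outcome_name: str = "attitude", se_flavor: str = "hc"
) -> pd.DataFrame:
    """Treated-minus-control mean difference with robust inference.

    Returns a single-row estimate table.  The donation outcome is expressed
    in percentage points of the 50-point endowment.  For binary treatment
    the HC2 sandwich variance equals the Welch form s1^2/n1 + s0^2/n0.
    A zero robust SE (constant outcomes within both arms) is flagged by NaN
    inference columns rather than a spurious zero p-value.
    """
    if se_flavor != "hc":
        raise ValueError("only the heteroskedasticity-robust flavor is supported")
    z = table["treated"].astype(int).to_numpy()
    arms = set(np.unique(z))
    if arms != {0, 1}:
        raise ValueError(f"both treatment arms must be nonempty, got arms {sorted(arms)}")
    y, label = _outcome_vector(table, outcome_name)

    y1, y0 = y[z == 1], y[z == 0]
    ate = float(y1.mean() - y0.mean())
    v1 = y1.var(ddof=1) / len(y1) if len(y1) > 1 else np.nan
    v0 = y0.var(ddof=1) / len(y0) if len(y0) > 1 else np.nan
    se = float(np.sqrt(v1 + v0))

    out = make_estimate_table([label], [ate], [se])
    out.attrs["n"] = {"treated": int(len(y1)), "control": int(len(y0))}
    out.attrs["degenerate"] = bool(not np.isfinite(se) or se == 0.0)
    return out


@dataclass(frozen=True)
class DonationSummary:
    """Distributional summary of the donation outcome."""

    median_share_pct: float
    modal_points: int
    share_full: float


def donation_distribution(table: pd.DataFrame) -> DonationSummary:
    """Median share (percent), modal point response, and full-amount share."""
    if len(table) == 0:
        raise ValueError("donation table is empty")
    points = table["donation_points"].to_numpy(dtype=float)
    median_pct = float(np.median(points) / 50.0 * 100.0)
    values, counts = np.unique(points, return_counts=True)
    modal = int(values[np.argmax(counts)])
    share_full = float(np.mean(points == 50))
    return DonationSummary(median_pct, modal, share_full)
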