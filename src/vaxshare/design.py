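"""Factorial design for the vignette experiment.

The experiment crosses three factors in a 2 x 2 x 5 full factorial:

``trade``
    0 = no negative impact on the domestic economy, 1 = economy shrinks ~5%.
``risk``
    0 = mutation risk does not increase, 1 = mutation risk increases.
``deal``
    categorical level in {0..4} encoding the international agreement; each
    level deterministically implies how many other countries participate and
    how much they give in total (billion EUR), see :data:`DEAL_CONDITIONS`.

For regression analysis the factors are mapped to four numeric condition
variables, named ``X1``..``X4`` throughout:

======  ==============================================  =================
column  meaning                                         units
======  ==============================================  =================
X1      total amount given by other countries           billion EUR
X2      number of other countries giving                count
X3      mutation-risk indicator                         0/1
X4      trade-impact indicator                          0/1
======  ==============================================  =================

All four are centered at the realized sample mean before interactions are
formed, so main-effect coefficients of the interacted regression read as
average effects.  Interaction columns are elementwise products of the
centered main-effect columns and are named with ``:`` separators, e.g.
``X1:X3`` or ``X2:X3:X4``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: deal level -> (number of other countries, total amount given, billion EUR)
DEAL_CONDITIONS: dict[int, tuple[int, int]] = {
    0: (0, 0),
    1: (20, 20),
    2: (40, 20),
    3: (20, 40),
    4: (40, 40),
}

DEAL_LEVELS = tuple(sorted(DEAL_CONDITIONS))

MAIN_TERMS = ("X1", "X2", "X3", "X4")

#: human-readable labels for the numeric condition columns
TERM_LABELS = {
    "X1": "amount given by others (billion EUR)",
    "X2": "number of others giving",
    "X3": "health risk",
    "X4": "trade impact",
}

#: slope-term order of the three-way interacted model (14 terms, no four-way)
FULL_TERMS = (
    "X1", "X2", "X3", "X4",
    "X1:X2", "X1:X3", "X1:X4", "X2:X3", "X2:X4", "X3:X4",
    "X1:X2:X3", "X1:X2:X4", "X1:X3:X4", "X2:X3:X4",
)

ASSIGNMENT_COLUMNS = ("respondent_id", "vignette_index", "trade", "risk", "deal")


def deal_to_conditions(deal: int) -> tuple[int, int]:
    """Map a deal level to ``(n_countries, total_amount)``.

    Raises
    ------
    ValueError
        If ``deal`` is not one of the five defined levels.
    """
    try:
        key = int(deal)
    except (TypeError, ValueError):
        raise ValueError(f"deal level must be an integer in {DEAL_LEVELS}, got {deal!r}")
    if key != deal or key not in DEAL_CONDITIONS:
        raise ValueError(f"deal level must be one of {DEAL_LEVELS}, got {deal!r}")
    return DEAL_CONDITIONS[key]


@dataclass(frozen=True)
class FactorLevels:
    """One cell of the factorial design."""

    trade: int
    risk: int
    deal: int

    def __post_init__(self) -> None:
        if self.trade not in (0, 1):
            raise ValueError(f"trade must be 0 or 1, got {self.trade!r}")
        if self.risk not in (0, 1):
            raise ValueError(f"risk must be 0 or 1, got {self.risk!r}")
        deal_to_conditions(self.deal)  # validates

    @property
    def conditions(self) -> tuple[int, int]:
        """``(n_countries, total_amount)`` implied by the deal level."""
        return deal_to_conditions(self.deal)


def full_factorial() -> pd.DataFrame:
    """Enumerate all 20 cells of the design as a data frame."""
    rows = [
        {"trade": t, "risk": r, "deal": d}
        for t, r, d in itertools.product((0, 1), (0, 1), DEAL_LEVELS)
    ]
    return pd.DataFrame(rows)


def conditions_frame(assignments: pd.DataFrame) -> pd.DataFrame:
    """Derive the raw (uncentered) numeric condition columns X1..X4.

    ``assignments`` must contain ``trade``, ``risk`` and ``deal`` columns.
    """
    for col in ("trade", "risk", "deal"):
        if col not in assignments.columns:
            raise ValueError(f"assignments table is missing required column {col!r}")
    bad = set(assignments["deal"].unique()) - set(DEAL_LEVELS)
    if bad:
        raise ValueError(f"unknown deal levels in assignments: {sorted(bad)}")
    n_countries = assignments["deal"].map(lambda d: DEAL_CONDITIONS[int(d)][0])
    amount = assignments["deal"].map(lambda d: DEAL_CONDITIONS[int(d)][1])
    return pd.DataFrame(
        {
            "X1": amount.astype(float).to_numpy(),
            "X2": n_countries.astype(float).to_numpy(),
            "X3": assignments["risk"].astype(float).to_numpy(),
            "X4": assignments["trade"].astype(float).to_numpy(),
        },
        index=assignments.index,
    )


def _interaction_terms(order: int) -> list[str]:
    terms = list(MAIN_TERMS)
    for k in (2, 3):
        if order >= k:
            terms += [":".join(c) for c in itertools.combinations(MAIN_TERMS, k)]
    return terms


def build_design_matrix(
    assignments: pd.DataFrame,
    interaction_order: int = 3,
    include_four_way: bool = False,
) -> pd.DataFrame:
    """Build the mean-centered design matrix with interactions.

    Parameters
    ----------
    assignments
        Table with columns ``respondent_id``, ``vignette_index``, ``trade``,
        ``risk``, ``deal``.
    interaction_order
        1 (mains only), 2 (adds all two-way products) or 3 (adds all
        three-way products; the default 14-term model).
    include_four_way
        If True, append the ``X1:X2:X3:X4`` column for sensitivity analysis.
        The default model excludes it.

    Returns
    -------
    pandas.DataFrame
        Columns ``respondent_id``, ``vignette_index`` followed by the model
        terms.  Main-effect columns are centered at the realized sample mean
        (mean zero to ~1e-10); interactions are products of centered columns.
        The list of slope terms is stored in ``.attrs["terms"]``.
    """
    if interaction_order not in (1, 2, 3):
        raise ValueError("interaction_order must be 1, 2 or 3")
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in assignments.columns]
    if missing:
        raise ValueError(f"assignments table is missing columns {missing}")
    if len(assignments) < 2:
        raise ValueError("need at least 2 observations to build a design matrix")

    raw = conditions_frame(assignments)
    for col in MAIN_TERMS:
        if raw[col].nunique() < 2:
            raise ValueError(
                f"condition column {col} ({TERM_LABELS[col]}) is constant; "
                "the factor is degenerate in this assignment set"
            )

    centered = raw - raw.mean(axis=0)
    out = assignments[["respondent_id", "vignette_index"]].copy()
    terms = _interaction_terms(interaction_order)
    if include_four_way and interaction_order == 3:
        terms = terms + ["X1:X2:X3:X4"]
    for term in terms:
        parts = term.split(":")
        col = centered[parts[0]].to_numpy().copy()
        for p in parts[1:]:
            col = col * centered[p].to_numpy()
        out[term] = col
    out.attrs["terms"] = list(terms)
    return out


def design_terms(design: pd.DataFrame) -> list[str]:
    """Slope-term columns of a design matrix built by :func:`build_design_matrix`."""
    terms = design.attrs.get("terms")
    if terms:
        return list(terms)
    return [c for c in design.columns if c not in ("respondent_id", "vignette_index")]
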