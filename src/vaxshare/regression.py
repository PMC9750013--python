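"""Centered factorial interaction regression with respondent fixed effects.

The outcome (cash or doses) is regressed on the centered condition columns
and their interactions, absorbing a fixed intercept per respondent by
within-respondent demeaning (numerically identical to including one dummy
column per respondent, which the test suite verifies).  Standard errors are
robust: cluster-robust by respondent by default — each respondent
contributes two vignettes — with a heteroskedasticity-robust (HC2-style)
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MAIN_TERMS, TERM_LABELS, design_terms
from .tables import make_estimate_table


@dataclass
class FactorialFit:
    """Fitted factorial fixed-effects regression.

    ``table`` holds one row per slope term (14 rows for the full three-way
    model); the absorbed intercept is summarized by ``grand_mean``, the
    sample mean of the outcome.
    """

    table: pd.DataFrame
    outcome: str
    se_flavor: str
    n_obs: int
    n_respondents: int
    grand_mean: float
    df_resid: int
    conf_level: float = 0.95


def _demean_by(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Subtract group means (one pass, no dummy expansion)."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if values.ndim == 1:
        sums = np.bincount(codes, weights=values, minlength=n_groups)
        return values - (sums / counts)[codes]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        sums = np.bincount(codes, weights=values[:, j], minlength=n_groups)
        out[:, j] = values[:, j] - (sums / counts)[codes]
    return out


def _collinear_columns(x: np.ndarray, terms: list[str]) -> list[str]:
    """Identify columns dropped by pivoted QR on a rank-deficient matrix."""
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [terms[i] for i in sorted(piv[rank:])]


def fit_factorial_fe(
    design: pd.DataFrame,
    outcomes: np.ndarray | pd.Series,
    se_flavor: str = "cluster",
    conf_level: float = 0.95,
    outcome_label: str = "cash",
) -> FactorialFit:
    """Fit the factorial regression with respondent fixed effects.

    Parameters
    ----------
    design
        Design matrix from :func:`vaxshare.design.build_design_matrix`
        (centered mains plus interactions, with ``respondent_id``).
    outcomes
        Outcome vector aligned with the rows of ``design``.
    se_flavor
        ``"cluster"`` (CR1 by respondent, t reference with G-1 df; default)
        or ``"hc"`` (HC2 using leverages of the demeaned regressors,
        t reference with the FE-adjusted residual df).

    Degrees of freedom count the absorbed respondent intercepts, so the
    residual df is n_obs - n_terms - n_respondents.
    """
    if se_flavor not in ("cluster", "hc"):
        raise ValueError("se_flavor must be 'cluster' or 'hc'")
    terms = design_terms(design)
    y = np.asarray(outcomes, dtype=float)
    if len(y) != len(design):
        raise ValueError("outcomes must align with the design matrix rows")

    ids, codes = np.unique(design["respondent_id"].to_numpy(), return_inverse=True)
    n, k, g = len(y), len(terms), len(ids)
    x = design[terms].to_numpy(dtype=float)

    xt = _demean_by(x, codes, g)
    yt = _demean_by(y, codes, g)

    within_var = (xt ** 2).sum(axis=0)
    dead = [t for t, v in zip(terms, within_var) if v <= n * 1e-20]
    if dead:
        raise ValueError(
            "no within-respondent variation in regressor(s) "
            f"{dead}; fixed effects absorb them entirely"
        )
    if np.linalg.matrix_rank(xt) < k:
        raise ValueError(
            "design matrix is rank deficient after demeaning; collinear "
            f"columns: {_collinear_columns(xt, terms)}"
        )

    xtx = xt.T @ xt
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (xt.T @ y)  # y and demeaned yt give identical slopes
    resid = yt - xt @ beta
    df_resid = n - k - g

    if se_flavor == "cluster":
        scores = xt * resid[:, None]
        grp_scores = np.zeros((g, k))
        for j in range(k):
            grp_scores[:, j] = np.bincount(codes, weights=scores[:, j], minlength=g)
        meat = grp_scores.T @ grp_scores
        # respondent FEs are nested within the clusters, so the absorbed
        # intercepts are NOT counted in the small-sample correction (the
        # within transformation already lives inside each cluster)
        correction = (g / (g - 1)) * ((n - 1) / max(n - k - 1, 1))
        cov = correction * xtx_inv @ meat @ xtx_inv
        df_inference = g - 1
    else:
        h = np.einsum("ij,jk,ik->i", xt, xtx_inv, xt)
        h = np.clip(h, 0.0, 1.0 - 1e-12)
        w = resid ** 2 / (1.0 - h)
        cov = xtx_inv @ (xt * w[:, None]).T @ xt @ xtx_inv
        df_inference = max(df_resid, 1)

    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    table = make_estimate_table(terms, beta, se, level=conf_level, df=df_inference)

    return FactorialFit(
        table=table,
        outcome=outcome_label,
        se_flavor=se_flavor,
        n_obs=n,
        n_respondents=g,
        grand_mean=float(np.mean(y)),
        df_resid=df_resid,
        conf_level=conf_level,
    )


def marginal_effects_table(fit: FactorialFit) -> pd.DataFrame:
    """Main-term rows of the fit, relabeled in natural units.

    With centered conditions the four main-effect coefficients read as
    average marginal effects of the conditions.
    """
    table = fit.table.set_index("term")
    missing = [t for t in MAIN_TERMS if t not in table.index]
    if missing:
        raise ValueError(f"fit is missing main terms {missing}")
    out = table.loc[list(MAIN_TERMS)].reset_index()
    out["term"] = [TERM_LABELS[t] for t in MAIN_TERMS]
    return out
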