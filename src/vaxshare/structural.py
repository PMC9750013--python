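"""Structural public-goods contribution model and maximum-likelihood fit.

A respondent facing scenario context (economic risk ``E``, health risk ``H``,
total contribution of other countries ``S``, their average contribution
``ybar``) values an own contribution ``y`` (billion EUR) as::

    u(y) = (alpha + beta*E + delta*H) * log(S + y) - gamma*(y - kappa*ybar)**2 - y**2

The first term is the diminishing-returns benefit of the public good, with
marginal benefit ``M = alpha + beta*E + delta*H`` shifted by the risk
conditions; the second penalizes deviation from a multiple ``kappa`` of the
peers' average contribution; the last is a convex own cost.

Setting du/dy = 0 and multiplying through by (S + y) gives the quadratic

    2*(gamma+1)*y**2 + 2*((gamma+1)*S - gamma*kappa*ybar)*y - (2*gamma*kappa*ybar*S + M) = 0

whose constant term is negative whenever M > 0, so there is exactly one
positive root: the optimal contribution ``y*``.  Reports are modelled as
``y* + eps`` with iid Gaussian noise, giving a six-parameter likelihood in
(alpha, beta, delta, gamma, kappa, sigma) maximized by multi-start
optimization; standard errors come from the inverse expected information at
the optimum.

A structural caveat the estimator handles explicitly: y* depends on the
parameters only through (alpha, beta, delta) / (1+gamma) and
gamma*kappa / (1+gamma), so the likelihood is *exactly flat* along a
one-dimensional ridge and the raw sextet is not point-identified.  The fit
returns one maximizer on the ridge; parameters whose uncertainty is
unbounded along the flat direction are reported with infinite standard
errors.  The identified combinations (see :func:`identified_combinations`)
have ordinary finite-SE behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DEAL_CONDITIONS, full_factorial
from .tables import make_estimate_table

PARAM_NAMES = ("alpha", "beta", "delta", "gamma", "kappa", "sigma")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class StructuralParams:
    """The parameter sextet of the contribution model.

    alpha : baseline marginal benefit of the public good
    beta  : increment to the marginal benefit under economic risk
    delta : increment under health risk
    gamma : weight on peer alignment (>= 0)
    kappa : peer-benchmark multiplier
    sigma : SD of the Gaussian reporting noise, billion EUR (> 0)
    """

    alpha: float
    beta: float
    delta: float
    gamma: float
    kappa: float
    sigma: float

    def __post_init__(self) -> None:
        # sigma = 0 is admitted for noiseless simulation; every density
        # evaluation (log_likelihood, fit_mle) requires sigma > 0
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")

    def marginal_benefit(self, econ_risk: float, health_risk: float) -> float:
        return self.alpha + self.beta * econ_risk + self.delta * health_risk

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "StructuralParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class ScenarioContext:
    """Scenario faced by one respondent-vignette observation.

    econ_risk / health_risk are raw 0/1 indicators; ``others_total`` is the
    sum of the other countries' contributions S (billion EUR) and
    ``others_mean`` their average (S / number of countries, 0 when nobody
    participates).
    """

    econ_risk: int
    health_risk: int
    others_total: float
    others_mean: float

    def __post_init__(self) -> None:
        if self.econ_risk not in (0, 1) or self.health_risk not in (0, 1):
            raise ValueError("econ_risk and health_risk must be 0/1")
        if self.others_total < 0 or self.others_mean < 0:
            raise ValueError("others_total and others_mean must be >= 0")
        if (self.others_total == 0) != (self.others_mean == 0):
            raise ValueError("others_mean must be 0 exactly when others_total is 0")

    @classmethod
    def from_factors(cls, trade: int, risk: int, deal: int) -> "ScenarioContext":
        """Build the context implied by a factorial cell.

        ``trade`` maps to economic risk, ``risk`` to health risk, and the deal
        level supplies (number of countries, total amount).
        """
        n_countries, total = DEAL_CONDITIONS[int(deal)]
        ybar = total / n_countries if n_countries else 0.0
        return cls(int(trade), int(risk), float(total), ybar)


def context_arrays(assignments: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Vectorized (E, H, S, ybar) arrays for an assignment table."""
    deal = assignments["deal"].astype(int).to_numpy()
    n_countries = np.array([DEAL_CONDITIONS[d][0] for d in deal], dtype=float)
    total = np.array([DEAL_CONDITIONS[d][1] for d in deal], dtype=float)
    ybar = np.divide(total, n_countries, out=np.zeros_like(total), where=n_countries > 0)
    e = assignments["trade"].astype(float).to_numpy()
    h = assignments["risk"].astype(float).to_numpy()
    return e, h, total, ybar


def utility(y: float, params: StructuralParams, ctx: ScenarioContext) -> float:
    """Evaluate the objective at contribution ``y`` (natural log benefit)."""
    s = ctx.others_total
    if s + y <= 0:
        raise ValueError(f"log domain error: others_total + y = {s + y} <= 0")
    m = params.marginal_benefit(ctx.econ_risk, ctx.health_risk)
    peer = y - params.kappa * ctx.others_mean
    return m * math.log(s + y) - params.gamma * peer * peer - y * y


def _optimal_vec(
    m: np.ndarray, gamma: float, kappa: float, s: np.ndarray, ybar: np.ndarray
) -> np.ndarray:
    """Positive root of the first-order-condition quadratic, elementwise.

    Requires m > 0 elementwise (checked by callers); the root is then unique
    and strictly positive, so the y >= 0 clamp never binds.
    """
    a = 2.0 * (gamma + 1.0)
    b = 2.0 * ((gamma + 1.0) * s - gamma * kappa * ybar)
    c = -(2.0 * gamma * kappa * ybar * s + m)
    disc = b * b - 4.0 * a * c
    root = (-b + np.sqrt(disc)) / (2.0 * a)
    return np.maximum(root, 0.0)


def optimal_contribution(params: StructuralParams, ctx: ScenarioContext) -> float:
    """Optimal own contribution ``y* = argmax_{y >= 0} u(y)``.

    Raises
    ------
    ValueError
        If the marginal benefit M is not positive in this context (no
        interior optimum is guaranteed).
    """
    m = params.marginal_benefit(ctx.econ_risk, ctx.health_risk)
    if not m > 0:
        raise ValueError(
            f"marginal benefit must be > 0 for an interior optimum, got M={m}"
        )
    y = float(
        _optimal_vec(
            np.array([m]), params.gamma, params.kappa,
            np.array([ctx.others_total]), np.array([ctx.others_mean]),
        )[0]
    )
    # boundary check: the interior root must beat contributing (almost) nothing
    eps = 1e-9 if ctx.others_total == 0 else 0.0
    if utility(y, params, ctx) < utility(eps, params, ctx):  # pragma: no cover
        return eps
    return y


def predicted_contributions(params: StructuralParams, assignments: pd.DataFrame) -> np.ndarray:
    """y* for every row of an assignment table (vectorized)."""
    e, h, s, ybar = context_arrays(assignments)
    m = params.alpha + params.beta * e + params.delta * h
    if np.any(m <= 0):
        raise ValueError("marginal benefit is not positive at every design cell")
    return _optimal_vec(m, params.gamma, params.kappa, s, ybar)


def _loglik_arrays(
    y: np.ndarray,
    e: np.ndarray,
    h: np.ndarray,
    s: np.ndarray,
    ybar: np.ndarray,
    params: StructuralParams,
) -> float:
    m = params.alpha + params.beta * e + params.delta * h
    if np.any(m <= 0):
        raise ValueError("marginal benefit is not positive at every design cell")
    ystar = _optimal_vec(m, params.gamma, params.kappa, s, ybar)
    if not params.sigma > 0:
        raise ValueError("sigma must be > 0 to evaluate the likelihood")
    resid = y - ystar
    return float(
        -0.5 * y.size * (_LOG2PI + 2.0 * math.log(params.sigma))
        - 0.5 * np.sum(resid * resid) / (params.sigma ** 2)
    )


def log_likelihood(
    responses: np.ndarray | pd.Series,
    assignments: pd.DataFrame,
    params: StructuralParams,
) -> float:
    """Gaussian reporting log-likelihood of observed cash contributions.

    Observations are treated as independent; each contributes the
    Normal(y*, sigma^2) log-density at the observed value.
    """
    y = np.asarray(responses, dtype=float)
    if len(y) != len(assignments):
        raise ValueError("responses and assignments must have equal length")
    e, h, s, ybar = context_arrays(assignments)
    return _loglik_arrays(y, e, h, s, ybar, params)


def identified_combinations(params: StructuralParams) -> dict[str, float]:
    """Point-identified functions of the structural parameters.

    The predicted-contribution surface, hence the likelihood, depends on
    (alpha, beta, delta, gamma, kappa) only through these combinations; two
    parameter vectors on the same ridge share them exactly.
    """
    c = 1.0 + params.gamma
    return {
        "alpha_scaled": params.alpha / c,
        "beta_scaled": params.beta / c,
        "delta_scaled": params.delta / c,
        "peer_pull": params.gamma * params.kappa / c,
        "sigma": params.sigma,
    }


def wald_ci(estimate: float, std_error: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval ``estimate +- z * std_error``.

    Uses the full-precision normal quantile (1.959964... at level 0.95).
    """
    if not std_error > 0:
        raise ValueError("std_error must be > 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * std_error, estimate + z * std_error


@dataclass
class FitConfig:
    """Settings for :func:`fit_mle`."""

    n_starts: int = 5
    seed: int = 0
    fix_gamma_zero: bool = False
    min_per_cell: int = 1
    conf_level: float = 0.95
    gamma_floor: float = 1e-8
    maxiter: int = 2000


@dataclass
class StructuralFit:
    """Result of a structural maximum-likelihood fit."""

    table: pd.DataFrame
    params: StructuralParams
    loglik: float
    converged: bool
    se_available: bool
    n_obs: int
    n_flat_directions: int = 0
    starts: list[dict] = field(default_factory=list)
    config: FitConfig | None = None


def _pack(params: StructuralParams, fix_gamma: bool) -> np.ndarray:
    if fix_gamma:
        return np.array([params.alpha, params.beta, params.delta, math.log(params.sigma)])
    return np.array([
        params.alpha, params.beta, params.delta,
        math.log(max(params.gamma, 1e-12)), params.kappa, math.log(params.sigma),
    ])


def _unpack(x: np.ndarray, fix_gamma: bool, gamma_floor: float) -> StructuralParams:
    if fix_gamma:
        a, b, d, ls = x
        # kappa is inert when gamma = 0; carry a neutral value internally
        return StructuralParams(a, b, d, 0.0, 1.0, math.exp(ls))
    a, b, d, lg, k, ls = x
    return StructuralParams(a, b, d, max(math.exp(lg), 0.0), k, math.exp(ls))


def _check_cell_counts(assignments: pd.DataFrame, min_per_cell: int) -> None:
    counts = assignments.groupby(["trade", "risk", "deal"]).size()
    grid = full_factorial()
    idx = pd.MultiIndex.from_frame(grid[["trade", "risk", "deal"]])
    counts = counts.reindex(idx, fill_value=0)
    thin = counts[counts < min_per_cell]
    if len(thin):
        raise ValueError(
            f"{len(thin)} design cells have fewer than {min_per_cell} observations; "
            f"first offenders: {thin.index.tolist()[:3]}"
        )


def fit_mle(
    responses: np.ndarray | pd.Series,
    assignments: pd.DataFrame,
    fit_config: FitConfig | None = None,
) -> StructuralFit:
    """Estimate (alpha, beta, delta, gamma, kappa, sigma) by maximum likelihood.

    sigma and gamma are optimized on the log scale; standard errors are
    Wald-type from the inverse numerical Hessian of the negative
    log-likelihood in the natural parameterization, with two-sided normal
    p-values and confidence intervals at ``fit_config.conf_level``.
    Multiple jittered starts guard against local optima; the best converged
    start wins.

    With ``fix_gamma_zero`` the peer term is switched off: gamma is fixed at
    0 and kappa, which then drops out of the model, is reported as NaN with
    no inference.
    """
    cfg = fit_config or FitConfig()
    y = np.asarray(responses, dtype=float)
    if len(y) != len(assignments):
        raise ValueError("responses and assignments must have equal length")
    _check_cell_counts(assignments, cfg.min_per_cell)

    fix_gamma = cfg.fix_gamma_zero
    e, h, s, ybar = context_arrays(assignments)
    sd_y = float(np.std(y, ddof=1)) if len(y) > 1 else 1.0
    sd_y = max(sd_y, 1e-3)

    def negloglik(x: np.ndarray) -> float:
        try:
            p = _unpack(x, fix_gamma, cfg.gamma_floor)
            return -_loglik_arrays(y, e, h, s, ybar, p)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12

    # alpha start from the no-deal baseline cell, where y* = sqrt(M / (2(gamma+1)))
    gamma0, kappa0 = 0.5, 1.0
    nodeal = (s == 0) & (e == 0) & (h == 0)
    mean_y0 = float(np.mean(y[nodeal])) if nodeal.any() else float(np.mean(y))
    alpha0 = max(2.0 * (gamma0 + 1.0) * mean_y0 ** 2, 1.0)
    base = StructuralParams(alpha0, 0.0, 0.0, gamma0, kappa0, sd_y)
    rng = np.random.default_rng(cfg.seed)

    starts: list[np.ndarray] = [_pack(base, fix_gamma)]
    for _ in range(max(cfg.n_starts - 1, 0)):
        jitter = rng.normal(0.0, [0.3, 0.2, 0.2, 0.5, 0.5, 0.2][: 4 if fix_gamma else 6])
        x0 = starts[0] + jitter * np.maximum(np.abs(starts[0]), 1.0)
        starts.append(x0)

    records: list[dict] = []
    best = None
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            negloglik, x0, method="Nelder-Mead",
            options={"maxiter": cfg.maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        res = optimize.minimize(
            negloglik, res.x, method="BFGS",
            options={"maxiter": cfg.maxiter, "gtol": 1e-6},
        )
        records.append(
            {"start": i, "x0": np.asarray(x0).tolist(),
             "loglik": -float(res.fun), "success": bool(res.success)}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"structural fit failed to converge on all {len(starts)} starts; "
            f"start log: {records}"
        )

    params = _unpack(best.x, fix_gamma, cfg.gamma_floor)
    loglik = -float(best.fun)

    se, n_flat = _information_std_errors(params, e, h, s, ybar, fix_gamma)
    se_available = all(np.isfinite(v) or np.isinf(v) for v in se.values())

    estimates = [getattr(params, p) for p in PARAM_NAMES]
    if fix_gamma:
        # gamma is fixed at 0, kappa drops out of the model: no inference
        estimates[PARAM_NAMES.index("kappa")] = float("nan")
        se["gamma"] = float("nan")
        se["kappa"] = float("nan")
    table = _structural_table(PARAM_NAMES, estimates, se, cfg.conf_level)

    return StructuralFit(
        table=table,
        params=params,
        loglik=loglik,
        converged=bool(best.success),
        se_available=se_available,
        n_obs=len(y),
        n_flat_directions=n_flat,
        starts=records,
        config=replace(cfg),
    )


def _information_std_errors(
    params: StructuralParams,
    e: np.ndarray,
    h: np.ndarray,
    s: np.ndarray,
    ybar: np.ndarray,
    fix_gamma: bool,
) -> tuple[dict[str, float], int]:
    """Wald standard errors from the expected information at the optimum.

    The reporting model is nonlinear least squares, so the information for
    the mean parameters is J'J / sigma^2 with J the Jacobian of the
    predicted contributions, and sigma is orthogonal with information
    2n / sigma^2.  The optimum-contribution surface is exactly invariant to
    a joint rescaling of (alpha, beta, delta, 1+gamma) holding
    gamma*kappa / (1+gamma) fixed, so the information matrix has an exact
    null direction: parameters loading on a zero-information direction get
    an *infinite* standard error (their uncertainty is unbounded) instead of
    a noise-driven finite one.  Returns the SE map and the number of flat
    directions found.
    """
    mean_names = ["alpha", "beta", "delta"] + ([] if fix_gamma else ["gamma", "kappa"])
    theta = np.array([getattr(params, p) for p in mean_names])
    n = e.size

    def predict(th: np.ndarray) -> np.ndarray:
        vals = dict(zip(mean_names, th))
        m = vals["alpha"] + vals["beta"] * e + vals["delta"] * h
        gamma = vals.get("gamma", 0.0)
        kappa = vals.get("kappa", 1.0)
        return _optimal_vec(m, max(gamma, 0.0), kappa, s, ybar)

    se = {p: float("nan") for p in PARAM_NAMES}
    try:
        cols = []
        for j in range(len(theta)):
            step = 1e-6 * max(abs(theta[j]), 1.0)
            up, dn = theta.copy(), theta.copy()
            up[j] += step
            dn[j] -= step
            cols.append((predict(up) - predict(dn)) / (2.0 * step))
        jac = np.column_stack(cols)
        info = jac.T @ jac / params.sigma ** 2

        scale = np.sqrt(np.diag(info))
        scale[scale == 0] = 1.0
        lam, vec = np.linalg.eigh(info / np.outer(scale, scale))
        tol = max(lam.max(), 1.0) * 1e-9
        flat = lam < tol
        inv_lam = np.where(flat, 0.0, 1.0 / np.where(flat, 1.0, lam))
        var_scaled = (vec ** 2 * inv_lam).sum(axis=1)
        loads_flat = (vec[:, flat] ** 2).sum(axis=1) > 1e-12
        for i, p in enumerate(mean_names):
            if loads_flat[i]:
                se[p] = float("inf")
            else:
                se[p] = math.sqrt(var_scaled[i]) / scale[i]
        se["sigma"] = params.sigma / math.sqrt(2.0 * n)
        return se, int(flat.sum())
    except (np.linalg.LinAlgError, ValueError):
        return se, 0


def _structural_table(
    names, estimates, se: dict[str, float], level: float
) -> pd.DataFrame:
    """Estimate table that renders unbounded uncertainty explicitly."""
    finite_se = [v if np.isfinite(se[p]) else float("nan") for p, v in
                 ((p, se[p]) for p in names)]
    table = make_estimate_table(list(names), estimates, finite_se, level=level)
    for i, p in enumerate(names):
        if np.isinf(se[p]):
            table.loc[i, "std.error"] = float("inf")
            table.loc[i, "statistic"] = 0.0
            table.loc[i, "p.value"] = 1.0
            table.loc[i, "conf.low"] = float("-inf")
            table.loc[i, "conf.high"] = float("inf")
    return table
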