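"""Shared fixtures: small synthetic panels generated once per session."""

import numpy as np
import pytest

import vaxshare as vs


@pytest.fixture(scope="session")
def truth():
    return vs.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def clean_panel():
    """Noiseless-heterogeneity, uncensored panel: the estimator's home turf."""
    cfg = vs.SimulationConfig(
        n_respondents=400, heterogeneity_sd=0.0, censor_at_zero=False, seed=7
    )
    roster = vs.cohort.generate_respondents(cfg)
    assignments = vs.cohort.assign_vignettes(roster, seed=cfg.seed)
    responses = vs.cohort.simulate_contributions(assignments, roster, cfg)
    return cfg, roster, assignments, responses


@pytest.fixture(scope="session")
def het_panel():
    """Panel with respondent heterogeneity and censoring on (the default)."""
    cfg = vs.SimulationConfig(n_respondents=300, heterogeneity_sd=2.0, seed=11)
    roster = vs.cohort.generate_respondents(cfg)
    assignments = vs.cohort.assign_vignettes(roster, seed=cfg.seed)
    responses = vs.cohort.simulate_contributions(assignments, roster, cfg)
    return cfg, roster, assignments, responses


@pytest.fixture(scope="session")
def het_design(het_panel):
    _, _, assignments, responses = het_panel
    merged = assignments.merge(responses, on=["respondent_id", "vignette_index"])
    return vs.build_design_matrix(merged), merged


def grid_argmax(params, ctx, hi=100.0, step=1e-3):
    """Independent grid-maximization oracle for the optimal contribution."""
    y = np.arange(0.0, hi + step / 2, step)
    m = params.marginal_benefit(ctx.econ_risk, ctx.health_risk)
    s, ybar = ctx.others_total, ctx.others_mean
    with np.errstate(divide="ignore"):
        u = m * np.log(s + y) - params.gamma * (y - params.kappa * ybar) ** 2 - y ** 2
    return y[np.nanargmax(np.where(s + y > 0, u, -np.inf))]
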