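import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import vaxshare as vs
from vaxshare.structural import (
    FitConfig,
    ScenarioContext,
    StructuralParams,
    fit_mle,
    identified_combinations,
    log_likelihood,
    optimal_contribution,
    utility,
    wald_ci,
)

from conftest import grid_argmax


def simple_assignments(cells):
    df = pd.DataFrame(cells, columns=["trade", "risk", "deal"])
    df.insert(0, "vignette_index", (np.arange(len(df)) % 2) + 1)
    df.insert(0, "respondent_id", np.arange(len(df)) // 2 + 1)
    return df


class TestUtility:
    def test_log_one_leaves_cost(self):
        p = StructuralParams(1, 0, 0, 0, 0, 1)
        ctx = ScenarioContext(0, 0, 0.0, 0.0)
        assert utility(1.0, p, ctx) == pytest.approx(-1.0)

    def test_zero_benefit_cost_only(self):
        p = StructuralParams(0, 0, 0, 0, 0, 1)
        ctx = ScenarioContext(0, 0, 1.0, 1.0)
        assert utility(2.0, p, ctx) == pytest.approx(-4.0)

    def test_reference_point_value(self, truth):
        # direct arithmetic oracle at the no-deal baseline optimum
        ctx = ScenarioContext(0, 0, 0.0, 0.0)
        expected = 240.62 * math.log(8.644) - 0.61 * 8.644**2 - 8.644**2
        assert expected == pytest.approx(398.688, abs=1e-3)
        assert utility(8.644, truth, ctx) == pytest.approx(expected, abs=1e-9)

    def test_log_domain_error(self, truth):
        ctx = ScenarioContext(0, 0, 0.0, 0.0)
        with pytest.raises(ValueError, match="domain"):
            utility(0.0, truth, ctx)

    def test_risk_indicators_shift_benefit(self, truth):
        assert truth.marginal_benefit(0, 0) == pytest.approx(240.62)
        assert truth.marginal_benefit(1, 0) == pytest.approx(230.30)
        assert truth.marginal_benefit(0, 1) == pytest.approx(278.41)


class TestOptimalContribution:
    def test_closed_form_reduction(self):
        # gamma = 0, S = 0: 2y^2 = M, so y* = sqrt(M/2) = 1 at M = 2
        p = StructuralParams(2, 0, 0, 0, 0, 1)
        assert optimal_contribution(p, ScenarioContext(0, 0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_baseline_cell(self, truth):
        ctx = ScenarioContext.from_factors(0, 0, 0)
        y = optimal_contribution(truth, ctx)
        assert round(y, 2) == 8.64
        assert abs(y - grid_argmax(truth, ctx)) < 2e-3

    def test_small_deal_cell(self, truth):
        ctx = ScenarioContext.from_factors(0, 0, 1)  # 20 countries, 20 bn
        y = optimal_contribution(truth, ctx)
        assert round(y, 2) == 4.97
        assert abs(y - grid_argmax(truth, ctx)) < 2e-3

    def test_nonpositive_benefit_rejected(self):
        p = StructuralParams(1, -2, 0, 0.5, 1, 1)
        with pytest.raises(ValueError, match="marginal benefit"):
            optimal_contribution(p, ScenarioContext(1, 0, 0.0, 0.0))

    def test_monotone_in_benefit(self):
        ctx = ScenarioContext(0, 1, 20.0, 1.0)
        ys = [
            optimal_contribution(StructuralParams(100, 0, d, 0.5, 2, 1), ctx)
            for d in (0, 20, 50, 100)
        ]
        assert np.all(np.diff(ys) > 0)

    def test_monotone_in_kappa(self):
        ctx = ScenarioContext(0, 0, 20.0, 1.0)
        ys = [
            optimal_contribution(StructuralParams(150, 0, 0, 0.8, k, 1), ctx)
            for k in (0.5, 1, 2, 5)
        ]
        assert np.all(np.diff(ys) > 0)

    def test_local_maximality(self, truth):
        for deal in range(5):
            ctx = ScenarioContext.from_factors(1, 1, deal)
            y = optimal_contribution(truth, ctx)
            u0 = utility(y, truth, ctx)
            for h in (1e-4, 1e-3):
                assert u0 >= utility(y + h, truth, ctx)
                assert u0 >= utility(max(y - h, 1e-9), truth, ctx)


@settings(max_examples=60, deadline=None)
@given(
    alpha=st.floats(20, 400),
    beta=st.floats(-15, 15),
    delta=st.floats(0, 60),
    gamma=st.floats(0, 3),
    kappa=st.floats(0, 8),
    trade=st.integers(0, 1),
    risk=st.integers(0, 1),
    deal=st.integers(0, 4),
)
def test_solver_matches_grid_oracle(alpha, beta, delta, gamma, kappa, trade, risk, deal):
    p = StructuralParams(alpha, beta, delta, gamma, kappa, 1.0)
    ctx = ScenarioContext.from_factors(trade, risk, deal)
    y = optimal_contribution(p, ctx)
    assert abs(y - grid_argmax(p, ctx, hi=40.0)) <= 2e-3


class TestLogLikelihood:
    def test_standard_normal_at_mode(self, truth):
        a = simple_assignments([(0, 0, 0)])
        p = StructuralParams(truth.alpha, truth.beta, truth.delta,
                             truth.gamma, truth.kappa, 1.0)
        ystar = optimal_contribution(p, ScenarioContext.from_factors(0, 0, 0))
        ll = log_likelihood(np.array([ystar]), a, p)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_duplication_doubles(self, clean_panel, truth):
        _, _, a, resp = clean_panel
        ll1 = log_likelihood(resp["cash"], a, truth)
        doubled = pd.concat([a, a], ignore_index=True)
        ll2 = log_likelihood(np.tile(resp["cash"].to_numpy(), 2), doubled, truth)
        assert ll2 == pytest.approx(2 * ll1)

    def test_matches_density_sum_oracle(self, truth):
        rng = np.random.default_rng(0)
        cells = [(rng.integers(0, 2), rng.integers(0, 2), rng.integers(0, 5))
                 for _ in range(30)]
        a = simple_assignments(cells)
        y = rng.normal(6, 10, size=30)
        expected = sum(
            stats.norm.logpdf(
                yi,
                loc=optimal_contribution(truth, ScenarioContext.from_factors(t, r, d)),
                scale=truth.sigma,
            )
            for yi, (t, r, d) in zip(y, cells)
        )
        assert log_likelihood(y, a, truth) == pytest.approx(expected, abs=1e-10)

    def test_sigma_zero_rejected(self, truth):
        a = simple_assignments([(0, 0, 0)])
        p = StructuralParams(truth.alpha, 0, 0, 0, 0, 0.0)
        with pytest.raises(ValueError, match="sigma"):
            log_likelihood(np.array([1.0]), a, p)


class TestWaldCI:
    def test_reference_rows_round_to_printed(self):
        lo, hi = wald_ci(240.62, 2.01)
        assert (round(lo, 2), round(hi, 2)) == (236.68, 244.56)
        lo, hi = wald_ci(5.22, 0.40)
        assert (round(lo, 2), round(hi, 2)) == (4.44, 6.00)

    def test_standard_normal_quantile(self):
        lo, hi = wald_ci(0.0, 1.0)
        assert (round(lo, 2), round(hi, 2)) == (-1.96, 1.96)

    @settings(max_examples=50, deadline=None)
    @given(est=st.floats(-100, 100), se=st.floats(0.01, 50),
           level=st.floats(0.5, 0.99))
    def test_symmetric_and_bracketing(self, est, se, level):
        lo, hi = wald_ci(est, se, level)
        assert lo < est < hi
        assert (est - lo) == pytest.approx(hi - est, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, 0.0)
        with pytest.raises(ValueError):
            wald_ci(0.0, 1.0, level=1.5)


class TestRidge:
    """The likelihood is exactly flat along the rescaling ridge."""

    def test_loglik_invariant_along_ridge(self, clean_panel, truth):
        _, _, a, resp = clean_panel
        ll0 = log_likelihood(resp["cash"], a, truth)
        for c in (0.7, 1.5, 3.0):
            g = c * (1 + truth.gamma) - 1
            k = c * truth.gamma * truth.kappa / g
            p = StructuralParams(c * truth.alpha, c * truth.beta, c * truth.delta,
                                 g, k, truth.sigma)
            assert log_likelihood(resp["cash"], a, p) == pytest.approx(ll0, abs=1e-8)
            ic0 = identified_combinations(truth)
            ic1 = identified_combinations(p)
            for key in ic0:
                assert ic1[key] == pytest.approx(ic0[key], rel=1e-9)


@pytest.fixture(scope="module")
def small_fit(clean_panel):
    _, _, a, resp = clean_panel
    return fit_mle(resp["cash"], a, FitConfig(n_starts=3, seed=1))


class TestFitMLE:
    def test_identified_combinations_recovered(self, small_fit, truth):
        # n = 400 respondents: loose CLT-scale tolerances on the identified scale
        got = identified_combinations(small_fit.params)
        want = identified_combinations(truth)
        assert got["alpha_scaled"] == pytest.approx(want["alpha_scaled"], abs=120)
        assert got["delta_scaled"] == pytest.approx(want["delta_scaled"], abs=150)
        assert got["peer_pull"] == pytest.approx(want["peer_pull"], abs=1.5)
        assert got["sigma"] == pytest.approx(want["sigma"], abs=1.5)

    def test_table_shape_and_consistency(self, small_fit):
        t = small_fit.table
        assert list(t["term"]) == list(vs.structural.PARAM_NAMES)
        finite = np.isfinite(t["std.error"].to_numpy())
        ratio = (t["estimate"] / t["std.error"]).to_numpy()[finite]
        assert np.allclose(ratio, t["statistic"].to_numpy()[finite], rtol=1e-9)
        mid = ((t["conf.low"] + t["conf.high"]) / 2).to_numpy()[finite]
        assert np.allclose(mid, t["estimate"].to_numpy()[finite], rtol=1e-6, atol=1e-9)
        # the flat ridge shows up as exactly one zero-information direction
        assert small_fit.n_flat_directions == 1
        assert np.isinf(t.set_index("term").loc["alpha", "std.error"])
        assert np.isfinite(t.set_index("term").loc["sigma", "std.error"])

    def test_loglik_at_estimate_beats_truth_neighborhood(self, small_fit, clean_panel, truth):
        _, _, a, resp = clean_panel
        assert small_fit.loglik >= log_likelihood(resp["cash"], a, truth) - 1e-6

    def test_noiseless_identifiability(self, truth):
        cfg = vs.SimulationConfig(
            n_respondents=100,
            params=StructuralParams(truth.alpha, truth.beta, truth.delta,
                                    truth.gamma, truth.kappa, 0.0),
            heterogeneity_sd=0.0, censor_at_zero=False, seed=23,
        )
        roster = vs.cohort.generate_respondents(cfg)
        a = vs.cohort.assign_vignettes(roster, seed=23)
        resp = vs.cohort.simulate_contributions(a, roster, cfg)
        at_truth = StructuralParams(truth.alpha, truth.beta, truth.delta,
                                    truth.gamma, truth.kappa, 0.05)
        ll_truth = log_likelihood(resp["cash"], a, at_truth)
        # single-coordinate perturbations leave the ridge -> strictly worse
        for bump in ({"alpha": 5}, {"beta": 5}, {"delta": 5}, {"gamma": 0.2},
                     {"kappa": 0.5}):
            vals = {p: getattr(at_truth, p) for p in vs.structural.PARAM_NAMES}
            for key, dv in bump.items():
                vals[key] += dv
            assert log_likelihood(resp["cash"], a, StructuralParams(**vals)) < ll_truth

    def test_fix_gamma_zero(self, clean_panel):
        _, _, a, resp = clean_panel
        fit = fit_mle(resp["cash"], a, FitConfig(n_starts=2, seed=2, fix_gamma_zero=True))
        t = fit.table.set_index("term")
        assert t.loc["gamma", "estimate"] == 0.0
        assert np.isnan(t.loc["kappa", "estimate"])
        # without the peer term everything remaining is identified
        assert np.isfinite(t.loc["alpha", "std.error"])
        assert fit.n_flat_directions == 0

    def test_min_per_cell_precondition(self, clean_panel):
        _, _, a, resp = clean_panel
        keep = a["deal"] != 4
        with pytest.raises(ValueError, match="design cells"):
            fit_mle(resp["cash"][keep], a[keep], FitConfig(n_starts=1))

    def test_length_mismatch(self, clean_panel):
        _, _, a, resp = clean_panel
        with pytest.raises(ValueError):
            fit_mle(resp["cash"][:-1], a, FitConfig(n_starts=1))
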