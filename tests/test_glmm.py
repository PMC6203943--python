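"""Mixed-model core: closed-form limits, independent GLM cross-check,
quadrature and Monte-Carlo oracles for the Laplace approximation, dispersion
diagnostic, and BIC forward selection."""

import numpy as np
import pandas as pd
import pytest

import deltacpue as dc
from deltacpue.formula import FormulaError, parse_formula
from deltacpue.glmm import (BinomialGLMM, GammaGLMM, HurdleContractError,
                            ModelSpec, build_design, compute_cpue,
                            dispersion_diagnostic, marginal_loglik_oracle,
                            stepwise_select)

from conftest import reduced_truth

FULL_TERMS = ("year", "month", "fleet", "observer")


def small_instance(seed=2, n_sets=400, n_vessels=8):
    truth = reduced_truth(seed=seed, n_sets=n_sets, n_vessels=n_vessels)
    records, truth = dc.generate_logbook(truth)
    return records, truth


# ---------------------------------------------------------------------------
# CPUE
# ---------------------------------------------------------------------------

def test_compute_cpue_values(small_logbook):
    df = pd.DataFrame({"count_blue": [10, 0], "hooks": [2000, 1282]})
    assert compute_cpue(df, "blue").tolist() == [5.0, 0.0]
    # brute-force recomputation over a synthetic dataset
    got = compute_cpue(small_logbook, "blue")
    want = [c * 1000 / h for c, h in
            zip(small_logbook["count_blue"], small_logbook["hooks"])]
    np.testing.assert_allclose(got, want)
    with pytest.raises(ValueError):
        compute_cpue(pd.DataFrame({"count_blue": [1], "hooks": [0]}), "blue")


# ---------------------------------------------------------------------------
# closed-form limits (no random term)
# ---------------------------------------------------------------------------

def test_binomial_intercept_is_logit_proportion():
    df = pd.DataFrame({"count_blue": [1] * 30 + [0] * 70,
                       "hooks": [1000] * 100, "vessel_id": ["v"] * 100})
    est = BinomialGLMM(fixed_terms=(), random_effect=None).fit(df)
    assert abs(est.coef_[0] - np.log(0.3 / 0.7)) < 1e-8


def test_gamma_intercept_is_log_sample_mean(rng):
    cpue = rng.gamma(2.0, 4.0, 300)
    counts = np.maximum(1, np.rint(cpue)).astype(int)
    df = pd.DataFrame({"count_blue": counts, "hooks": [1000] * 300,
                       "vessel_id": ["v"] * 300})
    est = GammaGLMM(fixed_terms=(), random_effect=None).fit(df)
    sample_mean = (counts * 1000 / 1000).mean()
    assert abs(np.exp(est.coef_[0]) - sample_mean) < 1e-8


def test_no_random_term_matches_statsmodels_glm():
    """The fixed-effects-only reduction agrees with an independent GLM fit."""
    import statsmodels.api as sm

    records, _ = small_instance(seed=13, n_sets=600)
    X, names, _ = build_design(records, FULL_TERMS)

    ours = BinomialGLMM(fixed_terms=FULL_TERMS, random_effect=None).fit(records)
    y = (records["count_blue"] > 0).astype(float)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.coef_, ref.params, atol=1e-6)
    assert abs(ours.loglik_ - ref.llf) < 1e-6

    pos = dc.positive_subset(records, "blue")
    oursg = GammaGLMM(fixed_terms=FULL_TERMS, random_effect=None).fit(pos)
    Xg, _, _ = build_design(pos, FULL_TERMS)
    yg = compute_cpue(pos, "blue")
    refg = sm.GLM(yg, Xg, family=sm.families.Gamma(
        link=sm.families.links.Log())).fit()
    np.testing.assert_allclose(oursg.coef_, refg.params, atol=1e-5)


def test_gamma_rejects_zero_response():
    df = pd.DataFrame({"count_blue": [0, 3], "hooks": [1000, 1000],
                       "vessel_id": ["a", "b"], "year": [2000, 2000]})
    with pytest.raises(HurdleContractError):
        GammaGLMM(fixed_terms=(), random_effect=None).fit(df)


# ---------------------------------------------------------------------------
# Laplace vs quadrature / Monte Carlo
# ---------------------------------------------------------------------------

def test_laplace_close_to_quadrature_both_parts():
    records, _ = small_instance(seed=2, n_sets=400, n_vessels=8)
    spec_b = ModelSpec("binomial", FULL_TERMS)
    fit_b = dc.fit_binomial_glmm(records, spec_b)
    ll_q = marginal_loglik_oracle(
        records, spec_b,
        {"coefficients": fit_b.coefficients,
         "sigma_vessel": fit_b.sigma_vessel}, n_nodes=60)
    assert abs(fit_b.loglik - ll_q) / fit_b.n_obs < 1e-3

    pos = dc.positive_subset(records, "blue")
    spec_g = ModelSpec("gamma", FULL_TERMS)
    fit_g = dc.fit_gamma_glmm(pos, spec_g)
    ll_qg = marginal_loglik_oracle(
        pos, spec_g,
        {"coefficients": fit_g.coefficients,
         "sigma_vessel": fit_g.sigma_vessel, "shape": fit_g.shape},
        n_nodes=60)
    assert abs(fit_g.loglik - ll_qg) / fit_g.n_obs < 1e-3


def test_oracle_degenerate_and_convergence():
    records, _ = small_instance(seed=3, n_sets=200, n_vessels=5)
    spec = ModelSpec("binomial", ("year", "fleet"))
    params0 = {"coefficients": {"Intercept": 0.3, "fleet[local]": -0.5},
               "sigma_vessel": 0.0}
    X, names, _ = build_design(records, spec.fixed_terms)
    beta = np.array([params0["coefficients"].get(nm, 0.0) for nm in names])
    eta = X @ beta
    y = (records["count_blue"] > 0).to_numpy(float)
    independent = float(np.sum(y * eta - np.logaddexp(0, eta)))
    assert marginal_loglik_oracle(records, spec, params0) == \
        pytest.approx(independent, abs=1e-10)

    params = {"coefficients": params0["coefficients"], "sigma_vessel": 0.7}
    ll50 = marginal_loglik_oracle(records, spec, params, n_nodes=50)
    ll100 = marginal_loglik_oracle(records, spec, params, n_nodes=100)
    assert abs(ll50 - ll100) < 1e-8


def test_oracle_matches_monte_carlo(rng):
    """GH quadrature agrees with direct Monte-Carlo integration of the
    vessel random effect."""
    records, _ = small_instance(seed=4, n_sets=150, n_vessels=5)
    spec = ModelSpec("binomial", ("year",))
    params = {"coefficients": {"Intercept": 0.2, "year[2001]": 0.3},
              "sigma_vessel": 0.6}
    ll_q = marginal_loglik_oracle(records, spec, params, n_nodes=80)

    X, names, _ = build_design(records, spec.fixed_terms)
    beta = np.array([params["coefficients"].get(nm, 0.0) for nm in names])
    xb = X @ beta
    y = (records["count_blue"] > 0).to_numpy(float)
    vessels, codes = np.unique(records["vessel_id"], return_inverse=True)
    n_draws = 200_000
    total, var_total = 0.0, 0.0
    for j in range(vessels.size):
        idx = codes == j
        u = rng.normal(0.0, params["sigma_vessel"], n_draws)
        eta = xb[idx][None, :] + u[:, None]
        ll = (y[idx][None, :] * eta - np.logaddexp(0, eta)).sum(axis=1)
        w = np.exp(ll - ll.max())
        mean_w = w.mean()
        total += np.log(mean_w) + ll.max()
        var_total += w.var() / (n_draws * mean_w ** 2)  # delta method on log
    assert abs(ll_q - total) < 3 * np.sqrt(var_total)


def test_oracle_refuses_large_instances():
    records, _ = small_instance(seed=5, n_sets=600, n_vessels=30)
    spec = ModelSpec("binomial", ("year",))
    with pytest.raises(ValueError, match="small instances"):
        marginal_loglik_oracle(records, spec,
                               {"coefficients": {}, "sigma_vessel": 0.5})


# ---------------------------------------------------------------------------
# limits and invariants of the fits
# ---------------------------------------------------------------------------

def test_sigma_zero_data_reduce_to_fixed_effects():
    truth = reduced_truth(seed=11, n_sets=4000, n_vessels=20)
    for eff in (truth.blue, truth.mako):
        eff.sigma_vessel_binomial = 0.0
        eff.sigma_vessel_gamma = 0.0
    records, _ = dc.generate_logbook(truth)
    mixed = BinomialGLMM(fixed_terms=FULL_TERMS,
                         random_effect="vessel_id").fit(records)
    fixed = BinomialGLMM(fixed_terms=FULL_TERMS, random_effect=None).fit(records)
    assert np.max(np.abs(mixed.coef_ - fixed.coef_)) < 1e-4


def test_nesting_monotonicity():
    """Adding a fixed term never decreases the maximized log-likelihood."""
    records, _ = small_instance(seed=6, n_sets=800, n_vessels=10)
    base = dc.fit_binomial_glmm(
        records, ModelSpec("binomial", ("year",)), compute_covariance=False)
    bigger = dc.fit_binomial_glmm(
        records, ModelSpec("binomial", ("year", "fleet")),
        compute_covariance=False)
    assert bigger.loglik >= base.loglik - 1e-6


def test_bic_definition_consistency():
    records, _ = small_instance(seed=7, n_sets=500, n_vessels=8)
    fit = dc.fit_binomial_glmm(records, ModelSpec("binomial", ("year",)),
                               compute_covariance=False)
    p = len(fit.coef_names) + 1                       # + log sigma
    assert fit.bic == pytest.approx(-2 * fit.loglik + p * np.log(fit.n_obs))


def test_needs_two_vessels_for_random_term():
    df = pd.DataFrame({"count_blue": [1, 0, 1, 0], "hooks": [1000] * 4,
                       "vessel_id": ["a"] * 4, "year": [2000] * 4})
    with pytest.raises(ValueError, match="vessels"):
        BinomialGLMM(fixed_terms=(), random_effect="vessel_id").fit(df)


def test_rank_deficient_design_rejected():
    df = pd.DataFrame({
        "count_blue": [1, 0, 1, 0] * 10, "hooks": [1000] * 40,
        "vessel_id": ["a", "b"] * 20,
        "fleet": ["local", "foreign"] * 20,
        "observer": ["yes", "no"] * 20,    # perfectly confounded with fleet
    })
    with pytest.raises(ValueError, match="rank deficient"):
        BinomialGLMM(fixed_terms=("fleet", "observer"),
                     random_effect=None).fit(df)


# ---------------------------------------------------------------------------
# dispersion diagnostic
# ---------------------------------------------------------------------------

def _cells_frame(cell_counts):
    """Logbook-like frame whose positive CPUE cells are exactly the given
    integer count patterns (hooks fixed at 1,000 so CPUE == count)."""
    rows = []
    for i, counts in enumerate(cell_counts):
        for c in counts:
            rows.append({"year": 2000 + i, "area": "West", "count_blue": c,
                         "hooks": 1000})
    return pd.DataFrame(rows)


def test_dispersion_slope_two_for_scaled_cells():
    """Cells that are scaled copies of one pattern have variance
    proportional to mean squared, hence slope exactly 2."""
    base = np.array([1, 2, 3, 5, 9])
    frame = _cells_frame([base * (2 ** i) for i in range(6)])
    diag = dispersion_diagnostic(frame, cell_terms=("year",))
    assert diag.available
    assert diag.slope == pytest.approx(2.0, abs=1e-8)


def test_dispersion_slope_zero_for_constant_variance():
    base = np.array([1, 2, 3, 5, 9])
    frame = _cells_frame([base + 10 * i for i in range(6)])
    diag = dispersion_diagnostic(frame, cell_terms=("year",))
    assert diag.slope == pytest.approx(0.0, abs=1e-8)


def test_dispersion_unavailable_when_too_few_cells():
    frame = _cells_frame([[1, 2, 3, 4, 5]])
    diag = dispersion_diagnostic(frame, cell_terms=("year",))
    assert not diag.available
    assert diag.slope is None
    assert "cells" in diag.message


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def test_stepwise_empty_candidates_is_noop():
    records, _ = small_instance(seed=8, n_sets=400, n_vessels=6)
    spec, table = stepwise_select(records, "binomial", candidate_terms=())
    assert spec.fixed_terms == ("year",)
    assert len(table) == 1


def test_stepwise_null_term_not_selected():
    """BIC prefers the null model when the candidate's true effect is 0."""
    wins = 0
    for rep in range(6):
        truth = reduced_truth(seed=300 + rep, n_sets=3000, n_vessels=12)
        for key in list(truth.blue.beta_binomial):
            if key.startswith("observer"):
                truth.blue.beta_binomial[key] = 0.0
        records, _ = dc.generate_logbook(truth)
        spec, _ = stepwise_select(records, "binomial",
                                  candidate_terms=("observer",))
        wins += "observer" not in spec.fixed_terms
    assert wins >= 4


# ---------------------------------------------------------------------------
# formula parsing (config surface)
# ---------------------------------------------------------------------------

def test_parse_formula_full():
    f = parse_formula(
        "presence ~ year + month + fleet + observer + (1|vessel)")
    assert f.response == "presence"
    assert f.fixed_terms == ("year", "month", "fleet", "observer")
    assert f.random_group == "vessel"


@pytest.mark.parametrize("bad", [
    "y ~ a + (1|v) + (1|w)",      # two random terms
    "y ~ a*b",                    # interactions unsupported
    "y z ~ a",                    # bad response
    "no tilde",
])
def test_parse_formula_rejects(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)
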