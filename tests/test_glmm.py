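import dataclasses
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bomarisk.glmm import (
    GlmmFit,
    ModelSpec,
    _group_codes,
    binarize_response,
    design_matrix,
    fit,
    laplace_loglik,
    penalized_loglik_mode,
    wald_table,
)
from bomarisk.synthetic import default_config, simulate_study, published_attempt_coefficients
from conftest import make_boma, make_visit
from _oracles import gh_marginal_loglik, mode_by_simplex

SPEC_BS = ModelSpec("attempt", ("intercept", "boma_type", "season"))


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def _cov():
    from bomarisk.synthetic import CovariateVector
    return {"B1": CovariateVector(1000.0, 500.0, 3000.0, 0.2, 0.4)}


@pytest.mark.parametrize("hyena_attempts,hyena_successes,response,expected", [
    (3, 0, "attempt", 1),
    (0, 0, "attempt", 0),
    (2, 1, "success", 1),
    (2, 0, "success", 0),
])
def test_binarize_hyena_coding(hyena_attempts, hyena_successes, response, expected):
    """Any spotted-hyena event in the window codes the boma-month as 1."""
    bomas = [make_boma("B1")]
    visits = [make_visit("B1", hyena_attempts=hyena_attempts,
                         hyena_successes=hyena_successes)]
    table = binarize_response(visits, bomas, _cov(), response)
    assert table.loc[0, "y"] == expected


def test_binarize_ignores_other_species():
    """The spatiotemporal response is restricted to spotted hyena."""
    bomas = [make_boma("B1")]
    visits = [make_visit("B1", attempts__lion=2)]
    table = binarize_response(visits, bomas, _cov(), "attempt")
    assert table.loc[0, "y"] == 0


@pytest.mark.parametrize("month,expected_season", [(6, 0), (10, 0), (11, 1), (5, 1)])
def test_binarize_season_from_visit_date(month, expected_season):
    """June-October is the dry season, November-May the wet season."""
    bomas = [make_boma("B1")]
    visits = [make_visit("B1", date=dt.date(2010, month, 15))]
    table = binarize_response(visits, bomas, _cov(), "attempt")
    assert table.loc[0, "season"] == expected_season


def test_binarize_rejects_unknown_response():
    with pytest.raises(ValueError, match="response"):
        binarize_response([], [], {}, "harvest")


# ---------------------------------------------------------------------------
# Laplace machinery vs independent oracles
# ---------------------------------------------------------------------------

def _toy_crossed(seed=4, n_v=2, n_t=2, reps=4):
    rng = np.random.default_rng(seed)
    v_idx = np.repeat(np.arange(n_v), n_t * reps)
    t_idx = np.tile(np.repeat(np.arange(n_t), reps), n_v)
    n = len(v_idx)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([-0.3, 0.7])
    u_v = rng.normal(0, 0.5, n_v)
    u_t = rng.normal(0, 0.5, n_t)
    y = (rng.random(n) < expit(X @ beta + u_v[v_idx] + u_t[t_idx])).astype(float)
    return beta, X, y, v_idx, t_idx


def test_mode_matches_simplex_oracle():
    """Newton conditional modes on a 2x2 crossed toy set match a
    derivative-free search on an independently coded objective."""
    beta, X, y, v_idx, t_idx = _toy_crossed()
    sigmas = (0.6, 0.4)
    mode = penalized_loglik_mode(beta, sigmas, X, y, v_idx, t_idx)
    assert mode.converged
    u_oracle = mode_by_simplex(beta, sigmas, X, y, v_idx, t_idx)
    u_ours = np.concatenate([mode.u_village, mode.u_year])
    assert np.max(np.abs(u_ours - u_oracle)) < 1e-4


def test_mode_zero_at_zero_sigma():
    beta, X, y, v_idx, t_idx = _toy_crossed()
    mode = penalized_loglik_mode(beta, (0.0, 0.0), X, y, v_idx, t_idx)
    assert np.all(mode.u_village == 0.0) and np.all(mode.u_year == 0.0)


def test_mode_zero_by_symmetry():
    """One village, one year, y balanced at x = 0: the mode is exactly 0."""
    X = np.ones((4, 1))
    y = np.array([1.0, 1.0, 0.0, 0.0])
    idx = np.zeros(4, int)
    mode = penalized_loglik_mode(np.zeros(1), (0.8, 0.0), X, y, idx, idx)
    assert abs(mode.u_village[0]) < 1e-10


@pytest.mark.parametrize("sigma,tol", [(0.1, 1e-3), (0.3, 1e-3), (0.5, 0.01)])
def test_laplace_matches_quadrature_oracle(sigma, tol):
    """Single grouping factor, 3 groups x 5 obs: Laplace marginal
    log-likelihood agrees with 51-node Gauss-Hermite integration."""
    rng = np.random.default_rng(8)
    groups = np.repeat(np.arange(3), 5)
    n = len(groups)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([-0.5, 0.8])
    y = (rng.random(n) < expit(X @ beta + rng.normal(0, sigma, 3)[groups])).astype(float)
    ll_gh = gh_marginal_loglik(beta, sigma, X, y, groups)
    ll_lap = laplace_loglik(beta, (sigma, 0.0), X, y, groups, np.zeros(n, int))
    assert abs(ll_gh - ll_lap) < tol


def test_laplace_balanced_null_against_oracle():
    """beta = 0 with balanced y: the fixed-effects part is n log(1/2); the
    Laplace value matches the quadrature oracle's correction on top of it."""
    groups = np.repeat(np.arange(4), 6)
    n = len(groups)
    X = np.ones((n, 1))
    y = np.tile([1.0, 0.0], n // 2)
    beta = np.zeros(1)
    ll_gh = gh_marginal_loglik(beta, 0.4, X, y, groups)
    ll_lap = laplace_loglik(beta, (0.4, 0.0), X, y, groups, np.zeros(n, int))
    assert laplace_loglik(beta, (0.0, 0.0), X, y, groups, np.zeros(n, int)) == \
        pytest.approx(n * math.log(0.5))
    assert abs(ll_gh - ll_lap) < 0.01


def test_laplace_sigma_limit_equals_logistic():
    """At sigma -> 0 the Laplace log-likelihood equals the plain logistic
    log-likelihood."""
    beta, X, y, v_idx, t_idx = _toy_crossed(seed=12)
    eta = X @ beta
    ll_logistic = float(y @ eta - np.logaddexp(0.0, eta).sum())
    ll = laplace_loglik(beta, (1e-8, 1e-8), X, y, v_idx, t_idx)
    assert abs(ll - ll_logistic) < 1e-4


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def attempt_table():
    study = simulate_study(default_config(seed=20090101))
    return binarize_response(study.visits, study.bomas, study.covariates, "attempt")


def test_fit_deterministic(attempt_table):
    a = fit(SPEC_BS, attempt_table)
    b = fit(SPEC_BS, attempt_table)
    assert np.array_equal(a.beta, b.beta)
    assert a.loglik == b.loglik
    assert (a.sigma_village, a.sigma_year) == (b.sigma_village, b.sigma_year)


def test_fit_sigma_zero_limit_matches_irls(attempt_table):
    """Data simulated without random effects: the GLMM collapses to plain
    logistic regression (statsmodels IRLS) to 1e-6."""
    import statsmodels.api as sm
    study = simulate_study(default_config(seed=55, sigma_village=0.0, sigma_year=0.0))
    table = binarize_response(study.visits, study.bomas, study.covariates, "attempt")
    f = fit(SPEC_BS, table, fixed_sigmas=(0.0, 0.0))
    assert f.sigma_village == 0.0 and f.sigma_year == 0.0
    X, _ = design_matrix(table, SPEC_BS.fixed_terms)
    ref = sm.Logit(table["y"].to_numpy(float), X).fit(disp=0)
    assert np.max(np.abs(f.beta - ref.params)) < 1e-6
    assert f.loglik == pytest.approx(ref.llf, abs=1e-6)


HYENA_ONLY = {"spotted_hyena": 1.0, "leopard": 0.0, "jackal": 0.0,
              "lion": 0.0, "cheetah": 0.0}


def _recovery_config(seed):
    """30,000 boma-months generated from the published hyena-attempt
    coefficients; hyena-only mixture so the simulated response is exactly the
    modelled one."""
    return default_config(n_pairs=250, visits_per_arm=(15000, 15000),
                          attempt_coefficients=published_attempt_coefficients(),
                          species_mixture=HYENA_ONLY,
                          sigma_village=0.3, sigma_year=0.3, seed=seed)


def test_fit_recovers_generating_parameters():
    """Large-sample recovery: a 30,000 boma-month study generated from the
    published attempt-model coefficients returns every coefficient within
    three standard errors."""
    truth = published_attempt_coefficients()
    study = simulate_study(_recovery_config(606))
    table = binarize_response(study.visits, study.bomas, study.covariates, "attempt")
    f = fit(SPEC_BS, table)
    assert f.converged
    for term in ("intercept", "boma_type", "season"):
        assert abs(f.coef(term) - truth[term]) < 3 * f.coef_se(term)


def test_recovery_bias_and_coverage_over_replicates():
    """Twenty replicate recovery studies: the mean wet-season estimate sits
    within 0.05 of the generating value 1.1009 and the 95% Wald intervals
    cover it in at least 85% of replicates."""
    seeds = np.random.default_rng(314).integers(0, 2**31, size=20)
    estimates, covered = [], 0
    for s in seeds:
        study = simulate_study(_recovery_config(int(s)))
        table = binarize_response(study.visits, study.bomas, study.covariates, "attempt")
        f = fit(SPEC_BS, table)
        est, se = f.coef("season"), f.coef_se("season")
        estimates.append(est)
        covered += abs(est - 1.1009) <= 1.96 * se
    assert abs(np.mean(estimates) - 1.1009) < 0.05
    assert covered >= 17


def test_loglik_monotone_in_nesting(attempt_table):
    """Adding a fixed term never decreases the maximized log-likelihood
    (up to optimizer tolerance)."""
    nested = [
        ModelSpec("attempt", ("intercept",)),
        ModelSpec("attempt", ("intercept", "boma_type")),
        ModelSpec("attempt", ("intercept", "boma_type", "season")),
        ModelSpec("attempt", ("intercept", "boma_type", "season", "ndvi")),
    ]
    lls = [fit(s, attempt_table).loglik for s in nested]
    for smaller, larger in zip(lls, lls[1:]):
        assert larger >= smaller - 1e-4


def test_village_relabeling_invariance(attempt_table):
    """Renaming village identifiers leaves the fit unchanged."""
    renamed = attempt_table.copy()
    renamed["village"] = "zz_" + renamed["village"].astype(str)
    a = fit(SPEC_BS, attempt_table)
    b = fit(SPEC_BS, renamed)
    assert np.max(np.abs(a.beta - b.beta)) < 1e-6
    assert a.loglik == pytest.approx(b.loglik, abs=1e-6)
    assert a.sigma_village == pytest.approx(b.sigma_village, abs=1e-6)


def test_fit_handles_sigma_boundary():
    """Fits on exchangeable data keep sigma estimates at or near the zero
    boundary without crashing, and k still counts both variance components."""
    study = simulate_study(default_config(seed=77, sigma_village=0.0, sigma_year=0.0))
    table = binarize_response(study.visits, study.bomas, study.covariates, "attempt")
    f = fit(SPEC_BS, table)
    assert f.sigma_village >= 0.0 and f.sigma_year >= 0.0
    assert f.sigma_village < 0.35 and f.sigma_year < 0.35  # noise scale, not signal
    assert f.k == 5


def test_fit_rejects_empty_table():
    with pytest.raises(ValueError, match="empty"):
        fit(SPEC_BS, pd.DataFrame(columns=["y", "village", "year", "season", "boma_type"]))


def test_spec_validation():
    with pytest.raises(ValueError, match="intercept"):
        ModelSpec("attempt", ("boma_type",))
    with pytest.raises(ValueError, match="unique"):
        ModelSpec("attempt", ("intercept", "season", "season"))
    with pytest.raises(ValueError, match="response"):
        ModelSpec("harvest", ("intercept",))
    assert SPEC_BS.k == 5


# ---------------------------------------------------------------------------
# Wald inference
# ---------------------------------------------------------------------------

def _fake_fit(terms, beta, se):
    p = len(terms)
    return GlmmFit(spec=ModelSpec("attempt", tuple(terms)), terms=tuple(terms),
                   beta=np.array(beta, float), se=np.array(se, float),
                   vcov=np.diag(np.square(se)), sigma_village=0.3, sigma_year=0.3,
                   loglik=-100.0, n_obs=1000, k=p + 2, converged=True,
                   u_hat={"village": {}, "year": {}}, scaling={})


def test_wald_z_p_ci_and_odds_ratio():
    """z = estimate/se, two-sided normal p, CI = estimate +/- 1.96 se,
    OR = exp(estimate); the intercept row carries no odds ratio."""
    f = _fake_fit(["intercept", "season"], [-2.9777, 1.1009], [0.3249, 0.2423])
    table = wald_table(f).set_index("term")
    season = table.loc["season"]
    assert season["z"] == pytest.approx(4.5430, abs=1e-3)
    assert season["odds_ratio"] == pytest.approx(3.007, abs=1e-3)
    assert season["ci_low"] == pytest.approx(1.1009 - 1.96 * 0.2423, abs=1e-9)
    assert season["p"] < 1e-5
    assert np.isnan(table.loc["intercept", "odds_ratio"])


def test_wald_zero_estimate_unit_odds():
    f = _fake_fit(["intercept", "boma_type"], [-1.0, 0.0], [0.2, 0.3])
    table = wald_table(f).set_index("term")
    assert table.loc["boma_type", "odds_ratio"] == 1.0


def test_wald_flags_undefined_se(caplog):
    f = _fake_fit(["intercept", "season"], [-1.0, 0.5], [0.2, np.nan])
    with caplog.at_level("WARNING"):
        table = wald_table(f).set_index("term")
    assert np.isnan(table.loc["season", "z"])
    assert "season" in caplog.text
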