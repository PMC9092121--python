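"""Gompertz PH fitting: likelihood, MLE, Wald inference, Bayesian variant."""

import json

import numpy as np
import pytest
from scipy import integrate

from lifegain import (ConvergenceError, GompertzPH, GompertzPHResults,
                      SimulationConfig, generate_cohort)
from lifegain.gompertz import build_design


def _model(entry, exit_, event, X=None, names=(), label="test"):
    return GompertzPH(entry, exit_, event, X, names, label=label)


# ---------------------------------------------------------------- likelihood

def test_loglike_exponential_closed_forms():
    m = _model([40.0], [41.0], [1.0])
    assert m.loglike([np.log(0.01), 0.0]) == pytest.approx(np.log(0.01) - 0.01)
    mc = _model([40.0], [41.0], [0.0])
    assert mc.loglike([np.log(0.01), 0.0]) == pytest.approx(-0.01)


def test_loglike_empty_cohort_is_zero_and_rejects_nonfinite():
    m = _model([], [], [])
    assert m.loglike([-5.0, 0.1]) == 0.0
    m2 = _model([40.0], [41.0], [1.0])
    with pytest.raises(ValueError):
        m2.loglike([np.nan, 0.1])


def test_loglike_matches_quadrature():
    """Analytic cumulative hazard equals numerical quadrature, subject by subject."""
    rng = np.random.default_rng(4)
    n = 100
    entry = rng.uniform(40, 75, n)
    exit_ = entry + rng.uniform(0.5, 20, n)
    event = rng.integers(0, 2, n).astype(float)
    X = rng.normal(size=(n, 2))
    params = np.array([np.log(3e-4), 0.1, -0.2, 0.15])
    m = _model(entry, exit_, event, X, ("a", "b"))

    ll = 0.0
    for i in range(n):
        lp = X[i] @ params[2:]
        haz = lambda a: np.exp(params[0] + lp) * np.exp(params[1] * (a - 40.0))
        H, _ = integrate.quad(haz, entry[i], exit_[i], epsabs=1e-13, epsrel=1e-13)
        if event[i]:
            ll += np.log(haz(exit_[i]))
        ll -= H
    assert m.loglike(params) == pytest.approx(ll, abs=1e-8)


def test_score_matches_finite_differences():
    rng = np.random.default_rng(7)
    n = 50
    entry = rng.uniform(40, 70, n)
    exit_ = entry + rng.uniform(1, 15, n)
    event = rng.integers(0, 2, n).astype(float)
    X = rng.normal(size=(n, 1))
    m = _model(entry, exit_, event, X, ("x",))
    p = np.array([-7.0, 0.08, -0.1])
    g = m.score(p)
    for j in range(3):
        h = 1e-6
        up, dn = p.copy(), p.copy()
        up[j] += h; dn[j] -= h
        fd = (m.loglike(up) - m.loglike(dn)) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)


# ------------------------------------------------------------------- fitting

def test_mle_recovers_exponential_truth():
    """Uncensored gamma=0 data: lambda within 3 SE of truth, gamma within 3 SE of 0."""
    cfg = SimulationConfig(n_men=20_000, n_women=0, entry_age_range=(40.0, 40.0),
                           true_lambda={"M": 0.02, "F": 0.02},
                           true_gamma={"M": 0.0, "F": 0.0}, true_betas={},
                           moveout_rate=0.0, admin_followup=1000.0, seed=9)
    df, _ = generate_cohort(cfg)
    m = GompertzPH(df["entry_age"], df["exit_age"], df["event"], label="men")
    res = m.fit()
    assert abs(res.params[0] - np.log(0.02)) < 3 * res.bse[0]
    assert abs(res.gamma) < 3 * res.bse[1]


def test_fixed_gamma_zero_equals_exponential_mle():
    """With gamma pinned at 0 the intercept fit is the closed-form rate D / person-years."""
    rng = np.random.default_rng(10)
    entry = np.full(500, 40.0)
    exit_ = entry + rng.exponential(1 / 0.03, 500)
    m = _model(entry, exit_, np.ones(500))
    res = m.fit(fix_gamma=0.0)
    rate_mle = 500 / (exit_ - entry).sum()
    assert res.lambda_ == pytest.approx(rate_mle, rel=1e-6)
    assert res.gamma == 0.0


def test_zero_events_and_degenerate_design_raise():
    m = _model([40.0] * 5, [45.0] * 5, [0.0] * 5, label="clones")
    with pytest.raises(ValueError, match="zero events"):
        m.fit()
    X = np.ones((5, 1))
    m2 = _model([40.0] * 5, [45.0] * 5, [1.0] * 5, X, ("const",))
    with pytest.raises(ValueError, match="constant"):
        m2.fit()
    X3 = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
    m3 = _model([40.0] * 5, [45.0] * 5, [1.0] * 5, X3, ("a", "b"))
    with pytest.raises(ValueError, match="collinear"):
        m3.fit()


def test_left_truncation_is_honoured():
    """Ignoring delayed entry biases gamma; the truncated likelihood does not."""
    cfg = SimulationConfig(n_men=20_000, n_women=0, true_betas={}, seed=14)
    df, _ = generate_cohort(cfg)
    gam_true = cfg.true_gamma["M"]
    correct = GompertzPH(df["entry_age"], df["exit_age"], df["event"]).fit()
    naive = GompertzPH(np.full(len(df), 40.0), df["exit_age"], df["event"]).fit()
    assert abs(correct.gamma - gam_true) < 4 * correct.bse[1]
    assert abs(naive.gamma - gam_true) > 10 * correct.bse[1]


def test_age_origin_shift_invariance():
    cfg = SimulationConfig(n_men=4000, n_women=0, seed=15)
    df, _ = generate_cohort(cfg)
    from lifegain import score_records, complete_case_filter
    kept, _ = complete_case_filter(score_records(df))
    X, names = build_design(kept, ("score",))
    m1 = GompertzPH(kept["entry_age"], kept["exit_age"], kept["event"], X, names)
    m2 = GompertzPH(kept["entry_age"] + 5, kept["exit_age"] + 5, kept["event"],
                    X, names, age_origin=45.0)
    b1, b2 = m1.fit().betas["score"], m2.fit().betas["score"]
    assert b1 == pytest.approx(b2, abs=1e-6)


# ------------------------------------------------------------- hazard ratios

def test_wald_hazard_ratio_arithmetic():
    res = GompertzPHResults.from_json(json.dumps({
        "param_names": ["log_lambda", "gamma", "x", "z"],
        "params": [-7.0, 0.1, -0.105, 0.0],
        "cov": np.diag([0.01, 1e-5, 0.02**2, 0.05**2]).tolist(),
        "free": [1, 1, 1, 1], "loglik": 0.0, "nobs": 10, "n_events": 5,
        "age_origin": 40.0, "label": "t"}))
    hrs = res.hazard_ratios()
    x = hrs[hrs["covariate"] == "x"].iloc[0]
    assert round(x["hr"], 2) == 0.90
    assert round(x["ci_low"], 3) == 0.866 and round(x["ci_high"], 3) == 0.936
    z = hrs[hrs["covariate"] == "z"].iloc[0]
    assert z["hr"] == 1.0
    assert z["ci_low"] <= 1.0 <= z["ci_high"]


def test_wald_ci_coverage_for_null_covariate():
    """A covariate with true HR = 1 is covered by the 95% CI at the nominal rate."""
    covered = 0
    for rep in range(100):
        cfg = SimulationConfig(n_men=1500, n_women=0, true_betas={"score": -0.08},
                               seed=1000 + rep)
        df, _ = generate_cohort(cfg)
        from lifegain import score_records, complete_case_filter
        kept, _ = complete_case_filter(score_records(df))
        res = GompertzPH.from_dataframe(kept, covariates=("score", "education"),
                                        sex="M").fit()
        # education has no effect in the generator
        i = res.param_names.index("education")
        lo, hi = res.conf_int()[i]
        covered += lo <= 0.0 <= hi
    assert 89 <= covered <= 99


def test_serialization_roundtrip(scored_cohort):
    res = GompertzPH.from_dataframe(scored_cohort, covariates=("band",),
                                    sex="F").fit()
    back = GompertzPHResults.from_json(res.to_json())
    np.testing.assert_allclose(back.params, res.params)
    np.testing.assert_allclose(back.cov, res.cov)
    assert back.param_names == res.param_names
    assert back.n_events == res.n_events
    # derived quantities still work without the data attached
    assert back.expectancy(40.0) == pytest.approx(res.expectancy(40.0))


def test_summary_mentions_key_quantities(scored_cohort):
    res = GompertzPH.from_dataframe(scored_cohort, covariates=("score",),
                                    sex="M").fit()
    text = res.summary()
    assert "gamma" in text and "score" in text and "events" in text


# ----------------------------------------------------------------- Bayesian

@pytest.fixture(scope="module")
def bayes_setup(scored_cohort):
    model = GompertzPH.from_dataframe(scored_cohort, covariates=("score",),
                                      sex="M")
    return model, model.fit()


def test_laplace_single_noiseless_draw_is_map(bayes_setup):
    model, _ = bayes_setup
    b = model.fit_bayes(draws=1, seed=3, scale=0.0)
    np.testing.assert_allclose(b.draws[0], b.map_params)


def test_posterior_draws_deterministic_given_seed(bayes_setup):
    model, _ = bayes_setup
    a = model.fit_bayes(draws=50, seed=11)
    b = model.fit_bayes(draws=50, seed=11)
    np.testing.assert_array_equal(a.draws, b.draws)
    m1 = model.fit_bayes(draws=50, seed=11, method="metropolis", burn=100)
    m2 = model.fit_bayes(draws=50, seed=11, method="metropolis", burn=100)
    np.testing.assert_array_equal(m1.draws, m2.draws)


def test_bernstein_von_mises_agreement(bayes_setup):
    """Flat-ish priors, large n: posterior mean within 1 SE of the MLE."""
    model, mle = bayes_setup
    b = model.fit_bayes(draws=2000, seed=5)
    post_mean = b.posterior_mean()
    for i in range(len(post_mean)):
        assert abs(post_mean[i] - mle.params[i]) < mle.bse[i], \
            mle.param_names[i]


def test_metropolis_reports_reasonable_acceptance(bayes_setup):
    model, _ = bayes_setup
    b = model.fit_bayes(draws=400, seed=2, method="metropolis", burn=400)
    assert 0.1 <= b.acceptance <= 0.6
    assert np.all(np.isfinite(b.draws))
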