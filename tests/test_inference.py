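"""MCMC fitting, convergence diagnostics, DIC, posterior summaries."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import jointprev as jp
from jointprev.mcmc import FitResult, MCMCConfig, _batch_mc_error


def _tiny_dataset(seed=21, n=600, n_counties=9, n_states=2):
    cfg = jp.SimulationConfig(n_counties=n_counties, n_states=n_states,
                              n_respondents=n, seed=seed)
    return jp.generate_dataset(cfg)


# ---------------------------------------------------------------------------
# run_mcmc


def test_same_seed_reproduces_chain_exactly():
    resp, cnty, geo, _ = _tiny_dataset()
    spec = jp.ModelSpecification.from_number(2)
    cfg = MCMCConfig(n_chains=2, n_iterations=120, seed=5)
    f1 = jp.run_mcmc(resp, cnty, geo.county_graph, geo.state_graph, spec, cfg)
    f2 = jp.run_mcmc(resp, cnty, geo.county_graph, geo.state_graph, spec, cfg)
    for k in f1.draws:
        np.testing.assert_array_equal(f1.draws[k], f2.draws[k])
    np.testing.assert_array_equal(f1.deviance, f2.deviance)


def test_draw_constraints_hold_throughout():
    resp, cnty, geo, _ = _tiny_dataset()
    spec = jp.ModelSpecification.from_number(3)
    fit = jp.run_mcmc(resp, cnty, geo.county_graph, geo.state_graph, spec,
                      MCMCConfig(n_chains=2, n_iterations=150, seed=6))
    assert np.allclose(fit.pooled("v").sum(axis=1), 0.0, atol=1e-8)
    assert np.allclose(fit.pooled("u").sum(axis=1), 0.0, atol=1e-8)
    assert np.allclose(fit.pooled("eta").sum(axis=2), 0.0, atol=1e-8)
    assert np.all(fit.pooled("lam")[:, 0] == 1.0)
    assert np.all(fit.pooled("beta")[:, :, 0] == 0.0)
    assert np.all(fit.pooled("sigma2_v") > 0.0)


def test_deviance_trace_matches_full_recomputation():
    """The incrementally maintained deviance equals -2x the weighted
    log-likelihood recomputed from scratch at the recorded draw."""
    resp, cnty, geo, _ = _tiny_dataset()
    spec = jp.ModelSpecification.from_number(3)
    fit = jp.run_mcmc(resp, cnty, geo.county_graph, geo.state_graph, spec,
                      MCMCConfig(n_chains=1, n_iterations=100, seed=7))
    d = fit.draws
    i = fit.n_kept - 1
    p = jp.ParameterSet(
        alpha=d["alpha"][0, i], beta=d["beta"][0, i], gamma=d["gamma"][0, i],
        eta=d["eta"][0, i], delta=d["delta"][0, i], v=d["v"][0, i], u=d["u"][0, i],
        lam=d["lam"][0, i], kappa=d["kappa"][0, i],
        sigma2_v=d["sigma2_v"][0, i], sigma2_u=d["sigma2_u"][0, i],
        Sigma_eta=d["Sigma_eta"][0, i])
    r2 = resp.copy()
    w = r2["weight"].to_numpy()
    r2["weight"] = w * len(w) / w.sum()
    dev = -2.0 * jp.weighted_loglik(r2, cnty, p, spec)
    assert fit.deviance[0, i] == pytest.approx(dev, rel=1e-8)


def test_intercept_posterior_matches_empirical_logodds_oracle():
    """With one county and one state the latent fields are pinned at zero and
    a single age group makes alpha_j + eta_{j,1} the saturated multinomial
    intercept; its posterior must concentrate at the empirical log-odds."""
    rng = np.random.default_rng(5)
    n = 20_000
    shares = np.array([0.05, 0.04, 0.02, 0.22, 0.40, 0.27])
    y = rng.choice(6, size=n, p=shares) + 1
    resp = pd.DataFrame({
        "id": np.arange(1, n + 1), "age_group": 1, "race": 1, "education": 1,
        "county": 1, "weight": 1.0, "category": y})
    cnty = pd.DataFrame({
        "county": [1], "state": [1], "poverty": [0.1], "log_density": [4.0],
        "top_black": [0], "top_hisp": [0], "top_other": [0]})
    g1 = jp.AdjacencyGraph(1, [[]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = jp.run_mcmc(resp, cnty, g1, g1, jp.ModelSpecification.from_number(1),
                          MCMCConfig(n_chains=2, n_iterations=2000, seed=7))
    emp = np.bincount(y - 1, minlength=6) / n
    logit = np.log(emp[:5] / emp[5])
    post = fit.pooled("alpha") + fit.pooled("eta")[:, :, 0]
    z = (post.mean(axis=0) - logit) / post.std(axis=0)
    assert np.all(np.abs(z) < 3.0)
    assert np.allclose(fit.pooled("v"), 0.0)


# ---------------------------------------------------------------------------
# Gelman-Rubin


class TestGelmanRubin:
    def test_identical_chains_hit_the_correction_floor(self, rng):
        x = rng.normal(0, 1, 5000)
        chains = np.stack([x, x])
        floor = math.sqrt((len(x) - 1) / len(x))
        assert jp.gelman_rubin(chains) == pytest.approx(floor, abs=1e-6)

    def test_independent_chains_from_same_distribution(self):
        r1 = np.random.default_rng(1).normal(0, 1, 5000)
        r2 = np.random.default_rng(2).normal(0, 1, 5000)
        assert jp.gelman_rubin(np.stack([r1, r2])) < 1.05

    def test_disjoint_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert jp.gelman_rubin(chains) > 5.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(jp.ValidationError):
            jp.gelman_rubin(rng.normal(0, 1, (1, 100)))

    def test_dict_input_returns_series(self, rng):
        out = jp.gelman_rubin({"a": rng.normal(0, 1, (2, 200)),
                               "b": rng.normal(0, 1, (2, 200))})
        assert list(out.index) == ["a", "b"]


# ---------------------------------------------------------------------------
# DIC


def _manual_fit(resp, cnty, draws_list, spec):
    """Assemble a FitResult from explicit parameter draws (one chain)."""
    keys = ("alpha", "beta", "gamma", "eta", "delta", "v", "u", "lam", "kappa",
            "sigma2_v", "sigma2_u", "Sigma_eta")
    stacked = {k: np.stack([np.asarray(getattr(p, k)) for p in draws_list])[None]
               for k in keys}
    cfg = MCMCConfig(n_chains=1, n_iterations=2 * len(draws_list), seed=0,
                     normalize_weights=False)
    dev = np.array([[-2.0 * jp.weighted_loglik(resp, cnty, p, spec)
                     for p in draws_list]])
    return FitResult(draws=stacked, deviance=dev, acceptance={}, spec=spec,
                     config=cfg, n_counties=len(cnty), n_states=1)


def _dic_fixture(rng):
    cnty = pd.DataFrame({
        "county": [1], "state": [1], "poverty": [0.1], "log_density": [4.0],
        "top_black": [0], "top_hisp": [0], "top_other": [0]})
    resp = pd.DataFrame({
        "id": [1, 2, 3], "age_group": [1, 2, 3], "race": [1, 1, 1],
        "education": [1, 1, 1], "county": [1, 1, 1], "weight": [1.0, 2.0, 1.5],
        "category": [1, 6, 4]})
    return resp, cnty


def test_dic_point_mass_posterior_has_zero_pd(rng):
    resp, cnty = _dic_fixture(rng)
    spec = jp.ModelSpecification.from_number(1)
    p = jp.ParameterSet.zeros(1, 1)
    fit = _manual_fit(resp, cnty, [p, p, p], spec)
    dic = jp.compute_dic(fit, resp, cnty)
    assert dic.p_d == pytest.approx(0.0, abs=1e-9)
    assert dic.dic == pytest.approx(fit.deviance[0, 0], rel=1e-12)


def test_dic_two_draw_arithmetic_oracle(rng):
    resp, cnty = _dic_fixture(rng)
    spec = jp.ModelSpecification.from_number(1)
    p1 = jp.ParameterSet.zeros(1, 1)
    p2 = jp.ParameterSet.zeros(1, 1)
    p2.alpha = np.array([0.4, -0.2, 0.1, 0.0, 0.3])
    fit = _manual_fit(resp, cnty, [p1, p2], spec)
    dic = jp.compute_dic(fit, resp, cnty)
    d1 = -2.0 * jp.weighted_loglik(resp, cnty, p1, spec)
    d2 = -2.0 * jp.weighted_loglik(resp, cnty, p2, spec)
    pmean = jp.ParameterSet.zeros(1, 1)
    pmean.alpha = (p1.alpha + p2.alpha) / 2
    d_mean = -2.0 * jp.weighted_loglik(resp, cnty, pmean, spec)
    dbar = (d1 + d2) / 2
    assert dic.dbar == pytest.approx(dbar, rel=1e-12)
    assert dic.p_d == pytest.approx(dbar - d_mean, rel=1e-10)
    assert dic.dic == pytest.approx(dic.dbar + dic.p_d, rel=1e-15)


def test_dic_empty_trace_rejected(rng):
    resp, cnty = _dic_fixture(rng)
    spec = jp.ModelSpecification.from_number(1)
    fit = _manual_fit(resp, cnty, [jp.ParameterSet.zeros(1, 1)], spec)
    fit.deviance = np.empty((1, 0))
    with pytest.raises(jp.ValidationError):
        jp.compute_dic(fit, resp, cnty)


# ---------------------------------------------------------------------------
# summaries


def test_summary_constant_draws(rng):
    resp, cnty = _dic_fixture(rng)
    spec = jp.ModelSpecification.from_number(1)
    p = jp.ParameterSet.zeros(1, 1)
    fit = _manual_fit(resp, cnty, [p] * 4, spec)
    s = jp.summarize(fit)
    row = s.loc["alpha[1]"]
    assert row["sd"] == 0.0
    assert row["mc_error"] == 0.0
    assert row["q2.5"] == row["mean"] == row["q97.5"]


def test_summary_standard_normal_draws():
    x = np.random.default_rng(3).normal(0, 1, 10_000)
    assert abs(x.mean()) < 0.03
    assert np.quantile(x, 0.025) == pytest.approx(-1.96, abs=0.05)
    assert _batch_mc_error(x) == pytest.approx(1 / math.sqrt(10_000), rel=0.5)


def test_summary_quantile_ordering():
    resp, cnty, geo, _ = _tiny_dataset()
    spec = jp.ModelSpecification.from_number(1)
    fit = jp.run_mcmc(resp, cnty, geo.county_graph, geo.state_graph, spec,
                      MCMCConfig(n_chains=2, n_iterations=150, seed=8))
    s = jp.summarize(fit)
    assert (s["q2.5"] <= s["mean"]).all()
    assert (s["mean"] <= s["q97.5"]).all()


def test_config_validation():
    with pytest.raises(jp.ValidationError):
        MCMCConfig(n_chains=0).validate()
    with pytest.raises(jp.ValidationError):
        MCMCConfig(burnin_fraction=1.0).validate()
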