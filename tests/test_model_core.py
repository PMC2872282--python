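"""Core model: linear predictor, probabilities, likelihood, priors,
constraints, top-decile coding."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfnorm, invwishart, multivariate_normal, norm

import jointprev as jp
from jointprev.model import eta_rw1_logpdf

from conftest import random_params


def spec(n):
    return jp.ModelSpecification.from_number(n)


# ---------------------------------------------------------------------------
# linear predictor


class TestLinearPredictor:
    def test_zero_parameters_give_zero_logodds(self, counties10, respondents20):
        p = jp.ParameterSet.zeros(10, 2)
        phi = jp.linear_predictor(respondents20, counties10, p, spec(3))
        assert phi.shape == (20, 5)
        assert np.all(phi == 0.0)

    def test_model1_masks_race_education_and_covariates(self, counties10,
                                                        respondents20, rng):
        p = random_params(rng)
        phi1 = jp.linear_predictor(respondents20, counties10, p, spec(1))
        p_zeroed = p.copy()
        p_zeroed.beta[:] = 0.0
        p_zeroed.gamma[:] = 0.0
        p_zeroed.delta[:] = 0.0
        phi3 = jp.linear_predictor(respondents20, counties10, p_zeroed, spec(3))
        np.testing.assert_array_equal(phi1, phi3)

    def test_matches_termwise_hand_summation(self, counties10, respondents20, rng):
        p = random_params(rng)
        phi = jp.linear_predictor(respondents20, counties10, p, spec(3))
        cnty = counties10.set_index("county")
        for i, row in enumerate(respondents20.itertuples(index=False)):
            c = int(row.county)
            x = cnty.loc[c, ["poverty", "log_density", "top_black", "top_hisp",
                             "top_other"]].to_numpy(dtype=float)
            s = int(cnty.loc[c, "state"])
            for j in range(5):
                expected = (
                    p.alpha[j]
                    + p.beta[j, int(row.race) - 1]
                    + p.gamma[j, int(row.education) - 1]
                    + p.eta[j, int(row.age_group) - 1]
                    + float(np.dot(p.delta[j], x))
                    + p.lam[j] * p.v[c - 1]
                    + p.kappa[j] * p.u[s - 1]
                )
                assert phi[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unknown_county_raises(self, counties10, respondents20):
        bad = respondents20.copy()
        bad.loc[0, "county"] = 99
        with pytest.raises(jp.ValidationError):
            jp.linear_predictor(bad, counties10, jp.ParameterSet.zeros(10, 2), spec(3))


# ---------------------------------------------------------------------------
# category probabilities


@pytest.mark.parametrize("phi,expected", [
    (np.zeros(5), np.full(6, 1 / 6)),
    (np.array([np.log(2.0), 0, 0, 0, 0]), np.array([2, 1, 1, 1, 1, 1]) / 7.0),
])
def test_category_probs_closed_forms(phi, expected):
    np.testing.assert_allclose(jp.category_probs(phi)[0], expected, atol=1e-14)


def test_category_probs_saturation_is_overflow_safe():
    pi = jp.category_probs(np.array([50.0, 0, 0, 0, 0]))[0]
    assert pi[0] > 1 - 1e-15
    assert np.all(pi[1:] < 1e-15)
    assert pi.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# weighted log-likelihood


def _one_respondent(weight, category=3):
    resp = pd.DataFrame({
        "id": [1], "age_group": [5], "race": [2], "education": [3],
        "county": [1], "weight": [weight], "category": [category],
    })
    cnty = pd.DataFrame({
        "county": [1], "state": [1], "poverty": [0.1], "log_density": [4.0],
        "top_black": [0], "top_hisp": [0], "top_other": [0],
    })
    return resp, cnty


def test_loglik_uniform_case():
    resp, cnty = _one_respondent(1.0)
    ll = jp.weighted_loglik(resp, cnty, jp.ParameterSet.zeros(1, 1), spec(1))
    assert ll == pytest.approx(math.log(1 / 6), abs=1e-12)


def test_loglik_linear_in_weights():
    resp, cnty = _one_respondent(2.5)
    ll = jp.weighted_loglik(resp, cnty, jp.ParameterSet.zeros(1, 1), spec(1))
    assert ll == pytest.approx(2.5 * math.log(1 / 6), abs=1e-12)


def test_loglik_matches_product_form_oracle(counties10, respondents20, rng):
    """Brute-force oracle: per-record product of pi^(w*d), exponentiated then
    logged, term by term."""
    p = random_params(rng)
    ll = jp.weighted_loglik(respondents20, counties10, p, spec(3))
    phi = jp.linear_predictor(respondents20, counties10, p, spec(3))
    oracle = 0.0
    for i in range(len(respondents20)):
        pi = np.exp(phi[i]) / (1 + np.exp(phi[i]).sum())
        pi = np.append(pi, 1 / (1 + np.exp(phi[i]).sum()))
        y = respondents20.loc[i, "category"] - 1
        w = respondents20.loc[i, "weight"]
        oracle += math.log(pi[y] ** w)
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_loglik_model_nesting(counties10, respondents20, rng):
    p = random_params(rng)
    p.beta[:] = 0.0
    p.gamma[:] = 0.0
    p.delta[:] = 0.0
    ll1 = jp.weighted_loglik(respondents20, counties10, p, spec(1))
    ll3 = jp.weighted_loglik(respondents20, counties10, p, spec(3))
    assert ll1 == ll3


def test_loglik_permutation_invariance(counties10, respondents20, rng):
    p = random_params(rng)
    shuffled = respondents20.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert jp.weighted_loglik(respondents20, counties10, p, spec(3)) == pytest.approx(
        jp.weighted_loglik(shuffled, counties10, p, spec(3)), rel=1e-12)


# ---------------------------------------------------------------------------
# intrinsic CAR kernel


def test_icar_constant_field_has_zero_quadratic(path5):
    base = jp.icar_logpdf_kernel(np.zeros(5), path5, 1.0, normalized=False)
    assert base == 0.0


def test_icar_two_node_single_difference():
    g = jp.AdjacencyGraph.from_edges(2, [(0, 1)])
    d = 1.7
    x = np.array([d / 2, -d / 2])
    val = jp.icar_logpdf_kernel(x, g, 1.0, normalized=False)
    zero = jp.icar_logpdf_kernel(np.zeros(2), g, 1.0, normalized=False)
    assert val - zero == pytest.approx(-d ** 2 / 2, abs=1e-12)


def test_icar_matches_degenerate_gaussian_spectral_oracle(path5, rng):
    """Density of the sum-zero Gaussian with precision L/sigma2, via explicit
    eigendecomposition, reproduced to 1e-8."""
    sigma2 = 0.7
    L = path5.laplacian()
    evals, evecs = np.linalg.eigh(L)
    keep = evals > 1e-9
    for _ in range(5):
        x = rng.normal(0, 1, 5)
        x -= x.mean()
        z = evecs[:, keep].T @ x  # coordinates in the non-null eigenspace
        oracle = multivariate_normal.logpdf(
            z, mean=np.zeros(keep.sum()), cov=np.diag(sigma2 / evals[keep]))
        assert jp.icar_logpdf_kernel(x, path5, sigma2) == pytest.approx(oracle, abs=1e-8)


def test_icar_translation_invariant_on_connected_graph(path5, rng):
    x = rng.normal(0, 1, 5)
    a = jp.icar_logpdf_kernel(x, path5, 0.5, normalized=False)
    b = jp.icar_logpdf_kernel(x + 3.3, path5, 0.5, normalized=False)
    assert a == pytest.approx(b, rel=1e-12)


def test_icar_doubling_sigma2_halves_penalty(path5, rng):
    x = rng.normal(0, 1, 5)
    x -= x.mean()

    def quad_part(s2):
        # subtract the value at x=0 to isolate the quadratic penalty
        return (jp.icar_logpdf_kernel(x, path5, s2, normalized=False)
                - jp.icar_logpdf_kernel(np.zeros(5), path5, s2, normalized=False))

    assert quad_part(2.0) == pytest.approx(quad_part(1.0) / 2, rel=1e-12)


def test_icar_asymmetric_graph_rejected():
    with pytest.raises(jp.ValidationError):
        jp.AdjacencyGraph(2, [[1], []])


# ---------------------------------------------------------------------------
# priors


def test_log_prior_componentwise_oracle(path5, single_node_graph):
    """At the null parameter point the joint prior equals the sum of its
    component log densities computed independently with scipy."""
    p = jp.ParameterSet.zeros(5, 1)
    p.sigma2_v = 1.0
    p.sigma2_u = 1.0
    sg = single_node_graph
    val = jp.log_prior(p, path5, sg, spec(3))

    expected = 0.0
    expected += 5 * norm.logpdf(0, scale=10.0)            # alpha
    expected += 15 * norm.logpdf(0, scale=10.0)           # free beta
    expected += 15 * norm.logpdf(0, scale=10.0)           # free gamma
    expected += 25 * norm.logpdf(0, scale=10.0)           # delta
    expected += 8 * norm.logpdf(1.0, scale=10.0)          # free loadings (pinned at 1)
    expected += jp.icar_logpdf_kernel(np.zeros(5), path5, 1.0)
    expected += jp.icar_logpdf_kernel(np.zeros(1), sg, 1.0)
    expected += 2 * halfnorm.logpdf(1.0)
    expected += eta_rw1_logpdf(np.zeros((5, 12)), np.eye(5))
    expected += invwishart.logpdf(np.eye(5), df=7, scale=np.eye(5))
    assert val == pytest.approx(expected, rel=1e-12)


def test_log_prior_negative_variance_is_minus_inf(path5, single_node_graph):
    p = jp.ParameterSet.zeros(5, 1)
    p.sigma2_v = -1.0
    assert jp.log_prior(p, path5, single_node_graph, spec(3)) == -math.inf


# ---------------------------------------------------------------------------
# constraints


class TestApplyConstraints:
    def test_idempotent(self, rng):
        p = random_params(rng, constrained=False)
        once = jp.apply_constraints(p)
        twice = jp.apply_constraints(once)
        for name in ("alpha", "beta", "gamma", "eta", "delta", "v", "u", "lam", "kappa"):
            np.testing.assert_allclose(getattr(once, name), getattr(twice, name),
                                       atol=1e-14)
        assert once.constraints_satisfied(tol=1e-10)

    def test_eta_centering(self):
        p = jp.ParameterSet.zeros(4, 2)
        p.eta[0, :] = 1.0
        out = jp.apply_constraints(p)
        np.testing.assert_allclose(out.eta[0], 0.0, atol=1e-15)

    def test_field_centering_preserves_differences(self, rng):
        p = jp.ParameterSet.zeros(6, 2)
        p.v = rng.normal(0.7, 0.2, 6)
        out = jp.apply_constraints(p)
        assert out.v.mean() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diff(out.v), np.diff(p.v), atol=1e-12)

    def test_intercept_shift_preserves_likelihood(self, counties10, respondents20, rng):
        p = random_params(rng, constrained=False)
        sp = spec(3)
        before = jp.weighted_loglik(respondents20, counties10, p, sp)
        shifted = jp.apply_constraints(p, shift_to_intercept=True)
        after = jp.weighted_loglik(respondents20, counties10, shifted, sp)
        assert after == pytest.approx(before, rel=1e-10)


# ---------------------------------------------------------------------------
# top-decile indicator


@pytest.mark.parametrize("values,expected_ones", [
    (np.arange(3110, dtype=float), 311),
    (np.arange(10, dtype=float), 1),
    (np.full(50, 3.3), 0),
])
def test_top_decile_counts(values, expected_ones):
    flags = jp.top_decile_indicator(values)
    assert flags.sum() == expected_ones
    assert set(np.unique(flags)) <= {0, 1}


def test_top_decile_flags_the_largest():
    flags = jp.top_decile_indicator(np.arange(10, dtype=float))
    assert flags[-1] == 1 and flags[:-1].sum() == 0


def test_top_decile_empty_input_rejected():
    with pytest.raises(jp.ValidationError):
        jp.top_decile_indicator(np.array([]))


# ---------------------------------------------------------------------------
# table validation


def test_out_of_range_race_names_row(counties10, respondents20):
    bad = respondents20.copy()
    bad.loc[7, "race"] = 5
    with pytest.raises(jp.ValidationError, match="row 7.*race"):
        jp.weighted_loglik(bad, counties10, jp.ParameterSet.zeros(10, 2), spec(3))


def test_nonpositive_weight_rejected(counties10, respondents20):
    bad = respondents20.copy()
    bad.loc[3, "weight"] = 0.0
    with pytest.raises(jp.ValidationError, match="row 3"):
        jp.weighted_loglik(bad, counties10, jp.ParameterSet.zeros(10, 2), spec(3))
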