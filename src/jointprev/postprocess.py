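"""Post-processing of fitted parameters into reportable epidemiological
quantities: age-standardised county prevalences, composite latent area
effects, marginal latent-effect variances, poverty-decile profiles, and
printed-style cross-tabulations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import (
    NCAT,
    CATEGORY_LABELS,
    ModelSpecification,
    ParameterSet,
    ValidationError,
    county_arrays,
    respondent_arrays,
)
from .mcmc import FitResult


def _draw_iter(params_or_fit):
    """Yield ParameterSet-like views; single item for a plain ParameterSet."""
    if isinstance(params_or_fit, ParameterSet):
        yield params_or_fit
        return
    fit: FitResult = params_or_fit
    d = fit.draws
    n = fit.n_chains * fit.n_kept
    pool = {k: fit.pooled(k) for k in ("alpha", "delta", "v", "u", "lam", "kappa")}
    for i in range(n):
        p = ParameterSet.zeros(pool["v"].shape[1], pool["u"].shape[1], J=fit.spec.J,
                               A=fit.spec.A)
        p.alpha = pool["alpha"][i]
        p.delta = pool["delta"][i]
        p.v = pool["v"][i]
        p.u = pool["u"][i]
        p.lam = pool["lam"][i]
        p.kappa = pool["kappa"][i]
        yield p


def _prevalence_one(params: ParameterSet, X: np.ndarray, state: np.ndarray,
                    include_covariates: bool) -> np.ndarray:
    J = params.J
    score = params.alpha[None, :] + np.outer(params.v, params.lam) \
        + params.kappa[None, :] * params.u[state][:, None]
    if include_covariates:
        score = score + X @ params.delta.T
    w = np.concatenate([np.exp(score), np.ones((len(X), 1))], axis=1)
    return w / w.sum(axis=1, keepdims=True)


def standardized_prevalence(params_or_fit, counties: pd.DataFrame,
                            spec: ModelSpecification,
                            at_posterior_mean: bool = False) -> pd.DataFrame:
    """Age-standardised county prevalences for all J+1 categories.

    Standardisation scores w_cj = exp(alpha_j [+ county covariate terms]
    + lam_j v_c + kappa_j u_{S_c}) with w_{c,J+1} = 1, normalised to
    probabilities p_cj = w_cj / sum_j' w_cj'. Given a FitResult the default
    is the posterior mean of the per-draw p_cj (the correct summary under
    the nonlinear transform); ``at_posterior_mean=True`` instead evaluates
    p at the posterior-mean parameters.
    """
    X, state = county_arrays(counties)
    if isinstance(params_or_fit, FitResult) and at_posterior_mean:
        params_or_fit = params_or_fit.posterior_mean_params()
    mats = [
        _prevalence_one(p, X, state, spec.include_county_covariates)
        for p in _draw_iter(params_or_fit)
    ]
    p = np.mean(mats, axis=0)
    out = pd.DataFrame(p, columns=list(CATEGORY_LABELS))
    out.insert(0, "county", counties.sort_values("county")["county"].to_numpy())
    return out


def composite_effects(params: ParameterSet, counties: pd.DataFrame) -> pd.DataFrame:
    """Composite latent area effect t_jc = lam_j v_c + kappa_j u_{S_c} per
    county and category; with the corner constraint the first category is
    exactly v_c + u_{S_c}."""
    _, state = county_arrays(counties)
    t = np.outer(params.v, params.lam) + params.kappa[None, :] * params.u[state][:, None]
    out = pd.DataFrame(t, columns=[f"t{j + 1}" for j in range(params.J)])
    out.insert(0, "county", counties.sort_values("county")["county"].to_numpy())
    return out


def marginal_latent_variance(params_or_fit, respondents: pd.DataFrame,
                             counties: pd.DataFrame,
                             reference_handling: str = "share_weighted") -> float:
    """Marginal variance over respondents of the latent spatial contribution
    s_i = lam_{j(i)} v_{C_i} + kappa_{j(i)} u_{S_i} using each respondent's
    observed category.

    Reference-category respondents have no latent term of their own; with
    ``reference_handling="share_weighted"`` (default) they are assigned the
    category-share-weighted average of the J per-category composite effects
    (an explicit approximation to an under-specified quantity);
    ``"exclude"`` restricts the variance to morbid-category respondents.
    For a FitResult the posterior mean of the per-draw variance is returned.
    """
    if reference_handling not in ("share_weighted", "exclude"):
        raise ValidationError("reference_handling must be 'share_weighted' or 'exclude'")
    X, state = county_arrays(counties)
    _, _, _, c, y, w = respondent_arrays(respondents, n_counties=len(X))
    if len(c) == 0:
        raise ValidationError("empty respondent set")
    morbid = y < NCAT - 1
    shares = np.bincount(y[morbid], weights=w[morbid], minlength=NCAT - 1)
    shares = shares / shares.sum() if shares.sum() > 0 else np.full(NCAT - 1, 1.0 / (NCAT - 1))
    out = []
    for p in _draw_iter(params_or_fit):
        t = np.outer(p.v, p.lam) + p.kappa[None, :] * p.u[state][:, None]  # (nC, J)
        s = np.where(morbid, t[c, np.minimum(y, NCAT - 2)], (t @ shares)[c])
        if reference_handling == "exclude":
            s = s[morbid]
        out.append(float(np.var(s)))
    return float(np.mean(out))


def poverty_decile_profile(t1: np.ndarray, poverty: np.ndarray) -> np.ndarray:
    """Mean composite effect per county poverty rank-decile.

    Counties are ranked by poverty and split into ten near-equal groups
    (any remainder goes to the lowest deciles); returns the ten group means
    in increasing-poverty order.
    """
    t1 = np.asarray(t1, dtype=float)
    poverty = np.asarray(poverty, dtype=float)
    if t1.shape != poverty.shape:
        raise ValidationError("t1 and poverty must have equal length")
    if len(t1) < 10:
        raise ValidationError("need at least 10 counties for a decile profile")
    order = np.argsort(poverty, kind="stable")
    groups = np.array_split(t1[order], 10)
    return np.array([g.mean() for g in groups])


def crosstab_prevalence(respondents: pd.DataFrame, group_by: str,
                        weighted: bool = False, age_standardize: bool = False,
                        round_digits: int | None = 1) -> pd.DataFrame:
    """Percentage of subjects in each of the six categories, by education,
    race, or state-of-residence-like grouping column.

    Unweighted percentages are count ratios x 100; with ``weighted`` the
    survey weights replace counts. ``age_standardize`` applies direct
    standardisation to the overall (weighted) age distribution. Rows sum to
    100 up to rounding (half-up to ``round_digits``; None disables rounding).
    Empty groups are omitted with a warning.
    """
    if group_by not in ("education", "race", "state", "county"):
        raise ValidationError("group_by must be education, race, state or county")
    df = respondents.copy()
    if group_by in ("state", "county") and group_by not in df.columns:
        raise ValidationError(f"respondent table lacks a {group_by!r} column")
    df["_w"] = df["weight"].to_numpy(dtype=float) if weighted else 1.0

    groups = np.sort(df[group_by].unique())
    if age_standardize:
        age_w = df.groupby("age_group")["_w"].sum()
        age_dist = age_w / age_w.sum()
    rows = {}
    for g in groups:
        sub = df[df[group_by] == g]
        if len(sub) == 0 or sub["_w"].sum() == 0:
            warnings.warn(f"group {g!r} empty; omitted", RuntimeWarning)
            continue
        if age_standardize:
            pct = np.zeros(NCAT)
            total_p = 0.0
            for a, pa in age_dist.items():
                cell = sub[sub["age_group"] == a]
                if len(cell) == 0:
                    continue
                wsum = cell.groupby("category")["_w"].sum()
                probs = np.zeros(NCAT)
                probs[wsum.index.to_numpy() - 1] = wsum.to_numpy() / wsum.sum()
                pct += pa * probs
                total_p += pa
            pct = 100.0 * pct / total_p
        else:
            wsum = sub.groupby("category")["_w"].sum()
            pct = np.zeros(NCAT)
            pct[wsum.index.to_numpy() - 1] = 100.0 * wsum.to_numpy() / wsum.sum()
        rows[g] = pct
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORY_LABELS))
    out.index.name = group_by
    if round_digits is not None:
        # half-up, matching printed tables
        q = 10.0 ** round_digits
        out = np.floor(out * q + 0.5) / q
    return out
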