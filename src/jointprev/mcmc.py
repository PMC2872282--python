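"""Metropolis-within-Gibbs fitting of the multilevel multinomial model.

The sampler mirrors a WinBUGS-era workflow: adaptive random-walk proposals
per parameter block, tuned during burn-in and frozen afterwards, with the
identifiability constraints (sum-to-zero age effects and latent fields,
corner-constrained loadings) re-applied after every sweep by shifting the
removed means into the intercepts so the likelihood is untouched.

Two implementation choices keep a desk-scale fit in the seconds-to-minutes
range without changing the target distribution:

* sufficient statistics — respondents are collapsed into (age, race,
  education, county) cells with survey-weighted outcome counts, so a
  likelihood evaluation is O(n_cells x categories) whatever the sample size;
* coloured single-site updates — parameters that are conditionally
  independent given the rest (counties within one colour class of the
  adjacency graph, even/odd age groups under the random-walk prior, race or
  education levels) are proposed and accepted simultaneously in one
  vectorised pass.

County covariates are standardised internally for proposal efficiency;
recorded draws are always on the original covariate scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .model import (
    NCAT,
    AdjacencyGraph,
    ModelSpecification,
    ParameterSet,
    PriorConfig,
    ValidationError,
    county_arrays,
    respondent_arrays,
    weighted_loglik,
)

_log = logging.getLogger("jointprev.mcmc")

_TARGET_SCALAR = 0.44
_TARGET_BLOCK = 0.25


@dataclass
class MCMCConfig:
    """Sampler settings. Defaults: two chains of 10,000 iterations with the
    first half discarded as burn-in (during which proposal scales adapt)."""

    n_chains: int = 2
    n_iterations: int = 10_000
    burnin_fraction: float = 0.5
    seed: int = 0
    adapt_window: int = 50
    normalize_weights: bool = True
    init_dispersal: tuple[float, ...] = (1.0, 3.0)
    init_retries: int = 20

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("need at least one chain")
        if not 0.0 < self.burnin_fraction < 1.0:
            raise ValidationError("burn-in fraction must lie in (0, 1)")
        if self.n_iterations < 2:
            raise ValidationError("need at least two iterations")

    @property
    def n_burnin(self) -> int:
        return int(self.n_iterations * self.burnin_fraction)


# ---------------------------------------------------------------------------
# cell aggregation


class CellData:
    """Survey data collapsed to covariate cells with weighted outcome counts."""

    def __init__(self, respondents: pd.DataFrame, counties: pd.DataFrame,
                 spec: ModelSpecification, normalize_weights: bool = True) -> None:
        X, state_of_county = county_arrays(counties)
        self.n_counties = len(X)
        self.n_states = int(state_of_county.max()) + 1
        a, r, e, c, y, w = respondent_arrays(respondents, self.n_counties, spec.A)
        if normalize_weights:
            w = w * (len(w) / w.sum())
        self.J = spec.J
        self.A = spec.A
        tab = (
            pd.DataFrame({"a": a, "r": r, "e": e, "c": c, "y": y, "w": w})
            .groupby(["c", "a", "r", "e", "y"])["w"].sum()
            .unstack("y", fill_value=0.0)
            .reindex(columns=range(NCAT), fill_value=0.0)
        )
        keys = tab.index.to_frame(index=False)
        self.a = keys["a"].to_numpy()
        self.r = keys["r"].to_numpy()
        self.e = keys["e"].to_numpy()
        self.c = keys["c"].to_numpy()
        self.W = tab.to_numpy()
        self.W5 = np.ascontiguousarray(self.W[:, : self.J])
        self.Wtot = self.W.sum(axis=1)
        self.n_cells = len(self.W)

        self.state_of_county = state_of_county
        self.state_cells = state_of_county[self.c]
        # covariates standardised by their *respondent-weighted* moments, so
        # that covariate effects are near-orthogonal to the intercepts in the
        # likelihood metric (constant columns left unscaled)
        Xr = X[self.c]
        self.x_mean = np.average(Xr, weights=self.Wtot, axis=0)
        sd = np.sqrt(np.average((Xr - self.x_mean) ** 2, weights=self.Wtot, axis=0))
        self.x_sd = np.where(sd > 0, sd, 1.0)
        self.Xs = (X - self.x_mean) / self.x_sd
        self.Xc = self.Xs[self.c]

    def row_loglik(self, phi: np.ndarray, rows=None) -> np.ndarray:
        """Per-cell weighted log-likelihood given category log-odds phi."""
        W5 = self.W5 if rows is None else self.W5[rows]
        Wtot = self.Wtot if rows is None else self.Wtot[rows]
        m = np.maximum(phi.max(axis=1), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(phi - m[:, None]).sum(axis=1))
        return (W5 * phi).sum(axis=1) - Wtot * lse


# ---------------------------------------------------------------------------
# adaptive scales


class _Adaptive:
    """Per-block random-walk scales with Robbins-Monro batch adaptation,
    frozen once burn-in ends (preserving detailed balance afterwards)."""

    def __init__(self, window: int) -> None:
        self.window = window
        self.scales: dict[str, float] = {}
        self.targets: dict[str, float] = {}
        self.acc: dict[str, float] = {}
        self.n: dict[str, float] = {}
        self.acc_total: dict[str, float] = {}
        self.n_total: dict[str, float] = {}
        self.batches: dict[str, int] = {}
        self.frozen = False

    def register(self, name: str, scale: float, target: float) -> None:
        self.scales[name] = scale
        self.targets[name] = target
        self.acc[name] = self.n[name] = 0.0
        self.acc_total[name] = self.n_total[name] = 0.0
        self.batches[name] = 0

    def record(self, name: str, accepted: float, proposed: float = 1.0) -> None:
        self.n[name] += proposed
        self.n_total[name] += proposed
        self.acc[name] += accepted
        self.acc_total[name] += accepted
        if not self.frozen and self.n[name] >= self.window:
            self.batches[name] += 1
            rate = self.acc[name] / self.n[name]
            step = 1.0 / math.sqrt(self.batches[name])
            self.scales[name] *= math.exp(step * (rate - self.targets[name]))
            _log.debug("adapt %s: window %d acceptance %.2f scale %.4g",
                       name, self.batches[name], rate, self.scales[name])
            self.acc[name] = self.n[name] = 0.0

    def rates(self) -> dict[str, float]:
        return {k: self.acc_total[k] / max(1.0, self.n_total[k]) for k in self.scales}


def _greedy_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Colour classes of mutually non-adjacent nodes (greedy; 2 on a lattice)."""
    colors = np.full(graph.n_nodes, -1)
    for i in range(graph.n_nodes):
        used = {colors[j] for j in graph.neighbors[i] if colors[j] >= 0}
        k = 0
        while k in used:
            k += 1
        colors[i] = k
    return [np.flatnonzero(colors == k) for k in range(colors.max() + 1)]


# ---------------------------------------------------------------------------
# chain initialisation


def _initial_params(cells: CellData, spec: ModelSpecification, priors: PriorConfig,
                    rng: np.random.Generator, dispersal: float) -> ParameterSet:
    J, A = spec.J, spec.A
    p = ParameterSet.zeros(cells.n_counties, cells.n_states, J=J, A=A)
    shares = cells.W.sum(axis=0) + 0.5
    shares = shares / shares.sum()
    p.alpha = np.log(shares[:J] / shares[J]) + rng.normal(0, 0.2 * dispersal, J)
    if spec.include_race_education:
        p.beta[:, 1:] = rng.normal(0, 0.1 * dispersal, (J, 3))
        p.gamma[:, 1:] = rng.normal(0, 0.1 * dispersal, (J, 3))
    if spec.include_county_covariates:
        p.delta = rng.normal(0, 0.1 * dispersal, (J, 5))
    p.eta = rng.normal(0, 0.05 * dispersal, (J, A))
    p.eta -= p.eta.mean(axis=1, keepdims=True)
    p.lam[1:] = 1.0 + rng.normal(0, 0.2 * dispersal, J - 1)
    p.kappa[1:] = 1.0 + rng.normal(0, 0.2 * dispersal, J - 1)
    p.v = rng.normal(0, 0.05 * dispersal, cells.n_counties)
    p.v -= p.v.mean()
    p.u = rng.normal(0, 0.05 * dispersal, cells.n_states)
    p.u -= p.u.mean()
    p.sigma2_v = float(np.exp(np.log(0.1) + rng.normal(0, 0.5 * dispersal)))
    p.sigma2_u = float(np.exp(np.log(0.1) + rng.normal(0, 0.5 * dispersal)))
    p.Sigma_eta = np.eye(J)
    return p


def _phi_cells(cells: CellData, p: ParameterSet, spec: ModelSpecification) -> np.ndarray:
    phi = p.alpha[None, :] + p.eta[:, cells.a].T
    if spec.include_race_education:
        phi = phi + p.beta[:, cells.r].T + p.gamma[:, cells.e].T
    if spec.include_county_covariates:
        phi = phi + cells.Xc @ p.delta.T
    phi = phi + p.v[cells.c][:, None] * p.lam[None, :]
    phi = phi + p.u[cells.state_cells][:, None] * p.kappa[None, :]
    return phi


def _icar_quad(x: np.ndarray, graph: AdjacencyGraph) -> float:
    e = graph.edges
    quad = float(np.sum((x[e[:, 0]] - x[e[:, 1]]) ** 2)) if len(e) else 0.0
    quad += float(np.sum(x[graph.islands] ** 2))
    return quad


# ---------------------------------------------------------------------------
# single chain


def _run_chain(cells: CellData, county_graph: AdjacencyGraph, state_graph: AdjacencyGraph,
               spec: ModelSpecification, cfg: MCMCConfig, priors: PriorConfig,
               rng: np.random.Generator, dispersal: float):
    J, A = spec.J, spec.A
    nC, nS = cells.n_counties, cells.n_states
    fixed_var = priors.fixed_sd ** 2
    load_var = priors.loading_sd ** 2
    delta_sd_int = priors.fixed_sd * cells.x_sd  # prior sd of standardised deltas
    rank_v = county_graph.n_nodes - county_graph.n_components + len(county_graph.islands)
    rank_u = state_graph.n_nodes - state_graph.n_components + len(state_graph.islands)

    deg_v = county_graph.degrees.astype(float)
    deg_u = state_graph.degrees.astype(float)
    island_v = deg_v == 0
    island_u = deg_u == 0
    Av_mat = county_graph.adjacency_matrix()
    Au_mat = state_graph.adjacency_matrix()
    classes_v = _greedy_coloring(county_graph)
    classes_u = _greedy_coloring(state_graph)
    ages_even = np.arange(0, A, 2)
    ages_odd = np.arange(1, A, 2)
    c_cells = cells.c
    s_cells = cells.state_cells

    for _attempt in range(cfg.init_retries):
        p = _initial_params(cells, spec, priors, rng, dispersal)
        phi = _phi_cells(cells, p, spec)
        rowll = cells.row_loglik(phi)
        if np.isfinite(rowll.sum()):
            break
    else:
        raise RuntimeError("could not find a finite starting point for the chain")

    Sigma_inv = np.linalg.inv(p.Sigma_eta)
    v_cells = p.v[c_cells]
    u_cells = p.u[s_cells]

    # incrementally maintained likelihood state: exp(phi), the multinomial
    # denominator S = 1 + sum_j exp(phi_j), its log, and per-cell loglik.
    # Overflowing proposals give -inf increments and are rejected; the state
    # itself always stays finite. Refreshed from scratch periodically to
    # shed float drift.
    W5, Wtot = cells.W5, cells.Wtot

    def refresh_state():
        phi = _phi_cells(cells, p, spec)
        expphi = np.exp(phi)
        S = 1.0 + expphi.sum(axis=1)
        logS = np.log(S)
        rowll = (W5 * phi).sum(axis=1) - Wtot * logS
        return expphi, S, logS, rowll

    expphi, S, logS, rowll = refresh_state()

    adapt = _Adaptive(cfg.adapt_window)
    for j in range(J):
        adapt.register(f"alpha[{j}]", 0.1, _TARGET_SCALAR)
        adapt.register(f"delta[{j}]", 0.05, _TARGET_BLOCK)
        adapt.register(f"beta[{j}]", 0.1, _TARGET_SCALAR)
        adapt.register(f"gamma[{j}]", 0.1, _TARGET_SCALAR)
        adapt.register(f"eta[{j}]", 0.1, _TARGET_SCALAR)
        if j > 0:
            adapt.register(f"lam[{j}]", 0.1, _TARGET_SCALAR)
            adapt.register(f"kappa[{j}]", 0.1, _TARGET_SCALAR)
    adapt.register("v", 0.2, _TARGET_SCALAR)
    adapt.register("u", 0.2, _TARGET_SCALAR)
    adapt.register("scale_v", 0.1, _TARGET_SCALAR)
    adapt.register("scale_u", 0.1, _TARGET_SCALAR)
    if spec.include_county_covariates:
        for k in range(5):
            adapt.register(f"shear[{k}]", 0.1, _TARGET_SCALAR)
    if spec.include_race_education:
        for j in range(J):
            adapt.register(f"elevel[{j}]", 0.1, _TARGET_SCALAR)
            adapt.register(f"rlevel[{j}]", 0.1, _TARGET_SCALAR)
    adapt.register("log_sigma2_v", 0.5, _TARGET_SCALAR)
    adapt.register("log_sigma2_u", 0.5, _TARGET_SCALAR)

    n_keep = cfg.n_iterations - cfg.n_burnin
    draws = {
        "alpha": np.empty((n_keep, J)), "beta": np.empty((n_keep, J, 4)),
        "gamma": np.empty((n_keep, J, 4)), "eta": np.empty((n_keep, J, A)),
        "delta": np.empty((n_keep, J, 5)), "v": np.empty((n_keep, nC)),
        "u": np.empty((n_keep, nS)), "lam": np.empty((n_keep, J)),
        "kappa": np.empty((n_keep, J)), "sigma2_v": np.empty(n_keep),
        "sigma2_u": np.empty(n_keep), "Sigma_eta": np.empty((n_keep, J, J)),
    }
    deviance = np.empty(n_keep)

    # -- update helpers ------------------------------------------------------

    def scalar_col_update(name: str, j: int, contrib_fn, prior_delta_fn, apply_fn):
        """Metropolis step shifting phi column j by contrib_fn(z) for every
        cell at once, via the maintained exp/denominator state."""
        nonlocal S, logS
        z = rng.normal(0.0, adapt.scales[name])
        contrib = contrib_fn(z)
        with np.errstate(over="ignore"):
            newexp_j = expphi[:, j] * np.exp(contrib)
        S_new = S + (newexp_j - expphi[:, j])
        with np.errstate(divide="ignore"):
            logS_new = np.log(S_new)
        dll = W5[:, j] * contrib - Wtot * (logS_new - logS)
        logr = float(dll.sum()) + prior_delta_fn(z)
        if math.log(rng.random()) < logr:
            expphi[:, j] = newexp_j
            S, logS = S_new, logS_new
            rowll[:] += dll
            apply_fn(z)
            adapt.record(name, 1.0)
        else:
            adapt.record(name, 0.0)

    def grouped_col_update(name: str, j: int, group_of_cell: np.ndarray, n_groups: int,
                           active: np.ndarray, prior_delta_fn, apply_fn):
        """Simultaneous scalar Metropolis updates over conditionally
        independent groups, one vectorised pass (no exp needed: the factor
        exp(z) is per group)."""
        z = np.zeros(n_groups)
        z[active] = rng.normal(0.0, adapt.scales[name], len(active))
        factor = np.exp(z)[group_of_cell]
        newexp_j = expphi[:, j] * factor
        S_new = S + (newexp_j - expphi[:, j])
        logS_new = np.log(S_new)
        dll = W5[:, j] * z[group_of_cell] - Wtot * (logS_new - logS)
        dll_g = np.bincount(group_of_cell, weights=dll, minlength=n_groups)
        logr = dll_g + prior_delta_fn(z)
        acc = np.zeros(n_groups, dtype=bool)
        acc[active] = np.log(rng.random(len(active))) < logr[active]
        if acc.any():
            rows = acc[group_of_cell]
            expphi[rows, j] = newexp_j[rows]
            S[rows] = S_new[rows]
            logS[rows] = logS_new[rows]
            rowll[rows] += dll[rows]
            apply_fn(z, acc)
        adapt.record(name, float(acc.sum()), float(len(active)))

    def field_update(name: str, field: np.ndarray, loadings: np.ndarray,
                     group_of_cell: np.ndarray, node_class: np.ndarray,
                     deg: np.ndarray, island: np.ndarray, Amat, sigma2: float,
                     cells_view: np.ndarray):
        """Coloured single-site ICAR field update: one colour class at a time,
        all J phi columns shift by dz * loadings."""
        n_nodes = len(field)
        dz = np.zeros(n_nodes)
        dz[node_class] = rng.normal(0.0, adapt.scales[name], len(node_class))
        Ax = Amat @ field
        base = dz * dz + 2.0 * field * dz
        dquad = np.where(island, base, deg * base - 2.0 * dz * Ax)
        with np.errstate(over="ignore", divide="ignore"):
            logr = -dquad / (2.0 * sigma2)
        factors = np.exp(np.outer(dz, loadings))[group_of_cell]  # (n_cells, J)
        newexp = expphi * factors
        S_new = 1.0 + newexp.sum(axis=1)
        logS_new = np.log(S_new)
        dll = dz[group_of_cell] * (W5 @ loadings) - Wtot * (logS_new - logS)
        logr = logr + np.bincount(group_of_cell, weights=dll, minlength=n_nodes)
        acc = np.zeros(n_nodes, dtype=bool)
        acc[node_class] = np.log(rng.random(len(node_class))) < logr[node_class]
        if acc.any():
            field[acc] += dz[acc]
            rows = acc[group_of_cell]
            expphi[rows] = newexp[rows]
            S[rows] = S_new[rows]
            logS[rows] = logS_new[rows]
            rowll[rows] += dll[rows]
            cells_view[rows] = field[group_of_cell][rows]
        adapt.record(name, float(acc.sum()), float(len(node_class)))

    # empirical-covariance (Haario-style) adaptation for the delta blocks,
    # learned during burn-in and frozen with the scales afterwards
    delta_n = 0
    delta_mean = np.zeros((J, 5))
    delta_m2 = np.zeros((J, 5, 5))
    delta_chol = [np.eye(5) for _ in range(J)]

    def delta_adapt_tick():
        nonlocal delta_n
        delta_n += 1
        d = p.delta - delta_mean
        delta_mean[:] = delta_mean + d / delta_n
        d2 = p.delta - delta_mean
        for j in range(J):
            delta_m2[j] += np.outer(d[j], d2[j])
        if delta_n >= 100 and delta_n % cfg.adapt_window == 0:
            for j in range(J):
                C = delta_m2[j] / (delta_n - 1) + 1e-9 * np.eye(5)
                try:
                    delta_chol[j] = np.linalg.cholesky(C)
                except np.linalg.LinAlgError:
                    pass

    def delta_block_update(j: int, zvec: np.ndarray, prior_delta_fn):
        """Joint random-walk update of the five county-covariate effects for
        one category."""
        nonlocal S, logS
        contrib = cells.Xc @ zvec
        with np.errstate(over="ignore"):
            newexp_j = expphi[:, j] * np.exp(contrib)
        S_new = S + (newexp_j - expphi[:, j])
        with np.errstate(divide="ignore"):
            logS_new = np.log(S_new)
        dll = W5[:, j] * contrib - Wtot * (logS_new - logS)
        if math.log(rng.random()) < float(dll.sum()) + prior_delta_fn(zvec):
            expphi[:, j] = newexp_j
            S, logS = S_new, logS_new
            rowll[:] += dll
            p.delta[j] += zvec
            adapt.record(f"delta[{j}]", 1.0)
        else:
            adapt.record(f"delta[{j}]", 0.0)

    def scale_move(name: str, field: np.ndarray, cells_field: np.ndarray,
                   loadings: np.ndarray, sigma_attr: str, rank_: int):
        """Joint rescaling along the loading/field scale ridge: field -> s*field,
        free loadings -> loadings/s, sigma2 -> s^2*sigma2. Only the first
        category's likelihood changes (its loading is pinned at 1); the ICAR
        quadratic form is invariant. Greatly improves mixing of the weakly
        identified (loadings, sigma2) block."""
        nonlocal S, logS
        eps = rng.normal(0.0, adapt.scales[name])
        s = math.exp(eps)
        contrib = (s - 1.0) * cells_field
        with np.errstate(over="ignore"):
            newexp_0 = expphi[:, 0] * np.exp(contrib)
        S_new = S + (newexp_0 - expphi[:, 0])
        with np.errstate(divide="ignore"):
            logS_new = np.log(S_new)
        dll = W5[:, 0] * contrib - Wtot * (logS_new - logS)
        sig2 = getattr(p, sigma_attr)
        sig2_new = s * s * sig2
        lp = -0.5 * rank_ * (2.0 * eps)  # ICAR rank term; quad/sigma2 invariant
        lp += -(sig2_new - sig2) / (2 * priors.sigma_scale ** 2) + eps  # half-N + jac
        lam_new = loadings[1:] / s
        lp += float(np.sum(-(lam_new ** 2 - loadings[1:] ** 2) / (2 * load_var)))
        lp += (len(field) - 1 - (J - 1)) * eps  # jacobian: centred field dim - free loadings
        if math.log(rng.random()) < float(dll.sum()) + lp:
            field *= s
            cells_field *= s
            loadings[1:] = lam_new
            setattr(p, sigma_attr, sig2_new)
            expphi[:, 0] = newexp_0
            S, logS = S_new, logS_new
            rowll[:] += dll
            adapt.record(name, 1.0)
        else:
            adapt.record(name, 0.0)

    def covariate_shear_move(k: int):
        """Exact likelihood-invariant shear along the v/delta ridge: shift the
        county field by h times covariate column k while subtracting h*lam_j
        from every delta_{jk}. phi is unchanged, so only the ICAR and normal
        priors enter the Metropolis ratio (unit Jacobian)."""
        h = rng.normal(0.0, adapt.scales[f"shear[{k}]"])
        xk = cells.Xs[:, k]
        v_new = p.v + h * xk
        dquad = _icar_quad(v_new, county_graph) - _icar_quad(p.v, county_graph)
        lp = -dquad / (2.0 * p.sigma2_v)
        dnew = p.delta[:, k] - h * p.lam
        lp += float(np.sum(-(dnew ** 2 - p.delta[:, k] ** 2) / (2 * delta_sd_int[k] ** 2)))
        if math.log(rng.random()) < lp:
            p.v[:] = v_new
            v_cells[:] = p.v[c_cells]
            p.delta[:, k] = dnew
            adapt.record(f"shear[{k}]", 1.0)
        else:
            adapt.record(f"shear[{k}]", 0.0)

    ref_edu = (cells.e == 0).astype(float)
    ref_race = (cells.r == 0).astype(float)

    def level_shift_move(name: str, j: int, ref_mask: np.ndarray, coef: np.ndarray):
        """Ridge move between the intercept and a corner-constrained effect
        block: alpha_j += h, all free coefficients -= h, so phi changes only
        on reference-level cells."""
        scalar_col_update(
            name, j, lambda z: z * ref_mask,
            lambda z, j=j: (
                -((p.alpha[j] + z) ** 2 - p.alpha[j] ** 2) / (2 * fixed_var)
                + float(np.sum(-((coef[j, 1:] - z) ** 2 - coef[j, 1:] ** 2)
                               / (2 * fixed_var)))
            ),
            lambda z, j=j: (
                p.alpha.__setitem__(j, p.alpha[j] + z),
                coef.__setitem__((j, slice(1, None)), coef[j, 1:] - z),
            ),
        )

    def sign_flip_move(field: np.ndarray, cells_field: np.ndarray,
                       loadings: np.ndarray):
        """Reflection move field -> -field, free loadings -> -loadings: a
        near-symmetry of the posterior when the field is weak (only the
        pinned first loading breaks it). Deterministic involution, unit
        Jacobian, symmetric priors cancel: accept on the category-1
        likelihood ratio."""
        nonlocal S, logS
        contrib = -2.0 * cells_field
        with np.errstate(over="ignore"):
            newexp_0 = expphi[:, 0] * np.exp(contrib)
        S_new = S + (newexp_0 - expphi[:, 0])
        with np.errstate(divide="ignore"):
            logS_new = np.log(S_new)
        dll = W5[:, 0] * contrib - Wtot * (logS_new - logS)
        if math.log(rng.random()) < float(dll.sum()):
            field *= -1.0
            cells_field *= -1.0
            loadings[1:] *= -1.0
            expphi[:, 0] = newexp_0
            S, logS = S_new, logS_new
            rowll[:] += dll

    def loading_prior_refresh(j: int, loadings: np.ndarray, cells_field: np.ndarray):
        """Independence Metropolis step proposing loading j from its prior;
        the prior cancels against the proposal so only the likelihood enters."""
        nonlocal S, logS
        new = rng.normal(0.0, priors.loading_sd)
        contrib = (new - loadings[j]) * cells_field
        with np.errstate(over="ignore"):
            newexp_j = expphi[:, j] * np.exp(contrib)
        S_new = S + (newexp_j - expphi[:, j])
        with np.errstate(divide="ignore"):
            logS_new = np.log(S_new)
        dll = W5[:, j] * contrib - Wtot * (logS_new - logS)
        if math.log(rng.random()) < float(dll.sum()):
            expphi[:, j] = newexp_j
            S, logS = S_new, logS_new
            rowll[:] += dll
            loadings[j] = new

    def eta_prior_delta(j: int, ages: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Change in -eps' Sigma^-1 eps / 2 when eta[j, a] += z[a], for a set
        of mutually non-adjacent ages under the RW1 prior."""
        eps = np.diff(p.eta, axis=1)  # (J, A-1)
        M = Sigma_inv @ eps  # (J, A-1)
        sjj = Sigma_inv[j, j]
        out = np.zeros(A)
        for a_ in ages:
            w = z[a_]
            d = 0.0
            if a_ >= 1:
                d += 2.0 * w * M[j, a_ - 1] + w * w * sjj
            if a_ <= A - 2:
                d += -2.0 * w * M[j, a_] + w * w * sjj
            out[a_] = -0.5 * d
        return out

    kept = 0
    for it in range(cfg.n_iterations):
        if it == cfg.n_burnin:
            adapt.frozen = True
        if it % 200 == 0:  # shed incremental float drift
            expphi, S, logS, rowll = refresh_state()

        for j in range(J):
            scalar_col_update(
                f"alpha[{j}]", j, lambda z: z,
                lambda z, j=j: -((p.alpha[j] + z) ** 2 - p.alpha[j] ** 2) / (2 * fixed_var),
                lambda z, j=j: p.alpha.__setitem__(j, p.alpha[j] + z),
            )
            if spec.include_race_education:
                grouped_col_update(
                    f"beta[{j}]", j, cells.r, 4, np.arange(1, 4),
                    lambda z, j=j: -((p.beta[j] + z) ** 2 - p.beta[j] ** 2) / (2 * fixed_var),
                    lambda z, acc, j=j: p.beta.__setitem__(j, p.beta[j] + np.where(acc, z, 0.0)),
                )
                grouped_col_update(
                    f"gamma[{j}]", j, cells.e, 4, np.arange(1, 4),
                    lambda z, j=j: -((p.gamma[j] + z) ** 2 - p.gamma[j] ** 2) / (2 * fixed_var),
                    lambda z, acc, j=j: p.gamma.__setitem__(j, p.gamma[j] + np.where(acc, z, 0.0)),
                )
            if spec.include_county_covariates:
                def delta_prior(zv, j=j):
                    new = p.delta[j] + zv
                    return float(np.sum(-(new ** 2 - p.delta[j] ** 2)
                                        / (2 * delta_sd_int ** 2)))

                zvec = adapt.scales[f"delta[{j}]"] * (delta_chol[j] @ rng.standard_normal(5))
                delta_block_update(j, zvec, delta_prior)
            # age effects: coloured scalar updates (even ages, then odd)
            for ages in (ages_even, ages_odd):
                grouped_col_update(
                    f"eta[{j}]", j, cells.a, A, ages,
                    lambda z, j=j, ages=ages: eta_prior_delta(j, ages, z),
                    lambda z, acc, j=j: p.eta.__setitem__(j, p.eta[j] + np.where(acc, z, 0.0)),
                )

        # latent fields: coloured single-site sweeps
        for cls in classes_v:
            field_update("v", p.v, p.lam, c_cells, cls, deg_v, island_v, Av_mat,
                         p.sigma2_v, v_cells)
        for cls in classes_u:
            field_update("u", p.u, p.kappa, s_cells, cls, deg_u, island_u, Au_mat,
                         p.sigma2_u, u_cells)

        # loadings (first loading pinned at 1): random-walk step plus an
        # independence proposal from the prior — the latter mixes instantly
        # whenever a loading is weakly identified (near-flat likelihood)
        for j in range(1, J):
            scalar_col_update(
                f"lam[{j}]", j, lambda z: z * v_cells,
                lambda z, j=j: -((p.lam[j] + z) ** 2 - p.lam[j] ** 2) / (2 * load_var),
                lambda z, j=j: p.lam.__setitem__(j, p.lam[j] + z),
            )
            scalar_col_update(
                f"kappa[{j}]", j, lambda z: z * u_cells,
                lambda z, j=j: -((p.kappa[j] + z) ** 2 - p.kappa[j] ** 2) / (2 * load_var),
                lambda z, j=j: p.kappa.__setitem__(j, p.kappa[j] + z),
            )
            loading_prior_refresh(j, p.lam, v_cells)
            loading_prior_refresh(j, p.kappa, u_cells)

        # ridge moves for the weakly identified scale of each latent level;
        # repeated because they are cheap and the ridge can be long
        for _ in range(3):
            scale_move("scale_v", p.v, v_cells, p.lam, "sigma2_v", rank_v)
            scale_move("scale_u", p.u, u_cells, p.kappa, "sigma2_u", rank_u)
        sign_flip_move(p.v, v_cells, p.lam)
        sign_flip_move(p.u, u_cells, p.kappa)
        if spec.include_county_covariates:
            for k in range(5):
                covariate_shear_move(k)
        if spec.include_race_education:
            for j in range(J):
                level_shift_move(f"elevel[{j}]", j, ref_edu, p.gamma)
                level_shift_move(f"rlevel[{j}]", j, ref_race, p.beta)

        # conditional variances, sampled on the log scale (prior-only targets)
        for name, graph_, vec, rank_, attr in (
            ("log_sigma2_v", county_graph, p.v, rank_v, "sigma2_v"),
            ("log_sigma2_u", state_graph, p.u, rank_u, "sigma2_u"),
        ):
            quad = _icar_quad(vec, graph_)
            theta = math.log(getattr(p, attr))
            prop = theta + rng.normal(0.0, adapt.scales[name])

            def sigma_target(th):
                if not -30.0 < th < 30.0:  # keep sigma2 in a sane floating range
                    return -math.inf
                s2 = math.exp(th)
                # ICAR kernel terms + half-Normal(sigma_scale) on sigma + log-Jacobian
                return (-0.5 * rank_ * th - quad / (2 * s2)
                        - s2 / (2 * priors.sigma_scale ** 2) + 0.5 * th)

            if math.log(rng.random()) < sigma_target(prop) - sigma_target(theta):
                setattr(p, attr, math.exp(prop))
                adapt.record(name, 1.0)
            else:
                adapt.record(name, 0.0)

        # cross-category innovation covariance: conjugate inverse-Wishart draw
        eps = np.diff(p.eta, axis=1)
        Sigma = invwishart.rvs(df=priors.eta_iw_df + (A - 1),
                               scale=np.eye(J) + eps @ eps.T, random_state=rng)
        p.Sigma_eta = np.atleast_2d(Sigma)
        Sigma_inv = np.linalg.inv(p.Sigma_eta)

        # learn the delta proposal covariance from the second half of burn-in
        # only (the first half is contaminated by initial drift)
        if spec.include_county_covariates and not adapt.frozen and it >= cfg.n_burnin // 2:
            delta_adapt_tick()

        # re-apply constraints, absorbing removed means into the intercepts
        eta_mean = p.eta.mean(axis=1)
        v_mean = p.v.mean()
        u_mean = p.u.mean()
        p.alpha += eta_mean + p.lam * v_mean + p.kappa * u_mean
        p.eta -= eta_mean[:, None]
        p.v -= v_mean
        p.u -= u_mean
        v_cells -= v_mean
        u_cells -= u_mean

        if it >= cfg.n_burnin:
            # report on the original covariate scale
            if spec.include_county_covariates:
                delta_orig = p.delta / cells.x_sd
                alpha_orig = p.alpha - p.delta @ (cells.x_mean / cells.x_sd)
            else:
                delta_orig = p.delta.copy()
                alpha_orig = p.alpha.copy()
            draws["alpha"][kept] = alpha_orig
            draws["beta"][kept] = p.beta
            draws["gamma"][kept] = p.gamma
            draws["eta"][kept] = p.eta
            draws["delta"][kept] = delta_orig
            draws["v"][kept] = p.v
            draws["u"][kept] = p.u
            draws["lam"][kept] = p.lam
            draws["kappa"][kept] = p.kappa
            draws["sigma2_v"][kept] = p.sigma2_v
            draws["sigma2_u"][kept] = p.sigma2_u
            draws["Sigma_eta"][kept] = p.Sigma_eta
            deviance[kept] = -2.0 * float(rowll.sum())
            kept += 1

    return draws, deviance, adapt.rates()


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Posterior draws (per chain), deviance trace, and acceptance rates."""

    draws: dict
    deviance: np.ndarray  # (n_chains, n_kept)
    acceptance: dict
    spec: ModelSpecification
    config: MCMCConfig
    n_counties: int
    n_states: int

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_kept(self) -> int:
        return self.deviance.shape[1]

    def scalar_draws(self, include_fields: bool = False) -> dict[str, np.ndarray]:
        """Flattened draws, name -> (n_chains, n_kept), 1-based labels.

        Covers the reported (structural) parameters: intercepts, race,
        education and county-covariate effects, age effects, free loadings
        and log conditional variances; ``include_fields`` adds the latent
        county/state fields.
        """
        out: dict[str, np.ndarray] = {}
        J, A = self.spec.J, self.spec.A
        d = self.draws
        for j in range(J):
            out[f"alpha[{j + 1}]"] = d["alpha"][..., j]
        if self.spec.include_race_education:
            for j in range(J):
                for r in range(1, 4):
                    out[f"beta[{j + 1},{r + 1}]"] = d["beta"][..., j, r]
                for e in range(1, 4):
                    out[f"gamma[{j + 1},{e + 1}]"] = d["gamma"][..., j, e]
        if self.spec.include_county_covariates:
            for j in range(J):
                for k in range(5):
                    out[f"delta[{j + 1},{k + 1}]"] = d["delta"][..., j, k]
        for j in range(J):
            for a in range(A):
                out[f"eta[{j + 1},{a + 1}]"] = d["eta"][..., j, a]
        for j in range(1, J):
            out[f"lam[{j + 1}]"] = d["lam"][..., j]
            out[f"kappa[{j + 1}]"] = d["kappa"][..., j]
        out["log_sigma2_v"] = np.log(d["sigma2_v"])
        out["log_sigma2_u"] = np.log(d["sigma2_u"])
        if include_fields:
            for c in range(self.n_counties):
                out[f"v[{c + 1}]"] = d["v"][..., c]
            for s in range(self.n_states):
                out[f"u[{s + 1}]"] = d["u"][..., s]
        return out

    def pooled(self, name: str) -> np.ndarray:
        """Draws for one block pooled over chains, shape (n_chains*n_kept, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def posterior_mean_params(self) -> ParameterSet:
        from .model import apply_constraints

        p = ParameterSet(
            alpha=self.pooled("alpha").mean(axis=0),
            beta=self.pooled("beta").mean(axis=0),
            gamma=self.pooled("gamma").mean(axis=0),
            eta=self.pooled("eta").mean(axis=0),
            delta=self.pooled("delta").mean(axis=0),
            v=self.pooled("v").mean(axis=0),
            u=self.pooled("u").mean(axis=0),
            lam=self.pooled("lam").mean(axis=0),
            kappa=self.pooled("kappa").mean(axis=0),
            sigma2_v=float(self.pooled("sigma2_v").mean()),
            sigma2_u=float(self.pooled("sigma2_u").mean()),
            Sigma_eta=self.pooled("Sigma_eta").mean(axis=0),
        )
        return apply_constraints(p)

    def psrf(self, include_fields: bool = False) -> pd.Series:
        return gelman_rubin(self.scalar_draws(include_fields))

    def summary(self, include_fields: bool = False) -> pd.DataFrame:
        return summarize(self, include_fields=include_fields)


# ---------------------------------------------------------------------------
# public entry points


def run_mcmc(respondents: pd.DataFrame, counties: pd.DataFrame,
             county_graph: AdjacencyGraph, state_graph: AdjacencyGraph,
             spec: ModelSpecification, config: MCMCConfig | None = None,
             priors: PriorConfig | None = None) -> FitResult:
    """Fit one model specification by adaptive Metropolis-within-Gibbs.

    Runs ``config.n_chains`` chains from dispersed starting points; the kept
    draws are the post-burn-in sweeps of each chain. Fully reproducible from
    ``config.seed``.
    """
    config = config or MCMCConfig()
    config.validate()
    priors = priors or PriorConfig()
    cells = CellData(respondents, counties, spec, normalize_weights=config.normalize_weights)
    if county_graph.n_nodes != cells.n_counties:
        raise ValidationError("county graph size does not match county table")
    if state_graph.n_nodes < cells.n_states:
        raise ValidationError("state graph size does not match county table")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, all_dev, all_acc = [], [], []
    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain])
        disp = config.init_dispersal[chain % len(config.init_dispersal)]
        draws, dev, acc = _run_chain(cells, county_graph, state_graph, spec, config,
                                     priors, rng, disp)
        all_draws.append(draws)
        all_dev.append(dev)
        all_acc.append(acc)
    stacked = {k: np.stack([d[k] for d in all_draws]) for k in all_draws[0]}
    acceptance = {k: float(np.mean([a[k] for a in all_acc])) for k in all_acc[0]}
    return FitResult(
        draws=stacked, deviance=np.stack(all_dev), acceptance=acceptance,
        spec=spec, config=config, n_counties=cells.n_counties, n_states=cells.n_states,
    )


def gelman_rubin(draws) -> float | pd.Series:
    """Potential scale reduction factor (between/within variance ratio with
    the small-sample correction); values <= 1.1 are reported as converged.

    ``draws`` is an (n_chains, n_draws) array for one parameter, or a dict of
    such arrays (returns a Series). Requires at least two chains.
    """
    if isinstance(draws, dict):
        return pd.Series({k: gelman_rubin(v) for k, v in draws.items()})
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("gelman_rubin needs >= 2 chains of equal length")
    m, n = x.shape
    if n < 2:
        raise ValidationError("chains too short")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return math.sqrt(V / W)


@dataclass
class DICResult:
    """Deviance Information Criterion decomposition: DIC = Dbar + pD with
    pD = Dbar - D(posterior mean). Lower DIC indicates better fit."""

    dbar: float
    p_d: float
    dic: float


def compute_dic(fit: FitResult, respondents: pd.DataFrame, counties: pd.DataFrame,
                spec: ModelSpecification | None = None) -> DICResult:
    """DIC from the fit's deviance trace and the deviance at the posterior
    mean of all parameters (same weight treatment as the fit)."""
    spec = spec or fit.spec
    if fit.deviance.size == 0:
        raise ValidationError("empty deviance trace")
    dbar = float(fit.deviance.mean())
    pmean = fit.posterior_mean_params()
    resp = respondents
    if fit.config.normalize_weights:
        resp = respondents.copy()
        w = resp["weight"].to_numpy(dtype=float)
        resp["weight"] = w * (len(w) / w.sum())
    d_at_mean = -2.0 * weighted_loglik(resp, counties, pmean, spec)
    p_d = dbar - d_at_mean
    if p_d < 0:
        warnings.warn(f"negative effective parameter count pD = {p_d:.2f}; "
                      "reported verbatim", RuntimeWarning)
    return DICResult(dbar=dbar, p_d=p_d, dic=dbar + p_d)


def _batch_mc_error(x: np.ndarray, n_batches: int = 50) -> float:
    if len(x) < n_batches:
        n_batches = max(2, len(x) // 2)
    batches = np.array_split(x, n_batches)
    means = np.array([b.mean() for b in batches])
    return float(means.std(ddof=1) / math.sqrt(len(means))) if len(means) > 1 else 0.0


def summarize(fit: FitResult, include_fields: bool = False) -> pd.DataFrame:
    """Posterior summary table: mean, sd, batch-means MC error, 2.5% and
    97.5% quantiles per scalar parameter (pooled over chains)."""
    rows = {}
    for name, arr in fit.scalar_draws(include_fields).items():
        x = arr.ravel()
        rows[name] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "mc_error": _batch_mc_error(x),
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "parameter"
    return df
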