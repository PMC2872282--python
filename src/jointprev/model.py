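"""Core model: data containers, linear predictor, likelihood, priors, constraints.

The outcome is a six-way classification of each survey respondent by
diabetic status crossed with weight status (obese / overweight / normal);
category 6 (normal weight, non-diabetic) is the non-morbid reference. A
multinomial logit links the J = 5 morbid categories to subject-level
covariates (age, race, education), county-level covariates (poverty, log
population density, race-composition top-decile flags) and two shared
spatially-structured latent factors — one per county, one per state — that
enter every category through category-specific loadings.

Tables use 1-based integer codes (age 1..12, race 1..4, education 1..4,
county 1..n_counties, category 1..6); arrays inside ``ParameterSet`` are
0-based NumPy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp
from scipy.stats import halfnorm, invwishart, norm

J_DEFAULT = 5
NCAT = 6
A_DEFAULT = 12
N_RACE = 4
N_EDU = 4
N_COUNTY_COVARIATES = 5

CATEGORY_LABELS = (
    "obese_diabetic",
    "overweight_diabetic",
    "normal_diabetic",
    "obese_nondiabetic",
    "overweight_nondiabetic",
    "normal_nondiabetic",
)

RESPONDENT_COLUMNS = ("id", "age_group", "race", "education", "county", "weight", "category")
COUNTY_COLUMNS = ("county", "state", "poverty", "log_density", "top_black", "top_hisp", "top_other")


class ValidationError(ValueError):
    """Raised when an input table, graph or parameter set violates its contract."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpecification:
    """Which predictor blocks enter the linear predictor.

    The incremental strategy fits three nested specifications:
    model 1 = age + latent factors only; model 2 adds the five county
    covariates; model 3 adds subject-level race and education.
    """

    include_race_education: bool
    include_county_covariates: bool
    J: int = J_DEFAULT
    A: int = A_DEFAULT

    @classmethod
    def from_number(cls, number: int, J: int = J_DEFAULT, A: int = A_DEFAULT) -> "ModelSpecification":
        if number == 1:
            return cls(False, False, J, A)
        if number == 2:
            return cls(False, True, J, A)
        if number == 3:
            return cls(True, True, J, A)
        raise ValidationError(f"model number must be 1, 2 or 3, got {number!r}")

    @property
    def number(self) -> int:
        if self.include_race_education and self.include_county_covariates:
            return 3
        if self.include_county_covariates:
            return 2
        return 1


# ---------------------------------------------------------------------------
# adjacency graph


class AdjacencyGraph:
    """Symmetric neighbour structure over ``n_nodes`` areas (no self-loops).

    Spectral quantities (Laplacian eigendecomposition, log pseudo-determinant)
    are computed lazily and cached; they depend only on the graph.
    """

    def __init__(self, n_nodes: int, neighbors: list) -> None:
        if n_nodes <= 0:
            raise ValidationError("graph must have at least one node")
        if len(neighbors) != n_nodes:
            raise ValidationError("neighbour list length must equal n_nodes")
        nbrs = []
        for i, nb in enumerate(neighbors):
            arr = np.unique(np.asarray(list(nb), dtype=int))
            if arr.size and (arr.min() < 0 or arr.max() >= n_nodes):
                raise ValidationError(f"node {i}: neighbour index out of range")
            if np.any(arr == i):
                raise ValidationError(f"node {i}: self-loop not allowed")
            nbrs.append(arr)
        for i, arr in enumerate(nbrs):
            for j in arr:
                if i not in nbrs[j]:
                    raise ValidationError(f"asymmetric adjacency: {j} missing neighbour {i}")
        self.n_nodes = n_nodes
        self.neighbors = nbrs
        self._cache: dict = {}

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "AdjacencyGraph":
        nbrs = [set() for _ in range(n_nodes)]
        for i, j in edges:
            if i == j:
                raise ValidationError("self-loop not allowed")
            nbrs[i].add(j)
            nbrs[j].add(i)
        return cls(n_nodes, [sorted(s) for s in nbrs])

    # -- basic structure ----------------------------------------------------

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def islands(self) -> np.ndarray:
        """Indices of degree-zero nodes (flagged, still permitted)."""
        return np.flatnonzero(self.degrees == 0)

    @property
    def edges(self) -> np.ndarray:
        """Array of (i, j) with i < j, each undirected edge once."""
        if "edges" not in self._cache:
            out = [(i, j) for i in range(self.n_nodes) for j in self.neighbors[i] if i < j]
            self._cache["edges"] = np.array(out, dtype=int).reshape(-1, 2)
        return self._cache["edges"]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_matrix(self) -> sparse.csr_matrix:
        e = self.edges
        if len(e) == 0:
            return sparse.csr_matrix((self.n_nodes, self.n_nodes))
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))

    def laplacian(self) -> np.ndarray:
        L = np.diag(self.degrees.astype(float))
        for i, j in self.edges:
            L[i, j] -= 1.0
            L[j, i] -= 1.0
        return L

    def component_labels(self) -> tuple[int, np.ndarray]:
        if "components" not in self._cache:
            n, labels = connected_components(self.adjacency_matrix(), directed=False)
            self._cache["components"] = (int(n), labels)
        return self._cache["components"]

    @property
    def n_components(self) -> int:
        return self.component_labels()[0]

    # -- spectral quantities -------------------------------------------------

    def _eig(self) -> tuple[np.ndarray, np.ndarray]:
        if "eig" not in self._cache:
            evals, evecs = np.linalg.eigh(self.laplacian())
            self._cache["eig"] = (evals, evecs)
        return self._cache["eig"]

    def log_pseudo_det(self) -> float:
        """log product of the Laplacian's non-zero eigenvalues."""
        if "logpdet" not in self._cache:
            evals, _ = self._eig()
            tol = 1e-9 * max(1.0, float(evals.max(initial=1.0)))
            self._cache["logpdet"] = float(np.log(evals[evals > tol]).sum())
        return self._cache["logpdet"]

    def laplacian_pinv(self) -> np.ndarray:
        evals, evecs = self._eig()
        tol = 1e-9 * max(1.0, float(evals.max(initial=1.0)))
        inv = np.where(evals > tol, 1.0 / np.where(evals > tol, evals, 1.0), 0.0)
        return (evecs * inv) @ evecs.T

    def center_by_component(self, x: np.ndarray) -> np.ndarray:
        """Subtract the mean of x within every connected component."""
        _, labels = self.component_labels()
        x = np.asarray(x, dtype=float).copy()
        for lab in np.unique(labels):
            m = labels == lab
            x[m] -= x[m].mean()
        return x


# ---------------------------------------------------------------------------
# parameters


def _zeros(*shape):
    return np.zeros(shape, dtype=float)


@dataclass
class ParameterSet:
    """All model unknowns for one specification.

    Shapes (0-based): ``alpha`` (J,), ``beta``/``gamma`` (J, 4) with column 0
    pinned to the reference race / education, ``eta`` (J, A) summing to zero
    over age within each category, ``delta`` (J, 5), ``v`` (n_counties,) and
    ``u`` (n_states,) centred latent fields, ``lam``/``kappa`` (J,) loadings
    with the first entry pinned to 1, conditional variances ``sigma2_v``,
    ``sigma2_u``, and ``Sigma_eta`` (J, J), the cross-category covariance of
    the age random-walk innovations.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    eta: np.ndarray
    delta: np.ndarray
    v: np.ndarray
    u: np.ndarray
    lam: np.ndarray
    kappa: np.ndarray
    sigma2_v: float = 1.0
    sigma2_u: float = 1.0
    Sigma_eta: np.ndarray = None

    def __post_init__(self):
        J = len(self.alpha)
        if self.Sigma_eta is None:
            self.Sigma_eta = np.eye(J)
        for name in ("alpha", "beta", "gamma", "eta", "delta", "v", "u", "lam", "kappa", "Sigma_eta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @classmethod
    def zeros(cls, n_counties: int, n_states: int, J: int = J_DEFAULT, A: int = A_DEFAULT) -> "ParameterSet":
        p = cls(
            alpha=_zeros(J),
            beta=_zeros(J, N_RACE),
            gamma=_zeros(J, N_EDU),
            eta=_zeros(J, A),
            delta=_zeros(J, N_COUNTY_COVARIATES),
            v=_zeros(n_counties),
            u=_zeros(n_states),
            lam=np.ones(J),
            kappa=np.ones(J),
        )
        return p

    @property
    def J(self) -> int:
        return len(self.alpha)

    @property
    def A(self) -> int:
        return self.eta.shape[1]

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            alpha=self.alpha.copy(), beta=self.beta.copy(), gamma=self.gamma.copy(),
            eta=self.eta.copy(), delta=self.delta.copy(), v=self.v.copy(), u=self.u.copy(),
            lam=self.lam.copy(), kappa=self.kappa.copy(),
            sigma2_v=float(self.sigma2_v), sigma2_u=float(self.sigma2_u),
            Sigma_eta=self.Sigma_eta.copy(),
        )

    def constraints_satisfied(self, tol: float = 1e-10) -> bool:
        return (
            np.all(self.beta[:, 0] == 0.0)
            and np.all(self.gamma[:, 0] == 0.0)
            and np.all(np.abs(self.eta.sum(axis=1)) < tol)
            and self.lam[0] == 1.0
            and self.kappa[0] == 1.0
            and abs(self.v.sum()) < tol * max(1, len(self.v))
            and abs(self.u.sum()) < tol * max(1, len(self.u))
            and self.sigma2_v > 0
            and self.sigma2_u > 0
        )


def apply_constraints(params: ParameterSet, shift_to_intercept: bool = False) -> ParameterSet:
    """Return a copy with all identifiability constraints enforced.

    Corner constraints zero the reference race/education columns and pin the
    first loadings to 1; the age effects are centred within category and the
    latent fields centred to sum zero. Idempotent. With
    ``shift_to_intercept=True`` the removed means are absorbed into the
    intercepts (``alpha_j += mean(eta_j) + lam_j*mean(v) + kappa_j*mean(u)``)
    so the linear predictor — hence the likelihood — is unchanged; this is
    the variant used inside the sampler.
    """
    out = params.copy()
    out.beta[:, 0] = 0.0
    out.gamma[:, 0] = 0.0
    out.lam[0] = 1.0
    out.kappa[0] = 1.0
    eta_mean = out.eta.mean(axis=1)
    v_mean = out.v.mean() if len(out.v) else 0.0
    u_mean = out.u.mean() if len(out.u) else 0.0
    out.eta -= eta_mean[:, None]
    out.v -= v_mean
    out.u -= u_mean
    if shift_to_intercept:
        out.alpha = out.alpha + eta_mean + out.lam * v_mean + out.kappa * u_mean
    return out


# ---------------------------------------------------------------------------
# table validation / array extraction


def validate_counties(counties: pd.DataFrame) -> None:
    missing = [c for c in COUNTY_COLUMNS if c not in counties.columns]
    if missing:
        raise ValidationError(f"county table missing columns: {missing}")
    n = len(counties)
    cid = counties["county"].to_numpy()
    if not np.array_equal(np.sort(cid), np.arange(1, n + 1)):
        raise ValidationError("county ids must be exactly 1..n_counties")
    if counties["state"].min() < 1:
        raise ValidationError("state indices must be >= 1")
    pov = counties["poverty"].to_numpy(dtype=float)
    if np.any((pov < 0) | (pov > 1)):
        bad = int(np.flatnonzero((pov < 0) | (pov > 1))[0])
        raise ValidationError(f"county row {bad}: poverty must lie in [0, 1]")
    for col in ("top_black", "top_hisp", "top_other"):
        vals = counties[col].to_numpy()
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"column {col} must be binary 0/1")
    if not np.all(np.isfinite(counties["log_density"].to_numpy(dtype=float))):
        raise ValidationError("log_density contains non-finite values")


def county_arrays(counties: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, state): county covariate matrix (n, 5) and 0-based state index,
    both in county-id order."""
    validate_counties(counties)
    df = counties.sort_values("county")
    X = df[["poverty", "log_density", "top_black", "top_hisp", "top_other"]].to_numpy(dtype=float)
    state = df["state"].to_numpy(dtype=int) - 1
    return X, state


def validate_respondents(respondents: pd.DataFrame, n_counties: int | None = None,
                         A: int = A_DEFAULT) -> None:
    missing = [c for c in RESPONDENT_COLUMNS if c not in respondents.columns]
    if missing:
        raise ValidationError(f"respondent table missing columns: {missing}")
    checks = {
        "age_group": (1, A),
        "race": (1, N_RACE),
        "education": (1, N_EDU),
        "category": (1, NCAT),
    }
    if n_counties is not None:
        checks["county"] = (1, n_counties)
    for col, (lo, hi) in checks.items():
        vals = respondents[col].to_numpy()
        bad = np.flatnonzero((vals < lo) | (vals > hi))
        if bad.size:
            raise ValidationError(
                f"respondent row {int(bad[0])}: column {col!r} value {vals[bad[0]]!r} "
                f"outside [{lo}, {hi}]"
            )
    w = respondents["weight"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(w > 0) | ~np.isfinite(w))
    if bad.size:
        raise ValidationError(f"respondent row {int(bad[0])}: weight must be positive and finite")


def respondent_arrays(respondents: pd.DataFrame, n_counties: int | None = None,
                      A: int = A_DEFAULT):
    """0-based (age, race, edu, county, category, weight) arrays."""
    validate_respondents(respondents, n_counties=n_counties, A=A)
    a = respondents["age_group"].to_numpy(dtype=int) - 1
    r = respondents["race"].to_numpy(dtype=int) - 1
    e = respondents["education"].to_numpy(dtype=int) - 1
    c = respondents["county"].to_numpy(dtype=int) - 1
    y = respondents["category"].to_numpy(dtype=int) - 1
    w = respondents["weight"].to_numpy(dtype=float)
    return a, r, e, c, y, w


# ---------------------------------------------------------------------------
# linear predictor, probabilities, likelihood


def linear_predictor(respondents: pd.DataFrame, counties: pd.DataFrame,
                     params: ParameterSet, spec: ModelSpecification) -> np.ndarray:
    """Category log-odds relative to the reference, shape (n, J).

    phi_ij = alpha_j [+ beta_{j,r_i} + gamma_{j,e_i}] + eta_{j,a_i}
             [+ sum_k delta_{jk} x_{k,C_i}] + lam_j v_{C_i} + kappa_j u_{S_{C_i}}
    with the bracketed blocks switched on by the model specification.
    """
    X, state = county_arrays(counties)
    a, r, e, c, _, _ = respondent_arrays(respondents, n_counties=len(X), A=spec.A)
    return _phi_from_arrays(a, r, e, c, X, state, params, spec)


def _phi_from_arrays(a, r, e, c, X, state, params: ParameterSet,
                     spec: ModelSpecification) -> np.ndarray:
    phi = params.alpha[None, :] + params.eta[:, a].T
    if spec.include_race_education:
        phi = phi + params.beta[:, r].T + params.gamma[:, e].T
    if spec.include_county_covariates:
        if not np.all(np.isfinite(X)):
            raise ValidationError("county covariates contain non-finite values")
        phi = phi + (X @ params.delta.T)[c]
    phi = phi + params.v[c][:, None] * params.lam[None, :]
    phi = phi + params.u[state[c]][:, None] * params.kappa[None, :]
    return phi


def log_category_probs(phi: np.ndarray) -> np.ndarray:
    """log pi for all J+1 categories (reference last), overflow-safe."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    full = np.concatenate([phi, np.zeros((len(phi), 1))], axis=1)
    lse = logsumexp(full, axis=1, keepdims=True)
    return full - lse


def category_probs(phi: np.ndarray) -> np.ndarray:
    """Multinomial-logit probabilities; rows sum to 1 exactly up to rounding."""
    return np.exp(log_category_probs(phi))


def weighted_loglik(respondents: pd.DataFrame, counties: pd.DataFrame,
                    params: ParameterSet, spec: ModelSpecification) -> float:
    """Survey-weighted multinomial log-likelihood sum_i w_i log pi_{i,y_i}.

    Weights are used exactly as supplied. If a respondent's observed-category
    probability underflows to zero the result is ``-inf`` (never an
    exception), so a Metropolis sampler can simply reject.
    """
    X, state = county_arrays(counties)
    a, r, e, c, y, w = respondent_arrays(respondents, n_counties=len(X), A=spec.A)
    phi = _phi_from_arrays(a, r, e, c, X, state, params, spec)
    logpi = log_category_probs(phi)
    with np.errstate(invalid="ignore"):
        val = float(np.sum(w * logpi[np.arange(len(y)), y]))
    return val


# ---------------------------------------------------------------------------
# intrinsic CAR


def icar_logpdf_kernel(x: np.ndarray, graph: AdjacencyGraph, sigma2: float,
                       normalized: bool = True) -> float:
    """Log density of the intrinsic CAR field with conditional variance sigma2.

    Pairwise-difference kernel -(1/(2*sigma2)) * sum_{i~j} (x_i - x_j)^2 over
    each undirected edge once; isolated nodes contribute independent
    Normal(0, sigma2) terms. The field is improper on each non-trivial
    connected component (rank n - n_components), proper on the sum-zero
    subspace, where with ``normalized=True`` the value equals the degenerate
    Gaussian log density with precision L/sigma2 (L the graph Laplacian):
    -(rank/2) log(2*pi*sigma2) + (1/2) log pdet(L) - x'Lx/(2*sigma2).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != graph.n_nodes:
        raise ValidationError("x length must equal number of nodes")
    if sigma2 <= 0:
        return -math.inf
    edges = graph.edges
    quad = float(np.sum((x[edges[:, 0]] - x[edges[:, 1]]) ** 2)) if len(edges) else 0.0
    islands = graph.islands
    quad += float(np.sum(x[islands] ** 2))
    # islands are proper Normal(0, sigma2); structured part has Laplacian rank
    rank = graph.n_nodes - graph.n_components + len(islands)
    val = -quad / (2.0 * sigma2) - 0.5 * rank * math.log(sigma2)
    if normalized:
        val += -0.5 * rank * math.log(2.0 * math.pi) + 0.5 * graph.log_pseudo_det()
    return val


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorConfig:
    """Hyperparameters of the (configurable) default priors.

    Fixed effects and free loadings: Normal(0, fixed_sd^2); the latent-field
    conditional standard deviations: half-Normal(0, sigma_scale^2); the age
    random-walk innovation covariance: inverse-Wishart(eta_iw_df, I).
    """

    fixed_sd: float = 10.0
    loading_sd: float = 10.0
    sigma_scale: float = 1.0
    eta_iw_df: float = float(J_DEFAULT + 2)


def eta_rw1_logpdf(eta: np.ndarray, Sigma: np.ndarray) -> float:
    """First-order random walk over age with MVN(0, Sigma) cross-category
    innovations; improper in the level (fixed by sum-to-zero centering)."""
    eps = np.diff(eta, axis=1)  # (J, A-1) innovations
    A1 = eps.shape[1]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -math.inf
    sol = np.linalg.solve(Sigma, eps)
    quad = float(np.sum(eps * sol))
    J = eta.shape[0]
    return -0.5 * quad - 0.5 * A1 * logdet - 0.5 * A1 * J * math.log(2.0 * math.pi)


def log_prior(params: ParameterSet, county_graph: AdjacencyGraph,
              state_graph: AdjacencyGraph, spec: ModelSpecification,
              priors: PriorConfig | None = None) -> float:
    """Joint log prior density over the free parameters of the specification.

    Returns ``-inf`` for support violations (non-positive variances,
    non-PD Sigma_eta) rather than raising.
    """
    pr = priors or PriorConfig()
    if params.sigma2_v <= 0 or params.sigma2_u <= 0:
        return -math.inf
    J = params.J
    total = float(np.sum(norm.logpdf(params.alpha, scale=pr.fixed_sd)))
    if spec.include_race_education:
        total += float(np.sum(norm.logpdf(params.beta[:, 1:], scale=pr.fixed_sd)))
        total += float(np.sum(norm.logpdf(params.gamma[:, 1:], scale=pr.fixed_sd)))
    if spec.include_county_covariates:
        total += float(np.sum(norm.logpdf(params.delta, scale=pr.fixed_sd)))
    total += float(np.sum(norm.logpdf(params.lam[1:], scale=pr.loading_sd)))
    total += float(np.sum(norm.logpdf(params.kappa[1:], scale=pr.loading_sd)))
    total += icar_logpdf_kernel(params.v, county_graph, params.sigma2_v)
    total += icar_logpdf_kernel(params.u, state_graph, params.sigma2_u)
    total += float(halfnorm.logpdf(math.sqrt(params.sigma2_v), scale=pr.sigma_scale))
    total += float(halfnorm.logpdf(math.sqrt(params.sigma2_u), scale=pr.sigma_scale))
    total += eta_rw1_logpdf(params.eta, params.Sigma_eta)
    try:
        total += float(invwishart.logpdf(params.Sigma_eta, df=pr.eta_iw_df, scale=np.eye(J)))
    except np.linalg.LinAlgError:
        return -math.inf
    return total


# ---------------------------------------------------------------------------
# county covariate coding


def top_decile_indicator(values) -> np.ndarray:
    """Code 1 for counties whose value strictly exceeds the empirical 90th
    percentile, taken as the order statistic at position ceil(0.9 n).

    With n distinct values exactly floor(n/10) counties are flagged (311 of
    3,110); ties at the threshold are coded 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("values must be a non-empty 1-d array")
    k = math.ceil(0.9 * v.size)
    thresh = np.partition(v, k - 1)[k - 1]
    return (v > thresh).astype(int)
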