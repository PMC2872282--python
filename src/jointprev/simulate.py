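"""Synthetic survey generator: BRFSS-like hierarchical data with known truth.

Produces a two-level nested geography (counties nested in states on a rook
lattice), spatially autocorrelated latent fields at both levels, county
covariates, respondent covariates, heterogeneous survey weights from an
inverse-stratum-probability design, and multinomial outcomes drawn from the
full-model linear predictor. Every quantity is reproducible from a single
master seed split into named streams.

Default effect sizes mirror magnitudes typical of fitted multilevel models
of adult-male obesity/diabetes in US county data: strong positive county
poverty effects on the obese-diabetic category, lower morbidity in denser
counties, higher morbidity for black and Hispanic men, lower for college
graduates, age gradients rising for the diabetic categories, and a county
conditional variance of 0.3 dominating the state one (0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    A_DEFAULT,
    J_DEFAULT,
    AdjacencyGraph,
    ModelSpecification,
    ParameterSet,
    ValidationError,
    _phi_from_arrays,
    category_probs,
    county_arrays,
    top_decile_indicator,
)

# named substreams of the master seed
_STREAMS = ("geography", "covariates", "latent", "assignment", "outcomes", "weights")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# geography


@dataclass
class GeographyLayout:
    """Rook-adjacency county lattice with contiguous state blocks."""

    nrows: int
    ncols: int
    county_state: np.ndarray  # 0-based state per county
    county_graph: AdjacencyGraph
    state_graph: AdjacencyGraph

    @property
    def n_counties(self) -> int:
        return self.nrows * self.ncols

    @property
    def n_states(self) -> int:
        return len(np.unique(self.county_state))


def _grid_shape(n: int) -> tuple[int, int]:
    """Most-square factorisation r x c = n with r <= c."""
    r = int(np.sqrt(n))
    while r >= 1:
        if n % r == 0:
            return r, n // r
        r -= 1
    return 1, n


def make_lattice_geography(n_counties: int, n_states: int, seed: int = 0) -> GeographyLayout:
    """Build the nested geography deterministically.

    Counties are laid out on the most-square grid factorising ``n_counties``;
    rook neighbours define the county graph. States are contiguous runs of
    near-equal length along a boustrophedon (snake) ordering of the grid, so
    every state is a connected block; states are adjacent iff any of their
    member counties are.
    """
    if n_states < 1 or n_counties < n_states:
        raise ValidationError("need n_counties >= n_states >= 1")
    nrows, ncols = _grid_shape(n_counties)

    def node(i, j):
        return i * ncols + j

    edges = []
    for i in range(nrows):
        for j in range(ncols):
            if i + 1 < nrows:
                edges.append((node(i, j), node(i + 1, j)))
            if j + 1 < ncols:
                edges.append((node(i, j), node(i, j + 1)))
    county_graph = AdjacencyGraph.from_edges(n_counties, edges)

    snake = []
    for i in range(nrows):
        cols = range(ncols) if i % 2 == 0 else range(ncols - 1, -1, -1)
        snake.extend(node(i, j) for j in cols)
    county_state = np.empty(n_counties, dtype=int)
    for s, block in enumerate(np.array_split(np.array(snake), n_states)):
        county_state[block] = s

    state_edges = set()
    for a, b in edges:
        sa, sb = county_state[a], county_state[b]
        if sa != sb:
            state_edges.add((min(sa, sb), max(sa, sb)))
    state_graph = AdjacencyGraph.from_edges(n_states, sorted(state_edges))
    return GeographyLayout(nrows, ncols, county_state, county_graph, state_graph)


# ---------------------------------------------------------------------------
# intrinsic CAR sampling


def sample_icar(graph: AdjacencyGraph, sigma2: float, rng, size: int | None = None) -> np.ndarray:
    """Draw from the intrinsic CAR with conditional variance ``sigma2``.

    Spectral construction: independent Normal(0, sigma2/lambda_k) weights on
    the Laplacian eigenvectors with non-zero eigenvalue, so the covariance is
    sigma2 * pinv(L) and each connected component sums to zero (isolated
    nodes come out exactly 0). ``rng`` may be a Generator or an int seed;
    with ``size`` given, returns (size, n_nodes) independent draws.
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    evals, evecs = graph._eig()
    tol = 1e-9 * max(1.0, float(evals.max(initial=1.0)))
    keep = evals > tol
    m = int(keep.sum())
    nd = 1 if size is None else size
    z = rng.standard_normal((nd, m)) * np.sqrt(sigma2 / evals[keep])
    x = z @ evecs[:, keep].T
    # remove numerical drift off the sum-zero subspace, component-wise
    _, labels = graph.component_labels()
    for lab in np.unique(labels):
        msk = labels == lab
        x[:, msk] -= x[:, msk].mean(axis=1, keepdims=True)
    return x[0] if size is None else x


# ---------------------------------------------------------------------------
# configuration and true parameters


def default_true_params(n_counties: int, n_states: int, J: int = J_DEFAULT,
                        A: int = A_DEFAULT) -> ParameterSet:
    """Generating parameters at realistic fitted magnitudes (see module doc).

    Intercepts reproduce overall male category shares of roughly
    (4.2, 3.1, 1.4, 22.4, 40.2, 28.8)% when all other terms are zero.
    """
    p = ParameterSet.zeros(n_counties, n_states, J=J, A=A)
    shares = np.array([4.2, 3.1, 1.4, 22.4, 40.2, 28.8])
    p.alpha = np.log(shares[:J] / shares[-1])
    # race (columns: white ref, black, hispanic, other) and education
    # (ref < high school, hs grad, some college, college grad) log-odds
    p.beta = np.array([
        [0.0, 0.60, 0.74, -0.12],
        [0.0, 0.81, 0.87, -0.01],
        [0.0, 0.56, 0.67, 0.34],
        [0.0, 0.39, 0.48, -0.63],
        [0.0, 0.08, 0.41, -0.31],
    ])[:J]
    p.gamma = np.array([
        [0.0, -0.09, 0.02, -0.66],
        [0.0, 0.13, 0.02, -0.25],
        [0.0, -0.12, -0.34, -0.50],
        [0.0, 0.26, 0.37, -0.16],
        [0.0, 0.15, 0.29, 0.15],
    ])[:J]
    # county covariates: poverty, log density, top-decile black/hisp/other
    p.delta = np.array([
        [2.07, -0.11, 0.07, -0.13, -0.08],
        [0.58, -0.07, -0.28, 0.03, -0.12],
        [0.07, 0.01, -0.04, 0.12, -0.15],
        [1.06, -0.08, -0.09, -0.25, -0.17],
        [0.15, -0.04, -0.08, -0.20, -0.09],
    ])[:J]
    p.lam = np.array([1.0, 1.25, 1.27, 2.44, 1.65])[:J]
    p.kappa = np.array([1.0, 1.09, 0.45, 0.48, 0.30])[:J]
    # smooth age profiles: rising log-odds with age for the diabetic
    # categories, near-flat for obesity/overweight without diabetes
    ages = np.arange(A) - (A - 1) / 2.0
    slopes = np.array([0.28, 0.28, 0.24, 0.02, -0.02])[:J]
    p.eta = slopes[:, None] * ages[None, :]
    p.eta -= p.eta.mean(axis=1, keepdims=True)
    p.sigma2_v = 0.3
    p.sigma2_u = 0.1
    return p


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    The default desk scale is 100 counties in 5 states with 20,000
    respondents. ``sampling_probs_age`` / ``sampling_probs_race`` define the
    stratified sampling design: covariate strata are drawn from the
    population distribution tilted by the stratum sampling probability and
    weighted by its inverse, emulating differential telephone-survey response
    (older and white respondents over-represented).
    """

    n_counties: int = 100
    n_states: int = 5
    n_respondents: int = 20_000
    seed: int = 0
    true_params: ParameterSet | None = None
    poverty_beta: tuple[float, float] = (2.5, 14.0)
    log_density_normal: tuple[float, float] = (4.0, 1.5)
    race_dirichlet: tuple[float, ...] = (8.0, 1.0, 1.0, 0.5)
    county_size_lognormal_sd: float = 1.0
    age_dist: tuple[float, ...] = (
        0.10, 0.08, 0.08, 0.09, 0.09, 0.10, 0.10, 0.09, 0.08, 0.07, 0.06, 0.06)
    race_dist: tuple[float, ...] = (0.70, 0.10, 0.12, 0.08)
    edu_dist: tuple[float, ...] = (0.10, 0.30, 0.30, 0.30)
    sampling_probs_age: tuple[float, ...] = (
        0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 1.00)
    sampling_probs_race: tuple[float, ...] = (1.00, 0.70, 0.60, 0.80)
    weight_jitter_sd: float = 0.0

    def validate(self) -> None:
        if self.n_states < 1 or self.n_counties < self.n_states:
            raise ValidationError("need n_counties >= n_states >= 1")
        if self.n_respondents < 1:
            raise ValidationError("need at least one respondent")
        for name in ("age_dist", "race_dist", "edu_dist"):
            d = np.asarray(getattr(self, name), dtype=float)
            if np.any(d < 0) or not np.isclose(d.sum(), 1.0):
                raise ValidationError(f"{name} must be a probability vector")
        for name in ("sampling_probs_age", "sampling_probs_race"):
            pvec = np.asarray(getattr(self, name), dtype=float)
            if np.any(pvec <= 0) or np.any(pvec > 1):
                raise ValidationError(f"{name} entries must lie in (0, 1]")


# ---------------------------------------------------------------------------
# weights


def assign_survey_weights(respondents: pd.DataFrame, scheme: dict,
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Attach inverse-stratum-probability survey weights.

    ``scheme`` maps per-age and per-race sampling probabilities
    (``{"age_probs": ..., "race_probs": ..., "jitter_sd": ...}``); the
    stratum probability is their product and the weight its inverse,
    optionally multiplied by lognormal jitter with the given log-sd.
    """
    age_p = np.asarray(scheme["age_probs"], dtype=float)
    race_p = np.asarray(scheme["race_probs"], dtype=float)
    if np.any(age_p <= 0) or np.any(race_p <= 0):
        raise ValidationError("sampling probabilities must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = respondents["age_group"].to_numpy(dtype=int) - 1
    r = respondents["race"].to_numpy(dtype=int) - 1
    w = 1.0 / (age_p[a] * race_p[r])
    jitter_sd = float(scheme.get("jitter_sd", 0.0))
    if jitter_sd > 0:
        w = w * np.exp(rng.normal(0.0, jitter_sd, size=len(w)))
    out = respondents.copy()
    out["weight"] = w
    return out


# ---------------------------------------------------------------------------
# dataset generation


def generate_counties(config: SimulationConfig, geography: GeographyLayout,
                      rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_counties
    poverty = rng.beta(*config.poverty_beta, size=n)
    log_density = rng.normal(*config.log_density_normal, size=n)
    race_comp = rng.dirichlet(config.race_dirichlet, size=n)  # white, black, hisp, other
    return pd.DataFrame({
        "county": np.arange(1, n + 1),
        "state": geography.county_state + 1,
        "poverty": poverty,
        "log_density": log_density,
        "top_black": top_decile_indicator(race_comp[:, 1]),
        "top_hisp": top_decile_indicator(race_comp[:, 2]),
        "top_other": top_decile_indicator(race_comp[:, 3]),
    })


def generate_dataset(config: SimulationConfig):
    """Forward-simulate a full survey: (respondents, counties, geography, truth).

    County covariates and latent ICAR fields are drawn per the config, each
    respondent is allocated to a county with probability proportional to a
    lognormal county size, covariate strata are drawn from the
    sampling-tilted population distribution with inverse-probability weights,
    and the outcome category is multinomial with the full-model (model 3)
    probabilities. Byte-identical for identical configs.
    """
    config.validate()
    rngs = _rngs(config.seed)
    geography = make_lattice_geography(config.n_counties, config.n_states, config.seed)
    counties = generate_counties(config, geography, rngs["covariates"])

    truth = (config.true_params.copy() if config.true_params is not None
             else default_true_params(config.n_counties, config.n_states))
    truth.v = sample_icar(geography.county_graph, truth.sigma2_v, rngs["latent"])
    truth.u = sample_icar(geography.state_graph, truth.sigma2_u, rngs["latent"])

    n = config.n_respondents
    sizes = rngs["assignment"].lognormal(0.0, config.county_size_lognormal_sd,
                                         size=config.n_counties)
    county_idx = rngs["assignment"].choice(config.n_counties, size=n, p=sizes / sizes.sum())

    # stratified sampling: draw (age, race) from population dist tilted by
    # the stratum sampling probability; education independent of the design
    age_pop = np.asarray(config.age_dist)
    race_pop = np.asarray(config.race_dist)
    age_sp = np.asarray(config.sampling_probs_age)
    race_sp = np.asarray(config.sampling_probs_race)
    joint = np.outer(age_pop * age_sp, race_pop * race_sp)
    joint = joint / joint.sum()
    strata = rngs["covariates"].choice(joint.size, size=n, p=joint.ravel())
    age_idx, race_idx = np.unravel_index(strata, joint.shape)
    edu_idx = rngs["covariates"].choice(len(config.edu_dist), size=n, p=config.edu_dist)

    respondents = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age_group": age_idx + 1,
        "race": race_idx + 1,
        "education": edu_idx + 1,
        "county": county_idx + 1,
        "weight": 1.0,
        "category": 1,
    })
    respondents = assign_survey_weights(
        respondents,
        {"age_probs": age_sp, "race_probs": race_sp, "jitter_sd": config.weight_jitter_sd},
        rngs["weights"],
    )

    spec = ModelSpecification(True, True, J=truth.J, A=truth.A)
    X, state = county_arrays(counties)
    phi = _phi_from_arrays(age_idx, race_idx, edu_idx, county_idx, X, state, truth, spec)
    pi = category_probs(phi)
    cum = np.cumsum(pi, axis=1)
    udraw = rngs["outcomes"].random(n)
    respondents["category"] = 1 + (udraw[:, None] > cum).sum(axis=1)
    return respondents, counties, geography, truth


def population_category_shares(config: SimulationConfig, geography: GeographyLayout,
                               counties: pd.DataFrame, truth: ParameterSet) -> np.ndarray:
    """Exact population category shares implied by the generating model.

    Enumerates every (age, race, education, county) cell with its population
    probability (no sampling tilt) using the lognormal county sizes implied
    by the config's assignment stream; the design-based oracle for what
    weighted estimates should recover.
    """
    rngs = _rngs(config.seed)
    sizes = rngs["assignment"].lognormal(0.0, config.county_size_lognormal_sd,
                                         size=config.n_counties)
    county_p = sizes / sizes.sum()
    A, R, E, C = len(config.age_dist), len(config.race_dist), len(config.edu_dist), config.n_counties
    a, r, e, c = np.meshgrid(np.arange(A), np.arange(R), np.arange(E), np.arange(C),
                             indexing="ij")
    a, r, e, c = a.ravel(), r.ravel(), e.ravel(), c.ravel()
    cell_p = (np.asarray(config.age_dist)[a] * np.asarray(config.race_dist)[r]
              * np.asarray(config.edu_dist)[e] * county_p[c])
    spec = ModelSpecification(True, True, J=truth.J, A=truth.A)
    X, state = county_arrays(counties)
    pi = category_probs(_phi_from_arrays(a, r, e, c, X, state, truth, spec))
    return cell_p @ pi
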