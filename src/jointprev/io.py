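"""Readers and writers: respondent/county tables (delimited text with
headers), GAL-style adjacency lists, and flat key-value run configuration.
All readers validate and raise row-addressed errors; every writer output
round-trips through its reader.
"""

from __future__ import annotations

import configparser
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    COUNTY_COLUMNS,
    RESPONDENT_COLUMNS,
    AdjacencyGraph,
    ValidationError,
    validate_counties,
    validate_respondents,
)

log = logging.getLogger("jointprev")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# tables


def read_respondents(path, n_counties: int | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RESPONDENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["weight"].isna().any():
        row = int(df.index[df["weight"].isna()][0])
        raise ValidationError(f"{path} row {row}: missing weight")
    validate_respondents(df, n_counties=n_counties)
    return df[list(RESPONDENT_COLUMNS)]


def write_respondents(df: pd.DataFrame, path) -> None:
    validate_respondents(df)
    df[list(RESPONDENT_COLUMNS)].to_csv(path, index=False)


def read_counties(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COUNTY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    validate_counties(df)
    return df[list(COUNTY_COLUMNS)]


def write_counties(df: pd.DataFrame, path) -> None:
    validate_counties(df)
    df[list(COUNTY_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# adjacency (GAL dialect: count line, then per node "id degree" + neighbour ids;
# ids are 1-based in the file)


def read_adjacency_gal(path) -> AdjacencyGraph:
    path = Path(path)
    tokens: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.extend(int(t) for t in line.split())
    if not tokens:
        raise ValidationError(f"{path}: empty GAL file")
    n = tokens[0]
    pos = 1
    nbrs: list[set[int]] = [set() for _ in range(n)]
    seen = set()
    while pos < len(tokens):
        if pos + 1 >= len(tokens):
            raise ValidationError(f"{path}: truncated node record at token {pos}")
        node_id, degree = tokens[pos], tokens[pos + 1]
        pos += 2
        if not 1 <= node_id <= n:
            raise ValidationError(f"{path}: node id {node_id} out of range 1..{n}")
        ids = tokens[pos:pos + degree]
        if len(ids) != degree:
            raise ValidationError(f"{path}: node {node_id} declares degree {degree} "
                                  f"but lists {len(ids)} neighbours")
        pos += degree
        for nb in ids:
            if not 1 <= nb <= n:
                raise ValidationError(f"{path}: neighbour id {nb} out of range 1..{n}")
            if nb == node_id:
                raise ValidationError(f"{path}: node {node_id} lists itself")
            nbrs[node_id - 1].add(nb - 1)
        seen.add(node_id)
    asym = [(i, j) for i in range(n) for j in nbrs[i] if i not in nbrs[j]]
    if asym:
        warnings.warn(f"{path}: symmetrizing {len(asym)} one-directional adjacencies",
                      RuntimeWarning)
        log.warning("%s: symmetrized %d one-directional adjacencies", path, len(asym))
        for i, j in asym:
            nbrs[j].add(i)
    return AdjacencyGraph(n, [sorted(s) for s in nbrs])


def write_adjacency_gal(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{graph.n_nodes}\n")
        for i, nb in enumerate(graph.neighbors):
            fh.write(f"{i + 1} {len(nb)}\n")
            if len(nb):
                fh.write(" ".join(str(j + 1) for j in nb) + "\n")


# ---------------------------------------------------------------------------
# fit persistence (runtime artifacts: compressed columnar draws + JSON meta)


def save_fit(fit, out_dir) -> None:
    import json

    from .mcmc import FitResult  # noqa: F401  (type reference)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "draws.npz", deviance=fit.deviance, **fit.draws)
    meta = {
        "model": fit.spec.number, "J": fit.spec.J, "A": fit.spec.A,
        "n_counties": fit.n_counties, "n_states": fit.n_states,
        "n_chains": fit.config.n_chains, "n_iterations": fit.config.n_iterations,
        "burnin_fraction": fit.config.burnin_fraction, "seed": fit.config.seed,
        "normalize_weights": fit.config.normalize_weights,
        "acceptance": fit.acceptance,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def load_fit(fit_dir):
    import json

    from .mcmc import FitResult, MCMCConfig
    from .model import ModelSpecification

    fit_dir = Path(fit_dir)
    meta = json.loads((fit_dir / "meta.json").read_text())
    data = np.load(fit_dir / "draws.npz")
    deviance = data["deviance"]
    draws = {k: data[k] for k in data.files if k != "deviance"}
    spec = ModelSpecification.from_number(meta["model"], J=meta["J"], A=meta["A"])
    cfg = MCMCConfig(
        n_chains=meta["n_chains"], n_iterations=meta["n_iterations"],
        burnin_fraction=meta["burnin_fraction"], seed=meta["seed"],
        normalize_weights=meta["normalize_weights"],
    )
    return FitResult(
        draws=draws, deviance=deviance, acceptance=meta["acceptance"], spec=spec,
        config=cfg, n_counties=meta["n_counties"], n_states=meta["n_states"],
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths and settings for a full pipeline run."""

    respondents: str = "respondents.csv"
    counties: str = "counties.csv"
    county_adj: str = "county_adj.gal"
    state_adj: str = "state_adj.gal"
    out_dir: str = "out"
    models: tuple[int, ...] = (1, 2, 3)
    n_chains: int = 2
    n_iterations: int = 10_000
    burnin_fraction: float = 0.5
    seed: int = 0
    normalize_weights: bool = True
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("respondents", "counties", "county_adj", "state_adj"):
            if not Path(getattr(self, name)).exists():
                raise ValidationError(f"missing input file for {name}: {getattr(self, name)}")
        for m in self.models:
            if m not in (1, 2, 3):
                raise ValidationError(f"model selector must be in {{1,2,3}}, got {m}")


def read_config(path) -> RunConfig:
    """Parse a sectioned key-value config file. Environment variables of the
    form JOINTPREV_RESPONDENTS etc. override the path entries only."""
    import os

    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise ValidationError(f"cannot read config file {path}")
    cfg = RunConfig()
    if cp.has_section("paths"):
        for key in ("respondents", "counties", "county_adj", "state_adj", "out_dir"):
            if cp.has_option("paths", key):
                setattr(cfg, key, cp.get("paths", key))
    for key in ("respondents", "counties", "county_adj", "state_adj", "out_dir"):
        env = os.environ.get(f"JOINTPREV_{key.upper()}")
        if env:
            setattr(cfg, key, env)
    if cp.has_section("fit"):
        s = cp["fit"]
        cfg.models = tuple(int(t) for t in s.get("models", "1 2 3").split())
        cfg.n_chains = s.getint("n_chains", cfg.n_chains)
        cfg.n_iterations = s.getint("n_iterations", cfg.n_iterations)
        cfg.burnin_fraction = s.getfloat("burnin_fraction", cfg.burnin_fraction)
        cfg.seed = s.getint("seed", cfg.seed)
        cfg.normalize_weights = s.getboolean("normalize_weights", cfg.normalize_weights)
        cfg.log_level = s.get("log_level", cfg.log_level)
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["paths"] = {
        "respondents": cfg.respondents, "counties": cfg.counties,
        "county_adj": cfg.county_adj, "state_adj": cfg.state_adj,
        "out_dir": cfg.out_dir,
    }
    cp["fit"] = {
        "models": " ".join(str(m) for m in cfg.models),
        "n_chains": str(cfg.n_chains), "n_iterations": str(cfg.n_iterations),
        "burnin_fraction": str(cfg.burnin_fraction), "seed": str(cfg.seed),
        "normalize_weights": str(cfg.normalize_weights), "log_level": cfg.log_level,
    }
    with open(path, "w") as fh:
        cp.write(fh)
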