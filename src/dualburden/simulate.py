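"""Synthetic survey generator with known truth.

Emulates a two-stage stratified cluster survey of under-five anthropometry
in a 15-region country: child and maternal covariates, nonlinear age and
maternal-anthropometry effects, structured (neighbour-correlated) and
unstructured region effects, survival-Gumbel dependence between the
stunting and wasting outcomes, gamma-distributed sampling weights and
30-child clusters.  A truth sidecar records every generating parameter and
the per-region true joint cell probabilities, so recovery of any pipeline
estimate can be checked without external data.

Default conditions: n = 4000 children, marginal baseline prevalences around
29 % (stunting, probit margin) and 7 % (wasting, cloglog margin), constant
Kendall's tau = 0.2 via a survival Gumbel copula, a stunting age profile
rising to a peak near 30 months, and a mild decreasing age trend for
wasting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .copulas import CopulaSpec, cell_probs, theta_from_tau
from .smoothers import graph_laplacian


def grid_region_graph(rows: int = 3, cols: int = 5) -> nx.Graph:
    """Rook-adjacency grid of regions labelled R01..R{rows*cols}."""
    g0 = nx.grid_2d_graph(rows, cols)
    mapping = {}
    for i, (r, c) in enumerate(sorted(g0.nodes())):
        mapping[(r, c)] = f"R{i+1:02d}"
    return nx.relabel_nodes(g0, mapping)


# default nonlinear truth profiles (age in months, Z scores, years)
def f_age_stunt(age):
    """Stunting age profile: rises to a peak near 30 months, then declines."""
    return 0.6 * np.exp(-(((np.asarray(age, float) - 30.0) / 15.0) ** 2))


def f_age_waste(age):
    """Wasting age profile: mild monotone decline over 0-59 months."""
    return -0.006 * (np.asarray(age, float) - 29.5)


def f_mhaz_stunt(z):
    """Maternal height-for-age effect on stunting: protective when high."""
    return -0.25 * np.asarray(z, float)


def zero_fn(x):
    return np.zeros_like(np.asarray(x, float))


@dataclass
class GeneratorConfig:
    """Generating truth for one synthetic survey."""

    n: int = 4000
    graph: nx.Graph = field(default_factory=grid_region_graph)
    link_stunt: str = "probit"
    link_waste: str = "cloglog"
    # marginal baseline prevalences the intercepts are calibrated to
    base_prev_stunt: float = 0.29
    base_prev_waste: float = 0.07
    # fixed-effect truth: {column-level name: coefficient}, per margin
    beta_stunt: dict = field(default_factory=lambda: {
        "sex[female]": -0.15, "location[rural]": 0.12,
        "wealth_quintile[2]": -0.05, "wealth_quintile[3]": -0.12,
        "wealth_quintile[4]": -0.20, "wealth_quintile[5]": -0.30,
    })
    beta_waste: dict = field(default_factory=lambda: {
        "sex[female]": -0.10,
    })
    # smooth truth functions per margin
    f_stunt: dict = field(default_factory=lambda: {
        "age_months": f_age_stunt, "maternal_haz": f_mhaz_stunt,
    })
    f_waste: dict = field(default_factory=lambda: {
        "age_months": f_age_waste,
    })
    sigma_structured: float = 0.3
    sigma_unstructured: float = 0.1
    copula: str = "gumbel"
    rotation: int = 180
    tau: float = 0.2
    tau_by_region: dict | None = None
    cluster_size: int = 30
    urban_share: float = 0.28
    seed: int = 0


_LINKS = {
    "probit": (norm.cdf, norm.ppf),
    "logit": (lambda e: 1.0 / (1.0 + np.exp(-e)),
              lambda p: np.log(p / (1.0 - p))),
    "cloglog": (lambda e: 1.0 - np.exp(-np.exp(e)),
                lambda p: np.log(-np.log(1.0 - p))),
}


def sample_positive_stable(alpha: float, size: int, rng: np.random.Generator):
    """Positive stable S(alpha, 1) draws via Chambers-Mallows-Stuck."""
    u = rng.uniform(0.0, np.pi, size)
    w = rng.exponential(1.0, size)
    a = np.sin(alpha * u) / np.sin(u) ** (1.0 / alpha)
    b = (np.sin((1.0 - alpha) * u) / w) ** ((1.0 - alpha) / alpha)
    return a * b


def sample_gumbel_pair(theta, size: int, rng: np.random.Generator,
                       rotation: int = 0):
    """Sample (u, v) from the Gumbel copula by the Marshall-Olkin route.

    V ~ positive-stable(1/theta); u = exp(-(E1/V)^(1/theta)) with E1, E2
    independent unit exponentials.  ``rotation=180`` returns the survival
    pair (1-u, 1-v).  theta may be a scalar or a length-``size`` array.
    """
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (size,)).copy()
    if np.any(theta < 1.0):
        raise ValueError("gumbel copula requires theta >= 1")
    u = np.empty(size)
    v = np.empty(size)
    e1 = rng.exponential(1.0, size)
    e2 = rng.exponential(1.0, size)
    near_one = theta < 1.0 + 1e-9
    if near_one.any():
        u[near_one] = np.exp(-e1[near_one])
        v[near_one] = np.exp(-e2[near_one])
    rest = ~near_one
    if rest.any():
        # group identical thetas so the CMS sampler runs vectorized
        for th in np.unique(theta[rest]):
            m = rest & (theta == th)
            V = sample_positive_stable(1.0 / th, int(m.sum()), rng)
            u[m] = np.exp(-((e1[m] / V) ** (1.0 / th)))
            v[m] = np.exp(-((e2[m] / V) ** (1.0 / th)))
    if rotation == 180:
        u, v = 1.0 - u, 1.0 - v
    elif rotation == 90:
        u = 1.0 - u
    elif rotation == 270:
        v = 1.0 - v
    return u, v


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    afb = truncnorm.rvs((12 - 22) / 4, (45 - 22) / 4, loc=22, scale=4,
                        size=n, random_state=rng)
    return pd.DataFrame({
        "age_months": rng.integers(0, 60, n).astype(float),
        "sex": rng.choice(["male", "female"], n, p=[0.51, 0.49]),
        "ethnicity": rng.choice(["majority", "minority"], n, p=[0.68, 0.32]),
        "maternal_haz": rng.normal(-1.0, 1.0, n),
        "maternal_whz": rng.normal(0.0, 1.0, n),
        "maternal_age_first_birth": afb,
        "maternal_education": rng.choice(
            ["none", "primary", "secondary", "higher"], n,
            p=[0.15, 0.40, 0.33, 0.12]),
        "maternal_working": rng.choice([0, 1], n, p=[0.45, 0.55]),
        "wealth_quintile": rng.integers(1, 6, n),
        "head_gender": rng.choice(["male", "female"], n, p=[0.81, 0.19]),
        "toilet_improved": rng.choice([0, 1], n, p=[0.38, 0.62]),
        "water_on_premise": rng.choice([0, 1], n, p=[0.52, 0.48]),
        "water_treated": rng.choice([0, 1], n, p=[0.60, 0.40]),
    })


def _fixed_effect_eta(df: pd.DataFrame, beta: dict) -> np.ndarray:
    eta = np.zeros(len(df))
    for key, b in beta.items():
        col, _, lev = key.partition("[")
        lev = lev.rstrip("]")
        series = df[col]
        if series.dtype != object:
            lev = type(series.iloc[0])(lev)
        eta += b * (series == lev).to_numpy(dtype=float)
    return eta


def _spatial_effects(graph: nx.Graph, sigma_s: float, sigma_u: float,
                     rng: np.random.Generator):
    """Structured effects from a proper CAR surrogate plus iid deviations.

    The structured field is drawn with covariance proportional to
    (L + 0.01 I)^-1, centered, and rescaled to standard deviation sigma_s.
    """
    levels = sorted(graph.nodes())
    R = len(levels)
    L = graph_laplacian(graph, levels)
    cov = np.linalg.inv(L + 0.01 * np.eye(R))
    z = rng.multivariate_normal(np.zeros(R), cov, method="cholesky")
    z = z - z.mean()
    sd = z.std()
    s = sigma_s * z / sd if (sigma_s > 0 and sd > 0) else np.zeros(R)
    u = rng.normal(0.0, sigma_u, R) if sigma_u > 0 else np.zeros(R)
    u = u - u.mean() if sigma_u > 0 else u
    return levels, dict(zip(levels, s)), dict(zip(levels, u))


def _backfill_z(y: np.ndarray, rng: np.random.Generator, loc: float,
                scale: float) -> np.ndarray:
    """Continuous Z scores consistent with the binary outcome.

    Truncated-normal draws on the correct side of the -2 cutoff, inside the
    retained [-6, 6] window, so re-classifying reproduces y exactly.
    """
    z = np.empty(y.shape[0])
    pos = y == 1
    a, b = (-6.0 - loc) / scale, (-2.0 - loc) / scale
    z[pos] = truncnorm.rvs(a, b, loc=loc, scale=scale, size=int(pos.sum()),
                           random_state=rng)
    # strictly-below cutoff: nudge exact boundary hits inward
    z[pos] = np.minimum(z[pos], -2.0 - 1e-9)
    a, b = (-2.0 - loc) / scale, (6.0 - loc) / scale
    z[~pos] = truncnorm.rvs(a, b, loc=loc, scale=scale, size=int((~pos).sum()),
                            random_state=rng)
    z[~pos] = np.maximum(z[~pos], -2.0)
    return z


def generate(config: GeneratorConfig,
             rng: np.random.Generator | None = None):
    """Generate one synthetic survey; returns (child table, truth sidecar).

    The child table matches the raw-input schema (one row per child with
    ``haz``/``whz`` rather than pre-made binary outcomes); the sidecar holds
    the generating parameters, the per-child true marginal probabilities and
    the per-region true mean joint cells.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    levels = sorted(cfg.graph.nodes())
    R = len(levels)
    if cfg.n < R:
        raise ValueError("need at least one child per region")

    df = _draw_covariates(cfg.n, rng)

    # region / cluster / stratum structure: equal allocation across regions,
    # clusters of cluster_size children nested within region, strata =
    # region x urban/rural with location constant within a cluster
    region = np.repeat(levels, int(np.ceil(cfg.n / R)))[: cfg.n]
    df["region_id"] = region
    pos_in_region = np.concatenate([
        np.arange((region == r).sum()) for r in levels
    ])
    cluster_id = np.array([
        f"{r}-C{p // cfg.cluster_size:03d}"
        for r, p in zip(region, pos_in_region)
    ])
    df["cluster_id"] = cluster_id
    uniq_clusters = pd.unique(cluster_id)
    urban = dict(zip(uniq_clusters,
                     rng.uniform(size=len(uniq_clusters)) < cfg.urban_share))
    df["location"] = np.where([urban[c] for c in cluster_id], "urban", "rural")
    df["stratum_id"] = df["region_id"] + "/" + df["location"]

    levels_, s_eff, u_eff = _spatial_effects(
        cfg.graph, cfg.sigma_structured, cfg.sigma_unstructured, rng)

    h1, g1 = _LINKS[cfg.link_stunt]
    h2, g2 = _LINKS[cfg.link_waste]

    eta1 = _fixed_effect_eta(df, cfg.beta_stunt)
    eta2 = _fixed_effect_eta(df, cfg.beta_waste)
    for col, f in cfg.f_stunt.items():
        fx = f(df[col].to_numpy(dtype=float))
        eta1 += fx - fx.mean()
    for col, f in cfg.f_waste.items():
        fx = f(df[col].to_numpy(dtype=float))
        eta2 += fx - fx.mean()
    eta1 += np.array([s_eff[r] + u_eff[r] for r in df["region_id"]])
    eta2 += np.array([s_eff[r] + u_eff[r] for r in df["region_id"]])
    # center realized effects so the intercept pins the baseline prevalence
    eta1 -= eta1.mean()
    eta2 -= eta2.mean()
    eta1 += g1(cfg.base_prev_stunt)
    eta2 += g2(cfg.base_prev_waste)

    p1 = h1(eta1)
    p2 = h2(eta2)
    if np.any((p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)):
        raise ValueError("marginal probabilities left (0,1) under this config")

    if cfg.tau_by_region is not None:
        tau_r = {r: float(cfg.tau_by_region[r]) for r in levels}
    else:
        tau_r = {r: float(cfg.tau) for r in levels}
    theta_r = {r: theta_from_tau(t, cfg.copula) for r, t in tau_r.items()}
    theta_i = np.array([theta_r[r] for r in df["region_id"]])

    if cfg.copula != "gumbel":
        raise NotImplementedError("the generator samples the Gumbel family")
    u, v = sample_gumbel_pair(theta_i, cfg.n, rng, rotation=cfg.rotation)
    y1 = (u <= p1).astype(int)
    y2 = (v <= p2).astype(int)

    df["haz"] = _backfill_z(y1, rng, loc=-1.1, scale=1.2)
    df["whz"] = _backfill_z(y2, rng, loc=-0.3, scale=1.1)

    w = rng.gamma(4.0, 0.25, cfg.n)
    df["weight"] = w / w.mean()
    df.insert(0, "child_id", [f"K{i:05d}" for i in range(cfg.n)])

    # per-region true mean cells under the generating copula
    spec = CopulaSpec(cfg.copula, cfg.rotation, 1.0)
    region_truth = {}
    for r in levels:
        m = (df["region_id"] == r).to_numpy()
        if m.any():
            cells = cell_probs(p1[m], p2[m], spec.with_theta(theta_r[r]))
            means = {
                "p1": float(p1[m].mean()), "p2": float(p2[m].mean()),
                "p00": float(cells.p00.mean()),
                "p01": float(cells.p01.mean()),
                "p10": float(cells.p10.mean()),
                "p11": float(cells.p11.mean()),
            }
        else:
            means = {k: float("nan") for k in
                     ("p1", "p2", "p00", "p01", "p10", "p11")}
        region_truth[r] = {
            **means,
            "theta": float(theta_r[r]), "tau": float(tau_r[r]),
            "structured": float(s_eff[r]), "unstructured": float(u_eff[r]),
        }

    truth = {
        "config": {
            "n": cfg.n, "link_stunt": cfg.link_stunt,
            "link_waste": cfg.link_waste,
            "base_prev_stunt": cfg.base_prev_stunt,
            "base_prev_waste": cfg.base_prev_waste,
            "copula": cfg.copula, "rotation": cfg.rotation,
            "tau": cfg.tau, "sigma_structured": cfg.sigma_structured,
            "sigma_unstructured": cfg.sigma_unstructured, "seed": cfg.seed,
        },
        "beta_stunt": dict(cfg.beta_stunt),
        "beta_waste": dict(cfg.beta_waste),
        "intercept_stunt": float(g1(cfg.base_prev_stunt)),
        "intercept_waste": float(g2(cfg.base_prev_waste)),
        "eta1": eta1, "eta2": eta2, "p1": p1, "p2": p2,
        "y1": y1, "y2": y2,
        "structured": s_eff, "unstructured": u_eff,
        "tau_by_region": tau_r, "theta_by_region": theta_r,
        "region_truth": region_truth,
    }
    return df, truth
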