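"""End-to-end drivers binding the pipeline stages to files on disk.

Each ``run_*`` function is a thin, idempotent wrapper over the library:
given a seed/config it simulates, describes, selects, fits or maps, and
writes plain CSV tables (leading ``#`` comment line with version, seed and
config hash) plus JSON metadata.  The numbered scripts under ``analysis/``
call these functions in order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import __version__
from .copulas import CopulaSpec, tau_from_theta, theta_from_eta
from .descriptives import (
    SurveyDesign,
    chisq_association,
    crosstab,
    prevalence_table,
)
from .model import FitConfig, FitResult, fit_model
from .preprocess import (
    ModelFrame,
    build_model_frame,
    read_adjacency,
    write_adjacency,
)
from .selection import two_step_selection
from .simulate import GeneratorConfig, generate
from .surfaces import region_surface, structured_effect_table

#: compact default model for routine fits: the covariates with generating
#: counterparts plus the full spatial structure
COMPACT_STUNT_TERMS = [
    "sex", "location", "wealth_quintile",
    "s(age_months)", "s(maternal_haz)", "mrf(region)", "iid(region)",
]
COMPACT_WASTE_TERMS = [
    "sex", "s(age_months)", "mrf(region)", "iid(region)",
]


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, seed, tag: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# dualburden v{__version__} seed={seed} config={tag}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the leading comment line."""
    return pd.read_csv(path, comment="#")


def run_simulate(outdir, config: GeneratorConfig | None = None,
                 seed: int | None = None, n: int | None = None) -> Path:
    """Simulate a survey and write children.csv + adjacency + truth sidecar."""
    outdir = Path(outdir)
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg.seed = seed
    if n is not None:
        cfg.n = n
    df, truth = generate(cfg)
    tag = _config_hash(truth["config"])
    _write_csv(df, outdir / "children.csv", cfg.seed, tag)
    write_adjacency(cfg.graph, outdir / "adjacency.txt")
    slim = {k: v for k, v in truth.items()
            if k not in ("eta1", "eta2", "p1", "p2", "y1", "y2")}
    slim["beta_stunt"] = truth["beta_stunt"]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(slim, fh, indent=1, default=float)
    return outdir


def load_data(data_csv, adjacency_path):
    """Load a child-record CSV and its region adjacency neighbour list."""
    df = pd.read_csv(data_csv, comment="#")
    graph = read_adjacency(adjacency_path)
    return df, graph


def run_describe(df: pd.DataFrame, outdir, seed="NA") -> dict:
    """Weighted prevalence table, 2x2 table and association test to CSV."""
    outdir = Path(outdir)
    from .preprocess import classify_frame

    if "y_stunt" not in df:
        df, _ = classify_frame(df)
    t1 = prevalence_table(df)
    tab = crosstab(df["y_stunt"], df["y_waste"])
    stat, dof, p = chisq_association(tab, correction=True)
    t2 = pd.DataFrame([{
        "n11": tab.n11, "n10": tab.n10, "n01": tab.n01, "n00": tab.n00,
        "n": tab.n, "chisq": stat, "df": dof, "p": p,
    }])
    tag = _config_hash({"n": len(df)})
    _write_csv(t1, outdir / "table1_prevalence.csv", seed, tag)
    _write_csv(t2, outdir / "table2_association.csv", seed, tag)
    return {"table1": t1, "table2": t2}


def build_frame(df: pd.DataFrame, graph, compact: bool = True,
                theta_terms: list | None = None) -> ModelFrame:
    stunt = COMPACT_STUNT_TERMS if compact else None
    waste = COMPACT_WASTE_TERMS if compact else None
    return build_model_frame(df, stunt, waste, graph,
                             theta_terms=theta_terms or [])


def run_select(frame: ModelFrame, outdir, seed="NA",
               config: FitConfig | None = None) -> dict:
    """Two-step copula/link selection; writes the candidate AIC/BIC table."""
    outdir = Path(outdir)
    step1, step2 = two_step_selection(frame, config=config)
    tag = _config_hash({"n": frame.n})
    table = pd.concat(
        [step1.table.assign(step=1), step2.table.assign(step=2)],
        ignore_index=True)
    _write_csv(table, outdir / "selection.csv", seed, tag)
    return {"step1": step1, "step2": step2}


def coef_table(fit: FitResult, robust: bool = True) -> pd.DataFrame:
    """Coefficient table (term, estimate, SE, z, p) for the fixed effects."""
    se_m = fit.se(robust=False)
    se_r = fit.se(robust=True) if fit.Vr is not None else se_m
    rows = []
    pen_cols = np.zeros(len(fit.delta), dtype=bool)
    for blk in fit.blocks:
        pen_cols[blk.sl] = True
    for j, name in enumerate(fit.colnames):
        if pen_cols[j]:
            continue
        est = fit.delta[j]
        se = se_r[j] if robust else se_m[j]
        z = est / se if se > 0 else np.nan
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        pred, _, term = name.partition(":")
        rows.append({"predictor": pred, "term": term, "estimate": est,
                     "se_model": se_m[j], "se_cluster": se_r[j],
                     "z": z, "p": p})
    return pd.DataFrame(rows)


def run_fit(frame: ModelFrame, outdir, seed="NA",
            copula: str = "gumbel", rotation: int = 180,
            link_stunt: str = "probit", link_waste: str = "cloglog",
            config: FitConfig | None = None) -> FitResult:
    """Fit the joint model and write coefficient + metadata tables."""
    outdir = Path(outdir)
    fit = fit_model(frame, copula=copula, rotation=rotation,
                    link_stunt=link_stunt, link_waste=link_waste,
                    config=config)
    tag = _config_hash({"copula": copula, "rotation": rotation,
                        "links": [link_stunt, link_waste], "n": frame.n})
    _write_csv(coef_table(fit), outdir / "coefficients.csv", seed, tag)
    from .selection import term_test_table

    _write_csv(term_test_table(fit), outdir / "term_tests.csv", seed, tag)
    meta = {
        "loglik": fit.loglik, "edf": fit.edf_total, "aic": fit.aic,
        "bic": fit.bic, "converged": bool(fit.converged),
        "grad_norm": fit.grad_norm, "n": fit.n,
        "lambda": {b.label: b.lam for b in fit.blocks},
        "edf_by_term": fit.edf_by_term,
        "copula": fit.copula.label,
        "links": [fit.link_stunt.name, fit.link_waste.name],
        "seed": seed, "config_hash": tag,
    }
    with open(outdir / "fit_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=float)
    return fit


def run_maps(fit: FitResult, outdir, seed="NA") -> pd.DataFrame:
    """Region-keyed joint-probability / dependence / spatial-effect tables."""
    outdir = Path(outdir)
    surf = region_surface(fit)
    tag = _config_hash({"n": fit.n})
    _write_csv(surf, outdir / "region_surface.csv", seed, tag)
    eff = structured_effect_table(fit)
    if eff is not None:
        _write_csv(eff, outdir / "structured_effects.csv", seed, tag)
    return surf


def mean_tau(fit: FitResult) -> float:
    """Average Kendall's tau implied by the fitted dependence predictor."""
    if not fit.theta_active:
        return 0.0
    eta3 = fit.frame.theta.X @ fit.coef("dependence")
    thetas = theta_from_eta(eta3, fit.copula.family)
    taus = [tau_from_theta(CopulaSpec(fit.copula.family, fit.copula.rotation, t))
            for t in np.unique(thetas)]
    # weight by rows at each distinct level
    uniq, counts = np.unique(thetas, return_counts=True)
    return float(np.average(taus, weights=counts))
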