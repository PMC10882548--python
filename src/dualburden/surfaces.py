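"""Post-fit prediction layer: joint-probability and dependence surfaces.

Turns a fitted copula geoadditive model into region-keyed numeric tables:
per-child joint cell probabilities, within-region (sampling-weighted)
averages of the four cells, the region-varying copula parameter and its
Kendall's tau, and the structured (MRF) spatial effects with pointwise
standard errors.  The tables are plain region-keyed frames so a choropleth
join against any boundary file is a single attribute merge downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .copulas import CopulaSpec, cell_probs, tau_from_theta, theta_from_eta
from .model import FitResult
from .preprocess import ModelFrame


def _etas(fit: FitResult, frame: ModelFrame, reference: bool = False):
    def xs(pred, name):
        X = pred.X
        if not reference:
            return X
        # reference profile: intercept + regional effects only (all fixed
        # effects at their reference level, smooths at their centered zero)
        keep = np.zeros(X.shape[1], dtype=bool)
        keep[0] = True
        for pb in pred.penalties:
            if pb.label in ("mrf(region)", "iid(region)"):
                keep[pb.sl] = True
        Xr = np.zeros_like(X)
        Xr[:, keep] = X[:, keep]
        return Xr

    eta1 = xs(frame.stunt, "stunting") @ fit.coef("stunting")
    eta2 = xs(frame.waste, "wasting") @ fit.coef("wasting")
    if fit.theta_active:
        eta3 = frame.theta.X @ fit.coef("dependence")
        theta = theta_from_eta(eta3, fit.copula.family)
    else:
        theta = np.zeros(frame.n)
    return eta1, eta2, theta


def predict_cells(fit: FitResult, frame: ModelFrame | None = None,
                  reference: bool = False) -> pd.DataFrame:
    """Row-wise marginal and joint cell probabilities under the fit.

    Returns one row per child with p1, p2, the four cells, theta and tau.
    The Frechet-Hoeffding bounds hold row-wise by construction of the cell
    probabilities.
    """
    frame = frame or fit.frame
    missing = set(frame.region) - set(fit.frame.graph.nodes())
    if missing:
        raise ValueError(f"regions absent from fit: {sorted(missing)}")
    eta1, eta2, theta = _etas(fit, frame, reference)
    p1 = fit.link_stunt.h(eta1)
    p2 = fit.link_waste.h(eta2)
    if fit.theta_active:
        spec = CopulaSpec(fit.copula.family, fit.copula.rotation, np.nan)
        object.__setattr__(spec, "theta", theta)
    else:
        spec = CopulaSpec("independence", 0, 0.0)
    cells = cell_probs(p1, p2, spec)
    fam = fit.copula.family
    if fit.theta_active:
        tau = np.array([
            tau_from_theta(CopulaSpec(fam, fit.copula.rotation, t))
            for t in np.atleast_1d(theta)
        ]) if fam in ("frank", "joe") else _tau_closed(fam, fit.copula.rotation, theta)
    else:
        tau = np.zeros(frame.n)
    return pd.DataFrame({
        "region_id": frame.region,
        "weight": frame.weights,
        "p1": p1, "p2": p2,
        "p00": cells.p00, "p01": cells.p01,
        "p10": cells.p10, "p11": cells.p11,
        "theta": np.broadcast_to(theta, p1.shape),
        "tau": np.broadcast_to(tau, p1.shape),
    })


def _tau_closed(family: str, rotation: int, theta):
    theta = np.asarray(theta, dtype=float)
    if family == "gumbel":
        tau = 1.0 - 1.0 / theta
    elif family == "clayton":
        tau = theta / (theta + 2.0)
    elif family == "gaussian":
        tau = (2.0 / np.pi) * np.arcsin(theta)
    else:
        raise ValueError(family)
    if rotation in (90, 270):
        tau = -tau
    return tau


def region_surface(fit: FitResult, frame: ModelFrame | None = None,
                   reference: bool = False) -> pd.DataFrame:
    """Within-region weighted averages of the predicted joint surface.

    One row per region of the adjacency graph with the averaged marginal
    probabilities, the four averaged joint cells (summing to one), the
    region-level copula parameter and Kendall's tau (from eta3 at the
    region's spatial level), and the structured MRF effects per margin with
    pointwise standard errors.  Regions without observations are emitted
    with n = 0 and missing means.
    """
    frame = frame or fit.frame
    cells = predict_cells(fit, frame, reference=reference)
    eff = structured_effect_table(fit)
    rows = []
    for region in sorted(fit.frame.graph.nodes()):
        m = cells["region_id"] == region
        if not m.any():
            row = {"region_id": region, "n": 0, "w_sum": 0.0,
                   "p1": np.nan, "p2": np.nan, "p00": np.nan, "p01": np.nan,
                   "p10": np.nan, "p11": np.nan, "theta": np.nan,
                   "tau": np.nan}
        else:
            sub = cells.loc[m]
            w = sub["weight"].to_numpy()
            avg = {c: float(np.average(sub[c], weights=w))
                   for c in ("p1", "p2", "p00", "p01", "p10", "p11")}
            # dependence at the region's spatial level: weighted mean of
            # eta3-driven theta within the region (constant when the
            # dependence model is region-level)
            theta_r = float(np.average(sub["theta"], weights=w))
            if fit.theta_active:
                tau_r = tau_from_theta(
                    CopulaSpec(fit.copula.family, fit.copula.rotation, theta_r))
            else:
                tau_r = 0.0
            row = {"region_id": region, "n": int(m.sum()),
                   "w_sum": float(w.sum()), **avg,
                   "theta": theta_r, "tau": tau_r}
        rows.append(row)
    out = pd.DataFrame(rows)
    if eff is not None:
        out = out.merge(eff, on="region_id", how="left")
    return out


def structured_effect_table(fit: FitResult) -> pd.DataFrame | None:
    """Centered MRF effect per region per margin with pointwise SEs.

    Effects are mapped back from the constrained parameterization
    (beta = Z gamma, so they sum to zero across regions); SEs come from the
    model-based covariance as sqrt(diag(Z V_gamma Z')).
    """
    cols = {}
    for margin, key in (("stunting", "mrf_stunt"), ("wasting", "mrf_waste")):
        blk = next((b for b in fit.blocks
                    if b.predictor == margin and b.label.endswith("mrf(region)")),
                   None)
        if blk is None:
            continue
        pred = fit.frame.stunt if margin == "stunting" else fit.frame.waste
        term = pred.smooths["mrf(region)"]
        Z = term.transform
        gamma = fit.delta[blk.sl]
        Vg = fit.V[blk.sl, blk.sl]
        beta = Z @ gamma
        se = np.sqrt(np.maximum(np.diag(Z @ Vg @ Z.T), 0.0))
        cols[key] = pd.Series(beta, index=term.levels)
        cols["se_" + key] = pd.Series(se, index=term.levels)
    if not cols:
        return None
    out = pd.DataFrame(cols)
    out.index.name = "region_id"
    return out.reset_index()
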