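"""Penalized design blocks for geoadditive linear predictors.

Each marginal predictor of the joint model is built from four effect types:
parametric fixed effects, smooth nonlinear effects of continuous covariates
(low-rank thin-plate regression splines), region-level i.i.d. deviations
(ridge penalty, the "unstructured" spatial effect), and region-level Markov
random field effects penalized by the adjacency-graph Laplacian (the
"structured" spatial effect, shrinking neighbouring regions toward each
other).

Every smooth block carries a symmetric positive semi-definite penalty matrix
and has its sum-to-zero identifiability constraint absorbed by an orthonormal
reparameterization, so the model intercept stays free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class SmoothTerm:
    """A penalized column block of a design matrix.

    ``columns`` is the n x q constrained basis, ``penalty`` its q x q PSD
    penalty.  ``transform`` maps constrained coefficients back to the
    interpretable parameterization (per-region effects for mrf/iid, basis
    coefficients for splines); ``levels`` labels the rows of that map.
    ``predict`` rebuilds basis columns for new covariate values.
    """

    label: str
    kind: str  # {"tprs", "mrf", "iid"}
    columns: np.ndarray
    penalty: np.ndarray
    transform: np.ndarray | None = None
    levels: list = field(default_factory=list)
    null_dim: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.columns.shape[1]


def _sum_to_zero_basis(m: int) -> np.ndarray:
    """Orthonormal basis Z (m x (m-1)) of the null space of the 1' constraint.

    Coefficients beta = Z @ gamma automatically satisfy sum(beta) = 0.
    """
    c = np.ones((m, 1))
    q, _ = np.linalg.qr(np.hstack([c, np.eye(m)[:, : m - 1]]))
    z = q[:, 1:]
    # sign convention: make the map deterministic
    for j in range(z.shape[1]):
        if z[np.argmax(np.abs(z[:, j])), j] < 0:
            z[:, j] = -z[:, j]
    return z


# ---------------------------------------------------------------------------
# thin-plate regression spline
# ---------------------------------------------------------------------------

def _crs_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline design in the value-at-knot parameterization.

    Row i gives f(x_i) as a linear combination of the function values at the
    knots, using the natural ("second derivative zero at the ends")
    interpolant.  Values outside the knot range are extrapolated linearly,
    matching the natural spline's behaviour.
    """
    x = np.asarray(x, dtype=float)
    k = knots.size
    h = np.diff(knots)
    # F maps knot values beta to interior second derivatives m (natural ends)
    Bm = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        Bm[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            Bm[i, i + 1] = h[i + 1] / 6.0
            Bm[i + 1, i] = h[i + 1] / 6.0
    F = np.zeros((k, k))
    F[1:-1, :] = np.linalg.solve(Bm, D)

    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    lo = knots[j]
    hi = knots[j + 1]
    am = (hi - xc) / hj
    ap = (xc - lo) / hj
    cm = ((hi - xc) ** 3 / hj - hj * (hi - xc)) / 6.0
    cp = ((xc - lo) ** 3 / hj - hj * (xc - lo)) / 6.0
    n = x.size
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j, :] + cp[:, None] * F[j + 1, :]
    # linear extrapolation beyond the ends (natural spline slope)
    below = x < knots[0]
    above = x > knots[-1]
    if below.any() or above.any():
        d = 1e-6 * (knots[-1] - knots[0])
        for mask, edge, sgn in ((below, knots[0], 1.0), (above, knots[-1], -1.0)):
            if mask.any():
                Xe = _crs_design(np.array([edge, edge + sgn * d]), knots)
                slope = (Xe[1] - Xe[0]) / (sgn * d)
                X[mask] = Xe[0] + (x[mask] - edge)[:, None] * slope
    return X


def _crs_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second derivative penalty, S = D' B^-1 D (PSD)."""
    k = knots.size
    h = np.diff(knots)
    Bm = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        Bm[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            Bm[i, i + 1] = h[i + 1] / 6.0
            Bm[i + 1, i] = h[i + 1] / 6.0
    S = D.T @ np.linalg.solve(Bm, D)
    return 0.5 * (S + S.T)


def spline_term(x: np.ndarray, k: int = 10, label: str = "s(x)") -> SmoothTerm:
    """Penalized regression spline block for one continuous covariate.

    A rank-k natural cubic regression spline on quantile knots with the exact
    integrated-squared-second-derivative penalty — the same contract as a
    thin-plate regression spline at this rank: the penalty is symmetric PSD
    with a two-dimensional null space (constant + linear) before the
    identifiability constraint, so a line is reproduced exactly in the
    lambda -> infinity limit.  The sum-to-zero constraint is absorbed by the
    orthonormal reparameterization ``Z`` of the null space of the observed
    column-sum functional, leaving k-1 columns; per-knot function values are
    recovered as Z @ gamma.
    """
    x = np.asarray(x, dtype=float)
    ux = np.unique(x)
    if k < 3:
        raise ValueError("spline basis needs k >= 3")
    if ux.size < k:
        raise ValueError(
            f"{label}: only {ux.size} distinct values; reduce k below {k}"
        )
    knots = np.unique(np.quantile(ux, np.linspace(0.0, 1.0, k)))
    if knots.size < k:  # heavily tied covariate; fall back to spread knots
        knots = np.linspace(ux[0], ux[-1], k)
    X = _crs_design(x, knots)
    S = _crs_penalty(knots)
    # absorb the sum-to-zero constraint sum_i f(x_i) = 0: beta = Z gamma with
    # Z an orthonormal basis of null(colsum(X))
    c = X.sum(axis=0)
    c = c / np.linalg.norm(c)
    Q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)[:, : k - 1]]))
    Z = Q[:, 1:]
    for j in range(Z.shape[1]):
        if Z[np.argmax(np.abs(Z[:, j])), j] < 0:
            Z[:, j] = -Z[:, j]
    cols = X @ Z
    Sz = Z.T @ S @ Z
    Sz = 0.5 * (Sz + Sz.T)
    s_norm = np.linalg.norm(Sz, ord=2)
    if s_norm > 0:
        Sz = Sz / s_norm
    return SmoothTerm(
        label=label,
        kind="tprs",
        columns=cols,
        penalty=Sz,
        transform=Z,
        levels=list(knots),
        null_dim=1,
        meta={"knots": knots, "Z": Z, "k": k, "penalty_scale": s_norm},
    )


def spline_predict(term: SmoothTerm, x_new: np.ndarray) -> np.ndarray:
    """Evaluate a fitted spline block's constrained basis at new values."""
    X = _crs_design(np.asarray(x_new, dtype=float), term.meta["knots"])
    return X @ term.meta["Z"]


# ---------------------------------------------------------------------------
# regional effects
# ---------------------------------------------------------------------------

def region_indicators(region_index: np.ndarray, levels: list) -> np.ndarray:
    lookup = {r: i for i, r in enumerate(levels)}
    idx = np.array([lookup[r] for r in region_index])
    X = np.zeros((len(region_index), len(levels)))
    X[np.arange(len(region_index)), idx] = 1.0
    return X


def graph_laplacian(graph: nx.Graph, levels: list) -> np.ndarray:
    """Adjacency-graph Laplacian (degree on diagonal, -1 between neighbours)."""
    L = np.asarray(
        nx.laplacian_matrix(graph, nodelist=levels).todense(), dtype=float
    )
    return L


def mrf_term(region_index: np.ndarray, graph: nx.Graph,
             label: str = "mrf(region)") -> SmoothTerm:
    """Markov random field smoother over the region adjacency graph.

    One indicator column per region with the graph Laplacian as penalty, so
    the quadratic form sums squared differences between adjacent regions'
    effects.  The sum-to-zero constraint is absorbed by the orthonormal
    reparameterization Z; per-region effects are recovered as Z @ gamma.
    Disconnected graphs are allowed — the penalty is rank
    (#regions - #components), an improper prior on the extra null directions.
    """
    levels = sorted(graph.nodes())
    missing = set(region_index) - set(levels)
    if missing:
        raise ValueError(f"regions not in adjacency graph: {sorted(missing)}")
    if any(graph.has_edge(r, r) for r in levels):
        raise ValueError("region graph must not contain self-loops")
    ncomp = nx.number_connected_components(graph)
    if ncomp > 1:
        import warnings

        warnings.warn(
            f"region graph has {ncomp} connected components; MRF penalty is "
            "rank deficient beyond the absorbed constraint",
            stacklevel=2,
        )
    X = region_indicators(region_index, levels)
    L = graph_laplacian(graph, levels)
    Z = _sum_to_zero_basis(len(levels))
    cols = X @ Z
    S = Z.T @ L @ Z
    S = 0.5 * (S + S.T)
    s_norm = np.linalg.norm(S, ord=2)
    S = S / s_norm
    observed = set(region_index)
    empty = [r for r in levels if r not in observed]
    return SmoothTerm(
        label=label,
        kind="mrf",
        columns=cols,
        penalty=S,
        transform=Z,
        levels=levels,
        null_dim=ncomp - 1,
        meta={"laplacian": L, "empty_regions": empty, "penalty_scale": s_norm},
    )


def iid_term(region_index: np.ndarray, levels: list | None = None,
             label: str = "iid(region)") -> SmoothTerm:
    """Unstructured (i.i.d.) region deviations as a ridge-penalized block.

    Indicator columns with an identity penalty — the classical random
    intercept represented as a penalized fixed effect; lambda -> infinity
    shrinks every deviation to zero.  Sum-to-zero absorbed as in
    :func:`mrf_term`.
    """
    if levels is None:
        levels = sorted(set(region_index))
    if len(levels) < 2:
        raise ValueError("iid region term needs at least 2 regions")
    X = region_indicators(region_index, levels)
    Z = _sum_to_zero_basis(len(levels))
    cols = X @ Z
    S = Z.T @ Z  # identity because Z is orthonormal
    S = 0.5 * (S + S.T)
    return SmoothTerm(
        label=label,
        kind="iid",
        columns=cols,
        penalty=S,
        transform=Z,
        levels=list(levels),
        null_dim=0,
    )
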