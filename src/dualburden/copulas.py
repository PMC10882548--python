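"""Bivariate copula families for binary-outcome joint models.

A copula C(u, v; theta) couples two marginal probabilities into a joint
distribution.  For a pair of binary outcomes with marginal success
probabilities p1 and p2, the four joint cell probabilities are

    P11 = C(p1, p2; theta)        P10 = p1 - P11
    P01 = p2 - P11                P00 = 1 - p1 - p2 + P11

so only CDF evaluations (never densities) are needed.  The module provides
the CDFs, their partial derivatives with respect to (u, v, theta) — used by
the analytic likelihood gradient — 90/180/270-degree rotations (180 degrees
is the "survival" copula), Kendall's-tau conversions, and the unconstrained
link between a linear predictor and the dependence parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate
from scipy.stats import norm

FAMILIES = ("independence", "gaussian", "clayton", "frank", "gumbel", "joe")
ROTATIONS = (0, 90, 180, 270)

#: rotation-asymmetric families for which the four rotations differ
ASYMMETRIC = ("clayton", "gumbel", "joe")

_EPS = 1e-12
_EXP_CAP = 20.0  # cap on exp() arguments in the theta link


class CopulaDomainError(ValueError):
    """Dependence parameter outside the family's admissible range."""


@dataclass(frozen=True)
class CopulaSpec:
    """A copula family with rotation and dependence parameter.

    ``rotation=180`` of the Gumbel family is the survival Gumbel copula.
    ``theta`` lives on the family's natural scale (Gumbel/Joe: theta >= 1,
    Clayton: theta > 0, Gaussian: |rho| < 1, Frank: theta != 0).
    """

    family: str
    rotation: int = 0
    theta: float = np.nan

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}")
        if self.rotation not in ROTATIONS:
            raise ValueError(f"rotation must be one of {ROTATIONS}")
        if self.family not in ASYMMETRIC and self.rotation not in (0, 180):
            # symmetric families are invariant under 90/270 paired with sign
            # flips; restrict to the canonical forms to avoid silent aliasing
            if self.family != "independence":
                raise ValueError(
                    f"{self.family} copula admits only rotations 0/180"
                )

    def with_theta(self, theta: float) -> "CopulaSpec":
        return replace(self, theta=float(theta))

    @property
    def label(self) -> str:
        if self.family == "independence":
            return "independence"
        if self.rotation == 0:
            return self.family
        if self.rotation == 180:
            return f"survival {self.family}"
        return f"{self.family} {self.rotation}deg"


def check_theta(family: str, theta) -> None:
    """Raise :class:`CopulaDomainError` if theta is outside the family domain."""
    th = np.asarray(theta, dtype=float)
    if family == "independence":
        return
    bad = {
        "gaussian": lambda t: (np.abs(t) >= 1.0),
        "clayton": lambda t: (t <= 0.0),
        "frank": lambda t: (t == 0.0),
        "gumbel": lambda t: (t < 1.0),
        "joe": lambda t: (t < 1.0),
    }[family]
    if np.any(bad(th)) or not np.all(np.isfinite(th)):
        bounds = {
            "gaussian": "|rho| < 1",
            "clayton": "theta > 0",
            "frank": "theta != 0",
            "gumbel": "theta >= 1",
            "joe": "theta >= 1",
        }[family]
        raise CopulaDomainError(
            f"{family} copula requires {bounds}; got theta={theta!r}"
        )


# ---------------------------------------------------------------------------
# base-family CDFs and partials (rotation 0)
# ---------------------------------------------------------------------------

def _clip01(x):
    return np.clip(np.asarray(x, dtype=float), _EPS, 1.0 - _EPS)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bvn_cdf(x, y, rho):
    """Standard bivariate normal CDF via the single-integral (arcsin) form.

    Phi2(x, y; rho) = Phi(x)Phi(y)
        + 1/(2 pi) * int_0^{arcsin rho} exp(-(x^2 + y^2 - 2 x y sin t)
                                            / (2 cos^2 t)) dt

    Vectorized with fixed 48-point Gauss-Legendre quadrature; the integrand
    is analytic on the interval so the rule converges to ~1e-13.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.asarray(np.arcsin(rho), dtype=float)
    # map nodes from [-1, 1] to [0, a]; broadcasts over per-row rho
    t = 0.5 * a[..., None] * (_GL_NODES + 1.0)
    w = 0.5 * a[..., None] * _GL_WEIGHTS
    sin_t = np.sin(t)
    cos2_t = np.cos(t) ** 2
    xx = x[..., None]
    yy = y[..., None]
    integrand = np.exp(-(xx**2 + yy**2 - 2.0 * xx * yy * sin_t) / (2.0 * cos2_t))
    return norm.cdf(x) * norm.cdf(y) + (integrand * w).sum(axis=-1) / (2.0 * np.pi)


def _bvn_pdf(x, y, rho):
    s = 1.0 - rho**2
    z = (x**2 - 2.0 * rho * x * y + y**2) / s
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(s))


def _base_partials(u, v, family: str, theta):
    """Return (C, dC/du, dC/dv, dC/dtheta) for an unrotated family."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _base_partials_raw(u, v, family, theta)


def _base_partials_raw(u, v, family: str, theta):
    u = _clip01(u)
    v = _clip01(v)
    th = np.asarray(theta, dtype=float)

    if family == "independence":
        C = u * v
        return C, v.copy() * np.ones_like(C), u.copy() * np.ones_like(C), np.zeros_like(C)

    if family == "gaussian":
        x = norm.ppf(u)
        y = norm.ppf(v)
        s = np.sqrt(1.0 - th**2)
        C = _bvn_cdf(x, y, th)
        dCdu = norm.cdf((y - th * x) / s)
        dCdv = norm.cdf((x - th * y) / s)
        dCdth = _bvn_pdf(x, y, th)
        return C, dCdu, dCdv, dCdth

    if family == "clayton":
        lu = np.log(u)
        lv = np.log(v)
        a = np.exp(-th * lu)  # u^-theta
        b = np.exp(-th * lv)
        S = a + b - 1.0
        C = S ** (-1.0 / th)
        dCdu = S ** (-1.0 / th - 1.0) * a / u
        dCdv = S ** (-1.0 / th - 1.0) * b / v
        dS = -(a * lu + b * lv)
        dCdth = C * (np.log(S) / th**2 - dS / (th * S))
        return C, dCdu, dCdv, dCdth

    if family == "frank":
        e1 = np.expm1(-th)           # e^-theta - 1
        eu = np.expm1(-th * u)
        ev = np.expm1(-th * v)
        A = 1.0 + eu * ev / e1
        C = -np.log(A) / th
        dCdu = np.exp(-th * u) * ev / (A * e1)
        dCdv = np.exp(-th * v) * eu / (A * e1)
        d_eu = -u * (eu + 1.0)
        d_ev = -v * (ev + 1.0)
        d_e1 = -(e1 + 1.0)
        dA = (d_eu * ev + eu * d_ev) / e1 - eu * ev * d_e1 / e1**2
        dCdth = np.log(A) / th**2 - dA / (th * A)
        return C, dCdu, dCdv, dCdth

    if family == "gumbel":
        x = -np.log(u)
        y = -np.log(v)
        xt = x**th
        yt = y**th
        A = xt + yt
        A1t = A ** (1.0 / th)
        C = np.exp(-A1t)
        dCdu = C * A ** (1.0 / th - 1.0) * x ** (th - 1.0) / u
        dCdv = C * A ** (1.0 / th - 1.0) * y ** (th - 1.0) / v
        dA1t = A1t * (-np.log(A) / th**2 + (xt * np.log(x) + yt * np.log(y)) / (th * A))
        dCdth = -C * dA1t
        return C, dCdu, dCdv, dCdth

    if family == "joe":
        a = (1.0 - u) ** th
        b = (1.0 - v) ** th
        M = a + b - a * b
        M1t = M ** (1.0 / th)
        C = 1.0 - M1t
        dCdu = M ** (1.0 / th - 1.0) * (1.0 - u) ** (th - 1.0) * (1.0 - b)
        dCdv = M ** (1.0 / th - 1.0) * (1.0 - v) ** (th - 1.0) * (1.0 - a)
        da = a * np.log(1.0 - u)
        db = b * np.log(1.0 - v)
        dM = da * (1.0 - b) + db * (1.0 - a)
        dM1t = M1t * (-np.log(M) / th**2 + dM / (th * M))
        dCdth = -dM1t
        return C, dCdu, dCdv, dCdth

    raise ValueError(f"unknown family {family!r}")


def copula_partials(u, v, spec: CopulaSpec):
    """CDF and partials of the (possibly rotated) copula.

    Returns ``(C, dC/du, dC/dv, dC/dtheta)`` as arrays broadcast over the
    inputs.  Rotations are handled by the chain rule on the identities

        C90(u, v)  = v - C(1-u, v)
        C180(u, v) = u + v - 1 + C(1-u, 1-v)
        C270(u, v) = u - C(u, 1-v)
    """
    check_theta(spec.family, spec.theta)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    r = spec.rotation if spec.family != "independence" else 0
    if r == 0:
        return _base_partials(u, v, spec.family, spec.theta)
    if r == 180:
        C0, du0, dv0, dt0 = _base_partials(1.0 - u, 1.0 - v, spec.family, spec.theta)
        C = u + v - 1.0 + C0
        return C, 1.0 - du0, 1.0 - dv0, dt0
    if r == 90:
        C0, du0, dv0, dt0 = _base_partials(1.0 - u, v, spec.family, spec.theta)
        return v - C0, du0, 1.0 - dv0, -dt0
    # r == 270
    C0, du0, dv0, dt0 = _base_partials(u, 1.0 - v, spec.family, spec.theta)
    return u - C0, 1.0 - du0, dv0, -dt0


def copula_cdf(u, v, spec: CopulaSpec):
    """Evaluate C(u, v; theta) honoring the rotation.

    Exact boundary behaviour (C(u, 1) = u, C(0, v) = 0, ...) is enforced
    rather than left to the clipped interior evaluation.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1) | (v < 0) | (v > 1)):
        raise ValueError("copula arguments must lie in [0, 1]")
    C = copula_partials(u, v, spec)[0]
    C = np.minimum(np.minimum(C, u), v)          # Frechet upper bound
    C = np.maximum(C, np.maximum(u + v - 1.0, 0.0))  # Frechet lower bound
    C = np.where(u == 0.0, 0.0, C)
    C = np.where(v == 0.0, 0.0, C)
    C = np.where(u == 1.0, v, C)
    C = np.where(v == 1.0, u, C)
    if C.ndim == 0:
        return float(C)
    return C


# ---------------------------------------------------------------------------
# joint cell probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellProbs:
    """The four joint probabilities of a bivariate binary outcome."""

    p00: np.ndarray
    p01: np.ndarray
    p10: np.ndarray
    p11: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.p00, self.p01, self.p10, self.p11], axis=-1)


def cell_probs(p1, p2, spec: CopulaSpec, *, clip: float = _EPS) -> CellProbs:
    """Joint cell probabilities for marginal probabilities ``p1``, ``p2``.

    ``p11 = C(p1, p2)`` and the remaining cells follow by additivity.  A cell
    more negative than -1e-8 before clipping signals a non-copula evaluation
    and raises; smaller negativity (floating point) is clipped to ``clip``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p11 = np.asarray(copula_cdf(p1, p2, spec), dtype=float)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    cells = np.stack([p00, p01, p10, p11])
    if np.any(cells < -1e-8):
        worst = float(cells.min())
        raise FloatingPointError(
            f"cell probability {worst:.3e} < -1e-8: non-copula evaluation "
            f"for {spec.label} theta={spec.theta}"
        )
    p00, p01, p10, p11 = (np.clip(c, clip, 1.0) for c in cells)
    return CellProbs(p00=p00, p01=p01, p10=p10, p11=p11)


# ---------------------------------------------------------------------------
# Kendall's tau
# ---------------------------------------------------------------------------

def _debye1(x: float) -> float:
    """Order-1 Debye function D1(x) = (1/x) int_0^x t/(e^t - 1) dt."""
    if x == 0.0:
        return 1.0
    val, _ = integrate.quad(lambda t: t / np.expm1(t), 0.0, abs(x))
    d1 = val / abs(x)
    if x < 0:
        d1 = d1 + abs(x) / 2.0
    return d1


def _joe_tau(theta: float) -> float:
    # Archimedean identity tau = 1 + 4 int_0^1 phi(t)/phi'(t) dt with the
    # Joe generator phi(t) = -log(1 - (1-t)^theta)
    def lam(t):
        q = (1.0 - t) ** theta
        q = np.clip(q, 1e-300, 1 - 1e-16)
        return np.log1p(-q) * (1.0 - q) / (theta * (1.0 - t) ** (theta - 1.0))

    val, _ = integrate.quad(lam, 0.0, 1.0, points=[0.0, 1.0], limit=200)
    return 1.0 + 4.0 * val


def tau_from_theta(spec: CopulaSpec) -> float:
    """Kendall's tau implied by the copula parameter.

    Closed forms: Gumbel tau = 1 - 1/theta, Clayton theta/(theta+2),
    Gaussian (2/pi) arcsin(rho), Frank 1 - (4/theta)(1 - D1(theta)); the Joe
    tau is computed by the Archimedean generator integral.  Rotations 90/270
    flip the sign; 180 (survival) preserves it.
    """
    check_theta(spec.family, spec.theta)
    th = float(spec.theta) if spec.family != "independence" else 0.0
    fam = spec.family
    if fam == "independence":
        tau = 0.0
    elif fam == "gumbel":
        tau = 1.0 - 1.0 / th
    elif fam == "clayton":
        tau = th / (th + 2.0)
    elif fam == "gaussian":
        tau = (2.0 / np.pi) * np.arcsin(th)
    elif fam == "frank":
        tau = 1.0 - (4.0 / th) * (1.0 - _debye1(th))
    else:  # joe
        tau = _joe_tau(th)
    if spec.rotation in (90, 270) and fam in ASYMMETRIC:
        tau = -tau
    return float(tau)


# ---------------------------------------------------------------------------
# dependence-parameter link
# ---------------------------------------------------------------------------

def theta_from_eta(eta, family: str):
    """Map an unconstrained predictor eta3 onto the family's theta domain.

    Gumbel/Joe: theta = 1 + exp(eta); Clayton: exp(eta); Gaussian:
    rho = tanh(eta); Frank: theta = eta (identity).  The exp argument is
    capped at 20 to guard overflow.
    """
    eta = np.asarray(eta, dtype=float)
    if family == "independence":
        return np.zeros_like(eta)
    if family in ("gumbel", "joe"):
        return 1.0 + np.exp(np.minimum(eta, _EXP_CAP))
    if family == "clayton":
        return np.exp(np.minimum(eta, _EXP_CAP))
    if family == "gaussian":
        return np.tanh(eta)
    if family == "frank":
        return eta + 0.0
    raise ValueError(f"unknown family {family!r}")


def eta_from_theta(theta, family: str):
    """Inverse of :func:`theta_from_eta` (undefined for independence)."""
    theta = np.asarray(theta, dtype=float)
    if family in ("gumbel", "joe"):
        return np.log(theta - 1.0)
    if family == "clayton":
        return np.log(theta)
    if family == "gaussian":
        return np.arctanh(theta)
    if family == "frank":
        return theta + 0.0
    raise ValueError(f"no eta link for family {family!r}")


def dtheta_deta(eta, family: str):
    """Derivative of :func:`theta_from_eta` with respect to eta."""
    eta = np.asarray(eta, dtype=float)
    if family == "independence":
        return np.zeros_like(eta)
    if family in ("gumbel", "joe", "clayton"):
        return np.exp(np.minimum(eta, _EXP_CAP)) * (eta <= _EXP_CAP)
    if family == "gaussian":
        return 1.0 / np.cosh(eta) ** 2
    if family == "frank":
        return np.ones_like(eta)
    raise ValueError(f"unknown family {family!r}")


def theta_from_tau(tau: float, family: str, rotation: int = 0) -> float:
    """Invert Kendall's tau to the family's theta (numeric for Frank/Joe)."""
    if rotation in (90, 270):
        tau = -tau
    if family == "independence":
        return 0.0
    if family == "gumbel":
        return 1.0 / (1.0 - tau)
    if family == "clayton":
        return 2.0 * tau / (1.0 - tau)
    if family == "gaussian":
        return float(np.sin(np.pi * tau / 2.0))
    from scipy.optimize import brentq

    if family == "frank":
        return float(brentq(
            lambda t: tau_from_theta(CopulaSpec("frank", 0, t)) - tau, 1e-6, 50.0
        ))
    if family == "joe":
        return float(brentq(
            lambda t: tau_from_theta(CopulaSpec("joe", 0, t)) - tau, 1.0 + 1e-9, 50.0
        ))
    raise ValueError(f"unknown family {family!r}")
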