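"""Copula families: CDF identities, derivatives, tau conversions, links."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import kendalltau

from dualburden.copulas import (
    ASYMMETRIC,
    CopulaDomainError,
    CopulaSpec,
    cell_probs,
    copula_cdf,
    copula_partials,
    dtheta_deta,
    eta_from_theta,
    tau_from_theta,
    theta_from_eta,
    theta_from_tau,
)
from dualburden.simulate import sample_gumbel_pair

#: one representative admissible theta per family
THETAS = {"gaussian": 0.5, "clayton": 1.5, "frank": 3.0, "gumbel": 2.0,
          "joe": 2.5}


def spec_grid():
    specs = [CopulaSpec("independence", 0, 0.0)]
    for fam, th in THETAS.items():
        rots = (0, 90, 180, 270) if fam in ASYMMETRIC else (0, 180)
        for r in rots:
            specs.append(CopulaSpec(fam, r, th))
    return specs


@pytest.mark.parametrize("spec", spec_grid(), ids=lambda s: s.label)
def test_boundary_conditions(spec):
    """C(u,1)=u, C(1,v)=v, C(u,0)=C(0,v)=0 for every family and rotation."""
    u = np.linspace(0.0, 1.0, 11)
    assert np.allclose(copula_cdf(u, np.ones_like(u), spec), u, atol=1e-10)
    assert np.allclose(copula_cdf(np.ones_like(u), u, spec), u, atol=1e-10)
    assert np.allclose(copula_cdf(u, np.zeros_like(u), spec), 0.0, atol=1e-10)
    assert np.allclose(copula_cdf(np.zeros_like(u), u, spec), 0.0, atol=1e-10)


def test_theta_one_is_independence():
    spec = CopulaSpec("gumbel", 0, 1.0)
    assert copula_cdf(0.5, 0.5, spec) == pytest.approx(0.25, abs=1e-12)
    u, v = np.meshgrid(np.linspace(0.05, 0.95, 7), np.linspace(0.05, 0.95, 7))
    assert np.allclose(copula_cdf(u, v, spec), u * v, atol=1e-10)


def test_gumbel_theta2_closed_form():
    # C(.5,.5;2) = exp(-sqrt(2) log 2), direct evaluation of the generator
    expected = np.exp(-np.sqrt(2.0) * np.log(2.0))
    got = copula_cdf(0.5, 0.5, CopulaSpec("gumbel", 0, 2.0))
    assert got == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("spec", spec_grid(), ids=lambda s: s.label)
def test_two_increasing_on_random_rectangles(spec, rng):
    """C-volume of every rectangle is nonnegative (2-increasing property)."""
    for _ in range(200):
        u1, u2 = np.sort(rng.uniform(0, 1, 2))
        v1, v2 = np.sort(rng.uniform(0, 1, 2))
        vol = (copula_cdf(u2, v2, spec) - copula_cdf(u2, v1, spec)
               - copula_cdf(u1, v2, spec) + copula_cdf(u1, v1, spec))
        assert vol >= -1e-12


@pytest.mark.parametrize("family", sorted(THETAS))
def test_rotation_involution(family, rng):
    """Applying the 180-degree (survival) rotation twice recovers the base."""
    th = THETAS[family]
    u = rng.uniform(0.01, 0.99, 50)
    v = rng.uniform(0.01, 0.99, 50)
    base = copula_cdf(u, v, CopulaSpec(family, 0, th))
    # rotating the already-rotated copula: C''(u,v) = u+v-1+C'(1-u,1-v)
    c180_at_flip = copula_cdf(1 - u, 1 - v, CopulaSpec(family, 180, th))
    twice = u + v - 1 + c180_at_flip
    assert np.allclose(twice, base, atol=1e-12)


def test_gumbel_cdf_monotone_in_theta():
    u, v = np.meshgrid(np.linspace(0.1, 0.9, 5), np.linspace(0.1, 0.9, 5))
    prev = None
    for th in [1.0, 1.3, 1.8, 2.5, 4.0, 8.0]:
        c = copula_cdf(u, v, CopulaSpec("gumbel", 0, th))
        if prev is not None:
            assert np.all(c >= prev - 1e-12)
        prev = c


def test_tau_closed_forms():
    assert tau_from_theta(CopulaSpec("gumbel", 0, 1.0)) == pytest.approx(0.0, abs=1e-12)
    assert tau_from_theta(CopulaSpec("gumbel", 0, 2.0)) == pytest.approx(0.5, abs=1e-12)
    assert tau_from_theta(CopulaSpec("gumbel", 180, 2.0)) == pytest.approx(0.5, abs=1e-12)
    assert tau_from_theta(CopulaSpec("gaussian", 0, 0.5)) == pytest.approx(1.0 / 3.0, abs=1e-12)
    assert tau_from_theta(CopulaSpec("clayton", 0, 2.0)) == pytest.approx(0.5, abs=1e-12)
    # 90/270 rotations flip the sign for asymmetric families
    assert tau_from_theta(CopulaSpec("gumbel", 90, 2.0)) == pytest.approx(-0.5, abs=1e-12)


def test_frank_and_joe_tau_against_quadrature():
    """tau = 1 - 4 int (dC/du)(dC/dv) du dv, evaluated independently."""
    for fam, th in [("frank", 3.0), ("joe", 2.5)]:
        spec = CopulaSpec(fam, 0, th)

        def integrand(u, v):
            _, du, dv, _ = copula_partials(np.array(u), np.array(v), spec)
            return float(du * dv)

        val, _ = integrate.dblquad(integrand, 0.001, 0.999, 0.001, 0.999)
        tau_num = 1.0 - 4.0 * val
        assert tau_from_theta(spec) == pytest.approx(tau_num, abs=5e-3)


def test_tau_matches_sampler():
    rng = np.random.default_rng(77)
    for th in [1.25, 2.0]:
        u, v = sample_gumbel_pair(th, 30_000, rng)
        emp = kendalltau(u, v).statistic
        assert emp == pytest.approx(1.0 - 1.0 / th, abs=0.02)


@pytest.mark.parametrize("family", ["gumbel", "joe", "clayton", "gaussian", "frank"])
@pytest.mark.parametrize("x", [-3.0, 0.0, 3.0])
def test_theta_eta_link_roundtrip(family, x):
    th = theta_from_eta(x, family)
    assert eta_from_theta(th, family) == pytest.approx(x, abs=1e-9)


def test_theta_link_values_and_limits():
    assert theta_from_eta(0.0, "gumbel") == pytest.approx(2.0)
    assert float(theta_from_eta(-30.0, "gumbel")) == pytest.approx(1.0, abs=1e-10)
    # link derivative positive and matching finite differences
    for fam in ["gumbel", "clayton", "gaussian", "frank"]:
        for e in [-1.0, 0.3, 2.0]:
            h = 1e-6
            fd = (theta_from_eta(e + h, fam) - theta_from_eta(e - h, fam)) / (2 * h)
            assert float(dtheta_deta(e, fam)) == pytest.approx(float(fd), rel=1e-6)


@pytest.mark.parametrize("spec", spec_grid(), ids=lambda s: s.label)
def test_partials_match_finite_differences(spec, rng):
    if spec.family == "independence":
        return
    u, v = 0.37, 0.62
    C, du, dv, dt = (float(x) for x in copula_partials(u, v, spec))
    h = 1e-6
    fd_u = (copula_partials(u + h, v, spec)[0] - copula_partials(u - h, v, spec)[0]) / (2 * h)
    fd_v = (copula_partials(u, v + h, spec)[0] - copula_partials(u, v - h, spec)[0]) / (2 * h)
    sp = CopulaSpec(spec.family, spec.rotation, spec.theta + h)
    sm = CopulaSpec(spec.family, spec.rotation, spec.theta - h)
    fd_t = (copula_partials(u, v, sp)[0] - copula_partials(u, v, sm)[0]) / (2 * h)
    assert du == pytest.approx(float(fd_u), abs=1e-7)
    assert dv == pytest.approx(float(fd_v), abs=1e-7)
    assert dt == pytest.approx(float(fd_t), abs=1e-7)


def test_cell_probs_independence_example():
    cells = cell_probs(0.3, 0.07, CopulaSpec("independence", 0, 0.0))
    assert float(cells.p00) == pytest.approx(0.651, abs=1e-12)
    assert float(cells.p01) == pytest.approx(0.049, abs=1e-12)
    assert float(cells.p10) == pytest.approx(0.279, abs=1e-12)
    assert float(cells.p11) == pytest.approx(0.021, abs=1e-12)


def test_cell_probs_survival_gumbel_half():
    # rotation identity: p11 = p1 + p2 - 1 + C_G(1-p1, 1-p2; theta)
    cells = cell_probs(0.5, 0.5, CopulaSpec("gumbel", 180, 2.0))
    expected = np.exp(-np.sqrt(2.0) * np.log(2.0))
    assert float(cells.p11) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    p1=st.floats(0.01, 0.99), p2=st.floats(0.01, 0.99),
    th=st.floats(1.0, 8.0),
    fam_rot=st.sampled_from([("gumbel", 0), ("gumbel", 180), ("joe", 180),
                             ("clayton", 0), ("frank", 0), ("gaussian", 0)]),
)
def test_cells_sum_to_one_and_frechet(p1, p2, th, fam_rot):
    fam, rot = fam_rot
    theta = {"gaussian": np.tanh(th - 1), "frank": th, "clayton": th}.get(fam, th)
    if fam == "frank" and theta == 0:
        theta = 0.5
    cells = cell_probs(p1, p2, CopulaSpec(fam, rot, theta))
    total = float(cells.p00 + cells.p01 + cells.p10 + cells.p11)
    assert total == pytest.approx(1.0, abs=1e-9)
    p11 = float(cells.p11)
    assert p11 >= max(0.0, p1 + p2 - 1.0) - 1e-9
    assert p11 <= min(p1, p2) + 1e-9


@pytest.mark.parametrize("family,bad", [
    ("gumbel", 0.5), ("joe", 0.0), ("clayton", -1.0), ("gaussian", 1.5),
    ("frank", 0.0),
])
def test_theta_domain_errors(family, bad):
    with pytest.raises(CopulaDomainError):
        copula_cdf(0.5, 0.5, CopulaSpec(family, 0, bad))


def test_theta_from_tau_inverts_tau():
    for fam in ["gumbel", "clayton", "gaussian", "frank", "joe"]:
        th = theta_from_tau(0.3, fam)
        assert tau_from_theta(CopulaSpec(fam, 0, th)) == pytest.approx(0.3, abs=1e-6)
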