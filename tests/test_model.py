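"""Joint likelihood, penalized fitting, EDF/AIC identities, covariances."""

import numpy as np
import pandas as pd
import pytest

from dualburden.copulas import CopulaSpec
from dualburden.model import (
    FitConfig,
    Link,
    _stack,
    cluster_sandwich,
    fit_model,
    loglik,
)
from dualburden.preprocess import build_model_frame
from dualburden.simulate import GeneratorConfig, generate


def _tiny_frame(graph):
    """Four children covering all outcome cells, trivial design."""
    df = pd.DataFrame({
        "y_stunt": [1, 1, 0, 0], "y_waste": [1, 0, 1, 0],
        "sex": ["male", "female", "male", "female"],
        "region_id": ["R01"] * 4, "weight": [1.0] * 4,
        "cluster_id": ["c1", "c1", "c2", "c2"],
        "stratum_id": ["s"] * 4,
    })
    return build_model_frame(df, [], [], graph, theta_terms=[])


class TestLoglik:
    def test_single_cell_probit_at_zero(self, graph15):
        """y=(1,1) under independence with eta1=eta2=0 gives log(1/4)."""
        frame = _tiny_frame(graph15)
        w = np.zeros(4)
        w[0] = 1.0  # isolate the (1,1) child
        ll, _ = loglik(np.zeros(2), frame, CopulaSpec("independence", 0, 0.0),
                       Link("probit"), Link("probit"), w, False)
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_independence_factorizes(self, small_frame):
        """Under the independence copula the joint log-likelihood is the sum
        of the two univariate Bernoulli log-likelihoods, for any delta."""
        rng = np.random.default_rng(4)
        frame = small_frame
        w = np.ones(frame.n)
        p = frame.stunt.p + frame.waste.p
        for _ in range(5):
            d = rng.normal(0, 0.5, p)
            ll, _ = loglik(d, frame, CopulaSpec("independence", 0, 0.0),
                           Link("probit"), Link("cloglog"), w, False)
            p1 = Link("probit").h(frame.stunt.X @ d[:frame.stunt.p])
            p2 = Link("cloglog").h(frame.waste.X @ d[frame.stunt.p:])
            ll1 = np.sum(np.log(np.where(frame.y1 == 1, p1, 1 - p1)))
            ll2 = np.sum(np.log(np.where(frame.y2 == 1, p2, 1 - p2)))
            assert ll == pytest.approx(ll1 + ll2, rel=1e-10)

    def test_gradient_matches_central_differences(self, graph15):
        cfg = GeneratorConfig(n=50, seed=21)
        df, _ = generate(cfg)
        frame = build_model_frame(df, ["sex"], ["sex"], cfg.graph,
                                  theta_terms=[])
        spec = CopulaSpec("gumbel", 180, 1.0)
        w = frame.weights / frame.weights.mean()
        _, _, _, p = _stack(frame, True)
        rng = np.random.default_rng(9)
        for _ in range(6):
            d = rng.normal(0, 0.4, p)
            _, g = loglik(d, frame, spec, Link("probit"), Link("cloglog"), w, True)
            j = int(rng.integers(0, p))
            h = 1e-6 * (1 + abs(d[j]))
            dp, dm = d.copy(), d.copy()
            dp[j] += h
            dm[j] -= h
            fd = (loglik(dp, frame, spec, Link("probit"), Link("cloglog"), w, True)[0]
                  - loglik(dm, frame, spec, Link("probit"), Link("cloglog"), w, True)[0]
                  ) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFit:
    def test_matches_univariate_glm_at_independence(self, small_frame):
        """With the copula fixed at independence and no penalties, each
        margin's estimates equal the single-equation GLM fit."""
        smapi = pytest.importorskip("statsmodels.api")
        fit = fit_model(small_frame, copula="independence",
                        link_stunt="probit", link_waste="cloglog",
                        config=FitConfig(weights_mode="unweighted"),
                        robust=False)
        g1 = smapi.GLM(small_frame.y1, small_frame.stunt.X,
                       family=smapi.families.Binomial(
                           smapi.families.links.Probit())).fit(tol=1e-12)
        g2 = smapi.GLM(small_frame.y2, small_frame.waste.X,
                       family=smapi.families.Binomial(
                           smapi.families.links.CLogLog())).fit(tol=1e-12)
        assert np.abs(fit.coef("stunting") - g1.params).max() < 1e-6
        assert np.abs(fit.coef("wasting") - g2.params).max() < 1e-6

    def test_unpenalized_edf_equals_coefficient_count(self, small_frame):
        fit = fit_model(small_frame, copula="gumbel", rotation=180,
                        robust=False)
        assert fit.edf_total == pytest.approx(len(fit.delta), abs=1e-6)

    def test_aic_bic_identities(self, small_frame):
        fit = fit_model(small_frame, copula="gumbel", rotation=180,
                        robust=False)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.edf_total,
                                        abs=1e-10)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + np.log(fit.n) * fit.edf_total, abs=1e-10)

    def test_spline_edf_tends_to_null_dim_under_heavy_smoothing(self, graph15):
        cfg = GeneratorConfig(n=800, seed=31)
        df, _ = generate(cfg)
        frame = build_model_frame(df, ["s(age_months)"], ["sex"], cfg.graph,
                                  theta_terms=[])
        fit = fit_model(frame, copula="independence",
                        config=FitConfig(select_lambda=False, lambda_init=1e8),
                        robust=False)
        assert fit.edf_by_term["stunting:s(age_months)"] == pytest.approx(
            1.0, abs=0.05)

    def test_refit_at_selected_lambda_reproduces_coefficients(self, graph15):
        cfg = GeneratorConfig(n=700, seed=32)
        df, _ = generate(cfg)
        frame = build_model_frame(df, ["sex", "s(age_months)"], ["sex"],
                                  cfg.graph, theta_terms=[])
        fit = fit_model(frame, copula="gumbel", rotation=180, robust=False)
        lams = tuple(b.lam for b in fit.blocks)
        refit = fit_model(frame, copula="gumbel", rotation=180,
                          config=FitConfig(select_lambda=False,
                                           lambda_init=lams), robust=False)
        assert np.abs(fit.delta - refit.delta).max() < 1e-8

    def test_degenerate_outcome_rejected(self, graph15):
        df = pd.DataFrame({
            "y_stunt": [1, 1, 1, 1], "y_waste": [1, 0, 1, 0],
            "sex": ["male", "female"] * 2,
            "region_id": ["R01"] * 4, "weight": [1.0] * 4,
            "cluster_id": ["c1", "c2"] * 2, "stratum_id": ["s"] * 4,
        })
        frame = build_model_frame(df, [], [], graph15, theta_terms=[])
        with pytest.raises(ValueError, match="both classes"):
            fit_model(frame, copula="independence")


class TestClusterSandwich:
    def test_equals_classical_sandwich_rowwise_clusters(self, graph15):
        cfg = GeneratorConfig(n=400, seed=41, f_stunt={}, f_waste={},
                              sigma_structured=0.0, sigma_unstructured=0.0)
        df, _ = generate(cfg)
        df["cluster_id"] = [f"row{i}" for i in range(len(df))]
        df["weight"] = 1.0
        frame = build_model_frame(df, ["sex"], ["sex"], cfg.graph,
                                  theta_terms=[])
        fit = fit_model(frame, copula="gumbel", rotation=180,
                        config=FitConfig(weights_mode="unweighted"))
        w = np.ones(frame.n)
        _, _, scores = loglik(fit.delta, frame, fit.copula, fit.link_stunt,
                              fit.link_waste, w, True, return_scores=True)
        classical = fit.V @ (scores.T @ scores) @ fit.V
        assert np.abs(fit.Vr - classical).max() < 1e-10

    def test_duplication_with_halved_weights_keeps_estimates(self, graph15):
        cfg = GeneratorConfig(n=300, seed=42, f_stunt={}, f_waste={},
                              sigma_structured=0.0, sigma_unstructured=0.0)
        df, _ = generate(cfg)
        frame1 = build_model_frame(df, ["sex"], ["sex"], cfg.graph,
                                   theta_terms=[])
        df2 = pd.concat([df, df], ignore_index=True)
        df2["weight"] = df2["weight"] / 2.0
        frame2 = build_model_frame(df2, ["sex"], ["sex"], cfg.graph,
                                   theta_terms=[])
        f1 = fit_model(frame1, copula="gumbel", rotation=180, robust=False)
        f2 = fit_model(frame2, copula="gumbel", rotation=180, robust=False)
        assert np.abs(f1.delta - f2.delta).max() < 1e-6

    def test_single_cluster_rejected(self, graph15):
        df = pd.DataFrame({
            "y_stunt": [1, 1, 0, 0] * 5, "y_waste": [1, 0, 1, 0] * 5,
            "sex": ["male", "female"] * 10,
            "region_id": ["R01"] * 20, "weight": [1.0] * 20,
            "cluster_id": ["c1"] * 20, "stratum_id": ["s"] * 20,
        })
        frame = build_model_frame(df, [], [], graph15, theta_terms=[])
        fit = fit_model(frame, copula="independence", robust=False)
        with pytest.raises(ValueError, match="clusters"):
            cluster_sandwich(fit, frame)
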