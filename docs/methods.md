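# Methods

## Model

Two binary outcomes per child — stunting (HAZ < −2) and wasting
(WHZ < −2) — are modelled jointly.  Each margin has a latent-variable
representation yⱼᵢ = 1{y*ⱼᵢ > 0}, y*ⱼᵢ = ηⱼᵢ + εⱼᵢ, where the error's CDF
fixes the link (standard normal → probit, logistic → logit, Gumbel-type →
complementary log-log).  The joint distribution of the pair is induced by a
copula applied to the two marginal probabilities, so only copula CDF
evaluations are needed (no densities): P₁₁ = C(p₁, p₂; θ) and the other
three cells follow by additivity.  The dependence parameter θ has its own
predictor η₃ mapped onto the family's domain by an unconstrained link
(Gumbel/Joe: θ = 1 + exp(η₃); Clayton: exp(η₃); Gaussian: tanh(η₃); Frank:
identity), and is reported as Kendall's τ.

Each linear predictor combines four effect types:

* parametric fixed effects (treatment coding, reference = first category);
* smooth effects of continuous covariates: rank-k natural cubic regression
  splines on quantile knots with the exact integrated-squared-second-
  derivative penalty.  This carries the same contract as a thin-plate
  regression spline at equal rank — symmetric PSD penalty with a
  two-dimensional null space (constant + linear) — so a straight line
  survives any amount of smoothing;
* structured regional effects: one coefficient per region penalized by the
  adjacency-graph Laplacian (an intrinsic MRF / pairwise-difference prior);
* unstructured regional effects: one coefficient per region with a ridge
  penalty (a random intercept represented as a penalized fixed effect).

Identifiability: every smooth/MRF/iid block has its sum-to-zero constraint
absorbed by an orthonormal reparameterization (QR basis of the constraint's
null space), leaving each predictor a free intercept.  Disconnected
adjacency graphs are accepted; the MRF penalty is then rank
(#regions − #components) and a warning is issued.

### Assumptions

The copula family is the same for all children (only θ varies); regional
dependence of the outcomes beyond the covariates is captured by the two
regional effect types; sampling weights enter as a pseudo-likelihood (the
design is informative only through the weights); clusters are the unit of
dependence for robust variances.

## Estimation

The weighted penalized log-likelihood ℓ(δ) − ½ Σₖ λₖ δ′Sₖδ, with
ℓ(δ) = Σᵢ wᵢ log P_{y₁ᵢy₂ᵢ}(δ), is maximized by L-BFGS followed by Newton
polishing, using a fully analytic gradient (closed-form copula partials
∂C/∂u, ∂C/∂v, ∂C/∂θ for every family and rotation, chained through the
links).  The Hessian is obtained by central differences of the analytic
gradient (step 10⁻⁴·(1+|δⱼ|), symmetrized); it drives the Newton steps, the
effective degrees of freedom EDF = tr{(Ĥ+S_λ)⁻¹Ĥ}, the model covariance
V = (Ĥ+S_λ)⁻¹ and the cluster sandwich V(Σ_c g_c g_c′)V with g_c the
summed per-row weighted scores of cluster c.

Convergence: max|∇| < 10⁻⁶·(1+|ℓ|) during smoothing search, tightened by
10⁻³ in a final polish so a refit at the selected λ̂ reproduces the optimum
to ~10⁻⁸.  Starting values: per-margin penalized IRLS fits at independence;
the dependence intercept starts mildly inside the domain (θ = 1.5 for
Gumbel/Joe).  Estimates with η₃ < −10 are effectively at the independence
boundary of the Gumbel family.

Smoothing parameters are selected by coordinate descent on AIC
(−2ℓ̂ + 2·EDF) over a per-term grid λ ∈ 10^{−3,…,3}, at most two cycles,
warm-starting every refit — a deterministic, reproducible scheme chosen
over faster criteria.  BIC (log n penalty) is reported alongside.

Sampling weights are normalized to mean 1 so AIC/BIC magnitudes stay
comparable across weighting modes; an unweighted mode is available.

## Model selection and tests

The two-step screen fits every candidate copula (family × rotation menu:
independence, Gaussian, Frank, and Clayton/Gumbel/Joe in 0° and survival
forms) with both margins probit, picks the AIC minimizer, then fits the
3×3 grid of marginal links at that copula.  Candidate failures are recorded
and skipped; AIC/BIC disagreements are noted, with AIC deciding.

Smooth and spatial terms are assessed by a Wald chi-square
T = γ̂′V_γ⁻γ̂ on the term's coefficient block, with a rank-r pseudo-inverse,
r = round(per-term EDF) (at least 1), and a χ²_r upper-tail p-value.
Calibration under the null sits near 7% at a nominal 5% over 200
replicates at n=500 — slightly liberal, as expected when the smoothing
parameter is selected on the same data.

**A note on copula-family identifiability.**  With binary outcomes the data
identify the family only through the shape of C(p₁(x), p₂(x)) across the
covariate range.  When one outcome is rare (wasting ≈ 7%), one-parameter
families sharing the same tail-dependence class — survival Gumbel,
survival Joe, Clayton — are empirically near-equivalent: on data generated
under survival Gumbel (τ = 0.4, n = 4000, covariate-rich margins) their
maximized log-likelihoods differ by ~1 unit and the AIC winner among them
is close to a coin flip, while families with the wrong tail behaviour
(Gaussian, Frank, independence) lose consistently.  Selection results at
this prevalence should therefore be read at the level of the
tail-dependence class, not the individual label.

## Survey-weighted descriptives

Weighted prevalence p̂ = Σwᵢyᵢ/Σwᵢ with Taylor-linearized variance: the
between-cluster variance of linearized residuals within strata, with the
with-replacement factor n_h/(n_h−1); a lonely PSU (single-cluster stratum)
is centered at the grand mean of cluster totals.  CIs are symmetric Wald
on the proportion scale, truncated to [0,1].  The 2×2 association test is
Pearson's chi-square with Yates continuity correction by default (the
conventional 2×2 choice), with an uncorrected option.

## Synthetic generator

The generator emulates a two-stage stratified cluster survey of a
15-region country (3×5 grid adjacency by default; any neighbour list can
be supplied).  Defaults, chosen once as a realistic emulation:

* n = 4000 children; baseline prevalences 29% (stunting, probit margin)
  and 7% (wasting, cloglog margin); survival-Gumbel dependence with
  constant τ = 0.2 (θ = 1.25), optionally region-varying;
* age ~ Uniform{0..59} months; maternal HAZ ~ N(−1,1), WHZ ~ N(0,1), age
  at first birth ~ N(22,4²) truncated to [12,45]; categoricals at
  DHS-plausible shares (51% male, 68% ethnic majority, education
  15/40/33/12%, quintiles uniform, 81% male household head, 62% improved
  toilet, 48% on-premise water, 40% treated water);
* stunting age profile 0.6·exp(−((age−30)/15)²) (rise to a peak near 30
  months, then decline), linear maternal-HAZ protection −0.25·z; wasting
  gets a mild declining age trend; fixed effects of ±0.05–0.3 on the
  linear-predictor scale (sex, location, wealth gradient);
* structured regional field drawn from a proper CAR surrogate
  ((L+0.01I)⁻¹ covariance), centered and scaled to σ_s = 0.3; i.i.d.
  regional deviations σ_u = 0.1;
* Gumbel pairs by the Marshall–Olkin construction (positive-stable mixing
  via Chambers–Mallows–Stuck), rotated for the survival form;
* continuous HAZ/WHZ back-filled by truncated normals on the correct side
  of −2 inside [−6,6], so re-classification reproduces the binary outcomes
  exactly; weights ~ Gamma(4, ¼) normalized to mean 1; clusters of 30
  children nested in region, strata = region × urban/rural.

The truth sidecar stores every generating parameter, the realized spatial
fields, and per-region expected joint cells, so recovery is testable
without external data.  What the generator does **not** emulate: real DHS
two-stage PSU selection probabilities, spatial covariate confounding,
missing data patterns (missingness is only exercised synthetically in
tests), and geographic realism of the adjacency.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated model, not robustness to the ways real survey data violate it.

## Numerical choices

Cell probabilities are clipped at 10⁻¹² before logs (cloglog margins can
reach p ≈ 0/1); marginal probabilities at 10⁻¹⁰.  A cell below −10⁻⁸
before clipping raises (a non-copula evaluation).  During optimization,
extreme θ trial points are contained by capping exp arguments at 20,
clamping C into the Fréchet envelope and zeroing non-finite derivatives —
the trial point then scores poorly and the line search retreats.  The
bivariate normal CDF uses the single-integral arcsin form with 48-point
Gauss–Legendre quadrature (~10⁻¹³, vectorized over rows).  Selection ties
break toward the earlier candidate in the documented menu order.  Spline
penalties are spectrally normalized so one λ grid serves all terms.
Region-level runs with ~270 children per region carry binomial noise of
±0.01–0.02 on joint prevalences; region-level estimates should be read
with that floor in mind.

## Scaling of the shipped experiments

The test suite runs simulation studies at sizes chosen for a single CPU:
recovery at the default n = 4000 with 200 coverage replicates at n = 1000;
selection consistency at 50 replicates of n = 4000 with fixed smoothing in
the screen; Wald calibration at 200 replicates of n = 500.  These sizes are
the package's own trade-off between statistical resolution and runtime.

## Known limitations

No REML/efficient smoothing selection (grid AIC only); no Bayesian
variant; copula densities (needed for continuous outcomes) are out of
scope; the Wald term test is mildly liberal after data-driven smoothing;
copula-family labels are weakly identified at rare-outcome prevalences
(see above); the per-region dependence surface inherits the MRF's
smoothing bias when regions truly differ sharply.
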