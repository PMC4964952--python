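# Methods

This note documents the statistical machinery in `cengrm`: the model and
its assumptions, the estimators, the numerical choices, what the synthetic
generator does and does not emulate, and known limitations.

## Censored Weibull regression with a log-mean link

The response model is `y_i ~ Weibull(α, λ_i)` with a shape α shared by all
sites and a covariate-dependent scale.  A shared shape is equivalent to a
shared coefficient of variation — a natural assumption for concentration
data whose spread grows with its level.  The link is placed on the mean,
`log μ_i = x_iᵀβ` with `μ_i = λ_i Γ(1 + 1/α)`, so `exp(β_j)` is a per-unit
multiplicative effect on the mean concentration; λ_i is derived from μ_i
at every likelihood evaluation.  This is numerically identical to the
standard log-scale-link accelerated-failure-time parameterisation: only
the intercept differs, by `log Γ(1 + 1/α̂)` (a unit test verifies both the
identity and agreement with `lifelines.WeibullAFTFitter` on left-censored
data).

Left-censored observations contribute `log F(τ_i)` — the log CDF at their
detection limit — to the independence log-likelihood.  Estimation
maximises over `(β, log α)` with L-BFGS plus damped Newton polishing:

* analytic gradient (per-site score vectors; also reused by the sandwich);
* Hessian by central finite differences of the analytic gradient with a
  relative step of 1e-5, symmetrised;
* starting values: OLS of `log y` (half-DL substitution for nondetects —
  used *only* for initialisation, never inference) and α₀ = 1;
* convergence: relative log-likelihood change < 1e-10 and gradient ∞-norm
  < 1e-6 (a fit ending with ∞-norm in [1e-6, 1e-3] is reported as
  `loose-gradient` rather than failed);
* log-space evaluation of `(t/λ)^α` with caps (e^700 in the likelihood,
  e^350 in the score, where only the direction matters) so extreme
  parameter proposals cannot overflow;
* `fix_alpha` pins the shape, e.g. at 1 for the exponential special case
  whose intercept MLE is `log ȳ` in closed form (tested to 1e-8).

Both percent-change conventions are reported for every effect: the exact
`100·(exp(β)−1)` and the small-coefficient shorthand `100·|β|`, because
applied summaries of such models routinely mix the two.

## Censored descriptive statistics

**ROS** assumes a lognormal body: Helsel–Cohn / Hirsch–Stedinger plotting
positions are computed over the distinct detection limits (censored values
rank below a detect of equal magnitude), log-detects are regressed on
normal scores, nondetects are imputed from the fitted line at their
positions, and moments are taken over the observed+imputed sample.
Preconditions: ≥3 detects and <80% censoring.

**Kaplan–Meier** flips left-censored data to right-censored about
`M = max(values, limits) + 1`, fits the product-limit estimator
(`lifelines`), converts the survival steps back to probability masses on
the original scale, and assigns any unresolved mass beyond the last event
to the smallest observed value (restricted-mean convention).  The variance
is rescaled by `n/(n−1)` so the zero-censoring case reproduces the
`ddof=1` sample standard deviation exactly.

Both reduce to ordinary sample statistics with no censoring; the half-DL
substitution mean is provided only as the biased comparator.

## Design matrix

* Sum-to-zero contrasts for categoricals: K levels → K−1 columns, last
  level (alphabetically) implied with coefficient `−Σβ_k`.  Interactions
  are elementwise products of the contrast columns with the continuous
  covariate, so interaction coefficients are category-specific deviations
  from the overall slope.
* Legendre coordinate polynomials: lon/lat affinely rescaled to [−1, 1]
  over a bounding box recorded in the fit; degree 2 yields 7 columns
  (P1, P2 per axis plus the P1·P1, P1·P2, P2·P1 cross products — the
  degree-≤2-per-axis convention that makes the coordinate block 7 df).
* Fourier seasonality: `cos/sin(2π·d/365)` with day-of-year d; Feb 29
  maps to day 60 and later leap-year days shift down one.
* Continuous covariates enter in native units so coefficients keep their
  per-unit reading; the bounding box and category level sets are frozen
  in the fit object and reused verbatim when scoring validation data.

## Spatial declustering and the variogram

The empirical residual semivariogram `γ(h) = Σ(r_i−r_j)²/2N(h)` (haversine
km bins) identifies the independence range: flat at the sill ⇒ no residual
dependence.  Declustering then builds quasi-independent subsets:

1. single-linkage hierarchical clustering cut at the range (default 25 km)
   — guarantees inter-subset separation above the cut;
2. subsets larger than 50 sites are recursively bisected by Ward linkage
   on locally projected km coordinates (single linkage chains; Ward
   equalises);
3. Ward splits can leave cross-subset pairs inside the range, so sites
   are removed greedily — highest count of cross-subset neighbours first,
   ties to the smaller site id — until full separation holds.  A
   `max_removals` cap emulates stopping at "nearly" separated; the
   default runs to exact separation so the postcondition is auditable.

A degree-metric mode (`metric="degrees"`, threshold 0.25°) is provided
because a 0.25° rule and a 25 km rule disagree in longitude away from the
equator.

## Cluster-robust inference

With subsets treated as independent, the sandwich covariance is
`V = H⁻¹ J H⁻¹`: H the observed information of the independence
log-likelihood at the MLE, J built from subset score sums `g_c`.  Because
the MLE shrinks the observed `g_c` toward zero, the plain outer product
(CR0) underestimates variance at a few dozen subsets; calibration studies
in this package measured ~13% downward bias at 50 subsets under strong
cluster frailty, enough to push nominal-5% tests to ~9%.  The default is
therefore the jackknife-type leverage correction
`(I − H_c H⁻¹)⁻¹ g_c` (per-subset information blocks `H_c` by finite
differences of clustered score sums), with the bias-reduced inverse-
square-root variant and the plain form available as options; all include
the `G/(G−1)` factor.  Leverage eigenvalues are floored at 0.1 so a
subset carrying nearly all information about a direction cannot blow up
the correction.  Robust Wald intervals use Student-t critical values on
`G−1` degrees of freedom, the conventional small-sample choice.

The **adjusted likelihood-ratio test** evaluates the independence
log-likelihood on a re-curved surface, `ℓ_A(θ) = ℓ(θ̂ + C(θ−θ̂))`, where C
matches the curvature at the MLE to `V⁻¹`.  C is built symmetrically:
`C = H^{−1/2} W^{−1/2} H^{1/2}` with `W = H^{1/2} V H^{1/2}` (the variance
inflation matrix, ≈ I under independence, ⪰ I under positive dependence).
Eigenvalues of Ŵ below 0.2 are floored with a warning: such directions
mean the robust covariance is deficient (too few subsets relative to
parameters) and would otherwise amplify the transformed surface into
numerical overflow.  The statistic `2[ℓ_A(θ̂) − max_null ℓ_A]` — the null
maximisation runs L-BFGS over the free coordinates with the exact chain-
rule gradient, started from both the reduced MLE and the truncated full
MLE — is referred to χ² with df = number of deleted columns.  An
eigenvalue-weighted reference distribution is a conceivable alternative;
the χ² reference is the implemented choice.

The term-deletion table tests each factor group (a covariate together
with all its interactions; the spatial block; the seasonal pair) by
refitting without the group; p-values below 1e-10 print as 0.  Backward
elimination drops the weakest group above the threshold (default 0.05),
refits and re-tests after every deletion; named "borderline" groups with
p below 0.10 can be protected.

## Synthetic surveys

The generator emulates the structure the method must survive: cluster
centres uniform in a lon/lat box with Gaussian site scatter (default 5 km);
geology as Voronoi cells of random seed points (spatially coherent,
15 levels); continuous covariates with equal cluster- and site-level
Gaussian components (sd 0.7 each; depth, TSSC, conductivity and specific
yield are mapped onto physical scales); sum-to-zero geology effects and
optional geology-specific slope deviations acting on centred covariates;
a lognormal cluster frailty `b_c ~ N(0, σ_b²)` multiplying the scale —
the simplest mechanism that makes the independence fit misspecified in
exactly the way the sandwich targets; and two detection limits (0.5 and
6.0, 25% of sites on the high limit).  The intercept is offset — solved
deterministically from the Weibull CDF before any response is drawn — so
the expected nondetect fraction hits the configured target (default 30%,
matching the motivating survey's 31%).  The `bangladesh_like` preset
(1600 sites, 200 clusters, shape 0.8, 15 geology levels, three geology
interactions) mirrors that survey's shape without claiming its values.
All draws come from one seeded generator in a fixed order, so datasets
are bit-reproducible; a `balanced_clusters` option gives exactly equal
subset sizes for calibration studies stated in that form.

What it does **not** emulate: covariate surfaces interpolated from sparse
monitoring networks (and their measurement error), geochemical structure
within geology units, continuous-range geostatistical correlation (the
frailty is block-structured), or informative censoring.  Passing recovery
and coverage tests on these surveys therefore demonstrates correctness of
the estimators under the stated dependence mechanism, not robustness to
every feature of real survey data.

## Study sizes and numerical defaults

The calibration studies run at the sizes their statements prescribe:
slope recovery over 200 replicates of n=1500 with 30% censoring and no
frailty (observed mean absolute slope error ≈ 0.015); interval coverage
over 300 replicates of 50 clusters × 30 with σ_b = 0.5 (robust ≈ 94–95%,
naive ≈ 60%); test size over 500 such replicates (adjusted ≈ 5%, raw
≈ 40%).  The pipeline demonstrations use 600–900 sites so the whole
acceptance run completes in well under a minute.  Matrix square roots use
symmetric eigendecompositions with relative eigenvalue floors (1e-10)
rather than Cholesky-with-jitter, which proved fragile near singularity.

## Limitations

* The adjusted inference needs clearly more subsets than parameters;
  below roughly 2–3 subsets per parameter the W-floor warning fires and
  p-values should be treated as approximate.
* No gamma or lognormal response alternative, no Bayesian fitting, no
  explicit spatial covariance modelling of the response, and no kriging
  of covariate surfaces — deliberate scope bounds.
* Measurement error in interpolated covariates is not propagated;
  estimated associations are attenuated relative to perfectly observed
  covariates.
* Exact replication of a historical declustering (subset counts and
  removal lists) depends on removal-order tie-breaking; this
  implementation fixes a deterministic rule and audits the separation
  postcondition instead.
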