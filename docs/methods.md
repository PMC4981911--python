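# Methods

`crtmi` implements and compares strategies for handling missing bivariate
continuous outcomes in two-arm cluster randomised trials (CRTs): complete-case
analysis (CCA), single-level multiple imputation (SMI), fixed-cluster-effects
multiple imputation (FMI) and multilevel joint-model multiple imputation
(MMI). This note records the models, the numerical choices, and what the
simulation machinery does and does not emulate.

## Data model

Individuals i are nested in clusters j; clusters are randomised to arms
k ∈ {0, 1}. Each individual carries an individual-level auxiliary covariate
X_i and a cluster-level auxiliary W_j (both standard normal in the
generator), and two continuous outcomes

    Y1_ijk = β1,0 + β1 k + βw,1 W_j + βx,1 X_i + u1_jk + e1_ijk
    Y2_ijk = β2,0 + β2 k + βw,2 W_j + βx,2 X_i + u2_jk + e2_ijk

with residuals (e1, e2) bivariate normal — SDs (σ1, σ2), correlation ρ — and
cluster random intercepts (u1, u2) bivariate normal — SDs (τ1, τ2),
correlation φ. Clustering is parameterised via the intra-cluster correlation
ICC_ℓ = τ_ℓ² / (τ_ℓ² + σ_ℓ²), defined on the model scale (the covariate
contributions are excluded from the ICC; the generator receives the ICC and
derives τ_ℓ = σ_ℓ √(ICC/(1−ICC))).

### Generator defaults and why

| parameter | default | rationale |
|---|---|---|
| intercepts (β1,0, β2,0) | 100, 50 | cost-like and QALY-like outcome scales |
| treatment effects (β1, β2) | 120, 10 | the true estimands of the study |
| residual SDs (σ1, σ2) | 40, 20 | moderate signal-to-noise on both outcomes |
| residual correlation ρ | 0.1 | weak within-person outcome correlation |
| ICC levels | 0.01–0.60 | spanning the range reported in reviews of medical CRTs |
| covariate effects βx, βw | σ/4 per outcome (10, 10, 5, 5) | see below |
| cluster-effect correlation φ | 0.1 | mirrors ρ; not separately identified by any target quantity |
| cluster designs | 25×10, 5×50, 15×Gamma(mean 20, cv 0.5) | many-small / few-large / unbalanced |

The covariate effects deserve comment because everything about CCA bias and
estimator precision runs through them. They must be large enough that the
auxiliaries are genuinely prognostic — otherwise MAR non-response on (X, W)
would be effectively MCAR and CCA would not be biased — but the marginal
outcome variance grows with them and with it every CI width. Setting each
effect to a quarter of the outcome's residual SD keeps the complete-data CI
width for the Y1 treatment effect in the 25-cluster design near 19 units,
the scale typical of a ~500-individual CRT with these variance components,
while a logistic dependence of non-response on X and W (with the association
doubled in the intervention arm) still biases CCA by roughly −4% on Y1.

Gamma cluster sizes are drawn with shape 1/cv², scale mean·cv², rounded
half-to-even and floored at 2 (a cluster of one individual contributes no
within-cluster information).

### Missingness mechanisms

Non-response indicators R_ℓ are independent Bernoulli draws with
logit π_ℓ = α0 + η_X X + η_W W, where the covariates entering depend on the
mechanism kind (individual / cluster / both / differential-by-treatment; the
differential kind uses arm-specific η). Because η_X X + η_W W is normal with
SD s = √(η_X² + η_W²), the marginal rate is a one-dimensional Gaussian
integral; α0 is calibrated by Brent root-finding on a 96-node Gauss–Hermite
quadrature of E[expit(α0 + sZ)] (validated in the tests against a 10⁷-draw
Monte-Carlo estimate). For the differential kind the default calibrates a
single α0 per outcome in the control arm; the intervention-arm rate is then
an emergent consequence of the stronger association (a per-arm-target
calibration mode is available). Missingness never depends on outcomes or
cluster effects, so every mechanism is MAR by construction.

## Imputation engines

All engines operate separately within each treatment arm (allowing different
covariance structure by arm), use both outcomes jointly, and are *proper*:
parameters are drawn from a posterior before outcomes are drawn from the
predictive, so between-imputation variance reflects parameter uncertainty.

**SMI** regresses (Y1, Y2) on an intercept and the auxiliaries (X and W),
ignoring clustering. Because both outcomes are Gaussian, chained-equations
cycling and joint sampling coincide, so the engine uses the exact conjugate
draw under a Jeffreys-style prior (flat coefficients, |Σ|^{−3/2}):
Σ ~ inverse-Wishart(n − p, residual SSCP), then the coefficient matrix from
its matrix-normal conditional. Rows with both outcomes observed form the
posterior; rows with one observed outcome are imputed from the conditional
normal given the co-outcome. A `cycles` argument is accepted for interface
compatibility with chained-equations conventions; it does not change the
sampled distribution.

**FMI** is SMI with indicator columns for every cluster except a reference
cluster, and without cluster-level covariates (they are collinear with the
indicators). The reference cluster is the one whose observed outcome mean is
nearest the arm mean (standardised two-outcome distance, ties to the
first-appearing cluster); clusters with no observed rows receive no
indicator and are therefore imputed from the reference cluster's
distribution.

**MMI** fits the bivariate random-intercept model by a Gibbs sampler with
data augmentation: cluster effects from their bivariate-normal full
conditionals; the cluster-effect covariance Φ and residual covariance Σ from
inverse-Wishart full conditionals (diffuse prior: df = 2, identity scale);
coefficients from their matrix-normal conditional; missing outcomes from
conditional normals given parameters, cluster effects and any observed
co-outcome. Chains are initialised at moment estimates (OLS coefficients,
residual covariances, cluster-mean covariances), which places the chain in
the posterior bulk immediately. Default burn-in/thinning is 1000/1000;
diagnosed autocorrelations (collected via `collect_params`) show the
slowest-mixing component is Φ when clusters are many and ICCs small
(lag-100 autocorrelation ≈ 0.2, lag-200 ≈ 0), so scaled-down runs use
burn-in/thinning of 100–200 after that check. With five clusters per arm
the chain is better behaved per iteration but the posterior itself is wide;
a burn-in of 5000 is the recommended conservative setting there.

Two implementations of the identical update equations exist: a sequential
per-dataset sampler and a replicate-batched sampler that advances many
independent chains in lockstep through vectorised arithmetic (used by the
scenario runner, where hundreds of replicates of the same design are
imputed). The two are cross-checked statistically in the tests, and the
sampler as a whole is validated against (a) recovery of generating Σ and Φ
on large designs and (b) a brute-force quadrature of the posterior
predictive mean of a missing value on a six-observation instance with the
coefficient matrix and Φ held fixed — the only regime in which direct
numerical integration over the remaining three-dimensional Σ posterior is
exact enough to serve as an oracle.

## Analysis model and pooling

The substantive model is the bivariate linear mixed model with treatment as
the only covariate and common variance components across arms. Because the
fixed part is saturated in arm, the per-cluster marginal covariance
I⊗Σ + J⊗Φ splits exactly into the cluster-mean direction (Σ + n_j Φ) and
within-cluster contrasts (Σ); the likelihood is a function of cluster-level
sufficient statistics only, fixed effects are profiled out by GLS, and the
six variance parameters are optimised on (log-SD, arctanh-correlation)
coordinates with analytic gradients (L-BFGS-B, restricted-likelihood
correction by default, ML by flag; correlations bounded at |r| ≤ tanh(4.5) ≈
0.99975 to keep the objective conditioned at degenerate fits; convergence at
relative objective change < 1e−9, up to three jittered restarts). The exact
log-likelihood (with constants) is exposed for validation and matches direct
evaluation of the 2n-dimensional Gaussian density to < 1e−6.

REML was chosen over ML for its small-sample behaviour with few clusters;
with J = 5 clusters per arm ML variance components are noticeably biased
downwards and CIs anti-conservative.

Per-imputation fits are combined by Rubin's rules — pooled estimate = mean;
total variance T = W + (1 + 1/M) B, with W the mean within-imputation
variance and B the between-imputation sample variance — and intervals use
normal quantiles (not a t reference), for comparability between CCA and MI
intervals. Incremental net benefit at willingness-to-pay λ is
INB(λ) = λ δ_Q − δ_C with variance λ² var(δ_Q) + var(δ_C) − 2λ cov(δ_C, δ_Q);
in the simulation convention Y1 plays cost and Y2 effect, and the roles are
explicit arguments for user data.

CCA keeps only records with BOTH outcomes observed (the bivariate model's
complete cases) — the appropriate notion here, and the reason missingness
compounds: at 20% per outcome about 36% of records are incomplete.

## Simulation harness

Scenarios are cells of a full factorial (3 cluster designs × 4 ICC pairs ×
4 mechanisms × 2 association strengths × 2 non-response patterns = 192).
Replicates derive child seeds counter-style from a per-scenario master seed,
so any replicate is reproducible in isolation. Within a replicate all
methods consume the identical masked dataset (pairing; it sharpens
between-method contrasts without affecting per-method summaries).
Performance criteria per method and estimand: coverage of the 95% CI (closed
endpoints), empirical bias, percent bias, RMSE, and average CI width (mean
upper limit minus mean lower limit), with the binomial Monte-Carlo SE
attached to coverage. Replicates whose handling or fitting fails are
excluded for that method and logged; a method losing more than 10% of
replicates is flagged. Non-convergence is essentially absent in the shipped
configurations.

### Bias estimation by paired differences

A replicate's treatment-effect estimate varies far more across generated
datasets than the *bias* of any method does; with five clusters per arm the
Monte-Carlo SE of a raw percent-bias estimate for the Y2 effect is several
points even at hundreds of replicates. The harness therefore provides a
complete-data benchmark "method" (`MethodSpec("full")`): within each
replicate, a method's bias can be estimated as the mean paired difference
between its estimate and the complete-data fit of the same dataset. The
complete-data GLS estimator is exactly unbiased (estimated variance
components are even functions of the errors), so the paired difference
estimates the same bias while the shared data cancel the generation noise —
a three- to four-fold reduction in Monte-Carlo SE in the configurations
shipped here. The acceptance script uses this estimator for the bias sweep.

### Problem sizes

Full-scale runs (N = 1000 replicates per scenario, all 192 scenarios,
burn-in/thinning 1000/1000) are supported but are cluster-scale work. The
shipped acceptance script and test suite run desk-scale versions chosen as
the package's own defaults: N = 200 replicates per coverage cell (coverage
MC-SE ≈ 1.5–2 points), M = 10 imputations, reduced burn-in/thinning
(100–200, after the autocorrelation check above; the long-burn-in
comparison keeps its 5000 vs 1000 burn-in distinction), and N = 300–400
for the bias sweep across six differential-missingness scenarios, where
bias is estimated by the paired differences described above (paired
percent-bias MC-SE roughly 0.2–1.1 points depending on design and
outcome).

## What the generator does and does not emulate

It emulates: balanced randomisation of clusters; cluster- and
individual-level prognostic auxiliaries; bivariate normal outcomes with
exchangeable within-cluster dependence; MAR non-response at realistic rates
(10–45%) driven by observed covariates, optionally interacting with
treatment. It does not emulate: skewed costs (real cost data are
right-skewed; normal-model imputation is only approximately valid there),
missing covariates, cluster-level unit non-response, informative cluster
size, random treatment-effect slopes, or MNAR mechanisms. Passing tests
therefore certify the machinery under correctly-specified Gaussian MAR
conditions, not robustness to those departures.

## Known limitations

- The fixed-effects engine's posterior uses rows with both outcomes
  observed; rows with a single observed outcome inform imputation only
  through their conditional draw, not the posterior (a monotone-sweep
  refinement would use them fully).
- The reference-cluster rule makes FMI's behaviour for entirely-missing
  clusters depend on a single cluster's distribution; with many empty
  clusters FMI is not recommended (and generally over-covers).
- Inverse-Wishart priors with identity scale are "diffuse" relative to
  outcome scales of order 10–100 but are not invariant; with very few
  clusters the Φ posterior is prior-sensitive, which is why the burn-in
  recommendation and the coverage caveats at J = 5 exist.
- The CLI `analyze` command pools the INB covariance across imputations
  with the same Rubin rules applied elementwise to the 2×2 covariance.
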