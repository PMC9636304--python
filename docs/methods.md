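# Methods

## Model

The thresholds model describes the response Y_pi of person p on item i
through its exceedance probabilities,

    P(Y_pi > y | θ_p) = F(α_i (θ_p − δ_i(y))),   y in the support S_i,

with a strictly increasing response function F, person parameter θ_p,
discrimination α_i > 0 and a non-decreasing difficulty function δ_i on
S_i. Conditional on θ_p responses are independent across items (local
independence), and both F and δ_i monotone imply latent monotonicity, so
the model is a monotone latent variable model. The threshold y is a value
on the *observable* response scale, which is what lets one likelihood
serve binary, ordinal, count and continuous items simultaneously.

Derived quantities:

* distribution function F_pi(y) = 1 − F(α_i(θ_p − δ_i(y)));
* continuous density f_pi(y) = f(α_i(θ_p − δ_i(y))) α_i δ_i′(y);
* discrete pmf by telescoping differences, with the conventions
  δ_i(−1) = −∞ (so the probability of exceeding −1 is one) and
  δ_i(top) = +∞ on a finite support;
* for linear δ_i(y) = δ_0i + δ_i y, E(Y_pi) = γ_i θ_p − γ_0i and
  var(Y_pi) = c γ_i²/α_i² with γ_i = 1/δ_i, γ_0i = (δ_0i + d/α_i)/δ_i.
  The constants (c, d) are the variance and mean of F; the package
  computes them at construction by adaptive quadrature of the density on
  [−60, 60] (wide enough that the logistic truncation error is far below
  1e−10) rather than hard-coding them, so they stay verifiable against
  simulation. Both shipped response functions are symmetric, hence d = 0.

Special cases recovered exactly: the binary model F(α_i(θ_p − δ_0i))
(normal-ogive / 2PL / Rasch), the graded response model when ordinal
thresholds are left free, a log-normal response model for normal F with
log difficulty, and a latent-trait analogue of classical test theory for
continuous linear items. Categorizing a continuous thresholds item at any
cut points τ_1 < … < τ_k yields again a thresholds (graded response) item
with thresholds δ_i(τ_r) — the package's `categorize` returns exactly that
item, and the acceptance suite verifies the stability numerically.

## Difficulty families and their parameterizations

Parametric families are δ(y) = δ_0 + δ·g(y) with g one of: y (real line),
log y (positive responses), log(1+y) (counts and finite ordinal scales),
the adapted logit log((1+y)/(k−y)) (finite ordinal, symmetric around
(k−1)/2), and a·F⁻¹(y) for data in the open unit interval. The constant a
defaults to 1 and is configurable (`transform_const`). Binary items store
only δ(0): any g would be absorbed into the intercept, so no slope exists
for them and a configured one is ignored with a warning.

Ordinal responses are shifted internally to start at 0 (`first_category`
in the item config records the original first label). On the shifted
scale, log(1+y′) coincides with log y on an original 1..k+1 labeling, so
log-family parameter values quoted on either scale agree.

B-spline difficulties use a cubic basis with equally spaced knots over the
observed response range (continuous items) or the support {0, …, k−1}
(ordinal items); 6 basis functions by default. Monotonicity is enforced
through non-decreasing coefficients, which is sufficient for a
non-decreasing spline. For optimization the coefficients are
reparameterized as (first coefficient, log-increments), turning the order
constraint into smooth unconstrained optimization; the same device handles
free ordinal thresholds. Unit-interval data are affinely mapped from their
(a, b) bounds onto (0, 1); exact-boundary observations are rejected
(δ diverges there) unless the config requests the standard compression
(y(n−1) + 1/2)/n.

## Estimation

Person parameters are integrated out under θ_p ~ N(0, σ_θ²), giving the
marginal log-likelihood l = Σ_p log ∫ Π_i f_pi(y_pi) φ_{0,σ_θ}(θ) dθ with
f_pi the density or pmf per item format — mixed formats need no special
treatment. The integral uses Gauss–Hermite quadrature with θ_q = √2 σ_θ
x_q, 61 nodes by default; the node count is configurable and fits are
insensitive to it beyond ~41 nodes for bounded items (count items with a
wide observed range are the slowest to converge, which is why the default
sits at 61). Per-person integrands are accumulated in log space with
log-sum-exp; discrete cell probabilities are floored at 1e−300 before
taking logs, which only affects quadrature nodes whose posterior weight
already underflows.

The score is analytic. Writing the per-person posterior over quadrature
nodes r_pq ∝ w_q Π_i f_pi(y_pi | θ_q), the derivative of l with respect to
any item parameter is Σ_p Σ_q r_pq ∂ log f_pi(y_pi | θ_q)/∂π (the Fisher
identity; identical to the direct integrand derivatives but numerically
better behaved), assembled from the exact derivatives of the continuous
density and of the pmf differences. The σ_θ component follows from the
node substitution θ_q = √2 σ_θ x_q, so the gradient is the exact gradient
of the quadrature-approximated objective — the property the
finite-difference oracle in the test suite checks to 1e−5 relative error.

Optimization is BFGS on the unconstrained parameterization (intercepts
free; log slope; log α; log σ_θ; log-increments for ordered coefficient
vectors), with gradient tolerance 1e−5 and at most 500 iterations.
Starting values: intercepts chosen so that δ(mean response) ≈ 0 (i.e.
−g(ȳ), clipped into the support interior), slopes and discriminations 1,
σ_θ = 1, spline coefficients from standardized responses evaluated at the
Greville abscissae. Non-convergence is reported in the `FitResult`
(`converged`, `gradient_norm`, `n_iter`), never raised.

Identifiability: with varying discriminations, α of the first item is
fixed at 1 and σ_θ is free; with all α fixed at 1, σ_θ is free. This
matches the parameter counts implied by the AIC bookkeeping of the model
class (e.g. six linear items: 13 = 6 intercepts + 6 slopes + σ_θ free
parameters; adding discriminations gives 18 with the first α pinned).
Parameter counts per item: binary 1, parametric 2 (+1 if α free),
free-ordinal k, B-spline M+1, plus σ_θ and any DIF coefficients.

Standard errors come from the inverse of the observed information, the
negative Hessian of the marginal log-likelihood in the *natural*
parameterization, computed by central differences of the analytic score
(step 1e−5·max(1, |v|)); the full matrix is inverted, not per-item blocks.

The common-slope constraint (δ_1 = … = δ_I) is available for items sharing
a parametric family, and the spline shape penalty
P_λ = λ Σ_{i≥2} Σ_{l≥2} [(δ_il − δ_i,l−1) − (δ_i−1,l − δ_i−1,l−1])²
couples spline shapes across items; λ = 0 is the plain likelihood, large λ
(the package tests use 1e6) yields shifted, shape-identical difficulty
functions. λ is user-supplied; no automatic tuning is performed (a
cross-validation wrapper would sit naturally on top of `fit_mml` but is
deliberately not bundled).

Missing responses simply drop out of the person's likelihood product
(missing-at-random); a person with no observed responses contributes a
constant and gets the prior back when scored.

## Person scoring and information

Given (estimated) item parameters, the posterior of θ is the response
likelihood times the N(0, σ_θ²) prior, normalized by the Gauss–Hermite
marginal. EAP and the posterior SD are computed on the quadrature grid;
MAP by bounded 1-D maximization on ±8σ_θ. Discrete items contribute pmf
factors where the continuous formula has densities — one code path for all
formats.

Discrete item information is implemented in both printed forms — the
general Σ_r (π_r′² − π_r π_r″)/π_r and the finite-support form without
second derivatives — with exact derivatives π_r′ = α(f(η_{r−1}) − f(η_r)),
π_r″ = α²(f′(η_{r−1}) − f′(η_r)); their numerical agreement (1e−10) is a
test of the algebra. Tail category probabilities use the survival function
where 1 − F would lose precision; count supports are truncated at
cumulative mass 1 − 1e−12. A category with (numerically) zero probability
raises rather than returning a silent infinity. For continuous items the
observed information α²((f′/f)² − f″/f) is closed-form (α² exactly under
normal F); the expected information integrates it over the implied
response distribution, which after substitution reduces to an integral in
v ~ F between the 1e−13 and 1 − 1e−13 quantiles.

## Differential item functioning

The person term θ_p is replaced by θ_p + x_pᵀγ_i inside F(α_i(·)) for the
items under test (γ sits inside the α_i multiplier, following the model's
predictor form). H0: γ_i = 0 is tested by a likelihood-ratio test with q
degrees of freedom, item at a time, with Benjamini–Hochberg adjustment
across items (the package's choice; no particular multiplicity procedure
is canonical here). Constant covariate columns are rejected at
configuration time — they are confounded with the intercept — as are
collinear designs.

## Synthetic data

The simulator draws continuous responses by the inverse construction
Y = δ⁻¹(θ − V/α) with V ~ F, and discrete responses by cdf inversion
(count supports walk categories, assigning the residual tail beyond
cumulative mass 1 − 1e−12 to the next category). Everything is driven by a
single integer seed.

Preset study designs, used by the tests and the acceptance script:

* **person_recovery** — 10 continuous linear items, intercepts
  −2.25 + (i−1)·0.5, slopes (1,1,1,1,2,2,2,2,3,3), α = 1, θ ~ N(0,1).
* **count** — 5 count items, log(1+y) difficulties, intercepts
  (−2.0, −2.5, −3.0, −3.5, −2.8) and slopes (1.0, 1.2, 1.4, 1.3, 0.9),
  σ_θ = 1, P = 200; the parameter ranges put typical counts in the 5–25
  range of verbal-fluency tasks while keeping the response tails
  realistic (slopes well below 1 make log-difficulty counts explode). The
  varying-discrimination variant uses α = (1.25, 0.8, 1.1, 0.9, 1.0) with
  the last α pinned at 1.
* **cognition_like** — 194 × 6 seven-category ratings, linear
  difficulties with intercepts/slopes near published estimates for a
  children's self-regulation scale; σ_θ = 1.5 (a rating-scale spread that
  places person variation across roughly two categories; the source
  application does not publish its latent scale).
* **fears_like** — 200 × 5 seven-category Likert ratings, log
  difficulties near published political-fear estimates; σ_θ = 1.
* **fluency_like** — 202 × 4 count items emulating verbal-fluency tasks
  (animal naming easiest, letter tasks harder); σ_θ = 1.09.

These presets emulate the marginal response distributions and design
sizes of the corresponding applications, not their sampling designs,
rater structures, or any dependence beyond the single latent trait. A
passing recovery test therefore demonstrates correctness of the
estimation machinery under the model, not robustness to model violations
in real data.

## Problem sizes and replication counts

Parameter recovery uses the count preset across 20 seeds (220 parameter
checks against 3-SE bands); person recovery uses P = 100; the DIF null
rejection rate and the slope-LRT null mean use 200 replicates each at
P = 150 (four binary items) and P = 80 (three continuous items)
respectively — sizes at which the χ² asymptotics are already accurate
while a full replication run stays in the minutes range on one CPU.

## Known limitations

* Only symmetric response functions (normal, logistic) ship; asymmetric F
  (e.g. extreme value) would need new moment constants and is untested.
* One latent dimension; no multidimensional extension.
* The likelihood-ratio χ² reference for the common-vs-varying slope test
  is asymptotic; at small P the test is mildly anticonservative, as usual.
* Penalized spline fits report the unpenalized log-likelihood at the
  penalized optimum; effective degrees of freedom for penalized AIC are
  not computed.
* Fit reports serialize estimates and standard errors, not the full
  covariance matrix.
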