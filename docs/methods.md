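# Methods

## The model

Each hypothesis test contributes a triple `(P, Z, H)`: a p-value, an
informative variable, and the unobserved truth (`H = 0` null, `H = 1`
alternative). After rank-based quantile normalization `Z ~ Uniform(0,1)`, and

* `H | Z = z ~ Bernoulli(1 - pi0(z))`,
* `P | H = 0 ~ Uniform(0,1)` regardless of z (Z is *informative*, not
  confounding: it never distorts null p-values),
* `P | H = 1, Z = z` has density `f1(p|z)`, decreasing in p.

The joint density is `f(p,z) = pi0(z) + (1 - pi0(z)) f1(p|z)` and the
posterior null probability `r(p,z) = pi0(z)/f(p,z)` is the optimal statistic:
regions `{r <= tau}` minimize the weighted misclassification risk
`(1-tau) Pr(reject, H=0) + tau Pr(accept, H=1)` among all rejection regions,
and the q-value of a test is the positive FDR of the smallest such region
containing it. Everything the package estimates plugs into this structure.

## Quantile normalization

The raw covariate is mapped to `z_i = (rank_i - 0.5)/m` with average ranks
under ties. The offset keeps every z strictly inside (0,1) so probit
transforms and logit links stay finite; ties receive identical z because
identical information must yield an identical prior. The transform uses ranks
only, hence is invariant to any strictly monotone rescaling of the covariate.
P-values of exactly 0 or 1 are clamped to `[1e-15, 1 - 1e-15]` for the same
reason; raw values are preserved in output tables.

## Estimating pi0(z)

All three estimators start from the thresholding identity: for
`xi = 1{P > lambda}`,

```
E[xi | Z = z] / (1 - lambda)  >=  pi0(z),
```

with equality when every alternative p-value falls below lambda. Estimating
the conditional mean of xi gives a *conservative* (upward-biased) estimate of
pi0(z) — the safe direction for FDR control.

* **GLM**: `xi ~ Bernoulli((1-lambda) * expit(b0 + b1 z))`, fitted by direct
  numerical maximum likelihood (L-BFGS with analytic gradient). The scaled
  mean is not a standard logistic link, and fitting it directly guarantees
  the estimate never exceeds 1, unlike rescaling an ordinary logistic fit.
  The linear predictor is capped at |eta| <= 30 so likelihood boundaries
  (e.g. xi identically 1) saturate instead of overflowing. The estimate is
  monotone in z by construction.
* **GAM**: the same likelihood with a cubic B-spline predictor (interior
  knots at equally spaced z-quantiles). The degrees of freedom are chosen
  from {3,4,5,6,8} by GCV `(deviance/m)/(1 - k/m)^2`; df = 1 degenerates to
  the GLM, so the families nest. Not constrained to be monotone.
* **Kernel**: factorizes `E[xi|z] = Pr(Z=z | P>lambda) Pr(P>lambda)`. The
  second factor uses Storey's scalar `#{p_i > lambda}/(m(1-lambda))`; the
  first is a Gaussian KDE (Silverman bandwidth) of the probit-transformed
  retained z values, back-transformed with the probit Jacobian and
  renormalized on [0,1] (the back-transform loses ~1e-3 of tail mass
  otherwise). Requires at least 20 retained tests.

All estimates are clipped into `[1e-8, 1]`: the floor prevents divisions by
zero downstream, the cap reflects that pi0 is a probability (the kernel
product can exceed 1 on uniform-z noise).

### Choosing lambda

Small lambda retains more data (low variance, high bias — alternatives with
`p > lambda` masquerade as nulls); large lambda the reverse. The selector
estimates `MISE(lambda) = ∫ bias² + variance dz` on a 101-point z grid:
variance from 100 bootstrap resamples (shared index draws across the grid,
so the comparison is paired), and bias as the excess of the lambda curve
above the largest-lambda reference curve beyond twice the reference's own
bootstrap standard error. The deadband matters: without it the reference's
sampling noise is charged as "bias" to every other lambda, and in the
pure-null case the selector would wrongly favour large lambda. Ties within
1e-4 break toward the smallest lambda (more data retained). The procedure is
a surrogate — the key requirements are determinism given the seed and
non-degeneracy — and the grid, replicate count and seed are all exposed.

The replication harness (`run_simulation_study`) runs with a fixed
`lambda = 0.5` rather than per-replicate selection: with Beta(a,1)
alternatives at the simulated effect sizes the estimates are insensitive to
lambda over a wide range, and a fixed value keeps the replicate distribution
interpretable.

## Estimating f(p,z)

The joint density must live on the unit square (boundary bias kills naive
kernel smoothers there) and may be monotone in p. The estimator:

1. maps both coordinates through the probit `ndtri`,
2. runs an adaptive Gaussian KDE on the plane where point i's bandwidth is
   `scale * d_k(i)`, the distance to its `ceil(fraction*m)`-th nearest
   neighbour; the pair (fraction, scale) is selected from
   {0.05, 0.1, 0.2, 0.35} x {1.0, 0.7, 0.5, 0.3} by leave-one-out
   log-likelihood (evaluated on a fixed 500-point subsample for large m; the
   sum over kernel centres is exact). Ties resolve to the smoother fit. The
   scale grid matters in practice: raw k-NN distances with a fractional k
   oversmooth enough to cost real power, and the leave-one-out criterion
   reliably detects this,
3. back-transforms with the probit Jacobian and tabulates the density on a
   128 x 128 grid,
4. optionally projects each z-gridline onto the non-increasing-in-p cone by
   pool-adjacent-violators, weighted by the trapezoid cell widths of the p
   grid (a least-squares projection in L2(dp)); the projection is idempotent
   and is on by default, since the two-group model with alternatives
   stochastically smaller than uniform implies the shape,
5. renormalizes to unit trapezoid mass (enforced to within 1%).

**Grid geometry.** The z axis is uniform, but the p axis uses
`p_i = (i/127)^4`. This is the load-bearing numerical choice: well-powered
alternatives concentrate below 1e-3, where a uniform 128-point grid has no
resolution — the tabulated density then caps the spike, the smallest
attainable local FDR is ~0.1, and the rule rejects almost nothing at a 5%
target. The power grid resolves the spike down to ~1e-9. Both grid endpoints
are evaluated half a cell inside [0,1], keeping the probit finite and
preventing a divergent boundary value (the truth behaves like `p^(a-1)` near
0) from dominating the quadrature; the residual under-reading of the spike
below the first node biases the local FDR upward, i.e. errs conservative.
Evaluation between nodes is bilinear, written as nested linear interpolation
so surfaces constant along an axis interpolate exactly (this keeps tied
density values tied, which the q-value averaging relies on).

Values are floored at 1e-10 so `r = pi0/f` is always finite.

## From r to decisions

`r_i = min(1, pi0(z_i)/f(p_i, z_i))` — the plug-in ratio can exceed 1, the
cap keeps it a probability. Q-values are running means of sorted r; tied r
share the mean at the last tied index (the defining set uses a non-strict
inequality). Rejections are `q <= alpha`; the rejection sets are nested in
alpha by monotonicity of q in r. The covariate-free baseline is the classic
Storey q-value (`pi0_S * m * p_(j)/j`, step-down minimum over suffixes),
with its pi0 capped at 1.

When the covariate carries no information, the machinery reduces to the
covariate-free construction: with a constant pi0 estimate and a density
surface replicated across z, functional q-values coincide exactly with 1-D
local-FDR q-values (tested to 1e-10).

## Oracles and quadrature

Simulation truth uses Beta(a(z), 1) alternatives, `f1(p|z) = a p^(a-1)` with
`a(z)` in (0,1): decreasing in p, closed-form everywhere, and a(z) encodes
power varying with the covariate. Supported pi0 shapes: constant,
logit-linear (monotone), cosine (non-monotone), and clipped linear.

pFDR/pFNR and Bayes-error oracles integrate the closed-form joint law on a
512 x 512 grid, with the p axis transformed as `p = s^4`: the substitution
turns the `p^(a-1)` integrand into `a * 4 * s^(4a-1)`, bounded for
`a >= 0.25`, so trapezoid quadrature converges without boundary clamps (for
`a < 0.25` the s = 0 node is approximated by its finite limit and accuracy
degrades gracefully). The printed integral representation of pFDR as
`∫_Γ r` is implemented as the conditional probability
`Pr(H=0 | T in Γ) = ∫_Γ pi0 / ∫_Γ f`, which is the quantity the q-value
definition requires; without the normalization pFDR(Γ) would not be a
probability for small regions.

## Simulation harness and what it shows

`run_simulation_study` replicates: generate data (replicate k re-seeds with
`seed + k`), run the full pipeline and the Storey baseline at the same
alpha, record false discovery proportion and true positives for each, report
means with Monte-Carlo standard errors; failures are recorded per replicate,
never dropped. Default study conditions are m = 3000 tests, 100 replicates,
`pi0(z) = 0.6 + 0.3z` with Beta(0.25, 1) alternatives for the informative
design, and constant pi0 = 0.75 with the same alternative for the
non-informative control — sizes at which the full suite runs in minutes on
one CPU while the Monte-Carlo standard errors are small enough for the
comparisons to be meaningful.

The generator draws independent tests with a covariate that is exactly
uniform and exactly satisfies the model. Real screens violate all of this:
p-values are dependent (linkage, gene correlation), the informative variable
may affect the null distribution (a confounder rather than an informative
variable), and f1 need not be monotone (two-sided tests with discreteness).
Passing the harness therefore shows the estimators are consistent and the
rule controls FDR *under the model*, not that those guarantees transfer to
any particular dataset. The dependence and multivariate-covariate settings
are out of scope.

## Known limitations

* pi0 estimators inherit the conservativeness of thresholding: with
  weakly-powered alternatives the upward bias is substantial at any lambda.
* The kernel pi0 estimator has the usual KDE bias at high-curvature points
  of pi0(z).
* The adaptive KDE's leave-one-out selector uses a fixed subsample of
  evaluation points for m > 500; selection is deterministic given the seed
  but can differ between machines only through BLAS reduction order
  (observed differences are ~1e-13, far below decision thresholds).
* `r` is capped at 1 and q-values are averages of capped values; in
  deep-null regions q saturates near 1 and carries no ranking information.
* The q-value estimator follows the cumulative-mean construction; it is not
  guaranteed monotone-consistent with an exact region-mass estimate, and no
  correction is applied.
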