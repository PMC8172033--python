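# Methods

## Model and censoring mechanism

Lifetimes follow the Dagum distribution, F(t) = (1 + λt^−θ)^−β on t > 0
with θ, β, λ > 0.  θ is the upper tail index (the survival function decays
like βλ t^−θ), β shapes the lower tail, and λ is a scale in units of t^θ.
The mean exists only for θ > 1; the package checks the analogous tail-order
condition before reporting predictive means.

Under progressive type-I interval censoring, n units start at t₀ = 0 and
are seen only at scheduled times t₁ < … < t_m.  Interval j yields a failure
count D_j; immediately afterwards R_j = ⌊p_j·S_j⌋ of the S_j survivors are
withdrawn (p_m = 1 ends the test).  Conditionally on the past, D_j is
Binomial(A_j, (F(t_j) − F(t_{j−1}))/(1 − F(t_{j−1}))) with A_j the units at
risk; the simulator draws exactly this chain, so the joint law of the counts
is the likelihood's own sampling model.  Removals apply to survivors after
the interval's failures are counted, and the floor is the exact ⌊·⌋.

## Likelihood, score, information

ℓ = Σ_j D_j log U_j + R_j log S_j with U_j = F(t_j) − F(t_{j−1}) and
S_j = 1 − F(t_j).  All first and second derivatives are exact closed forms
obtained by differentiating F in (θ, β, λ) and composing through
d²(D log U + R log S); the observed information is the negative Hessian,
symmetrised to machine precision.  Every CDF evaluation routes through
log1p/expm1 in log(λ t^−θ), so likelihood and derivatives stay finite at the
extreme proposals an MCMC chain visits; U_j is computed as S_{j−1} − S_j,
which is accurate when both CDF values are near 1.

The maximiser works on log-parameters (positivity for free; the chain rule
maps the analytic score) with BFGS followed by damped Newton refinement on
the analytic Hessian; convergence is certified by the score's infinity norm
falling below 1e−6·n.  The default start sets θ = β = 1 and λ equal to the
midpoint of the interval containing the median failure (with θ = β = 1 the
model median is exactly λ); a deterministic 3×3×3 multi-start grid around
that point is used only if the default start fails.  Wald intervals are
estimate ± z·SE, untruncated by default (a truncation flag exists).

**Identifiability.** β̂ and λ̂ are strongly anti-correlated under grouped
inspection (≈ −0.99 at the default 5-point design), and the likelihood is
nearly flat along the ridge β → ∞, λ → 0 (the Fréchet limit
F → exp(−cλ t^−θ)).  For some finite samples the supremum sits on that
boundary: the fit then reports a numerically singular observed information
(non-positive-definite or condition number above 1e12) and flags the
covariance as unavailable rather than inventing curvature.  Monte-Carlo
means of β̂ are right-skewed by ridge excursions at moderate n even though
medians sit on the truth; summaries in the replicate harness report both
mean-based and variance-decomposed columns so the skew is visible.

## Priors and posterior sampling

Priors are independent per parameter: gamma with shape aᵢ and rate bᵢ
(mean aᵢ/bᵢ) — defaults θ ~ G(10,10), β ~ G(0.5,10), λ ~ G(0.1,10) — or
flat U(0, c) with c = 5 by default.  No conjugacy exists, so the sampler is
componentwise Gaussian random-walk Metropolis on log-parameters with the
log-scale Jacobian in the target.  Proposal scales start at 0.3 and are
re-tuned every 100 sweeps during burn-in toward an acceptance rate in
[0.20, 0.45], then frozen, keeping the retained chain time-homogeneous.
Defaults: 20 000 iterations, 5 000 burn-in, thinning 1.  Monte-Carlo
standard errors use batch means with √N batches.  A dataset with no
failures cannot inform the likelihood; the result is flagged
prior-dominated rather than refused.

Point estimates: SEL = posterior mean; BSEL = ω·MLE + (1−ω)·SEL, default
ω = 0.3.  Intervals are equal-tailed posterior quantiles (τ/2, 1 − τ/2);
highest-posterior-density intervals are out of scope.

## Prediction

Given the parameters, the (r+s)-th order statistic of the original n units,
conditional on the r-th failure at t_r, is the s-th order statistic of
n − r draws from the law truncated above t_r; its density carries the beta
normalising constant (n−r)!/((s−1)!(n−r−s)!) and its CDF is the regularised
incomplete beta function at the truncated probability transform.  The
two-sample target is the classical r-th order statistic of m_future iid
draws.  Predictive quantities average these over posterior draws
(Monte-Carlo integration; nested quadrature over a 3-d parameter space
buys nothing once draws exist).  Bounds are solved by bracketed Brent
root-finding on the monotone predictive CDF to 1e−10; the point predictor
is the predictive mean computed by integrating the predictive survival
function, except when any posterior draw implies tail order θ(k−s+1) ≤ 1
(divergent mean), in which case the predictive median is substituted and
flagged.  An algebraically equivalent binomial-expansion form of the
one-sample density is retained purely as a cross-check; the alternating sum
cancels catastrophically beyond n − r ≈ 15, so the direct product form is
used everywhere else.

The observed data are interval counts, not ordered failure times, so
one-sample prediction is exposed as a function of user-supplied (r, t_r) —
e.g. the cumulative failure count at the last inspection and that
inspection time.  The package does not attempt to impute exact order
statistics from grouped counts.

## Inspection-time design

Before data exist, the information in a plan is the expected information:
the deterministic mean recursion of the censoring chain (binomial draws
replaced by means, floors by identity) plugged into the observed-information
formulas — the multinomial expected information.  Criteria:

- trace(I⁻¹): sum of asymptotic parameter variances;
- I_w = ∫₀¹ V_p w(p) dp with V_p = g_pᵀ I⁻¹ g_p the delta-method variance
  of t̂_p, g_p the exact gradient of the quantile function, and w a
  probability weight on (0,1) (default uniform).  The integrand diverges
  integrably as p → 1, so integration runs on [ε, 1−ε], ε = 1e−4 by
  default and configurable.

With m = 2 inspection times the criteria do not exist: every likelihood
term is a function of (F(t₁), F(t₂)), so the score spans at most two
directions and the 3-parameter information is singular; the code raises an
error naming the non-identified direction, and m ≥ 3 is required for
optimisation.  Times are optimised on (log t₁, log gaps) — any iterate is a
strictly increasing grid — by Nelder-Mead from three quantile-spaced
starts; removal proportions are design inputs held fixed (default: none
until the terminal removal).  I_w (not trace) is scale-equivariant: under
t → ct with λ → λc^θ every V_p scales by c², so the optimal grid scales
by c.

## Synthetic-data generator and what the tests show

The generator *is* the model's own sampling chain, with the standard
settings used throughout: truth (θ, β, λ) = (2, 2, 1), removal schemes
p = (0, 0.2, 0.5, 0.75, 1) and (0, 0.4, 0.7, 0.9, 1) (plus the no-removal
scheme), n ∈ {50, …, 2000}, and inspection times at the true-law quantiles
of (0.15, 0.35, 0.55, 0.75, 0.95) — the time rule is an explicit choice,
recorded in every output header, since a real experiment would fix times
from engineering constraints.  Because the generator and the likelihood
share one model, passing tests certify internal correctness and calibration
(derivatives, sampling law, coverage, predictive calibration) but say
nothing about Dagum misspecification on real data: no contamination,
rounding, tied inspection clocks, or covariates are emulated.

## Numerical choices and limitations

- Simulation seeds: one integer spawns independent substreams per replicate
  (SeedSequence), so every table is bit-reproducible.
- Quantile round-trips hold to 1e−10 away from p ∈ {0, 1}; hazard raises on
  survival underflow instead of returning inf.
- MLE fits need at least one failure; design evaluation needs rank-3
  information; credible intervals need ≥ 100 draws.
- Monte-Carlo problem sizes in the test-suite (replicate counts of a few
  hundred, chains of 10⁴–10⁵ sweeps, 10⁵-draw empirical CDFs) were chosen
  so each statistical check resolves its stated tolerance with seeded
  streams while the whole suite stays lightweight.
- The replicate harness reports |mean − truth| as the bias column (the
  convention of grouped-censoring simulation tables) together with MSE and
  variance so that MSE = bias² + variance is checkable row by row.
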