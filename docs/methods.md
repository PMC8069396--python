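# Methods

## The model

`hlowg` implements the Type I half-logistic odd Weibull generated
(Type I HLOW-G) family of lifetime distributions.  Starting from a baseline
distribution G on (0, ∞) with density g, the odds ratio

    t(x) = G(x; φ) / (1 − G(x; φ))

is passed through an odd-Weibull layer with shape β > 0 and a type I
half-logistic layer with scale λ > 0:

    F(x; λ, β, φ) = (1 − e^{−λ t(x)^β}) / (1 + e^{−λ t(x)^β})
                  = tanh(λ t(x)^β / 2),

    f(x; λ, β, φ) = 2λβ g G^{β−1} (1−G)^{−(β+1)} e^{−λ t^β} (1 + e^{−λ t^β})^{−2},

    h(x; λ, β, φ) = λβ g G^{β−1} (1−G)^{−(β+1)} (1 + e^{−λ t^β})^{−1}.

The two extra parameters buy flexible hazard shapes (increasing, decreasing,
unimodal, bathtub) from simple baselines.  Six baselines are built in:
exponential, Rayleigh, Lindley, Weibull, Fréchet, Lomax.  Conventions that
matter:

* **Fréchet**: G(x) = exp(−(a/x)^b) with a the scale and b the shape.  This
  orientation is the one under which the fitted application values behave
  sensibly (the fitted CDF places ≈ 0.51 of its mass below the sample mean of
  the aluminum-coupon data), and it reproduces published machine output
  exactly (see "Validation anchors" below).
* **Weibull**: G(x) = 1 − exp(−(x/b)^a), a shape, b scale.
* **Lindley**: the standard one-parameter form
  G(x) = 1 − (1 + ax/(a+1)) e^{−ax}; its quantile function uses the
  secondary branch of the Lambert W function.

### Numerical evaluation

Everything flows through log t = log G − log(1−G), with log(1−G) coded
directly per baseline (e.g. −ax for the exponential), so the odds ratio never
suffers cancellation near G ≈ 1.  The working variable w = λ e^{β log t} may
overflow for fitted shapes as large as β ≈ 17; the CDF is evaluated as
tanh(w/2) (saturates cleanly), the survival function in the simplified form
2e^{−w}/(1+e^{−w}) which keeps relative accuracy deep in the right tail, and
the log-density assembles additive log terms only.

The quantile function inverts the two layers in closed form,
t = [ (log(1+u) − log(1−u)) / λ ]^{1/β}, and then inverts the baseline via
its `ppf` at t/(1+t) when t ≤ 1 and its `isf` at 1/(1+t) when t > 1 — each
branch keeps full relative precision in the regime where the other would
round t away.  Random generation is inverse-transform only, from a seeded
`numpy` Generator; a fixed seed fully determines the output.

## Distributional summaries

All summaries are computed by direct adaptive quadrature
(`scipy.integrate.quad`, 400-subinterval budget):

* moment-type integrals in probability space, E[h(X)] = ∫₀¹ h(Q(u)) du,
  which sidesteps the infinite domain and concentrates effort where the mass
  is; incomplete moments integrate over (0, F(t)); residual-life moments over
  the conditioning event's u-range;
* density-power integrals (Rényi, Havrda–Charvát, Arimoto, Tsallis) in x
  space over the [10⁻¹², 1−10⁻¹²] inter-quantile range; all four entropies
  are deterministic transforms of the single integral ∫ f^ρ, so their mutual
  identities hold exactly by construction; Shannon entropy is computed
  separately as E[−log f(X)] in u-space.

The family also admits a formal representation as an infinite mixture of
exponentiated-G densities.  It is deliberately **not** used here: after the
summation interchange the inner binomial sum diverges termwise, so the
coefficient arrays are not computable.  What does converge is the
single-index binomial expansion of the half-logistic factor,
(1+e^{−w})^{−2} = Σᵢ (−1)^i (i+1) e^{−iw}; it is retained as
`properties.binomial_expansion_pdf` and used as an independent series oracle
for the density, with the alternating-series truncation bound checked in the
tests.

Skewness is the standardized third central moment and kurtosis the plain
μ₄/σ⁴ (normal → 3); an excess variant is exposed behind the
`excess=True` flag.  Some published renderings of these formulas drop a term
(the 2μ′₁³ in the skewness numerator) or print the excess form; the standard
definitions implemented here are the ones that reproduce published machine
output for this family (below).  The octile-based Kenney–Keeping skewness and
Moors kurtosis are provided alongside for heavy-tailed settings where moments
are fragile.

### Validation anchors

The quadrature moments of the Fréchet sub-model at the published Bayes-SEL
estimates (λ, β, a, b) = (0.4696, 17.1055, 27.7908, 0.2562) come out as

    mean 131.277, variance 499.965, skewness −0.5725, kurtosis 3.3745,
    index of dispersion 3.8084,

which agree digit for digit with published machine-computed descriptives for
this fit (printed there under a row label that appears transposed with the
sample statistics of the data).  These five simultaneous 4–6-digit
agreements pin down both the Fréchet parameterization and the moment
pipeline, and they are frozen as regression anchors in the test suite.  For
the exponential sub-model at (0.0019, 0.9711, 4.1595) the quadrature gives
mean 1.5218, variance 0.0780, skewness −1.2339, kurtosis 5.3093, confirmed
by a 2×10⁶-draw simulation; no printed descriptive row matches these, and a
scan over the rounding range of the printed parameters shows the discrepancy
cannot be explained by rounding.

## Estimation

### Classical

Four objectives share one harness: negative log-likelihood, least squares
V = Σ(z_j − j/(n+1))², weighted least squares with weights
(n+1)²(n+2)/(j(n−j+1)), and the Cramér–von Mises distance
1/(12n) + Σ(z_j − (2j−1)/(2n))², where z_j is the fitted CDF at the j-th
order statistic (stable sort; ties keep positional ranks).  One published
form of the log-likelihood carries the half-logistic term as
−2Σ log(1−e^{−λt^β}); that is inconsistent with the density's
(1+e^{−λt^β})^{−2} factor, and the density-consistent +2Σ log(1+e^{−λt^β})
is implemented (the analytic score components carry the matching sign and
are verified against finite differences in the tests).

Optimization is multi-start local search over log-parameters (positivity for
free): L-BFGS-B followed by a Nelder–Mead polish, from a moment-matched
initial guess (baseline scale pinned to the sample median, unit shapes)
perturbed by log-uniform factors in [10⁻², 10²].  Default 10 starts; the
simulation study uses fewer (see below).

Standard errors: MLE uses the inverse observed information from a
central-difference Hessian on the natural scale (relative step 10⁻⁴); a
non-positive-definite Hessian yields estimates without standard errors plus
a warning.  The distance estimators have no textbook asymptotic variance
here, so a nonparametric bootstrap (default B = 200, single-start refits
from the point estimate) is offered instead.

**Identifiability caveat**: the (λ, β, φ) surface contains a long, nearly
flat ridge — quite different parameter vectors produce nearly identical
CDFs.  Point estimates from different objectives can therefore disagree
substantially while fitting equally well; the tests check distributional
recovery (sup-distance of the fitted CDF) for the distance methods rather
than parameter-wise recovery.

### Bayesian

Independent Gamma(shape, rate) priors on every parameter.  Prior elicitation
follows the mean/variance inversion: a prior centred at m with variance v
gets shape m²/v and rate m/v; v = 0.4 is the informative setting and v = 2.5
the non-informative one.

The posterior is explored by a hybrid Metropolis-within-Gibbs sampler.
Three parameters (λ, β, and the Fréchet b) admit Gamma-shaped approximate
full conditionals obtained by dropping the (1+e^{−w})^{−2} factor (and, for
β, the e^{−λΣt^β} factor) from the likelihood; the baseline parameter `a`
has no tractable conditional and is updated by a Gaussian random walk with
variance V_a, accepted by the usual ratio.

Because the printed conditionals are *not* exact — they omit
parameter-dependent likelihood factors — the default `corrected` mode uses
them only as independence proposals accepted by the exact
Metropolis–Hastings ratio against the full posterior, and cycles each such
update with an adaptive log-scale random-walk kernel for the same parameter.
Cycling two valid kernels preserves the target while guaranteeing mixing
even where the Gamma proposal is a poor approximation (for β it is
essentially never accepted at realistic sample sizes).  The `as_printed`
mode draws from the Gamma conditionals directly, guarding non-positive rates
(which do occur, e.g. in the β conditional of the exponential sub-model) by
the random-walk fallback with a warning; this mode exists for comparison and
targets a visibly different distribution in the tests.

Proposal scales (V_a and the random-walk steps) are tuned during burn-in
toward a 20–45% acceptance window and frozen afterwards, preserving detailed
balance of the post-burn-in chain.  Default schedule: 55,000 draws, 5,000
burn-in, thinning 10 (5,000 retained); the simulation study uses a shortened
11,000 / 1,000 / 10 schedule to stay desk-scale.  The λ–a ridge mixes
slowly: point estimates stabilize on the short schedule, but the Geweke
stationarity check needs roughly a 33,000-draw run, which is what the
convergence test uses.

Point estimates: posterior mean under squared-error loss; under the
generalized entropy loss with shape κ ≠ 0, [E(ψ^{−κ})]^{−1/κ}, so κ = −1
recovers the posterior mean, κ = −2 the precautionary-loss and κ = 1 the
entropy-loss estimates.  Reported uncertainty is the posterior standard
deviation of the retained draws.  The Geweke diagnostic compares the first
10% and last 50% window means, with the spectral density at zero estimated
by a lag-windowed autocovariance sum whose window is 4% of the segment
length (Bartlett weights).

## Goodness of fit

AkIC = 2·nll + 2k, CAkIC = AkIC + 2k(k+1)/(n−k−1), BsIC = 2·nll + k log n,
HQIC = 2·nll + 2k log log n.  EDF statistics use the plain A² and W² forms
(no small-sample modification); the Cramér–von Mises statistic is literally
the CVME objective evaluated at the fitted parameters (one shared
implementation).  The KS p-value comes from the asymptotic Kolmogorov
distribution at √n·D with parameters treated as known; when the parameters
were estimated from the same data this is optimistic, which the report notes
but does not correct, matching how such comparison tables are usually
produced.  The TTT transform returns the scaled total-time-on-test points;
concavity (curve above the diagonal) diagnoses an increasing failure rate.

## Simulation study

The study draws `reps` replicates per sample size from a sub-model at fixed
truth — defaults are the conditions of the published design: 1,000
replicates, n = 20, 25, …, 150, truths (1.3, 1.8, 1.5, 1.9) for the Fréchet
and (1.3, 2.3, 1.5) for the exponential sub-model — applies each requested
estimator, and reports average bias and MSE per parameter in a tidy
DataFrame.  Per-replicate seeds are derived deterministically from
(base_seed, n, j) and kept below 2³¹, so any cell can be reproduced in
isolation.  Replicates where an optimizer fails are dropped and counted; a
method failing on more than 20% of replicates at some n attaches a warning
to the result.  The classical arms use 3 optimizer starts by default (the
objectives are smooth enough there; the multi-start stability test justifies
this), and the Bayesian arms the shortened chain schedule.

The test suite runs reduced replications (200 replicates at n ∈ {20, 50,
150}) chosen so the whole default suite stays in the tens of minutes on one
CPU; they verify the qualitative findings (MSE decreasing in n for every
estimator and parameter; Bayes-SEL under informative priors no worse than
MLE) rather than any numeric table, since the source design published its
simulation results only as figures.

## What the synthetic data does and does not show

Fixtures emulate the two published applications by inverse-transform
sampling at the published fitted parameter values (101 aluminum-coupon
fatigue lifetimes, Fréchet sub-model; 63 glass-fibre strengths, exponential
sub-model).  The generator reproduces the fitted model exactly, so it
validates the estimation and goodness-of-fit machinery under correct
specification; it cannot exhibit model misspecification, measurement
rounding, or the finite-population quirks of the real datasets, so passing
tests say nothing about how well the family fits *other* real data.  The
classic datasets themselves are not bundled (provenance); loaders accept
user-supplied files at `data/aluminum_coupons.txt` and
`data/glass_fibres.txt`, and the real-data reproduction test activates
automatically when they are present.

## Known limitations

* No censoring or covariates; complete iid positive samples only.
* Bayesian inference is implemented for the Fréchet and exponential
  sub-models only (as in the source design).
* Moments of heavy-tailed configurations may genuinely diverge; the
  quadrature raises an infinite-moment error based on its own error
  estimate rather than proving divergence analytically.
* The KS p-value ignores parameter estimation (documented above).
* GEL point estimates require strictly positive draws, which the positive
  orthant guarantees unless a chain degenerates.
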