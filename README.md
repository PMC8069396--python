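# hlowg

Lifetime modelling with the **Type I half-logistic odd Weibull generated
(Type I HLOW-G)** family of distributions, for survival/reliability analysts
who need hazard shapes (increasing, decreasing, unimodal, bathtub) that
simple baselines cannot produce.

Given a baseline CDF G(x; φ) on (0, ∞) with odds ratio
t(x) = G/(1−G), the family applies an odd-Weibull layer (shape β > 0) and a
type I half-logistic layer (scale λ > 0):

    F(x; λ, β, φ) = (1 − e^{−λ t(x)^β}) / (1 + e^{−λ t(x)^β}) = tanh(λ t(x)^β / 2)

with density f = 2λβ g G^{β−1} (1−G)^{−(β+1)} e^{−λt^β} (1+e^{−λt^β})^{−2}
and hazard h = λβ g G^{β−1} (1−G)^{−(β+1)} (1+e^{−λt^β})^{−1}.

The package provides:

* six baselines (exponential, Rayleigh, Lindley, Weibull, Fréchet, Lomax)
  with numerically safe log-survival evaluation;
* cdf / pdf / hazard / survival / quantile / seeded inverse-transform
  sampling for any baseline;
* distributional summaries by direct quadrature: raw and central moments,
  octile skewness/kurtosis, MGF, incomplete moments, mean deviations,
  Bonferroni/Lorenz curves, probability weighted moments, (reversed)
  residual-life moments, Rényi/Shannon/Havrda–Charvát/Arimoto/Tsallis
  entropies, order-statistic densities;
* five estimation methods: maximum likelihood (with analytic score),
  ordinary and weighted least squares on the EDF, Cramér–von Mises minimum
  distance, and Bayesian estimation for the Fréchet/exponential sub-models
  via a corrected Metropolis-within-Gibbs sampler with Gamma priors and
  SEL/GEL (precautionary, entropy) point estimates;
* a goodness-of-fit battery (−logL, AkIC, CAkIC, BsIC, HQIC, AD, CvM, KS
  with p-value, TTT transform) and a bias/MSE Monte Carlo study harness.

See `docs/methods.md` for the model, the numerical choices and their
rationale, and known limitations.

## Worked example

Emulate the glass-fibre strength application (63 observations drawn from the
exponential sub-model at its published Bayes-SEL fit), then fit by maximum
likelihood from the command line:

```sh
hlowg rvs --baseline exponential --params 0.0019,0.9711,4.1595 -n 63 --seed 1 -o glass_emulated.txt
hlowg fit --data glass_emulated.txt --baseline exponential --method mle --starts 6 --seed 0
```

which prints (abridged):

```json
{
 "n": 63,
 "fit": {
  "method": "mle",
  "param_names": ["lam", "beta", "a"],
  "estimates": [0.001094, 1.169445, 3.714930],
  "standard_errors": [0.000972, 2.168680, 7.047127],
  "objective_value": -1.980866,
  "converged": true
 },
 "gof": {
  "AkIC": 2.038269, "BsIC": 8.467673,
  "AD": 0.154446, "CvM": 0.024377,
  "KS": 0.055196, "ks_pvalue": 0.990752
 }
}
```

Reading: the recovered (λ̂, β̂, â) = (0.0011, 1.17, 3.71) sits near the
generating values — exactly as near as this family's long likelihood ridge
allows (the large standard errors on β and a are real: quite different
parameter vectors give nearly the same CDF) — and the KS distance 0.055
with p ≈ 0.99 says the fitted CDF tracks the 63-point sample closely.

The same from Python:

```python
import hlowg

p = hlowg.HlowParams(0.0019, 0.9711, hlowg.make_baseline("exponential", [4.1595]))
rep = hlowg.central_measures(p)
print(rep.mean, rep.variance, rep.index_of_dispersion)
# 1.5218 0.0780 0.0513  -> under-dispersed, as a strength distribution should be
```

Theoretical descriptives of the Fréchet sub-model at the aluminum-coupon
fit (0.4696, 17.1055, 27.7908, 0.2562) come out as mean 131.277, variance
499.965, skewness −0.5725, kurtosis 3.3745 — an over-dispersed,
left-skewed lifetime distribution (index of dispersion 3.81).

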