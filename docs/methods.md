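# Methods

## Model

The package implements the DUS Topp–Leone-G family: a baseline CDF
`G(x; ξ)` is passed through the Topp–Leone generator
`H(x) = [1 − (1 − G(x))²]^ν` (shape `ν > 0`) and then the DUS transform
`F(x) = (e^{H(x)} − 1)/(e − 1)`.  The DUS layer is parameter-free; the
family therefore has exactly one parameter more than its baseline.  The
concrete model, DUS-TLE, uses the exponential CDF `G(x) = 1 − e^{−ρx}`
(rate `ρ > 0`, units 1/x), giving

    F(x; ν, ρ) = (exp[(1 − e^{−2ρx})^ν] − 1)/(e − 1),  x > 0.

All evaluation uses these closed forms.  Series expansions of the density
(power/binomial rearrangements) are deliberately not used as computation
paths: the closed form is exact, cheaper, and immune to the index-bookkeeping
errors such expansions invite.

Support conventions: `pdf(x) = 0` and `logpdf(x) = −∞` for `x ≤ 0`;
`ppf(1)` raises rather than returning `+∞`, so optimizers can never receive
a silent non-finite value.  For `ν < 1` the density diverges as `x → 0+`;
it is evaluated only at `x > 0`.

## Numerics

* `log(1 − e^{−t})` switches between `log(−expm1(−t))` (t < log 2) and
  `log1p(−e^{−t})`, the standard cancellation-free split.  This term is
  multiplied by `ν − 1` in the log-likelihood, so its accuracy matters.
* The survival function and hazard avoid the cancellation in `1 − F` by
  computing `1 − H = −expm1(ν log T)` directly; the hazard is assembled in
  log space and stays accurate even where `F` rounds to 1 in doubles
  (e.g. `2ρx ≈ 60`).
* Sampling is exact inverse-transform through the closed-form quantile
  `x_u = −log(1 − [log(1 + (e−1)u)]^{1/ν})/(2ρ)`, seeded via
  `numpy.random.default_rng`; no rejection constants, no tuning.
* Moments, MGF, Rényi entropy and order-statistic normalizations use
  adaptive quadrature (`scipy.integrate.quad`, relative tolerance 1e-10)
  on `(0, ppf(1 − 1e−12))`; the exponential tail makes the truncation
  negligible.  The MGF exists only for `t < 2ρ`; larger `t` raises.
* Skewness and kurtosis are the standardized moment ratios
  `μ₃/μ₂^{3/2}` and `μ₄/μ₂²` (non-excess) — the default convention where
  none is stated.

## Frequentist estimation

Seven estimators are minimized/maximized over `(log ν, log ρ)`, which
removes the positivity constraint and makes scale equivariance exact
(`x → cx` maps solutions to `(ν, ρ/c)`).  Each runs from a fixed 5-point
multi-start cross (`ν, ρ ∈ {0.25, 1, 4}` around (1, 1)) because the
distance objectives can be multimodal at small n, and the best optimum is
polished by Nelder–Mead at tight tolerances (1e-13 on the objective).
The ML path uses L-BFGS-B with the exact analytic score, re-derived by
differentiating the log-likelihood (the score printed in some references
for this family contains misprints; the implemented gradient is validated
against finite differences in the test suite, as are the exact CDF
partials used to check stationarity of the distance estimators).

Maximum product of spacings uses spacings of the fitted CDF at the order
statistics with `F(x₍₀₎) = 0`, `F(x₍ₙ₊₁₎) = 1`; a spacing collapsed by
tied observations is replaced by the density at the tied point (the
Cheng–Amin convention — both bundled datasets contain exact ties, so this
path is exercised by real data).  The Anderson–Darling objective is the
standard A² statistic; its affine-equivalent unnormalized form gives the
same argmin (tested).  Fitted CDF values are clamped to
`[1e−15, 1 − 1e−15]` before logs.

A caveat surfaced by testing: on noiseless "plotting position" data
`x_j = Q(j/(n+1))`, the minimum-distance estimators return the truth
essentially exactly, but ML and the right-tailed AD estimator carry an
O(1/n) construction offset (ML: 2.4% at n = 500, 0.7% at n = 2000) —
such data are bias-neutral only for estimators whose objective is built
from those plotting positions.

## Bayesian estimation

Independent gamma priors `ν ~ Gamma(p₁, q₁)`, `ρ ~ Gamma(p₂, q₂)`
(shape/rate), defaulting to shape 2, rate 1 — weakly informative with
prior mean 2 on both parameters; configurable.  The posterior is sampled
by Gaussian random-walk Metropolis on `(log ν, log ρ)` including the log
Jacobian.  Proposal SDs start at 0.2 and are rescaled every 200 burn-in
iterations by `exp(rate − 0.3)` toward a ~0.3 acceptance rate, then
frozen, so the retained chain is a valid fixed-kernel MH chain.  Defaults
M = 20,000 iterations with 5,000 burn-in; a split-R̂ helper is provided as
a convergence check (examples show R̂ ≈ 1.008 on the mortality data).

Point estimates from the retained draws: posterior mean (squared-error
loss); `−(1/η) log E[e^{−ηφ}]` (LINEX, computed via logsumexp so large
draws cannot overflow); `(E[φ^{−l}])^{−1/l}` (general entropy loss, a
posterior power mean; `l = −1` recovers the mean exactly).  Loss shapes
default to `η = ±0.5` and `l = ±0.5`, labelled explicitly — published
comparisons of this model family pair two settings per loss without
printing them, so these are package choices.  For the same reason (and
because the published Bayesian bias/RMSE columns behave inconsistently
with posterior concentration), the Bayesian pathway is validated by
property tests — seed determinism, posterior concentration within 5% of
the truth at n = 2000, error shrinking with n — rather than by
reproducing table values.

## Simulation harness

`run_scenario` draws datasets from the model by inverse transform and
refits each estimator on the *same* data per replicate (paired design;
child seeds are `SeedSequence(seed, spawn_key=(n, rep))`), which removes
dataset noise from between-method contrasts.  Failed or non-converged
fits are excluded and counted (`n_failed`), with a warning above 5%.
Bias, RMSE and MSE are reported with Monte-Carlo standard errors, so
results at different replication counts are comparable; the stored raw
estimates satisfy `RMSE² = bias² + variance` exactly.

Replication sizes: the package defaults to 2,000 replicates per cell
(the published design uses 10,000), and the test suite's cross-checks
against the published n = 200 comparison rows use 150–300 replicates —
in every case the 3×MC-SE band computed from the run itself is the
acceptance band, so smaller runs are honestly wider, not quietly looser.

Two conventions of the published comparison tables were identified by
recomputation and are important when reading results against them: the
column headed "RMSE" prints the **mean squared error** (our MSE column
matches it across methods; the literal RMSE is ~4–5× larger at n = 200),
and the bias column prints **|bias|** (the MPS estimator's bias is
negative; only its magnitude matches).  `SimTable` therefore carries
`bias`, `rmse` and `mse` side by side.

## Goodness of fit

`AIC = 2k + 2·NLL`, `CAIC = AIC + 2k(k+1)/(n−k−1)`,
`BIC = k log n + 2·NLL`, `HQIC = 2k log(log n) + 2·NLL` — the CAIC and
HQIC variants were selected because they reproduce the published
application tables exactly.  The KS p-value uses the asymptotic
Kolmogorov distribution with fitted parameters treated as known (no
Lilliefors/bootstrap correction) — this matches the published p-values,
and is optimistic in the usual way when parameters are estimated from the
same data.  Sample summary statistics use variance denominator n−1,
moment-ratio skewness/kurtosis with denominator n, and linear-interpolation
quartiles, which reproduce the published summary rows.

## Bundled data

`tfp_africa` (n = 37 total-factor-productivity values) and
`pwid_mortality` (n = 65 mortality rates) are embedded and
checksum-pinned.  Two recorded inconsistencies in their published
presentation: the summary table accompanying the productivity data prints
a mean of 1.677297 while the listed values average 1.6973 (the values are
authoritative here), and the mortality data's published W = 0.054 and
A = 0.351 do not follow from the listed values at the fitted MLE
(recomputation gives 0.0585 and 0.3804, while the same formulas reproduce
the productivity dataset's W and A exactly).  Tests assert the recomputed
values.

## What the synthetic data does and does not show

The generator produces i.i.d. draws from the model itself, so the
simulation study measures estimator behaviour *under correct
specification* — bias, efficiency, and their decay with n.  It says
nothing about robustness to contamination, censoring, rounding (the real
datasets are rounded to 2–3 digits), or dependence; none of those
features is emulated.  The likelihood assumes fully observed positive
values; there is no censored-data support.

## Known limitations

* KS/W/A p-values ignore parameter estimation (see above); model ranking
  by information criteria is unaffected.
* The generic generator accepts any baseline satisfying the `Baseline`
  contract, but only exponential and a Weibull test baseline are
  exercised; heavy-tailed baselines may need a different quadrature cutoff.
* Credible intervals are not implemented (point estimation only).
* MCMC is a single-chain sampler; the split-R̂ diagnostic is within-chain.
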