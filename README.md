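# dustl

Tools for the **DUS Topp–Leone family of lifetime distributions**, centred
on its exponential sub-model (DUS-TLE), for analysts who need a flexible
two-parameter model for positive, skewed, time-to-event-like data —
mortality rates, failure times, productivity indices — together with a
broad menu of estimators and honest model-comparison statistics.

## The model

Two CDF transformers are composed around a baseline CDF `G`:

* the Topp–Leone generator, `H(x) = [1 − (1 − G(x))²]^ν` with shape `ν > 0`;
* the DUS transform, `F(x) = (e^{H(x)} − 1)/(e − 1)`,

which adds shape flexibility without adding parameters beyond `ν`.  With an
exponential baseline `G(x) = 1 − e^{−ρx}` this collapses to the DUS-TLE
distribution

```
F(x; ν, ρ) = ( exp[(1 − e^{−2ρx})^ν] − 1 ) / (e − 1),   x > 0,  ν, ρ > 0
```

with closed-form density, hazard rate and quantile function.  For `ν > 1`
the density is unimodal with vanishing tails at both ends, and the hazard
can be increasing, bathtub-like or reversed-bathtub depending on `ν`.

The package provides:

* `dustl.distribution` — exact evaluation of the generic family and
  DUS-TLE (`cdf`, `pdf`, `logpdf`, `sf`, `hazard`, `ppf`), plus exact
  inverse-transform sampling;
* `dustl.properties` — moments, MGF, Rényi entropy and order-statistic
  densities by stable quadrature;
* `dustl.estimation` — seven estimators of `(ν, ρ)`: maximum likelihood,
  maximum product of spacings, least squares, weighted least squares,
  Cramér–von Mises, Anderson–Darling, right-tailed Anderson–Darling;
* `dustl.bayes` — random-walk Metropolis posterior sampling under gamma
  priors, with point estimates under squared-error, LINEX and general
  entropy losses;
* `dustl.gof` — NLL, AIC/CAIC/BIC/HQIC, KS (with asymptotic p-value),
  Cramér–von Mises `W` and Anderson–Darling `A`;
* `dustl.simulation` — a paired Monte-Carlo harness tabulating bias and
  (R)MSE of every estimator across sample sizes;
* `dustl.datasets` — two bundled, checksum-pinned application datasets.

## Worked example

```python
from dustl import fit_mle, evaluate_fit, load_dataset

ds = load_dataset("pwid_mortality")   # 65 mortality rates, people who inject drugs
r = fit_mle(ds.sample)
print(r.nu, r.rho)                    # 2.2929 0.3517
rep = evaluate_fit(ds.sample, r)
print(rep.aic, rep.ks, rep.ks_pvalue) # 243.104 0.081 0.783
```

The fitted shape `ν ≈ 2.29 > 1` says the mortality-rate distribution has an
interior mode rather than an exponential-style peak at zero; the KS
distance of 0.081 with p ≈ 0.78 means the fitted CDF is statistically
indistinguishable from the empirical one at this sample size.  On the
productivity data (`"tfp_africa"`, n = 37) the same call gives
`ν = 1.5484, ρ = 0.4679` with AIC 111.159 and KS p ≈ 0.93.

The `examples/` directory has one short narrative script per capability
(distribution basics, application fits, Bayesian estimation, the
Monte-Carlo study, moments/entropy).  A thin CLI mirrors the main entry
points:

```bash
dustl fit --data tfp_africa --method mle
dustl gof --data pwid_mortality --method mle
dustl sample --nu 1.75 --rho 2.75 -n 100 --seed 1 --out draws.csv
dustl simulate --scenario table2 --reps 2000 --methods mle --seed 1
```

## Notes

`docs/methods.md` documents the model, the numerical choices, the
simulation design (including the conventions the published-style
comparison tables use for bias and squared error), and known limitations.
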