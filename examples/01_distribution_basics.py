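"""Evaluate the DUS-TLE distribution and draw reproducible samples.

The DUS-TLE law has CDF F(x) = (exp[(1 - e^{-2 rho x})^nu] - 1)/(e - 1):
an exponential baseline sharpened by the Topp-Leone shape nu and the DUS
transform.  For nu > 1 the density is unimodal with an interior peak.
"""

import numpy as np

from dustl import DUSTLE

d = DUSTLE(nu=1.75, rho=2.75)

print(f"median lifetime:            {d.median():.4f}")
print(f"cdf at the median:          {d.cdf(d.median()):.6f}  (= 0.5 by construction)")
print(f"density at the median:      {float(d.pdf(d.median())):.4f}")
print(f"hazard rate at the median:  {float(d.hazard(d.median())):.4f}")

x = d.rvs(100_000, seed=42)
print(f"\n100,000 draws (seed 42): sample mean {x.mean():.4f}, sample sd {x.std(ddof=1):.4f}")

u = np.array([0.1, 0.5, 0.9])
print("\nquantile / CDF round trip:")
for ui, qi in zip(u, d.ppf(u)):
    print(f"  F(Q({ui:.1f})) = {float(d.cdf(qi)):.12f}")
# The round trip returns the probabilities exactly: sampling by inverting
# the closed-form quantile function is exact, not approximate.
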