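"""Goodness-of-fit and model-comparison statistics.

For one fitted distribution on one dataset this module computes the negative
log-likelihood and the four information criteria

    AIC  = 2k + 2 NLL
    CAIC = AIC + 2k(k+1)/(n-k-1)
    BIC  = k log n + 2 NLL
    HQIC = 2k log(log n) + 2 NLL

together with the Kolmogorov-Smirnov distance (asymptotic p-value with the
fitted parameters treated as known), the Cramer-von Mises statistic W and
the Anderson-Darling statistic A, all evaluated against the fitted CDF at
the order statistics.  Plain sample summary statistics round out the
module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .distribution import DUSTLE
from .estimation import Sample, fit, FitResult, ad_statistic_from_cdf

__all__ = [
    "GoFReport",
    "information_criteria",
    "ks_test",
    "cvm_statistic",
    "ad_statistic",
    "summary_stats",
    "evaluate_fit",
    "compare_table",
]

_CLAMP = 1e-15


@dataclass(frozen=True)
class GoFReport:
    """Model-comparison report for one fitted model on one dataset."""

    nll: float
    aic: float
    caic: float
    bic: float
    hqic: float
    ks: float
    ks_pvalue: float
    W: float
    A: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def information_criteria(nll: float, k: int, n: int) -> tuple:
    """(AIC, CAIC, BIC, HQIC) from the negative log-likelihood."""
    if k > 0 and n <= k + 1:
        raise ValueError("CAIC undefined: need n > k + 1")
    aic = 2.0 * k + 2.0 * nll
    caic = aic + (2.0 * k * (k + 1) / (n - k - 1) if k > 0 else 0.0)
    bic = k * math.log(n) + 2.0 * nll
    hqic = 2.0 * k * math.log(math.log(n)) + 2.0 * nll
    return aic, caic, bic, hqic


def _sorted_cdf(sample, cdf) -> tuple:
    xs = Sample.from_values(sample).sorted_values if not isinstance(sample, Sample) else sample.sorted_values
    return xs, np.asarray(cdf(xs), dtype=float)


def ks_test(sample, cdf) -> tuple:
    """Two-sided KS statistic and asymptotic p-value against a fitted CDF.

    D = max_j max(j/n - F_(j), F_(j) - (j-1)/n); the p-value comes from the
    Kolmogorov limiting distribution of sqrt(n) D with parameters treated
    as known (no Lilliefors-type correction).
    """
    xs, F = _sorted_cdf(sample, cdf)
    n = xs.size
    j = np.arange(1, n + 1)
    D = float(max((j / n - F).max(), (F - (j - 1) / n).max()))
    return D, float(kolmogorov(math.sqrt(n) * D))


def cvm_statistic(sample, cdf) -> float:
    """Cramer-von Mises W = 1/(12n) + sum (F_(j) - (2j-1)/(2n))^2."""
    xs, F = _sorted_cdf(sample, cdf)
    n = xs.size
    r = F - (2 * np.arange(1, n + 1) - 1) / (2 * n)
    return float(1.0 / (12 * n) + np.sum(r * r))


def ad_statistic(sample, cdf) -> float:
    """Anderson-Darling A^2 against a fully specified CDF."""
    _, F = _sorted_cdf(sample, cdf)
    return ad_statistic_from_cdf(np.clip(F, _CLAMP, 1 - _CLAMP))


def evaluate_fit(sample, result_or_params, k: int = 2) -> GoFReport:
    """Full GoF report for DUS-TLE parameters on a sample.

    ``result_or_params`` is a FitResult or a (nu, rho) pair; ``k`` is the
    number of fitted parameters charged by the information criteria.
    """
    if isinstance(result_or_params, FitResult):
        nu, rho = result_or_params.nu, result_or_params.rho
    else:
        nu, rho = result_or_params
    s = sample if isinstance(sample, Sample) else Sample.from_values(sample)
    dist = DUSTLE(nu, rho)
    nll = -float(np.sum(dist.logpdf(s.sorted_values)))
    aic, caic, bic, hqic = information_criteria(nll, k, s.n)
    D, p = ks_test(s, dist.cdf)
    W = cvm_statistic(s, dist.cdf)
    A = ad_statistic(s, dist.cdf)
    return GoFReport(nll, aic, caic, bic, hqic, D, p, W, A, k, s.n)


def compare_table(reports: dict) -> pd.DataFrame:
    """Assemble reports into a comparison table, one model per row.

    Columns follow the conventional order NLL, AIC, CAIC, BIC, HQIC, W, A,
    KS, p-value.
    """
    cols = ["nll", "aic", "caic", "bic", "hqic", "W", "A", "ks", "ks_pvalue"]
    rows = {name: {c: getattr(r, c) for c in cols} for name, r in reports.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[cols].rename_axis("model")


def summary_stats(sample) -> dict:
    """Descriptive statistics of a sample.

    Variance uses denominator n-1; skewness m3/m2^{3/2} and kurtosis
    m4/m2^2 use central moments with denominator n (non-excess kurtosis);
    quartiles use linear interpolation; se is sd/sqrt(n).
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    n = x.size
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    sd = math.sqrt(var)
    m2 = float(x.var(ddof=0))
    d = x - mean
    if m2 == 0:
        skew = kurt = math.nan
    else:
        skew = float(np.mean(d**3) / m2**1.5)
        kurt = float(np.mean(d**4) / m2**2)
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": mean,
        "var": var,
        "sd": sd,
        "min": float(x.min()),
        "max": float(x.max()),
        "iqr": float(q75 - q25),
        "skewness": skew,
        "kurtosis": kurt,
        "se": sd / math.sqrt(n),
        "range": float(x.max() - x.min()),
        "n": n,
    }
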