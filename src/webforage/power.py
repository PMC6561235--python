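"""Exact power for detecting a Pearson correlation under bivariate
normality, via Fisher's (1915) density of the sample correlation
coefficient. Used for the a-priori sample-size computation."""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats


def sample_correlation_pdf(r, rho: float, n: int):
    """Density of the sample correlation r for true correlation rho and
    sample size n (bivariate normal population)."""
    r = np.asarray(r, dtype=float)
    lognorm = (np.log(n - 2) + special.gammaln(n - 1)
               - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5))
    logf = (lognorm + (n - 1) / 2 * np.log1p(-rho ** 2)
            + (n - 4) / 2 * np.log1p(-r ** 2)
            - (n - 1.5) * np.log1p(-rho * r))
    return np.exp(logf) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def correlation_power(n: int, rho: float, alpha: float = 0.05) -> float:
    """Power of the two-sided t-test of rho = 0 at sample size n."""
    if n < 4:
        raise ValueError("need n >= 4")
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    rcrit = tcrit / np.sqrt(n - 2 + tcrit ** 2)
    lo, _ = integrate.quad(sample_correlation_pdf, -1, -rcrit, args=(rho, n))
    hi, _ = integrate.quad(sample_correlation_pdf, rcrit, 1, args=(rho, n))
    return float(lo + hi)


def min_n_for_correlation(rho: float = 0.3, power: float = 0.8,
                          alpha: float = 0.05, n_max: int = 10000) -> int:
    """Smallest n whose exact power reaches the target."""
    for n in range(5, n_max + 1):
        if correlation_power(n, rho, alpha) >= power:
            return n
    raise RuntimeError("power target not reached within n_max")


__all__ = ["sample_correlation_pdf", "correlation_power", "min_n_for_correlation"]
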