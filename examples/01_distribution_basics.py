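"""Dagum distribution basics: CDF, density, hazard, quantiles, sampling.

The Dagum law F(t) = (1 + lam * t**-theta)**-beta is a flexible heavy-tailed
lifetime model; its hazard can be decreasing or upside-down bathtub shaped.
"""

import numpy as np

from dagumcens import DagumParams, cdf, hazard, pdf, quantile, rvs

params = DagumParams(theta=2.0, beta=2.0, lam=1.0)

print("F(1)      =", cdf(1.0, params), " (probability of failure by t = 1)")
print("f(1)      =", pdf(1.0, params), " (density at t = 1)")
print("h(1)      =", hazard(1.0, params), " (instantaneous failure rate)")
print("median    =", quantile(0.5, params))
print("90th pct  =", quantile(0.9, params))

x = rvs(params, 100_000, seed=1)
print("sample mean of 1e5 draws =", round(x.mean(), 4), " (theta > 1, so the mean exists)")
print("sample median            =", round(np.median(x), 4), " vs quantile(0.5) above")
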