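"""Simulate a progressively type-I interval-censored sample and fit it.

n = 1000 units are inspected at 5 pre-scheduled times (the true-law
quantiles of 0.15 ... 0.95); at each inspection a fixed fraction of the
survivors is withdrawn.  Only the per-interval failure and removal counts
are observed.  The MLE maximises the grouped-data likelihood with an
analytic score; Wald intervals come from the inverse observed information.
"""

import numpy as np

from dagumcens import DagumParams, InspectionScheme, fit_mle, quantile, simulate

truth = DagumParams(2.0, 2.0, 1.0)
times = quantile(np.array([0.15, 0.35, 0.55, 0.75, 0.95]), truth)
scheme = InspectionScheme(times, removal_props=(0.0, 0.2, 0.5, 0.75, 1.0))

data = simulate(truth, n=1000, scheme=scheme, seed=7)
print("inspection times :", np.round(times, 3))
print("failures  D_j    :", data.failures)
print("removals  R_j    :", data.removals, " (sum D + sum R =", data.n, ")")

res = fit_mle(data, level=0.95)
print("\nconverged:", res.converged, " log-likelihood:", round(res.loglik_at_max, 2))
for name in ("theta", "beta", "lam"):
    lo, hi = res.wald_intervals[name]
    print(f"{name:>5}: estimate {getattr(res.estimates, name):6.3f}   "
          f"95% Wald [{lo:6.3f}, {hi:6.3f}]   (truth {getattr(truth, name)})")
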