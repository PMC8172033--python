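"""Choosing inspection times before running the experiment.

Given planning values of the parameters and a budget of m inspections, the
expected information of the plan is built from the mean failure/removal
recursion; the trace criterion trace(I^-1) (sum of asymptotic variances) or
the quantile-variance measure I_w is then minimised over the time grid.
Three inspections are the minimum that identifies all three parameters.
"""

import numpy as np

from dagumcens import DagumParams, optimize_scheme, quantile_variance

planning = DagumParams(2.0, 2.0, 1.0)

for m in (3, 4, 5):
    ev = optimize_scheme(planning, n=50, m=m, criterion="trace")
    print(f"m = {m}: optimal times {np.round(ev.scheme.times, 3)}  "
          f"trace(I^-1) = {ev.criterion_value:.4f}")

ev3 = optimize_scheme(planning, n=50, m=3, criterion="I_w")
print(f"\nI_w-optimal (uniform weight over p): times {np.round(ev3.scheme.times, 3)}  "
      f"I_w = {ev3.criterion_value:.4f}")

v = quantile_variance(planning, ev3.scheme, 50, p=0.5)
print("asymptotic variance of the estimated median under that plan:", round(v, 4))
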