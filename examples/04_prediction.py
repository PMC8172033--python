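"""Bayesian prediction of future order statistics.

One-sample: the experiment continues — given the 20th failure of 30 units
occurred at time t_r, predict the time of the 21st.  Two-sample: predict
the 5th smallest lifetime in an independent future batch of 12 units.
Both average the conditional order-statistic law over posterior draws.
"""

import numpy as np

from dagumcens import (
    DagumParams, InspectionScheme, PriorSpec, one_sample_predict, quantile,
    sample_posterior, simulate, two_sample_predict,
)

truth = DagumParams(2.0, 2.0, 1.0)
times = quantile(np.array([0.15, 0.35, 0.55, 0.75, 0.95]), truth)
data = simulate(truth, 500, InspectionScheme(times, (0, 0, 0, 0, 1)), seed=5)
draws = sample_posterior(data, PriorSpec.noninformative(), n_iter=4_000, burn_in=2_000, seed=9)
thin = draws.draws[::10]  # 200 draws are plenty for the predictive average

one = one_sample_predict(thin, s=1, r=20, n=30, t_r=1.1, level=0.95)
print("one-sample: next failure after t_r = 1.1 (20 of 30 failed)")
print("  point predictor :", round(one.point, 4))
print("  predictive median:", round(one.median, 4))
print("  95% bounds      :", np.round(one.bounds, 4))

two = two_sample_predict(thin, r=5, m_future=12, level=0.95)
print("\ntwo-sample: 5th order statistic of a future batch of 12")
print("  point predictor :", round(two.point, 4))
print("  95% bounds      :", np.round(two.bounds, 4))
print("\nBounds solve P(Y <= L) = 0.025 and P(Y <= U) = 0.975 on the predictive CDF.")
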