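"""Optimal inspection-time design for progressive type-I interval censoring.

Before any data exist, the information an inspection plan carries about the
parameters is measured through the expected information matrix I(phi):
expected per-interval failure/removal counts (the deterministic mean
recursion of the censoring plan) plugged into the observed-information
formulas.  Two design criteria are offered:

* ``trace`` — trace(I^{-1}), the sum of asymptotic parameter variances;
* ``I_w``  — the weighted average over p of the delta-method asymptotic
  variance of the plug-in quantile estimator t_p-hat,
  integral_0^1 V_p w(p) dp with V_p = g_p' I^{-1} g_p and g_p the gradient
  of the quantile t_p in (theta, beta, lam).

Times are optimised on the gap scale (log of the first time and of each
increment), which keeps every candidate grid strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, optimize

from .censoring import InspectionScheme, expected_counts
from .distribution import DagumParams, quantile
from .likelihood import LikelihoodWorkspace

__all__ = [
    "DesignEvaluation",
    "quantile_gradient",
    "expected_information",
    "quantile_variance",
    "info_measure",
    "optimize_scheme",
]


@dataclass
class DesignEvaluation:
    scheme: InspectionScheme
    criterion_name: str
    criterion_value: float
    info_matrix: np.ndarray
    converged: bool = True


def quantile_gradient(p: float, params: DagumParams) -> np.ndarray:
    """Gradient of t_p = ((p**(-1/beta) - 1)/lam)**(-1/theta) in (theta, beta, lam)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    th, b, lam = params.theta, params.beta, params.lam
    tp = float(quantile(p, params))
    e = np.expm1(-np.log(p) / b)  # p**(-1/b) - 1
    logA = np.log(e) - np.log(lam)
    d_th = tp * logA / th**2
    # d(logA)/d(beta) = p^{-1/b} log(p) / (b^2 * e)
    dlogA_db = (e + 1.0) * np.log(p) / (b**2 * e)
    d_b = -(tp / th) * dlogA_db
    d_lam = tp / (th * lam)
    return np.array([d_th, d_b, d_lam])


def expected_information(params: DagumParams, scheme: InspectionScheme, n: float) -> np.ndarray:
    """Pre-data information: expected counts plugged into the observed-
    information formulas (the multinomial expected information)."""
    ed, er = expected_counts(params, n, scheme)
    ws = LikelihoodWorkspace((np.asarray(scheme.times), ed, er))
    _, _, h = ws.value_grad_hess(params.theta, params.beta, params.lam)
    return -h


def _inv_info(info: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(info)
    if np.min(w) <= 1e-12 * max(np.max(w), 1.0):
        i = int(np.argmin(w))
        raise np.linalg.LinAlgError(
            "information matrix is singular; non-identified direction "
            f"(theta, beta, lam) ~ {np.round(v[:, i], 4)}"
        )
    return (v / w) @ v.T


def quantile_variance(
    params: DagumParams,
    scheme: InspectionScheme,
    n: float,
    p: float,
    info: np.ndarray | None = None,
) -> float:
    """Delta-method asymptotic variance of the plug-in quantile t_p-hat:
    g_p' I^{-1}(phi) g_p with the expected information of the plan."""
    if info is None:
        info = expected_information(params, scheme, n)
    g = quantile_gradient(p, params)
    return float(g @ _inv_info(info) @ g)


def info_measure(
    params: DagumParams,
    scheme: InspectionScheme,
    n: float,
    weight: Callable | None = None,
    eps: float = 1e-4,
    check_weight: bool = True,
) -> float:
    """Quantile-variance information measure I_w = integral V_p w(p) dp.

    ``weight`` defaults to the uniform weight w(p) = 1; any supplied weight
    must integrate to 1 over (0, 1) (checked numerically).  The integrand can
    diverge as p -> 0 or 1, so integration runs over [eps, 1-eps] with the
    truncation level reported via the ``eps`` argument.
    """
    if weight is None:
        w = lambda p: 1.0
    else:
        w = weight
        if check_weight:
            total, _ = integrate.quad(w, 0.0, 1.0, limit=200)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"weight must integrate to 1 on (0,1); got {total:.6g}")
    info = expected_information(params, scheme, n)
    inv = _inv_info(info)

    def integrand(p):
        g = quantile_gradient(p, params)
        return float(g @ inv @ g) * w(p)

    val, _ = integrate.quad(integrand, eps, 1.0 - eps, limit=400)
    return val


def _criterion_value(params, times, props, n, criterion, weight, eps):
    scheme = InspectionScheme(times, props)
    if criterion == "trace":
        info = expected_information(params, scheme, n)
        return float(np.trace(_inv_info(info))), info
    info = expected_information(params, scheme, n)
    val = info_measure(params, scheme, n, weight=weight, eps=eps, check_weight=False)
    return val, info


def optimize_scheme(
    params: DagumParams,
    n: float,
    m: int,
    criterion: str = "trace",
    bounds: tuple | None = None,
    removal_props=None,
    weight: Callable | None = None,
    eps: float = 1e-4,
) -> DesignEvaluation:
    """Choose inspection times t_1 < ... < t_m minimising a design criterion.

    Removal proportions are design inputs held fixed (default: no
    intermediate removals, terminal removal of all survivors).  The search
    runs Nelder-Mead on (log t_1, log gap_2, ..., log gap_m) from several
    quantile-spaced starting grids; ``bounds = (t_lo, t_hi)`` constrains all
    times to that window through a smooth penalty.
    """
    if m < 2:
        raise ValueError("need at least m = 2 inspection times")
    if criterion not in ("trace", "I_w"):
        raise ValueError("criterion must be 'trace' or 'I_w'")
    props = tuple(removal_props) if removal_props is not None else (0.0,) * (m - 1) + (1.0,)
    if len(props) != m:
        raise ValueError("removal_props must have length m")

    def objective(x):
        times = np.cumsum(np.exp(x))
        pen = 0.0
        if bounds is not None:
            lo, hi = bounds
            if times[0] < lo:
                pen += 1e4 * (lo - times[0]) ** 2
                times = times + (lo - times[0])
            if times[-1] > hi:
                pen += 1e4 * (times[-1] - hi) ** 2
                times = times * (hi / times[-1])
        try:
            val, _ = _criterion_value(params, times, props, n, criterion, weight, eps)
        except (np.linalg.LinAlgError, ValueError):
            return 1e300
        return val + pen

    starts = []
    for probs in (
        np.linspace(0.1, 0.9, m),
        np.linspace(0.05, 0.6, m),
        np.linspace(0.3, 0.98, m),
    ):
        t0 = quantile(probs, params)
        gaps = np.diff(np.concatenate(([0.0], t0)))
        starts.append(np.log(np.clip(gaps, 1e-8, None)))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res

    times = np.cumsum(np.exp(best.x))
    if bounds is not None:
        lo, hi = bounds
        if times[0] < lo:
            times = times + (lo - times[0])
        if times[-1] > hi:
            times = times * (hi / times[-1])
    val, info = _criterion_value(params, times, props, n, criterion, weight, eps)
    scheme = InspectionScheme(times, props)
    return DesignEvaluation(
        scheme=scheme,
        criterion_name=criterion,
        criterion_value=val,
        info_matrix=info,
        converged=bool(best.success) and best.fun < 1e299,
    )
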