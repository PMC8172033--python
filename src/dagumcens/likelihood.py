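"""Likelihood inference for progressively type-I interval-censored Dagum data.

The grouped-data log-likelihood is

    l(phi) = sum_j [ D_j log(F(t_j) - F(t_{j-1})) + R_j log(1 - F(t_j)) ],

with t_0 = 0 and phi = (theta, beta, lam).  Both the score vector and the
observed information matrix are assembled from closed-form first and second
derivatives of the Dagum CDF in the parameters, so the maximiser runs a
quasi-Newton search with an exact gradient and the Wald covariance is the
inverse negative Hessian at the optimum.

The parametrisation used internally is log(theta), log(beta), log(lam):
positivity comes for free and the chain rule maps the analytic score onto
the transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .censoring import CensoredDataset
from .distribution import DagumParams

__all__ = [
    "MLEResult",
    "loglik",
    "score",
    "observed_information",
    "fit_mle",
    "LikelihoodWorkspace",
]


def _cdf_and_derivs(theta: float, beta: float, lam: float, t: np.ndarray):
    """CDF value, gradient and Hessian in (theta, beta, lam) at each time.

    Everything is routed through log(v) with v = lam * t**(-theta) and
    log(z) = log1p(v), so the pieces stay finite for extreme shapes.  At
    t = 0 the CDF and all of its parameter derivatives vanish by continuity.

    Returns
    -------
    F : (k,) CDF values
    S : (k,) survival values, computed via expm1 (accurate near F = 1)
    G : (3, k) gradient of F per time point
    H : (3, 3, k) Hessian of F per time point
    """
    t = np.asarray(t, dtype=float)
    k = t.shape[0]
    F = np.zeros(k)
    S = np.ones(k)
    G = np.zeros((3, k))
    H = np.zeros((3, 3, k))
    pos = t > 0
    if not np.any(pos):
        return F, S, G, H
    tp = t[pos]
    L = np.log(tp)
    logv = np.log(lam) - theta * L
    lz = np.logaddexp(0.0, logv)  # log(1 + v)
    Fp = np.exp(-beta * lz)
    Sp = -np.expm1(-beta * lz)
    A1 = np.exp(logv - (beta + 1.0) * lz)  # v (1+v)^{-beta-1}
    A2 = np.exp(logv - (beta + 2.0) * lz)  # v (1+v)^{-beta-2}
    A2v = np.exp(2.0 * logv - (beta + 2.0) * lz)  # v^2 (1+v)^{-beta-2}

    F_th = beta * L * A1
    F_b = -lz * Fp
    F_la = -(beta / lam) * A1

    F_thth = -beta * L * L * (A2 - beta * A2v)
    F_thb = L * A1 * (1.0 - beta * lz)
    F_thla = (beta * L / lam) * (A2 - beta * A2v)
    F_bb = lz * lz * Fp
    F_bla = (A1 / lam) * (beta * lz - 1.0)
    F_lala = (beta * (beta + 1.0) / lam**2) * A2v

    F[pos], S[pos] = Fp, Sp
    G[0, pos], G[1, pos], G[2, pos] = F_th, F_b, F_la
    H[0, 0, pos] = F_thth
    H[0, 1, pos] = H[1, 0, pos] = F_thb
    H[0, 2, pos] = H[2, 0, pos] = F_thla
    H[1, 1, pos] = F_bb
    H[1, 2, pos] = H[2, 1, pos] = F_bla
    H[2, 2, pos] = F_lala
    return F, S, G, H


class LikelihoodWorkspace:
    """Pre-extracted arrays for one dataset, for repeated likelihood evaluation.

    Holds the inspection grid (with the leading t_0 = 0), the failure and
    removal counts, and offers value / value+gradient / full-derivative
    evaluations.  Counts may be real-valued: the design module plugs expected
    counts into the same formulas to build pre-data information.
    """

    def __init__(self, data):
        if isinstance(data, CensoredDataset):
            times = np.asarray(data.scheme.times, dtype=float)
            D = np.asarray(data.failures, dtype=float)
            R = np.asarray(data.removals, dtype=float)
        else:  # (times, D, R) triple with real-valued counts
            times, D, R = (np.asarray(x, dtype=float) for x in data)
            order = np.argsort(times)  # storage order of rows is immaterial
            times, D, R = times[order], D[order], R[order]
        self.times = times
        self.grid = np.concatenate(([0.0], times))
        self.D = D
        self.R = R
        self.n_total = float(D.sum() + R.sum())

    # -- fast value-only path (used heavily by the MCMC sampler) --
    def value(self, theta: float, beta: float, lam: float) -> float:
        logv = np.log(lam) - theta * np.log(self.times)
        lz = np.logaddexp(0.0, logv)
        S = -np.expm1(-beta * lz)
        S_full = np.concatenate(([1.0], S))
        U = S_full[:-1] - S_full[1:]  # F(t_j) - F(t_{j-1})
        ll = 0.0
        with np.errstate(divide="ignore"):
            d_mask = self.D > 0
            if np.any(d_mask):
                if np.any(U[d_mask] <= 0.0):
                    return -np.inf
                ll += float(self.D[d_mask] @ np.log(U[d_mask]))
            r_mask = self.R > 0
            if np.any(r_mask):
                if np.any(S[r_mask] <= 0.0):
                    return -np.inf
                ll += float(self.R[r_mask] @ np.log(S[r_mask]))
        return ll

    def value_grad_hess(self, theta: float, beta: float, lam: float):
        """Log-likelihood, score 3-vector and Hessian 3x3 matrix."""
        F, S, G, H = _cdf_and_derivs(theta, beta, lam, self.grid)
        U = S[:-1] - S[1:]  # equals F[1:] - F[:-1], stable near F ~ 1
        GU = G[:, 1:] - G[:, :-1]
        HU = H[:, :, 1:] - H[:, :, :-1]
        Sj = S[1:]
        GS = -G[:, 1:]
        HS = -H[:, :, 1:]

        ll = 0.0
        grad = np.zeros(3)
        hess = np.zeros((3, 3))
        d_mask = self.D > 0
        r_mask = self.R > 0
        if np.any(d_mask & (U <= 0.0)) or np.any(r_mask & (Sj <= 0.0)):
            return -np.inf, np.full(3, np.nan), np.full((3, 3), np.nan)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            if np.any(d_mask):
                D, Ud = self.D[d_mask], U[d_mask]
                GUd, HUd = GU[:, d_mask], HU[:, :, d_mask]
                ll += float(D @ np.log(Ud))
                grad += (GUd * (D / Ud)).sum(axis=1)
                hess += np.einsum("k,ijk->ij", D / Ud, HUd)
                hess -= np.einsum("k,ik,jk->ij", D / Ud**2, GUd, GUd)
            if np.any(r_mask):
                R, Sr = self.R[r_mask], Sj[r_mask]
                GSr, HSr = GS[:, r_mask], HS[:, :, r_mask]
                ll += float(R @ np.log(Sr))
                grad += (GSr * (R / Sr)).sum(axis=1)
                hess += np.einsum("k,ijk->ij", R / Sr, HSr)
                hess -= np.einsum("k,ik,jk->ij", R / Sr**2, GSr, GSr)
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(hess))):
            # a count sits on an interval whose probability underflowed
            return -np.inf, np.full(3, np.nan), np.full((3, 3), np.nan)
        hess = (hess + hess.T) / 2.0  # exact symmetry (einsum is bit-asymmetric)
        return ll, grad, hess


def _as_workspace(data) -> LikelihoodWorkspace:
    return data if isinstance(data, LikelihoodWorkspace) else LikelihoodWorkspace(data)


def loglik(params: DagumParams, data) -> float:
    """Interval-censored log-likelihood; -inf when a positive count sits on a
    zero-probability interval."""
    return _as_workspace(data).value(params.theta, params.beta, params.lam)


def score(params: DagumParams, data) -> np.ndarray:
    """Analytic score (dl/dtheta, dl/dbeta, dl/dlam)."""
    _, g, _ = _as_workspace(data).value_grad_hess(params.theta, params.beta, params.lam)
    return g


def observed_information(params: DagumParams, data) -> np.ndarray:
    """Observed information: negative Hessian of the log-likelihood.

    Symmetric by construction.  With real-valued expected counts in place of
    the observed D_j, R_j this is the pre-data (expected) information.
    """
    _, _, h = _as_workspace(data).value_grad_hess(params.theta, params.beta, params.lam)
    return -h


@dataclass
class MLEResult:
    """Maximum-likelihood fit with Wald inference.

    ``vcov`` is the inverse observed information at the optimum (None when
    the information matrix is singular), ``wald_intervals`` maps parameter
    name -> (lower, upper) at the requested level.
    """

    estimates: DagumParams
    vcov: np.ndarray | None
    wald_intervals: dict
    converged: bool
    loglik_at_max: float
    level: float
    n_iter: int = 0

    @property
    def se(self) -> dict:
        if self.vcov is None:
            return {k: np.nan for k in ("theta", "beta", "lam")}
        d = np.sqrt(np.clip(np.diag(self.vcov), 0.0, np.inf))
        return dict(zip(("theta", "beta", "lam"), d))


def _loggrad(ws: LikelihoodWorkspace, x: np.ndarray):
    """Negative log-likelihood with gradient and Hessian in log-parameters."""
    phi = np.exp(x)
    ll, g, h = ws.value_grad_hess(phi[0], phi[1], phi[2])
    if not np.isfinite(ll):
        return np.inf, np.full(3, np.nan), np.full((3, 3), np.nan)
    gx = g * phi
    hx = h * np.outer(phi, phi) + np.diag(gx)
    return -ll, -gx, -hx


def _default_init(ws: LikelihoodWorkspace) -> DagumParams:
    # theta = beta = 1; pick lam so the model median hits the midpoint of the
    # interval containing the median failure (with theta = beta = 1 the
    # median is exactly lam).
    D = ws.D
    total = D.sum()
    if total <= 0:
        mid = float(np.median(ws.times))
        return DagumParams(1.0, 1.0, mid)
    cum = np.cumsum(D)
    j = int(np.searchsorted(cum, total / 2.0))
    j = min(j, len(ws.times) - 1)
    lo = ws.grid[j]
    hi = ws.times[j]
    mid = 0.5 * (lo + hi)
    if mid <= 0:
        mid = hi / 2.0
    return DagumParams(1.0, 1.0, mid)


def fit_mle(
    data,
    init: DagumParams | None = None,
    level: float = 0.95,
    truncate_at_zero: bool = False,
) -> MLEResult:
    """Maximise the interval-censored log-likelihood.

    Optimises over log-parameters with the analytic score (BFGS); falls back
    to a deterministic 3x3x3 multi-start grid around the default start when
    the first attempt fails to converge.  Wald intervals are
    estimate +/- z_{tau/2} * SE, untruncated by default.
    """
    ws = _as_workspace(data)
    if ws.D.sum() <= 0:
        raise ValueError("dataset has no observed failures; the MLE is not identifiable")

    def negloglik_and_grad(x):
        th, b, la = np.exp(x)
        ll, g, _ = ws.value_grad_hess(th, b, la)
        if not np.isfinite(ll):
            return 1e300, np.zeros(3)
        # chain rule: d/d log(phi) = phi * d/d phi
        return -ll, -g * np.exp(x)

    starts = []
    base = init if init is not None else _default_init(ws)
    starts.append(base.as_array())
    if init is None:
        for f1 in (0.5, 1.0, 2.0):
            for f2 in (0.5, 1.0, 2.0):
                for f3 in (0.5, 1.0, 2.0):
                    cand = base.as_array() * np.array([f1, f2, f3])
                    starts.append(cand)

    def polish(x):
        """Newton refinement on the log scale with step damping; BFGS often
        stops with 'precision loss' while the analytic Newton step can still
        push the score to ~1e-10."""
        f, gx, hx = _loggrad(ws, x)
        for _ in range(30):
            if not np.isfinite(f) or np.linalg.norm(gx, np.inf) < 1e-10 * max(1.0, ws.n_total):
                break
            try:
                step = np.linalg.solve(hx, gx)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            t = 1.0
            for _ in range(30):
                f_new, g_new, h_new = _loggrad(ws, x - t * step)
                if np.isfinite(f_new) and f_new < f:
                    x, f, gx, hx = x - t * step, f_new, g_new, h_new
                    break
                t /= 2.0
            else:
                break
        return x, f, gx

    # a small score relative to the sample size certifies stationarity
    def stationary(gx):
        return np.all(np.isfinite(gx)) and np.linalg.norm(gx, np.inf) <= 1e-6 * max(1.0, ws.n_total)

    best = None
    for s_idx, start in enumerate(starts):
        res = optimize.minimize(
            negloglik_and_grad,
            np.log(start),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        x_p, f_p, g_p = polish(res.x)
        cand = (f_p, x_p, g_p)
        if best is None or cand[0] < best[0] - 1e-10:
            best = cand
        if s_idx == 0 and stationary(best[2]):
            break  # default start reached a stationary point; skip the grid

    x = best[1]
    est = DagumParams(*np.exp(x))
    ll, g, h = ws.value_grad_hess(est.theta, est.beta, est.lam)
    info = -h
    vcov = None
    try:
        eigvals = np.linalg.eigvalsh(info)
        # numerically singular information (e.g. the optimum ran up the
        # beta -> inf, lam -> 0 Frechet ridge): no usable curvature
        if eigvals[0] <= 0 or eigvals[-1] / eigvals[0] > 1e12:
            raise np.linalg.LinAlgError("singular observed information")
        vcov = np.linalg.inv(info)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            vcov = None
    except np.linalg.LinAlgError:
        vcov = None

    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    intervals = {}
    names = ("theta", "beta", "lam")
    for i, name in enumerate(names):
        val = getattr(est, name)
        if vcov is not None:
            half = z * np.sqrt(max(vcov[i, i], 0.0))
            lo, hi = val - half, val + half
            if truncate_at_zero:
                lo = max(lo, 0.0)
        else:
            lo, hi = np.nan, np.nan
        intervals[name] = (lo, hi)

    converged = stationary(best[2]) and np.isfinite(ll)
    return MLEResult(
        estimates=est,
        vcov=vcov,
        wald_intervals=intervals,
        converged=converged,
        loglik_at_max=float(ll),
        level=level,
    )
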