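"""Dagum (Burr III with scale) distribution primitives.

The Dagum distribution is a heavy-tailed positive lifetime law with CDF

    F(t; theta, beta, lam) = (1 + lam * t**(-theta))**(-beta),   t > 0,

where ``theta`` and ``beta`` are shape parameters and ``lam`` is a scale
parameter (in units of t**theta).  It accommodates decreasing, unimodal and
upside-down-bathtub hazard shapes, which makes it a flexible parametric
model for failure-time and consumption data.

All tail-sensitive quantities are evaluated through ``log1p``/``expm1`` so
that the CDF and its complement stay accurate for extreme arguments — the
likelihood code calls these kernels at wild parameter proposals during MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DagumParams",
    "cdf",
    "logcdf",
    "pdf",
    "logpdf",
    "survival",
    "logsf",
    "hazard",
    "quantile",
    "rvs",
]


@dataclass(frozen=True)
class DagumParams:
    """Parameter vector (theta, beta, lam), all strictly positive.

    Attributes
    ----------
    theta : float
        Tail-index shape parameter; the upper tail decays like t**(-theta).
    beta : float
        Second shape parameter controlling behaviour near the origin.
    lam : float
        Scale parameter, in units of t**theta.
    """

    theta: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("theta", "beta", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.beta, self.lam], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "DagumParams":
        return cls(float(x[0]), float(x[1]), float(x[2]))


def _check_t(t, allow_zero: bool):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if allow_zero:
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
    else:
        if np.any(t <= 0):
            raise ValueError("t must be strictly positive")
    return t


def logcdf(t, params: DagumParams):
    """log F(t) = -beta * log1p(lam * t**(-theta)); t = 0 maps to -inf."""
    t = _check_t(t, allow_zero=True)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.full(t.shape, -np.inf)
    pos = t > 0
    with np.errstate(over="ignore"):
        # log(lam * t**-theta) computed in log space to dodge overflow of t**-theta
        log_w = np.log(params.lam) - params.theta * np.log(t[pos])
        out[pos] = -params.beta * np.logaddexp(0.0, log_w)
    return float(out[0]) if scalar else out


def cdf(t, params: DagumParams):
    """CDF (1 + lam t**-theta)**-beta, with cdf(0) = 0 by continuity."""
    return np.exp(logcdf(t, params))


def logsf(t, params: DagumParams):
    """log survival = log(1 - F(t)), stable when F is close to 1."""
    t = _check_t(t, allow_zero=True)
    lc = np.asarray(logcdf(t, params))
    scalar = lc.ndim == 0
    lc = np.atleast_1d(lc)
    with np.errstate(divide="ignore"):
        out = np.log(-np.expm1(lc))
    out[lc == 0.0] = -np.inf  # F==1 exactly (t == inf is excluded by _check_t)
    return float(out[0]) if scalar else out


def survival(t, params: DagumParams):
    """Survival function R(t) = 1 - (1 + lam t**-theta)**-beta."""
    t = _check_t(t, allow_zero=True)
    return -np.expm1(logcdf(t, params))


def logpdf(t, params: DagumParams):
    t = _check_t(t, allow_zero=False)
    th, b, lam = params.theta, params.beta, params.lam
    log_w = np.log(lam) - th * np.log(t)  # log(lam * t**-theta)
    log_z = np.logaddexp(0.0, log_w)  # log(1 + lam t**-theta)
    return np.log(th) + np.log(b) + log_w - np.log(t) - (b + 1.0) * log_z


def pdf(t, params: DagumParams):
    """Density theta*beta*lam * t**(-theta-1) * (1 + lam t**-theta)**(-beta-1)."""
    return np.exp(logpdf(t, params))


def hazard(t, params: DagumParams):
    """Hazard rate pdf / survival.

    Raises
    ------
    FloatingPointError
        If the survival function underflows to exactly zero at ``t`` so the
        ratio is not representable.
    """
    t = _check_t(t, allow_zero=False)
    s = survival(t, params)
    if np.any(np.asarray(s) == 0.0):
        raise FloatingPointError("survival underflowed to 0; hazard not representable")
    return pdf(t, params) / s


def quantile(p, params: DagumParams):
    """Quantile t_p = ((p**(-1/beta) - 1) / lam)**(-1/theta), 0 < p < 1.

    Exact functional inverse of :func:`cdf`; also the inversion kernel used
    by :func:`rvs`.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    th, b, lam = params.theta, params.beta, params.lam
    # p**(-1/b) - 1 == expm1(-log(p)/b), accurate for p near 1
    a = np.expm1(-np.log(p) / b)
    return np.exp(-(np.log(a) - np.log(lam)) / th)


def rvs(params: DagumParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` variates by inversion: quantile(U) for U ~ Uniform(0,1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return quantile(u, params)
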