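"""Progressive type-I interval censoring: schemes, datasets, simulation, CSV I/O.

Under this censoring plan, ``n`` units go on test at time 0 and are inspected
only at pre-scheduled times t_1 < ... < t_m.  At inspection j the number of
failures D_j since the previous inspection is recorded, and a pre-fixed
proportion p_j of the survivors is withdrawn from the test:
R_j = floor(p_j * S_j) where S_j is the number still alive at t_j.  The last
proportion p_m = 1 removes every remaining unit, terminating the experiment.
The observed data are the triples (D_j, R_j, t_j).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import DagumParams, cdf

__all__ = [
    "InspectionScheme",
    "CensoredDataset",
    "simulate",
    "expected_counts",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class InspectionScheme:
    """Pre-scheduled inspection times and per-inspection removal proportions.

    ``times`` must be strictly increasing and positive; ``removal_props``
    has the same length with every entry in [0, 1] and the final entry equal
    to 1 (terminal removal of all survivors).
    """

    times: tuple = field()
    removal_props: tuple = field()

    def __init__(self, times, removal_props):
        times = tuple(float(t) for t in times)
        props = tuple(float(p) for p in removal_props)
        if len(times) != len(props) or len(times) == 0:
            raise ValueError("times and removal_props must be equal-length, non-empty")
        if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("inspection times must be positive and strictly increasing")
        if any(p < 0 or p > 1 for p in props):
            raise ValueError("removal proportions must lie in [0, 1]")
        if props[-1] != 1.0:
            raise ValueError("the final removal proportion must be 1 (terminal removal)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "removal_props", props)

    @property
    def m(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CensoredDataset:
    """Observed triples (D_j, R_j, t_j) plus the initial sample size n."""

    n: int
    scheme: InspectionScheme
    failures: tuple
    removals: tuple

    def __init__(self, n, scheme, failures, removals):
        n = int(n)
        failures = tuple(int(d) for d in failures)
        removals = tuple(int(r) for r in removals)
        m = scheme.m
        if len(failures) != m or len(removals) != m:
            raise ValueError("failures and removals must have one entry per inspection")
        if any(d < 0 for d in failures) or any(r < 0 for r in removals):
            raise ValueError("counts must be non-negative")
        at_risk = n
        for j, (d, r) in enumerate(zip(failures, removals)):
            if d + r > at_risk:
                raise ValueError(
                    f"interval {j + 1}: D+R = {d + r} exceeds the {at_risk} units at risk"
                )
            at_risk -= d + r
        if scheme.removal_props[-1] == 1.0 and at_risk != 0:
            raise ValueError(
                f"with terminal removal p_m = 1 the counts must exhaust n; {at_risk} unaccounted"
            )
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "scheme", scheme)
        object.__setattr__(self, "failures", failures)
        object.__setattr__(self, "removals", removals)

    @property
    def m(self) -> int:
        return self.scheme.m

    def total_failures(self) -> int:
        return sum(self.failures)


def simulate(params: DagumParams, n: int, scheme: InspectionScheme, seed=None) -> CensoredDataset:
    """Simulate one progressively type-I interval-censored dataset.

    Iterates over inspections with A_j units at risk entering interval j:
    D_j ~ Binomial(A_j, (F(t_j) - F(t_{j-1})) / (1 - F(t_{j-1}))) and
    R_j = floor(p_j * (A_j - D_j)), with all survivors removed at t_m.
    Failures are the random outcome and removals the pre-fixed floor of the
    survivor count, so the plan itself stays deterministic given the data.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    F = cdf(np.array(scheme.times), params)
    F_prev = 0.0
    at_risk = n
    failures, removals = [], []
    for j in range(scheme.m):
        if at_risk == 0 or F_prev >= 1.0:
            failures.append(0)
            removals.append(0)
            continue
        q = (F[j] - F_prev) / (1.0 - F_prev)
        q = min(max(q, 0.0), 1.0)
        d = int(rng.binomial(at_risk, q))
        survivors = at_risk - d
        if j == scheme.m - 1:
            r = survivors
        else:
            r = int(np.floor(scheme.removal_props[j] * survivors))
        failures.append(d)
        removals.append(r)
        at_risk = survivors - r
        F_prev = F[j]
    return CensoredDataset(n, scheme, failures, removals)


def expected_counts(params: DagumParams, n: float, scheme: InspectionScheme):
    """Per-interval expected failure/removal counts (real-valued).

    Replaces the binomial draws of :func:`simulate` by their means and the
    floor by the identity, giving the deterministic recursion used to build
    the pre-data (expected) information in the design module.  Conservation
    sum(D) + sum(R) = n holds exactly.

    Returns
    -------
    (ED, ER) : pair of ndarrays of length m
    """
    F = cdf(np.array(scheme.times), params)
    F_prev = 0.0
    at_risk = float(n)
    ed = np.zeros(scheme.m)
    er = np.zeros(scheme.m)
    for j in range(scheme.m):
        if at_risk <= 0.0 or F_prev >= 1.0:
            break
        q = min(max((F[j] - F_prev) / (1.0 - F_prev), 0.0), 1.0)
        d = at_risk * q
        survivors = at_risk - d
        r = survivors if j == scheme.m - 1 else scheme.removal_props[j] * survivors
        ed[j], er[j] = d, r
        at_risk = survivors - r
        F_prev = F[j]
    return ed, er


def write_dataset(dataset: CensoredDataset, path) -> None:
    """Write a dataset as CSV with header ``interval,t_right,D,R``.

    The initial sample size and removal proportions travel in ``#``-comment
    lines so that a single file round-trips the full dataset.
    """
    df = pd.DataFrame(
        {
            "interval": np.arange(1, dataset.m + 1),
            "t_right": dataset.scheme.times,
            "D": dataset.failures,
            "R": dataset.removals,
        }
    )
    buf = io.StringIO()
    buf.write(f"# n = {dataset.n}\n")
    props = ",".join(repr(p) for p in dataset.scheme.removal_props)
    buf.write(f"# removal_props = {props}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_dataset(path) -> CensoredDataset:
    """Read a dataset written by :func:`write_dataset`.

    Invariant violations (counts exceeding the at-risk total, non-increasing
    times) are reported with the offending row number.
    """
    n = None
    props = None
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("n"):
                n = int(body.split("=", 1)[1])
            elif body.startswith("removal_props"):
                props = [float(x) for x in body.split("=", 1)[1].split(",")]
    if n is None:
        raise ValueError("dataset file is missing the '# n = ...' header comment")
    df = pd.read_csv(io.StringIO(text), comment="#")
    required = {"interval", "t_right", "D", "R"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset CSV must have columns {sorted(required)}")
    times = df["t_right"].to_numpy(dtype=float)
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise ValueError(f"row {i + 1}: t_right {times[i]} not greater than previous {times[i - 1]}")
    if props is None:
        # infer: no intermediate removals recorded => conventional interval censoring
        props = [0.0] * (len(times) - 1) + [1.0]
    scheme = InspectionScheme(times, props)
    failures = df["D"].to_numpy(dtype=int)
    removals = df["R"].to_numpy(dtype=int)
    at_risk = n
    for j, (d, r) in enumerate(zip(failures, removals)):
        if d + r > at_risk:
            raise ValueError(f"row {j + 1}: D+R = {d + r} exceeds the {at_risk} units at risk")
        at_risk -= d + r
    return CensoredDataset(n, scheme, failures, removals)
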