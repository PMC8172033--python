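"""Likelihood, analytic score/information, and the maximum-likelihood fit."""

import numpy as np
import pytest

from dagumcens import (
    DagumParams,
    CensoredDataset,
    InspectionScheme,
    cdf,
    fit_mle,
    loglik,
    observed_information,
    quantile,
    score,
    simulate,
    survival,
)
from dagumcens.likelihood import LikelihoodWorkspace

from conftest import TRUE, make_scheme, random_params


def _random_dataset(rng, n_max=300):
    p = random_params(rng)
    m = int(rng.integers(2, 7))
    probs = np.sort(rng.uniform(0.05, 0.97, m))
    probs = np.unique(probs)
    times = quantile(probs, p)
    props = np.append(rng.uniform(0, 0.6, len(times) - 1), 1.0)
    scheme = InspectionScheme(times, props)
    data = simulate(p, int(rng.integers(30, n_max)), scheme, seed=int(rng.integers(2**31)))
    return p, data


def test_loglik_single_interval_reductions():
    scheme = InspectionScheme([1.3], [1.0])
    all_fail = CensoredDataset(50, scheme, [50], [0])
    assert loglik(TRUE, all_fail) == pytest.approx(50 * np.log(cdf(1.3, TRUE)), rel=1e-13)
    all_survive = CensoredDataset(50, scheme, [0], [50])
    assert loglik(TRUE, all_survive) == pytest.approx(
        50 * np.log(survival(1.3, TRUE)), rel=1e-13
    )


def test_loglik_matches_direct_cdf_oracle():
    """Independent recomputation of each interval probability from the CDF."""
    scheme = make_scheme(props=(0.0, 0.2, 0.5, 0.75, 1.0))
    data = simulate(TRUE, 200, scheme, seed=1)
    rng = np.random.default_rng(2)
    for _ in range(20):
        p = random_params(rng)
        F = np.array([cdf(t, p) for t in scheme.times])
        Fprev = np.concatenate(([0.0], F[:-1]))
        expected = np.sum(np.array(data.failures) * np.log(F - Fprev)) + np.sum(
            np.array(data.removals) * np.log(1 - F)
        )
        assert loglik(p, data) == pytest.approx(expected, rel=1e-12)


def test_loglik_minus_inf_on_impossible_interval():
    # an interval with positive failures but zero probability mass
    scheme = InspectionScheme([1e-280, 1.0], [0.0, 1.0])
    data = CensoredDataset(10, scheme, [3, 4], [0, 3])
    assert loglik(DagumParams(3.0, 2.0, 1.0), data) == -np.inf


def test_score_matches_finite_differences():
    rng = np.random.default_rng(10)
    worst = 0.0
    for _ in range(50):
        p_true, data = _random_dataset(rng)
        p = random_params(rng, -0.4, 0.6)
        if not np.isfinite(loglik(p, data)):
            continue
        g = score(p, data)
        x0 = p.as_array()
        for i in range(3):
            h = 1e-6 * x0[i]
            e = np.eye(3)[i] * h
            num = (
                loglik(DagumParams(*(x0 + e)), data) - loglik(DagumParams(*(x0 - e)), data)
            ) / (2 * h)
            rel = abs(g[i] - num) / max(abs(num), 1e-8)
            worst = max(worst, rel)
    assert worst < 1e-5


def test_score_vanishes_at_mle(dataset_medium):
    res = fit_mle(dataset_medium)
    g = score(res.estimates, dataset_medium)
    assert np.max(np.abs(g)) < 1e-6 * dataset_medium.n


def test_score_no_failure_term_dropout():
    """With D = 0 everywhere, only the removal terms survive in the score."""
    scheme = InspectionScheme([1.0, 2.0], [0.0, 1.0])
    data = CensoredDataset(20, scheme, [0, 0], [0, 20])
    p = DagumParams(2, 2, 1)
    g = score(p, data)
    # direct derivative of 20*log(1 - F(2)) in beta
    h = 1e-7
    num = (
        20 * np.log(survival(2.0, DagumParams(2, 2 + h, 1)))
        - 20 * np.log(survival(2.0, DagumParams(2, 2 - h, 1)))
    ) / (2 * h)
    assert g[1] == pytest.approx(num, rel=1e-6)


def test_observed_information_symmetric_and_matches_numeric_hessian():
    rng = np.random.default_rng(20)
    worst = 0.0
    for _ in range(25):
        p_true, data = _random_dataset(rng)
        p = random_params(rng, -0.3, 0.5)
        if not np.isfinite(loglik(p, data)):
            continue
        info = observed_information(p, data)
        assert np.array_equal(info, info.T)
        x0 = p.as_array()
        # numerical second derivatives: central differences of the score
        # (itself validated against differences of the log-likelihood)
        num = np.zeros((3, 3))
        for j in range(3):
            h = 1e-6 * x0[j]
            e = np.eye(3)[j] * h
            num[:, j] = -(
                score(DagumParams(*(x0 + e)), data) - score(DagumParams(*(x0 - e)), data)
            ) / (2 * h)
        num = (num + num.T) / 2.0
        # matrix-relative error: entries near zero carry pure FD roundoff
        worst = max(worst, np.max(np.abs(info - num)) / np.max(np.abs(num)))
    assert worst < 1e-4


def test_information_psd_at_mle(dataset_medium):
    res = fit_mle(dataset_medium)
    info = observed_information(res.estimates, dataset_medium)
    assert np.min(np.linalg.eigvalsh(info)) > 0


def test_mle_recovers_truth_large_n(dataset_large):
    res = fit_mle(dataset_large)
    assert res.converged
    est = res.estimates.as_array()
    assert np.all(np.abs(est - TRUE.as_array()) / TRUE.as_array() < 0.15)
    for name in ("theta", "beta", "lam"):
        lo, hi = res.wald_intervals[name]
        assert lo < getattr(res.estimates, name) < hi


def test_mle_invariant_to_row_order(dataset_medium):
    d = dataset_medium
    perm = [2, 0, 4, 1, 3]
    # reordering the stored rows must not change the fit: rebuild via workspace
    ws = LikelihoodWorkspace(d)
    ws_perm = LikelihoodWorkspace(
        (ws.times[perm], ws.D[perm], ws.R[perm])
    )
    p = DagumParams(1.8, 2.2, 0.9)
    assert ws.value(*p.as_array()) == pytest.approx(ws_perm.value(*p.as_array()), rel=1e-13)


def test_merging_intervals_changes_likelihood(dataset_medium):
    """Negative control: collapsing two adjacent intervals loses information."""
    d = dataset_medium
    times = list(d.scheme.times)
    D = list(d.failures)
    R = list(d.removals)
    merged_times = times[1:]
    merged_D = [D[0] + D[1]] + D[2:]
    merged_R = [R[0] + R[1]] + R[2:]
    ws = LikelihoodWorkspace((np.array(merged_times), np.array(merged_D, float), np.array(merged_R, float)))
    p = DagumParams(2.1, 1.9, 1.05)
    assert ws.value(*p.as_array()) != pytest.approx(loglik(p, d), rel=1e-6)


def test_mse_decreases_with_n():
    scheme = make_scheme()
    sizes = (50, 100, 500, 2000)
    mses = []
    for n in sizes:
        errs = []
        for rep in range(60):
            d = simulate(TRUE, n, scheme, seed=1_000_000 + 7919 * rep + n)
            try:
                r = fit_mle(d)
            except ValueError:
                continue
            if r.converged:
                errs.append((r.estimates.as_array() - TRUE.as_array()) ** 2)
        mses.append(np.mean(errs, axis=0))
    mses = np.array(mses)
    # theta MSE should fall monotonically; total MSE must fall substantially
    assert np.all(np.diff(mses[:, 0]) < 0)
    assert mses[-1].sum() < 0.2 * mses[0].sum()


def test_fit_requires_failures():
    scheme = InspectionScheme([1.0], [1.0])
    data = CensoredDataset(10, scheme, [0], [10])
    with pytest.raises(ValueError):
        fit_mle(data)
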