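"""Hazard function, event-history likelihood and priors."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from snbda import (
    DiffusionRecord,
    ParameterSet,
    hazard,
    log_likelihood,
    log_prior,
    simulate_diffusion_gillespie,
)
from snbda.model import LikelihoodCache


def test_parameter_set_model_structure():
    p1 = ParameterSet(1, log_lambda0=0.5)
    assert p1.s_prime == 0.0 and p1.beta == 0.0
    with pytest.raises(ValueError):
        ParameterSet(2, log_lambda0=0.0)  # needs log_s_prime
    with pytest.raises(ValueError):
        ParameterSet(4, log_lambda0=0.0)
    p3 = ParameterSet(3, log_lambda0=0.0, log_s_prime=0.0, log_beta_mag=1.0, beta_sign=-1)
    assert p3.beta == pytest.approx(-np.e)
    assert p3.s == pytest.approx(1.0)  # s = s'/lambda0


@pytest.mark.parametrize(
    "logval, expected",
    [(0.0, 0.0), (10.0, 0.0), (-10.0, 0.0), (11.0, -np.inf), (-10.5, -np.inf)],
)
def test_log_prior_box(logval, expected):
    p = ParameterSet(2, log_lambda0=logval, log_s_prime=0.0)
    assert log_prior(p) == expected


def test_hazard_values():
    A = np.array([[0.0, 0.5], [0.5, 0.0]])
    p1 = ParameterSet(1, log_lambda0=0.0)
    # informed individuals have hazard zero
    assert hazard(0, [True, False], p1, A) == 0.0
    # null model: naive hazard is the baseline rate
    assert hazard(0, [False, False], p1, A) == pytest.approx(1.0)
    # social model: s' * a_ij * z_j + lambda0 = 2 * 0.5 * 1 + 1 = 2
    p2 = ParameterSet(2, log_lambda0=0.0, log_s_prime=np.log(2.0))
    assert hazard(0, [False, True], p2, A) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        hazard(0, [False, False], p1, A, covariates=[np.nan, 0.0])
    with pytest.raises(ValueError):
        hazard(5, [False, False], p1, A)


def test_reparameterisation_consistency():
    # classical form lambda0 * (s * sum a z + 1) equals the s' form with
    # s' = lambda0 * s
    rng = np.random.default_rng(0)
    A = rng.uniform(0, 1, (6, 6))
    np.fill_diagonal(A, 0)
    z = np.array([True, False, True, False, False, True])
    lambda0, s = 0.7, 3.0
    p = ParameterSet(2, log_lambda0=np.log(lambda0), log_s_prime=np.log(lambda0 * s))
    for i in range(6):
        classical = 0.0 if z[i] else lambda0 * (s * float(A[i] @ z) + 1.0)
        assert hazard(i, z, p, A) == pytest.approx(classical)


def _record(times, censored=None, horizon=None):
    times = np.asarray(times, dtype=float)
    if censored is None:
        censored = np.zeros(times.size, dtype=bool)
    if horizon is None:
        horizon = float(times.max())
    return DiffusionRecord(list(range(times.size)), times, censored, horizon)


def test_loglik_single_individual_exponential():
    rec = _record([2.5])
    p = ParameterSet(1, log_lambda0=np.log(0.4))
    ll = log_likelihood(rec, np.zeros((1, 1)), None, p)
    assert ll == pytest.approx(np.log(0.4) - 0.4 * 2.5)


def test_loglik_zero_network_social_term_inert():
    rec = _record([0.5, 1.2, 3.0, 4.4])
    A = np.zeros((4, 4))
    p1 = ParameterSet(1, log_lambda0=-0.3)
    for log_sp in (-5.0, 0.0, 5.0):
        p2 = ParameterSet(2, log_lambda0=-0.3, log_s_prime=log_sp)
        assert log_likelihood(rec, A, None, p2) == pytest.approx(
            log_likelihood(rec, A, None, p1)
        )


def test_loglik_censoring_survival_only():
    # a censored individual adds -lambda0 * T and no event term
    A = np.zeros((3, 3))
    lam = 0.6
    p = ParameterSet(1, log_lambda0=np.log(lam))
    full = log_likelihood(_record([1.0, 2.0, 5.0]), A, None, p)
    cens = log_likelihood(
        _record([1.0, 2.0, 5.0], censored=[False, False, True], horizon=5.0),
        A,
        None,
        p,
    )
    assert full - cens == pytest.approx(np.log(lam))


def test_loglik_matches_quadrature_oracle():
    """3-individual worked case against numerical integration of the
    hazard paths (independent oracle built on the hazard operation)."""
    A = np.array([[0.0, 0.6, 0.1], [0.4, 0.0, 0.3], [0.2, 0.5, 0.0]])
    c = np.array([0.5, -1.0, 0.2])
    times = np.array([1.0, 2.5, 4.0])
    rec = _record(times)
    p = ParameterSet(
        3,
        log_lambda0=np.log(0.3),
        log_s_prime=np.log(1.5),
        log_beta_mag=np.log(0.8),
        beta_sign=-1,
    )

    def z_at(t):
        return times <= t  # informed status just after the events at <= t

    expected = 0.0
    for k, t_k in enumerate(times):
        z = times < t_k  # state just before the event
        expected += np.log(hazard(k, z, p, A, c))
    for i in range(3):
        integral, err = quad(
            lambda u: hazard(i, times <= u, p, A, c),
            0.0,
            times[i],
            points=list(times[times < times[i]]),
            limit=200,
            epsabs=1e-12,
            epsrel=1e-12,
        )
        expected -= integral
    assert log_likelihood(rec, A, c, p) == pytest.approx(expected, abs=1e-8)


def test_loglik_exponential_mle_closed_form():
    rec = simulate_diffusion_gillespie(np.zeros((60, 60)), 0.5, 0.0, seed=21)
    cache = LikelihoodCache(rec, np.zeros((60, 60)))
    res = minimize_scalar(
        lambda lam: -cache.loglik(lam, 0.0, 0.0),
        bounds=(1e-6, 50.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert res.x == pytest.approx(60 / rec.times.sum(), abs=1e-6)


def test_loglik_unimodal_beyond_mle():
    rec = _record([0.5, 1.5, 2.5, 4.0])
    cache = LikelihoodCache(rec, np.zeros((4, 4)))
    mle = 4 / rec.times.sum()
    lams = np.linspace(mle, mle * 20, 50)
    lls = [cache.loglik(l, 0.0, 0.0) for l in lams]
    assert all(a > b for a, b in zip(lls, lls[1:]))


def test_tied_times_rejected_then_jittered():
    rec = _record([1.0, 1.0, 2.0])
    A = np.zeros((3, 3))
    p = ParameterSet(1, log_lambda0=0.0)
    with pytest.raises(ValueError):
        log_likelihood(rec, A, None, p)
    with pytest.warns(UserWarning):
        ll = LikelihoodCache(rec, A, tie_jitter=True).loglik_params(p)
    assert np.isfinite(ll)


def test_seeded_innovator_conditioning():
    # with the innovator seeded, only the later individual contributes
    rec = _record([1.0, 3.0])
    A = np.zeros((2, 2))
    lam = 0.8
    p = ParameterSet(1, log_lambda0=np.log(lam))
    ll = log_likelihood(rec, A, None, p, seeded_innovator=True)
    assert ll == pytest.approx(np.log(lam) - lam * 3.0)


def test_loglik_rejects_all_censored():
    rec = _record([1.0, 1.0], censored=[True, True], horizon=1.0)
    with pytest.raises(ValueError):
        log_likelihood(rec, np.zeros((2, 2)), None, ParameterSet(1, log_lambda0=0.0))


def test_loglik_continuous_in_parameters(clustered_study):
    rec = clustered_study.diffusions[0]
    cache = LikelihoodCache(rec, clustered_study.network, clustered_study.covariates)
    base = cache.loglik(0.2, 2.0, 0.1)
    for eps in (1e-6, 1e-7):
        assert abs(cache.loglik(0.2 + eps, 2.0, 0.1) - base) < 1e-3
        assert abs(cache.loglik(0.2, 2.0 + eps, 0.1) - base) < 1e-3
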