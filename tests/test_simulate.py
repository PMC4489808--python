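"""Generators: cluster/CSR patterns, environmental fields, Gillespie diffusion."""

import numpy as np
import pytest
from scipy import stats

from snbda import (
    EnvironmentalField,
    Window,
    generate_study,
    linear_field,
    simulate_csr,
    simulate_diffusion_gillespie,
    simulate_hardcore,
    simulate_matern_cluster,
)
from snbda.simulate import normalise_covariate


def test_matern_expected_count():
    kappa, mu = 8.0, 3.25  # expected kappa * mu * |W| = 26 points
    counts = []
    for s in range(300):
        try:
            counts.append(simulate_matern_cluster(kappa, mu, 0.05, seed=s).n)
        except RuntimeError:  # an empty realisation is a count of zero
            counts.append(0)
    counts = np.asarray(counts, dtype=float)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 26.0) < 3 * se


def test_matern_deterministic_and_in_window():
    a = simulate_matern_cluster(10, 4, 0.05, seed=3)
    b = simulate_matern_cluster(10, 4, 0.05, seed=3)
    assert np.array_equal(a.coords, b.coords)
    assert np.all(a.window.contains(a.coords))


def test_matern_vanishing_offspring_gives_empty():
    with pytest.raises(RuntimeError):
        simulate_matern_cluster(0.5, 1e-9, 0.05, seed=0)


def test_csr_basics():
    single = simulate_csr(1, seed=0)
    assert single.n == 1 and single.window.contains(single.coords).all()
    a, b = simulate_csr(100, seed=5), simulate_csr(100, seed=5)
    assert np.array_equal(a.coords, b.coords)
    with pytest.raises(ValueError):
        simulate_csr(0)


def test_csr_coordinates_uniform():
    pattern = simulate_csr(10_000, seed=6)
    for axis in (0, 1):
        p = stats.kstest(pattern.coords[:, axis], "uniform").pvalue
        assert p > 0.001


def test_hardcore_spacing():
    pattern = simulate_hardcore(100, 0.06, seed=7)
    d = pattern.pairwise_distances()
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 0.06


def test_field_normalisation():
    field = linear_field()
    coords = simulate_csr(200, seed=8).coords
    c = field.at(coords)
    assert c.mean() == pytest.approx(0.0, abs=1e-12)
    assert c.std() == pytest.approx(1.0, rel=1e-12)
    mm = normalise_covariate(3 * coords[:, 0] - 2 * coords[:, 1], "minmax")
    assert mm.min() == 0.0 and mm.max() == 1.0
    # the gradient orders points: larger 3x - 2y, larger normalised value
    raw = 3 * coords[:, 0] - 2 * coords[:, 1]
    assert stats.spearmanr(raw, c).statistic == pytest.approx(1.0)
    with pytest.raises(ValueError):
        EnvironmentalField(lambda x, y: x, normalisation="bogus")


def test_gillespie_asocial_times_are_exponential():
    lam = 0.7
    rec = simulate_diffusion_gillespie(
        np.zeros((2000, 2000)), lambda0=lam, s_prime=0.0, seed=9
    )
    assert not rec.censored.any()
    p = stats.kstest(rec.times, "expon", args=(0, 1 / lam)).pvalue
    assert p > 0.001


def test_gillespie_zero_network_matches_asocial():
    A = np.zeros((50, 50))
    a = simulate_diffusion_gillespie(A, 1.0, 0.0, seed=10)
    b = simulate_diffusion_gillespie(A, 1.0, 5.0, seed=10)
    assert np.array_equal(a.times, b.times)


def test_gillespie_times_distinct_and_positive():
    A = np.full((30, 30), 0.5)
    np.fill_diagonal(A, 0.0)
    rec = simulate_diffusion_gillespie(A, 1.0, 2.0, seed=11)
    t = np.sort(rec.times)
    assert np.all(np.diff(t) > 0) and t[0] > 0
    assert len(rec.innovator_ids) == 1


def test_gillespie_censoring():
    rec = simulate_diffusion_gillespie(
        np.zeros((50, 50)), lambda0=0.01, s_prime=0.0, horizon=1.0, seed=12
    )
    assert rec.censored.any()
    assert np.all(rec.times[rec.censored] == 1.0)
    assert rec.n_events == (~rec.censored).sum()


def test_gillespie_strong_social_completes_cluster_first():
    # two 5-member cliques, no cross-links: with s' >> lambda0 the clique
    # of the innovator finishes before the other clique starts
    n = 10
    A = np.zeros((n, n))
    A[:5, :5] = 1.0
    A[5:, 5:] = 1.0
    np.fill_diagonal(A, 0.0)
    wins = 0
    for s in range(200):
        rec = simulate_diffusion_gillespie(A, 1.0, 1e4, seed=(13, s))
        first = int(np.argmin(rec.times))
        own = slice(0, 5) if first < 5 else slice(5, 10)
        other = slice(5, 10) if first < 5 else slice(0, 5)
        wins += rec.times[own].max() < rec.times[other].min()
    assert wins >= 0.95 * 200


def test_gillespie_covariate_accelerates_acquisition():
    n = 40
    c = np.linspace(-2, 2, n)
    rhos = []
    for s in range(30):
        rec = simulate_diffusion_gillespie(
            np.zeros((n, n)), 1.0, 0.0, beta=1.0, covariates=c, seed=(14, s)
        )
        rhos.append(stats.spearmanr(rec.times, c).statistic)
    assert np.mean(rhos) < -0.3


def test_gillespie_input_validation():
    with pytest.raises(ValueError):
        simulate_diffusion_gillespie(np.zeros((3, 3)), 0.0, 1.0)
    with pytest.raises(ValueError):
        simulate_diffusion_gillespie(np.zeros((3, 3)), 1.0, -1.0)
    with pytest.raises(ValueError):
        simulate_diffusion_gillespie(np.zeros((3, 3)), 1.0, 1.0, covariates=[1.0])


def test_generate_study_structure(clustered_study):
    study = clustered_study
    assert study.network.n == study.pattern.n == len(study.covariates)
    assert len(study.diffusions) == 10
    assert study.manifest["kind"] == "clustered"
    assert all(rec.informative for rec in study.diffusions)
    # replicate diffusions differ but share the population
    assert not np.array_equal(study.diffusions[0].times, study.diffusions[1].times)


def test_generate_study_deterministic():
    a = generate_study(seed=5, n_diffusions=2)
    b = generate_study(seed=5, n_diffusions=2)
    assert np.array_equal(a.pattern.coords, b.pattern.coords)
    assert np.array_equal(a.diffusions[1].times, b.diffusions[1].times)


def test_generate_study_csr_is_asocial():
    study = generate_study(kind="csr", seed=3, n_diffusions=1)
    assert study.manifest["s_prime"] == 0.0
    assert study.pattern.n == 26


def test_generate_study_uniform_env():
    study = generate_study(kind="uniform_env", seed=3, n_diffusions=1)
    assert np.all(study.covariates == 0.0)
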