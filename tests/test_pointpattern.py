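"""Second-order statistics, envelopes, radius suggestion, union of discs."""

import numpy as np
import pytest

from snbda import (
    PcfResult,
    PointPattern,
    Window,
    area_interaction_logdensity,
    csr_envelope,
    pair_correlation,
    ripley_k,
    simulate_csr,
    simulate_hardcore,
    simulate_matern_cluster,
    suggest_interaction_radius,
    union_of_discs_area,
)
from snbda.geometry import Disc, disc_overlap_area

R_GRID = np.linspace(0.01, 0.25, 25)


def test_ripley_k_csr_close_to_theory():
    pattern = simulate_csr(500, seed=1)
    k = ripley_k(pattern, R_GRID)
    ratio = k / (np.pi * R_GRID**2)
    assert 0.9 < ratio.mean() < 1.1


def test_ripley_k_no_pairs_below_r():
    p = PointPattern(["a", "b"], [[0.2, 0.5], [0.7, 0.5]], None, Window())
    assert ripley_k(p, np.array([0.4]))[0] == 0.0


def test_ripley_k_coincident_points_maximal():
    coords = np.tile([[0.5, 0.5]], (20, 1))
    p = PointPattern(list(range(20)), coords, None, Window())
    k = ripley_k(p, np.array([0.01, 0.1]))
    # every pair is within any positive r; the estimate saturates at |W|
    assert np.all(k >= p.window.area)


def test_ripley_k_flags_out_of_range_r():
    pattern = simulate_csr(50, seed=2)
    with pytest.warns(UserWarning):
        k = ripley_k(pattern, np.array([0.1, 0.6]))
    assert np.isfinite(k[0]) and np.isnan(k[1])


def test_pair_correlation_csr_near_one():
    pattern = simulate_csr(500, seed=3)
    pcf = pair_correlation(pattern, R_GRID)
    g = pcf.g_values[pcf.reliable]
    assert 0.8 < np.median(g) < 1.2


def test_pair_correlation_clustered_exceeds_one():
    pattern = simulate_matern_cluster(40, 5, 0.05, seed=4)
    pcf = pair_correlation(pattern, R_GRID)
    near = pcf.r_grid <= 0.1
    assert np.nanmax(pcf.g_values[near]) > 1


def test_pair_correlation_hardcore_below_one():
    pattern = simulate_hardcore(120, 0.07, seed=5)
    pcf = pair_correlation(pattern, np.linspace(0.01, 0.05, 5), bandwidth=0.01)
    # no pairwise distances exist below the hard-core spacing, so the
    # kernel estimate is zero (hence < 1) at distances below it
    assert np.all(pcf.g_values < 1)


def test_pair_correlation_rejects_bad_bandwidth():
    pattern = simulate_csr(20, seed=0)
    with pytest.raises(ValueError):
        pair_correlation(pattern, R_GRID, bandwidth=0.0)


def test_relabelling_invariance():
    pattern = simulate_csr(60, seed=6)
    perm = np.random.default_rng(0).permutation(60)
    shuffled = PointPattern(
        [pattern.ids[i] for i in perm], pattern.coords[perm], None, pattern.window
    )
    assert ripley_k(pattern, R_GRID) == pytest.approx(ripley_k(shuffled, R_GRID))
    assert pair_correlation(pattern, R_GRID).g_values == pytest.approx(
        pair_correlation(shuffled, R_GRID).g_values
    )


def test_envelope_deterministic_and_ordered():
    pattern = simulate_csr(40, seed=7)
    lo1, hi1 = csr_envelope(pattern, R_GRID, n_sim=5, seed=9)
    lo2, hi2 = csr_envelope(pattern, R_GRID, n_sim=5, seed=9)
    assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)
    assert np.all(lo1 <= hi1)


def test_envelope_contains_mean_of_curves():
    # min/max envelope necessarily brackets any average of the curves;
    # check against an independently simulated CSR g as a coverage smoke test
    pattern = simulate_csr(100, seed=8)
    lo, hi = csr_envelope(pattern, R_GRID, n_sim=99, seed=10)
    pcf = pair_correlation(pattern, R_GRID)
    ok = pcf.reliable
    inside = (pcf.g_values[ok] >= lo[ok]) & (pcf.g_values[ok] <= hi[ok])
    assert inside.mean() > 0.8


def _synthetic_pcf(g):
    r = np.linspace(0.01, 0.1, 10)
    return PcfResult(
        r,
        np.asarray(g, dtype=float),
        np.zeros_like(r),
        envelope_low=np.full_like(r, 0.5),
        envelope_high=np.full_like(r, 1.5),
    )


def test_suggest_radius_spike():
    g = np.ones(10)
    g[4] = 2.5  # spike at r = 0.05
    s = suggest_interaction_radius(_synthetic_pcf(g))
    assert s.radius == pytest.approx(0.05)
    assert not s.csr and not s.regular


def test_suggest_radius_csr_flag():
    s = suggest_interaction_radius(_synthetic_pcf(np.ones(10)))
    assert s.csr and s.radius is None


def test_suggest_radius_regular_case():
    g = np.ones(10)
    g[2] = 0.1
    s = suggest_interaction_radius(_synthetic_pcf(g))
    assert s.regular and s.radius == pytest.approx(0.03)


def test_suggest_radius_tie_breaks_small_r():
    g = np.ones(10)
    g[3] = g[7] = 2.0
    s = suggest_interaction_radius(_synthetic_pcf(g))
    assert s.radius == pytest.approx(0.04)


def test_suggest_radius_requires_envelope():
    r = np.linspace(0.01, 0.1, 10)
    with pytest.raises(ValueError):
        suggest_interaction_radius(PcfResult(r, np.ones(10), np.zeros(10)))


def one_point(x, y):
    return PointPattern(["a"], [[x, y]], None, Window())


def test_union_single_disc():
    area = union_of_discs_area(one_point(0.5, 0.5), 0.1, resolution=600)
    assert area == pytest.approx(np.pi * 0.01, rel=0.01)


def test_union_disjoint_and_overlapping():
    p2 = PointPattern(["a", "b"], [[0.25, 0.5], [0.75, 0.5]], None, Window())
    r = 0.1
    assert union_of_discs_area(p2, r, 600) == pytest.approx(2 * np.pi * r**2, rel=0.01)
    close = PointPattern(["a", "b"], [[0.45, 0.5], [0.55, 0.5]], None, Window())
    lens = disc_overlap_area(Disc((0.45, 0.5), r), Disc((0.55, 0.5), r))
    expected = 2 * np.pi * r**2 - lens
    assert union_of_discs_area(close, r, 600) == pytest.approx(expected, rel=0.01)


def test_union_monotone_in_radius():
    pattern = simulate_csr(15, seed=11)
    areas = [union_of_discs_area(pattern, r, 256) for r in (0.02, 0.05, 0.1, 0.2)]
    assert all(a <= b for a, b in zip(areas, areas[1:]))
    assert areas[-1] <= pattern.window.area + 1e-9


def test_area_interaction_logdensity():
    pattern = simulate_csr(10, seed=12)
    n = pattern.n
    base = area_interaction_logdensity(pattern, 0.05, xi=2.0, gamma=1.0, beta=1.0)
    assert base == pytest.approx(n * np.log(2.0))
    doubled = area_interaction_logdensity(pattern, 0.05, xi=4.0, gamma=1.0, beta=1.0)
    assert doubled - base == pytest.approx(n * np.log(2.0))
    empty = area_interaction_logdensity(
        None, 0.05, xi=2.0, gamma=3.0, beta=2.0, covariate_total=1.5
    )
    assert empty == pytest.approx(1.5 * np.log(2.0))
    with pytest.raises(ValueError):
        area_interaction_logdensity(pattern, 0.05, xi=-1.0, gamma=1.0, beta=1.0)


def test_area_interaction_gamma_penalises_union():
    pattern = simulate_csr(10, seed=13)
    u = union_of_discs_area(pattern, 0.05, 256)
    with_gamma = area_interaction_logdensity(
        pattern, 0.05, xi=1.0, gamma=2.0, beta=1.0, resolution=256
    )
    assert with_gamma == pytest.approx(-u * np.log(2.0), rel=1e-6)
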