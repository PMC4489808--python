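"""Planar point patterns and second-order exploratory statistics.

A point pattern here records the home-base (nest) locations of the
individuals in a population inside a rectangular observation window,
together with an optional per-individual interaction radius.  The
second-order statistics — Ripley's K function and the pair correlation
function g(r) — describe how clustered or regular the pattern is at each
spatial scale, and are the basis for choosing the interaction radius used
to build the social network.

Under complete spatial randomness (CSR) g(r) = 1 at every distance;
g(r) > 1 indicates clustering (attraction) and g(r) < 1 regularity
(repulsion).  Simulation envelopes from CSR patterns with the same number
of points provide a pointwise reference band for judging departures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Window",
    "PointPattern",
    "PcfResult",
    "RadiusSuggestion",
    "ripley_k",
    "pair_correlation",
    "csr_envelope",
    "suggest_interaction_radius",
    "union_of_discs_area",
    "area_interaction_logdensity",
    "stoyan_bandwidth",
]


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window [x0, x1] x [y0, y1]."""

    x0: float = 0.0
    x1: float = 1.0
    y0: float = 0.0
    y1: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("window must have positive side lengths")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return (
            (coords[..., 0] >= self.x0)
            & (coords[..., 0] <= self.x1)
            & (coords[..., 1] >= self.y0)
            & (coords[..., 1] <= self.y1)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        xy = rng.uniform(size=(n, 2))
        xy[:, 0] = self.x0 + xy[:, 0] * self.width
        xy[:, 1] = self.y0 + xy[:, 1] * self.height
        return xy


UNIT_SQUARE = Window(0.0, 1.0, 0.0, 1.0)


@dataclass
class PointPattern:
    """Individuals' ids, planar coordinates and interaction radii.

    Radii may be omitted (``None``) when the pattern is used purely for
    exploratory statistics; building an association matrix requires them.
    A scalar radius is broadcast to all individuals.
    """

    ids: list
    coords: np.ndarray
    radii: np.ndarray | float | None = None
    window: Window = field(default_factory=lambda: UNIT_SQUARE)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.ids = list(self.ids)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("a point pattern needs at least one point")
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.ids) != n:
            raise ValueError("ids and coords disagree on n")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in point pattern")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.window.contains(self.coords)):
            raise ValueError("all points must lie inside the window")
        if self.radii is not None:
            r = np.broadcast_to(np.asarray(self.radii, dtype=float), (n,)).copy()
            if np.any(r <= 0) or not np.all(np.isfinite(r)):
                raise ValueError("interaction radii must be positive")
            self.radii = r

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def intensity(self) -> float:
        """Estimated intensity: points per unit area of the window."""
        return self.n / self.window.area

    def with_radius(self, radius) -> "PointPattern":
        return PointPattern(self.ids, self.coords.copy(), radius, self.window)

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


@dataclass
class PcfResult:
    """Pair correlation / Ripley-K estimates on a common distance grid.

    ``reliable`` flags grid points where the kernel estimate of g rests on
    enough pairwise distances to be trusted; envelopes, when present, are
    pointwise bounds from CSR simulations.
    """

    r_grid: np.ndarray
    g_values: np.ndarray
    k_values: np.ndarray
    envelope_low: np.ndarray | None = None
    envelope_high: np.ndarray | None = None
    reliable: np.ndarray | None = None
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        if self.r_grid.ndim != 1 or np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if self.envelope_low is not None and self.envelope_high is not None:
            if np.any(self.envelope_low > self.envelope_high + 1e-12):
                raise ValueError("envelope low exceeds high")
        if self.reliable is None:
            self.reliable = np.ones_like(self.r_grid, dtype=bool)


@dataclass(frozen=True)
class RadiusSuggestion:
    """Outcome of the interaction-radius heuristic.

    ``radius`` is None when the pattern is consistent with CSR; ``regular``
    marks the repulsion case (g below the lower envelope), where a radius
    is still reported but the zones of influence rarely overlap.
    """

    radius: float | None
    csr: bool
    regular: bool = False


def _translation_weights(coords: np.ndarray, window: Window) -> np.ndarray:
    """Translation edge-correction factors e_ij >= 1 for a rectangle."""
    dx = np.abs(coords[:, None, 0] - coords[None, :, 0])
    dy = np.abs(coords[:, None, 1] - coords[None, :, 1])
    return (window.width * window.height) / (
        (window.width - dx) * (window.height - dy)
    )


def _check_r_grid(pattern: PointPattern, r_grid: np.ndarray) -> np.ndarray:
    r_grid = np.asarray(r_grid, dtype=float)
    limit = pattern.window.shorter_side / 2.0
    bad = r_grid >= limit
    if np.any(bad):
        warnings.warn(
            f"distances >= {limit:.4g} (half the shorter window side) are "
            "outside the reliable range; flagged as NaN",
            stacklevel=3,
        )
    return bad


def ripley_k(pattern: PointPattern, r_grid: Sequence[float]) -> np.ndarray:
    """Translation-edge-corrected estimate of Ripley's K function.

    K(r) is the expected number of further points within distance r of a
    typical point, divided by the intensity; under CSR, K(r) = pi r^2.
    """
    if pattern.n < 2:
        raise ValueError("Ripley's K needs at least two points")
    r_grid = np.asarray(r_grid, dtype=float)
    bad = _check_r_grid(pattern, r_grid)
    d = pattern.pairwise_distances()
    w = _translation_weights(pattern.coords, pattern.window)
    iu = ~np.eye(pattern.n, dtype=bool)
    dvals = d[iu]
    wvals = w[iu]
    scale = pattern.window.area / (pattern.n * (pattern.n - 1))
    k = np.array([scale * wvals[dvals <= r].sum() for r in r_grid])
    k[bad] = np.nan
    return k


def stoyan_bandwidth(pattern: PointPattern, c: float = 0.15) -> float:
    """Stoyan's rule-of-thumb bandwidth c / sqrt(intensity)."""
    return c / np.sqrt(pattern.intensity)


def pair_correlation(
    pattern: PointPattern,
    r_grid: Sequence[float],
    bandwidth: float | str = "auto",
    min_pairs: int = 5,
) -> PcfResult:
    """Kernel estimate of the pair correlation function g(r).

    Uses an Epanechnikov kernel on the pairwise distances with translation
    edge correction; ``bandwidth='auto'`` applies Stoyan's rule of thumb.
    Grid points supported by fewer than ``min_pairs`` pairwise distances
    within one bandwidth, and grid points below one bandwidth (where the
    kernel window extends past zero distance), are flagged unreliable —
    at small r the estimate of g is undefined in practice.
    """
    if pattern.n < 2:
        raise ValueError("pair correlation needs at least two points")
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("r_grid must be positive for g(r)")
    if bandwidth == "auto":
        h = stoyan_bandwidth(pattern)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    bad = _check_r_grid(pattern, r_grid)

    d = pattern.pairwise_distances()
    w = _translation_weights(pattern.coords, pattern.window)
    iu = ~np.eye(pattern.n, dtype=bool)
    dvals = d[iu]
    wvals = w[iu]

    # Epanechnikov kernel, half-width h
    u = (r_grid[:, None] - dvals[None, :]) / h
    kern = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2) / h, 0.0)
    scale = pattern.window.area / (pattern.n * (pattern.n - 1))
    g = scale * (kern * wvals[None, :]).sum(axis=1) / (2.0 * np.pi * r_grid)

    n_support = (np.abs(u) <= 1.0).sum(axis=1)
    # below one bandwidth the kernel window spills past zero distance and
    # the 1/(2 pi r) factor blows up: the estimate is undefined there
    reliable = (n_support >= min_pairs) & ~bad & (r_grid >= h)
    g = np.where(bad, np.nan, g)
    k = ripley_k(pattern, r_grid)
    return PcfResult(r_grid, g, k, reliable=reliable, bandwidth=h)


def csr_envelope(
    pattern: PointPattern,
    r_grid: Sequence[float],
    n_sim: int = 99,
    seed: int | np.random.SeedSequence | None = 0,
    bandwidth: float | str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise min/max envelope of g(r) under CSR.

    Simulates ``n_sim`` binomial processes (same n, same window) and takes
    the pointwise minimum and maximum of their pair correlation estimates.
    An observed g outside the band is evidence against CSR at that scale.
    """
    if n_sim < 2:
        raise ValueError("need at least two simulations for an envelope")
    r_grid = np.asarray(r_grid, dtype=float)
    if bandwidth == "auto":
        # fix the bandwidth across simulations so curves are comparable
        bandwidth = stoyan_bandwidth(pattern)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_sim, r_grid.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_sim):
            xy = pattern.window.sample_uniform(pattern.n, rng)
            sim = PointPattern(list(range(pattern.n)), xy, None, pattern.window)
            curves[s] = pair_correlation(sim, r_grid, bandwidth=bandwidth).g_values
    return curves.min(axis=0), curves.max(axis=0)


def suggest_interaction_radius(pcf: PcfResult) -> RadiusSuggestion:
    """Heuristic interaction radius from a pair-correlation plot.

    Returns the distance at which g most exceeds the upper CSR envelope
    (the scale of strongest clustering).  If g never exceeds the upper
    envelope but dips below the lower one, the distance of the deepest dip
    is returned with ``regular=True``.  If g stays inside the envelope the
    pattern is consistent with CSR and no radius is suggested.  Ties break
    toward the smaller distance: local associations are the target, so
    large spatial scales are avoided.
    """
    if pcf.envelope_low is None or pcf.envelope_high is None:
        raise ValueError("PcfResult must carry a CSR envelope")
    ok = pcf.reliable & np.isfinite(pcf.g_values)
    if not np.any(ok):
        raise ValueError("no reliable g(r) values to work with")
    g = pcf.g_values
    excess = np.where(ok, g - pcf.envelope_high, -np.inf)
    if np.max(excess) > 0:
        idx = int(np.argmax(excess))  # argmax returns the first (smallest r) tie
        return RadiusSuggestion(float(pcf.r_grid[idx]), csr=False)
    deficit = np.where(ok, g - pcf.envelope_low, np.inf)
    if np.min(deficit) < 0:
        idx = int(np.argmin(deficit))
        return RadiusSuggestion(float(pcf.r_grid[idx]), csr=False, regular=True)
    return RadiusSuggestion(None, csr=True)


def union_of_discs_area(
    pattern: PointPattern, r: float, resolution: int = 512
) -> float:
    """Area of the union of discs of radius r centred at the points.

    Evaluated on a ``resolution`` x ``resolution`` grid of cell centres
    clipped to the observation window, so the returned value is the area
    of the union intersected with the window.
    """
    if r <= 0:
        raise ValueError("disc radius must be positive")
    if resolution < 1:
        raise ValueError("resolution must be a positive integer")
    w = pattern.window
    xs = np.linspace(w.x0, w.x1, resolution, endpoint=False) + w.width / (
        2 * resolution
    )
    ys = np.linspace(w.y0, w.y1, resolution, endpoint=False) + w.height / (
        2 * resolution
    )
    from scipy.spatial import cKDTree

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(pattern.coords)
    dist, _ = tree.query(grid, k=1)
    frac = np.mean(dist <= r)
    return float(frac * w.area)


def area_interaction_logdensity(
    pattern: PointPattern | None,
    r: float,
    xi: float,
    gamma: float,
    beta: float,
    covariate_total: float = 0.0,
    resolution: int = 512,
) -> float:
    """Unnormalised log density of the area-interaction point process.

    The model weights a configuration by xi^n * gamma^(-|U|) * beta^c,
    where |U| is the window-clipped area of the union of interaction discs
    and c a covariate total over the points; gamma > 1 rewards overlapping
    discs (clustering), gamma < 1 penalises them (regularity).  This is
    the evaluation only — no fitting of (xi, gamma, beta) is done here.
    """
    if xi <= 0 or gamma <= 0 or beta <= 0:
        raise ValueError("xi, gamma and beta must be positive")
    if pattern is None:  # empty configuration: only the covariate term survives
        n, u = 0, 0.0
    else:
        n = pattern.n
        u = union_of_discs_area(pattern, r, resolution)
    return n * np.log(xi) - u * np.log(gamma) + covariate_total * np.log(beta)
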