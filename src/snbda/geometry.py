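"""Zones of influence and spatially derived association matrices.

Each individual's zone of influence is a disc of its interaction radius
around its home base.  The association a_ij — the influence of individual
j on individual i — is the area of intersection of the two zones divided
by the area of one of them.  With the default (receiver) normalisation
the denominator is the receiver i's own zone, so a_ij reads as the
proportion of i's zone, hence of i's time, spent under j's influence.
When radii differ the matrix is asymmetric: the same overlap is a larger
fraction of the smaller zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointpattern import PointPattern

__all__ = [
    "Disc",
    "AssociationMatrix",
    "disc_overlap_area",
    "disc_overlap_area_mc",
    "association_matrix",
]


@dataclass(frozen=True)
class Disc:
    """A zone of influence: a disc with a centre and positive radius."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("disc radius must be positive")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass
class AssociationMatrix:
    """n x n matrix of associations a_ij with the ids labelling rows/cols.

    Entry [i, j] is the influence of j on i; all entries lie in [0, 1]
    and the diagonal is zero (no self-influence).
    """

    values: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n matching ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise ValueError("association values must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)


def _lens_area(d: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Vectorised circle-circle intersection (lens) area."""
    d = np.asarray(d, dtype=float)
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), d.shape)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), d.shape)
    out = np.zeros_like(d)

    contained = d <= np.abs(r1 - r2)
    out[contained] = np.pi * np.minimum(r1, r2)[contained] ** 2

    partial = (~contained) & (d < r1 + r2)
    if np.any(partial):
        dd, a, b = d[partial], r1[partial], r2[partial]
        cos1 = np.clip((dd**2 + a**2 - b**2) / (2 * dd * a), -1.0, 1.0)
        cos2 = np.clip((dd**2 + b**2 - a**2) / (2 * dd * b), -1.0, 1.0)
        tri = (-dd + a + b) * (dd + a - b) * (dd - a + b) * (dd + a + b)
        out[partial] = (
            a**2 * np.arccos(cos1)
            + b**2 * np.arccos(cos2)
            - 0.5 * np.sqrt(np.maximum(tri, 0.0))
        )
    return out


def disc_overlap_area(d1: Disc, d2: Disc) -> float:
    """Exact area of intersection of two discs.

    Zero for disjoint discs, the full smaller disc when one contains the
    other, otherwise the closed-form two-segment lens area.
    """
    dist = float(np.hypot(d1.center[0] - d2.center[0], d1.center[1] - d2.center[1]))
    return float(_lens_area(np.array([dist]), d1.radius, d2.radius)[0])


def disc_overlap_area_mc(
    d1: Disc, d2: Disc, n_samples: int = 100_000, seed=None
) -> float:
    """Hit-or-miss Monte Carlo estimate of the disc intersection area.

    Samples uniformly in the bounding box of the intersection region and
    scores the fraction of points falling inside both discs; unbiased,
    with standard error sqrt(p (1-p)) * box_area / sqrt(n).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    (x1, y1), (x2, y2) = d1.center, d2.center
    lox, hix = max(x1 - d1.radius, x2 - d2.radius), min(x1 + d1.radius, x2 + d2.radius)
    loy, hiy = max(y1 - d1.radius, y2 - d2.radius), min(y1 + d1.radius, y2 + d2.radius)
    if lox >= hix or loy >= hiy:
        return 0.0
    rng = np.random.default_rng(seed)
    xs = rng.uniform(lox, hix, n_samples)
    ys = rng.uniform(loy, hiy, n_samples)
    inside = ((xs - x1) ** 2 + (ys - y1) ** 2 <= d1.radius**2) & (
        (xs - x2) ** 2 + (ys - y2) ** 2 <= d2.radius**2
    )
    box = (hix - lox) * (hiy - loy)
    return float(inside.mean() * box)


def association_matrix(
    pattern: PointPattern, normalisation: str = "receiver"
) -> AssociationMatrix:
    """Spatially derived association matrix from zone-of-influence overlap.

    Parameters
    ----------
    pattern
        Point pattern with positive interaction radii set.
    normalisation
        ``"receiver"`` (default): a_ij = |Z_i ∩ Z_j| / |Z_i|, the fraction
        of the receiver i's zone covered by j's — the proportion of time i
        spends under j's influence.  ``"sender"`` divides by the sender
        j's zone instead.

    Zones are not clipped at the window boundary: the zone of influence
    is a property of the individual, not of the survey region.
    """
    if pattern.radii is None:
        raise ValueError("pattern must carry interaction radii")
    if pattern.n < 2:
        raise ValueError("need at least two individuals")
    if normalisation not in ("receiver", "sender"):
        raise ValueError("normalisation must be 'receiver' or 'sender'")
    radii = np.asarray(pattern.radii, dtype=float)
    d = pattern.pairwise_distances()
    lens = _lens_area(d, radii[:, None], radii[None, :])
    zone = np.pi * radii**2
    if normalisation == "receiver":
        values = lens / zone[:, None]
    else:
        values = lens / zone[None, :]
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return AssociationMatrix(values, pattern.ids)
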