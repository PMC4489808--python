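"""Wave-of-advance baseline analysis.

The classical spatial test for social transmission regresses how far an
individual sits from the innovator against how long after the innovation
it first performed the behaviour.  A clean travelling wave gives a
strong linear relationship; a diffusion driven by a patchy social
network typically does not, even when social transmission is strong —
which is exactly the contrast this baseline is kept around to show.

The literature is loose about which variable goes on which axis; the
default here regresses distance on time (slope in distance per unit
time, the wave speed), with ``orientation="time_on_distance"`` for the
transpose.  R^2 is orientation-invariant; the slope is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .pointpattern import PointPattern
from .simulate import DiffusionRecord

__all__ = ["WaveResult", "wave_of_advance"]


@dataclass(frozen=True)
class WaveResult:
    """OLS fit of the wave-of-advance regression."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r_squared: float
    n: int
    orientation: str = "distance_on_time"


def wave_of_advance(
    pattern: PointPattern,
    record: DiffusionRecord,
    innovator_id=None,
    orientation: str = "distance_on_time",
) -> WaveResult:
    """Ordinary least squares of distance-from-innovator vs time.

    The innovator is the individual with the earliest uncensored
    acquisition time (a tie is an error: the origin of the wave must be
    unambiguous); it can be overridden with ``innovator_id``, which must
    still be the earliest acquirer.  All other uncensored individuals
    enter the regression with time measured from the innovation.
    """
    if orientation not in ("distance_on_time", "time_on_distance"):
        raise ValueError("unknown orientation")
    if list(pattern.ids) != list(record.ids):
        raise ValueError("pattern and diffusion record ids do not match")
    if not record.informative:
        raise ValueError("diffusion record has no acquisition events")

    t = np.where(record.censored, np.inf, record.times)
    tmin = t.min()
    earliest = np.flatnonzero(t == tmin)
    if innovator_id is None:
        if earliest.size > 1:
            raise ValueError("tied earliest times: innovator is ambiguous")
        innovator = int(earliest[0])
    else:
        innovator = record.ids.index(innovator_id)
        if t[innovator] != tmin:
            raise ValueError("innovator_id does not have the earliest time")

    mask = (~record.censored) & (np.arange(record.n) != innovator)
    if mask.sum() < 3:
        raise ValueError("need at least three non-innovator uncensored individuals")
    dist = np.hypot(
        pattern.coords[mask, 0] - pattern.coords[innovator, 0],
        pattern.coords[mask, 1] - pattern.coords[innovator, 1],
    )
    dt = record.times[mask] - record.times[innovator]

    x, y = (dt, dist) if orientation == "distance_on_time" else (dist, dt)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: predictor has no variation")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return WaveResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        n=int(mask.sum()),
        orientation=orientation,
    )
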