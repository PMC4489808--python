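"""Hazard models of social transmission and their likelihood.

Three nested continuous-time models describe the rate at which a naive
individual i first performs the behaviour:

* model 1 (asocial null):       lambda_i = lambda0
* model 2 (social):             lambda_i = s' * sum_j a_ij z_j + lambda0
* model 3 (social + environment):
      lambda_i = s' * sum_j a_ij z_j + lambda0 * exp(beta * c_i)

where z_j is 1 once j has performed the behaviour, a_ij the association
of j on i, c_i a normalised environmental covariate, lambda0 the baseline
(asocial) learning rate, s' the rate of social transmission per unit
association with informed individuals, and beta the environmental effect.
Informed individuals have hazard zero.  The equivalent classical
parameterisation uses s = s'/lambda0, the social rate relative to the
asocial rate.

Because the network and the covariates are static, every individual's
hazard is piecewise constant between acquisition events, and the exact
event-history (time-of-acquisition) log-likelihood is

    sum_events log lambda_learner(t_k-)  -  sum_i  integral_0^{end_i} lambda_i(u) du

with end_i the individual's acquisition time or the censoring horizon;
each integral is a finite sum of rate x interval terms.

Parameters are carried on the natural-log scale with independent
Uniform(-10, 10) priors on log lambda0, log s' and log |beta|.  The
environmental effect is signed: its magnitude gets the uniform log prior
and its sign an independent 50/50 prior, so negative effects are in the
support.  (A plain uniform prior on beta itself is available via
``beta_prior="uniform"``.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import AssociationMatrix
from .simulate import DiffusionRecord

__all__ = [
    "ParameterSet",
    "MODEL_PARAMS",
    "hazard",
    "log_likelihood",
    "log_prior",
    "LikelihoodCache",
    "PRIOR_LOW",
    "PRIOR_HIGH",
]

PRIOR_LOW = -10.0
PRIOR_HIGH = 10.0

# Parameters active in each nested model, in update order.
MODEL_PARAMS = {
    1: ("log_lambda0",),
    2: ("log_lambda0", "log_s_prime"),
    3: ("log_lambda0", "log_s_prime", "log_beta_mag"),
}

# Proposal half-widths: 3 for the environmental parameter (pilot-tuned for
# its wide, weakly identified posterior), 1 elsewhere.
DEFAULT_TUNING = {"log_lambda0": 1.0, "log_s_prime": 1.0, "log_beta_mag": 3.0}


@dataclass
class ParameterSet:
    """Parameters of one nested model, on the natural-log scale.

    ``model_id`` 1, 2 or 3 selects which fields are active; inactive
    fields are ignored.  ``beta_sign`` (+1/-1) carries the sign of the
    environmental effect, whose magnitude is exp(log_beta_mag).
    """

    model_id: int
    log_lambda0: float = 0.0
    log_s_prime: float | None = None
    log_beta_mag: float | None = None
    beta_sign: int = 1
    prior_low: float = PRIOR_LOW
    prior_high: float = PRIOR_HIGH
    beta_prior: str = "log_magnitude"
    tuning: dict = field(default_factory=lambda: dict(DEFAULT_TUNING))

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError("model_id must be 1, 2 or 3")
        if self.beta_sign not in (-1, 1):
            raise ValueError("beta_sign must be +1 or -1")
        if self.beta_prior not in ("log_magnitude", "uniform"):
            raise ValueError("beta_prior must be 'log_magnitude' or 'uniform'")
        for name in MODEL_PARAMS[self.model_id]:
            if getattr(self, name) is None:
                raise ValueError(f"model {self.model_id} requires {name}")

    @property
    def active_params(self) -> tuple:
        return MODEL_PARAMS[self.model_id]

    @property
    def lambda0(self) -> float:
        return math.exp(self.log_lambda0)

    @property
    def s_prime(self) -> float:
        if self.model_id == 1 or self.log_s_prime is None:
            return 0.0
        return math.exp(self.log_s_prime)

    @property
    def beta(self) -> float:
        if self.model_id != 3 or self.log_beta_mag is None:
            return 0.0
        if self.beta_prior == "uniform":
            # the stored value IS beta in this parameterisation
            return self.log_beta_mag
        return self.beta_sign * math.exp(self.log_beta_mag)

    @property
    def s(self) -> float:
        """Classical relative social rate s = s' / lambda0."""
        return self.s_prime / self.lambda0

    def updated(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


def log_prior(params: ParameterSet) -> float:
    """Log prior density, up to a constant: 0 inside the box, -inf outside.

    Each active log-parameter has a Uniform(prior_low, prior_high) prior
    on the closed interval (boundary values are inside the support); the
    sign of the environmental effect contributes only a constant.
    """
    for name in params.active_params:
        v = getattr(params, name)
        if not (params.prior_low <= v <= params.prior_high):
            return -np.inf
    return 0.0


def hazard(
    i: int,
    informed: Sequence[bool],
    params: ParameterSet,
    A: AssociationMatrix | np.ndarray,
    covariates: Sequence[float] | None = None,
) -> float:
    """Instantaneous acquisition rate of individual i given the state.

    Zero for an informed individual; otherwise the social term (rate s'
    per unit association with informed neighbours) plus the asocial term
    lambda0 * exp(beta * c_i).
    """
    z = np.asarray(informed, dtype=bool)
    mat = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    n = mat.shape[0]
    if not 0 <= i < n:
        raise ValueError("individual index out of range")
    if z.shape != (n,):
        raise ValueError("status vector must have length n")
    if z[i]:
        return 0.0
    c_i = 0.0
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if np.any(np.isnan(c)):
            raise ValueError("covariates contain NaN")
        c_i = c[i]
    return float(
        params.s_prime * float(mat[i] @ z) + params.lambda0 * math.exp(params.beta * c_i)
    )


class LikelihoodCache:
    """Parameter-independent sufficient statistics of one diffusion.

    For a static network the log-likelihood reduces to

        sum_k log(s' * S_k + lambda0 * exp(beta c_k))
        - s' * W  -  lambda0 * sum_i exp(beta c_i) * E_i

    where, for the k-th acquisition event, S_k is the learner's total
    association with the individuals informed just before the event and
    c_k its covariate; W is the association-weighted naive exposure
    integral and E_i individual i's total time at risk.  All of these are
    computed once, making a likelihood evaluation O(n).
    """

    def __init__(
        self,
        record: DiffusionRecord,
        A: AssociationMatrix | np.ndarray,
        covariates: Sequence[float] | None = None,
        seeded_innovator: bool = False,
        tie_jitter: bool = False,
    ):
        mat = (
            A.values if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
        )
        n = record.n
        if mat.shape != (n, n):
            raise ValueError("association matrix does not match the record")
        if isinstance(A, AssociationMatrix) and list(A.ids) != list(record.ids):
            raise ValueError("association matrix ids do not match the record")
        c = (
            np.zeros(n)
            if covariates is None
            else np.asarray(covariates, dtype=float).copy()
        )
        if c.shape != (n,) or np.any(np.isnan(c)):
            raise ValueError("covariates must be length n and NaN-free")

        times = record.times.copy()
        unc = ~record.censored
        ev_idx = np.flatnonzero(unc)
        if ev_idx.size == 0:
            raise ValueError("diffusion record has no acquisition events")
        ev_t = times[ev_idx]
        order = np.argsort(ev_t, kind="stable")
        ev_idx, ev_t = ev_idx[order], ev_t[order]
        if np.any(np.diff(ev_t) == 0):
            if not tie_jitter:
                raise ValueError(
                    "tied acquisition times; enable tie_jitter or perturb the data"
                )
            import warnings

            warnings.warn("breaking tied acquisition times with deterministic jitter")
            T = record.horizon if np.isfinite(record.horizon) else ev_t.max()
            ev_t = ev_t + 1e-9 * T * np.arange(ev_t.size)

        end = np.where(unc, times, record.horizon)
        if not np.all(np.isfinite(end)):
            raise ValueError("censored individuals need a finite horizon")

        m = ev_idx.size
        # total association with informed set, per individual, per interval
        z = np.zeros(n)
        S_event = np.zeros(m)
        W = 0.0
        prev_t = 0.0
        exposure = end.copy()
        skip = np.zeros(n, dtype=bool)
        if seeded_innovator:
            # innovator's event is conditioned on: no event term, no risk
            skip[ev_idx[0]] = True
            exposure[ev_idx[0]] = 0.0
        for k in range(m):
            t_k = ev_t[k]
            S = mat @ z  # association with informed set during this interval
            at_risk = (end >= prev_t) & ~(z > 0) & ~skip
            dur = np.minimum(end, t_k) - prev_t
            W += float((S * np.clip(dur, 0.0, None) * at_risk).sum())
            S_event[k] = S[ev_idx[k]]
            z[ev_idx[k]] = 1.0
            prev_t = t_k
        # tail interval: censored individuals at risk beyond the last event
        tail = (end > prev_t) & ~(z > 0) & ~skip
        if tail.any():
            S = mat @ z
            W += float((S * (end - prev_t) * tail).sum())

        keep_ev = ~skip[ev_idx]
        self.n = n
        self.S_event = S_event[keep_ev]
        self.c_event = c[ev_idx[keep_ev]]
        self.W = W
        self.exposure = exposure
        self.c = c
        self.n_events = int(keep_ev.sum())

    def loglik(self, lambda0: float, s_prime: float, beta: float) -> float:
        """Event-history log-likelihood at the given natural-scale rates."""
        with np.errstate(over="ignore"):
            asoc_ev = lambda0 * np.exp(beta * self.c_event)
            lam_ev = s_prime * self.S_event + asoc_ev
            if np.any(lam_ev <= 0):
                return -np.inf
            survival = s_prime * self.W + lambda0 * float(
                (np.exp(beta * self.c) * self.exposure).sum()
            )
        if not np.isfinite(survival) or not np.all(np.isfinite(lam_ev)):
            # overflowing hazards carry an infinite cumulative hazard
            return -np.inf
        return float(np.log(lam_ev).sum() - survival)

    def loglik_params(self, params: ParameterSet) -> float:
        return self.loglik(params.lambda0, params.s_prime, params.beta)


def log_likelihood(
    data: DiffusionRecord,
    A: AssociationMatrix | np.ndarray,
    covariates: Sequence[float] | None,
    params: ParameterSet,
    seeded_innovator: bool = False,
) -> float:
    """Time-of-acquisition log-likelihood of one diffusion.

    Returns -inf when an observed event has zero hazard under ``params``
    (inconsistent inputs, e.g. underflow of the asocial rate with no
    informed neighbours).
    """
    cache = LikelihoodCache(data, A, covariates, seeded_innovator=seeded_innovator)
    return cache.loglik_params(params)
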