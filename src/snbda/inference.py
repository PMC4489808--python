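"""Bayesian inference for the social-transmission hazard models.

Within-model sampling is component-wise uniform random-walk Metropolis on
the log-scale parameters: each parameter alpha in turn receives a
proposal Uniform[alpha - eps, alpha + eps] with a parameter-specific
tuning half-width eps.  Model discrimination treats the model indicator
as an additional parameter and samples it with reversible-jump moves:
a jump to another nested model keeps the shared parameters and draws any
newly introduced parameters from their priors, so the Jacobian is one and
the acceptance ratio reduces to the likelihood ratio.  Posterior model
probabilities are retained-visit fractions, and the Bayes factor between
two models (under the uniform model prior) is their ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import AssociationMatrix
from .model import (
    DEFAULT_TUNING,
    MODEL_PARAMS,
    PRIOR_HIGH,
    PRIOR_LOW,
    LikelihoodCache,
    ParameterSet,
    log_prior,
)
from .simulate import DiffusionRecord

__all__ = [
    "McmcTrace",
    "PosteriorSummary",
    "mh_sample",
    "rjmcmc_sample",
    "posterior_summary",
    "bayes_factor",
    "bayes_factor_from_counts",
    "pilot_tune",
]

ALL_PARAM_NAMES = ("log_lambda0", "log_s_prime", "log_beta_mag")


@dataclass
class McmcTrace:
    """Raw MCMC output: per-iteration log-scale parameter values.

    ``params[name]`` is an array of length ``n_iter`` with NaN where the
    parameter was inactive (RJMCMC visiting a smaller model).  ``models``
    holds the per-iteration model indicator (constant for plain MH).
    Acceptance counts are per parameter plus, for RJMCMC, the
    between-model move under the key ``"jump"``.
    """

    n_iter: int
    burn_in: int
    params: dict
    models: np.ndarray
    accept: dict
    attempts: dict
    seed: object = None
    beta_sign: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.burn_in

    def retained(self, name: str) -> np.ndarray:
        """Post-burn-in draws of one parameter (NaN where inactive)."""
        return self.params[name][self.burn_in :]

    def retained_models(self) -> np.ndarray:
        return self.models[self.burn_in :]

    def acceptance_rate(self, name: str) -> float:
        att = self.attempts.get(name, 0)
        return self.accept.get(name, 0) / att if att else float("nan")


@dataclass
class PosteriorSummary:
    """Posterior means and symmetric 95% credible intervals (log scale).

    ``params[name] = (mean, low, high)`` where low/high are the 2.5% and
    97.5% quantiles of the retained draws (linear interpolation of order
    statistics); ``model_probs`` are retained-visit fractions.
    """

    params: dict
    model_probs: dict = field(default_factory=dict)
    n_retained: int = 0

    def __str__(self) -> str:  # Table-style "mean(low,high)" rendering
        lines = []
        for name, (m, lo, hi) in self.params.items():
            lines.append(f"{name}: {m:.3f}({lo:.3f},{hi:.3f})")
        if self.model_probs:
            probs = ", ".join(
                f"model {k}: {v:.4f}" for k, v in sorted(self.model_probs.items())
            )
            lines.append(probs)
        return "\n".join(lines)


def _prepare_cache(data, A, covariates, seeded_innovator):
    """LikelihoodCache(s), or None for the prior-only (flat likelihood) case.

    ``data`` may be a single diffusion record or a sequence of them
    (replicate diffusions on the same network contribute additively to
    the log-likelihood).
    """
    if data is None:
        return None
    if isinstance(data, DiffusionRecord):
        data = [data]
    return [
        LikelihoodCache(rec, A, covariates, seeded_innovator=seeded_innovator)
        for rec in data
    ]


def _loglik(caches, params: ParameterSet) -> float:
    if caches is None:
        return 0.0
    return sum(c.loglik_params(params) for c in caches)


def _init_params(model_id, rng, tuning, beta_prior) -> ParameterSet:
    vals = {name: rng.uniform(PRIOR_LOW, PRIOR_HIGH) for name in MODEL_PARAMS[model_id]}
    sign = int(rng.choice([-1, 1]))
    return ParameterSet(
        model_id, beta_sign=sign, beta_prior=beta_prior, tuning=tuning, **vals
    )


def _mh_sweep(state: ParameterSet, cache, ll: float, rng) -> tuple:
    """One component-wise Metropolis sweep; returns (state, ll, accepted)."""
    accepted = {}
    for name in state.active_params:
        eps = state.tuning.get(name, 1.0)
        cur = getattr(state, name)
        prop_val = cur + rng.uniform(-eps, eps)
        kwargs = {name: prop_val}
        if name == "log_beta_mag" and state.beta_prior == "log_magnitude":
            # symmetric sign flip alongside the magnitude walk
            if rng.uniform() < 0.5:
                kwargs["beta_sign"] = -state.beta_sign
        prop = state.updated(**kwargs)
        if log_prior(prop) == -np.inf:
            accepted[name] = False
            continue
        ll_prop = _loglik(cache, prop)
        if np.log(rng.uniform()) < ll_prop - ll:
            state, ll = prop, ll_prop
            accepted[name] = True
        else:
            accepted[name] = False
    return state, ll, accepted


def _record(params_store, i, state: ParameterSet):
    for name in ALL_PARAM_NAMES:
        v = getattr(state, name)
        params_store[name][i] = np.nan if (v is None or name not in state.active_params) else v


def mh_sample(
    model_id: int,
    data: DiffusionRecord | None,
    A: AssociationMatrix | np.ndarray | None,
    covariates: Sequence[float] | None = None,
    params0: ParameterSet | None = None,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    tuning: dict | None = None,
    seed=None,
    beta_prior: str = "log_magnitude",
    seeded_innovator: bool = False,
) -> McmcTrace:
    """Component-wise random-walk Metropolis within one model.

    Passing ``data=None`` switches the likelihood off, so the chain
    targets the prior — the standard sampler validity check.  The chain
    is reproducible given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    tuning = dict(DEFAULT_TUNING, **(tuning or {}))
    if any(eps <= 0 for eps in tuning.values()):
        raise ValueError("tuning half-widths must be positive")
    rng = np.random.default_rng(seed)
    cache = _prepare_cache(data, A, covariates, seeded_innovator)

    if params0 is None:
        state = _init_params(model_id, rng, tuning, beta_prior)
    else:
        state = params0.updated(tuning=tuning, beta_prior=beta_prior)
        if log_prior(state) == -np.inf:
            raise ValueError("initial parameters outside the prior support")
    ll = _loglik(cache, state)

    names = MODEL_PARAMS[model_id]
    params_store = {n_: np.full(n_iter, np.nan) for n_ in ALL_PARAM_NAMES}
    signs = np.ones(n_iter, dtype=int)
    accept = {n_: 0 for n_ in names}
    attempts = {n_: 0 for n_ in names}
    for i in range(n_iter):
        state, ll, acc = _mh_sweep(state, cache, ll, rng)
        for n_, a in acc.items():
            attempts[n_] += 1
            accept[n_] += a
        _record(params_store, i, state)
        signs[i] = state.beta_sign
    return McmcTrace(
        n_iter,
        burn_in,
        params_store,
        np.full(n_iter, model_id),
        accept,
        attempts,
        seed,
        beta_sign=signs,
    )


def rjmcmc_sample(
    model_ids: Sequence[int],
    data: DiffusionRecord | None,
    A: AssociationMatrix | np.ndarray | None,
    covariates: Sequence[float] | None = None,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    tuning: dict | None = None,
    move_prob: float = 0.5,
    seed=None,
    beta_prior: str = "log_magnitude",
    seeded_innovator: bool = False,
) -> McmcTrace:
    """Reversible-jump MCMC over a set of nested hazard models.

    Each iteration attempts, with probability ``move_prob``, a jump to a
    uniformly chosen other model — shared parameters are kept and newly
    activated ones drawn from their priors, accepted with probability
    min(1, likelihood ratio) — and then performs a within-model
    Metropolis sweep.  The model indicator trace gives posterior model
    probabilities as visit fractions.
    """
    model_ids = sorted(set(int(m) for m in model_ids))
    if len(model_ids) < 2:
        raise ValueError("RJMCMC needs at least two models")
    if any(m not in MODEL_PARAMS for m in model_ids):
        raise ValueError("model ids must be a subset of {1, 2, 3}")
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    tuning = dict(DEFAULT_TUNING, **(tuning or {}))
    rng = np.random.default_rng(seed)
    cache = _prepare_cache(data, A, covariates, seeded_innovator)

    state = _init_params(model_ids[0], rng, tuning, beta_prior)
    ll = _loglik(cache, state)

    params_store = {n_: np.full(n_iter, np.nan) for n_ in ALL_PARAM_NAMES}
    models = np.zeros(n_iter, dtype=int)
    signs = np.ones(n_iter, dtype=int)
    accept = {n_: 0 for n_ in ALL_PARAM_NAMES}
    accept["jump"] = 0
    attempts = {n_: 0 for n_ in ALL_PARAM_NAMES}
    attempts["jump"] = 0

    # carry last-seen values of inactive parameters so a jump back can
    # start from fresh prior draws (drawn at jump time, not remembered)
    for i in range(n_iter):
        if rng.uniform() < move_prob:
            attempts["jump"] += 1
            others = [m for m in model_ids if m != state.model_id]
            target = others[rng.integers(len(others))]
            kwargs = {}
            for name in MODEL_PARAMS[target]:
                if name in state.active_params:
                    kwargs[name] = getattr(state, name)
                else:  # birth: draw from the prior (Jacobian 1)
                    kwargs[name] = rng.uniform(PRIOR_LOW, PRIOR_HIGH)
            sign = state.beta_sign
            if "log_beta_mag" in MODEL_PARAMS[target] and "log_beta_mag" not in state.active_params:
                sign = int(rng.choice([-1, 1]))
            prop = ParameterSet(
                target,
                beta_sign=sign,
                beta_prior=beta_prior,
                tuning=tuning,
                **kwargs,
            )
            ll_prop = _loglik(cache, prop)
            # prior and proposal densities cancel; model proposal symmetric
            if np.log(rng.uniform()) < ll_prop - ll:
                state, ll = prop, ll_prop
                accept["jump"] += 1
        state, ll, acc = _mh_sweep(state, cache, ll, rng)
        for n_, a in acc.items():
            attempts[n_] += 1
            accept[n_] += a
        _record(params_store, i, state)
        models[i] = state.model_id
        signs[i] = state.beta_sign
    return McmcTrace(
        n_iter,
        burn_in,
        params_store,
        models,
        accept,
        attempts,
        seed,
        beta_sign=signs,
    )


def posterior_summary(
    trace: McmcTrace, burn_in: int | None = None
) -> PosteriorSummary:
    """Means and symmetric 95% credible intervals of the retained draws.

    Quantiles use linear interpolation of the order statistics (the
    default numpy rule).  For RJMCMC traces each parameter is summarised
    over the iterations in which it was active, and model probabilities
    are the retained-visit fractions.
    """
    if burn_in is None:
        burn_in = trace.burn_in
    if not 0 <= burn_in < trace.n_iter:
        raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
    out = {}
    for name, values in trace.params.items():
        v = values[burn_in:]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        out[name] = (
            float(v.mean()),
            float(np.quantile(v, 0.025)),
            float(np.quantile(v, 0.975)),
        )
    if not out:
        raise ValueError("no retained draws to summarise")
    models = trace.models[burn_in:]
    uniq, counts = np.unique(models, return_counts=True)
    probs = {int(m): float(cnt) / models.size for m, cnt in zip(uniq, counts)}
    return PosteriorSummary(out, probs, n_retained=models.size)


def bayes_factor_from_counts(count_a: int, count_b: int) -> float:
    """Bayes factor of model a over model b from retained-visit counts.

    Under a uniform prior over the candidate models the posterior odds
    equal the Bayes factor, so the ratio of visit counts estimates it.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_b == 0:
        warnings.warn(
            "model b never visited; Bayes factor reported as +inf "
            f"(counts {count_a}/{count_b})"
        )
        return float("inf")
    return count_a / count_b


def bayes_factor(trace: McmcTrace, model_a: int, model_b: int) -> float:
    """Bayes factor of ``model_a`` over ``model_b`` from an RJMCMC trace."""
    models = trace.retained_models()
    ca = int((models == model_a).sum())
    cb = int((models == model_b).sum())
    if ca == 0:
        warnings.warn(f"model {model_a} never visited after burn-in")
    return bayes_factor_from_counts(ca, cb)


def pilot_tune(
    model_id: int,
    data: DiffusionRecord,
    A,
    covariates=None,
    seed=None,
    n_pilot: int = 500,
    target: tuple[float, float] = (0.2, 0.5),
    max_rounds: int = 8,
    tuning: dict | None = None,
    **mh_kwargs,
) -> dict:
    """Adjust proposal half-widths until acceptance rates hit ``target``.

    Runs short pilot chains, doubling eps when acceptance is above the
    band and halving it when below — the usual pilot-tuning exercise run
    before the production chain.
    """
    tuning = dict(DEFAULT_TUNING, **(tuning or {}))
    ss = np.random.SeedSequence(seed)
    for round_seed in ss.spawn(max_rounds):
        trace = mh_sample(
            model_id,
            data,
            A,
            covariates,
            n_iter=n_pilot,
            burn_in=0,
            tuning=tuning,
            seed=round_seed,
            **mh_kwargs,
        )
        done = True
        for name in MODEL_PARAMS[model_id]:
            rate = trace.acceptance_rate(name)
            if rate > target[1]:
                tuning[name] *= 2.0
                done = False
            elif rate < target[0]:
                tuning[name] /= 2.0
                done = False
        if done:
            break
    return tuning
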