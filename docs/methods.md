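# Methods

## Model

A population of n individuals occupies fixed home bases in a rectangular
observation window. Individual i's zone of influence is the disc
B(ν_i, r_i) of interaction radius r_i around its home base; the
association of j on i is

    a_ij = |B(ν_i, r_i) ∩ B(ν_j, r_j)| / |B(ν_i, r_i)|.

Normalising by the *receiver's* zone makes a_ij the fraction of i's zone
covered by j — the proportion of i's time spent under j's influence —
and reproduces the expected asymmetry when radii differ: the same
overlap is a larger share of the smaller zone. Dividing by the sender's
zone instead is available via `association_matrix(..., normalisation="sender")`
(the two conventions are transposes of each other). Zones are *not*
clipped at the window boundary: the zone is a property of the
individual, not of the survey region. Overlap areas use the closed-form
circle–circle lens formula; `disc_overlap_area_mc` retains a hit-or-miss
Monte Carlo estimator as an independent cross-check (unbiased, standard
error `box·sqrt(p(1−p)/N)`).

Given the static network A and normalised covariates c, a naive
individual acquires the behaviour with hazard

    λ_i(t) = (1 − z_i(t)) ( s′ Σ_{j≠i} a_ij z_j(t) + λ0 exp(β c_i) ),

nested as model 1 (λ0 only), model 2 (λ0, s′), model 3 (λ0, s′, β).
s′ is the social transmission rate per unit association; the classical
relative rate is s = s′/λ0.

## Likelihood

The data are exact first-performance times (censoring at the horizon is
supported). Because the network and covariates are static, each hazard
is piecewise constant between acquisition events, and the event-history
log-likelihood

    Σ_k log λ_{learner(k)}(t_k⁻) − Σ_i ∫_0^{end_i} λ_i(u) du

is exact, with `end_i` the acquisition time or the censoring horizon.
`LikelihoodCache` reduces it to parameter-independent sufficient
statistics (per-event social exposure S_k, the association-weighted
naive-exposure integral W, per-individual time at risk), so an
evaluation costs O(n) — this is what makes replicate MCMC studies cheap.
Multiple diffusions on the same network contribute additively; the
inference functions accept a single record or a list.

Conventions: t = 0 at the start of observation; the innovator's event is
modelled like any other (asocial) acquisition unless
`seeded_innovator=True`, which conditions on it (no event term, no
exposure). Tied event times are rejected by default; an explicit
`tie_jitter` option breaks them with a deterministic 1e−9·T perturbation
and a warning. Hazards that overflow or vanish at an observed event
yield −inf rather than an exception inside samplers.

## Priors and parameterisation

log λ0, log s′ and log |β| carry independent Uniform(−10, 10) priors
(closed interval; the boundary is inside the support). The
environmental effect is signed: its magnitude gets the uniform log prior
and its sign an independent 50/50 prior, so negative effects — which
real covariates routinely produce — have support; `beta_prior="uniform"`
switches to a plain uniform prior on β itself. Posterior summaries
report the sampled coordinates (natural-log scale) as mean and 2.5%/97.5%
quantiles with numpy's linear interpolation of order statistics.

## Sampling

Within-model updates are component-wise uniform random walks,
U[α − ε, α + ε] per parameter, with default half-widths ε = 1 for the
rate parameters and ε = 3 for the environmental parameter (its posterior
is wide and weakly identified; `pilot_tune` adjusts ε toward acceptance
rates of 0.2–0.5 by doubling/halving over short pilot chains). The sign
of β is proposed to flip with probability 1/2 alongside its magnitude
update — a symmetric move.

Model discrimination treats the model indicator as a parameter. With
probability 0.5 per iteration (configurable) a jump to a uniformly
chosen other model is attempted: shared parameters are kept, newly
activated ones drawn from their priors. Because proposal and prior
densities cancel and the models are nested with identity mappings on
shared parameters (Jacobian 1), the acceptance probability is
min(1, likelihood ratio). This is the simplest valid reversible-jump
scheme and mixes well at these dimensions (1–3 parameters). Defaults:
20,000 iterations with 2,000 burn-in. Posterior model probabilities are
retained-visit fractions; the Bayes factor between two models under the
uniform model prior is their ratio (infinite, with a warning, when the
denominator model is never visited). All samplers are bit-reproducible
given a seed.

Caveat for validity checks: raw random-walk draws are autocorrelated, so
distributional tests (e.g. KS against the prior) are applied to thinned
chains run with wide proposals; see `tests/test_acceptance.py`.

## Point-pattern diagnostics

Ripley's K uses the translation edge correction for rectangular windows
with the unbiased pair-count normalisation n(n−1)/|W|; distances beyond
half the shorter window side are flagged NaN with a warning. The pair
correlation g(r) is estimated by Epanechnikov-kernel smoothing of the
pairwise distances with Stoyan's rule-of-thumb bandwidth h = 0.15/√ξ
(ξ = n/|W|). Estimates are flagged unreliable where fewer than five
pairwise distances fall within one bandwidth or where r < h (the kernel
window spills past zero distance and the 1/(2πr) factor makes the
estimate explode) — at very small distances g is undefined in practice.

CSR envelopes are pointwise min/max of g over n_sim (default 99)
binomial patterns with the same n and window, at a fixed bandwidth so
curves are comparable. The interaction-radius heuristic returns the
distance at which g most exceeds the upper envelope (ties break toward
the smaller r — associations are local, so large scales are avoided); a
pattern below the lower envelope returns the deepest-dip distance with a
`regular` flag; a pattern inside the envelope returns no radius with a
CSR flag. Note that for cluster processes g is largest at small r, so
the suggestion typically lands just above the reliability cutoff and
near the cluster scale; it is a starting point, to be combined with
biological knowledge and sensitivity analysis over r.

The area-interaction machinery is evaluation-only: `union_of_discs_area`
computes |U_{ν,r}| (the union of interaction discs clipped to the
window) on a resolution² grid of cell centres (default 512², accurate to
well under 1% at these geometries), and `area_interaction_logdensity`
returns the unnormalised log density n·log ξ − |U|·log γ + c·log β.
Fitting the area-interaction process is out of scope.

## Synthetic data

The generator reproduces the structure of the study system the method
targets, and its defaults are the study conditions:

- **Pattern**: Matérn-cluster process, parents Poisson(κ) on the window
  dilated by the cluster radius, Poisson(μ) offspring uniform in a disc.
  Defaults κ = 8, μ = 3.25, cluster radius 0.05 on the unit square — 26
  expected nests in tight clusters, analysed at interaction radius 0.05.
  Realised n is Poisson-variable (occasionally far from 26); that
  variation is part of the process and is not conditioned away.
- **Environment**: the linear gradient E(x, y) = 3x − 2y, z-scored over
  the n individuals (min-max scaling available). The uniform-environment
  variant uses a constant covariate.
- **Diffusions**: exact Gillespie simulation of the hazard above;
  defaults λ0 = exp(−1.6) ≈ 0.20 and s′ = exp(0.84) ≈ 2.32, β = 0 —
  the magnitudes of a strongly social system — with ten replicate
  diffusions per study and no censoring (a finite horizon censors).
- **Controls**: `kind="csr"` draws a binomial (CSR) pattern and purely
  asocial diffusions (s′ = 0); a minimal sequential-inhibition hard-core
  generator produces regular patterns for tests.

A master seed spawns independent streams for the pattern and each
diffusion, so any component is reproducible in isolation.

What the generator does *not* emulate: observation error in locations or
times, time-varying home bases, individual heterogeneity in asocial
rates, non-constant baselines, and directed observation effort. Tests
passing on these synthetic systems therefore demonstrate the estimator's
correctness and power under the model's own assumptions, not robustness
to their violation.

## Validation scale

The validation suite works at deliberately modest problem sizes chosen
to exercise the study conditions: 50-replicate parameter-recovery and
radius-selection studies at n ≈ 26, MCMC chains of 4,000–20,000
iterations, 99-simulation envelopes, and 10⁵-sample Monte Carlo
geometry checks. Coverage checks allow Monte Carlo slack (≥85% observed
for nominal 95% intervals over 50 replicates); distributional checks use
lenient thresholds (KS p > 0.001) because their purpose is to catch
implementation errors, not small approximation effects.

## Known limitations

- The disc-overlap association is geometric: it ignores movement,
  temporal overlap and habitat barriers; constant influence within the
  zone (no distance decay).
- Exactly tied acquisition times have likelihood zero under a
  continuous-time model; they signal data coarsening that the model does
  not represent (the jitter option is a pragmatic workaround).
- Prior-draw reversible jumps would mix poorly in higher-dimensional
  model spaces; they are adequate for these three nested models.
- With weak social information the s′ posterior reproduces the prior's
  lower tail (small s′ is never excluded); report interval widths, not
  just means, when the network is sparse.
- The radius heuristic assumes the clustering scale is the interaction
  scale — a modelling judgement, not a fact; sensitivity analysis over r
  is recommended whenever the pair-correlation plot shows structure at
  several scales.
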