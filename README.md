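# snbda — spatial network-based diffusion analysis

Network-based diffusion analysis (NBDA) detects and quantifies social
transmission by asking whether the times at which individuals first
perform a novel behaviour follow a social network. Often no direct
association data exist — only the locations of nests or home bases.
`snbda` fills that gap: it derives the social network from space itself,
and fits continuous-time models of social transmission to diffusion data
in a Bayesian framework.

It is aimed at behavioural ecologists and epidemiological modellers with
data of the form *who sits where, and when did each individual first show
the behaviour* — territorial species with identifiable home bases being
the canonical case.

## The model

Each individual occupies a **zone of influence**: a disc of interaction
radius *r* around its home base. The association of individual *j* on
*i* is the normalised overlap of their zones,

    a_ij = |Z_i ∩ Z_j| / |Z_i|,

the proportion of *i*'s zone (hence of *i*'s time) spent under *j*'s
influence; with unequal radii the matrix is asymmetric. Disc overlaps
are computed in closed form (a Monte Carlo estimator is kept as a
cross-check).

A naive individual *i* acquires the behaviour with hazard

    λ_i(t) = (1 − z_i(t)) ( s′ Σ_j a_ij z_j(t) + λ0 exp(β c_i) ),

where `z_j(t)` indicates whether *j* is already informed, `λ0` is the
baseline (asocial) learning rate, `s′` the rate of social transmission
per unit association with informed individuals (equivalently s = s′/λ0
relative to baseline), and `β` the effect of a normalised environmental
covariate `c_i`. Three nested models — {λ0}, {λ0, s′}, {λ0, s′, β} —
are fitted to the exact acquisition times via the event-history
likelihood, with Uniform(−10, 10) priors on the log parameters,
component-wise random-walk Metropolis updates, and reversible-jump MCMC
for model discrimination (posterior model probabilities and Bayes
factors from retained-visit counts).

The interaction radius is chosen from the data: the pair correlation
function g(r), compared against simulation envelopes from complete
spatial randomness (CSR), identifies the spatial scale of strongest
clustering. A wave-of-advance regression (distance from the innovator
vs time since innovation) is included as the classical baseline, and a
Gillespie simulator generates exact synthetic diffusions for power
studies and validation.

## Worked example

`examples/04_fit_and_discriminate.py` simulates a clustered population
(~26 nests in tight clusters on the unit square), derives the network at
radius 0.05, simulates ten diffusions with log λ0 = −1.60 and
log s′ = 0.84, and fits the models:

```
28 individuals, 10 diffusions
generating values: log lambda0 = -1.60, log s' = 0.84

model 2 posterior, mean (95% credible interval), natural-log scale:
log_lambda0: -1.594(-1.833,-1.361)
log_s_prime: 0.813(0.655,0.965)

reversible-jump model discrimination:
  model 2: posterior probability 0.7046
  model 3: posterior probability 0.2954
Bayes factor, social vs social+environment: 2.38
```

The posterior means recover the generating rates, the asocial null
(model 1) is never visited — strong evidence of social transmission —
and the environmental model earns no extra support because the data were
generated without an environmental effect. On the same diffusion the
wave-of-advance baseline (`examples/05_wave_of_advance.py`) reports
R² = 0.025: distance from the innovator explains almost nothing, the
blind spot of the classical approach.

The other examples cover the association geometry (`01`), radius choice
by pair-correlation envelopes (`02`), and Gillespie simulation (`03`).
A thin CLI wraps the same functions
(`snbda simulate | explore | associations | fit | rjmcmc | wave | pipeline`);
`snbda pipeline --config cfg.yaml` runs the whole workflow and writes
every intermediate product plus a reproducibility manifest.

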