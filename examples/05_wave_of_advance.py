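"""Wave-of-advance baseline vs the network analysis on the same data.

The classical wave-of-advance test regresses distance-from-innovator on
time-since-innovation.  On a clustered social diffusion it fits poorly —
the behaviour hops between clusters rather than advancing as a front —
while the network-based analysis on the same data detects the social
effect clearly.
"""

from snbda import generate_study, posterior_summary, rjmcmc_sample, wave_of_advance

study = generate_study(kind="clustered", seed=42)
record = study.diffusions[0]

res = wave_of_advance(study.pattern, record)
print(f"wave-of-advance OLS (distance on time), n = {res.n}:")
print(f"  slope {res.slope:.3f} +/- {res.slope_se:.3f}, "
      f"p = {res.p_value:.3f}, R^2 = {res.r_squared:.3f}")

trace = rjmcmc_sample(
    [1, 2], record, study.network, study.covariates,
    n_iter=10_000, burn_in=1_000, seed=3,
)
p2 = posterior_summary(trace).model_probs.get(2, 0.0)
print(f"\nnetwork analysis on the same diffusion: P(social model) = {p2:.3f}")
print("(low R^2 says distance from the innovator explains almost none of"
      " the timing; the network model nonetheless finds strong social"
      " transmission — the contrast the wave approach misses)")
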