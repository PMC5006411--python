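"""Generate one synthetic multicenter trial and fit all seven methods.

The scenario: 18 centers of 50 subjects, control outcome rate 0.25, true
risk difference 0.10, intracenter correlation 0.05, a binary baseline
covariate (prevalence 0.3) raising risk by 50 %.
"""

import rdgee

spec = rdgee.ScenarioSpec(
    true_link="identity", n_centers=18, n_per_center=50,
    pi_c=0.25, true_rd=0.10, icc=0.05,
    covariate_effect="fifty_percent", seed=2024,
)
params = rdgee.derive_params(spec)
print(f"derived: alpha={params.alpha:.3f} beta={params.beta:.3f} "
      f"gamma={params.gamma:.3f} sigma2={params.sigma2:.4f}")

data = rdgee.simulate_trial(spec)
results = rdgee.analyze_trial(data, include_covariate=True)
print(rdgee.results_table(results).round(3).to_string(index=False))

# One replicate's estimates scatter around the true RD of 0.10; the six
# GEE models agree closely with each other because they target the same
# marginal (population-averaged) risk difference.
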