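"""A small coverage/bias benchmark on a reduced factorial grid.

Runs two contrasting scenarios at 300 replicates each (a desk-scale
version of the full 432-scenario x 1000-replicate study) and prints the
per-method performance table.
"""

import rdgee

scenarios = [
    # identity response, no covariate: everything behaves
    rdgee.ScenarioSpec(true_link="identity", pi_c=0.25, true_rd=0.10,
                       icc=0.05, n_per_center=10, seed=3, scenario_index=0),
    # log response with covariate and a large center variance: the
    # unadjusted method underestimates its SE
    rdgee.ScenarioSpec(true_link="log", pi_c=0.10, true_rd=0.10, icc=0.05,
                       n_per_center=50, covariate_effect="fifty_percent",
                       seed=3, scenario_index=1),
]

results = [rdgee.run_scenario(s, n_reps=300) for s in scenarios]
table = rdgee.summarize_results(results)
wide = table.pivot_table(index=["link", "covariate", "method"],
                         columns="metric", values="value").round(3)
print(wide)

# Expect GEE coverage near 0.95 in both scenarios, while the unadjusted
# 2x2 interval undercovers (<0.90) under the log response: its Wald SE
# ignores the between-center variability that the treatment effect
# inherits there.  Bias stays within a few thousandths throughout.
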