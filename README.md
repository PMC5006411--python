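# rdgee

Absolute risk-difference estimation for clustered binary outcomes from
multicenter and cluster-randomized trials, with a simulation framework for
benchmarking the competing estimators.

## The problem

Trials with binary outcomes should report the absolute risk difference
RD = π(1) − π(0), the quantity clinicians and patients actually weigh. In a
multicenter trial, outcomes from the same center are correlated (intracenter
correlation ρ), and randomization is usually stratified by center, so the
analysis must account for center. `rdgee` implements the seven estimators a
trial statistician would compare:

six marginal (population-averaged) regression models fitted by generalized
estimating equations with an exchangeable working correlation —

| model | mean model | RD estimate |
|---|---|---|
| binomial / Poisson / normal, identity link | π_ij = α + β·x_ij (+ γ·z_ij) | β̂ directly |
| binomial / Poisson, log link | log π_ij = α + β·x_ij (+ γ·z_ij) | marginal standardization |
| binomial, logit link | logit π_ij = α + β·x_ij (+ γ·z_ij) | marginal standardization |

— plus the unadjusted pooled 2×2 table (e₁/n₁ − e₀/n₀, Wald SE).

For the nonlinear links the RD is the **average risk difference**

    RD̂ = (1/n) Σ_ij [ π̂_ij(1) − π̂_ij(0) ],

each subject's outcome probability predicted under both counterfactual
treatment assignments at their own covariate value, with a delta-method
standard error propagated through the robust sandwich covariance. Because
the number of centers J is small, the robust variance is inflated by
J/(J−p−1) (p non-intercept regressors) before forming the Wald interval
RD̂ ± 1.96·SE.

## Worked example

The package ships an eight-center randomized trial of an active drug
against an infection (273 subjects; per-center cure rates 0–86 %):

```python
import rdgee

data = rdgee.load_beitler_landis()
print(rdgee.results_table(rdgee.analyze_trial(data)).round(3))
```

```
           method    rd    se  ci_low  ci_high   icc
binomial-identity 0.126 0.059   0.011    0.241 0.217
 poisson-identity 0.125 0.058   0.012    0.238 0.218
  normal-identity 0.127 0.060   0.011    0.244 0.216
     binomial-log 0.126 0.059   0.011    0.241 0.217
      poisson-log 0.125 0.058   0.012    0.238 0.218
   binomial-logit 0.126 0.059   0.011    0.241 0.217
       unadjusted 0.094 0.058  -0.020    0.209   NaN
```

All six GEE models agree: the drug cures about 12.6 more patients per 100
than control (95 % CI excluding zero) once the large between-center
variation (ICC ≈ 0.22) is accounted for. The unadjusted estimate is pulled
down to 0.094 (CI crossing zero) by one center's allocation imbalance —
dropping that center (`data.drop_centers([2])`) brings the two approaches
together (0.133 vs 0.129). See `examples/` for runnable scripts covering
each capability.

## Simulation framework

`rdgee.simulate_trial` generates clustered binary trials from an identity-
or log-link response with a Normal random center effect calibrated to a
target ICC, permuted-block randomization (block size 4) stratified by
center, and an optional binary baseline covariate. `rdgee.run_scenario` /
`rdgee.factorial_grid` replicate the full 432-cell factorial design
(2 links × 4 RDs × 3 control rates × 3 ICCs × 3 center sizes × 2 covariate
settings), scoring every method on convergence rate, bias and 95 % CI
coverage. A thin CLI wraps the library:

```sh
rdgee analyze --input trial_counts.csv                  # Table of RD estimates
rdgee simulate --scenario scenario.yaml --reps 100 --out sims/
rdgee grid --config grid.yaml --reps 1000 --seed 1 --out results.csv
```

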