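# Methods

## Marginal models and the GEE fitter

All six regression estimators share the population-averaged mean model
g(π_ij) = α + β·x_ij (+ γ·z_ij) for subject i in center j, where x is the
binary treatment indicator and z an optional binary baseline covariate.
They differ only in the link g (identity, log, logit) and in the working
variance function (binomial π(1−π), Poisson π, normal constant). The
Poisson and normal "families" are deliberate misspecifications for binary
data; the robust sandwich covariance keeps their inference valid, which is
why the package reports only sandwich standard errors (model-based SEs are
out of scope).

Fitting is Fisher-scoring GEE under an exchangeable working correlation:
within a center every outcome pair shares correlation ρ, across centers
outcomes are independent. The exchangeable structure makes every estimator
invariant to center relabeling and within-center record order (asserted by
permutation tests in the suite), and its correlation matrix has a
closed-form inverse, so each scoring step costs O(n·q²) without any matrix
factorization per cluster.

Moment estimators follow the conventions of the estimating-equation
software lineage this field uses: Pearson-residual scale
φ = Σe²/(N−q), and exchangeable correlation
ρ̂ = Σ_j Σ_{i<k} e_ij e_kj / (φ·[Σ_j n_j(n_j−1)/2 − q]), with q the number
of mean parameters including the intercept. Different packages subtract
slightly different constants in these denominators; for the bundled
eight-center example the resulting ICC differs by less than 0.002 across
conventions. The statsmodels GEE implementation, used in the test suite as
an independent oracle only, agrees with this fitter to ~1e−9 on both
coefficients and ρ̂.

### Convergence semantics

Simulation benchmarking of these models is as much about *when they fail*
as about their estimates, so failure is a counted outcome, never an
exception. A fit is `converged=False` when any of the following occurs:

* the starting-value computation fails. Starting values are the standard
  GLM initialization for binary data — mustart = (y+½)/2 followed by one
  weighted least-squares step on the adjusted response — and a starting
  β whose fitted means are family-inadmissible is a failure (the classic
  "cannot find valid starting values" mode of log-binomial fitting);
* any iterate of either scoring pass (an independence pass for starting
  values, then the exchangeable pass) produces inadmissible fitted means:
  binomial μ outside (0,1), identity-Poisson μ ≤ 0;
* a scoring system is singular, an update is non-finite, the iteration cap
  (default 100) is reached before the coefficient change drops below the
  tolerance (default 1e−6), or the final sandwich has a negative diagonal.

No step-halving is attempted: halved steps can creep arbitrarily close to
the parameter boundary and then satisfy the step-size criterion at a point
that is not a solution, converting a boundary failure into a silently
wrong "success". This rule set reproduces the known fragility ranking —
the log-binomial model fails for most replicates when a covariate pushes a
cell mean near 1 (about 74 % in the boundary scenario below), while the
identity binomial/Poisson models fail for a few percent at small sample
sizes and the logit, log-Poisson and normal models essentially never fail.

## Risk-difference estimation

Identity links report β̂ directly. Log and logit links are marginally
standardized over the analysis sample itself: every subject's π̂_ij(1) and
π̂_ij(0) are computed at their own covariate value (Eqs. above), and the RD
is their mean over all n subjects of both arms. The delta-method gradient
has the closed forms

* log link: ∂/∂α = mean(π̂₁−π̂₀), ∂/∂β = mean(π̂₁), ∂/∂γ = mean(z·(π̂₁−π̂₀));
* logit link: the same expressions with π̂ replaced by the logistic
  variance v̂ = π̂(1−π̂);

each verified in the suite against a central-finite-difference gradient to
six significant digits. Predicted probabilities can exceed 1 under the
identity and log links; they are used as-is (with a warning), since the
marginal model does not constrain them — this is a documented weakness of
those links, not of the implementation.

### Small-cluster correction

With few clusters the sandwich variance is anti-conservative. The factor
J/(J−p−1), with p the number of non-intercept regressors, multiplies the
robust **variance**; standard errors are therefore scaled by
√(J/(J−p−1)). The variance reading is fixed by arithmetic on the bundled
example: the published interval (0.011, 0.241) around RD 0.126 implies
SE 0.0587 = 0.0508 (raw sandwich) × √(8/6), whereas an SE-scale factor
would give 0.0677 and a visibly wider interval. The reported `se` column
is the corrected SE, and the 95 % interval is RD̂ ± 1.96·SE (fixed normal
quantile, not a t quantile). The unadjusted 2×2 method gets the plain Wald
SE with no correction. The correction requires J > p+1 and is an error
otherwise.

## Synthetic-trial generator

The generator emulates a stratified multicenter RCT: J centers (default
18) of n_j subjects each, treatment assigned within center in permuted
blocks of four (a trailing odd block splits ⌊r/2⌋/⌈r/2⌉ at random — the
design sizes 10/50/100 leave only an even remainder of 2, so this choice
is immaterial there), covariate z ~ Bernoulli(0.3), and a shared center
effect ν_j ~ Normal(0, σ²) on the link scale:

* identity: π_ij = α + βx + γz + ν_j, with α = π_c, β = RD,
  γ ∈ {0, 0.5·π_c}, and σ² = ρ·π̄(1−π̄) for π̄ = α + 0.5β + 0.3γ;
* log: log π_ij = α + βx + γz + ν_j, with α = log π_c, γ ∈ {0, log 1.5},
  β = log(1 + RD/exp(α + 0.3γ)), and σ² = ρ·(1−π̄)/π̄ for
  π̄ = exp(α + 0.5β + 0.3γ) (a variance-transformation approximation).

Defaults are the factorial design levels: π_c ∈ {0.10, 0.25, 0.50},
RD ∈ {0, 0.05, 0.10, 0.15}, ρ ∈ {0.01, 0.05, 0.10}, n_j ∈ {10, 50, 100},
giving σ² ∈ [0.001, 0.025] (identity) and [0.006, 0.90] (log). Whenever a
drawn ν_j makes any π_ij leave (0,1), a fresh ν_j is drawn for that center
with treatment and covariates held fixed (cap 10 000, configurable). Two
consequences are properties of this generating process and are documented
rather than corrected:

* rejection truncates the center-effect distribution, slightly shrinking
  the realized between-center variance at large σ²;
* under the log link the realized marginal RD exceeds the nominal RD by
  roughly the factor E[e^ν]·(0.7+0.3e^γ)/e^{0.3γ} ≈ e^{σ²/2}·(1.02), a
  2–12 % relative inflation across the grid. The back-calculated β is
  exact only as σ² → 0; generator self-consistency is therefore tested at
  a small-σ² cell (π_c = 0.25, ρ = 0.01), and the inflation at
  large-σ² cells is visible in the benchmark as the upward bias of *all*
  estimators there. What passing tests show is that the generator matches
  its stated construction — not that the log-link construction itself is
  marginally exact, which it is not.

The identity-link marginal RD is exact for any σ²: the center effect is
shared by both arms and cancels from the arm difference.

Reproducibility: replicate r of scenario s under master seed m uses
`numpy.random.default_rng([m, s, r])`, so any replicate can be regenerated
in isolation and results are independent of execution order or worker
count (`joblib` parallelism is optional and off by default).

## Benchmark harness

Each scenario runs all seven methods on every replicate. Convergence rate,
bias (mean of estimate − true RD; the benchmark's "absolute bias" is this
signed mean on the RD scale) and 95 % CI coverage (closed-interval
inclusion of the true RD) are aggregated per method over the replicates
where *that* method converged, mirroring how non-convergence is handled in
practice. Monte-Carlo standard errors accompany bias and coverage so tests
and reports can state bands honestly. The full design is 432 scenarios;
the shipped tests and the acceptance script use targeted subsets at
200–1000 replicates (a few minutes on one CPU), chosen to exercise the
qualitatively distinct regimes: the well-behaved identity cells, the
log-response cells where the unadjusted interval undercovers (for small
true RD the shared center effect cancels from the arm difference, so
undercoverage only emerges as RD grows — the benchmark cell uses RD=0.10),
and the boundary cell (π_c = 0.50 with covariate) where the log-binomial
model fails en masse.

## Known limitations

* Only exchangeable (and internal independence) working correlation; no
  GLMMs, no fixed center effects, no model-based SEs.
* One binary covariate at most; no interactions; binary outcomes only.
* The small-cluster correction is the single J/(J−p−1) variance factor;
  residual-type corrections and bootstrap intervals are not implemented.
* Equal center sizes by default (a size vector is accepted); center sizes
  drawn from a distribution are not modeled.
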