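"""Factorial simulation harness.

Runs the seven estimators (six GEE models + the unadjusted 2x2 method)
over replicated synthetic trials and aggregates three performance
measures per scenario per method:

* convergence rate — fraction of replicates where the model ran and
  converged to finite, admissible estimates (always 1 for the closed-form
  unadjusted method);
* bias — mean of (estimated RD − true RD), over converged replicates only;
* coverage — fraction of converged replicates whose 95 % CI contains the
  true RD (closed-interval inclusion).

Conditioning on convergence is per method: a replicate where only the
log-binomial model fails still contributes to every other method.

Reproducibility: replicate r of scenario s under master seed m uses the
generator ``default_rng([m, s, r])``, so results are independent of
execution order and worker count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialData
from .estimate import ALL_METHODS, RDEstimate, analyze_trial
from .exceptions import ConfigError, RdgeeError
from .gee import FitControl
from .simulate import ScenarioSpec, simulate_trial

__all__ = [
    "MethodPerformance",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "factorial_grid",
    "summarize_results",
    "DEFAULT_FACTOR_LEVELS",
]

#: the full factorial design: 2 x 4 x 3 x 3 x 3 x 2 = 432 scenarios
DEFAULT_FACTOR_LEVELS: dict[str, tuple] = {
    "true_link": ("identity", "log"),
    "true_rd": (0.0, 0.05, 0.10, 0.15),
    "pi_c": (0.10, 0.25, 0.50),
    "icc": (0.01, 0.05, 0.10),
    "n_per_center": (10, 50, 100),
    "covariate_effect": ("none", "fifty_percent"),
}


@dataclass(frozen=True)
class MethodPerformance:
    """Per-method aggregate over one scenario's replicates."""

    method: str
    n_reps: int
    n_converged: int
    convergence_rate: float
    bias: float          # mean(est - true RD) over converged reps; NaN if none
    bias_mcse: float     # Monte-Carlo SE of the bias estimate
    coverage: float      # fraction of converged reps covering the true RD
    coverage_mcse: float


@dataclass(frozen=True)
class ScenarioResult:
    scenario: ScenarioSpec
    methods: dict[str, MethodPerformance]

    def to_rows(self) -> list[dict]:
        s = self.scenario
        base = {
            "link": s.true_link,
            "n_per_center": s.n_per_center,
            "pi_c": s.pi_c,
            "true_rd": s.true_rd,
            "icc": s.icc,
            "covariate": s.covariate_effect,
        }
        rows = []
        for m in self.methods.values():
            for metric, value in (
                ("convergence_rate", m.convergence_rate),
                ("bias", m.bias),
                ("coverage", m.coverage),
            ):
                rows.append(
                    {**base, "method": m.method, "metric": metric, "value": value,
                     "n_converged": m.n_converged, "n_reps": m.n_reps}
                )
        return rows


def run_replicate(
    data: TrialData,
    true_rd: float,
    methods: tuple[str, ...] = ALL_METHODS,
    include_covariate: bool = False,
    control: FitControl | None = None,
) -> dict[str, RDEstimate | None]:
    """Attempt every method on one dataset; failures become None markers."""
    return analyze_trial(data, methods, include_covariate, control)


def _covered(est: RDEstimate, true_rd: float) -> bool:
    return est.ci_low <= true_rd <= est.ci_high


def run_scenario(
    spec: ScenarioSpec,
    n_reps: int,
    methods: tuple[str, ...] = ALL_METHODS,
    control: FitControl | None = None,
    n_jobs: int = 1,
) -> ScenarioResult:
    """Replicate one scenario and aggregate per-method performance.

    Covariate adjustment in the fitted models follows the scenario: models
    include the baseline covariate exactly when the generator does.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")

    def one_rep(r: int) -> dict[str, tuple[float, bool] | None]:
        rng = np.random.default_rng([spec.seed, spec.scenario_index, r])
        data = simulate_trial(spec, rng)
        ests = run_replicate(data, spec.true_rd, methods, spec.has_covariate, control)
        return {
            m: None if e is None else (e.rd, _covered(e, spec.true_rd))
            for m, e in ests.items()
        }

    if n_jobs != 1:
        from joblib import Parallel, delayed

        reps = Parallel(n_jobs=n_jobs)(delayed(one_rep)(r) for r in range(n_reps))
    else:
        reps = [one_rep(r) for r in range(n_reps)]

    perf = {}
    for m in methods:
        vals = [rep[m] for rep in reps]
        conv = [v for v in vals if v is not None]
        k = len(conv)
        if k:
            errs = np.array([v[0] for v in conv]) - spec.true_rd
            cov = float(np.mean([v[1] for v in conv]))
            bias = float(errs.mean())
            bias_mcse = float(errs.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
            cov_mcse = float(np.sqrt(cov * (1 - cov) / k))
        else:
            bias = bias_mcse = cov = cov_mcse = float("nan")
        perf[m] = MethodPerformance(
            method=m, n_reps=n_reps, n_converged=k,
            convergence_rate=k / n_reps, bias=bias, bias_mcse=bias_mcse,
            coverage=cov, coverage_mcse=cov_mcse,
        )
    return ScenarioResult(scenario=spec, methods=perf)


def factorial_grid(
    levels: dict | None = None,
    master_seed: int = 0,
    n_centers: int = 18,
) -> list[ScenarioSpec]:
    """Cartesian product of factor levels (defaults: the full 432-cell design).

    Each scenario gets a deterministic index so its replicate streams are
    independent and reproducible under the one master seed.
    """
    lv = dict(DEFAULT_FACTOR_LEVELS)
    if levels:
        for key, values in levels.items():
            if key not in lv:
                raise ConfigError(f"unknown factor {key!r}")
            values = tuple(values)
            if not values:
                raise ConfigError(f"factor {key!r} has no levels")
            lv[key] = values
    keys = list(DEFAULT_FACTOR_LEVELS)
    specs = []
    for i, combo in enumerate(itertools.product(*(lv[k] for k in keys))):
        specs.append(
            ScenarioSpec(
                **dict(zip(keys, combo)),
                n_centers=n_centers,
                seed=master_seed,
                scenario_index=i,
            )
        )
    return specs


def summarize_results(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format performance table: scenario factors x method x metric."""
    if not results:
        raise ConfigError("no scenario results to summarize")
    rows = []
    for r in results:
        rows.extend(r.to_rows())
    return pd.DataFrame(rows)


def run_grid(
    specs: list[ScenarioSpec],
    n_reps: int,
    methods: tuple[str, ...] = ALL_METHODS,
    control: FitControl | None = None,
    n_jobs: int = 1,
    on_error: str = "record",
) -> tuple[list[ScenarioResult], list[tuple[ScenarioSpec, str]]]:
    """Run many scenarios; generator-level failures are recorded, not fatal."""
    results, failures = [], []
    for spec in specs:
        try:
            results.append(run_scenario(spec, n_reps, methods, control, n_jobs))
        except RdgeeError as exc:
            if on_error == "raise":
                raise
            failures.append((spec, str(exc)))
    return results, failures


def plot_metric(
    table: pd.DataFrame,
    metric: str = "coverage",
    out: str | None = None,
):
    """Faceted summary plot (rows: pi_c, cols: icc; x: n_per_center).

    Returns the matplotlib Figure.  Intended for reduced grids; with one
    facet it degrades to a single panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["metric"] == metric]
    pi_levels = sorted(sub["pi_c"].unique())
    icc_levels = sorted(sub["icc"].unique())
    fig, axes = plt.subplots(
        len(pi_levels), len(icc_levels),
        figsize=(3.2 * len(icc_levels), 2.6 * len(pi_levels)),
        squeeze=False, sharey=True,
    )
    for a, pi in enumerate(pi_levels):
        for b, icc in enumerate(icc_levels):
            ax = axes[a][b]
            cell = sub[(sub["pi_c"] == pi) & (sub["icc"] == icc)]
            for method, grp in cell.groupby("method"):
                grp = grp.sort_values("n_per_center")
                ax.plot(grp["n_per_center"], grp["value"], marker="o", label=method)
            if metric == "coverage":
                ax.axhline(0.95, color="gray", lw=0.8, ls="--")
            ax.set_title(f"pi_c={pi}, ICC={icc}", fontsize=8)
    axes[0][0].legend(fontsize=6)
    fig.supxlabel("subjects per center")
    fig.supylabel(metric)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
    return fig
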