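"""Synthetic multicenter-trial generator for clustered binary outcomes.

Datasets are drawn from one of two true response functions on the
probability of outcome for subject i in center j:

    identity:  pi_ij = alpha + beta*x_ij + gamma*z_ij + nu_j
    log:       log(pi_ij) = alpha + beta*x_ij + gamma*z_ij + nu_j

with treatment x assigned by permuted-block randomization (block size 4)
stratified by center, baseline covariate z ~ Bernoulli(0.3), and a random
center effect nu_j ~ Normal(0, sigma^2) inducing the intracenter
correlation.  The center-effect variance is matched to a target ICC rho:

    identity:  sigma^2 = rho * pibar * (1 - pibar),   pibar = a + 0.5 b + 0.3 g
    log:       sigma^2 = rho * (1 - pibar) / pibar,   pibar = exp(a + 0.5 b + 0.3 g)

For the log link the treatment coefficient is back-calculated so the
marginal risk difference at covariate prevalence 0.3 equals the target:
beta = log(1 + RD / exp(alpha + 0.3*gamma)).  This back-calculation is
exact only as sigma^2 -> 0: the lognormal center effect has mean
exp(sigma^2/2) > 1, so at large ICC / small control rate the realized
marginal RD modestly exceeds the target (see the methods note).

Whenever a draw of nu_j makes any pi_ij in the center leave (0, 1), a
fresh nu_j is drawn for that center (treatment and covariates kept fixed)
until all probabilities are admissible.  This truncates the center-effect
distribution; it is part of the generating process, not corrected for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data import TrialData
from .exceptions import ConfigError, DataError

__all__ = [
    "ScenarioSpec",
    "DerivedParams",
    "derive_params",
    "block_randomize",
    "simulate_trial",
]

COVARIATE_PREVALENCE = 0.3
BLOCK_SIZE = 4


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation design.

    ``covariate_effect`` is ``"none"`` (gamma = 0, no covariate recorded) or
    ``"fifty_percent"`` — a 50 % risk increase in carriers (gamma = 0.5*pi_c
    on the identity scale, log 1.5 on the log scale).
    """

    true_link: str = "identity"
    n_centers: int = 18
    n_per_center: int | tuple[int, ...] = 10
    pi_c: float = 0.25
    true_rd: float = 0.10
    icc: float = 0.05
    covariate_effect: str = "none"
    seed: int = 0
    scenario_index: int = 0
    max_redraw: int = 10_000

    def __post_init__(self):
        if self.true_link not in ("identity", "log"):
            raise ConfigError(f"true_link must be 'identity' or 'log', got {self.true_link!r}")
        if self.covariate_effect not in ("none", "fifty_percent"):
            raise ConfigError(
                f"covariate_effect must be 'none' or 'fifty_percent', "
                f"got {self.covariate_effect!r}"
            )
        if self.n_centers < 2:
            raise ConfigError("need at least 2 centers")
        if not 0.0 < self.pi_c < 1.0:
            raise ConfigError(f"pi_c must be in (0, 1), got {self.pi_c}")
        if not 0.0 <= self.icc < 1.0:
            raise ConfigError(f"icc must be in [0, 1), got {self.icc}")
        sizes = self.center_sizes
        if any(s < 2 for s in sizes):
            raise ConfigError("every center needs at least 2 subjects")
        derive_params(self)  # validates admissibility of the cell probabilities

    @property
    def center_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_center, int):
            return (self.n_per_center,) * self.n_centers
        sizes = tuple(int(s) for s in self.n_per_center)
        if len(sizes) != self.n_centers:
            raise ConfigError("n_per_center vector length must equal n_centers")
        return sizes

    @property
    def has_covariate(self) -> bool:
        return self.covariate_effect != "none"

    def replace(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class DerivedParams:
    """Link-scale regression parameters and the matched center variance."""

    alpha: float
    beta: float
    gamma: float
    sigma2: float
    pi_bar: float


def derive_params(spec: ScenarioSpec) -> DerivedParams:
    """Map a scenario (pi_c, RD, ICC, covariate effect) to model parameters."""
    q = COVARIATE_PREVALENCE
    if spec.true_link == "identity":
        alpha = spec.pi_c
        beta = spec.true_rd
        gamma = 0.5 * spec.pi_c if spec.has_covariate else 0.0
        pi_bar = alpha + 0.5 * beta + q * gamma
        sigma2 = spec.icc * pi_bar * (1.0 - pi_bar)
        top = alpha + beta + gamma  # cell (treatment=1, z=1) at nu=0
        if top >= 1.0:
            raise ConfigError(
                f"identity-link probability {top:.3f} >= 1 at (treatment=1, z=1)"
            )
    else:
        alpha = math.log(spec.pi_c)
        gamma = math.log(1.5) if spec.has_covariate else 0.0
        beta = math.log(1.0 + spec.true_rd / math.exp(alpha + q * gamma))
        pi_bar = math.exp(alpha + 0.5 * beta + q * gamma)
        sigma2 = spec.icc * (1.0 - pi_bar) / pi_bar
        top = math.exp(alpha + beta + gamma)
        if top >= 1.0:
            raise ConfigError(
                f"log-link probability {top:.3f} >= 1 at (treatment=1, z=1)"
            )
    return DerivedParams(alpha, beta, gamma, sigma2, pi_bar)


def block_randomize(n_j: int, rng: np.random.Generator, block_size: int = BLOCK_SIZE) -> np.ndarray:
    """Permuted-block treatment allocation within one center.

    Complete blocks assign exactly half to treatment; a trailing incomplete
    block of size r gets floor(r/2) or ceil(r/2) treated, chosen at random,
    so per-center imbalance never exceeds 1.
    """
    if n_j < 2:
        raise ConfigError("block randomization needs at least 2 subjects")
    half = block_size // 2
    blocks = []
    full, rem = divmod(n_j, block_size)
    base = np.array([1] * half + [0] * (block_size - half), dtype=np.int8)
    for _ in range(full):
        blocks.append(rng.permutation(base))
    if rem:
        k = rem // 2
        if rem % 2 == 1 and rng.integers(2) == 1:
            k += 1
        tail = np.array([1] * k + [0] * (rem - k), dtype=np.int8)
        blocks.append(rng.permutation(tail))
    return np.concatenate(blocks)


def simulate_trial(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> TrialData:
    """Draw one trial dataset from the scenario's generating process.

    Per center: allocate treatment by permuted blocks, draw the covariate
    (if any), then draw the center effect nu_j — rejecting and redrawing it
    until every subject's pi_ij lies strictly inside (0, 1) — and finally
    the Bernoulli outcomes.  Deterministic given (seed, scenario_index)
    when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, spec.scenario_index])
    p = derive_params(spec)
    sigma = math.sqrt(p.sigma2)
    sizes = spec.center_sizes
    centers, xs, zs, ys = [], [], [], []
    for j, n_j in enumerate(sizes, start=1):
        x = block_randomize(n_j, rng)
        if spec.has_covariate:
            z = (rng.random(n_j) < COVARIATE_PREVALENCE).astype(np.int8)
        else:
            z = np.zeros(n_j, dtype=np.int8)
        base = p.alpha + p.beta * x + p.gamma * z
        for attempt in range(spec.max_redraw):
            nu = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            eta = base + nu
            pi = eta if spec.true_link == "identity" else np.exp(eta)
            if np.all(pi > 0.0) and np.all(pi < 1.0):
                break
            if sigma == 0.0:
                raise DataError(
                    f"center {j}: probabilities inadmissible even at nu=0"
                )
        else:
            raise DataError(
                f"center {j}: no admissible center effect in "
                f"{spec.max_redraw} redraws (scenario {spec})"
            )
        y = (rng.random(n_j) < pi).astype(np.int8)
        centers.append(np.full(n_j, j))
        xs.append(x)
        zs.append(z)
        ys.append(y)
    return TrialData(
        center=np.concatenate(centers),
        treatment=np.concatenate(xs),
        outcome=np.concatenate(ys),
        covariate=np.concatenate(zs) if spec.has_covariate else None,
    )
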