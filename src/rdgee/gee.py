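"""GEE fitting for marginal models of clustered binary outcomes.

Fits the population-averaged mean model

    g(pi_ij) = alpha + beta * x_ij [+ gamma * z_ij]

by Fisher-scoring generalized estimating equations under an exchangeable
working correlation (all outcome pairs within a center share correlation
rho; pairs across centers are independent).  Six family/link combinations
are supported for risk-difference work: binomial, Poisson or normal with
identity link; binomial or Poisson with log link; binomial with logit link.
The Poisson and normal families are working-variance devices for binary
data — the robust sandwich covariance keeps inference valid under that
misspecification.

Numerical failure is a *result*, not an exception: simulation studies need
to count non-convergence (the log-binomial model in particular fails
whenever fitted means reach 1).  Any inadmissible iterate, singular step,
iteration-cap hit or non-finite estimate yields ``converged=False``.

Moment estimators follow the usual estimating-equation software
conventions: the scale is ``phi = sum(e_ij^2) / (N - q)`` for Pearson
residuals ``e`` and ``q`` mean parameters, and the exchangeable correlation
is the scaled sum of within-center residual cross-products with denominator
``sum_j n_j (n_j - 1) / 2 - q``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import TrialData
from .exceptions import ConfigError, DataError, NotConvergedError

__all__ = ["ModelSpec", "FitControl", "GEEFit", "fit_gee", "predict_prob", "GEE_MODELS"]

#: the six family/link combinations accepted for RD estimation,
#: keyed by the label used in results tables
GEE_MODELS: dict[str, tuple[str, str]] = {
    "binomial-identity": ("binomial", "identity"),
    "poisson-identity": ("poisson", "identity"),
    "normal-identity": ("normal", "identity"),
    "binomial-log": ("binomial", "log"),
    "poisson-log": ("poisson", "log"),
    "binomial-logit": ("binomial", "logit"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A marginal-model choice: distribution family, link, covariate on/off."""

    family: str
    link: str
    include_covariate: bool = False

    def __post_init__(self):
        if (self.family, self.link) not in GEE_MODELS.values():
            raise ConfigError(
                f"unsupported family/link combination "
                f"({self.family!r}, {self.link!r}); choose one of "
                + ", ".join(GEE_MODELS)
            )

    @property
    def label(self) -> str:
        return f"{self.family}-{self.link}"

    @classmethod
    def from_label(cls, label: str, include_covariate: bool = False) -> "ModelSpec":
        if label not in GEE_MODELS:
            raise ConfigError(f"unknown model label {label!r}")
        fam, link = GEE_MODELS[label]
        return cls(fam, link, include_covariate)


@dataclass(frozen=True)
class FitControl:
    """Iteration controls.

    ``fixed_rho`` pins the working correlation (0 gives the independence
    special case used for cross-checks) instead of estimating it.
    """

    max_iter: int = 100
    tol: float = 1e-6
    fixed_rho: float | None = None


@dataclass
class GEEFit:
    """A fitted GEE model bundle.

    ``coefficients`` is ordered (intercept, treatment[, covariate]);
    ``robust_cov`` is the sandwich covariance on the same order; ``icc`` the
    estimated exchangeable correlation; ``n_params_p`` counts non-intercept
    regressors (used by the small-cluster SE correction).
    """

    spec: ModelSpec
    coefficients: np.ndarray
    coef_names: tuple[str, ...]
    robust_cov: np.ndarray
    icc: float
    scale: float
    converged: bool
    n_clusters: int
    n_params_p: int
    n_iter: int
    data: TrialData = field(repr=False)
    message: str = ""

    def require_converged(self) -> "GEEFit":
        if not self.converged:
            raise NotConvergedError(
                f"model {self.spec.label} did not converge ({self.message})"
            )
        return self

    def predict_prob(self, treatment: int, covariate: int | None = None) -> float:
        return predict_prob(self, treatment, covariate)


# -- link/family helpers --------------------------------------------------

def _inverse_link(link: str, eta: np.ndarray) -> np.ndarray:
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(eta)
    return 1.0 / (1.0 + np.exp(-eta))  # logit


def _dmu_deta(link: str, mu: np.ndarray) -> np.ndarray:
    if link == "identity":
        return np.ones_like(mu)
    if link == "log":
        return mu
    return mu * (1.0 - mu)


def _variance(family: str, mu: np.ndarray) -> np.ndarray:
    if family == "binomial":
        return mu * (1.0 - mu)
    if family == "poisson":
        return mu
    return np.ones_like(mu)  # normal: constant working variance


def _admissible(family: str, link: str, mu: np.ndarray) -> bool:
    """Can the family variance be evaluated at these fitted means?

    Binomial needs mu strictly inside (0, 1) — a log- or identity-link
    iterate at or above 1 is the classic log-binomial failure mode.
    Poisson with identity link needs mu > 0.
    """
    if not np.all(np.isfinite(mu)):
        return False
    if family == "binomial":
        return bool(np.all(mu > 0.0) and np.all(mu < 1.0))
    if family == "poisson" and link == "identity":
        return bool(np.all(mu > 0.0))
    return True


def predict_prob(fit: GEEFit, treatment: int, covariate: int | None = None) -> float:
    """Probability-scale fitted value g^{-1}(alpha + beta*t [+ gamma*z]).

    For identity and log links the value can fall outside [0, 1]; it is
    returned as-is (with a warning) since the marginal model does not
    constrain it.
    """
    fit.require_converged()
    if fit.spec.include_covariate and covariate is None:
        raise ConfigError("model includes a covariate; pass covariate=0 or 1")
    eta = fit.coefficients[0] + fit.coefficients[1] * treatment
    if fit.spec.include_covariate:
        eta = eta + fit.coefficients[2] * covariate
    value = float(_inverse_link(fit.spec.link, np.asarray(eta)))
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"fitted probability {value:.4f} outside [0, 1] "
            f"({fit.spec.label} link does not constrain it)",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def _design_matrix(data: TrialData, spec: ModelSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(data.n), data.treatment.astype(float)]
    names = ["intercept", "treatment"]
    if spec.include_covariate:
        if data.covariate is None:
            raise DataError("model includes a covariate but the data has none")
        cols.append(data.covariate.astype(float))
        names.append("covariate")
    return np.column_stack(cols), tuple(names)


def _moment_estimates(
    e: np.ndarray, starts: np.ndarray, n: int, q: int, pairs: float
) -> tuple[float, float]:
    """Scale phi and exchangeable rho from Pearson residuals."""
    phi = float(e @ e) / (n - q)
    s = np.add.reduceat(e, starts)
    s2 = np.add.reduceat(e * e, starts)
    cross = float(((s * s - s2) / 2.0).sum())
    rho = cross / (phi * (pairs - q))
    return phi, rho


def fit_gee(
    data: TrialData,
    spec: ModelSpec,
    control: FitControl | None = None,
) -> GEEFit:
    """Fit a marginal model by GEE with exchangeable working correlation.

    Returns a :class:`GEEFit` whose ``converged`` flag is False on any
    numerical failure (inadmissible fitted means, singular working
    information, iteration cap, non-finite results); structural problems
    (missing covariate, single center, no within-center pairs) raise.
    """
    control = control or FitControl()
    data.require_multicenter()
    X, names = _design_matrix(data, spec)
    n, q = X.shape
    if n <= q:
        raise DataError("more parameters than observations")

    # order records cluster-contiguously (stable, first-appearance codes)
    order = np.argsort(data.center_codes, kind="stable")
    Xo = X[order]
    y = data.outcome[order].astype(float)
    sizes = data.cluster_sizes.astype(float)
    starts = np.concatenate(([0], np.cumsum(sizes[:-1]))).astype(np.int64)
    J = data.n_centers
    pairs = float((sizes * (sizes - 1) / 2.0).sum())
    if control.fixed_rho is None and pairs - q <= 0:
        raise DataError(
            "cannot estimate the exchangeable correlation: too few "
            "within-center pairs"
        )
    rho_floor = -1.0 / (sizes.max() - 1.0) + 1e-8 if sizes.max() > 1 else 0.0

    family, link = spec.family, spec.link

    def failed(beta, it, msg):
        nan_cov = np.full((q, q), np.nan)
        return GEEFit(
            spec=spec, coefficients=np.asarray(beta, float), coef_names=names,
            robust_cov=nan_cov, icc=np.nan, scale=np.nan, converged=False,
            n_clusters=J, n_params_p=q - 1, n_iter=it, data=data, message=msg,
        )

    # standard GLM initialization for binary outcomes: mustart=(y+1/2)/2,
    # one weighted least-squares step on the adjusted response.  An
    # inadmissible starting fit is a failure (the "cannot find valid
    # starting values" mode of the reference software).
    mustart = (y + 0.5) / 2.0
    dmu0 = _dmu_deta(link, mustart)
    eta0 = {"identity": mustart, "log": np.log(mustart),
            "logit": np.log(mustart / (1 - mustart))}[link]
    z0 = eta0 + (y - mustart) / dmu0
    w0 = dmu0**2 / _variance(family, mustart)
    try:
        beta0 = np.linalg.solve((Xo * w0[:, None]).T @ Xo, (Xo * w0[:, None]).T @ z0)
    except np.linalg.LinAlgError:
        return failed(np.zeros(q), 0, "singular starting-value system")

    def weighted_sums(Xt, r, rho):
        """B = sum_j D'V^-1 D and u = sum_j D'V^-1 (y-mu), up to 1/phi.

        Uses the closed-form inverse of the exchangeable correlation
        matrix: R^-1 = [I - rho/(1+(n-1)rho) * J] / (1-rho).
        """
        c = rho / (1.0 + (sizes - 1.0) * rho)  # per-cluster
        sX = np.add.reduceat(Xt, starts, axis=0)       # (J, q)
        sr = np.add.reduceat(r, starts)                # (J,)
        B = (Xt.T @ Xt - np.einsum("j,jp,jq->pq", c, sX, sX)) / (1.0 - rho)
        u = (Xt.T @ r - (c * sr) @ sX) / (1.0 - rho)
        return B, u, c, sX, sr

    def scoring_loop(beta_start, rho_fixed, halving: int):
        """Fisher scoring; returns (beta, n_iter, message-or-None).

        Any inadmissible iterate is outright failure (``halving`` is kept
        at 0: halved steps can creep to the parameter boundary and fake
        convergence there, so no step rescue is attempted).
        """
        beta = beta_start.copy()
        mu = _inverse_link(link, Xo @ beta)
        if not _admissible(family, link, mu):
            return beta, 0, "inadmissible starting values"
        for it in range(1, control.max_iter + 1):
            v = _variance(family, mu)
            sv = np.sqrt(v)
            e = (y - mu) / sv
            if rho_fixed is not None:
                rho = rho_fixed
            else:
                _, rho = _moment_estimates(e, starts, n, q, pairs)
            rho = float(np.clip(rho, rho_floor, 1.0 - 1e-8))
            Xt = Xo * (_dmu_deta(link, mu) / sv)[:, None]
            B, u, _, _, _ = weighted_sums(Xt, e, rho)
            try:
                step = np.linalg.solve(B, u)
            except np.linalg.LinAlgError:
                return beta, it, "singular working information"
            if not np.all(np.isfinite(step)):
                return beta, it, "non-finite update"
            trial = beta + step
            mu = _inverse_link(link, Xo @ trial)
            halves = 0
            while not _admissible(family, link, mu):
                if halves >= halving:
                    return trial, it, "inadmissible fitted means"
                step /= 2.0
                trial = beta + step
                mu = _inverse_link(link, Xo @ trial)
                halves += 1
            beta = trial
            if float(np.max(np.abs(step))) < control.tol:
                return beta, it, None
        return beta, control.max_iter, "iteration limit reached"

    # stage 1: independence (rho=0) fit for starting values — the analogue
    # of the GLM fit the estimating-equation software seeds from; its
    # failure is the dominant non-convergence mode for the log-binomial
    beta, it1, err = scoring_loop(beta0, 0.0, halving=0)
    if err is not None:
        return failed(beta, it1, f"starting-value (independence) fit: {err}")
    # stage 2: exchangeable working correlation, no step rescue
    beta, it, err = scoring_loop(beta, control.fixed_rho, halving=0)
    if err is not None:
        return failed(beta, it, err)

    # final quantities at the solution
    eta = Xo @ beta
    mu = _inverse_link(link, eta)
    if not _admissible(family, link, mu):
        return failed(beta, it, "inadmissible fitted means at solution")
    v = _variance(family, mu)
    sv = np.sqrt(v)
    e = (y - mu) / sv
    if control.fixed_rho is not None:
        phi = float(e @ e) / (n - q)
        rho = control.fixed_rho
        rho_report = rho
    else:
        phi, rho_report = _moment_estimates(e, starts, n, q, pairs)
        rho = float(np.clip(rho_report, rho_floor, 1.0 - 1e-8))
    Xt = Xo * (_dmu_deta(link, mu) / sv)[:, None]
    B, _, c, sX, sr = weighted_sums(Xt, e, rho)
    # sandwich: B^-1 (sum_j g_j g_j') B^-1, phi cancels
    Xr = np.add.reduceat(Xt * e[:, None], starts, axis=0)       # (J, q)
    g = (Xr - (c * sr)[:, None] * sX) / (1.0 - rho)
    M = g.T @ g
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        return failed(beta, it, "singular working information at solution")
    cov = Binv @ M @ Binv
    cov = (cov + cov.T) / 2.0
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
        return failed(beta, it, "non-finite estimates")
    if np.any(np.diag(cov) < 0):
        return failed(beta, it, "negative sandwich variance")
    return GEEFit(
        spec=spec, coefficients=beta, coef_names=names, robust_cov=cov,
        icc=float(rho_report), scale=phi, converged=True, n_clusters=J,
        n_params_p=q - 1, n_iter=it, data=data, message="converged",
    )


def refit(fit: GEEFit, control: FitControl) -> GEEFit:
    """Re-fit the same model/data under different iteration controls."""
    return fit_gee(fit.data, replace(fit.spec), control)
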