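"""Risk-difference estimation from fitted marginal models.

Identity-link models report the treatment coefficient directly as the RD.
Log- and logit-link models are marginally standardized: every subject's
outcome probability is predicted under treatment and under control (own
covariate value, treatment set counterfactually), and the RD is the mean
of the per-subject differences over the whole analysis sample,

    RD = (1/n) * sum_ij [ pi_ij(1) - pi_ij(0) ].

Its standard error comes from the delta method applied to the robust
sandwich covariance of the coefficients.  With few centers J the sandwich
is anti-conservative, so the robust variance is inflated by J/(J-p-1)
(p non-intercept regressors) — equivalently the SE by its square root —
before forming the 95 % Wald interval RD ± 1.96 * SE_corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialData
from .exceptions import ConfigError, DataError, NotConvergedError
from .gee import GEE_MODELS, FitControl, GEEFit, ModelSpec, fit_gee
from .unadjusted import unadjusted_rd

__all__ = [
    "RDEstimate",
    "rd_from_identity",
    "average_rd",
    "delta_se_average_rd",
    "apply_small_sample_correction",
    "estimate_rd",
    "analyze_trial",
    "results_table",
    "ALL_METHODS",
]

Z95 = 1.96  # fixed normal quantile for the Wald interval

#: all seven method labels, in customary reporting order
ALL_METHODS: tuple[str, ...] = tuple(GEE_MODELS) + ("unadjusted",)


@dataclass(frozen=True)
class RDEstimate:
    """A risk-difference result on the probability scale.

    ``se_corrected`` carries the small-cluster inflation
    sqrt(J/(J-p-1)); the Wald bounds are rd ± 1.96 * se_corrected.
    """

    rd: float
    se_raw: float
    se_corrected: float
    ci_low: float
    ci_high: float
    method: str
    n_used: int
    icc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rd": self.rd,
            "se": self.se_corrected,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "icc": self.icc,
        }


def apply_small_sample_correction(se_raw: float, J: int, p: int) -> float:
    """Inflate a robust SE for a small number of clusters.

    The factor J/(J-p-1) multiplies the robust *variance*; the SE is
    scaled by sqrt(J/(J-p-1)).  Requires J > p + 1.
    """
    if J <= p + 1:
        raise ConfigError(
            f"small-sample correction undefined for J={J}, p={p} (need J > p+1)"
        )
    return float(se_raw) * float(np.sqrt(J / (J - p - 1.0)))


def _wrap(rd, se_raw, fit: GEEFit) -> RDEstimate:
    se_corr = apply_small_sample_correction(se_raw, fit.n_clusters, fit.n_params_p)
    return RDEstimate(
        rd=float(rd),
        se_raw=float(se_raw),
        se_corrected=se_corr,
        ci_low=float(rd - Z95 * se_corr),
        ci_high=float(rd + Z95 * se_corr),
        method=fit.spec.label,
        n_used=fit.data.n,
        icc=fit.icc,
    )


def rd_from_identity(fit: GEEFit) -> RDEstimate:
    """RD from an identity-link fit: the treatment coefficient itself."""
    fit.require_converged()
    if fit.spec.link != "identity":
        raise ConfigError("rd_from_identity requires an identity-link fit")
    i = fit.coef_names.index("treatment")
    rd = fit.coefficients[i]
    se_raw = np.sqrt(fit.robust_cov[i, i])
    if abs(rd) > 1:
        warnings.warn(
            f"identity-link RD {rd:.3f} outside [-1, 1]", RuntimeWarning, stacklevel=2
        )
    return _wrap(rd, se_raw, fit)


def _counterfactual_probs(fit: GEEFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject pi_hat(1), pi_hat(0) and covariate vector z."""
    a, b = fit.coefficients[0], fit.coefficients[1]
    if fit.spec.include_covariate:
        z = fit.data.covariate.astype(float)
        g = fit.coefficients[2]
    else:
        z = np.zeros(fit.data.n)
        g = 0.0
    eta1 = a + b + g * z
    eta0 = a + g * z
    if fit.spec.link == "log":
        return np.exp(eta1), np.exp(eta0), z
    return 1 / (1 + np.exp(-eta1)), 1 / (1 + np.exp(-eta0)), z


def _average_rd_gradient(fit: GEEFit) -> tuple[float, np.ndarray]:
    """Average RD and its gradient in the coefficients.

    log link:   d/da = mean(p1 - p0), d/db = mean(p1), d/dg = mean(z*(p1-p0))
    logit link: same with p replaced by the logistic variance v = p(1-p).
    """
    p1, p0, z = _counterfactual_probs(fit)
    rd = float(np.mean(p1 - p0))
    if fit.spec.link == "log":
        w1, w0 = p1, p0
    else:
        w1, w0 = p1 * (1 - p1), p0 * (1 - p0)
    grad = [np.mean(w1 - w0), np.mean(w1)]
    if fit.spec.include_covariate:
        grad.append(np.mean(z * (w1 - w0)))
    return rd, np.asarray(grad)


def delta_se_average_rd(fit: GEEFit) -> float:
    """Delta-method SE of the subject-averaged RD (uncorrected)."""
    fit.require_converged()
    if fit.spec.link not in ("log", "logit"):
        raise ConfigError("delta-method SE applies to log/logit fits")
    _, grad = _average_rd_gradient(fit)
    var = float(grad @ fit.robust_cov @ grad)
    if var < 0:
        raise NotConvergedError(
            f"negative delta-method variance for {fit.spec.label}"
        )
    return float(np.sqrt(var))


def average_rd(fit: GEEFit) -> RDEstimate:
    """Marginally standardized RD from a log- or logit-link fit."""
    fit.require_converged()
    if fit.spec.link == "identity":
        raise ConfigError("use rd_from_identity for identity-link fits")
    rd, _ = _average_rd_gradient(fit)
    p1, p0, _ = _counterfactual_probs(fit)
    if fit.spec.link == "log" and (p1.max() > 1 or p0.max() > 1):
        warnings.warn(
            "log-link fitted probabilities exceed 1; averaged RD may be distorted",
            RuntimeWarning,
            stacklevel=2,
        )
    return _wrap(rd, delta_se_average_rd(fit), fit)


def estimate_rd(fit: GEEFit) -> RDEstimate:
    """Dispatch on the fit's link: identity coefficient or averaged RD."""
    if fit.spec.link == "identity":
        return rd_from_identity(fit)
    return average_rd(fit)


def analyze_trial(
    data: TrialData,
    methods: tuple[str, ...] = ALL_METHODS,
    include_covariate: bool = False,
    control: FitControl | None = None,
) -> dict[str, RDEstimate | None]:
    """Run the selected methods on one trial; non-converged fits map to None."""
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ConfigError(f"unknown method(s): {sorted(unknown)}")
    if not methods:
        raise ConfigError("at least one method must be selected")
    if np.unique(data.treatment).size < 2:
        raise DataError("data contains a single treatment arm")
    out: dict[str, RDEstimate | None] = {}
    for label in methods:
        if label == "unadjusted":
            try:
                out[label] = unadjusted_rd(data)
            except DataError:
                out[label] = None
            continue
        spec = ModelSpec.from_label(label, include_covariate)
        fit = fit_gee(data, spec, control)
        out[label] = estimate_rd(fit) if fit.converged else None
    return out


def results_table(results: dict[str, RDEstimate | None]) -> pd.DataFrame:
    """One row per method: method, rd, se, ci_low, ci_high, icc."""
    rows = []
    for label, est in results.items():
        if est is None:
            rows.append(
                {"method": label, "rd": np.nan, "se": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "icc": np.nan}
            )
        else:
            rows.append(est.to_dict())
    return pd.DataFrame(rows, columns=["method", "rd", "se", "ci_low", "ci_high", "icc"])
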