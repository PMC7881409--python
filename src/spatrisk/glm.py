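"""Non-spatial Poisson log-linear model for area counts.

O_i ~ Poisson(E_i · exp(α + βᵀx_i)): a Poisson GLM with log link and
log E_i as offset, fitted by iteratively reweighted least squares (via
statsmodels). Reports MLEs, Wald 95% intervals on exp(β), deviance,
−2 log likelihood and a plug-in DIC (−2loglik + 2p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .data import StudyDataset, ValidationError


class SingularityError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient."""


class ConvergenceError(RuntimeError):
    """IRLS did not converge; carries the last iterate."""

    def __init__(self, msg, last_params=None):
        super().__init__(msg)
        self.last_params = last_params


@dataclass
class GlmFit:
    """Result of a Poisson GLM fit with offset log E."""

    terms: list[str]  # "intercept" + covariate names
    coefficients: np.ndarray
    cov: np.ndarray
    minus2loglik: float
    deviance: float
    converged: bool
    iterations: int
    n_obs: int
    fitted_means: np.ndarray
    exp_beta: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        se = np.sqrt(np.diag(self.cov))
        z = 1.959963984540054  # Φ⁻¹(0.975)
        self.exp_beta = pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "se": se,
                "exp_beta": np.exp(self.coefficients),
                "ci_low": np.exp(self.coefficients - z * se),
                "ci_high": np.exp(self.coefficients + z * se),
            }
        )

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def _design(dataset: StudyDataset, covariates: Sequence[str], sex: str):
    recs = dataset.for_sex(sex)
    y = np.array([r.observed for r in recs], dtype=float)
    expected = np.array([r.expected for r in recs], dtype=float)
    if np.any(expected <= 0):
        raise ValidationError("expected counts must be > 0 for a GLM fit")
    cols = [np.ones(len(recs))]
    for c in covariates:
        vals = [getattr(r, c) for r in recs]
        if any(v is None for v in vals):
            missing = [r.area_id for r, v in zip(recs, vals) if v is None]
            raise ValidationError(f"covariate {c!r} missing for areas {missing}")
        cols.append(np.array(vals, dtype=float))
    X = np.column_stack(cols)
    return y, expected, X, [r.area_id for r in recs]


def fit_poisson_glm(
    dataset: StudyDataset,
    covariates: Sequence[str] = (),
    sex: str = "both",
    scale_covariates: bool = False,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> GlmFit:
    """Maximum-likelihood fit of the offset Poisson log-linear model.

    ``scale_covariates`` z-scores each covariate first (off by default so
    coefficients stay on the covariates' natural units).
    """
    y, expected, X, _ = _design(dataset, covariates, sex)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularityError("design matrix is rank-deficient")
    if scale_covariates and X.shape[1] > 1:
        X = X.copy()
        X[:, 1:] = (X[:, 1:] - X[:, 1:].mean(axis=0)) / X[:, 1:].std(axis=0)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(expected))
    try:
        res = model.fit(maxiter=max_iter, tol=tol)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularityError(str(exc)) from exc
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", res.params
        )
    mu = res.fittedvalues
    return GlmFit(
        terms=["intercept"] + list(covariates),
        coefficients=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        minus2loglik=minus2loglik_poisson(y, mu),
        deviance=float(res.deviance),
        converged=bool(res.converged),
        iterations=int(res.fit_history["iteration"]),
        n_obs=len(y),
        fitted_means=np.asarray(mu),
    )


def minus2loglik_poisson(y: np.ndarray, mu: np.ndarray) -> float:
    """−2 Σ [y log μ − μ − log y!], with 0·log 0 = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(-2.0 * np.sum(term - mu - gammaln(y + 1)))


def saturated_deviance_poisson(y: np.ndarray, mu: np.ndarray) -> float:
    """2 Σ [y log(y/μ) − (y − μ)] — deviance against the saturated model."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    y_safe = np.where(y > 0, y, 1.0)
    term = np.where(y > 0, y * np.log(y_safe / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def glm_dic(fit: GlmFit) -> tuple[float, float]:
    """Plug-in DIC for a maximum-likelihood fit.

    DIC ≈ −2loglik + 2p with p the number of free parameters (the
    effective-parameter count collapses to p for a flat-prior point fit).
    Returns ``(dic, minus2loglik)``.
    """
    if not fit.converged:
        raise ConvergenceError("refusing DIC for a non-converged fit")
    return fit.minus2loglik + 2.0 * fit.n_params, fit.minus2loglik
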