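"""Shared Poisson-GLM fitting core with explained deviance D².

All count models in the package (window-level, gene-level, power
simulation) go through :func:`fit_poisson_glm`: a Poisson GLM with log
link and a log-exposure offset, so the linear predictor models a rate per
eligible site.  Model quality is summarised by the explained deviance

    D² = 1 − residual deviance / null deviance,

the GLM generalisation of explained variance; the null model is the
intercept-plus-offset fit.  Overdispersion is estimated (Pearson χ² /
residual df) and reported but never used to rescale deviances, so D² stays
comparable across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class GlmResult:
    predictors: list
    coefficients: np.ndarray            # intercept first
    residual_deviance: float
    null_deviance: float
    d2: float
    deviance_p: float                   # LR test of the model vs the null
    dispersion: float                   # Pearson chi2 / df_resid
    overdispersed: bool
    n_obs: int
    model: object = field(default=None, repr=False)

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.predictors.index(name) + 1])


def fit_poisson_glm(y, X, exposure, predictor_names=None) -> GlmResult:
    """Fit ``y ~ X`` as Poisson counts with ``log(exposure)`` offset.

    ``y``: counts per unit (window/gene); ``X``: 2-D predictor matrix (a
    1-D array is treated as a single predictor); ``exposure``: positive
    eligible-site (x patient) counts.  Raises on non-finite inputs,
    constant predictors, or non-convergence.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(len(y), 0)
    exposure = np.asarray(exposure, float)
    if np.any(exposure <= 0):
        raise ValueError("exposure must be positive for every observation")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("non-finite values in response or predictors")
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few observations for the requested predictors")
    if X.shape[1] and (X.std(axis=0) == 0).any():
        raise ValueError("constant predictor column")
    names = list(predictor_names) if predictor_names is not None else [
        f"x{i}" for i in range(X.shape[1])]

    offset = np.log(exposure)
    design = sm.add_constant(X, has_constant="add") if X.shape[1] else \
        np.ones((len(y), 1))
    fit = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset).fit()
    if not fit.converged:
        raise RuntimeError("Poisson GLM did not converge")
    null_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson(),
                      offset=offset).fit()
    dev, null_dev = float(fit.deviance), float(null_fit.deviance)
    d2 = 0.0 if null_dev == 0 else 1.0 - dev / null_dev
    df = X.shape[1]
    lr = max(null_dev - dev, 0.0)
    p = float(stats.chi2.sf(lr, df)) if df else 1.0
    df_resid = max(len(y) - df - 1, 1)
    dispersion = float(fit.pearson_chi2) / df_resid
    return GlmResult(
        predictors=names,
        coefficients=np.asarray(fit.params, float),
        residual_deviance=dev,
        null_deviance=null_dev,
        d2=float(d2),
        deviance_p=p,
        dispersion=dispersion,
        overdispersed=dispersion > 2.0,
        n_obs=len(y),
        model=fit,
    )


def poisson_deviance(y, mu) -> float:
    """Poisson deviance 2 Σ [y log(y/μ) − (y − μ)] with 0·log0 = 0."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def nested_deviance_test(full: GlmResult, reduced: GlmResult):
    """Likelihood-ratio (deviance) test of a reduced model nested in a full
    one; returns (delta_d2, p)."""
    df = len(full.predictors) - len(reduced.predictors)
    if df <= 0:
        raise ValueError("full model must have more predictors than reduced")
    lr = max(reduced.residual_deviance - full.residual_deviance, 0.0)
    return full.d2 - reduced.d2, float(stats.chi2.sf(lr, df))
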