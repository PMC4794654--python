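"""Shared ordinary-least-squares effect estimation.

One predictor of interest plus optional covariates and an intercept;
complete-case analysis; two-sided p from the t distribution with residual
degrees of freedom (the exact small-sample reference, not the asymptotic
normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class EffectEstimate:
    """Coefficient of the predictor of interest in an adjusted OLS fit."""

    beta: float
    se: float
    p: float
    n: int
    estimable: bool
    note: str = ""

    @staticmethod
    def inestimable(n: int, note: str) -> "EffectEstimate":
        return EffectEstimate(float("nan"), float("nan"), float("nan"), n, False, note)


def ols_effect(y: pd.Series, x: pd.Series,
               covariates: pd.DataFrame | None = None) -> EffectEstimate:
    """OLS of ``y`` on ``x`` plus covariates and an intercept.

    Rows with any missing value are dropped. Returns an inestimable result
    (never a silent zero) when there are too few complete cases or the
    predictor is constant after missingness.
    """
    parts = [y.rename("__y__"), x.rename("__x__")]
    n_cov = 0
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates)
        n_cov = covariates.shape[1]
    data = pd.concat(parts, axis=1).dropna()
    n = len(data)
    n_params = 2 + n_cov  # intercept + predictor + covariates
    if n < n_params + 1:
        return EffectEstimate.inestimable(n, "too few complete cases")
    if data["__x__"].nunique() < 2:
        return EffectEstimate.inestimable(n, "constant predictor")
    design = sm.add_constant(data.drop(columns="__y__"), has_constant="add")
    fit = sm.OLS(data["__y__"].astype(float), design.astype(float)).fit()
    return EffectEstimate(
        beta=float(fit.params["__x__"]),
        se=float(fit.bse["__x__"]),
        p=float(fit.pvalues["__x__"]),
        n=n,
        estimable=True,
    )
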