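"""Association between the genetic score and glycemic reductions.

The primary model regresses each change trait on the tertile index coded
1/2/3 as a single linear trend, adjusted for covariates; treating the raw
integer score as a continuous predictor is the stated sensitivity analysis.
Three covariate sets are fitted: the base set (age, sex, baseline BMI), the
base set plus the week-0 value of the same trait, and the base set plus the
prescribed dose. Indicator-coded tertile contrasts (T2 and T3 against T1)
are reported additionally but are not the primary analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._ols import EffectEstimate, ols_effect
from .score import tertile_index
from .screening import TRAITS

COVARIATE_SETS = ("base", "base+baseline", "base+dose")
MODES = ("tertile-index", "continuous-score")
_BASELINE_COLUMN = {"d_fpg": "fpg0", "d_2hpg": "pg2h0", "d_hba1c": "hba1c0"}

ASSOCIATION_COLUMNS = [
    "trait", "mode", "covariate_set", "beta", "se", "p", "n",
    "estimable", "significant",
]


def fit_association(deltas: pd.Series, predictor: pd.Series,
                    covariates: pd.DataFrame | None = None) -> EffectEstimate:
    """Covariate-adjusted OLS of one change trait on a score predictor."""
    return ols_effect(deltas, predictor, covariates)


def summarize_by_tertile(deltas: pd.DataFrame, tertiles: pd.Series) -> pd.DataFrame:
    """Per-tertile mean +/- SEM for each change trait (no inference).

    Groups of size one get an undefined SEM and empty groups are emitted as
    flagged rows rather than silently dropped.
    """
    rows = []
    groups = ("T1", "T2", "T3")
    for trait in TRAITS:
        for group in groups:
            members = deltas.loc[tertiles[tertiles == group].index, trait].dropna()
            n = len(members)
            rows.append({
                "trait": trait,
                "tertile": group,
                "n": n,
                "mean": members.mean() if n else np.nan,
                "sem": members.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "flag": "" if n > 1 else ("empty" if n == 0 else "single subject"),
            })
    return pd.DataFrame(rows)


class ScoreAssociation(BaseEstimator):
    """Score-efficacy association suite across modes and covariate sets.

    ``fit`` expects per-subject tables aligned on subject id: the change
    traits, scores, tertile labels, base covariates (age/sex/bmi0), baseline
    trait values (``fpg0``/``pg2h0``/``hba1c0``) and the dose covariate.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per trait x predictor mode x covariate set.
    contrasts_ : pandas.DataFrame
        Indicator-coded T2/T3 vs T1 contrasts per trait (base covariates).
    summary_ : pandas.DataFrame
        Per-tertile mean +/- SEM table.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, deltas: pd.DataFrame, scores: pd.Series, tertiles: pd.Series,
            covariates: pd.DataFrame, baselines: pd.DataFrame | None = None,
            dose: pd.Series | None = None):
        trend = tertile_index(tertiles).astype(float)
        predictors = {"tertile-index": trend, "continuous-score": scores.astype(float)}
        rows = []
        for trait in TRAITS:
            for mode in MODES:
                for covariate_set in COVARIATE_SETS:
                    covs = covariates.copy()
                    if covariate_set == "base+baseline":
                        if baselines is None:
                            continue
                        covs = covs.join(baselines[[_BASELINE_COLUMN[trait]]], how="left")
                    elif covariate_set == "base+dose":
                        if dose is None:
                            continue
                        covs = covs.join(dose.rename("dose_mg"), how="left")
                    estimate = fit_association(deltas[trait], predictors[mode], covs)
                    rows.append({
                        "trait": trait, "mode": mode, "covariate_set": covariate_set,
                        "beta": estimate.beta, "se": estimate.se, "p": estimate.p,
                        "n": estimate.n, "estimable": estimate.estimable,
                        "significant": bool(estimate.estimable and estimate.p < self.alpha),
                    })
        self.results_ = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
        self.contrasts_ = self._tertile_contrasts(deltas, tertiles, covariates)
        self.summary_ = summarize_by_tertile(deltas, tertiles)
        return self

    def _tertile_contrasts(self, deltas, tertiles, covariates) -> pd.DataFrame:
        """Joint fit with T2/T3 indicators (T1 reference), base covariates."""
        indicators = pd.get_dummies(tertiles).reindex(
            columns=["T1", "T2", "T3"], fill_value=0
        ).astype(float)
        indicators[tertiles.isna()] = np.nan
        rows = []
        for trait in TRAITS:
            data = pd.concat(
                [deltas[trait].rename("y"), indicators[["T2", "T3"]], covariates],
                axis=1,
            ).dropna()
            n_params = 4 + covariates.shape[1]
            if len(data) < n_params + 1 or data["T2"].nunique() < 2 or data["T3"].nunique() < 2:
                for level in ("T2", "T3"):
                    rows.append({"trait": trait, "contrast": f"{level} vs T1",
                                 "beta": np.nan, "se": np.nan, "p": np.nan,
                                 "n": len(data), "estimable": False})
                continue
            design = sm.add_constant(data.drop(columns="y"), has_constant="add")
            fit = sm.OLS(data["y"], design).fit()
            for level in ("T2", "T3"):
                rows.append({
                    "trait": trait, "contrast": f"{level} vs T1",
                    "beta": float(fit.params[level]), "se": float(fit.bse[level]),
                    "p": float(fit.pvalues[level]), "n": int(fit.nobs),
                    "estimable": True,
                })
        return pd.DataFrame(rows)
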