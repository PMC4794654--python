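"""Per-SNP additive-model screening of glycemic-change traits.

For every SNP and every change trait (week-48 value minus baseline of
fasting glucose, post-load 2h glucose, and HbA1c) an ordinary
least-squares regression of the change on the 0/1/2 allele count is fitted
with adjustment for age, sex and baseline BMI. Each SNP is then oriented to
its *effect allele* — the allele whose count carries a negative coefficient
(greater glycemic reduction) — and SNPs enter the combined genetic score
when any trait shows a sufficiently negative coefficient or a screening
p-value below a liberal threshold. The screen is deliberately permissive
(p < 0.2, no multiplicity correction): it is a pre-selection for a joint
score, not a discovery analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._ols import EffectEstimate, ols_effect
from .io import GenotypeMatrix

#: change-trait names and the visit measurement each derives from
TRAITS = ("d_fpg", "d_2hpg", "d_hba1c")
TRAIT_SOURCE = {"d_fpg": "fpg", "d_2hpg": "pg2h", "d_hba1c": "hba1c"}
DEFAULT_COVARIATES = ("age", "sex", "bmi0")

RESULT_COLUMNS = [
    "snp_id", "trait", "beta", "se", "p", "n", "estimable", "note",
    "counted_allele", "effect_allele", "oriented", "flipped", "ambiguous",
]


# ---------------------------------------------------------------------------
# change traits and per-subject covariates


def compute_deltas(phenotypes: pd.DataFrame, final_week: int | None = None) -> pd.DataFrame:
    """Week-``final`` minus week-0 value per trait and subject.

    A change value exists only when both the baseline and the final visit
    carry a measurement of that trait; subjects who left the study early
    have all change values missing (they enter the survival analysis, not
    the change regressions).
    """
    if phenotypes.duplicated(subset=["subject_id", "week"]).any():
        raise ValueError("duplicate (subject_id, week) rows in phenotype table")
    if final_week is None:
        final_week = int(phenotypes["week"].max())
    subjects = pd.Index(phenotypes["subject_id"].unique(), name="subject_id")
    week0 = phenotypes[phenotypes["week"] == 0].set_index("subject_id")
    if not subjects.isin(week0.index).all():
        missing = subjects[~subjects.isin(week0.index)].tolist()
        raise ValueError(f"subjects without a week-0 row: {missing}")
    final = phenotypes[phenotypes["week"] == final_week].set_index("subject_id")
    deltas = pd.DataFrame(index=subjects)
    for trait, source in TRAIT_SOURCE.items():
        base = week0[source].reindex(subjects)
        end = final[source].reindex(subjects) if len(final) else pd.Series(np.nan, index=subjects)
        deltas[trait] = end - base
    return deltas


def subject_covariates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Age, sex and baseline BMI per subject (taken from the week-0 row)."""
    week0 = phenotypes[phenotypes["week"] == 0].set_index("subject_id")
    return week0[["age", "sex", "bmi0"]].copy()


def baseline_values(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Week-0 trait values per subject, columns ``fpg0``, ``pg2h0``, ``hba1c0``."""
    week0 = phenotypes[phenotypes["week"] == 0].set_index("subject_id")
    return week0[["fpg", "pg2h", "hba1c"]].rename(
        columns={"fpg": "fpg0", "pg2h": "pg2h0", "hba1c": "hba1c0"}
    )


def final_dose(phenotypes: pd.DataFrame) -> pd.Series:
    """Last prescribed dose (mg) per subject."""
    ordered = phenotypes.sort_values("week")
    doses = ordered.dropna(subset=["dose_mg"]).groupby("subject_id")["dose_mg"].last()
    return doses.rename("dose_mg")


def mean_dose(phenotypes: pd.DataFrame) -> pd.Series:
    """Visit-averaged prescribed dose (mg) per subject (sensitivity option)."""
    return phenotypes.groupby("subject_id")["dose_mg"].mean().rename("dose_mg")


# ---------------------------------------------------------------------------
# per-SNP regression


def fit_additive(trait_values: pd.Series, dosage: pd.Series,
                 covariates: pd.DataFrame | None = None) -> EffectEstimate:
    """Additive-model OLS of a change trait on an allele count.

    The coefficient, its standard error and a two-sided t-distribution
    p-value refer to the allele-count term.
    """
    return ols_effect(trait_values, dosage, covariates)


# ---------------------------------------------------------------------------
# orientation and selection


@dataclass(frozen=True)
class SelectionRule:
    """Inclusion rule for the combined analysis.

    A SNP is selected when ANY of the four conditions holds on its oriented
    results: coefficient at or below the trait-specific threshold for any
    trait (boundary qualifies, ``<=``), or any trait's p-value strictly
    below ``p_threshold``.
    """

    beta_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"d_fpg": -0.5, "d_2hpg": -1.0, "d_hba1c": -0.5}
    )
    p_threshold: float = 0.2

    def __post_init__(self):
        for trait, threshold in self.beta_thresholds.items():
            if threshold >= 0:
                raise ValueError(f"beta threshold for {trait} must be negative")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p threshold must lie in (0, 1)")


def orient_results(results: pd.DataFrame, snp_meta: pd.DataFrame) -> pd.DataFrame:
    """Orient every SNP to a single effect allele.

    The trait with the smallest p-value among estimable fits decides the
    orientation (ties broken by canonical trait order); when its coefficient
    is positive the counted allele is swapped, which negates the
    coefficients of *all* traits of that SNP while standard errors and
    p-values are unchanged (the regression refit with coding x -> 2 - x).
    Exactly-zero coefficients keep the input orientation and are flagged
    ambiguous. Idempotent.
    """
    results = results.copy()
    for column, default in (("effect_allele", None), ("oriented", False),
                            ("flipped", False), ("ambiguous", False)):
        if column not in results.columns:
            results[column] = default
    trait_rank = {trait: i for i, trait in enumerate(TRAITS)}
    for snp_id, block in results.groupby("snp_id", sort=False):
        meta = snp_meta.loc[snp_id]
        # current coding may already have been flipped by a previous pass
        counted = block["counted_allele"].iloc[0] if "counted_allele" in block \
            else meta["counted_allele"]
        other = meta["ref"] if counted == meta["alt"] else meta["alt"]
        estimable = block[block["estimable"]]
        if estimable.empty:
            results.loc[block.index, ["effect_allele", "oriented", "ambiguous"]] = \
                [counted, True, True]
            continue
        best = estimable.loc[
            estimable.assign(_rank=estimable["trait"].map(trait_rank))
            .sort_values(["p", "_rank"]).index[0]
        ]
        if best["beta"] > 0:
            results.loc[block.index, "beta"] = -results.loc[block.index, "beta"]
            results.loc[block.index, "effect_allele"] = other
            results.loc[block.index, "counted_allele"] = other
            results.loc[block.index, "flipped"] = True
        else:
            results.loc[block.index, "effect_allele"] = counted
            if best["beta"] == 0:
                results.loc[block.index, "ambiguous"] = True
        results.loc[block.index, "oriented"] = True
    return results


def select_snps(oriented: pd.DataFrame,
                rule: SelectionRule | None = None) -> pd.DataFrame:
    """Apply the inclusion rule to oriented screening results.

    Returns one row per SNP with ``selected`` and a ``qualifying`` string
    listing the conditions met (``trait:beta`` / ``trait:p``). Missing
    p-values never satisfy the p condition.
    """
    rule = rule or SelectionRule()
    rows = []
    for snp_id, block in oriented.groupby("snp_id", sort=False):
        tokens = []
        for _, row in block.iterrows():
            if not row["estimable"]:
                continue
            threshold = rule.beta_thresholds.get(row["trait"])
            if threshold is not None and row["beta"] <= threshold:
                tokens.append(f"{row['trait']}:beta")
            if pd.notna(row["p"]) and row["p"] < rule.p_threshold:
                tokens.append(f"{row['trait']}:p")
        effect_allele = block["effect_allele"].iloc[0]
        rows.append({
            "snp_id": snp_id,
            "effect_allele": effect_allele,
            "selected": bool(tokens),
            "qualifying": ";".join(tokens),
        })
    return pd.DataFrame(rows, columns=["snp_id", "effect_allele", "selected", "qualifying"])


class AdditiveScreener(BaseEstimator):
    """Per-SNP additive screening, orientation and panel selection.

    Parameters mirror the selection rule so the screen composes with
    scikit-learn parameter search utilities. ``fit`` expects the genotype
    matrix (``X``), the change-trait table (``y``, columns ``d_fpg``,
    ``d_2hpg``, ``d_hba1c``) and a covariate table aligned on subject id.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per SNP x trait with oriented beta/se/p and allele bookkeeping.
    selection_ : pandas.DataFrame
        Per-SNP selection decision with qualifying conditions.
    panel_ : pandas.DataFrame
        Selected SNPs with their effect alleles (input to the genetic score).
    selection_warning_ : str or None
        Set when the rule selects nothing; downstream stages should stop.
    """

    def __init__(self, beta_threshold_fpg: float = -0.5,
                 beta_threshold_2hpg: float = -1.0,
                 beta_threshold_hba1c: float = -0.5,
                 p_threshold: float = 0.2):
        self.beta_threshold_fpg = beta_threshold_fpg
        self.beta_threshold_2hpg = beta_threshold_2hpg
        self.beta_threshold_hba1c = beta_threshold_hba1c
        self.p_threshold = p_threshold

    @property
    def rule(self) -> SelectionRule:
        return SelectionRule(
            beta_thresholds={
                "d_fpg": self.beta_threshold_fpg,
                "d_2hpg": self.beta_threshold_2hpg,
                "d_hba1c": self.beta_threshold_hba1c,
            },
            p_threshold=self.p_threshold,
        )

    def fit(self, X, y: pd.DataFrame, covariates: pd.DataFrame | None = None):
        if isinstance(X, GenotypeMatrix):
            dosage, snp_meta = X.dosage, X.snp_meta
        else:
            dosage = pd.DataFrame(X)
            snp_meta = pd.DataFrame(
                {"chrom": ".", "ref": "A1", "alt": "A2", "counted_allele": "A2"},
                index=pd.Index(dosage.columns, name="snp_id"),
            )
        subjects = dosage.index.intersection(y.index)
        dosage = dosage.loc[subjects]
        deltas = y.loc[subjects]
        covs = covariates.loc[covariates.index.intersection(subjects)] \
            if covariates is not None else None

        rows = []
        for snp_id in dosage.columns:
            for trait in TRAITS:
                estimate = fit_additive(deltas[trait], dosage[snp_id], covs)
                rows.append({
                    "snp_id": snp_id, "trait": trait,
                    "beta": estimate.beta, "se": estimate.se, "p": estimate.p,
                    "n": estimate.n, "estimable": estimate.estimable,
                    "note": estimate.note,
                    "counted_allele": snp_meta.loc[snp_id, "counted_allele"],
                })
        results = pd.DataFrame(rows)
        self.results_ = orient_results(results, snp_meta)
        self.selection_ = select_snps(self.results_, self.rule)
        selected = self.selection_[self.selection_["selected"]]
        self.panel_ = selected[["snp_id", "effect_allele"]].reset_index(drop=True)
        self.selection_warning_ = None if len(selected) else \
            "selection rule matched no SNPs; downstream stages not applicable"
        return self
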