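"""Time-to-glycemic-target survival analysis across score tertiles.

Two attainment definitions are supported per trait: a fixed glycemic
threshold (FPG < 7.0 mmol/L, 2h glucose < 11.1 mmol/L, HbA1c < 7.0%) and a
relative criterion (decrease strictly greater than 20% of the baseline
value). The event time is the first post-baseline visit week at which the
criterion holds. Subjects withdrawn for inadequately controlled glycemia
are non-responders: they demonstrably did not attain, so by default they
are carried event-free to the end of follow-up (week 48) rather than
censored at withdrawal; a censor-at-withdrawal convention is available.
Lost-to-follow-up subjects are censored at their last observed visit.
Groups (score tertiles) are compared with the Mantel-Cox log-rank test
(overall and all pairwise, unadjusted) and a Cox proportional-hazards model
with the tertile entered as a 1/2/3 trend plus age, sex and baseline BMI;
ties at the discrete visit weeks use Efron's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _two_sample_logrank
from lifelines.statistics import multivariate_logrank_test
from sklearn.base import BaseEstimator

from .score import tertile_index

#: fixed glycemic targets per trait (mmol/L for glucose, % for HbA1c)
TARGETS = {"fpg": 7.0, "pg2h": 11.1, "hba1c": 7.0}
CRITERIA = ("threshold", "relative20")


@dataclass(frozen=True)
class AttainmentSpec:
    """One attainment definition: a trait plus the criterion applied to it."""

    trait: str
    criterion: str = "threshold"
    threshold: float | None = None  # defaults to TARGETS[trait]
    rel_fraction: float = 0.2

    def __post_init__(self):
        if self.trait not in TARGETS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def cutoff(self) -> float:
        return self.threshold if self.threshold is not None else TARGETS[self.trait]

    def holds(self, baseline: float, value: float) -> bool:
        if self.criterion == "threshold":
            return value < self.cutoff
        return (baseline - value) / baseline > self.rel_fraction  # strict >


@dataclass(frozen=True)
class SubjectOutcome:
    subject_id: str
    time: float
    event: int
    nonresponder: bool = False
    excluded: str | None = None


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    warning: str = ""


@dataclass(frozen=True)
class CoxResult:
    coef: float
    hazard_ratio: float
    se: float
    p: float
    n: int
    n_events: int
    note: str = ""


# ---------------------------------------------------------------------------
# attainment evaluation


def evaluate_attainment(visits: pd.DataFrame, spec: AttainmentSpec,
                        nonresponder: str = "week48",
                        horizon: float = 48.0) -> SubjectOutcome:
    """Time and event indicator for one subject's visit rows.

    ``visits`` holds that subject's phenotype rows (any order). Subjects
    already below a fixed threshold at baseline cannot attain and are
    returned with an ``excluded`` reason instead of a time.
    """
    if nonresponder not in ("week48", "censor"):
        raise ValueError("nonresponder convention must be 'week48' or 'censor'")
    rows = visits.sort_values("week")
    subject_id = str(rows["subject_id"].iloc[0])
    base_rows = rows[rows["week"] == 0]
    if base_rows.empty or pd.isna(base_rows[spec.trait].iloc[0]):
        raise ValueError(f"subject {subject_id}: no baseline {spec.trait} measurement")
    baseline = float(base_rows[spec.trait].iloc[0])
    if spec.criterion == "relative20" and baseline <= 0:
        raise ValueError(f"subject {subject_id}: baseline {spec.trait} must be positive")
    if spec.criterion == "threshold" and baseline < spec.cutoff:
        return SubjectOutcome(subject_id, np.nan, 0, excluded="baseline already below target")
    post = rows[rows["week"] > 0]
    if post.empty:
        raise ValueError(f"subject {subject_id}: no post-baseline visits")
    for _, row in post.iterrows():
        value = row[spec.trait]
        if pd.notna(value) and spec.holds(baseline, float(value)):
            return SubjectOutcome(subject_id, float(row["week"]), 1)
    status = rows["status"].iloc[-1]
    last_week = float(post["week"].iloc[-1])
    if status == "withdrawn_control" and nonresponder == "week48":
        return SubjectOutcome(subject_id, float(horizon), 0, nonresponder=True)
    if status == "withdrawn_control":
        return SubjectOutcome(subject_id, last_week, 0, nonresponder=True)
    return SubjectOutcome(subject_id, last_week, 0)


def build_survival_data(phenotypes: pd.DataFrame, tertiles: pd.Series,
                        covariates: pd.DataFrame, spec: AttainmentSpec,
                        nonresponder: str = "week48"
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject survival dataset under one attainment definition.

    Subjects without a tertile label (e.g. missing panel genotypes) are
    skipped; baseline-excluded subjects are collected as warnings.
    """
    horizon = float(phenotypes["week"].max())
    warnings_list: list[str] = []
    records = []
    labelled = tertiles.dropna()
    for subject_id, rows in phenotypes.groupby("subject_id", sort=False):
        if subject_id not in labelled.index:
            continue
        if not (rows["week"] > 0).any():  # lost before first follow-up visit
            warnings_list.append(f"{subject_id}: no post-baseline visits")
            continue
        outcome = evaluate_attainment(rows, spec, nonresponder=nonresponder,
                                      horizon=horizon)
        if outcome.excluded:
            warnings_list.append(f"{subject_id}: {outcome.excluded}")
            continue
        record = {
            "subject_id": subject_id,
            "time": outcome.time,
            "event": outcome.event,
            "nonresponder": outcome.nonresponder,
            "tertile": labelled.loc[subject_id],
        }
        if subject_id in covariates.index:
            record.update(covariates.loc[subject_id].to_dict())
        records.append(record)
    data = pd.DataFrame(records)
    if not data.empty:
        data = data.set_index("subject_id")
        data["trend"] = tertile_index(data["tertile"]).astype(float)
    return data, warnings_list


# ---------------------------------------------------------------------------
# group comparisons


def logrank(time: pd.Series, group: pd.Series, event: pd.Series) -> LogRankResult:
    """Mantel-Cox log-rank test: overall k-group plus all pairwise tests."""
    groups = sorted(pd.Series(group).unique())
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two non-empty groups")
    if int(np.sum(event)) == 0:
        return LogRankResult(0.0, len(groups) - 1, 1.0, warning="no events")
    overall = multivariate_logrank_test(time, group, event)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            mask_a = np.asarray(group) == a
            mask_b = np.asarray(group) == b
            pair = _two_sample_logrank(
                np.asarray(time)[mask_a], np.asarray(time)[mask_b],
                event_observed_A=np.asarray(event)[mask_a],
                event_observed_B=np.asarray(event)[mask_b],
            )
            rows.append({"group_a": a, "group_b": b,
                         "chi2": float(pair.test_statistic),
                         "p": float(pair.p_value)})
    return LogRankResult(
        chi2=float(overall.test_statistic),
        df=len(groups) - 1,
        p=float(overall.p_value),
        pairwise=pd.DataFrame(rows),
    )


def cox_fit(data: pd.DataFrame, covariate_cols=("age", "sex", "bmi0"),
            predictor: str = "trend") -> CoxResult:
    """Cox proportional-hazards fit of the tertile trend, Efron ties.

    Zero-variance covariates are dropped with a note; non-convergence and
    monotone likelihood raise or flag explicitly rather than returning a
    silent zero.
    """
    if data["event"].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    if data[predictor].nunique() < 2:
        raise ValueError("Cox predictor is constant")
    notes = []
    keep = [predictor]
    for col in covariate_cols:
        if col in data.columns and data[col].nunique() > 1:
            keep.append(col)
        else:
            notes.append(f"dropped constant covariate {col}")
    frame = data[["time", "event", *keep]].dropna().astype(float)
    fitter = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            # tight Newton tolerances: the default stopping rules can leave
            # the coefficient ~1e-6 short of the optimum on small,
            # flat-likelihood datasets because the final step is not applied
            fitter.fit(frame, duration_col="time", event_col="event",
                       fit_options={"precision": 1e-13, "r_precision": 1e-14,
                                    "max_steps": 500})
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    for warning in caught:
        if "convergence" in str(warning.message).lower() or \
                "complete separation" in str(warning.message).lower():
            notes.append(str(warning.message).splitlines()[0])
    return CoxResult(
        coef=float(fitter.params_[predictor]),
        hazard_ratio=float(np.exp(fitter.params_[predictor])),
        se=float(fitter.standard_errors_[predictor]),
        p=float(fitter.summary.loc[predictor, "p"]),
        n=int(fitter._n_examples),
        n_events=int(frame["event"].sum()),
        note="; ".join(notes),
    )


def attainment_rates(time: pd.Series, group: pd.Series,
                     event: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier cumulative attainment (1 - survival) per group and week."""
    timeline = np.unique(np.asarray(time, dtype=float))
    rows = []
    for label in sorted(pd.Series(group).unique()):
        mask = np.asarray(group) == label
        times = np.asarray(time, dtype=float)[mask]
        events = np.asarray(event)[mask]
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        surv = kmf.survival_function_at_times(timeline).to_numpy()
        for week, s in zip(timeline, surv):
            rows.append({
                "group": label,
                "week": float(week),
                "cumulative_attainment": float(1.0 - s),
                "n_at_risk": int((times >= week).sum()),
            })
    return pd.DataFrame(rows)


class AttainmentAnalysis(BaseEstimator):
    """Survival analysis of one attainment definition across tertiles.

    ``fit`` expects the longitudinal phenotype table, tertile labels and a
    per-subject covariate table. Fitted attributes carry the dataset, the
    overall and pairwise log-rank results, the adjusted Cox fit and the
    per-group cumulative attainment curve.
    """

    def __init__(self, trait: str = "hba1c", criterion: str = "relative20",
                 nonresponder: str = "week48",
                 covariate_cols=("age", "sex", "bmi0")):
        self.trait = trait
        self.criterion = criterion
        self.nonresponder = nonresponder
        self.covariate_cols = covariate_cols

    def fit(self, phenotypes: pd.DataFrame, tertiles: pd.Series,
            covariates: pd.DataFrame):
        spec = AttainmentSpec(trait=self.trait, criterion=self.criterion)
        self.data_, self.warnings_ = build_survival_data(
            phenotypes, tertiles, covariates, spec, nonresponder=self.nonresponder
        )
        if self.data_.empty or self.data_["tertile"].nunique() < 2:
            raise ValueError("attainment analysis needs at least two tertile groups")
        self.logrank_ = logrank(self.data_["time"], self.data_["tertile"],
                                self.data_["event"])
        try:
            self.cox_ = cox_fit(self.data_, covariate_cols=self.covariate_cols)
        except (ValueError, RuntimeError) as exc:
            self.cox_ = None
            self.cox_error_ = str(exc)
        self.curves_ = attainment_rates(self.data_["time"], self.data_["tertile"],
                                        self.data_["event"])
        return self
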