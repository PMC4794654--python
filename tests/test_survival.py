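"""Attainment evaluation, log-rank, Cox and Kaplan-Meier behaviour."""

import numpy as np
import pandas as pd
import pytest

from oracles import cox_oracle, km_oracle, mantel_cox_oracle
from pgxscore.survival import (
    AttainmentAnalysis,
    AttainmentSpec,
    attainment_rates,
    build_survival_data,
    cox_fit,
    evaluate_attainment,
    logrank,
)

WEEKS = (0, 2, 4, 12, 24, 32, 48)


def visits(subject_id, fpg=None, pg2h=None, hba1c=None, weeks=WEEKS, status=None):
    n = len(weeks)
    frame = pd.DataFrame({
        "subject_id": subject_id,
        "week": list(weeks),
        "fpg": fpg if fpg is not None else [np.nan] * n,
        "pg2h": pg2h if pg2h is not None else [np.nan] * n,
        "hba1c": hba1c if hba1c is not None else [np.nan] * n,
    })
    frame["status"] = ["active"] * (n - 1) + [status or "active"]
    return frame


class TestEvaluateAttainment:
    def test_first_threshold_crossing(self):
        rows = visits("S1", fpg=[10.0, 9.5, 8.0, 6.9, 6.5, 6.0, 5.8])
        outcome = evaluate_attainment(rows, AttainmentSpec("fpg"))
        assert (outcome.time, outcome.event) == (12.0, 1)

    def test_relative20_strict_boundary(self):
        exactly_20 = visits("S1", fpg=[10.0, 9.9, 9.8, 9.7, 8.0, 9.6, 9.5])
        spec = AttainmentSpec("fpg", criterion="relative20")
        outcome = evaluate_attainment(exactly_20, spec)
        assert outcome.event == 0  # 20% exactly does not qualify
        just_past = visits("S1", fpg=[10.0, 9.9, 9.8, 9.7, 7.9, 9.6, 9.5])
        outcome = evaluate_attainment(just_past, spec)
        assert (outcome.time, outcome.event) == (24.0, 1)

    def test_withdrawer_is_nonresponder_at_week_48(self):
        rows = visits("S1", hba1c=[9.0, 8.9, 8.8, 8.7, 8.8], weeks=WEEKS[:5],
                      status="withdrawn_control")
        outcome = evaluate_attainment(rows, AttainmentSpec("hba1c"))
        assert (outcome.time, outcome.event, outcome.nonresponder) == (48.0, 0, True)
        censored = evaluate_attainment(rows, AttainmentSpec("hba1c"),
                                       nonresponder="censor")
        assert (censored.time, censored.event) == (24.0, 0)

    def test_lost_subject_censored_at_last_visit(self):
        rows = visits("S1", hba1c=[9.0, 8.9, 8.8], weeks=WEEKS[:3], status="lost")
        outcome = evaluate_attainment(rows, AttainmentSpec("hba1c"))
        assert (outcome.time, outcome.event) == (4.0, 0)

    def test_baseline_below_target_excluded(self):
        rows = visits("S1", fpg=[6.5, 6.0, 5.9, 5.8, 5.7, 5.6, 5.5])
        outcome = evaluate_attainment(rows, AttainmentSpec("fpg"))
        assert outcome.excluded is not None

    def test_nonpositive_baseline_rejected_for_relative(self):
        rows = visits("S1", fpg=[0.0, 5.0], weeks=(0, 2))
        with pytest.raises(ValueError, match="positive"):
            evaluate_attainment(rows, AttainmentSpec("fpg", criterion="relative20"))

    def test_threshold_equals_relative_when_baseline_is_ratio(self):
        """baseline = cutoff / 0.8 makes 'value < cutoff' and '>20% drop'
        the same event: both analyses must agree subject by subject."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            base = 7.0 / 0.8
            values = [base] + list(rng.uniform(5.5, 9.5, 6))
            rows = visits("S1", fpg=values)
            a = evaluate_attainment(rows, AttainmentSpec("fpg", criterion="threshold"))
            b = evaluate_attainment(rows, AttainmentSpec("fpg", criterion="relative20"))
            assert (a.time, a.event) == (b.time, b.event)


TWO_GROUP_FIXTURE = pd.DataFrame({
    "time": [2.0, 4.0, 12.0, 4.0, 24.0, 48.0],
    "event": [1, 1, 0, 1, 0, 1],
    "group": ["A", "A", "A", "B", "B", "B"],
})


class TestLogRank:
    def test_exchangeable_groups_give_null_statistic(self):
        time = pd.Series([2.0, 4.0, 12.0, 2.0, 4.0, 12.0])
        event = pd.Series([1, 1, 1, 1, 1, 1])
        group = pd.Series(["A"] * 3 + ["B"] * 3)
        result = logrank(time, group, event)
        assert result.chi2 == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_matches_hand_evaluated_mantel_cox(self):
        d = TWO_GROUP_FIXTURE
        result = logrank(d["time"], d["group"], d["event"])
        chi2, o_minus_e, variance = mantel_cox_oracle(d["time"], d["event"], d["group"])
        assert result.chi2 == pytest.approx(chi2, abs=1e-10)
        # two-group statistic is the squared standardised O-E sum
        assert result.chi2 == pytest.approx(o_minus_e ** 2 / variance, abs=1e-12)

    def test_invariant_to_group_relabeling(self):
        d = TWO_GROUP_FIXTURE
        relabeled = d["group"].map({"A": "B", "B": "A"})
        assert logrank(d["time"], relabeled, d["event"]).chi2 == pytest.approx(
            logrank(d["time"], d["group"], d["event"]).chi2, abs=1e-12)

    def test_late_censored_subject_keeps_prior_terms(self):
        d = TWO_GROUP_FIXTURE
        extended = pd.concat([d, pd.DataFrame(
            {"time": [60.0], "event": [0], "group": ["B"]})], ignore_index=True)
        base_chi2, base_oe, base_var = mantel_cox_oracle(
            d["time"], d["event"], d["group"])
        ext = logrank(extended["time"], extended["group"], extended["event"])
        ext_chi2, ext_oe, ext_var = mantel_cox_oracle(
            extended["time"], extended["event"], extended["group"])
        assert ext.chi2 == pytest.approx(ext_chi2, abs=1e-10)
        # the added late-censored subject enters every prior risk set
        assert ext_oe != pytest.approx(base_oe)

    def test_zero_events_warns_with_unit_p(self):
        result = logrank(pd.Series([4.0, 8.0]), pd.Series(["A", "B"]),
                         pd.Series([0, 0]))
        assert result.p == 1.0 and result.warning == "no events"

    def test_three_group_power_under_strong_effect(self):
        """Hazard doubling per tertile at n=300 is detected >80% of the time."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            group = np.repeat([1, 2, 3], 100)
            rate = 0.02 * 2.0 ** (group - 1)
            raw = rng.exponential(1.0 / rate)
            event = (raw <= 48).astype(int)
            time = np.minimum(raw, 48.0)
            result = logrank(pd.Series(time), pd.Series(group), pd.Series(event))
            rejections += result.p < 0.05
        assert rejections / n_reps > 0.8


class TestCox:
    def test_matches_partial_likelihood_oracle(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        data = pd.DataFrame({"time": time, "event": event, "trend": x})
        result = cox_fit(data, covariate_cols=())
        oracle = cox_oracle(time, event, x)
        assert result.coef == pytest.approx(oracle, abs=1e-6)

    def test_oracle_agreement_on_larger_untied_sample(self):
        rng = np.random.default_rng(6)
        n = 40
        x = rng.choice([0.0, 1.0], n)
        raw = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        raw += rng.uniform(0, 1e-6, n)  # break ties
        event = (raw <= 30).astype(int)
        time = np.where(event == 1, raw, 30.0 + rng.uniform(0, 1e-6, n))
        data = pd.DataFrame({"time": time, "event": event, "trend": x})
        result = cox_fit(data, covariate_cols=())
        assert result.coef == pytest.approx(cox_oracle(time, event, x), abs=1e-5)

    def test_constant_predictor_raises(self):
        data = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1],
                             "trend": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(data, covariate_cols=())

    def test_no_events_raises(self):
        data = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0],
                             "trend": [1.0, 2.0]})
        with pytest.raises(ValueError, match="event"):
            cox_fit(data, covariate_cols=())

    def test_null_type_one_error_near_nominal(self):
        """With no group effect the Wald test rejects at ~5%."""
        rng = np.random.default_rng(10)
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            n = 120
            trend = rng.choice([1.0, 2.0, 3.0], n)
            raw = rng.exponential(1.0 / 0.03, n)
            event = (raw <= 48).astype(int)
            time = np.minimum(raw, 48.0)
            data = pd.DataFrame({"time": time, "event": event, "trend": trend})
            result = cox_fit(data, covariate_cols=())
            rejections += result.p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09


class TestAttainmentRates:
    def test_product_limit_on_five_subject_fixture(self):
        time = pd.Series([2.0, 4.0, 4.0, 12.0, 24.0])
        event = pd.Series([1, 1, 0, 1, 0])
        group = pd.Series(["G"] * 5)
        curve = attainment_rates(time, group, event).set_index("week")
        survival = km_oracle(time, event)  # {2: 0.8, 4: 0.6, 12: 0.3}
        assert curve.loc[2.0, "cumulative_attainment"] == pytest.approx(1 - survival[2.0])
        assert curve.loc[4.0, "cumulative_attainment"] == pytest.approx(1 - survival[4.0])
        assert curve.loc[12.0, "cumulative_attainment"] == pytest.approx(0.7)
        assert curve.loc[24.0, "cumulative_attainment"] == pytest.approx(0.7)
        assert curve.loc[2.0, "n_at_risk"] == 5

    def test_all_events_at_first_visit_saturate(self):
        curve = attainment_rates(pd.Series([2.0, 2.0]), pd.Series(["G", "G"]),
                                 pd.Series([1, 1]))
        assert (curve["cumulative_attainment"] == 1.0).all()

    def test_no_events_give_flat_zero_curve(self):
        curve = attainment_rates(pd.Series([2.0, 48.0]), pd.Series(["G", "G"]),
                                 pd.Series([0, 0]))
        assert (curve["cumulative_attainment"] == 0.0).all()


class TestAttainmentAnalysisEstimator:
    def test_full_fit_on_simulated_cohort(self, small_study):
        from pgxscore.qc import qc_filter
        from pgxscore.score import GeneticScorer
        from pgxscore.screening import compute_deltas, subject_covariates
        from pgxscore.screening import AdditiveScreener

        genotypes, cohort, _ = small_study
        filtered, _ = qc_filter(genotypes)
        deltas = compute_deltas(cohort)
        covariates = subject_covariates(cohort)
        screener = AdditiveScreener().fit(filtered, deltas, covariates)
        scorer = GeneticScorer(panel=screener.panel_).fit(filtered)
        analysis = AttainmentAnalysis(trait="hba1c", criterion="relative20").fit(
            cohort, scorer.tertiles_, covariates)
        assert analysis.logrank_.df == analysis.data_["tertile"].nunique() - 1
        assert set(analysis.data_["event"]) <= {0, 1}
        assert ((analysis.data_["time"] > 0) & (analysis.data_["time"] <= 48)).all()
        assert len(analysis.logrank_.pairwise) == 3
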