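"""Cut-off scan/selection, Cox evaluation, ROC AUC and BMI categorization."""

import numpy as np
import pandas as pd
import pytest

from hi3.errors import FittingError, ValidationError
from hi3.stratify import (
    CutoffScan,
    bmi_category,
    categorize_bmi,
    default_grid,
    derive_risk_groups,
    endpoint_events,
    fit_cox,
    roc_auc,
    scan_cutoffs,
    select_cutoff,
    validate_cohort,
)
from hi3.synthetic import SurvivalModel, simulate_survival


def pairwise_auc(scores, labels):
    """All-pairs concordance with ties counted one-half (Mann-Whitney)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def make_cohort(n, seed, model=None, hi=None):
    rng = np.random.default_rng(seed)
    if hi is None:
        hi = rng.random(n)
    model = model or SurvivalModel(age_loghr_per_year=0.0)
    surv = simulate_survival(hi, model, rng)
    return surv.assign(hi=hi)


class TestGridAndValidation:
    def test_default_grid_has_19_candidates(self):
        grid = default_grid()
        assert len(grid) == 19
        assert grid[0] == 0.2 and grid[-1] == 0.65
        assert np.allclose(np.diff(grid), 0.025)

    def test_censored_subject_with_cause_rejected(self):
        df = pd.DataFrame({"hi": [0.3, 0.5], "followup_days": [100.0, 200.0],
                           "event": [0, 1], "cause": ["cancer", "cancer"]})
        with pytest.raises(ValidationError, match="cause 'none'"):
            validate_cohort(df)

    def test_cause_specific_censoring_conserves_subjects(self):
        cohort = make_cohort(500, 11, SurvivalModel(hi_loghr=2.0, age_loghr_per_year=0.0))
        for endpoint in ("all_cause", "cardio_respiratory"):
            events = endpoint_events(cohort, endpoint)
            assert events.sum() + (events == 0).sum() == len(cohort)
        cr = endpoint_events(cohort, "cardio_respiratory")
        assert cr.sum() == cohort["cause"].isin(["cardiovascular", "respiratory"]).sum()


class TestScan:
    def test_scan_covers_every_candidate(self):
        cohort = make_cohort(400, 3)
        scan = scan_cutoffs(cohort)
        assert len(scan.table) == 19
        assert scan.table["usable"].all()
        assert (scan.table["n_above"] == [(cohort.hi >= c).sum() for c in default_grid()]).all()

    def test_null_cohort_has_hr_near_one(self):
        # event probability independent of hi
        cohort = make_cohort(3000, 4, SurvivalModel(
            baseline_hazard_per_year=0.01, hi_loghr=0.0, age_loghr_per_year=0.0))
        scan = scan_cutoffs(cohort)
        assert abs(np.log(scan.usable["hr"]).mean()) < 0.35

    def test_no_events_is_an_error(self):
        df = pd.DataFrame({"hi": [0.3, 0.5], "followup_days": [100.0, 200.0], "event": [0, 0]})
        with pytest.raises(FittingError, match="no events"):
            scan_cutoffs(df)

    def test_degenerate_candidates_flagged_unusable(self):
        cohort = make_cohort(200, 5, hi=np.random.default_rng(5).uniform(0.3, 0.5, 200))
        scan = scan_cutoffs(cohort)
        table = scan.table.set_index("cutoff")
        assert not table.loc[0.6, "usable"]  # nobody above 0.6
        assert np.isnan(table.loc[0.6, "hr"])


class TestSelect:
    def _scan(self, rows):
        return CutoffScan(table=pd.DataFrame(rows))

    def test_agreeing_criteria(self):
        scan = self._scan([
            {"cutoff": 0.3, "hr": 2.0, "p": 0.01, "n_above": 50, "usable": True},
            {"cutoff": 0.4, "hr": 3.0, "p": 0.001, "n_above": 30, "usable": True},
        ])
        assert select_cutoff(scan) == 0.4

    def test_tie_broken_by_larger_hr(self):
        scan = self._scan([
            {"cutoff": 0.3, "hr": 2.8, "p": 0.01, "n_above": 50, "usable": True},
            {"cutoff": 0.4, "hr": 3.1, "p": 0.01, "n_above": 30, "usable": True},
        ])
        assert select_cutoff(scan) == 0.4

    def test_unusable_candidates_ignored(self):
        scan = self._scan([
            {"cutoff": 0.3, "hr": np.nan, "p": np.nan, "n_above": 0, "usable": False},
            {"cutoff": 0.4, "hr": 2.0, "p": 0.02, "n_above": 30, "usable": True},
        ])
        assert select_cutoff(scan) == 0.4
        with pytest.raises(FittingError):
            select_cutoff(self._scan([{"cutoff": 0.3, "hr": np.nan, "p": np.nan,
                                       "n_above": 0, "usable": False}]))

    def test_planted_step_scan_matches_manual_argmin(self):
        cohort = make_cohort(2000, 6, SurvivalModel(
            baseline_hazard_per_year=0.004, hi_loghr=0.0,
            step_cutoffs=(0.45,), step_loghrs=(np.log(3),), age_loghr_per_year=0.0))
        scan = scan_cutoffs(cohort)
        chosen = select_cutoff(scan)
        usable = scan.usable
        manual = usable.loc[usable["p"].idxmin(), "cutoff"]
        assert chosen == manual


class TestDeriveRiskGroups:
    def test_two_step_hazard_recovers_ordered_cutoffs(self):
        """Planted hazard steps at 0.45 and 0.65 are recovered in most replicates.

        The index distribution is right-skewed to match a realistic cohort
        (~15% above 0.45, ~1% above 0.65): with a symmetric distribution the
        single most significant binary split is the outer step, so the
        staged search targets 0.65 first and the experiment tests nothing.
        """
        model = SurvivalModel(baseline_hazard_per_year=0.004, hi_loghr=0.0,
                              step_cutoffs=(0.45, 0.65), step_loghrs=(np.log(3), np.log(3)),
                              age_loghr_per_year=0.0)
        lm_hits = mh_hits = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(600 + rep)
            hi = rng.beta(3.75, 8.25, 4000)  # ~15% above 0.45, ~0.8% above 0.65
            cohort = simulate_survival(hi, model, rng).assign(hi=hi)
            derivation = derive_risk_groups(cohort)
            lm_hits += abs(derivation.low_medium - 0.45) <= 0.0251
            if derivation.medium_high is not None:
                assert derivation.low_medium < derivation.medium_high
                mh_hits += abs(derivation.medium_high - 0.65) <= 0.0251
        assert lm_hits > n_reps / 2
        assert mh_hits > n_reps / 2

    def test_degenerate_cohort_fails_informatively(self):
        cohort = make_cohort(300, 8, hi=np.random.default_rng(8).uniform(0.0, 0.15, 300))
        with pytest.raises(FittingError):
            derive_risk_groups(cohort)

    def test_second_stage_equals_scan_on_filtered_table(self):
        cohort = make_cohort(2000, 9, SurvivalModel(hi_loghr=2.0, age_loghr_per_year=0.0))
        derivation = derive_risk_groups(cohort)
        if derivation.scan2 is not None:
            subset = cohort[cohort["hi"] >= derivation.low_medium]
            grid2 = default_grid()[default_grid() > derivation.low_medium]
            direct = scan_cutoffs(subset, grid2)
            pd.testing.assert_frame_equal(derivation.scan2.table, direct.table)

    def test_small_second_stage_reports_unavailable(self):
        rng = np.random.default_rng(10)
        hi = np.concatenate([rng.uniform(0.0, 0.4, 500), rng.uniform(0.6, 0.9, 8)])
        cohort = make_cohort(len(hi), 10, SurvivalModel(hi_loghr=2.5, age_loghr_per_year=0.0), hi=hi)
        derivation = derive_risk_groups(cohort, min_subjects=20)
        if derivation.low_medium >= 0.4:  # second-stage subset is the tiny tail
            assert derivation.medium_high is None
            with pytest.raises(FittingError):
                _ = derivation.cutoffs


class TestFitCox:
    def _group_cohort(self, n, seed, loghr, p_high=0.3):
        rng = np.random.default_rng(seed)
        high = rng.random(n) < p_high
        lam = 0.004 * np.exp(loghr * high)
        t = rng.exponential(1 / lam)
        return pd.DataFrame({
            "followup_days": np.minimum(t, 12.0) * 365.25,
            "event": (t <= 12.0).astype(int),
            "group": pd.Categorical(np.where(high, "High", "Low"), categories=["Low", "High"]),
        })

    def test_recovers_planted_hazard_ratio(self):
        table = fit_cox(self._group_cohort(2000, 42, np.log(3)), "group")
        assert table.loc[0, "level"] == "High"
        assert table.loc[0, "ci_low"] < 3.0 < table.loc[0, "ci_high"]
        assert 2.0 < table.loc[0, "hr"] < 4.5

    def test_null_effect_estimates_near_one(self):
        hrs = []
        for seed in range(5):
            table = fit_cox(self._group_cohort(1500, 100 + seed, 0.0), "group")
            hrs.append(table.loc[0, "hr"])
        assert abs(np.log(hrs).mean()) < 0.25

    def test_adjustment_reduces_confounding_bias(self):
        """An age effect that drives both the index and the hazard biases the
        unadjusted HR; adjusting for age should move the estimate toward truth."""
        rng = np.random.default_rng(77)
        n = 4000
        age = np.clip(rng.normal(62, 8, n), 50, 90)
        hi = np.clip(0.05 + 0.02 * (age - 50) + rng.normal(0, 0.08, n), 0, 1)
        true_loghr = np.log(2.0)
        high = hi >= np.quantile(hi, 0.7)
        lam = 0.003 * np.exp(true_loghr * high + 0.08 * (age - 62))
        t = rng.exponential(1 / lam)
        cohort = pd.DataFrame({
            "followup_days": np.minimum(t, 12.0) * 365.25,
            "event": (t <= 12.0).astype(int),
            "group": pd.Categorical(np.where(high, "High", "Low"), categories=["Low", "High"]),
            "age": age,
            "sex": rng.choice(["f", "m"], n),
            "education": rng.choice(["primary", "secondary"], n),
            "bmi_cat": rng.choice(["underweight/normal", "overweight"], n),
            "antihtn": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "n_cvd": rng.integers(0, 3, n),
            "smoking": rng.choice(["never", "past"], n),
            "alcohol": rng.choice(["cage_0", "cage_1_2"], n),
        })
        unadj = fit_cox(cohort, "group", adjusted=False).loc[0, "hr"]
        adj = fit_cox(cohort, "group", adjusted=True).loc[0, "hr"]
        assert abs(np.log(adj) - true_loghr) < abs(np.log(unadj) - true_loghr)

    def test_single_level_exposure_rejected(self):
        cohort = self._group_cohort(100, 1, 0.0)
        cohort["group"] = "Low"
        with pytest.raises(ValidationError):
            fit_cox(cohort, "group")


class TestRocAuc:
    def test_score_equal_to_label_is_perfect(self):
        df = pd.DataFrame({"followup_days": np.full(40, 100.0),
                           "event": np.tile([0, 1], 20)})
        df["score"] = df["event"].astype(float)
        assert roc_auc(df, "score") == 1.0

    def test_independent_score_near_chance(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "followup_days": np.full(4000, 100.0),
            "event": rng.integers(0, 2, 4000),
            "score": rng.random(4000),
        })
        assert abs(roc_auc(df, "score") - 0.5) < 0.03

    def test_matches_pairwise_concordance_with_ties(self, rng):
        for _ in range(5):
            n = 80
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            df = pd.DataFrame({"followup_days": np.full(n, 50.0), "event": labels,
                               "score": scores})
            assert roc_auc(df, "score") == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"followup_days": [10.0, 20.0], "event": [1, 1], "score": [0.1, 0.2]})
        with pytest.raises(ValidationError):
            roc_auc(df, "score")


class TestBmi:
    @pytest.mark.parametrize("weight,height,expected", [
        (70.0, 1.75, "underweight/normal"),   # BMI 22.86
        (76.5625, 1.75, "overweight"),        # BMI exactly 25
        (91.875, 1.75, "obese"),              # BMI exactly 30
        (107.1875, 1.75, "morbidly obese"),   # BMI exactly 35
    ])
    def test_boundaries(self, weight, height, expected):
        assert categorize_bmi(weight, height) == expected

    def test_category_function_direct(self):
        assert bmi_category(24.999) == "underweight/normal"
        assert bmi_category(34.999) == "obese"

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            categorize_bmi(-70.0, 1.75)
        with pytest.raises(ValidationError):
            categorize_bmi(70.0, 0.0)
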