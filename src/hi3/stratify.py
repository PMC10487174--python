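"""Risk-group cut-off derivation and survival-based evaluation.

The cut-offs separating Low/Medium/High risk are data-driven: a grid of
candidate HI thresholds (0.2 to 0.65 in steps of 0.025 by default) is
scanned, and at each candidate a univariate Cox proportional-hazards model
is fit on the binary indicator ``hi >= c`` for all-cause mortality. The
selected cut-off is the candidate with the smallest p-value (ties broken
by larger hazard ratio, then smaller cut-off) — a total-order refinement
of "maximal HR and minimal p", which is not by itself a total order; the
full scan table is always available so other rules can be applied. The
search is run twice: once on the full cohort for the Low/Medium boundary,
then again restricted to subjects above it for the Medium/High boundary.

Evaluation against mortality uses Cox models (hazard ratios with 95% CIs,
unadjusted and adjusted for the standard covariate set) and nonparametric
ROC analysis (AUC of a score for the binary died-by-end-of-follow-up
label). Subjects without an event are right-censored at the end of
follow-up; cause-specific endpoints treat deaths from other causes as
censored at the death time (cause-specific hazards; no competing-risk
subdistribution model). Event-time ties use lifelines' Efron
approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.metrics import roc_auc_score

from .errors import FittingError, ValidationError

logger = logging.getLogger("hi3.stratify")

CAUSES = ("cardiovascular", "respiratory", "cancer", "other", "none")
ENDPOINTS = ("all_cause", "cardio_respiratory")
#: causes counted as events under the combined cardio-respiratory endpoint
CARDIO_RESP_CAUSES = ("cardiovascular", "respiratory")
#: covariate set of the fully adjusted models
ADJUSTMENT_COVARIATES = (
    "age", "sex", "education", "bmi_cat", "antihtn",
    "diabetes", "n_cvd", "smoking", "alcohol",
)
#: covariates treated as categorical (dummy-coded against their first level)
CATEGORICAL_COVARIATES = ("sex", "education", "bmi_cat", "smoking", "alcohol")

GRID_START, GRID_STOP, GRID_STEP = 0.2, 0.65, 0.025


def default_grid() -> np.ndarray:
    """The candidate cut-off grid: 0.2 to 0.65 inclusive in steps of 0.025 (19 values)."""
    n = int(round((GRID_STOP - GRID_START) / GRID_STEP)) + 1
    return np.round(GRID_START + GRID_STEP * np.arange(n), 4)


def validate_cohort(cohort: pd.DataFrame, require_hi: bool = True) -> pd.DataFrame:
    """Check the survival columns of a cohort table.

    Requires ``followup_days, event`` (plus ``hi`` by default, and
    ``cause`` consistent with ``event`` when present: censored subjects
    have cause 'none').
    """
    cols = ("hi", "followup_days", "event") if require_hi else ("followup_days", "event")
    for col in cols:
        if col not in cohort.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    if not cohort["event"].isin([0, 1]).all():
        raise ValidationError("event column must be 0/1")
    if not (cohort["followup_days"] > 0).all():
        raise ValidationError("followup_days must be positive")
    if "cause" in cohort.columns:
        bad = ~cohort["cause"].isin(CAUSES)
        if bad.any():
            raise ValidationError(f"unknown causes: {sorted(cohort.loc[bad, 'cause'].unique())}")
        inconsistent = (cohort["event"] == 0) & (cohort["cause"] != "none")
        if inconsistent.any():
            raise ValidationError("censored subjects (event=0) must have cause 'none'")
    return cohort


def endpoint_events(cohort: pd.DataFrame, endpoint: str = "all_cause") -> pd.Series:
    """0/1 event indicator under an endpoint; other-cause deaths count as censored."""
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    if endpoint == "all_cause":
        return cohort["event"].astype(int)
    if "cause" not in cohort.columns:
        raise ValidationError("cause column required for the cardio-respiratory endpoint")
    return ((cohort["event"] == 1) & cohort["cause"].isin(CARDIO_RESP_CAUSES)).astype(int)


def _fit_cox_df(df: pd.DataFrame, duration_col: str = "T", event_col: str = "E") -> CoxPHFitter:
    """Fit a CoxPH model, converting convergence problems into FittingError."""
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=FutureWarning)
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except (ConvergenceError, RuntimeWarning, np.linalg.LinAlgError, ValueError) as exc:
            raise FittingError(f"Cox model did not converge: {exc}") from exc
    return cph


@dataclass(frozen=True)
class CutoffScan:
    """Result of a cut-off grid search: one row per candidate.

    ``table`` columns: cutoff, hr, p, n_above, usable. Unusable candidates
    (degenerate split or non-converged fit) are kept in the table with
    NaN statistics rather than dropped silently.
    """

    table: pd.DataFrame
    endpoint: str = "all_cause"

    @property
    def usable(self) -> pd.DataFrame:
        return self.table[self.table["usable"]]


def scan_cutoffs(
    cohort: pd.DataFrame,
    grid=None,
    endpoint: str = "all_cause",
) -> CutoffScan:
    """Univariate Cox scan over candidate HI cut-offs.

    For each candidate ``c`` the model ``h(t) = h0(t) * exp(beta * 1[hi >= c])``
    is fit; the hazard ratio ``exp(beta)`` and its p-value are recorded.
    Candidates leaving fewer than one subject on either side, or whose fit
    fails, are flagged unusable.
    """
    validate_cohort(cohort)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    events = endpoint_events(cohort, endpoint)
    if events.sum() == 0:
        raise FittingError(f"no events under endpoint {endpoint!r}; cannot scan cut-offs")
    hi = cohort["hi"].to_numpy(float)
    durations = cohort["followup_days"].to_numpy(float)
    rows = []
    for c in grid:
        above = hi >= c
        n_above = int(above.sum())
        row = {"cutoff": float(c), "hr": np.nan, "p": np.nan,
               "n_above": n_above, "usable": False}
        if 0 < n_above < len(hi):
            df = pd.DataFrame({"T": durations, "E": events.to_numpy(), "above": above.astype(float)})
            try:
                cph = _fit_cox_df(df)
                row["hr"] = float(np.exp(cph.params_["above"]))
                row["p"] = float(cph.summary.loc["above", "p"])
                row["usable"] = True
            except FittingError as exc:
                logger.warning("cut-off %.3f: %s", c, exc)
        else:
            logger.warning("cut-off %.3f leaves an empty group (n_above=%d); skipped", c, n_above)
        rows.append(row)
    return CutoffScan(table=pd.DataFrame(rows), endpoint=endpoint)


def select_cutoff(scan: CutoffScan, rule: str = "min_p") -> float:
    """Pick the optimal cut-off from a scan.

    ``min_p`` (default): smallest p-value, ties broken by larger HR, then
    by smaller cut-off. ``max_hr``: largest HR, ties broken by smaller p,
    then smaller cut-off.
    """
    usable = scan.usable
    if usable.empty:
        raise FittingError("no usable candidate cut-off in the scan")
    if rule == "min_p":
        keys = usable.sort_values(["p", "hr", "cutoff"], ascending=[True, False, True])
    elif rule == "max_hr":
        keys = usable.sort_values(["hr", "p", "cutoff"], ascending=[False, True, True])
    else:
        raise ValidationError(f"unknown selection rule {rule!r}")
    return float(keys.iloc[0]["cutoff"])


@dataclass(frozen=True)
class CutoffDerivation:
    """Two-stage cut-off derivation output.

    ``medium_high`` is None when the second stage was infeasible (subset
    below the minimum size); ``scan2`` is then None as well.
    """

    low_medium: float
    medium_high: float | None
    scan1: CutoffScan
    scan2: CutoffScan | None

    @property
    def cutoffs(self):
        from .health_index import RiskCutoffs

        if self.medium_high is None:
            raise FittingError("second-stage cut-off unavailable; no Medium/High boundary")
        return RiskCutoffs(low_medium=self.low_medium, medium_high=self.medium_high)


def derive_risk_groups(
    cohort: pd.DataFrame,
    grid=None,
    endpoint: str = "all_cause",
    rule: str = "min_p",
    min_subjects: int = 20,
    min_events: int = 5,
    second_stage: str = "above_first",
) -> CutoffDerivation:
    """Derive both risk cut-offs by repeated grid search.

    Stage 1 scans the full cohort and selects the Low/Medium boundary.
    Stage 2 (default ``above_first``) re-scans only subjects at or above
    that boundary, over grid candidates strictly above it, for the
    Medium/High boundary; ``second_stage='full'`` scans the whole cohort
    over candidates above the first cut-off instead. If the second-stage
    subset has fewer than ``min_subjects`` subjects or ``min_events``
    events, the second cut-off is reported as unavailable.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    scan1 = scan_cutoffs(cohort, grid, endpoint)
    low_medium = select_cutoff(scan1, rule)

    if second_stage == "above_first":
        subset = cohort[cohort["hi"] >= low_medium]
    elif second_stage == "full":
        subset = cohort
    else:
        raise ValidationError(f"unknown second_stage mode {second_stage!r}")
    grid2 = grid[grid > low_medium]
    n_events = int(endpoint_events(subset, endpoint).sum()) if len(subset) else 0
    if len(subset) < min_subjects or n_events < min_events or grid2.size == 0:
        logger.warning(
            "second-stage scan infeasible (n=%d, events=%d, candidates=%d); "
            "Medium/High cut-off unavailable", len(subset), n_events, grid2.size,
        )
        return CutoffDerivation(low_medium=low_medium, medium_high=None, scan1=scan1, scan2=None)
    try:
        scan2 = scan_cutoffs(subset, grid2, endpoint)
        medium_high = select_cutoff(scan2, rule)
    except FittingError as exc:
        logger.warning("second-stage scan failed (%s); Medium/High cut-off unavailable", exc)
        return CutoffDerivation(low_medium=low_medium, medium_high=None, scan1=scan1, scan2=None)
    return CutoffDerivation(low_medium=low_medium, medium_high=medium_high, scan1=scan1, scan2=scan2)


def _design_matrix(cohort: pd.DataFrame, exposure: str, reference, adjusted: bool):
    """Dummy-coded design for fit_cox; returns (design df, exposure dummy columns)."""
    exp_col = cohort[exposure]
    if isinstance(exp_col.dtype, pd.CategoricalDtype):
        levels = [lv for lv in exp_col.cat.categories if lv in set(exp_col.dropna())]
    else:
        levels = sorted(exp_col.dropna().unique().tolist())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} absent from column {exposure!r}")
    parts = {}
    exposure_cols = []
    for lv in levels:
        if lv == reference:
            continue
        name = f"{exposure}[{lv}]"
        parts[name] = (exp_col == lv).astype(float)
        exposure_cols.append(name)
    if adjusted:
        for cov in ADJUSTMENT_COVARIATES:
            if cov not in cohort.columns:
                raise ValidationError(f"adjusted model requires covariate column {cov!r}")
            if cov in CATEGORICAL_COVARIATES:
                dummies = pd.get_dummies(cohort[cov].astype(str), prefix=cov, drop_first=True)
                for name in dummies.columns:
                    parts[name] = dummies[name].astype(float)
            else:
                parts[cov] = cohort[cov].astype(float)
    return pd.DataFrame(parts, index=cohort.index), exposure_cols, reference


def fit_cox(
    cohort: pd.DataFrame,
    exposure: str,
    adjusted: bool = False,
    endpoint: str = "all_cause",
    reference=None,
) -> pd.DataFrame:
    """Cox PH hazard ratios for a categorical exposure versus its reference level.

    Returns one row per non-reference level with columns
    ``level, n, hr, ci_low, ci_high, p`` (95% CIs). With ``adjusted`` the
    model also includes age, sex, education, BMI category, antihypertensive
    use, diabetes, number of cardiovascular conditions, smoking status and
    alcohol class. Censored subjects contribute follow-up time to the end
    of observation; under the cardio-respiratory endpoint, deaths from
    other causes are censored at death.
    """
    validate_cohort(cohort, require_hi=False)
    if exposure not in cohort.columns:
        raise ValidationError(f"exposure column {exposure!r} not in cohort table")
    events = endpoint_events(cohort, endpoint)
    if events.sum() == 0:
        raise FittingError(f"no events under endpoint {endpoint!r}")
    design, exposure_cols, reference = _design_matrix(cohort, exposure, reference, adjusted)
    if not exposure_cols:
        raise ValidationError(f"exposure {exposure!r} has a single level; nothing to compare")
    df = design.copy()
    df["T"] = cohort["followup_days"].astype(float)
    df["E"] = events
    try:
        cph = _fit_cox_df(df)
    except FittingError as exc:
        raise FittingError(
            f"Cox fit failed for exposure {exposure!r} (adjusted={adjusted}, "
            f"endpoint={endpoint}): {exc}"
        ) from exc
    summary = cph.summary
    rows = []
    for name in exposure_cols:
        level = name[name.index("[") + 1 : -1]
        rows.append({
            "level": level,
            "reference": reference,
            "n": int((design[name] == 1).sum()),
            "hr": float(np.exp(summary.loc[name, "coef"])),
            "ci_low": float(np.exp(summary.loc[name, "coef lower 95%"])),
            "ci_high": float(np.exp(summary.loc[name, "coef upper 95%"])),
            "p": float(summary.loc[name, "p"]),
        })
    return pd.DataFrame(rows)


def roc_auc(cohort: pd.DataFrame, score: str = "hi", endpoint: str = "all_cause") -> float:
    """AUC of a score for the binary died-by-end-of-follow-up label.

    Nonparametric (rank-based); equals the Mann–Whitney concordance
    probability with ties counted one-half. This is the fixed-horizon
    binary-label AUC, not a time-dependent survival AUC.
    """
    if score not in cohort.columns:
        raise ValidationError(f"score column {score!r} not in cohort table")
    labels = endpoint_events(cohort, endpoint).to_numpy()
    if labels.min() == labels.max():
        raise ValidationError(f"outcome has a single class under endpoint {endpoint!r}")
    values = cohort[score].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"score column {score!r} contains non-finite values")
    return float(roc_auc_score(labels, values))


def roc_points(cohort: pd.DataFrame, score: str = "hi", endpoint: str = "all_cause") -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for a score and endpoint."""
    from sklearn.metrics import roc_curve

    labels = endpoint_events(cohort, endpoint).to_numpy()
    if labels.min() == labels.max():
        raise ValidationError(f"outcome has a single class under endpoint {endpoint!r}")
    fpr, tpr, thr = roc_curve(labels, cohort[score].to_numpy(float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


BMI_CATEGORIES = ("underweight/normal", "overweight", "obese", "morbidly obese")


def bmi_category(bmi: float) -> str:
    """WHO-based BMI class over half-open intervals [<25, 25–30, 30–35, >=35)."""
    if not (bmi > 0 and np.isfinite(bmi)):
        raise ValidationError(f"BMI must be positive and finite, got {bmi}")
    if bmi < 25:
        return BMI_CATEGORIES[0]
    if bmi < 30:
        return BMI_CATEGORIES[1]
    if bmi < 35:
        return BMI_CATEGORIES[2]
    return BMI_CATEGORIES[3]


def categorize_bmi(weight_kg: float, height_m: float) -> str:
    """BMI class from weight (kg) and height (m): BMI = weight / height**2."""
    if not (weight_kg > 0 and height_m > 0):
        raise ValidationError("weight and height must be positive")
    return bmi_category(weight_kg / height_m**2)
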