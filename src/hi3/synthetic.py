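"""Synthetic cohort generator for end-to-end testing of the health index pipeline.

The generator emulates the statistical structure the method consumes, not
the physiology behind it:

* **Beat-to-beat sBP** — baseline + slow sinusoidal oscillation +
  autocorrelated (AR(1)) Gaussian noise. The noise-to-oscillation ratio is
  the irregularity knob: larger noise SD yields stochastically larger
  sample entropy, which is the only property of the signal the index uses.
* **SART sessions** — 207 trials; each GO trial is omitted with a
  per-subject lapse probability, each NO-GO trial is (incorrectly)
  responded to with a commission probability; reaction times are Gaussian
  with a floor.
* **Gait** — two walks per subject around a latent usual speed.
* **Survival** — event times from an exponential proportional-hazards
  model whose log-hazard is linear in the subject's health index (the one
  computed from the simulated measurements through the package's own
  component pipeline), with optional planted step terms and an age effect;
  administrative censoring at the follow-up horizon (12 years by default,
  matching a long prospective ageing cohort). Cause of death is a logistic
  mixture in the index so cardio-respiratory deaths are enriched at high
  index values.

A per-subject latent health deficit u in (0, 1), mildly age-driven, couples
the three measurement domains so that the composed index is a meaningful
risk score. All randomness flows from a single integer seed; identical
parameters and seed give byte-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from . import entropy, gait, sart
from .entropy import BeatSeries, EntropyParams
from .errors import UndefinedEntropyError, ValidationError
from .gait import GaitRecord
from .health_index import compute_hi, fit_reference_ranges
from .sart import SartSession
from .stratify import categorize_bmi


@dataclass(frozen=True)
class BpModel:
    """Beat-to-beat sBP simulator: baseline + sinusoid + AR(1) noise."""

    n_beats: int = 330
    baseline_mean_mmhg: float = 130.0
    baseline_sd_mmhg: float = 12.0
    osc_amplitude_mmhg: float = 4.0
    osc_period_beats: float = 10.0
    ar_coef: float = 0.6
    noise_sd_range_mmhg: tuple = (0.5, 6.0)
    beat_interval_mean_s: float = 0.95
    beat_interval_sd_s: float = 0.05


@dataclass(frozen=True)
class SartModel:
    """SART simulator: per-trial lapse probabilities and GO RT distribution."""

    p_omit_range: tuple = (0.005, 0.30)
    p_commit_range: tuple = (0.30, 0.90)
    go_rt_mean_ms: float = 380.0
    go_rt_sd_ms: float = 80.0
    rt_floor_ms: float = 100.0


@dataclass(frozen=True)
class GaitModel:
    """Gait simulator: usual speed declining with the latent deficit, two noisy walks."""

    best_speed_cms: float = 150.0
    decline_cms: float = 75.0
    between_subject_sd_cms: float = 8.0
    walk_noise_sd_cms: float = 6.0
    min_speed_cms: float = 30.0


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential proportional-hazards outcome model driven by the health index.

    ``baseline_hazard_per_year`` is the hazard at index 0; the default,
    combined with the default index coupling (the composed index has mean
    near 0.5 after min–max normalization), gives roughly 10–15% 12-year
    all-cause mortality, the rate typical of community-dwelling cohorts
    aged 50+;
    ``hi_loghr`` is the log-hazard slope per unit index. ``step_cutoffs`` /
    ``step_loghrs`` plant additional log-hazard jumps at index thresholds
    for cut-off-recovery experiments. Cause mixing: the probability that a
    death is cardio-respiratory is expit(cr_intercept + cr_slope * hi).
    """

    baseline_hazard_per_year: float = 0.002
    hi_loghr: float = 3.0
    step_cutoffs: tuple = ()
    step_loghrs: tuple = ()
    age_loghr_per_year: float = 0.05
    age_center_years: float = 62.0
    horizon_years: float = 12.0
    loss_to_followup_per_year: float = 0.0
    cr_intercept: float = -1.5
    cr_slope: float = 2.5
    cardio_frac_of_cr: float = 0.75
    cancer_frac_of_noncr: float = 0.6


@dataclass(frozen=True)
class CohortSimParams:
    """All knobs of the cohort simulator; one seed drives every draw."""

    n_subjects: int = 500
    seed: int = 0
    bp: BpModel = field(default_factory=BpModel)
    sart: SartModel = field(default_factory=SartModel)
    gait: GaitModel = field(default_factory=GaitModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    entropy_params: EntropyParams = field(default_factory=EntropyParams)
    resting_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.survival.horizon_years <= 0:
            raise ValidationError("follow-up horizon must be positive")


def _lerp(bounds, u):
    lo, hi = bounds
    return lo + (hi - lo) * np.asarray(u)


def simulate_bp_series(
    params: BpModel,
    rng: np.random.Generator,
    noise_sd_mmhg: float | None = None,
    baseline_mmhg: float | None = None,
    subject_id: str = "",
) -> BeatSeries:
    """One subject's time-stamped beat series; at least 60 beats."""
    n = params.n_beats
    if n < 60:
        raise ValidationError("need at least 60 beats per series")
    if noise_sd_mmhg is None:
        noise_sd_mmhg = float(np.mean(params.noise_sd_range_mmhg))
    if baseline_mmhg is None:
        baseline_mmhg = params.baseline_mean_mmhg
    intervals = np.clip(
        rng.normal(params.beat_interval_mean_s, params.beat_interval_sd_s, n), 0.3, None
    )
    times = np.cumsum(intervals)
    osc = params.osc_amplitude_mmhg * np.sin(2 * np.pi * np.arange(n) / params.osc_period_beats)
    burn = 50
    innov = rng.normal(0.0, 1.0, n + burn)
    phi = params.ar_coef
    noise = lfilter([1.0], [1.0, -phi], innov)[burn:]
    noise *= noise_sd_mmhg * np.sqrt(1.0 - phi**2)
    values = np.clip(baseline_mmhg + osc + noise, 20.0, None)
    return BeatSeries(values, times, subject_id=subject_id)


def simulate_sart_session(
    params: SartModel,
    rng: np.random.Generator,
    p_omit: float = 0.05,
    p_commit: float = 0.5,
    subject_id: str = "",
) -> SartSession:
    """One complete 207-trial SART session with the given lapse probabilities."""
    if not (0.0 <= p_omit <= 1.0 and 0.0 <= p_commit <= 1.0):
        raise ValidationError("lapse probabilities must lie in [0, 1]")
    digits = sart.CANONICAL_DIGITS.copy()
    u = rng.random(sart.N_TRIALS)
    rts = np.maximum(params.rt_floor_ms,
                     rng.normal(params.go_rt_mean_ms, params.go_rt_sd_ms, sart.N_TRIALS))
    go = digits != sart.NOGO_DIGIT
    responded = np.where(go, u >= p_omit, u < p_commit)
    rt_ms = np.where(responded, rts, 0.0)
    return SartSession(digits, rt_ms, subject_id=subject_id)


def simulate_gait_record(
    params: GaitModel,
    rng: np.random.Generator,
    deficit: float = 0.3,
    subject_id: str = "",
) -> GaitRecord:
    """Two walks around a latent usual speed declining with the health deficit."""
    mean_speed = (
        params.best_speed_cms
        - params.decline_cms * deficit
        + rng.normal(0.0, params.between_subject_sd_cms)
    )
    walks = np.clip(
        mean_speed + rng.normal(0.0, params.walk_noise_sd_cms, 2),
        params.min_speed_cms, None,
    )
    return GaitRecord(tuple(walks), subject_id=subject_id)


def simulate_survival(
    true_hi,
    params: SurvivalModel,
    rng: np.random.Generator,
    age_years=None,
) -> pd.DataFrame:
    """Survival outcomes for an index vector under the proportional-hazards model.

    Returns a frame with ``followup_days, event, cause``; subjects alive at
    the horizon are censored there (cause 'none'), as are any random
    losses to follow-up when that rate is non-zero.
    """
    hi = np.asarray(true_hi, dtype=float)
    if not np.all(np.isfinite(hi)):
        raise ValidationError("true_hi must be finite")
    log_hazard = np.log(params.baseline_hazard_per_year) + params.hi_loghr * hi
    for c, b in zip(params.step_cutoffs, params.step_loghrs):
        log_hazard = log_hazard + b * (hi >= c)
    if age_years is not None and params.age_loghr_per_year != 0.0:
        log_hazard = log_hazard + params.age_loghr_per_year * (
            np.asarray(age_years, float) - params.age_center_years
        )
    rate = np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    if params.loss_to_followup_per_year > 0:
        t_lost = rng.exponential(1.0 / params.loss_to_followup_per_year, hi.size)
    else:
        t_lost = np.full(hi.size, np.inf)
    t_censor = np.minimum(t_lost, params.horizon_years)
    event = (t_event <= t_censor).astype(int)
    followup_years = np.minimum(t_event, t_censor)

    u_cr, u_cardio, u_cancer = rng.random((3, hi.size))
    p_cr = expit(params.cr_intercept + params.cr_slope * hi)
    cause = np.where(
        u_cr < p_cr,
        np.where(u_cardio < params.cardio_frac_of_cr, "cardiovascular", "respiratory"),
        np.where(u_cancer < params.cancer_frac_of_noncr, "cancer", "other"),
    )
    cause = np.where(event == 1, cause, "none")
    return pd.DataFrame({
        "followup_days": np.maximum(followup_years * 365.25, 0.5),
        "event": event,
        "cause": cause,
    })


@dataclass(frozen=True)
class SimulatedCohort:
    """In-memory simulated cohort: raw measurements plus the assembled cohort table."""

    params: CohortSimParams
    bp_series: dict
    sart_sessions: dict
    gait_records: dict
    cohort: pd.DataFrame  # per-subject components, hi, survival, covariates


def _simulate_covariates(rng: np.random.Generator, age: np.ndarray, u: np.ndarray) -> pd.DataFrame:
    n = age.size
    sex = np.where(rng.random(n) < 0.54, "female", "male")
    education = rng.choice(["primary", "secondary", "tertiary"], size=n, p=[0.30, 0.45, 0.25])
    height = np.where(sex == "female", rng.normal(1.62, 0.06, n), rng.normal(1.76, 0.07, n))
    weight = np.clip(rng.normal(75.0, 13.0, n), 40.0, None)
    bmi_cat = [categorize_bmi(w, h) for w, h in zip(weight, height)]
    antihtn = (rng.random(n) < 0.15 + 0.40 * u).astype(int)
    diabetes = (rng.random(n) < 0.04 + 0.12 * u).astype(int)
    n_cvd = np.minimum(rng.poisson(0.2 + 1.8 * u), 6)
    smoking = rng.choice(["never", "past", "current"], size=n, p=[0.50, 0.35, 0.15])
    alcohol = rng.choice(["cage_0", "cage_1_2", "cage_3plus"], size=n, p=[0.70, 0.22, 0.08])
    frailty_index = np.clip(0.04 + 0.25 * u + rng.normal(0.0, 0.05, n), 0.0, 0.7)
    return pd.DataFrame({
        "age": age, "sex": sex, "education": education, "bmi_cat": bmi_cat,
        "antihtn": antihtn, "diabetes": diabetes, "n_cvd": n_cvd,
        "smoking": smoking, "alcohol": alcohol, "frailty_index": frailty_index,
    })


def simulate_cohort(params: CohortSimParams) -> SimulatedCohort:
    """Simulate a full cohort and assemble its analysis table.

    Measurements are generated per subject, the three components are then
    computed through the package's own entropy/SART/gait operations,
    reference ranges are fit on the simulated cohort, the index is
    composed, and survival is drawn with the hazard driven by that index.
    Subjects whose entropy is undefined are excluded from the table (as
    they would be from a real analysis) but their raw files are kept.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    ids = [f"S{i:05d}" for i in range(1, n + 1)]

    age = np.clip(rng.normal(62.0, 8.0, n), 50.0, 90.0)
    u = np.clip(0.05 + 0.011 * (age - 50.0) + rng.normal(0.0, 0.13, n), 0.01, 0.99)

    noise_sd = _lerp(params.bp.noise_sd_range_mmhg, u)
    baselines = rng.normal(params.bp.baseline_mean_mmhg, params.bp.baseline_sd_mmhg, n)
    p_omit = _lerp(params.sart.p_omit_range, u)
    p_commit = _lerp(params.sart.p_commit_range, u)

    bp_series: dict = {}
    sessions: dict = {}
    gaits: dict = {}
    rows = []
    for i, sid in enumerate(ids):
        series = simulate_bp_series(params.bp, rng, noise_sd[i], baselines[i], sid)
        session = simulate_sart_session(params.sart, rng, p_omit[i], p_commit[i], sid)
        record = simulate_gait_record(params.gait, rng, u[i], sid)
        bp_series[sid] = series
        sessions[sid] = session
        gaits[sid] = record
        try:
            sampen = entropy.resting_sampen(
                series, params.entropy_params, params.resting_window_s
            )
        except UndefinedEntropyError:
            sampen = np.nan
        rows.append({
            "subject_id": sid,
            "sampen": sampen,
            "nbp": sart.count_nbp(session),
            "ugs": record.ugs,
        })
    components = pd.DataFrame(rows)
    covariates = _simulate_covariates(rng, age, u)

    complete = components.dropna(subset=["sampen"]).reset_index(drop=True)
    ranges = fit_reference_ranges(complete)
    keep = components["sampen"].notna().to_numpy()
    hi = np.array([
        compute_hi(r.sampen, r.nbp, r.ugs, ranges).hi for r in complete.itertuples()
    ])
    surv = simulate_survival(hi, params.survival, rng, age_years=age[keep])

    cohort = pd.concat(
        [
            complete,
            pd.Series(hi, name="hi"),
            surv.reset_index(drop=True),
            covariates.loc[keep].reset_index(drop=True),
        ],
        axis=1,
    )
    return SimulatedCohort(
        params=params, bp_series=bp_series, sart_sessions=sessions,
        gait_records=gaits, cohort=cohort,
    )


# ---------------------------------------------------------------------------
# On-disk cohort: one BP and one SART CSV per subject, gait + cohort tables,
# and a manifest with parameter values and content hashes.
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_cohort(params: CohortSimParams, out_dir) -> dict:
    """Write a simulated cohort to ``out_dir`` and return its manifest.

    Layout: ``bp/<subject_id>.csv``, ``sart/<subject_id>.csv``,
    ``gait.csv``, ``cohort.csv``, ``manifest.json``. Existing cohort files
    in the target directory are an error (no silent overwrite).
    """
    out_dir = Path(out_dir)
    if (out_dir / "cohort.csv").exists() or (out_dir / "manifest.json").exists():
        raise ValidationError(f"output collision: {out_dir} already holds a cohort")
    sim = simulate_cohort(params)
    (out_dir / "bp").mkdir(parents=True, exist_ok=True)
    (out_dir / "sart").mkdir(parents=True, exist_ok=True)

    files = []
    for sid, series in sim.bp_series.items():
        path = out_dir / "bp" / f"{sid}.csv"
        entropy.write_beat_csv(series, path)
        files.append(path)
    for sid, session in sim.sart_sessions.items():
        path = out_dir / "sart" / f"{sid}.csv"
        sart.session_to_frame(session).to_csv(path, index=False)
        files.append(path)

    gait_df = pd.DataFrame({
        "subject_id": list(sim.gait_records),
        "walk1_cms": [r.walk_speeds[0] for r in sim.gait_records.values()],
        "walk2_cms": [r.walk_speeds[1] if len(r.walk_speeds) > 1 else np.nan
                      for r in sim.gait_records.values()],
    })
    gait_path = out_dir / "gait.csv"
    gait_df.to_csv(gait_path, index=False)
    files.append(gait_path)

    cohort_path = out_dir / "cohort.csv"
    sim.cohort.to_csv(cohort_path, index=False)
    files.append(cohort_path)

    manifest = {
        "params": asdict(params),
        "seed": params.seed,
        "n_subjects": params.n_subjects,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
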