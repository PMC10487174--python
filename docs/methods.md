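# Methods

## The index

The package computes a 3-item health index (HI) for older adults from three
objective measurements, each separately predictive of mortality:

1. **Sample entropy of resting systolic blood pressure (SampEn).**
   Beat-to-beat sBP is recorded supine; the final 60 s of rest is the
   analysis window (the most stationary stretch after stabilization). For a
   window x of length N, B^m(r) is the average fraction of length-m
   template pairs within Chebyshev distance r·SD (self-matches excluded,
   counts divided by N−m−1, templates taken at the first N−m positions for
   both lengths), A^m(r) the same for length m+1, and

       SampEn(m, r, N) = −ln(A^m(r) / B^m(r)).

   Defaults m = 1, r = 0.4, following the (m, r) pair optimized for
   mortality prediction from 1-minute resting sBP. Higher SampEn = more
   irregular signal = worse.

2. **SART number of bad performances (NBP).** The Sustained Attention to
   Response Task presents 23 cycles of the digits 1..9 (207 trials);
   participants respond to every digit except 3. A cycle with ≥ 2 mistakes
   (commission: response on 3; omission: no response on a GO digit) is one
   bad performance; NBP ∈ [0, 23]. Higher = worse.

3. **Usual gait speed (UGS).** Mean steady-state speed (cm/s) over two
   walks at self-selected pace. Lower = worse.

Each component is min–max normalized to the full range observed in a
reference cohort, the gait component is inverted (1 − scaled), and the HI
is the unweighted mean of the three normalized components, on [0, 1] with
1 = worst. The exact normalization used by the original instrument is not
public; min–max to the observed range with direction inversion is the
simplest scheme consistent with a [0, 1] composite and is isolated in
`normalize_component`, so an alternative formula is a one-point change.
Out-of-range values in new subjects clamp to [0, 1] with a warning rather
than extrapolate. Subjects missing any component are excluded (and
itemized), never imputed.

## Numerical conventions

- Tolerance comparison is a closed ball (≤ r·SD), so a constant series
  (SD = 0) still matches itself and yields SampEn = 0.
- SD is the population SD (divisor N) of the analysed window; sample SD is
  available via `EntropyParams.sd_ddof=1`.
- Zero matches at either template length raise `UndefinedEntropyError`
  instead of returning an arbitrary number; callers decide exclusion.
- Resting-window selection is closed on the left (beats with onset time
  ≥ t_max − 60 s), so a series spanning exactly the window is returned
  unchanged. Without timestamps, the last `round(60 × beat_rate)` beats are
  used (default rate 1 beat/s, configurable).
- A SART "response" is any rt > 0; no anticipation cut-off is applied by
  default (a configurable minimum-RT filter exists, default off).
- Risk-group boundaries are half-open with the cut-off value in the worse
  group: hi = 0.45 → Medium, hi = 0.65 → High.
- Cox models use lifelines (Efron tie handling). A fit that does not
  converge — including lifelines' low-variance/separation warnings, which
  are escalated to errors — marks a scan candidate unusable (kept in the
  table with NaN statistics) or raises `FittingError` with context.

## Cut-off derivation

Candidate thresholds run from 0.2 to 0.65 in steps of 0.025 (19 values).
At each candidate c a univariate Cox model is fit on the indicator
hi ≥ c for all-cause mortality. "Maximal HR and minimal p" is not a total
order, so the implemented rule is: smallest p, ties broken by larger HR,
then by smaller cut-off (`max_hr` rule available; the full scan table is
always emitted so users can apply other rules). The search runs twice:
stage 1 on the full cohort gives the Low/Medium boundary; stage 2, by
default restricted to subjects at or above it and to candidates strictly
above it, gives the Medium/High boundary (`second_stage="full"` scans the
whole cohort instead). A second-stage subset below 20 subjects or 5 events
reports the second cut-off as unavailable rather than fitting noise.

## Evaluation

Hazard ratios with 95% CIs are reported per exposure level against a
reference (Low-Risk), unadjusted and adjusted for age, sex, education, BMI
category (WHO half-open classes: <25, 25–30, 30–35, ≥35), antihypertensive
use, diabetes, number of cardiovascular conditions, smoking and alcohol
class. Endpoints: all-cause, and combined cardio-respiratory with
other-cause deaths censored at death (cause-specific hazards; no
Fine–Gray subdistribution model). Subjects without events are
right-censored at end of follow-up. AUC is the rank-based (Mann–Whitney,
ties = ½) AUC of a score for the *binary* died-by-end-of-follow-up label —
a fixed-horizon binary AUC, not a time-dependent survival AUC; the
continuous index is the default score, with group codes usable as an
ordinal score.

## Synthetic cohorts

Real reference data are not redistributable, so a generator emulates the
statistical structure each stage consumes:

- **sBP**: baseline (N(130, 12) mmHg between subjects) + sinusoid
  (amplitude 4 mmHg, period 10 beats ≈ a 0.1 Hz Mayer-type slow wave at
  ~1 beat/s) + AR(1) noise (φ = 0.6) with per-subject stationary SD
  between 0.5 and 6 mmHg. The noise-to-oscillation ratio is the only
  property the index consumes; no claim of hemodynamic realism. Note that
  at m = 1 a noise-free sinusoid retains SampEn ≈ 0.79 — a single sample
  cannot distinguish the rising from the falling branch — while at m = 2
  it is exactly 0; the generator's monotone coupling (more noise → higher
  SampEn) is what downstream stages rely on.
- **SART**: per-GO-trial omission probability 0.005–0.30 and per-NO-GO
  commission probability 0.30–0.90 across subjects (commission errors are
  common even in attentive adults); GO RTs ~ N(380, 80) ms floored at
  100 ms. The per-cycle bad-performance probability has a closed binomial
  form used as the oracle for the mean NBP.
- **Gait**: usual speed 150 − 75·u cm/s plus between-subject (SD 8) and
  per-walk (SD 6) noise.
- **Survival**: exponential proportional hazards with log-hazard linear in
  the HI composed from the simulated measurements through the package's own
  component pipeline (slope 3 per unit index), plus an age effect
  (0.05/year) and optional planted step terms; administrative censoring at
  the 12-year horizon (random loss to follow-up available, default off).
  The default baseline hazard (0.002/yr) yields roughly 10–15% 12-year
  all-cause mortality, typical of community-dwelling cohorts aged 50+.
  Cause of death is a logistic mixture in the index
  (P(cardio-respiratory) = expit(−1.5 + 2.5·hi), cardio:respiratory
  75:25, cancer:other 60:40 among the rest), the simplest mechanism that
  enriches cardio-respiratory deaths at high index values.

A latent health deficit u ∈ (0, 1) per subject, mildly age-driven
(u = 0.05 + 0.011·(age − 50) + N(0, 0.13), clipped), couples the three
measurement domains. All draws flow from one `numpy` Generator seeded by a
single integer; identical parameters and seed give byte-identical files
(hashes recorded in the cohort manifest).

What the generator does **not** emulate: waveform-level hemodynamics,
measurement artifacts, informative censoring, missing-not-at-random
patterns, or cohort-matched marginal distributions. Passing tests
therefore demonstrate that the pipeline computes its definitions correctly
and recovers planted statistical structure — not that the index is valid
in any particular real population.

## Experiment sizes in the test suite

Planted-structure experiments use the sizes at which the recovery
properties are claimed: cut-off recovery uses 50 replicates of n = 2000
with a right-skewed index distribution, Beta(3.75, 8.25), matching a
realistic cohort's risk-group mix (~15% above 0.45, ~0.8% above 0.65,
median ≈ 0.34) and a baseline hazard (0.0066/yr) giving ~10% 12-year
mortality around a 3-fold step at 0.45. The skew matters: with a
symmetric index distribution the single most significant binary split of a
two-step hazard is the *outer* step, so the staged search would correctly
target 0.65 first and the recovery experiment would not probe the planted
0.45 boundary at all. Cox parameter recovery uses 50 replicates of
n = 2000 with a planted group log-HR of log 3; the two-step derivation
check uses n = 4000.

## Known limitations

- The normalization constants of the original instrument are not
  reproduced; indices computed here are comparable only against ranges fit
  on (or configured for) a user-supplied reference cohort.
- The cut-off search optimizes a Wald p-value over a fixed grid; adjacent
  candidates are highly correlated and localization is inherently noisy at
  typical event counts (~200), so single-replicate selections can land one
  or two grid steps from a planted boundary.
- Competitor frailty instruments are accepted only as pre-computed columns;
  their construction from raw items is out of scope.
- No parametric survival models, no time-dependent AUC, no Fine–Gray
  competing-risk model.
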