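# Methods

This note documents the models, conventions and design choices behind
`orthohrv`, in the spirit of a statistical software methods appendix.

## Orthostatic deltas

All deltas are *supine minus standing*: ΔR̄R = R̄R(sup) − R̄R(sta),
ΔRMSSD = RMSSD(sup) − RMSSD(sta), ΔLnRMSSD analogous.  With this sign a
normal stand-up response (RR shortening through vagal withdrawal) gives
positive values, and a *low* delta marks a blunted autonomic response,
i.e. poor recovery.  Literature descriptions sometimes phrase the same
quantity as a "standing–supine difference"; the supine-minus-standing
convention is used consistently here because it keeps the healthy
response positive.

## Session quality control

Raw RR exports are text files, one interval in ms per line.  Artifact
correction mimics the behaviour (not the proprietary algorithm) of the
common desktop HRV tools: a beat is corrected when it deviates from the
median of its 11 nearest *accepted* neighbours by more than a threshold
(default 450 ms, a deliberately conservative "very low" level; tighter
thresholds are a parameter everywhere).  Corrected beats are replaced by
monotone piecewise-cubic (PCHIP) interpolation over accepted beats, so
the beat count is preserved — correction, not deletion — and the window
arithmetic stays simple.  The correction is idempotent: a second pass
flags nothing.  A session in which either posture needed ≥ 5% of beats
corrected is flagged `rejected` and retained (cohort tables stay
rectangular); all downstream statistics skip rejected rows.

The analysis window is the minimal *suffix* of beats spanning at least
300 s (it may slightly exceed 300 s; partial-beat handling at the window
boundary is otherwise arbitrary, so the beat-complete rule is documented
and deterministic).  Interval values are never resampled at this stage.

## HRV indices

Time domain: mean RR (ms), mean HR = 60000/meanRR, RMSSD =
√(mean of squared successive differences), LnRMSSD = ln RMSSD.  A zero
RMSSD yields LnRMSSD = NaN (flagged missing, never −∞).

Frequency domain: the tachogram (interval vs cumulative beat time) is
cubic-spline resampled at 4 Hz, and band powers come from a Welch
periodogram with 150-s Hann segments at 50% overlap and per-segment
linear detrending.  These four settings emulate common desktop-software
defaults and are all configuration keys.  LF is integrated over
[0.04, 0.15) Hz and HF over [0.15, 0.40] Hz — half-open/closed-top so no
bin is double counted.  Normalized units use HFnu = HF/(LF+HF); VLF is
computed but excluded from the denominator.  When LF+HF falls below a
numerical floor (10⁻¹⁰ ms², e.g. a constant series) the normalized units
and LF/HF are undefined (NaN).  For a pure sinusoid of amplitude A the
in-band power recovers A²/2 within ~15% (windowing and spectral-leakage
losses), which the tests assert.

## Workload

Edwards TRIMP weights minutes in the five HR zones (50–60 … 90–100% of
individual HRmax) by the zone index 1–5.  Conventions the method leaves
open, fixed here: time below 50% HRmax carries no load (a weight-0
zone), supra-maximal samples clip into zone 5, and duration is
attributed sample-and-hold (each sample owns the interval to the next
timestamp; the last sample owns the median sampling interval).  TRIMP is
therefore additive under trace concatenation and monotone in any single
sample's HR.  RPE (Borg CR-10, 0–10, one decimal) is carried through
as an input.

## Well-being

WB is the plain sum of four 1–7 items (perceived fatigue, sleep quality,
DOMS, stress), range 4–28; ΔWB(t) = WB(t) − WB(t−1) is defined only for
consecutive days.  Items are stored exactly as entered; orientation is
never reversed silently.  (Questionnaire instructions of the 1 = poor /
7 = very good type conflict with treating "perceived fatigue" as
increasing in tiredness; both orientations are representable, and the
synthetic generator's choice is documented below.)

## Correlations and Williams' test

Correlations are Pearson on pooled athlete-day rows by default
(pairwise-complete deletion, rejected sessions excluded), with exact
t-transform p-values; a stage-mean aggregation mode is provided for
analyses of day-level quantities such as stage distance.  No
multiple-testing correction is applied to the correlation grid by
default; a Benjamini–Hochberg helper exists but is opt-in.

Two dependent correlations sharing a variable (e.g. r(fatigue, ΔR̄R) vs
r(fatigue, ΔLnRMSSD)) are compared with Williams' test in the Steiger
(1980) t2 formulation, df = n−3; a correlation triple whose 3×3 matrix
has non-positive determinant is rejected as inconsistent.  Its type-I
error under a simulated trivariate-normal null is verified to sit in
[0.035, 0.065] at α = 0.05.

## Model selection

`fit_ols` is ordinary least squares (QR/least-squares via numpy) with an
always-included intercept, unbiased residual variance, two-sided t
p-values, R² and adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).  It is
cross-checked against `statsmodels.OLS` in the test suite.  Mixed or
random-effects extensions are deliberately out of scope: the target
analysis reports a single pooled coefficient set, so pooled OLS is the
primary method.

The AIC convention is the full Gaussian likelihood with the variance
profiled out and counted as a parameter:

    AIC = n·ln(2π·RSS/n) + n + 2(p+1).

Only *rankings* are meaningful, and any constant shift in the convention
cancels in them (this equals the statsmodels value plus exactly 2).  AIC
is undefined at RSS = 0 (a saturated fit must not win by default).

`best_subset_search` enumerates all 2^m subsets of the m candidate
predictors (the empty subset is the intercept-only model; 8 candidates →
256 fits), dropping rows listwise per model over that model's own
columns, and sorts by AIC with deterministic tie-breaking (fewer
predictors first, then lexicographic subset).  Candidates constant
across usable rows are excluded with a warning; subsets that are
rank-deficient on the given rows (possible in very small cohorts, where
athlete-level covariates span fewer dimensions than athletes) are
skipped with a warning.

The published equations (the best ΔR̄R model, the best ΔLnRMSSD model,
and the coach-friendly WB-based model) ship as an immutable JSON fixture
with their printed coefficients; `predict` evaluates them on named
covariates and `flag_recovery` applies the decision rule *imbalance iff
measured < predicted − margin* (margin default 0; a multiple of the
model's residual SD is a sensible field choice).

## Synthetic cohort generator

The generator's defaults emulate the motivating study setting: 10
athletes; profiles drawn from truncated normals at V̇O₂max 53.6 ± 5.2
ml·min⁻¹·kg⁻¹, HRmax 185.7 ± 7.2 bpm, weekly training volume
187.5 ± 51.5 km·week⁻¹; a calendar of 4 baseline days, 21 stages with
rest days after stages 9 and 15 (positions configurable — the historical
placement is not documented precisely), and 1 post-event day; stage
distances ~N(200, 40²) km truncated at 50 km.  (A 200-km average over 21
stages is not exactly consistent with a 3,540-km total; the mean is the
configurable knob and no reconciliation is attempted.)

Choices the source material leaves open, made once and fixed:

- **Fatigue process.** No fatigue dynamic is specified anywhere, so a
  transparent first-order linear recurrence is used:
  F_t = ρ·F_{t−1} + κ·TRIMP_t, F₀ = 0 (defaults ρ = 0.6, κ = 0.005
  per TRIMP point), giving geometric decay on rest days and a
  closed-form steady state κc/(1−ρ) for checking.  When
  `training_attenuates_fatigue` is on (default), κ is scaled inversely
  with the athlete's weekly training volume, which reproduces the
  observed pattern that better-trained athletes lose less well-being
  per stage.
- **Item orientation.** The generated perceived-fatigue item *rises*
  with latent fatigue (matching how regressions treat it), while sleep
  quality, DOMS and stress items are well-being-oriented and fall as
  fatigue accumulates; all four are equal-width bins of the standardized
  latent state plus ordinal noise, clipped to 1–7.  Net effect: WB
  drifts down along the event.
- **Observable generation.** Morning measurements on day t use the
  latent state after day t−1.  RPE exists on stage days only (monotone
  in stage distance plus noise, clipped to 0–10); where the generative
  ΔR̄R equation needs an RPE on a non-stage day it uses 0 (no recent
  exertion).  ΔR̄R is the configured linear predictor (defaults: the
  published best equation's coefficients) plus N(0, noise_sd²) with
  noise_sd = 30 ms — chosen as a realistic day-to-day orthostatic
  variability scale; the supine mean-RR target is the standing target
  plus the generated delta, so the construction is self-consistent.
- **Tachograms.** Two fixed-frequency sinusoids (0.25 Hz in the HF band,
  0.10 Hz in the LF band) plus white noise on nominal beat times,
  linearly rescaled so realized mean RR and RMSSD hit their targets
  *exactly*; band powers are then analytically checkable.  This is a
  deliberate idealization — no respiratory coupling dynamics, no
  autoregressive structure, no circadian drift — so passing tests show
  pipeline correctness, not physiological realism.
- **Ectopic injection.** ⌊fraction·n⌋ beats are modified in
  short/compensating-long pairs (premature beat at 60% of the local
  mean, the next interval absorbing the difference), preserving total
  recording time.
- **Determinism.** All randomness flows from one master seed through
  named substreams (athletes, calendar, workload, observables, one per
  tachogram), so identical configurations give byte-identical outputs
  and any piece can be regenerated independently.

## Problem sizes used in the checks

The automated checks run at sizes chosen to make the statistical
assertions sharp while staying desk-scale: coefficient-recovery and
enumeration checks use ~2,000 stage rows (96 synthetic athletes);
support-selection uses 50 replicates of that size; correlation-sign
stability uses 100 study-scale replicates (10 athletes); test
calibrations use 10,000 simulated nulls at n = 30–50; the RMSSD oracle
uses 1,000 random series.

## Known limitations

- AIC-based all-subset selection is not consistent: adding a single
  irrelevant predictor lowers AIC with asymptotic probability
  P(χ²₁ > 2) ≈ 0.157, independent of sample size and noise scale.  With
  three irrelevant candidates the probability of selecting *exactly* the
  generating support is therefore bounded near 0.843³ ≈ 0.60, and the
  measured rate in the replicate experiment sits there (~0.6).  The
  selected model is almost always a superset of the true support; users
  who need sparsistency should rank by BIC-style penalties instead.
- Pooled OLS ignores within-athlete correlation, so p-values on
  athlete-level covariates are anti-conservative relative to a
  mixed-model analysis; rankings are less affected.
- The artifact detector is a local-median rule, not a reimplementation
  of any proprietary correction; its default 450-ms threshold is
  conservative and will not catch premature beats on a normal baseline
  (deviation ≈ 0.4·mean RR) — choose the threshold to match the artifact
  scale of the data.
- Spectral indices inherit the usual caveats of short-window Welch
  estimates and of uncontrolled breathing frequency.
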