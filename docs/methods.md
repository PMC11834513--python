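# Methods

This note documents the models, algorithms and numerical choices behind
`icpmorph`, in the order data flows through the package.

## The signal model

ICP is treated as a uniformly sampled pressure series in mm Hg at
`fs ≥ 100 Hz` (lower rates are accepted only with an explicit override,
because the systolic upstroke and sub-peak structure alias below that).
Time is elapsed seconds from the first sample; absolute timestamps never
enter any computation. On disk, recordings are plain CSV
(`time_s,icp_mmhg[,valid]`) for fixtures and worked examples, or HDF5
(`/patients/<id>/icp` with `fs`/`t0` attributes) for long recordings.
CSV sampling must be uniform to one part in 10⁴; the rate is inferred
from the median time step.

## Synthetic pulses and cohorts

### Single pulse

One cardiac cycle is rendered on the unit interval x ∈ [0, 1) as

    h(x) = Σₖ aₖ · exp(−(x − λₖ)² / 2w²) · exp(−d·x)  −  ramp(x)  +  m·sin(πx)

with sub-peak amplitudes aₖ and latencies λₖ (defaults 0.15, 0.40, 0.65
of the cycle for P1, P2, P3), common width w = 0.08, taper d = 0.3, and
a half-sine "mound" of amplitude m = 0.35. The linear ramp pins both
cycle endpoints to zero; the result is min–max rescaled so the rendered
pulse has an exact peak-to-peak pressure (`scale`) on a `baseline`.

The mound term deserves a comment: without it the late diastole of a
pure sum-of-Gaussians pulse is flat to within sensor noise, and no
minimum-seeking detector can localize the pulse foot to ±20 ms. Real ICP
(like arterial) pulses decay visibly through diastole into a sharp foot;
the half-sine gives exactly that falling runoff while leaving the cycle
endpoints near baseline. Its amplitude was chosen together with the
class presets so that all four class archetypes classify correctly by
construction and the foot slope is resolvable; it is configurable per
shape.

Class-conditional presets (relative amplitudes a₁,a₂,a₃): class 1 =
(1.0, 0.6, 0.4), class 2 = (0.8, 1.0, 0.5), class 3 = (0.7, 1.0, 0.9),
class 4 = a single broad bump (0, 1, 0) with w = 0.18. These satisfy
the verbal class definitions by construction and are presets for
testing, not claims about real ICP morphology.

### Recording and cohort

A recording concatenates beats with per-beat cycle length from a normal
heart-rate model (default 70 ± 3 bpm, clipped to 40–180), per-beat class
drawn from the patient's class mix, per-beat amplitude with 8%
coefficient of variation, then shifts to the patient's target mean ICP
and adds a respiratory sinusoid (1 mm Hg at 0.25 Hz), white noise
(0.1 mm Hg, roughly transducer quantization scale), and — optionally —
artifact segments of three kinds (flat-line, ±20–40 mm Hg spike bursts,
dropout to ~0 mm Hg) until a target fraction of samples is corrupted.
Ground truth records every beat's onset sample, class (0 for beats
touching corrupted samples), and true peak-to-peak amplitude.

Cohort-level structure, drawn once per patient:

* age and target mean ICP from piecewise-linear inverse-CDF quantile
  specs, defaulting to quartiles ≈ (29.3, 49.1, 60.2) years and
  (8.6, 11.2, 14.9) mm Hg — values whose ceilings give the canonical
  (30, 50, 61) / (9, 12, 15) factor boundaries;
* class mix: softmax over base log-probabilities (0.25, 0.35, 0.25,
  0.15) shifted by (i − 2.5)·(β_age·z_age + u), with β_age = 0.35 per SD
  of age and patient heterogeneity u ~ N(0, 0.45). This yields a
  cohort-mean PSI ≈ 2.3 and an age partial η² on PSI around 0.3,
  matching the magnitude reported for severe-TBI cohorts;
* pulse amplitude: 8 + 2.0·z_icp + β_int·z_age·z_icp + N(0, 3) mm Hg
  (β_int default 0.6; the recovery experiments set it to 0), floored at
  2 mm Hg;
* mortality: logistic in standardized age, mean ICP and amplitude with
  coefficients (1.0, 0.2, 0.6) and intercept −2.0, giving ≈ 18–20%
  six-month mortality.

z-scores use the robust median/IQR standardization of the quantile
specs. No quantitative dose–response between age and morphology is
available to calibrate β_age against, so it is an order-of-magnitude
choice fixed here and exposed in `CohortSimConfig`.

The generator emulates the *structure* real analyses depend on (three
sub-peaks, HR variability, respiration, artifacts, covariate-driven
class mix and amplitude, outcome model). It does not model ICP genesis
(no Windkessel/compartment physiology, no ABP coupling, no slow waves,
no drift), and its artifact taxonomy is generic rather than
device-specific. Passing tests therefore demonstrate correctness of the
pipeline's algorithms under controlled conditions, not clinical
performance on real recordings.

`synth_cohort_summaries` draws per-patient summaries directly from the
same latent covariate model (shared `_draw_patient`), sampling 240 beats
per patient and averaging. It exists so statistical-power experiments
over tens of thousands of patients need not render waveforms; the
waveform path is exercised end-to-end at smaller scale.

## Beat detection

Three passes over the recording:

1. band-pass 0.66–3 Hz (order-2 Butterworth, zero-phase), covering
   40–180 bpm;
2. per 10-s block, dominant cycle length from the normalized
   autocorrelation of the band-passed block, searching lags in the
   cardiac band and requiring a peak ≥ 0.15 — blocks without one are
   flagged and contribute no onsets (a constant or aperiodic signal
   yields zero onsets);
3. candidate systolic upstrokes are maxima of the first difference of a
   lightly smoothed signal (Savitzky–Golay, 50 ms window), with height
   ≥ 25% of the block's 98th-percentile derivative and a refractory
   distance of 0.6 cycles.

Because the refractory rule cannot see across block boundaries, a global
non-maximum suppression then removes any upstroke within 0.55 cycles of
a stronger one. Each onset is the minimum of a 50-ms moving average
within 0.4 cycles before its upstroke, with one correction: the
moving-average minimum of an asymmetric V-shaped valley sits
`half·(a_L − a_R)/(a_L + a_R)` samples into the shallower side (a_L/a_R
the falling/rising slopes, `half` the half-window). The pulse foot is
such a valley — slow diastolic runoff, fast upstroke — so the shift is
estimated from local slopes and undone. Without this correction the
detector's median localization error is −1 to −2 samples and its ±20 ms
recall drops several points on lower-amplitude recordings.

Beats span consecutive onsets as half-open intervals `[onsetₖ,
onsetₖ₊₁)`; the last onset has no closing boundary and is discarded, so
the diastolic minimum always belongs to the *following* beat. On
artifact-free simulated recordings at typical amplitude (8 mm Hg), onset
recall and precision exceed 0.99 at ±20 ms; both degrade smoothly as
pulse amplitude approaches the noise floor.

## Artifact rejection

A beat is rejected if any of: duration outside 0.3–2.0 s (40–200 bpm),
peak-to-peak range outside 0.1–50 mm Hg, any sample outside −10 to
100 mm Hg, a one-sample jump above 10 mm Hg, or overlap with a masked
region. These limits are physiological-plausibility defaults, all
configurable (`ArtifactThresholds`); whether they match any particular
clinical pipeline's rules is unknowable, which is a stated fidelity
limit of the package.

## Normalization and classification

Valid beats are linearly resampled to exactly 180 samples and min–max
scaled, in that order — resampling first guarantees the 180-sample
vector attains 0 and 1 exactly (interpolating an already-normalized beat
can miss the extremes between grid points). The result is invariant
under positive affine maps of the raw beat, which the property suite
checks to 10⁻⁹.

Sub-peak detection smooths the normalized pulse (Gaussian, σ = 4 of 180
samples) and takes local maxima with topographic prominence ≥ 0.02.
Smoothing is essential at realistic noise: unsmoothed, 5% noise creates
spurious prominent peaks that break the single-peak (class 4) rule.
Candidates are assigned roles by latency band — P1 ∈ [5%, 35%), P2 ∈
[35%, 55%), P3 ∈ [55%, 85%) of the cycle — the most prominent candidate
winning a contested band; candidates outside all bands are ignored. The
band placement follows the standard positioning of the three sub-peaks
in the ICP literature and is configurable.

Classification applies, in order, on heights h₁,h₂,h₃ (absent → −∞):
no roles → artifact; one role → class 4; h₁ ≥ h₂ and h₁ ≥ h₃ → class 1;
h₂ > h₁ and h₁ ≥ h₃ → class 2; otherwise → class 3. Ties use ≥ as
written, so exact equality falls to the lower (more benign) class. The
boundary between classes 2 and 3 — how prominent P3 must be relative to
P1 — admits more than one reading; the rule here (class 3 whenever P3
exceeds P1) is one faithful realization and is deliberately isolated
behind `classify_pulse` so a different rule set, or a learned
classifier, can be swapped in. On noise-free presets accuracy is 100%;
at 5% noise it stays ≥ 95% per class (≥ 99% in practice).

## Windowed indices and summaries

PSI windows are left-aligned half-open 5-min intervals on pulse onset
times, shifted by 10 s, stamped at the window center; windows with fewer
than 60 non-artifact pulses (≈ 1 pulse / 5 s) give a missing value
rather than an unstable estimate. AmpICP tiles the recording with 2-s
windows aligned to the recording start (not beat-aligned): at heart
rates ≥ 60 bpm each window holds ≥ 2 complete beats, so max − min
approximates the pulse's peak-to-peak; windows overlapping artifact
intervals or masked samples are invalid, and the trailing partial window
is dropped. Note two small upward biases of this estimator relative to
per-beat ground truth: beat-to-beat amplitude jitter (the window range
tracks the larger beat) and any slow modulation inside the window
(respiration adds up to its own amplitude). Windowed mean ICP uses 10-s
windows and requires ≥ 50% valid samples.

Patient summaries are unweighted means of valid windows whose start
precedes min(168 h, time of decompressive craniectomy); the seven-day
horizon is interpreted as 168 h of elapsed recording. Cohort filters:
EVD-monitored patients are excluded (pulse morphology is not evaluable
during CSF drainage), craniectomy before monitoring excludes the
patient, and a seven-day mean ICP above 40 mm Hg (terminal intracranial
hypertension) excludes the patient; an all-invalid recording yields
`no-data`. Exclusions carry their reason.

## Cohort statistics

* **Quartile factors.** Q1/median/Q3 by the linear-interpolation
  quantile definition, each rounded *up* to an integer ("upwards
  rounded"), giving four levels ≤b₁, (b₁,b₂], (b₂,b₃], >b₃ with roughly
  equal occupancy. Degenerate inputs and boundaries that collapse after
  rounding raise.
* **Factorial ANOVA.** Two-way with interaction on the (generally
  unbalanced) 4×4 design, Type III sums of squares with sum-to-zero
  coding — the convention of the commercial packages this design is
  usually run in; on balanced data it reduces to the classical
  decomposition, which the tests verify against closed forms. Partial
  η² = SS_effect/(SS_effect + SS_error). Any empty cell raises, naming
  the cell. Post-hoc: all pairwise comparisons of marginal means (per
  factor, m = 6) and cell means (m = 120) using the pooled MSE with
  df_error, Bonferroni-adjusted as min(1, m·p) with m reported.
* **Multiple regression.** OLS of the standardized response on
  standardized age and mean ICP plus Rotterdam-score indicator (dummy)
  columns against the lowest observed score; coefficients are therefore
  standardized β. Complete-case with the dropped-row count logged;
  variance inflation factors reported; rank deficiency raises with the
  aliased columns named.
* **Group comparison.** Independent-samples t-test with pooled
  variance, reported as mean ± SD per group.
* **Logistic regression / ROC.** Maximum-likelihood fit; the reported
  χ² is the likelihood-ratio statistic against the intercept-only model
  with df = number of predictors. AUC uses the rank (concordance)
  method with the Hanley–McNeil standard error; a dedicated O(n²)
  pair-counting oracle in the tests confirms equality including ties.
  Multivariate redundancy is operationalized as backward elimination:
  repeatedly drop the predictor with the largest likelihood-ratio
  p-value while it exceeds α = 0.05. Complete separation (or
  non-convergence) is flagged and falls back to a weakly penalized fit
  with a warning.

Missing data are handled complete-case per analysis with logged counts,
so each analysis has its own N.

## Problem sizes

The bundled experiments use desk-scale sizes chosen to make every claim
checkable quickly: 10-minute recordings for detector scoring, 500 pulses
per class for classifier fidelity, 400-patient summary cohorts for the
statistics battery, and 100 replicates of 200-patient cohorts for the
effect-ordering recovery experiment (which succeeds in ~100% of
replicates at the default effect sizes). Seven-day clinical recordings
are three orders of magnitude longer than the simulated ones; nothing in
the window logic depends on duration, but runtime on full-length data
has not been profiled.

## Known limitations

* The four-class rules realize published verbal class definitions, not
  any trained model's learned boundary; agreement with a specific
  deep-network classifier is not claimed.
* AmpICP is computed on the raw signal per fixed 2-s tiling; beat-wise
  computation within windows would differ slightly in the presence of
  respiration or irregular rhythm.
* The simulator's defaults are calibrated qualitatively (effect-size
  ordering, cohort means), not to reproduce any particular cohort's
  numbers; mortality-model associations are weaker for PSI than for
  amplitude by construction.
* Multi-device recordings are assumed already merged into one
  contiguous series per patient.
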