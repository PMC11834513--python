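# icpmorph

Morphological analysis of intracranial-pressure (ICP) pulse waveforms for
neurocritical care research.

Every cardiac cycle produces a small ICP oscillation whose shape reflects
cerebrospinal compliance: a compliant system shows the classical
three-peaked pulse (P1 percussion, P2 tidal, P3 dicrotic wave), while a
stiffening system lets P2 and P3 grow until the pulse rounds into a
single-peak wave. This package implements the full analysis chain used to
study that progression in cohorts of traumatic-brain-injury patients:

1. **Beat segmentation** — band-pass the signal to the cardiac band,
   estimate cycle length by autocorrelation in 10-s blocks, mark systolic
   upstrokes, and localize each pulse onset at the preceding minimum.
2. **Normalization** — each valid beat is resampled to 180 samples and
   min–max scaled to [0, 1], removing amplitude and heart-rate effects.
3. **Morphology classification** — deterministic sub-peak rules assign
   each pulse a class *i* ∈ {1, 2, 3, 4}: 1 = dominant P1 (normal),
   2 = P2 elevated but P1 > P3, 3 = P2 and P3 both elevated,
   4 = single visible peak (pathological); undetectable pulses are
   artifacts.
4. **Indices** — the pulse shape index in sliding 5-min windows
   (shift 10 s),

   PSI = Σ_{i=1..4} i · pᵢ,

   where pᵢ is the fraction of non-artifact pulses of class *i* (so
   1 ≤ PSI ≤ 4 and PSI is the mean class number); the pulse amplitude
   AmpICP = max − min of the signal in non-overlapping 2-s windows; and
   windowed mean ICP.
5. **Patient summaries** — seven-day averages with cohort filters
   (EVD-monitored patients excluded, truncation at decompressive
   craniectomy, exclusion above 40 mm Hg mean ICP).
6. **Cohort statistics** — age and mean ICP cut at upwards-rounded
   quartiles into 4×4 factors; factorial ANOVA (Type III) with partial
   η² and Bonferroni post-hoc tests; multiple regression with Rotterdam
   CT score dummies; group t-tests; logistic regression with ROC/AUC and
   backward likelihood-ratio elimination.

Real high-resolution ICP cohorts are access-restricted, so the package
bundles a synthetic-cohort generator (`icpmorph.simulate`) that renders
pulsatile ICP with controllable sub-peak prominence, heart-rate
variability, respiration, noise and artifacts, plus a cohort-level joint
distribution of age, mean ICP, morphology mix and mortality — with
per-beat ground truth, so every stage above is scoreable.

## Worked example

```python
import numpy as np
import icpmorph as im

cfg = im.CohortSimConfig(seed=3, duration_s=600.0, hr_mean=60, hr_sd=3)
rec, truth = im.synth_recording(cfg)
out = im.process_recording(rec)
print(len(truth.onsets), len(out["onsets"]))
print(round(float(np.nanmean(out["psi"]["psi"])), 3),
      round(truth.classes[truth.classes > 0].mean(), 3))
```

prints

```
601 605
2.131 2.106
```

— on a 10-minute simulated recording at 60 bpm the detector reports 605
onsets for 601 true beats (recall 0.98, precision 0.97 at a ±20 ms
tolerance against ground truth; this random patient has a fairly low
pulse amplitude of 5.5 mm Hg), and the windowed PSI (2.131) agrees with
the ground-truth mean class number (2.106) to within 0.03.

The `analysis/` scripts run the same chain as a narrative: simulate a
waveform cohort (`01`), extract/classify/summarize it against ground
truth (`02`), run the cohort statistics on a 400-patient summary cohort
(`03`), and repeat the ANOVA on 100 simulated cohorts to check that the
injected structure — age driving pulse shape, mean ICP driving pulse
amplitude — is recovered (`04`). Outputs land in `results/`.

A thin CLI mirrors the pipeline: `icpmorph simulate | extract | classify
| psi | summarize | stats` (see `--help` on each).

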