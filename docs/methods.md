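# Methods

This note documents the generative model behind the synthetic cohorts, the
signal-processing and feature definitions, the classifiers, the evaluation
protocol, and the numerical/design choices that were genuinely open. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design being emulated

A clinic cohort of ~20 people with PD wearing six IMU sensors (dorsal
hand, forearm, thigh; both sides; tri-axial accelerometer ±4 G and
gyroscope ±1000 °/s, both at 62.5 Hz) while performing 13 short motor
tasks in four groups (functional, clinical, fine motor, gross motor).
Day 1 comprises six repeated assessment sessions, the first before
medication; a single day-2 session follows weeks later, after sensors
were removed and re-applied, with only the first 15 subjects returning.
A clinician rates bradykinesia, tremor and dyskinesia 0–4 per task
performance and body side. Dyskinesia scores are generated for schema
completeness but no dyskinesia detector is built (prevalence is
configured low, mirroring why such models are typically not attempted).

## Generative model

Per subject, drawn once (deterministically from the cohort seed):
dominant side; tremor frequency ~ U[4, 6] Hz; per-symptom propensity;
baseline movement amplitude ~ N(0.15, 0.04) G (floored at 0.02);
medication responsiveness ~ U[0.5, 1].

**Propensities.** The across-subject distribution of the fraction of task
performances showing a symptom is matched to the configured prevalence
mean/SD (bradykinesia 0.485 ± 0.217, tremor 0.22 ± 0.244, dyskinesia
0.08 ± 0.115) with a moment-matched Beta. A Beta rather than a truncated
normal because truncation at [0, 1] shifts the mean (for the tremor
parameters by ≈ +0.08), which would break prevalence recovery; the Beta
keeps the mean exact, and at tremor-like parameters places real mass at
zero — subjects who never show tremor, as happens clinically.

**Scores.** Per (subject, side, day, session, task): presence ~
Bernoulli(propensity × 0.4 if the non-dominant side); if present, a
latent severity ~ U[0.5, 4.5) is multiplied by the session's medication
factor and rounded to 0–4. The medication factor is 1 in the first
(pre-dose) day-1 session and `1 − responsiveness × (1 − 0.7)` afterwards
(day 2 is treated as medicated). Because a medicated latent severity can
fall below the score-1 threshold, realized prevalence under medication is
slightly below the configured mean; prevalence-recovery checks therefore
set the medication multiplier to 1.

**Signals.** Voluntary movement is band-limited Gaussian noise
(0.5–3 Hz), unit-normalized per channel and scaled by subject baseline ×
task-group motion scale, with gravity as a constant 1 G on the
accelerometer z axis (only its DC property matters: the 0.5 Hz high-pass
removes it). Gyroscope channels use the same construction scaled by
150 °/s per G. White measurement noise (0.01 G, 1 °/s) is added and
values are clipped to the sensor ranges.

*Bradykinesia* (severity s) multiplies the voluntary-motion amplitude by
`0.7^s` and lowers the upper band edge proportionally (reduced spectral
content). *Tremor* (severity s) enters hand/forearm sensors in two ways:
(i) the movement energy of all channels is modulated at the subject's
tremor frequency with depth `min(0.95, 0.25 s)` — muscle-activity bursts
at tremor frequency — and (ii) an amplitude-modulated sinusoidal carrier
(0.06 G per severity unit; 0.7× on the forearm; gyro carrier 250 °/s per
G) rides on the x/y axes. The modulation term is what makes the
*magnitude* of the gravity-removed signal oscillate at the tremor
frequency: a purely additive zero-mean carrier would put its
magnitude-spectrum power at DC and twice the tremor frequency
(rectification), and the dominant-frequency feature would miss the 4–6 Hz
band. Task-group symptom expression scales both effects (0.5 in
gross-motor tasks, where large voluntary movements mask symptoms — this
is what makes gross-motor detection hardest, qualitatively matching
clinical experience).

*Day 2* applies a fixed random rotation per (subject, side, location) —
axis uniform on the sphere, angle ~ N(0°, 15°) — to both sensor triads,
emulating sensor replacement. Note that many of the features (magnitude
spectra, sample entropy, per-axis moments) are largely
rotation-tolerant, so the simulated day-2 domain shift is mild; how much
it degrades transfer is an empirical output of the session experiment,
not a construction guarantee.

**Determinism.** Every random draw comes from a `default_rng` keyed by
the cohort seed plus the (subject, day, session, task, side, location)
tuple, so cohorts are bit-identical across runs and independent of
generation order; determinism is checked by file checksum.

## Preprocessing

5-s windows (312 samples = floor(5 × 62.5); step 156 = 50% overlap;
trailing partial windows discarded; a recording shorter than one window
yields none, with a warning). Filters are 4th-order Butterworth designs
applied forward–backward (zero phase; offline analysis, and tremor phase
should not be distorted — the stated order is the design order, so the
magnitude response is squared). Accelerometer channels are high-passed
at 0.5 Hz for both symptoms; the 3 Hz low-pass for bradykinesia applies
to all channels, high-pass first. The gyroscope is not high-passed (it
has no gravity component). Filtering uses maximal *even*-reflection
padding: the 0.5 Hz high-pass has a ~2 s impulse response, longer than
the default pad on a 5-s clip, and odd reflection injects edge kinks
whose low-frequency energy leaks through the 3 Hz low-pass (with even
padding a 5 Hz tone is attenuated to ~9% RMS on the bradykinesia path;
with the defaults it was only ~25%).

Labels: score > 0 → 1, per task performance, propagated to all of its
clips; the label side is the subject's dominant-symptom side.
Multi-sensor examples concatenate the sample-aligned windows of the
selected sensors channel-wise (simulated streams are sample-aligned;
cross-device clock alignment is out of scope). Task performances without
an annotation are excluded with a warning.

## Features (56 per sensor)

Per modality (acc, gyro), in schema order: range, skew, excess kurtosis
per axis (9); normalized cross-correlation peak and lag (s) for the
three axis pairs, normalized by L·SD·SD so the zero-lag self-correlation
is exactly 1, peak ties resolved toward the smallest |lag| (6); dominant
frequency of the mean-subtracted Euclidean magnitude — Hann-windowed
periodogram zero-padded to ≥512 points (bin width < 0.25 Hz), argmax
above 0.25 Hz (1); RMS of the mean-subtracted magnitude ("relative
magnitude", a movement-intensity feature; the term is used loosely in
the field, so the definition is fixed here and recorded in the feature
manifest) (1); the first four moments of the normalized power spectrum
treated as a distribution over frequency — spectral mean, variance,
skewness, excess kurtosis (4); mean, variance, skewness and excess
kurtosis of the jerk magnitude, jerk being the per-axis first difference
× sampling rate, then the per-sample norm (4); sample entropy
SampEn(m=2, r=0.2·SD) per axis, Chebyshev distance, self-matches
excluded, both template lengths counted over the first N−m templates (3).

The Hann window matters: boxcar leakage sidelobes skew the spectral
moments of narrowband signals (a symmetric two-tone spectrum acquired
spectral skewness ≈ 2.4 without it). Degenerate inputs (zero variance,
zero power) return 0 rather than NaN; when both SampEn template counts
are zero the value is capped at ln of the number of countable pairs.
Vectors are always finite; the schema (names, units, definitions) ships
as a JSON manifest next to extracted tables.

## Classifiers

**Random forest:** 50 trees (the tree count a practitioner would settle
on via the out-of-bag error method; the OOB error estimate is exposed on
the fitted model), √p features per split, bootstrap, balanced class
weights (tremor positives are a minority of clips and no explicit
rebalancing scheme is assumed), fixed seed.

**CNN:** conv(kernel 32, 16 filters, ReLU) → maxpool(4) → conv(16, 32,
ReLU) → maxpool(6) → dense(32, ReLU, dropout 0.5) → dense(32, ReLU,
dropout 0.5) → softmax(2), on the raw filtered clip (312 × 6; 'same'
padding, stride 1, pooling floors the length). It is implemented as a
compact numpy network (im2col convolutions, inverted dropout, Adam,
class-weighted cross-entropy; defaults 30 epochs, batch 64, lr 1e-3),
fully deterministic given its seed. The builder reports per-layer and
total trainable parameters from the closed-form sums; for the reference
architecture at 312 × 6 this is 25,778. No natural combination of
padding and channel choices reproduces the originally reported 24,722
for this architecture family, so the builder reports its own count
rather than forcing a match. Both model families serialize with a JSON
sidecar (spec, seed, input schema) and reload to bit-identical
predictions.

## Evaluation protocol

LOSO: per held-out subject, a model trained on all other subjects scores
that subject's clips; AUROC is computed per subject and averaged
(per-subject ROC, not pooled — the mean-across-subjects estimand; a
pooled variant is easy to add but the per-subject mean is the default).
The 95% CI is a t-interval over subject AUROCs (the CI construction was
an open choice). Subjects with single-class test labels are excluded
*per condition* with a logged reason — AUROC is undefined for them, and
exclusion per condition rather than globally keeps, e.g., a subject who
shows tremor only in some task group in the conditions where they are
evaluable. Paired condition contrasts use the paired t-test on
per-subject AUROCs, dropping pairs with a missing arm, two-sided, with
no multiple-testing correction by default (a Holm helper exists).
Constant pairwise differences (to float precision) report t = ±inf,
p = 0 rather than a rounding-driven finite statistic.

Experiments: (1) *sensor combinations* — hand vs both hands vs
hand+forearm+thigh, identical LOSO splits, pairwise paired tests;
(2) *activity groups* — one model over all tasks, test clips stratified
by group, each group vs the clinical tasks; (3) *learning curve* —
random training subsets of increasing size, evaluated on the left-out
subjects, repeated (CI across repeat means); (4) *sessions* — training
on session 1 vs all day-1 sessions, tested on the held-out subject's
day-1 or day-2 clips (training never includes day 2; whether day-1
testing should also hold out sessions was open — subject-level holdout
with all day-1 sessions in the test pool is used).

## Problem sizes

Tests and the acceptance script run scaled-down cohorts chosen to
exercise every mechanism with stable statistics: 12 subjects × 4 tasks ×
2 sessions (hand only, 30 s per task, ~1000 clips) for discrimination
and the 20-permutation null; 19 subjects × 3 tasks at half effect size
and doubled noise for the learning curve (50 repeats); 8 subjects with
all six sensors for the sensor/activity experiments; 10 subjects × 6
sessions + day 2 for the session experiment; 400 subjects
(annotation-level only) for prevalence recovery.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of a clinic cohort —
spectral signatures, label structure, prevalence heterogeneity,
medication and replacement effects — not real PD movement. Passing
discrimination tests shows the pipeline is wired correctly and can
recover effects that are present by construction; it says nothing about
absolute AUROC on real recordings, which depend on symptom expression
far messier than this model (intermittent tremor, task-dependent
kinematics, rater noise, sensor artifacts). Real-data headline numbers
are therefore out of scope by design; the synthetic experiments are
expected to reproduce *qualitative* orderings (single hand sensor
sufficient; gross-motor hardest; learning curve rises then flattens)
and they do.

## Known limitations

No biomechanical limb model, no EMG, no dyskinesia signal model, no
clock drift or resampling between physical sensors, one rater with no
rating noise model, and binary labels only (no severity regression).
The CNN implementation is sized for clip-scale problems (thousands of
examples) on one CPU, not for large-scale training.
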