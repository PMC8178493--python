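# Methods

This note documents the models behind `apeqol`: what the synthetic data
generator emulates, how formants are measured, how the statistics are
computed, and where the genuinely open design choices were resolved.

## Vowel synthesis

Sustained vowels are produced by a source-filter (Klatt-style) synthesizer.

**Source.** An impulse train at the fundamental frequency F0 with 1%
cycle-to-cycle period jitter and a 1% sinusoidal vibrato at 5 Hz; both are
typical of sustained phonation and, importantly for analysis, smear the
harmonic line structure slightly.  Aspiration noise is added at
`noise_level` (default 0.05 relative RMS) **before** the spectral-tilt
filter, so the voiced and unvoiced components share one spectral envelope;
injecting it after the tilt leaves the noise floor with an uncompensated
rising slope under analysis pre-emphasis and biases low F1 estimates
upward by 50–70 Hz.  The glottal tilt is a single pole at 0.9925
(44.1 kHz), i.e. roughly −6 dB/oct through the speech band; the 0.97
pre-emphasis zero applied at the 10–11 kHz analysis rate cancels it almost
exactly.

**Filter.** Cascaded second-order resonators at (F1, B1), (F2, B2) and two
fixed upper resonances (3500 Hz / 250 Hz and 4500 Hz / 300 Hz, kept below
the male analysis band edge).  Default bandwidths are B1 = 80 Hz,
B2 = 120 Hz.  Output is peak-normalized to 0.9 and written as 16-bit PCM
mono WAV at 44.1 kHz, one second per vowel.

**Formant targets.** Male defaults are the Hillenbrand et al. (1995)
adult-male means for /ɑ/, /i/, /u/.  Female defaults are the male values
under a uniform 1.14× vocal-tract-length scaling.  Two reasons: (i) FCR is
scale-invariant, so uniform scaling gives both genders the same baseline
FCR — the property that makes FCR poolable across gender, which the
stage-ROC analysis relies on; (ii) female F1 values from the older
Peterson–Barney tables (e.g. /i/ F1 = 310 Hz) sit between glottal
harmonics at typical female F0 (190–210 Hz) and incur the well-known
high-F0 LPC bias of +50 Hz and more, which would make the generator's own
ground truth unrecoverable by any envelope-based method.  Default F0 is
120 Hz (male) and 190 Hz (female), with an 8-Hz between-speaker SD.

## Severity model

Disease severity acts through a single centralization weight λ ∈ [0, 1]:
every formant moves to (1−λ)·F + λ·centroid, where the centroid is the
mean over the three vowels computed separately for F1 and F2.  λ = 0 is
healthy; λ = 1 collapses the triangle (FCR = 2, VSA = 0).

* Pre-operative: λ_T = {T0: 0, T1: 0.04, T2: 0.09, T3: 0.15, T4: 0.22},
  monotone by construction.
* Post-operative: the resection extent adds λ_surg = {PG: 0.06, HG: 0.12,
  STG/TG: 0.20} (partial / hemi / subtotal-total glossectomy).
* A per-subject λ perturbation (SD 0.02) and two idiosyncrasy terms — a
  vocal-tract scale factor (SD 4%, FCR-neutral) and per-formant
  multiplicative jitter (SD 6%) — provide between-speaker variation.  The
  jitter matters for identifiability: the articulation outcome is driven by
  the speaker's *realized* FCR, so FCR carries label-relevant variance that
  the other 14 metrics only track through λ.

**Perceptual link.** Each of the 12 syllables is coded deviated with
probability `logistic(b0 + b1·(FCR − 1.07) + offset_group)`, b0 = −2,
b1 = 40, offsets {alveolar: 0, alveolo-palatal: +0.7, velar: −0.4} — the
alveolo-palatal group is the most error-prone, the velar group the least.
b1 ≥ 0 is enforced: a larger FCR never lowers the misarticulation
probability.  b1 and the offsets were calibrated once so that the planted
dominance structure is recoverable at the study size (156 screening
sessions): with a weaker link the weakest per-syllable SVMs (velar, few
deviated cases) produce sign-flipped near-zero FCR weights.

**SHI link.** A latent total score −110 + 120·FCR plus subject noise
(SD 6) is spread over 30 items (latent/30 each) with item noise (SD 0.6),
rounded and clipped to the 0–4 item scale.  All items share the latent, so
internal consistency is high (Cronbach's α ≈ 0.9 at the default noise) and
FCR–SHI correlations are strong, mirroring the validated-questionnaire
setting the pipeline targets.

**Cohort layout.** The 33-patient validation cohort (20 male / 13 female)
reproduces the canonical clinical table exactly: per-gender T
distributions, resection extents, reconstruction counts (18/2 vs 9/4) and
flap types (15 ALT + 3 other vs 8 + 1).  Severity and resection are
assigned jointly monotone (more advanced T → larger resection), which is
clinically coherent and keeps the marginals intact.  One deterministic
dropout (the last enrolled patient) removes a post-operative session:
65 sessions, 97% follow-up.  The screening set draws T class from
{0: 0.35, 1: 0.13, 2: 0.16, 3: 0.16, 4: 0.20} across 80 male and 76
female single-visit speakers.

## Formant measurement

`read_wav` accepts PCM WAV, averages multi-channel input to mono, and
resamples anything that is not 44.1 kHz (both logged).

`find_steady_segment` automates the framing of a 200-ms stable phonation
window: among all windows whose RMS reaches 10% of the loudest window's
RMS, it minimizes variance of short-time log-energy plus variance of the
spectral centroid (in kHz) across 25-ms subframes; ties (within an
absolute 1e−6 cost tolerance, far below any audible difference) break
toward the earliest start.

`estimate_formants`, method `lp` (default): downsample to twice the
formant ceiling (5000 Hz male / 5500 Hz female), pre-emphasize (0.97),
autocorrelation LPC of order 2 + rate/1000 on 25-ms Hamming subframes
(5-ms hop), keep polynomial roots with frequency in (90 Hz, ceiling−50),
bandwidth < 400 Hz and modulus > 0.7, sort ascending, and take the median
F1/F2 across subframes.  Quality = fraction of subframes yielding at least
two admissible formants.  On the default synthesis grid (2 genders × 3
vowels × 3 F0 values) recovery is within ±40 Hz in 180/180 runs, worst
error 37 Hz.

Method `fft512` retains a spectral-envelope dialect: 512-point magnitude
spectra with cepstral smoothing (2-ms lifter cutoff), peak picking with a
0.35 log-unit prominence floor and parabolic interpolation.  The 512-point
frames are taken from the same downsampled band as `lp`; at the original
44.1 kHz a 512-sample window spans barely 1.4 pitch periods and its
~344-Hz Hamming mainlobe cannot separate F1 from the tilt lobe at all, so
the dialect is only meaningful on the downsampled signal.  Agreement with
`lp` is within one 44.1-kHz bin (±86 Hz) on the default targets.

Repetitions of the same vowel aggregate by the median of their F1 and F2
(the natural robust choice when three repetitions are recorded).

## The 15 metrics

Six raw formants (F1 and F2 of /ɑ/, /i/, /u/), FCR, VSA (triangle area in
the F1–F2 plane, Hz²), Joos-VSA = log10 VSA, and per-vowel
compact–diffuse and grave–acute correlates.  CD defaults to formant
proximity F2 − F1 (compact = small separation) and GA to spectral balance
(F1 + F2)/2 (grave = low); both formulas sit behind a config object
(`MetricFormulas`) so they can be swapped without touching callers.
A zero-area (collinear) vowel triangle leaves Joos-VSA undefined; the
session is flagged incomplete and excluded from SVM training but kept in
all bookkeeping.

## Marker screening

One soft-margin linear SVM (C = 1, no class weighting) per (gender,
syllable) on the z-scored 15 metrics, positive class = correct
articulation, so a metric whose increase raises the misarticulation
probability receives a negative weight.  Standardization is required for
cross-feature weight comparability, which the ranking presumes.  CV
metrics (accuracy, AUC, sensitivity, specificity, PPV, NPV) come from
stratified 10-fold out-of-fold predictions with a fixed seed; folds shrink
to the smallest class size when needed.  Ratios with empty denominators
are reported missing, never zero.

Ranking: mean |weight| across the 24 models per feature (absolute value so
sign conventions cannot cancel), ties broken by canonical feature order.
Cross-gender dimorphism: per-feature two-tailed t-test over the 12
syllable weights, uncorrected p primary and Holm-adjusted p attached;
zero-variance-in-both-genders features are reported missing.

## Validation statistics

* Cronbach's α = k/(k−1)·(1 − Σ item variances / variance of totals),
  sample variances; undefined (NaN, with a warning) when the totals do not
  vary.  Note α = 1 requires tau-equivalent items (equal variances), not
  merely r = 1.
* Mann–Whitney uses exact enumeration when both groups have ≤ 8
  observations and no ties, otherwise the normal approximation with tie
  correction.  Fisher's exact test is two-sided by summation of tables no
  more probable than the observed one (verified against hypergeometric
  enumeration).
* Stage trends are OLS on the numeric T code (patients only, 1–4), with
  t-based slope CIs and R².
* Two-way ANOVA uses type-III sums of squares under sum-to-zero coding
  (correct mains in unbalanced designs).  With exactly zero residual
  variance, terms with nonzero SS are reported p = 0 and zero-SS terms
  p = 1 rather than NaN.
* The pre/post mixed model is a subject-random-intercept linear model fit
  by REML.  Fixed-effect terms get Wald F statistics against containment
  denominator df: within-subject terms use n_obs − n_subjects − (number of
  time-involving columns), between-subject terms n_subjects − (number of
  between columns including the intercept).  In the balanced
  single-factor complete-data case this reproduces the paired t-test
  exactly (REML gives Var(time effect) = sd²_diff/n and df = n−1).
  Pairwise pre-vs-post contrasts within each factor level are Sidak
  corrected; uncorrected p is also emitted.  Factor levels with one
  subject are excluded with a warning.  Type-I error of the interaction
  test is 5% within Monte-Carlo error over 500 null replicates (n = 30).

## ROC diagnostics

Empirical ROC over thresholds at the midpoints between distinct observed
scores (plus sentinels); trapezoidal AUC, which equals the
concordant-pair fraction with half credit for ties (asserted against a
brute-force pair count to 1e−12).  The optimal cutoff maximizes Youden's
J, reported as the midpoint between adjacent distinct scores; J ties break
toward higher specificity.  The AUC CI uses the Hanley–McNeil variance
(normal approximation); DeLong is available via `ci="delong"`.  Stage
dichotomies (T0–2 vs T3–4 and T0 vs T1–4) are evaluated on pre-operative
sessions of the merged screening + validation feature tables.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* of the clinical
study: severity-monotone centralization, an FCR-driven misarticulation
link with the alveolo-palatal predilection, FCR-linked SHI scores with
high internal consistency, the cohort bookkeeping, and gender-dimorphic
formants with a gender-neutral FCR.  Passing tests therefore demonstrate
that the pipeline recovers planted structure of realistic size and noise —
not that any particular clinical effect size holds in real speech.  Real
consonant articulation is simulated as a binary label (no consonant audio
is synthesized); prosody, nasality, voice-source pathology (F0, jitter,
shimmer as clinical measures) and radiotherapy effects are all out of
scope.  Numeric agreement with published clinical values should only be
expected for quantities that are fixed by design (session counts,
balance-table p-values, metric algebra), not for cohort-dependent
estimates such as AUCs or trend slopes.

## Problem sizes

The test suite and the acceptance script run the study at its native sizes
(156 screening sessions, 33 + 20 validation/control speakers).  Replicate
counts per check are chosen to keep Monte-Carlo error well inside each
asserted margin: 50 audio-pipeline replicates for marker-screening
dominance, 500 null replicates for type-I calibration, 20 replicates for
generator monotonicity, 20 for the acceptance script's dominance rates.
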