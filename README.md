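# apeqol

Acoustic-marker screening and clinical validation for sustained-vowel
speech, aimed at structurally based articulation disorders such as those
caused by oral tongue cancer and glossectomy.

Tongue lesions and tongue surgery restrict lingual mobility, which pulls
the corner vowels /ɑ/, /i/, /u/ toward the centre of the F1–F2 vowel
space.  The **formant centralization ratio**

```
FCR = (F2/u/ + F2/ɑ/ + F1/i/ + F1/u/) / (F2/i/ + F1/ɑ/)
```

rises as the vowel triangle collapses (exactly 2 at total collapse), is
scale-invariant — so it pools across the sexual dimorphism of formant
frequencies — and can be measured from three one-second vowel recordings.
`apeqol` implements the full workflow that screens FCR out of 15 candidate
vowel metrics and validates it clinically:

1. **synthetic_cohort** — a Klatt-style source-filter vowel synthesizer
   plus a cohort generator (33 pre/post surgical patients, healthy
   controls, and a 156-speaker cross-sectional screening set) with a
   severity model linking tumour stage and resection extent to formant
   centralization, misarticulation, and Speech Handicap Index (SHI)
   scores.  Everything downstream runs with no external data.
2. **formant_extraction** — WAV input, automated 200-ms steady-segment
   framing, and F1/F2 estimation by LPC root-finding (a 512-point-FFT
   envelope picker is available as `method="fft512"`).
3. **formant_metrics** — the 15 analyzed parameters per session: six raw
   formants, FCR, vowel space area (VSA), Joos-VSA (log10 VSA), and
   compact–diffuse / grave–acute correlates per vowel.
4. **perceptual** — a 12-syllable consonant corpus (alveolar,
   alveolo-palatal, velar), binary correct/deviated coding, and percent
   consonants correct (PCC).
5. **marker_screening** — per-syllable, per-gender linear SVMs on the
   z-scored metrics; the weight matrices rank the metrics and recover FCR
   as the dominant, uniformly negative predictor.
6. **clinical_validation** — SHI scoring and Cronbach's alpha, cohort
   balance tests (Fisher/chi-square), stage-trend regression, two-way
   type-III ANOVA, and pre/post mixed-effects models with a subject random
   intercept.
7. **diagnostics** — ROC analysis of FCR for the stage dichotomies
   T0–2 vs T3–4 and T0 vs T1–4, with Youden-J optimal cutoffs and
   Hanley–McNeil confidence intervals.

## Worked example

```python
from apeqol import (CohortConfig, simulate_cohort,
                    find_steady_segment, estimate_formants, trend_regression)

cohort = simulate_cohort(CohortConfig(seed=1))
clip = cohort.session_clip("pat01_pre", "A")          # sustained /a/, 1 s @ 44.1 kHz
seg = find_steady_segment(clip)                        # 200-ms steady window
m = estimate_formants(seg, gender="male", vowel="A")
print(f"/a/ F1 = {m.f1:.0f} Hz, F2 = {m.f2:.0f} Hz (quality {m.quality:.2f})")

pre = cohort.sessions.query("cohort == 'patient' and timepoint == 'pre'")
trend = trend_regression(pre.true_fcr, pre.t_class)
print(f"pre-op FCR vs T: slope = {trend['slope']:.3f} "
      f"(95% CI {trend['ci95'][0]:.3f}-{trend['ci95'][1]:.3f}), "
      f"R^2 = {trend['r_squared']:.2f}, p = {trend['p']:.4f}")
```

prints

```
/a/ F1 = 809 Hz, F2 = 1391 Hz (quality 1.00)
pre-op FCR vs T: slope = 0.047 (95% CI 0.026-0.068), R^2 = 0.41, p = 0.0001
```

The first line is the measured first and second formant of one patient's
pre-operative /ɑ/ (quality = fraction of analysis subframes yielding two
admissible formants).  The second line is the pre-operative stage trend:
FCR increases by about 0.05 per T class across the 33 patients, explaining
~40% of the variance.

The same pipeline is available from the shell:

```sh
apeqol all --seed 1 --out runs/demo        # synth -> extract -> screen -> validate -> roc
apeqol synth --seed 1 --out runs/demo      # or stage by stage
```

Each stage writes CSV/JSON artifacts and a manifest into the output
directory; `apeqol all` finishes by reporting the dominant marker (FCR
under the default generator).

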