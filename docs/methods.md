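# Methods

This note documents how each stage of the pipeline works, the tunable
parameters and their defaults, the numerical choices made where the design
was open, and what the synthetic-data generators do and do not emulate.

## Audio representation

All stages operate on mono float waveforms in [−1, 1] with an explicit
sample rate. Integer PCM is rescaled at the I/O boundary (1/32768 for
16-bit) and multi-channel audio is mean-downmixed, so every downstream
threshold is independent of bit depth and channel count. The pipeline is
sample-rate agnostic; tests exercise 16 kHz and 44.1 kHz. Short-time
analysis defaults to 25 ms frames with a 10 ms hop; a trailing partial
frame is discarded (frame count = ⌊(N−L)/H⌋ + 1).

## Voice activity detection

A deterministic relative-energy detector. Frame log-energies (20 ms frames,
10 ms hop) are compared against a threshold 35 dB below the 95th-percentile
frame energy, which makes the segmentation exactly invariant to global
amplitude scaling. Smoothing proceeds in three steps:

1. **Hangover**: non-speech gaps of at most 3 frames between speech frames
   are filled. Filling gaps rather than extending trailing edges keeps the
   outer boundaries at the energy onsets/offsets.
2. **Merging**: speech intervals separated by less than `min_pause_s`
   (150 ms) are merged.
3. **Duration gating**: intervals shorter than `min_speech_s` (100 ms) are
   dropped.

Frame decisions are first attributed to hop-wide slots centred on each
frame and then *refined to sub-frame precision*: around each coarse
boundary, 2 ms energy windows locate the exact onset/offset under the same
relative threshold. On clean audio this puts boundaries within a few
milliseconds of truth, and internal pause durations within ~5 ms per pause.

**Speaking time** is the onset-to-offset span (internal pauses included);
**pause time** is the non-speech portion of that span. The reference
calculation 2.13/10.82 = 0.197 divides internal pause time by the full
span, which fixes this definition. Leading and trailing silence count
toward neither, so results do not depend on how long a participant waits
before speaking.

## Prosody

**Syllable counting.** Prompts are fixed, so syllables come from a bundled
ARPAbet lexicon covering the five sentences: a word's count is its number
of stress-carrying vowel nuclei. Out-of-lexicon words fall back to an
orthographic vowel-cluster heuristic with a silent-final-e correction.
Sentence 1 counts 15 syllables; its 40-phone phonetization matches the
task's published phoneme count.

**Speaking rate** = prompt syllables / detected speaking time. The per-visit
rate is the unweighted mean of the five per-sentence rates (the aggregation
across sentences is not otherwise constrained; the mean is the symmetric
choice).

**Pitch.** Frame-wise normalized autocorrelation (40 ms frames, 10 ms hop;
search band 50–400 Hz; voicing threshold 0.5 on the peak correlation). To
avoid octave errors the shortest candidate lag whose local peak reaches 90%
of the band maximum is chosen, then refined by parabolic interpolation —
this recovers programmed f0 within a few hundredths of a hertz on clean
synthetic vowels. Average pitch and pitch variance are the sample mean and
sample variance (n−1 denominator) over voiced frames only; unvoiced frames
carry no f0 and are excluded. Pitch variance is reported on the raw Hz²
scale.

## Articulation

**Formants.** Autocorrelation-method LPC per frame (25 ms/10 ms, Hamming
window, order 2 + sample_rate/1000). Pre-emphasis uses a coefficient of
0.7 rather than the 0.97 used for the cepstral front end: heavy
pre-emphasis biases low F1 estimates toward the nearest harmonic when f0 is
high (at f0 = 200 Hz a 300 Hz F1 drifted ~100 Hz; at 0.7 the error is
under 20 Hz across f0 ∈ [100, 200]). Candidate poles need positive
imaginary part, bandwidth < 400 Hz and frequency in [90, Nyquist − 50] Hz;
the two lowest qualifying frequencies are F1 and F2, and frames with fewer
than two candidates are marked invalid.

**Vowel space area** is the convex-hull area of the per-frame (F1, F2)
points over the concatenated five readings, restricted to voiced speech
frames, after trimming each axis to its [5th, 95th] percentile range to
reject outlier frames. A hull requires ≥ 3 non-collinear points; degenerate
clouds raise an explicit error. The hull-over-all-voiced-frames definition
is used because the concatenated-stream input provides no vowel identities,
which corner-vowel quadrilateral methods would require.

**GOP scoring.** The acoustic model is a per-phone diagonal Gaussian over
13 mel-cepstral coefficients (26 triangular mel filters, DCT-II), trained
on synthetic renditions of each phone in the prompt inventory — the scoring
mathematics is the standard length-normalized log-likelihood ratio, while
the model itself is deliberately small and self-contained. Phone segment
boundaries come from monotonic dynamic-programming forced alignment of
frame features to the prompt's expected phone string (every phone ≥ 1
frame; segments tile the span in prompt order). Vowel and consonant
precision are unweighted means of segment GOP scores by class; duration
weighting is a possible alternative but was not adopted, keeping each
phone's contribution equal. GOP magnitudes depend on the acoustic model's
variances and are comparable only within a fixed model; analyses use them
relatively, which is all the mixed models require.

## Normalization

The five sentence-task scalars (speaking rate, average pitch, pitch
variance, vowel and consonant precision) are converted to percentiles of
the empirical CDF over an age/sex-matched subset of a normative corpus.
Matching takes same-sex records within ±5 years; if fewer than 30 match,
the window doubles until the subset reaches 30 or the same-sex corpus is
exhausted (30 stabilizes the empirical CDF; the doubling rule guarantees
totality). Percentiles use the midrank convention,
100·(#{ref < x} + ½·#{ref = x})/n, which is symmetric under ties and maps
the reference median of an odd-sized distinct sample to exactly 50. Vowel
space area and pause rate pass through unnormalized: a sentence-reading
reference corpus supports neither a reliable vowel space area nor any
spontaneous-speech norm.

## Clinical questionnaires

SCAT-5 Symptom Evaluation: 22 items, each 0–6; scored as symptom count
(items > 0, range 0–22) and symptom severity (sum, range 0–132). BDI: 21
items, each 0–3; total 0–63, banded none (0–13), mild (14–19), moderate
(20–28), severe (29–63) — the bands partition the range exactly. RAVLT
delayed recall is carried as a supplied z-score covariate only.

## Longitudinal models

Analysis windows mirror the collection design: between-group comparisons
use samples from the first 30 days (acute phase); within-subject
headache-state comparisons use PTH samples from the first 90 days (more
samples per subject).

Models are linear mixed models fitted by **maximum likelihood** (not REML),
so likelihood-ratio tests on fixed effects are valid. Fixed effects are
age, sex, and the term under test (group, or headache status); random
effects are a per-subject intercept, plus — in the random-slope variant — a
per-subject slope for headache status with free intercept–slope
covariance. The LRT p-value is the upper chi-squared tail of
2·(llₑᵤₗₗ − llᵣₑ𝒹) at the parameter-count difference; the reduced model
drops only the term under test. If the reduced fit beats the full fit by
more than 1e-4 in log-likelihood the pair is reported as inconsistent
rather than producing a spurious p-value.

Convergence is a reported outcome, not an exception: a fit is flagged
converged when the optimizer reports success and all coefficients, standard
errors and variance components are finite and non-negative. Degenerate
responses (zero variance) are reported as non-converged. Both model
variants are always reported side by side in the within-subject analysis,
because a significant random-slope-model p-value can reflect either a mean
headache effect or between-subject variability in that effect. Raw group
means and their difference accompany every p-value to convey direction —
they are cohort means, not model estimates. No multiple-testing correction
is applied; p-values are per-feature and unadjusted.

## Synthetic data

**Speech audio** is source–filter synthesis: a deterministic impulse train
at the target f0 drives cascaded second-order resonators at specified
formant frequencies/bandwidths; obstruent consonants are band-limited noise
bursts (seeded), sonorants weak vowel-like resonances. This gives exact
ground truth for f0, formants, phone timing and pause structure — the
entire verification surface of the acoustic stages. It does *not* emulate
coarticulation, f0 declination, amplitude dynamics, channel noise or
speaker variability, so passing signal-recovery tests demonstrates
correctness of the estimators on clean, stationary inputs, not robustness
to field recordings.

**The normative corpus** generator draws ages uniform on [18, 75], balanced
sexes, and features from age/sex-dependent Gaussians (male mean pitch
120 Hz vs female 210 Hz; speaking rate declining 0.005 syll/s per year;
precision scores clipped at 0). It emulates the *role* of a large
reference population for the percentile transform, not the distribution of
any real corpus.

**The cohort** simulator follows the study design: visits every 3 days over
12 weeks (29 visits/subject), defaults 19 PTH / 31 HC, PTH ages ~N(42.5,
13.7²), HC ~N(38.7, 12.5²) clipped to 18–65, sex frequencies 13/19 and
18/31 female, headache on ~36% of PTH visits with intensities ~N(4.5, 2.1)
clipped to 1–10, and optional independent missed-visit thinning. Responses
are generated exactly under the mixed-model structure (subject intercepts,
per-subject headache slopes with specified mean and SD, Gaussian
residuals), so the fitted models are correctly specified — parameter
recovery therefore validates the estimation and testing machinery, not
robustness to model misspecification. Effect sizes are free parameters;
the defaults encode the reported directions (PTH: longer pauses, less
precise articulation; headache days: slower speech) at plausible fractions
of the between-subject spread.

## Problem sizes in the test suite

Desk-scale sizes keep the suite fast while leaving the statistics
well-powered: parameter recovery uses 50-subject cohorts (±3 SE bands),
the null-calibration check uses 500 replicates of a 20-subject, 4-week
cohort (LRT rejection rate must fall in [0.03, 0.08] at α = 0.05), and the
probability-integral-transform check uses a 20 000-point reference with
1 000 draws (KS non-rejection at α = 0.01). The full suite runs in about
half a minute.

## Known limitations

- The VAD, pitch, formant and GOP components are designed for the clean,
  close-microphone recordings of a guided speech task; none is
  noise-robust.
- The GOP acoustic model is trained on the synthetic phone inventory;
  scores on real speech would require retraining on a real corpus, and the
  absolute scale of precision scores is model-dependent either way.
- Pitch variance on the raw Hz² scale conflates within-speaker variation
  with register; a perceptual (semitone) scale is a possible alternative
  not used here.
- Random-slope models on small cohorts frequently sit at the variance
  boundary; such fits are reported with their convergence flags rather
  than silently dropped or forced.
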