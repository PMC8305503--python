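# pthspeech

Longitudinal speech-biomarker analysis for post-traumatic headache (PTH)
after mild traumatic brain injury. Speech changes measurably during headache
— slower sentence reading, longer pauses, altered articulation — and a short
speech task repeated every few days can track that burden objectively. This
package implements the full analysis chain for such a study, for speech
scientists and biostatisticians: acoustic feature extraction from the
recordings, normative percentile normalization, and longitudinal
mixed-effects modelling, together with a synthetic-data module that
generates audio and cohorts with known ground truth so every stage is
verifiable without access to clinical recordings.

## The measures and models

Per visit, a participant reads five fixed sentences and speaks spontaneously
for a short period. Seven measures are extracted:

| measure | task | definition |
|---|---|---|
| sentence speaking rate | reading | prompt syllables / detected speaking time (syll/s) |
| spontaneous pause rate | spontaneous | internal pause time / onset-to-offset span |
| average pitch | reading | sample mean of the voiced f0 contour (Hz) |
| pitch variance | reading | sample variance (n−1) of the voiced f0 contour (Hz²) |
| vowel articulation precision | reading | mean goodness-of-pronunciation (GOP) over vowel phones |
| consonant articulation precision | reading | mean GOP over consonant phones |
| vowel space area | reading | convex-hull area of the voiced (F1, F2) cloud (Hz²) |

Speaking time is onset-to-offset, so 15 syllables read over a 4.01 s span
give 15/4.01 = 3.74 syll/s, and 2.13 s of internal pauses in a 10.82 s span
give a pause rate of 2.13/10.82 = 0.197. GOP scores a phone segment *X* of
*d* frames against an acoustic model as

    GOP = (1/d) [ log L(X | intended phone) − max_q log L(X | q) ] ≤ 0,

zero when the intended phone beats every competitor. The five
sentence-task scalar measures are mapped to percentiles of an empirical CDF
over an age/sex-matched subset of a normative corpus (midrank convention);
vowel space area and pause rate stay on their raw scales.

Cohort inference uses linear mixed models fitted by maximum likelihood:
between groups (samples from the first 30 days),
`y ~ age + sex + group + (1 | subject)`; within PTH subjects (first
90 days), headache vs headache-free days with either a random intercept or
an additional per-subject random slope for headache status. Each effect is
tested by a chi-squared likelihood-ratio test against the model without the
group/headache term; raw group means and their difference are reported
alongside for direction. P-values are per-feature and unadjusted.

## Worked example

Synthesize one visit (five sentence readings, sentence 1 rendered at a
4.01 s speaking span, plus a spontaneous sample with 2.13 s of pauses in a
10.82 s span) and extract its features:

```python
import pthspeech as p
from pthspeech.synthetic_data import plan_for_prompt, plan_spontaneous, synthesize_sentence
from pthspeech.pipeline import extract_visit_features, RunConfig

sentences = []
for i, prompt in enumerate(p.load_prompts()):
    span = 4.01 if i == 0 else None
    audio, _, _ = synthesize_sentence(plan_for_prompt(prompt, speech_duration_s=span),
                                      16000, seed=10 + i)
    sentences.append(audio)
spont, _, _ = synthesize_sentence(plan_spontaneous(), 16000, seed=99)
for name, value in extract_visit_features(sentences, spont, RunConfig()).items():
    print(f"{name:22s} {value:12.4f}")
```

```
speaking_rate                4.2656
mean_pitch                 120.1078
pitch_variance               2.5863
vowel_precision           -838.9336
consonant_precision       -386.2927
vowel_space_area        493210.1836
pause_rate                   0.1965
```

The pause rate recovers the programmed 0.197; mean pitch recovers the
programmed 120 Hz source; the speaking rate is the mean over the five
sentences (sentence 1 alone yields 3.74 syll/s). GOP precisions are
negative log-likelihood ratios — closer to zero is more precise — and the
vowel space area is the F1–F2 hull of the synthetic vowel inventory.

A command-line interface mirrors the library:

```bash
pthspeech simulate --kind cohort --seed 1 --out cohort.csv
pthspeech analyze --features cohort.csv --out-dir results/
pthspeech report --results-dir results/
```

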