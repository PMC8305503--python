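"""Synthetic study inputs with exact ground truth.

Three generators stand in for data the study design requires:

* **Speech audio** — source-filter synthesis (impulse-train glottal source
  through cascaded second-order formant resonators; consonants as
  band-limited noise bursts) with programmed f0, formants, phone timing and
  silent pauses, so pitch, formant, VAD and alignment estimates can be
  checked against known truth.
* **A normative corpus** — age/sex-stratified feature records emulating the
  role of a large sentence-reading reference population for percentile
  normalization.
* **A longitudinal cohort** — subjects visiting every 3 days over 12 weeks
  (defaults 19 PTH / 31 HC), with per-subject random intercepts, a
  per-subject random headache slope, and known group/headache effects, for
  parameter-recovery tests of the mixed models.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .articulation import AcousticModel, mfcc_features, train_acoustic_model
from .audio_core import AudioSignal
from .cohort_analysis import SpeechSample
from .normalization import FeatureVector, NormativeRecord
from .prosody import VOWEL_PHONES, phonetize
from .segmentation import SpeechSegmentation

# --------------------------------------------------------------------------
# phone synthesis specifications

@dataclass(frozen=True)
class VowelSpec:
    """A steady synthetic vowel: pitch, three formants, duration, level."""

    f0_hz: float
    formant_freqs_hz: Tuple[float, float, float]
    formant_bandwidths_hz: Tuple[float, float, float] = (80.0, 100.0, 140.0)
    duration_s: float = 0.5
    amplitude: float = 0.5

    def __post_init__(self) -> None:
        f = self.formant_freqs_hz
        if not (0 < f[0] < f[1] < f[2]):
            raise ValueError("formants must be strictly increasing")
        if self.duration_s <= 0 or not (0 < self.amplitude <= 1):
            raise ValueError("invalid duration or amplitude")


#: Canonical (F1, F2, F3) targets for the vowels of the reading prompts,
#: typical adult American English values.
VOWEL_FORMANTS: Dict[str, Tuple[float, float, float]] = {
    "IY": (270, 2290, 3010),
    "IH": (390, 1990, 2550),
    "EH": (530, 1840, 2480),
    "AE": (660, 1720, 2410),
    "AA": (730, 1090, 2440),
    "AO": (570, 840, 2410),
    "UW": (300, 870, 2240),
    "UH": (440, 1020, 2240),
    "AH": (640, 1190, 2390),
    "ER": (490, 1350, 1690),
    "EY": (400, 2100, 2600),
    "AY": (660, 1400, 2500),
    "AW": (700, 1200, 2400),
    "OW": (450, 900, 2400),
    "OY": (500, 1100, 2500),
}

#: Sonorant consonants rendered as weak vowel-like resonances.
SONORANT_FORMANTS: Dict[str, Tuple[float, float, float]] = {
    "M": (250, 1000, 2200),
    "N": (250, 1400, 2300),
    "NG": (280, 2000, 2600),
    "R": (310, 1060, 1380),
    "L": (360, 1300, 2700),
    "W": (300, 700, 2200),
    "Y": (280, 2200, 3000),
}

#: Obstruent consonants rendered as band-limited noise: (lo_hz, hi_hz, amp).
NOISE_BANDS: Dict[str, Tuple[float, float, float]] = {
    "S": (4000, 7500, 0.20),
    "Z": (3500, 7000, 0.20),
    "SH": (2000, 5500, 0.25),
    "ZH": (1900, 5200, 0.22),
    "CH": (2200, 6000, 0.25),
    "JH": (1800, 5200, 0.25),
    "F": (1200, 7000, 0.12),
    "V": (500, 2500, 0.15),
    "TH": (1400, 6500, 0.10),
    "DH": (600, 3000, 0.12),
    "HH": (500, 4000, 0.10),
    "T": (3000, 6500, 0.18),
    "D": (2500, 5500, 0.18),
    "K": (1400, 3500, 0.18),
    "G": (1100, 2800, 0.18),
    "P": (500, 1500, 0.15),
    "B": (400, 1200, 0.15),
}

#: Nominal phone durations (seconds) before any rescaling.
_DUR_VOWEL = 0.12
_DUR_SONORANT = 0.08
_DUR_FRICATIVE = 0.08
_DUR_STOP = 0.05
_STOPS = frozenset("T D K G P B".split())


def _phone_duration(label: str) -> float:
    base = label.rstrip("012")
    if base in VOWEL_PHONES:
        return _DUR_VOWEL
    if base in SONORANT_FORMANTS:
        return _DUR_SONORANT
    if base in _STOPS:
        return _DUR_STOP
    return _DUR_FRICATIVE


# --------------------------------------------------------------------------
# waveform synthesis

def synthesize_vowel(spec: VowelSpec, sample_rate: int) -> AudioSignal:
    """Impulse train at f0 through cascaded formant resonators."""
    nyquist = sample_rate / 2
    if max(spec.formant_freqs_hz) >= nyquist:
        raise ValueError("formant above Nyquist")
    n = int(round(spec.duration_s * sample_rate))
    source = np.zeros(n)
    period = sample_rate / spec.f0_hz
    pulses = np.round(np.arange(0, n, period)).astype(int)
    source[pulses[pulses < n]] = 1.0
    y = source
    for freq, bw in zip(spec.formant_freqs_hz, spec.formant_bandwidths_hz):
        r = np.exp(-np.pi * bw / sample_rate)
        theta = 2 * np.pi * freq / sample_rate
        a = [1.0, -2 * r * np.cos(theta), r * r]
        y = sps.lfilter([1.0], a, y)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = y * (spec.amplitude / peak)
    return AudioSignal(samples=y, sample_rate=sample_rate)


def _band_noise(lo: float, hi: float, amp: float, duration_s: float,
                sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration_s * sample_rate))
    hi = min(hi, sample_rate / 2 - 100)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    noise = sps.sosfilt(sos, rng.standard_normal(n))
    peak = np.max(np.abs(noise))
    return noise * (amp / peak) if peak > 0 else noise


def synthesize_phone(
    label: str,
    duration_s: float,
    sample_rate: int,
    rng: np.random.Generator,
    f0_hz: float = 120.0,
    formant_scale: float = 1.0,
    amplitude: float = 0.5,
) -> np.ndarray:
    """Audio for one phone; vowels/sonorants are voiced, obstruents noise."""
    base = label.rstrip("012")
    if base in VOWEL_PHONES or base in SONORANT_FORMANTS:
        formants = VOWEL_FORMANTS.get(base) or SONORANT_FORMANTS[base]
        level = amplitude if base in VOWEL_PHONES else amplitude * 0.6
        scaled = tuple(min(f * formant_scale, sample_rate / 2 - 200) for f in formants)
        spec = VowelSpec(
            f0_hz=f0_hz,
            formant_freqs_hz=scaled,  # type: ignore[arg-type]
            duration_s=duration_s,
            amplitude=level,
        )
        return synthesize_vowel(spec, sample_rate).samples
    if base in NOISE_BANDS:
        lo, hi, amp = NOISE_BANDS[base]
        return _band_noise(lo, hi, amp, duration_s, sample_rate, rng)
    raise ValueError(f"no synthesis spec for phone {label!r}")


# --------------------------------------------------------------------------
# sentence plans

@dataclass(frozen=True)
class PlanSegment:
    label: str  # phone label, or "SIL" for a pause
    duration_s: float
    formant_scale: float = 1.0

    @property
    def is_pause(self) -> bool:
        return self.label == "SIL"


@dataclass(frozen=True)
class SentencePlan:
    segments: Tuple[PlanSegment, ...]
    f0_hz: float = 120.0

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    @property
    def speech_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments if not s.is_pause)

    def phone_labels(self) -> List[str]:
        return [s.label for s in self.segments if not s.is_pause]


def plan_for_prompt(
    sentence_text: str,
    speech_duration_s: Optional[float] = None,
    f0_hz: float = 120.0,
    formant_jitter: float = 0.0,
    jitter_seed: int = 0,
) -> SentencePlan:
    """Build a phone-by-phone plan for a reading prompt.

    Per-phone durations follow nominal values, rescaled so the voiced span
    totals ``speech_duration_s`` when given. ``formant_jitter`` applies a
    multiplicative perturbation of that relative magnitude to each vowel's
    formants (seeded), emulating imprecise articulation.
    """
    words = [w for w in sentence_text.split() if any(c.isalpha() for c in w)]
    phones: List[str] = []
    for word in words:
        pron = phonetize(word)
        if pron is None:
            raise ValueError(f"word {word!r} not in bundled lexicon")
        phones.extend(pron)
    durations = np.array([_phone_duration(p) for p in phones])
    if speech_duration_s is not None:
        durations = durations * (speech_duration_s / durations.sum())
    rng = np.random.default_rng(jitter_seed)
    segments = []
    for label, dur in zip(phones, durations):
        scale = 1.0
        if formant_jitter > 0 and label.rstrip("012") in VOWEL_PHONES:
            scale = 1.0 + formant_jitter * rng.uniform(-1.0, 1.0)
        segments.append(PlanSegment(label=label, duration_s=float(dur), formant_scale=scale))
    return SentencePlan(segments=tuple(segments), f0_hz=f0_hz)


def plan_spontaneous(
    span_s: float = 10.82,
    pause_total_s: float = 2.13,
    n_pauses: int = 3,
    f0_hz: float = 120.0,
) -> SentencePlan:
    """A spontaneous-speech-like plan: speech chunks separated by pauses.

    The onset-to-offset span equals ``span_s`` and the internal pauses sum
    to ``pause_total_s``, so the programmed pause rate is
    pause_total_s / span_s.
    """
    if not 0 <= pause_total_s < span_s:
        raise ValueError("pause total must be shorter than the span")
    chunk_phones = ["AA1", "M", "IY1", "D", "OW1", "N", "EH1", "S"]
    n_chunks = n_pauses + 1 if pause_total_s > 0 else 1
    speech_total = span_s - pause_total_s
    chunk_s = speech_total / n_chunks
    pause_s = pause_total_s / n_pauses if n_pauses else 0.0
    segments: List[PlanSegment] = []
    for c in range(n_chunks):
        durs = np.array([_phone_duration(p) for p in chunk_phones])
        durs = durs * (chunk_s / durs.sum())
        for label, dur in zip(chunk_phones, durs):
            segments.append(PlanSegment(label=label, duration_s=float(dur)))
        if c < n_chunks - 1:
            segments.append(PlanSegment(label="SIL", duration_s=pause_s))
    return SentencePlan(segments=tuple(segments), f0_hz=f0_hz)


def synthesize_sentence(
    plan: SentencePlan,
    sample_rate: int = 16000,
    seed: int = 0,
    leading_silence_s: float = 0.2,
    trailing_silence_s: float = 0.2,
) -> Tuple[AudioSignal, SpeechSegmentation, List[Tuple[str, float, float]]]:
    """Render a plan to audio with ground-truth timing.

    Returns the waveform, the true speech/pause segmentation, and the true
    phone boundaries as (label, start_s, end_s) in signal time.
    """
    rng = np.random.default_rng(seed)
    pieces = [np.zeros(int(round(leading_silence_s * sample_rate)))]
    t = leading_silence_s
    boundaries: List[Tuple[str, float, float]] = []
    speech_intervals: List[List[float]] = []
    for seg in plan.segments:
        n = int(round(seg.duration_s * sample_rate))
        if seg.is_pause:
            pieces.append(np.zeros(n))
        else:
            audio = synthesize_phone(
                seg.label, seg.duration_s, sample_rate, rng,
                f0_hz=plan.f0_hz, formant_scale=seg.formant_scale,
            )
            # short cross-fade ramps avoid clicks at phone joins
            ramp = min(32, audio.size // 4)
            if ramp > 0:
                audio = audio.copy()
                audio[:ramp] *= np.linspace(0, 1, ramp)
                audio[-ramp:] *= np.linspace(1, 0, ramp)
            pieces.append(audio)
            boundaries.append((seg.label, t, t + n / sample_rate))
            if speech_intervals and abs(speech_intervals[-1][1] - t) < 1e-9:
                speech_intervals[-1][1] = t + n / sample_rate
            else:
                speech_intervals.append([t, t + n / sample_rate])
        t += n / sample_rate
    pieces.append(np.zeros(int(round(trailing_silence_s * sample_rate))))
    samples = np.concatenate(pieces)
    sig = AudioSignal(samples=samples, sample_rate=sample_rate)
    truth = SpeechSegmentation(
        speech_intervals=tuple((s, e) for s, e in speech_intervals),
        total_duration_s=sig.duration_s,
    )
    return sig, truth, boundaries


# --------------------------------------------------------------------------
# acoustic model trained on the synthetic phone inventory

@lru_cache(maxsize=4)
def default_acoustic_model(sample_rate: int = 16000, seed: int = 0) -> AcousticModel:
    """Per-phone diagonal Gaussians trained on synthesized phone examples.

    Each phone in the synthesis inventory is rendered at several pitches
    and durations; MFCC frames from all renditions train the Gaussian.
    """
    rng = np.random.default_rng(seed)
    inventory = sorted(set(VOWEL_FORMANTS) | set(SONORANT_FORMANTS) | set(NOISE_BANDS))
    examples: Dict[str, List[np.ndarray]] = {}
    for phone in inventory:
        feats = []
        for f0 in (100.0, 140.0, 200.0):
            for dur in (0.12, 0.2):
                audio = synthesize_phone(phone, dur, sample_rate, rng, f0_hz=f0)
                mf, _ = mfcc_features(AudioSignal(audio, sample_rate))
                if mf.shape[0]:
                    feats.append(mf)
        examples[phone] = feats
    return train_acoustic_model(examples)


# --------------------------------------------------------------------------
# normative corpus

def generate_normative_corpus(n: int, seed: int = 0) -> List[NormativeRecord]:
    """Synthetic age/sex-stratified normative feature records.

    Ages uniform on [18, 75]; sexes balanced. Feature distributions encode
    the stylized facts the normalization is meant to remove: female mean
    pitch ~210 Hz vs male ~120 Hz, speaking rate declining 0.005 syll/s per
    year of age, and age/sex-free articulation-precision scores.
    """
    if n < 100:
        raise ValueError("need n >= 100 for a usable reference corpus")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 75, size=n)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    records = []
    for age, sex in zip(ages, sexes):
        male = sex == "male"
        features = {
            "speaking_rate": 4.2 - 0.005 * (age - 18) + rng.normal(0, 0.4),
            "mean_pitch": (120.0 if male else 210.0) - 0.2 * (age - 18) + rng.normal(0, 15),
            "pitch_variance": float(rng.gamma(4.0, 100.0)),
            "vowel_precision": min(0.0, rng.normal(-1.0, 0.3)),
            "consonant_precision": min(0.0, rng.normal(-1.5, 0.4)),
        }
        records.append(NormativeRecord(age=float(age), sex=str(sex), features=features))
    return records


# --------------------------------------------------------------------------
# longitudinal cohort simulation

@dataclass(frozen=True)
class FeatureEffect:
    """Generative parameters for one speech measure."""

    population_mean: float
    intercept_sd: float
    residual_sd: float
    group_effect: float = 0.0     # added for PTH subjects
    headache_effect: float = 0.0  # mean shift on headache days (PTH)
    slope_sd: float = 0.0         # between-subject SD of the headache shift
    age_slope: float = 0.0        # per year, centred at age 40
    sex_effect: float = 0.0       # added for male subjects


#: Default generative parameters. Directions follow the study's findings:
#: PTH shows longer pauses and less precise articulation; headache days show
#: slower speech and longer pauses. Magnitudes are plausible fractions of
#: the between-subject spread.
DEFAULT_EFFECTS: Dict[str, FeatureEffect] = {
    "speaking_rate": FeatureEffect(4.0, 0.30, 0.25, group_effect=-0.10,
                                   headache_effect=-0.20, slope_sd=0.10,
                                   age_slope=-0.005, sex_effect=0.10),
    "pause_rate": FeatureEffect(0.20, 0.05, 0.05, group_effect=0.05,
                                headache_effect=0.04, slope_sd=0.02,
                                age_slope=0.0005),
    "mean_pitch": FeatureEffect(210.0, 20.0, 10.0, sex_effect=-90.0,
                                age_slope=-0.2, slope_sd=2.0),
    "pitch_variance": FeatureEffect(400.0, 80.0, 60.0, sex_effect=-100.0,
                                    slope_sd=10.0),
    "vowel_precision": FeatureEffect(-1.0, 0.20, 0.15, group_effect=-0.15,
                                     headache_effect=-0.05, slope_sd=0.05),
    "consonant_precision": FeatureEffect(-1.5, 0.25, 0.20, group_effect=-0.20,
                                         headache_effect=-0.10, slope_sd=0.05),
    "vowel_space_area": FeatureEffect(250000.0, 40000.0, 30000.0,
                                      group_effect=-20000.0,
                                      headache_effect=-10000.0,
                                      slope_sd=5000.0, sex_effect=30000.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated longitudinal cohort (study defaults)."""

    n_pth: int = 19
    n_hc: int = 31
    visit_interval_days: int = 3
    duration_weeks: int = 12
    headache_probability: float = 0.36
    missed_visit_probability: float = 0.0
    effects: Dict[str, FeatureEffect] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    seed: int = 0

    def visit_days(self) -> List[int]:
        return list(range(0, self.duration_weeks * 7 + 1, self.visit_interval_days))


def simulate_cohort(spec: CohortSpec) -> List[SpeechSample]:
    """Simulate per-visit speech measures under the mixed-model structure.

    response = mean + age/sex terms + group effect + subject intercept
             + (headache effect + subject slope deviation) * headache day
             + residual,
    with visits every ``visit_interval_days`` through ``duration_weeks``.
    """
    from .normalization import ALL_FEATURES

    unknown = set(spec.effects) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"effects for unknown features: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    samples: List[SpeechSample] = []
    days = spec.visit_days()
    subjects = [("PTH", i) for i in range(spec.n_pth)] + [("HC", i) for i in range(spec.n_hc)]
    for group, idx in subjects:
        pth = group == "PTH"
        age = float(np.clip(rng.normal(42.5 if pth else 38.7, 13.7 if pth else 12.5), 18, 65))
        p_female = 13 / 19 if pth else 18 / 31
        sex = "female" if rng.random() < p_female else "male"
        male = sex == "male"
        intercepts = {k: rng.normal(0.0, e.intercept_sd) for k, e in spec.effects.items()}
        slopes = {
            k: rng.normal(e.headache_effect, e.slope_sd) if pth else 0.0
            for k, e in spec.effects.items()
        }
        for day in days:
            if rng.random() < spec.missed_visit_probability:
                continue
            headache = bool(pth and rng.random() < spec.headache_probability)
            intensity = int(np.clip(round(rng.normal(4.5, 2.1)), 1, 10)) if headache else None
            values: Dict[str, float] = {name: float("nan") for name in ALL_FEATURES}
            for name, e in spec.effects.items():
                mu = (
                    e.population_mean
                    + e.age_slope * (age - 40.0)
                    + (e.sex_effect if male else 0.0)
                    + (e.group_effect if pth else 0.0)
                    + intercepts[name]
                    + (slopes[name] if headache else 0.0)
                )
                values[name] = mu + rng.normal(0.0, e.residual_sd)
            samples.append(
                SpeechSample(
                    subject_id=f"{group}{idx:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    day=day,
                    headache_present=headache,
                    headache_intensity=intensity,
                    features=FeatureVector(**values),
                )
            )
    return samples
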