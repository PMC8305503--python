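"""Prosodic features: speaking rate, pause rate, and pitch statistics.

Sentence speaking rate is the syllable count of the known reading prompt
divided by the detected speaking time (syllables/second); with 15 syllables
read in 4.01 s the rate is 15/4.01 = 3.74 syll/s. The spontaneous pause
rate is internal pause time divided by the onset-to-offset span (2.13 s of
pauses in a 10.82 s span gives 0.197).

Pitch is estimated by frame-wise normalized autocorrelation over a
configurable f0 search band; average pitch and pitch variance are the
sample mean and sample variance (n-1 denominator) of the voiced frames of
the contour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np

from .audio_core import AudioSignal, frame_signal
from .errors import EmptyPromptError, InsufficientVoicingError, NoSpeechError
from .segmentation import SpeechSegmentation, pause_time, speaking_time

# --------------------------------------------------------------------------
# syllable counting from the reading prompt

_VOWEL_RE = re.compile(r"[AEIOU]+[0-9]$|[AEIOU]+[0-9]?")


def _load_lexicon() -> Dict[str, List[str]]:
    text = resources.files("pthspeech.data").joinpath("lexicon.txt").read_text()
    lex: Dict[str, List[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, *phones = line.split()
        lex[word] = phones
    return lex


_LEXICON = _load_lexicon()

#: ARPAbet vowel symbols (stress digit stripped).
VOWEL_PHONES = frozenset(
    "AA AE AH AO AW AY EH ER EY IH IY OW OY UH UW".split()
)


def load_prompts() -> List[str]:
    """The five fixed sentence-reading prompts, in task order."""
    text = resources.files("pthspeech.data").joinpath("prompts.txt").read_text()
    prompts = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            prompts.append(line.split(". ", 1)[1])
    return prompts


def phonetize(word: str) -> List[str] | None:
    """Lexicon pronunciation for a word, or None if out of lexicon."""
    return _LEXICON.get(re.sub(r"[^A-Za-z']", "", word).upper())


def _heuristic_syllables(word: str) -> int:
    """Orthographic vowel-cluster count with a silent-final-e correction."""
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        return 0
    clusters = len(re.findall(r"[aeiouy]+", w))
    if w.endswith("e") and not w.endswith("le") and clusters > 1:
        clusters -= 1
    return max(clusters, 1)


def count_syllables(sentence_text: str) -> int:
    """Count syllables in a prompt as lexicon vowel nuclei (heuristic fallback)."""
    words = [w for w in re.split(r"\s+", sentence_text.strip()) if re.search(r"[A-Za-z]", w)]
    if not words:
        raise EmptyPromptError("empty sentence prompt")
    total = 0
    for word in words:
        phones = phonetize(word)
        if phones is not None:
            total += sum(1 for p in phones if p[-1].isdigit())
        else:
            total += _heuristic_syllables(word)
    return total


# --------------------------------------------------------------------------
# rates

def sentence_speaking_rate(syllable_count: int, seg: SpeechSegmentation) -> float:
    """Syllables per second over the detected speaking span."""
    if syllable_count <= 0:
        raise ValueError("syllable_count must be positive")
    return syllable_count / speaking_time(seg)


def spontaneous_pause_rate(seg: SpeechSegmentation) -> float:
    """Ratio of internal pause time to the speaking span."""
    return pause_time(seg) / speaking_time(seg)


# --------------------------------------------------------------------------
# pitch

@dataclass(frozen=True)
class PitchContour:
    times_s: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray


@dataclass(frozen=True)
class ProsodyFeatures:
    speaking_rate_syl_per_s: float
    pause_rate: float
    mean_pitch_hz: float
    pitch_variance_hz2: float


#: Frame/hop for pitch analysis; 40 ms frames hold >= 2 periods at 50 Hz.
PITCH_FRAME_S = 0.040
PITCH_HOP_S = 0.010
VOICING_THRESHOLD = 0.5


def estimate_pitch(
    signal: AudioSignal,
    f0_min: float = 50.0,
    f0_max: float = 400.0,
) -> PitchContour:
    """Estimate an f0 contour by normalized autocorrelation peak search.

    Each frame is mean-removed; the normalized autocorrelation is searched
    in the lag band [1/f0_max, 1/f0_min]. To avoid octave (period-doubling)
    errors the shortest lag whose local peak reaches 90% of the band maximum
    is taken, refined by parabolic interpolation. Frames whose peak
    correlation falls below the voicing threshold are marked unvoiced.
    Deterministic for fixed input.
    """
    if signal.samples.size == 0:
        raise ValueError("signal is empty")
    sr = signal.sample_rate
    if not (0 < f0_min < f0_max < sr / 2):
        raise ValueError("need 0 < f0_min < f0_max < Nyquist")
    frames = frame_signal(signal, PITCH_FRAME_S, PITCH_HOP_S)
    lag_min = max(2, int(np.floor(sr / f0_max)))
    lag_max = int(np.ceil(sr / f0_min))
    n = len(frames)
    f0 = np.zeros(n)
    voiced = np.zeros(n, dtype=bool)
    centre = frames.frame_length_s / 2.0
    for i in range(n):
        x = frames.frames[i] - frames.frames[i].mean()
        energy = np.dot(x, x)
        if energy <= 0:
            continue
        L = x.size
        hi = min(lag_max, L - 1)
        if hi <= lag_min:
            continue
        lags = np.arange(lag_min, hi + 1)
        # normalized autocorrelation r(k) = sum x[n] x[n+k] / sqrt(E0 Ek)
        full = np.correlate(x, x, mode="full")[L - 1:]
        csum = np.concatenate(([0.0], np.cumsum(x * x)))
        e0 = csum[L - lags] - csum[0]
        ek = csum[L] - csum[lags]
        denom = np.sqrt(np.maximum(e0 * ek, 1e-20))
        r = full[lags] / denom
        peak_mask = np.zeros_like(r, dtype=bool)
        if r.size >= 3:
            peak_mask[1:-1] = (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])
        if not peak_mask.any():
            continue
        best = r[peak_mask].max()
        if best < VOICING_THRESHOLD:
            continue
        candidates = np.where(peak_mask & (r >= 0.9 * best))[0]
        k = candidates[0]
        lag = float(lags[k])
        if 0 < k < r.size - 1:  # parabolic refinement
            denom2 = r[k - 1] - 2 * r[k] + r[k + 1]
            if denom2 < 0:
                lag += 0.5 * (r[k - 1] - r[k + 1]) / denom2
        f0_i = sr / lag
        if f0_min <= f0_i <= f0_max:
            f0[i] = f0_i
            voiced[i] = True
    return PitchContour(times_s=frames.origin_times + centre, f0_hz=f0, voiced=voiced)


def pitch_statistics(contour: PitchContour) -> Tuple[float, float]:
    """Sample mean and sample variance (n-1) of voiced-frame f0."""
    f0 = contour.f0_hz[contour.voiced]
    if f0.size < 2:
        raise InsufficientVoicingError("need at least 2 voiced frames")
    return float(f0.mean()), float(f0.var(ddof=1))


def pitch_contour_table(contour: PitchContour):
    """Contour export as a DataFrame (time_s, f0_hz, voiced)."""
    import pandas as pd

    return pd.DataFrame(
        {"time_s": contour.times_s, "f0_hz": contour.f0_hz, "voiced": contour.voiced}
    )
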