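import numpy as np
import pytest
from scipy import signal as sps

from pthspeech.audio_core import AudioSignal
from pthspeech.synthetic_data import (
    VowelSpec,
    default_acoustic_model,
    plan_for_prompt,
    plan_spontaneous,
    synthesize_sentence,
    synthesize_vowel,
)

SENTENCE_1 = "The supermarket chain shut down because of poor management."


@pytest.fixture(scope="session")
def acoustic_model():
    return default_acoustic_model(16000, 0)


@pytest.fixture(scope="session")
def vowel_700_1200():
    spec = VowelSpec(f0_hz=120.0, formant_freqs_hz=(700, 1200, 2400), duration_s=0.6)
    return synthesize_vowel(spec, 16000)


@pytest.fixture(scope="session")
def speech_noise_burst():
    """1 s silence + 2 s of speech-band noise at 0.3 amplitude + 1 s silence."""
    rng = np.random.default_rng(1)
    sos = sps.butter(4, [300, 3000], btype="bandpass", fs=16000, output="sos")
    noise = sps.sosfilt(sos, rng.standard_normal(32000))
    noise = 0.3 * noise / np.abs(noise).max()
    samples = np.concatenate([np.zeros(16000), noise, np.zeros(16000)])
    return AudioSignal(samples, 16000)


@pytest.fixture(scope="session")
def sentence1_reading():
    """Sentence 1 synthesized to a 4.01 s speaking span (truth attached)."""
    plan = plan_for_prompt(SENTENCE_1, speech_duration_s=4.01)
    return synthesize_sentence(plan, 16000, seed=2)


@pytest.fixture(scope="session")
def spontaneous_sample():
    """Spontaneous-task audio: 10.82 s span with 2.13 s of internal pauses."""
    plan = plan_spontaneous(span_s=10.82, pause_total_s=2.13, n_pauses=3)
    return synthesize_sentence(plan, 16000, seed=3)
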