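"""Audio I/O, framing, and short-time signal utilities.

All downstream stages operate on :class:`AudioSignal`, a float waveform in
[-1, 1] with its sample rate. Amplitudes are normalized at the I/O boundary
so thresholds elsewhere in the pipeline are independent of bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .errors import AudioFormatError, EmptySignalError

#: Default short-time analysis window (seconds).
DEFAULT_FRAME_S = 0.025
#: Default hop between analysis windows (seconds).
DEFAULT_HOP_S = 0.010


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitude values, nominal range [-1, 1], finite.
    sample_rate : int
        Sampling rate in Hz, positive.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FrameSequence:
    """Fixed-length windows cut from a signal at a constant hop."""

    frames: np.ndarray  # shape (n_frames, frame_length)
    frame_length_s: float
    hop_s: float
    origin_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.frames)


def read_wav(path) -> AudioSignal:
    """Read a PCM WAV file into a mono, [-1, 1]-scaled :class:`AudioSignal`.

    Integer PCM is scaled by its full-scale value (1/32768 for 16-bit);
    multi-channel audio is mean-downmixed to mono.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wavfile raises plain ValueError
        raise AudioFormatError(f"cannot read {path!r} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise EmptySignalError(f"{path!r} contains no audio samples")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim > 1:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(signal: AudioSignal, path) -> None:
    """Write a signal as 16-bit PCM WAV; round-trips within one LSB."""
    if signal.samples.size == 0:
        raise EmptySignalError("refusing to write an empty signal")
    clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
    pcm = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(path, signal.sample_rate, pcm)


def frame_signal(
    signal: AudioSignal,
    frame_length_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
) -> FrameSequence:
    """Cut a signal into overlapping fixed-length frames.

    A trailing partial frame is discarded; a signal shorter than one frame
    yields an empty sequence. Frame count is floor((N - L) / H) + 1.
    """
    if hop_s <= 0 or frame_length_s <= 0 or hop_s > frame_length_s:
        raise ValueError("need 0 < hop_s <= frame_length_s")
    sr = signal.sample_rate
    length = int(round(frame_length_s * sr))
    hop = int(round(hop_s * sr))
    n = signal.samples.size
    if n < length:
        return FrameSequence(
            frames=np.empty((0, length)),
            frame_length_s=frame_length_s,
            hop_s=hop_s,
            origin_times=np.empty(0),
        )
    count = (n - length) // hop + 1
    starts = np.arange(count) * hop
    idx = starts[:, None] + np.arange(length)[None, :]
    return FrameSequence(
        frames=signal.samples[idx],
        frame_length_s=frame_length_s,
        hop_s=hop_s,
        origin_times=starts / sr,
    )
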