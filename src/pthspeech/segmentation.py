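"""Voice activity detection (VAD) and speech/pause timing.

Frame log-energies are thresholded relative to the 95th-percentile frame
energy, so the segmentation is invariant to global amplitude scaling.
Short non-speech gaps are smoothed over ("hangover"), gaps shorter than
``min_pause_s`` are merged, and speech runs shorter than ``min_speech_s``
are dropped. Speaking time is defined as the onset-to-offset span, which
includes internal pauses; pause time is the non-speech part of that span.
Leading and trailing silence count toward neither, so results do not depend
on how long the speaker waits before talking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .audio_core import AudioSignal, frame_signal
from .errors import NoSpeechError

_ENERGY_FLOOR = 1e-12


@dataclass(frozen=True)
class VadConfig:
    """Tunable VAD parameters.

    The 20 ms / 10 ms frame grid makes each frame decision attributable to
    a single hop-wide stretch of signal, keeping detected boundaries within
    one hop of the true onset/offset on clean audio.
    """

    frame_length_s: float = 0.020
    hop_s: float = 0.010
    energy_threshold_db: float = 35.0
    min_speech_s: float = 0.100
    min_pause_s: float = 0.150
    hangover_frames: int = 3

    def __post_init__(self) -> None:
        if min(self.frame_length_s, self.hop_s, self.energy_threshold_db,
               self.min_speech_s, self.min_pause_s) <= 0 or self.hangover_frames <= 0:
            raise ValueError("all VAD parameters must be positive")
        if self.min_pause_s < self.hop_s:
            raise ValueError("min_pause_s must be >= hop_s")


@dataclass(frozen=True)
class SpeechSegmentation:
    """Ordered, disjoint speech intervals within a recording."""

    speech_intervals: Tuple[Tuple[float, float], ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end in self.speech_intervals:
            if not (0.0 <= start < end <= self.total_duration_s + 1e-9):
                raise ValueError(f"interval ({start}, {end}) outside signal")
            if start < prev_end:
                raise ValueError("speech intervals must be sorted and disjoint")
            prev_end = end

    @property
    def span_start_s(self) -> float:
        if not self.speech_intervals:
            raise NoSpeechError("no speech intervals")
        return self.speech_intervals[0][0]

    @property
    def span_end_s(self) -> float:
        if not self.speech_intervals:
            raise NoSpeechError("no speech intervals")
        return self.speech_intervals[-1][1]


def _fill_short_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Set to True any False run of length <= max_gap flanked by True."""
    out = mask.copy()
    n = len(mask)
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            if 0 < i and j < n and (j - i) <= max_gap:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def detect_voice_activity(signal: AudioSignal, config: VadConfig = VadConfig()) -> SpeechSegmentation:
    """Segment a recording into speech intervals by relative-energy VAD.

    Deterministic for fixed input and config. An all-silence input returns
    a segmentation with no speech intervals (not an error).
    """
    if signal.samples.size == 0:
        raise ValueError("signal is empty")
    frames = frame_signal(signal, config.frame_length_s, config.hop_s)
    duration = signal.duration_s
    if len(frames) == 0:
        return SpeechSegmentation(speech_intervals=(), total_duration_s=duration)

    energy = np.maximum(np.mean(frames.frames ** 2, axis=1), _ENERGY_FLOOR)
    energy_db = 10.0 * np.log10(energy)
    ref_db = np.percentile(energy_db, 95)
    mask = energy_db > ref_db - config.energy_threshold_db
    if ref_db <= 10.0 * np.log10(_ENERGY_FLOOR) + 1e-9:
        # digital silence throughout
        return SpeechSegmentation(speech_intervals=(), total_duration_s=duration)

    mask = _fill_short_gaps(mask, config.hangover_frames)

    # fine-grained (2 ms) energies for sub-frame boundary refinement
    fine_w = max(1, int(round(0.002 * signal.sample_rate)))
    n_fine = signal.samples.size // fine_w
    fine = signal.samples[: n_fine * fine_w].reshape(n_fine, fine_w)
    fine_db = 10.0 * np.log10(np.maximum(np.mean(fine ** 2, axis=1), _ENERGY_FLOOR))
    fine_active = fine_db > ref_db - config.energy_threshold_db
    fine_step = fine_w / signal.sample_rate

    def _refine(t: float, kind: str) -> float:
        lo = max(0, int((t - config.frame_length_s) / fine_step))
        hi = min(n_fine, int((t + config.frame_length_s) / fine_step) + 1)
        idx = np.nonzero(fine_active[lo:hi])[0]
        if idx.size == 0:
            return t
        if kind == "start":
            return (lo + idx[0]) * fine_step
        return (lo + idx[-1] + 1) * fine_step

    # frame decisions attributed to hop-wide slots centred on each frame,
    # then snapped to the fine-energy onset/offset
    offset = (config.frame_length_s - config.hop_s) / 2.0
    intervals: List[List[float]] = []
    origins = frames.origin_times
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            start = max(0.0, origins[i] + offset)
            end = min(duration, origins[j] + offset + config.hop_s)
            start, end = _refine(start, "start"), _refine(end, "end")
            if end > start:
                intervals.append([start, end])
            i = j + 1
        else:
            i += 1

    # merge gaps shorter than min_pause_s
    merged: List[List[float]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < config.min_pause_s:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)

    kept = [iv for iv in merged if iv[1] - iv[0] >= config.min_speech_s]
    return SpeechSegmentation(
        speech_intervals=tuple((s, e) for s, e in kept),
        total_duration_s=duration,
    )


def speaking_time(seg: SpeechSegmentation) -> float:
    """Onset-to-offset speaking span in seconds, internal pauses included."""
    if not seg.speech_intervals:
        raise NoSpeechError("no speech detected")
    return seg.span_end_s - seg.span_start_s


def pause_time(seg: SpeechSegmentation) -> float:
    """Total internal pause time: the non-speech part of the speaking span."""
    if not seg.speech_intervals:
        raise NoSpeechError("no speech detected")
    speech = sum(end - start for start, end in seg.speech_intervals)
    return speaking_time(seg) - speech


def segmentation_table(seg: SpeechSegmentation):
    """Interval table (start_s, end_s, label in {speech, pause}) as a DataFrame."""
    import pandas as pd

    rows = []
    prev_end = None
    for start, end in seg.speech_intervals:
        if prev_end is not None and start > prev_end:
            rows.append((prev_end, start, "pause"))
        rows.append((start, end, "speech"))
        prev_end = end
    return pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
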