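"""Articulatory features: LPC formants, vowel space area, and
goodness-of-pronunciation (GOP) scoring.

Formants are estimated by autocorrelation-method linear prediction on
pre-emphasized, Hamming-windowed frames; the first two qualifying LPC pole
frequencies give F1 and F2. The vowel space area is the convex-hull area of
the voiced-frame (F1, F2) cloud over the concatenated sentence readings,
after percentile trimming; a reduced area indicates centralized, less
distinct vowel articulation.

GOP scores a phone segment as the length-normalized log-likelihood ratio
between the intended phone and the best competing phone under a per-phone
diagonal-Gaussian acoustic model over 13 mel-cepstral coefficients:

    GOP = (1/d) [ log L(X | intended) - max_q log L(X | q) ]  <=  0,

zero exactly when the intended phone is the inventory maximizer. Vowel and
consonant articulation precision are the unweighted means of GOP over the
segments of each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.fft import dct
from scipy.linalg import solve_toeplitz
from scipy.spatial import ConvexHull, QhullError

from .audio_core import AudioSignal, frame_signal
from .errors import (
    AlignmentError,
    DegenerateAreaError,
    MissingClassError,
    UnknownPhoneError,
)
from .prosody import VOWEL_PHONES
from .segmentation import SpeechSegmentation

PREEMPHASIS = 0.97
#: Milder tilt compensation for LPC analysis; heavy pre-emphasis biases F1
#: toward harmonics when f0 is high.
FORMANT_PREEMPHASIS = 0.7
FORMANT_FRAME_S = 0.025
FORMANT_HOP_S = 0.010
MAX_BANDWIDTH_HZ = 400.0
MIN_FORMANT_HZ = 90.0

N_MFCC = 13
N_MEL_FILTERS = 26


def default_lpc_order(sample_rate: int) -> int:
    """Rule-of-thumb LPC order: 2 + sample_rate/1000, rounded."""
    return 2 + int(round(sample_rate / 1000.0))


# --------------------------------------------------------------------------
# formants

@dataclass(frozen=True)
class FormantTrack:
    times_s: np.ndarray
    f1_hz: np.ndarray
    f2_hz: np.ndarray
    valid: np.ndarray


def _lpc_coefficients(frame: np.ndarray, order: int) -> Optional[np.ndarray]:
    """Autocorrelation-method LPC; returns a = [1, a1..ap] or None."""
    r = np.correlate(frame, frame, mode="full")[frame.size - 1:frame.size + order]
    if r[0] <= 0:
        return None
    r = r + 1e-9 * r[0] * (np.arange(order + 1) == 0)  # tiny ridge for stability
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate(([1.0], a))


def estimate_formants(signal: AudioSignal, order: Optional[int] = None) -> FormantTrack:
    """Per-frame F1/F2 from LPC pole angles.

    Candidate poles must have positive imaginary part, bandwidth below
    400 Hz, and frequency inside [90, Nyquist - 50] Hz; frames with fewer
    than two qualifying poles are marked invalid.
    """
    if signal.samples.size == 0:
        raise ValueError("signal is empty")
    sr = signal.sample_rate
    if order is None:
        order = default_lpc_order(sr)
    emphasized = AudioSignal(
        np.append(
            signal.samples[0],
            signal.samples[1:] - FORMANT_PREEMPHASIS * signal.samples[:-1],
        ),
        sr,
    )
    frames = frame_signal(emphasized, FORMANT_FRAME_S, FORMANT_HOP_S)
    window = np.hamming(frames.frames.shape[1]) if len(frames) else None
    n = len(frames)
    f1 = np.zeros(n)
    f2 = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    f_hi = sr / 2 - 50.0
    for i in range(n):
        a = _lpc_coefficients(frames.frames[i] * window, order)
        if a is None:
            continue
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        if roots.size == 0:
            continue
        freqs = np.angle(roots) * sr / (2 * np.pi)
        mags = np.abs(roots)
        bw = -sr / np.pi * np.log(np.maximum(mags, 1e-12))
        keep = (bw < MAX_BANDWIDTH_HZ) & (freqs > MIN_FORMANT_HZ) & (freqs < f_hi)
        cand = np.sort(freqs[keep])
        if cand.size >= 2:
            f1[i], f2[i] = cand[0], cand[1]
            valid[i] = True
    centre = FORMANT_FRAME_S / 2.0
    return FormantTrack(times_s=frames.origin_times + centre, f1_hz=f1, f2_hz=f2, valid=valid)


def _in_intervals(times: np.ndarray, intervals: Sequence[Tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for start, end in intervals:
        mask |= (times >= start) & (times <= end)
    return mask


def vowel_space_area(
    track: FormantTrack,
    seg: SpeechSegmentation,
    voiced_times: Optional[np.ndarray] = None,
    voiced_flags: Optional[np.ndarray] = None,
) -> float:
    """Convex-hull area (Hz^2) of the trimmed voiced-speech (F1, F2) cloud.

    Frames must be valid and lie inside a speech interval; when a voicing
    track is supplied (frame times + flags from the pitch contour), frames
    nearest an unvoiced pitch frame are excluded too. Each axis is trimmed
    to its [5th, 95th] percentile range before the hull.
    """
    mask = track.valid & _in_intervals(track.times_s, seg.speech_intervals)
    if voiced_times is not None and voiced_flags is not None and voiced_times.size:
        idx = np.searchsorted(voiced_times, track.times_s)
        idx = np.clip(idx, 0, voiced_times.size - 1)
        left = np.clip(idx - 1, 0, voiced_times.size - 1)
        nearer_left = np.abs(track.times_s - voiced_times[left]) < np.abs(
            track.times_s - voiced_times[idx]
        )
        nearest = np.where(nearer_left, left, idx)
        mask &= voiced_flags[nearest]
    pts = np.column_stack([track.f1_hz[mask], track.f2_hz[mask]])
    if pts.shape[0] >= 3:
        lo1, hi1 = np.percentile(pts[:, 0], [5, 95])
        lo2, hi2 = np.percentile(pts[:, 1], [5, 95])
        keep = (
            (pts[:, 0] >= lo1) & (pts[:, 0] <= hi1)
            & (pts[:, 1] >= lo2) & (pts[:, 1] <= hi2)
        )
        pts = pts[keep]
    if pts.shape[0] < 3:
        raise DegenerateAreaError("fewer than 3 formant points after trimming")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateAreaError("formant points are degenerate") from exc
    return float(hull.volume)  # 2-D: volume is the area


# --------------------------------------------------------------------------
# MFCC front end (13 mel-cepstral coefficients)

def _mel(hz: np.ndarray) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + hz / 700.0)


def _inv_mel(mel: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)


def mfcc_features(
    signal: AudioSignal,
    frame_length_s: float = 0.025,
    hop_s: float = 0.010,
) -> Tuple[np.ndarray, np.ndarray]:
    """13-dimensional mel-cepstral features per frame.

    Returns (features, frame_centre_times). Standard chain: pre-emphasis,
    Hamming window, power spectrum, 26 triangular mel filters, log, DCT-II.
    """
    sr = signal.sample_rate
    emphasized = AudioSignal(
        np.append(signal.samples[0], signal.samples[1:] - PREEMPHASIS * signal.samples[:-1]),
        sr,
    )
    frames = frame_signal(emphasized, frame_length_s, hop_s)
    if len(frames) == 0:
        return np.empty((0, N_MFCC)), np.empty(0)
    window = np.hamming(frames.frames.shape[1])
    nfft = int(2 ** np.ceil(np.log2(frames.frames.shape[1])))
    spectrum = np.abs(np.fft.rfft(frames.frames * window, nfft)) ** 2

    mel_pts = np.linspace(_mel(np.array(0.0)), _mel(np.array(sr / 2.0)), N_MEL_FILTERS + 2)
    hz_pts = _inv_mel(mel_pts)
    bins = np.floor((nfft + 1) * hz_pts / sr).astype(int)
    fbank = np.zeros((N_MEL_FILTERS, nfft // 2 + 1))
    for m in range(1, N_MEL_FILTERS + 1):
        lo, mid, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, mid):
            if mid > lo:
                fbank[m - 1, k] = (k - lo) / (mid - lo)
        for k in range(mid, hi):
            if hi > mid:
                fbank[m - 1, k] = (hi - k) / (hi - mid)
    filter_energy = np.log(np.maximum(spectrum @ fbank.T, 1e-12))
    feats = dct(filter_energy, type=2, axis=1, norm="ortho")[:, :N_MFCC]
    centre = frame_length_s / 2.0
    return feats, frames.origin_times + centre


# --------------------------------------------------------------------------
# acoustic model, forced alignment, GOP

@dataclass(frozen=True)
class AcousticModel:
    """Per-phone diagonal Gaussian over frame feature vectors."""

    means: Dict[str, np.ndarray]
    variances: Dict[str, np.ndarray]
    feature_dim: int

    @property
    def phone_inventory(self) -> frozenset:
        return frozenset(self.means)

    def log_likelihood(self, phone: str, features: np.ndarray) -> float:
        """Summed diagonal-Gaussian log density of frames under one phone."""
        if phone not in self.means:
            raise UnknownPhoneError(phone)
        mu = self.means[phone]
        var = self.variances[phone]
        x = np.atleast_2d(features)
        const = -0.5 * (self.feature_dim * np.log(2 * np.pi) + np.log(var).sum())
        return float(
            x.shape[0] * const - 0.5 * (((x - mu) ** 2) / var).sum()
        )

    def frame_log_likelihoods(self, features: np.ndarray) -> Tuple[List[str], np.ndarray]:
        """Per-frame log density matrix, shape (n_phones, n_frames)."""
        phones = sorted(self.means)
        x = np.atleast_2d(features)
        out = np.empty((len(phones), x.shape[0]))
        for i, p in enumerate(phones):
            mu, var = self.means[p], self.variances[p]
            const = -0.5 * (self.feature_dim * np.log(2 * np.pi) + np.log(var).sum())
            out[i] = const - 0.5 * (((x - mu) ** 2) / var).sum(axis=1)
        return phones, out


def train_acoustic_model(
    examples: Dict[str, Iterable[np.ndarray]],
    var_floor: float = 1e-3,
) -> AcousticModel:
    """Fit per-phone Gaussians from labelled frame-feature examples."""
    means: Dict[str, np.ndarray] = {}
    variances: Dict[str, np.ndarray] = {}
    dim = None
    for phone, feats in examples.items():
        stacked = np.vstack([np.atleast_2d(f) for f in feats])
        dim = stacked.shape[1] if dim is None else dim
        means[phone] = stacked.mean(axis=0)
        variances[phone] = np.maximum(stacked.var(axis=0), var_floor)
    if dim is None:
        raise ValueError("no training examples")
    return AcousticModel(means=means, variances=variances, feature_dim=dim)


@dataclass(frozen=True)
class PhoneSegment:
    phone_label: str
    phone_class: str  # "vowel" | "consonant"
    start_s: float
    end_s: float
    frame_count: int
    frame_slice: Tuple[int, int] = (0, 0)
    gop: Optional[float] = None


def phone_class(label: str) -> str:
    return "vowel" if label.rstrip("012") in VOWEL_PHONES else "consonant"


def force_align(
    features: np.ndarray,
    frame_times: np.ndarray,
    phone_sequence: Sequence[str],
    model: AcousticModel,
) -> List[PhoneSegment]:
    """Monotonic DP alignment of frames to the expected phone sequence.

    Maximizes the summed per-frame Gaussian log-likelihood subject to every
    phone receiving at least one frame; segments tile the frame span in
    prompt order.
    """
    if not phone_sequence:
        raise ValueError("phone_sequence is empty")
    n_frames = features.shape[0]
    n_phones = len(phone_sequence)
    if n_frames < n_phones:
        raise AlignmentError(f"{n_frames} frames < {n_phones} phones")
    base = [p.rstrip("012") for p in phone_sequence]
    for p in base:
        if p not in model.means:
            raise UnknownPhoneError(p)
    inv, ll_matrix = model.frame_log_likelihoods(features)
    row = {p: i for i, p in enumerate(inv)}
    ll = np.vstack([ll_matrix[row[p]] for p in base])  # (n_phones, n_frames)

    NEG = -np.inf
    score = np.full((n_phones, n_frames), NEG)
    back = np.zeros((n_phones, n_frames), dtype=np.int8)  # 1 = came from phone above
    score[0, 0] = ll[0, 0]
    for t in range(1, n_frames):
        score[0, t] = score[0, t - 1] + ll[0, t]
    for p in range(1, n_phones):
        for t in range(p, n_frames):
            stay = score[p, t - 1]
            advance = score[p - 1, t - 1]
            if advance > stay:
                score[p, t] = advance + ll[p, t]
                back[p, t] = 1
            else:
                score[p, t] = stay + ll[p, t]
    # backtrack
    boundaries = np.zeros(n_phones, dtype=int)  # first frame of each phone
    p, t = n_phones - 1, n_frames - 1
    while p > 0:
        if back[p, t] == 1:
            boundaries[p] = t
            p -= 1
        t -= 1
    hop = frame_times[1] - frame_times[0] if n_frames > 1 else 0.01
    segments: List[PhoneSegment] = []
    for i, label in enumerate(phone_sequence):
        first = boundaries[i]
        last = boundaries[i + 1] - 1 if i + 1 < n_phones else n_frames - 1
        segments.append(
            PhoneSegment(
                phone_label=label,
                phone_class=phone_class(label),
                start_s=float(frame_times[first] - hop / 2),
                end_s=float(frame_times[last] + hop / 2),
                frame_count=int(last - first + 1),
                frame_slice=(int(first), int(last + 1)),
            )
        )
    return segments


def gop_score(segment: PhoneSegment, features: np.ndarray, model: AcousticModel) -> float:
    """Length-normalized log-likelihood ratio of intended vs best phone.

    Always <= 0; equals 0 iff the intended phone maximizes the likelihood
    over the whole inventory.
    """
    first, last = segment.frame_slice
    if last <= first:
        raise ValueError("segment has no frames")
    seg_feats = features[first:last]
    base = segment.phone_label.rstrip("012")
    ll_intended = model.log_likelihood(base, seg_feats)
    ll_best = max(model.log_likelihood(q, seg_feats) for q in model.means)
    return (ll_intended - ll_best) / segment.frame_count


def articulation_precision(segments: Sequence[PhoneSegment], which: str) -> float:
    """Unweighted mean GOP over segments of one class ('vowel'/'consonant')."""
    scores = [s.gop for s in segments if s.phone_class == which and s.gop is not None]
    if not scores:
        raise MissingClassError(f"no scored {which} segments")
    return float(np.mean(scores))


@dataclass(frozen=True)
class ArticulationFeatures:
    vowel_precision: float
    consonant_precision: float
    vowel_space_area_hz2: float
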