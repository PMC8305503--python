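"""Age/sex normative percentile normalization.

Sentence-task features (speaking rate, average pitch, pitch variance, vowel
and consonant articulation precision) are converted to percentiles of an
empirical CDF estimated from an age/sex-matched subset of a normative
reference corpus. Vowel space area and spontaneous pause rate pass through
unnormalized: the reference corpus is a sentence-reading corpus, so it
supports neither a reliable vowel space area nor a spontaneous-speech norm.

Ties use the midrank convention, percentile = 100 (n_less + n_equal/2) / n,
so the transform is symmetric and bounded in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .errors import UnmatchableReferenceError

#: Features normalized against the reference corpus, in canonical order.
NORMALIZED_FEATURES = (
    "speaking_rate",
    "mean_pitch",
    "pitch_variance",
    "vowel_precision",
    "consonant_precision",
)
#: Features reported on their raw scale.
PASSTHROUGH_FEATURES = ("vowel_space_area", "pause_rate")
ALL_FEATURES = NORMALIZED_FEATURES + PASSTHROUGH_FEATURES

DEFAULT_AGE_WINDOW_YEARS = 5.0
MIN_SUBSET_SIZE = 30


@dataclass(frozen=True)
class NormativeRecord:
    age: float
    sex: str  # "female" | "male"
    features: Dict[str, float]


@dataclass(frozen=True)
class FeatureVector:
    """The seven per-visit raw speech measures."""

    speaking_rate: float
    mean_pitch: float
    pitch_variance: float
    vowel_precision: float
    consonant_precision: float
    vowel_space_area: float
    pause_rate: float

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in ALL_FEATURES}


@dataclass(frozen=True)
class NormalizedFeatureVector:
    """Percentile-normalized measures plus the two passthrough measures."""

    percentiles: Dict[str, float]
    reference_n: Dict[str, int]


def match_reference_subset(
    corpus: Sequence[NormativeRecord],
    age: float,
    sex: str,
    window: float = DEFAULT_AGE_WINDOW_YEARS,
    min_size: int = MIN_SUBSET_SIZE,
) -> List[NormativeRecord]:
    """Same-sex records within +/- window years; the window doubles until
    the subset reaches ``min_size`` or the same-sex corpus is exhausted."""
    same_sex = [r for r in corpus if r.sex == sex]
    if not same_sex:
        raise UnmatchableReferenceError(f"no {sex!r} records in corpus")
    w = window
    while True:
        subset = [r for r in same_sex if abs(r.age - age) <= w]
        if len(subset) >= min_size or len(subset) == len(same_sex):
            return subset
        w *= 2


def empirical_percentile(reference_values: Sequence[float], x: float) -> float:
    """Midrank empirical-CDF percentile of x within the reference sample."""
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference sample")
    less = np.count_nonzero(ref < x)
    equal = np.count_nonzero(ref == x)
    return 100.0 * (less + 0.5 * equal) / ref.size


def normalize_features(
    raw: FeatureVector,
    corpus: Sequence[NormativeRecord],
    age: float,
    sex: str,
    window: float = DEFAULT_AGE_WINDOW_YEARS,
    min_size: int = MIN_SUBSET_SIZE,
) -> NormalizedFeatureVector:
    """Percentile-normalize the five sentence-task features; pass the rest through."""
    subset = match_reference_subset(corpus, age, sex, window=window, min_size=min_size)
    percentiles: Dict[str, float] = {}
    reference_n: Dict[str, int] = {}
    for name in NORMALIZED_FEATURES:
        ref = [r.features[name] for r in subset if name in r.features]
        percentiles[name] = empirical_percentile(ref, getattr(raw, name))
        reference_n[name] = len(ref)
    for name in PASSTHROUGH_FEATURES:
        percentiles[name] = getattr(raw, name)
        reference_n[name] = 0
    return NormalizedFeatureVector(percentiles=percentiles, reference_n=reference_n)


def corpus_from_frame(frame: pd.DataFrame) -> List[NormativeRecord]:
    """Build records from a corpus table (id, age, sex, feature columns)."""
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            NormativeRecord(
                age=float(d["age"]),
                sex=str(d["sex"]),
                features={k: float(d[k]) for k in NORMALIZED_FEATURES if k in d},
            )
        )
    return records


def corpus_to_frame(corpus: Sequence[NormativeRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(corpus):
        row = {"id": i, "age": r.age, "sex": r.sex}
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)
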