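"""End-to-end orchestration: audio -> features -> normalization -> models.

A manifest CSV lists, per visit, the five sentence WAVs, the spontaneous
WAV and the visit metadata. ``run_extraction`` produces one feature row per
visit (seven raw measures); ``run_normalization`` adds the five percentile
columns; ``run_analysis`` fits the between-group (30-day window) and
within-subject (90-day window) mixed models and emits results tables with
raw group means, differences, LRT p-values and convergence flags.

Visits whose audio fails a stage carry explicit NaN markers rather than
being dropped, so count(input visits) == count(output rows).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import articulation as art
from . import cohort_analysis as coh
from . import normalization as norm
from . import prosody
from .audio_core import read_wav
from .errors import PthSpeechError
from .segmentation import VadConfig, detect_voice_activity
from .synthetic_data import default_acoustic_model

logger = logging.getLogger("pthspeech")

SENTENCE_COLUMNS = [f"sentence{i}" for i in range(1, 6)]
METADATA_COLUMNS = ["subject_id", "group", "age", "sex", "day", "headache", "intensity"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a deterministic pipeline run."""

    manifest_path: Optional[Path] = None
    corpus_path: Optional[Path] = None
    output_dir: Optional[Path] = None
    vad: VadConfig = field(default_factory=VadConfig)
    f0_min: float = 50.0
    f0_max: float = 400.0
    between_group_window_days: int = coh.BETWEEN_GROUP_WINDOW_DAYS
    within_subject_window_days: int = coh.WITHIN_SUBJECT_WINDOW_DAYS
    seed: int = 0


def extract_visit_features(
    sentence_signals: Sequence,
    spontaneous_signal,
    config: RunConfig = RunConfig(),
    acoustic_model=None,
) -> Dict[str, float]:
    """The seven speech measures for one visit.

    Sentence-task measures (rate, pitch, precision, vowel space area) come
    from the five readings; the pause rate from the spontaneous sample.
    Failed stages yield NaN for the affected measures.
    """
    out: Dict[str, float] = {k: float("nan") for k in norm.ALL_FEATURES}
    prompts = prosody.load_prompts()

    if sentence_signals and all(s is not None for s in sentence_signals):
        try:
            rates = []
            for prompt, sig in zip(prompts, sentence_signals):
                seg = detect_voice_activity(sig, config.vad)
                rates.append(
                    prosody.sentence_speaking_rate(prosody.count_syllables(prompt), seg)
                )
            out["speaking_rate"] = float(np.mean(rates))
        except PthSpeechError as exc:
            logger.warning("speaking rate failed: %s", exc)

        sr = sentence_signals[0].sample_rate
        from .audio_core import AudioSignal

        concat = AudioSignal(
            np.concatenate([s.samples for s in sentence_signals]), sr
        )
        try:
            contour = prosody.estimate_pitch(concat, config.f0_min, config.f0_max)
            mean_pitch, pitch_var = prosody.pitch_statistics(contour)
            out["mean_pitch"], out["pitch_variance"] = mean_pitch, pitch_var
        except PthSpeechError as exc:
            contour = None
            logger.warning("pitch failed: %s", exc)
        try:
            seg_all = detect_voice_activity(concat, config.vad)
            track = art.estimate_formants(concat)
            if contour is not None:
                out["vowel_space_area"] = art.vowel_space_area(
                    track, seg_all, contour.times_s, contour.voiced
                )
            else:
                out["vowel_space_area"] = art.vowel_space_area(track, seg_all)
        except PthSpeechError as exc:
            logger.warning("vowel space area failed: %s", exc)

        model = acoustic_model or default_acoustic_model(sr, config.seed)
        try:
            scored: List[art.PhoneSegment] = []
            for prompt, sig in zip(prompts, sentence_signals):
                phones: List[str] = []
                for word in prompt.split():
                    pron = prosody.phonetize(word)
                    if pron:
                        phones.extend(pron)
                feats, times = art.mfcc_features(sig)
                segments = art.force_align(feats, times, phones, model)
                for seg_ in segments:
                    scored.append(
                        art.PhoneSegment(
                            **{**seg_.__dict__, "gop": art.gop_score(seg_, feats, model)}
                        )
                    )
            out["vowel_precision"] = art.articulation_precision(scored, "vowel")
            out["consonant_precision"] = art.articulation_precision(scored, "consonant")
        except PthSpeechError as exc:
            logger.warning("articulation scoring failed: %s", exc)

    if spontaneous_signal is not None:
        try:
            seg = detect_voice_activity(spontaneous_signal, config.vad)
            out["pause_rate"] = prosody.spontaneous_pause_rate(seg)
        except PthSpeechError as exc:
            logger.warning("pause rate failed: %s", exc)
    return out


def run_extraction(config: RunConfig) -> pd.DataFrame:
    """Extract per-visit features for every row of the manifest."""
    manifest = pd.read_csv(config.manifest_path)
    model = None
    rows = []
    for i, row in manifest.iterrows():
        t0 = time.perf_counter()
        sentence_signals = []
        for col in SENTENCE_COLUMNS:
            try:
                sentence_signals.append(read_wav(row[col]))
            except Exception as exc:  # noqa: BLE001 - missing audio is a data issue
                logger.warning("visit %d: %s unreadable (%s)", i, col, exc)
                sentence_signals.append(None)
        try:
            spont = read_wav(row["spontaneous"])
        except Exception as exc:  # noqa: BLE001
            logger.warning("visit %d: spontaneous unreadable (%s)", i, exc)
            spont = None
        if model is None and sentence_signals and sentence_signals[0] is not None:
            model = default_acoustic_model(sentence_signals[0].sample_rate, config.seed)
        feats = extract_visit_features(sentence_signals, spont, config, model)
        out_row = {k: row[k] for k in METADATA_COLUMNS if k in row}
        out_row.update(feats)
        rows.append(out_row)
        logger.info("visit %d extracted in %.2fs", i, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def run_normalization(features: pd.DataFrame, corpus: pd.DataFrame) -> pd.DataFrame:
    """Add percentile-normalized columns (suffix ``_norm``) to a feature table."""
    records = norm.corpus_from_frame(corpus)
    out = features.copy()
    for name in norm.NORMALIZED_FEATURES:
        out[f"{name}_norm"] = np.nan
    for i, row in features.iterrows():
        if any(pd.isna(row[f]) for f in norm.NORMALIZED_FEATURES):
            continue
        raw = norm.FeatureVector(
            **{f: float(row[f]) for f in norm.ALL_FEATURES}
        )
        normalized = norm.normalize_features(raw, records, float(row["age"]), str(row["sex"]))
        for name in norm.NORMALIZED_FEATURES:
            out.loc[i, f"{name}_norm"] = normalized.percentiles[name]
    return out


def _response_columns(features: pd.DataFrame) -> List[tuple]:
    cols = []
    for name in norm.ALL_FEATURES:
        if name in features.columns:
            cols.append((name, name, "raw"))
        if f"{name}_norm" in features.columns:
            cols.append((name, f"{name}_norm", "normalized"))
    return cols


def run_analysis(features: pd.DataFrame, config: RunConfig = RunConfig()) -> Dict[str, pd.DataFrame]:
    """Fit both analyses for every available feature/scale.

    Returns ``{"between_group": ..., "within_subject": ...}`` tables with
    one row per feature, scale and model variant.
    """
    results: Dict[str, pd.DataFrame] = {}

    bg = features[features["day"] <= config.between_group_window_days]
    rows = []
    for feature, column, scale in _response_columns(features):
        data = bg.dropna(subset=[column])
        if data.empty or data[column].nunique() <= 1:
            logger.info("between-group: %s skipped (no usable data)", column)
            continue
        full = coh.fit_random_intercept_model(data, column, "PTH_vs_HC")
        reduced = coh.fit_random_intercept_model(data, column, None)
        p = np.nan
        if full.converged and reduced.converged:
            p = coh.lrt_pvalue(full, reduced)
        mean_hc, mean_pth, diff = coh.group_direction_summary(data, column, by="group")
        coef, se = full.fixed_effects.get("group[PTH]", (np.nan, np.nan))
        rows.append(
            dict(feature=feature, scale=scale, model="random_intercept",
                 n=full.n_obs, coefficient=coef, SE=se, LRT_p=p,
                 converged=full.converged and reduced.converged,
                 mean_HC=mean_hc, mean_PTH=mean_pth, diff=diff)
        )
    results["between_group"] = pd.DataFrame(rows)

    ws = features[
        (features["group"] == "PTH")
        & (features["day"] <= config.within_subject_window_days)
    ]
    rows = []
    if ws.empty or ws["headache"].nunique() < 2:
        logger.info("within-subject analysis skipped: no PTH samples in both states")
    else:
        for feature, column, scale in _response_columns(features):
            data = ws.dropna(subset=[column])
            if data.empty or data[column].nunique() <= 1:
                continue
            for model_kind in ("random_intercept", "random_intercept_random_slope"):
                if model_kind == "random_intercept":
                    full = coh.fit_random_intercept_model(data, column, "headache_status")
                    reduced = coh.fit_random_intercept_model(data, column, None)
                else:
                    try:
                        full = coh.fit_random_slope_model(data, column, True)
                        reduced = coh.fit_random_slope_model(data, column, False)
                    except ValueError as exc:
                        logger.info("within-subject %s skipped: %s", column, exc)
                        continue
                p = np.nan
                if full.converged and reduced.converged:
                    try:
                        p = coh.lrt_pvalue(full, reduced)
                    except PthSpeechError as exc:
                        logger.warning("LRT failed for %s (%s): %s", column, model_kind, exc)
                mean_free, mean_ha, diff = coh.group_direction_summary(data, column, by="headache")
                coef, se = full.fixed_effects.get("headache", (np.nan, np.nan))
                rows.append(
                    dict(feature=feature, scale=scale, model=model_kind,
                         n=full.n_obs, coefficient=coef, SE=se, LRT_p=p,
                         converged=full.converged and reduced.converged,
                         mean_headache_free=mean_free, mean_headache=mean_ha, diff=diff)
                )
    results["within_subject"] = pd.DataFrame(rows)
    return results
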