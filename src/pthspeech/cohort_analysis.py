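"""Longitudinal cohort model: sample windows, mixed-effects fits, LRTs.

Two analyses mirror the study design. Between-group: speech samples from
the first 30 days, compared across PTH and healthy-control cohorts with a
random-intercept model (fixed effects: age, sex, group). Within-subject:
PTH samples from the first 90 days, headache days vs headache-free days,
with either a random-intercept model or a random-intercept + random-slope
model in which the headache effect varies by subject (with intercept-slope
covariance).

Models are fitted by maximum likelihood (not REML) so that likelihood-ratio
tests on fixed effects are valid; the LRT p-value is the upper chi-squared
tail of twice the log-likelihood difference at the parameter-count
difference. Non-convergence is a reported outcome, never an exception:
only converged models should be interpreted. Raw per-group means are
reported alongside, to give the direction of each effect. No
multiple-testing correction is applied; p-values are per-feature and
unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import FittingInconsistencyError
from .normalization import FeatureVector, NormalizedFeatureVector

#: days of data used when comparing PTH with healthy controls
BETWEEN_GROUP_WINDOW_DAYS = 30
#: days of PTH data used when comparing headache vs headache-free states
WITHIN_SUBJECT_WINDOW_DAYS = 90

LL_TOLERANCE = 1e-4


@dataclass(frozen=True)
class SpeechSample:
    """One visit's speech measures plus metadata."""

    subject_id: str
    group: str  # "PTH" | "HC"
    age: float
    sex: str  # "female" | "male"
    day: int
    headache_present: bool
    headache_intensity: Union[int, None]
    features: FeatureVector
    normalized: Union[NormalizedFeatureVector, None] = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.headache_present != (self.headache_intensity is not None):
            raise ValueError("intensity present iff headache_present")
        if self.group == "HC" and self.headache_present:
            raise ValueError("HC samples are headache-free by design")


@dataclass(frozen=True)
class MixedModelFit:
    fixed_effects: Dict[str, Tuple[float, float]]  # name -> (coef, se)
    random_effect_variances: Dict[str, float]
    residual_variance: float
    log_likelihood: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_params: int
    model_kind: str = "random_intercept"


def samples_to_frame(samples: Sequence[SpeechSample]) -> pd.DataFrame:
    """Long-format table: one row per visit, raw and normalized features."""
    rows = []
    for s in samples:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "day": s.day,
            "headache": int(s.headache_present),
            "intensity": s.headache_intensity,
        }
        row.update(s.features.as_dict())
        if s.normalized is not None:
            row.update({f"{k}_norm": v for k, v in s.normalized.percentiles.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return samples_to_frame(list(samples))


def filter_window(samples, analysis: str):
    """Apply the study's sample-window rules.

    ``between_group`` keeps all samples from the first 30 days;
    ``within_subject`` keeps PTH samples from the first 90 days.
    Accepts and returns either a list of SpeechSample or a DataFrame.
    """
    if analysis not in ("between_group", "within_subject"):
        raise ValueError(f"unknown analysis {analysis!r}")
    if isinstance(samples, pd.DataFrame):
        if analysis == "between_group":
            return samples[samples["day"] <= BETWEEN_GROUP_WINDOW_DAYS]
        return samples[(samples["group"] == "PTH") & (samples["day"] <= WITHIN_SUBJECT_WINDOW_DAYS)]
    if analysis == "between_group":
        return [s for s in samples if s.day <= BETWEEN_GROUP_WINDOW_DAYS]
    return [s for s in samples if s.group == "PTH" and s.day <= WITHIN_SUBJECT_WINDOW_DAYS]


def _design(frame: pd.DataFrame, response: str, group_term: Union[str, None]):
    y = frame[response].to_numpy(dtype=float)
    cols = {"Intercept": np.ones(len(frame)), "age": frame["age"].to_numpy(dtype=float),
            "sex[male]": (frame["sex"] == "male").to_numpy(dtype=float)}
    if group_term == "PTH_vs_HC":
        cols["group[PTH]"] = (frame["group"] == "PTH").to_numpy(dtype=float)
    elif group_term == "headache_status":
        cols["headache"] = frame["headache"].to_numpy(dtype=float)
    elif group_term is not None:
        raise ValueError(f"unknown group_term {group_term!r}")
    X = pd.DataFrame(cols, index=frame.index)
    groups = frame["subject_id"].to_numpy()
    return y, X, groups


def _failed_fit(n_obs: int, n_subjects: int, n_params: int, kind: str) -> MixedModelFit:
    return MixedModelFit(
        fixed_effects={},
        random_effect_variances={},
        residual_variance=float("nan"),
        log_likelihood=float("nan"),
        converged=False,
        n_obs=n_obs,
        n_subjects=n_subjects,
        n_params=n_params,
        model_kind=kind,
    )


def _fit_mixedlm(y, X, groups, exog_re, kind: str) -> MixedModelFit:
    n_obs = len(y)
    n_subjects = len(np.unique(groups))
    n_re = 1 if exog_re is None else exog_re.shape[1]
    n_cov = n_re * (n_re + 1) // 2
    n_params = X.shape[1] + n_cov + 1  # fixed + covariance + residual
    if n_obs == 0 or np.var(y) == 0:
        return _failed_fit(n_obs, n_subjects, n_params, kind)
    model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=False, maxiter=500)
        except Exception:
            return _failed_fit(n_obs, n_subjects, n_params, kind)
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    variances: Dict[str, float] = {"intercept": float(cov_re[0, 0])}
    if n_re == 2:
        variances["headache_slope"] = float(cov_re[1, 1])
        variances["intercept_slope_cov"] = float(cov_re[0, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fe = np.asarray(result.fe_params, dtype=float)
        bse = np.asarray(result.bse_fe, dtype=float)
    converged = (
        bool(result.converged)
        and np.isfinite(result.llf)
        and bool(np.all(np.isfinite(fe)))
        and bool(np.all(np.isfinite(bse)))
        and all(np.isfinite(v) for v in variances.values())
        and variances["intercept"] >= 0
        and variances.get("headache_slope", 0.0) >= 0
    )
    fixed = {name: (float(fe[i]), float(bse[i])) for i, name in enumerate(X.columns)}
    return MixedModelFit(
        fixed_effects=fixed,
        random_effect_variances=variances,
        residual_variance=float(result.scale),
        log_likelihood=float(result.llf),
        converged=converged,
        n_obs=n_obs,
        n_subjects=n_subjects,
        n_params=n_params,
        model_kind=kind,
    )


def fit_random_intercept_model(
    samples,
    response: str,
    group_term: Union[str, None] = "PTH_vs_HC",
) -> MixedModelFit:
    """ML fit of response ~ age + sex (+ group term) + per-subject intercept.

    ``group_term`` is "PTH_vs_HC", "headache_status", or None (the reduced
    model for the LRT). A degenerate response yields converged=False.
    """
    frame = _as_frame(samples)
    y, X, groups = _design(frame, response, group_term)
    return _fit_mixedlm(y, X, groups, None, "random_intercept")


def fit_random_slope_model(
    samples,
    response: str,
    include_headache_term: bool = True,
) -> MixedModelFit:
    """Random intercept + per-subject random slope for headache status.

    Intended for the within-subject PTH set; requires subjects observed in
    both headache states for the slope variance to be identified.
    """
    frame = _as_frame(samples)
    states = frame.groupby("subject_id")["headache"].nunique()
    if (states >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects observed in both headache states")
    term = "headache_status" if include_headache_term else None
    y, X, groups = _design(frame, response, term)
    exog_re = np.column_stack([np.ones(len(frame)), frame["headache"].to_numpy(dtype=float)])
    return _fit_mixedlm(y, X, groups, exog_re, "random_intercept_random_slope")


def lrt_pvalue(full: MixedModelFit, reduced: MixedModelFit) -> float:
    """Chi-squared likelihood-ratio p-value for nested converged fits."""
    if not (full.converged and reduced.converged):
        raise ValueError("both models must have converged")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("reduced model must have fewer parameters than full")
    delta = full.log_likelihood - reduced.log_likelihood
    if delta < -LL_TOLERANCE:
        raise FittingInconsistencyError(
            f"reduced model beats full by {-delta:.3g} in log-likelihood"
        )
    return float(stats.chi2.sf(2.0 * max(delta, 0.0), df))


def group_direction_summary(
    samples,
    response: str,
    by: str = "group",
) -> Tuple[float, float, float]:
    """Raw sample means of the two groups and their difference (B - A).

    ``by="group"`` contrasts HC (A) vs PTH (B); ``by="headache"`` contrasts
    headache-free (A) vs headache (B) rows. These are cohort means, not
    model estimates; they convey the direction of an effect.
    """
    frame = _as_frame(samples)
    if by == "group":
        a = frame.loc[frame["group"] == "HC", response]
        b = frame.loc[frame["group"] == "PTH", response]
    elif by == "headache":
        a = frame.loc[frame["headache"] == 0, response]
        b = frame.loc[frame["headache"] == 1, response]
    else:
        raise ValueError(f"unknown contrast {by!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return mean_a, mean_b, mean_b - mean_a
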