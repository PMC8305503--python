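import numpy as np
import pytest
from scipy import stats

from pthspeech.cohort_analysis import (
    MixedModelFit,
    filter_window,
    fit_random_intercept_model,
    fit_random_slope_model,
    group_direction_summary,
    lrt_pvalue,
    samples_to_frame,
)
from pthspeech.errors import FittingInconsistencyError
from pthspeech.synthetic_data import CohortSpec, FeatureEffect, simulate_cohort


def _cohort_frame(effects, seed, **kwargs):
    spec = CohortSpec(effects=effects, seed=seed, **kwargs)
    return samples_to_frame(simulate_cohort(spec))


class TestFilterWindow:
    def test_day_rules(self):
        samples = simulate_cohort(CohortSpec(n_pth=2, n_hc=2, duration_weeks=14, seed=0))
        bg = filter_window(samples, "between_group")
        ws = filter_window(samples, "within_subject")
        assert all(s.day <= 30 for s in bg)
        assert all(s.day <= 90 and s.group == "PTH" for s in ws)
        # a PTH day-33 sample is only in the within-subject set
        pth_mid = [s for s in samples if s.group == "PTH" and 30 < s.day <= 90]
        assert pth_mid and all(s in ws for s in pth_mid)
        # day-91+ samples are in neither
        late = [s for s in samples if s.day > 90]
        assert late and not any(s in ws or s in bg for s in late)

    def test_dataframe_variant_agrees(self):
        samples = simulate_cohort(CohortSpec(n_pth=2, n_hc=2, seed=0))
        frame = samples_to_frame(samples)
        assert len(filter_window(frame, "between_group")) == len(
            filter_window(samples, "between_group")
        )


class TestRandomInterceptModel:
    def test_group_effect_recovered_within_3se(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 1.0, 1.0, group_effect=1.0)}
        df = _cohort_frame(eff, seed=11, n_pth=25, n_hc=25)
        fit = fit_random_intercept_model(df, "speaking_rate", "PTH_vs_HC")
        assert fit.converged
        coef, se = fit.fixed_effects["group[PTH]"]
        assert abs(coef - 1.0) <= 3 * se

    def test_constant_response_reports_nonconvergence(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 0.0, 0.0)}
        df = _cohort_frame(eff, seed=1, n_pth=5, n_hc=5)
        fit = fit_random_intercept_model(df, "speaking_rate", "PTH_vs_HC")
        assert not fit.converged

    def test_location_equivariance(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 0.8, 0.6, group_effect=0.5)}
        df = _cohort_frame(eff, seed=21, n_pth=15, n_hc=15)
        fit1 = fit_random_intercept_model(df, "speaking_rate", "PTH_vs_HC")
        shifted = df.copy()
        shifted["speaking_rate"] = shifted["speaking_rate"] + 100.0
        fit2 = fit_random_intercept_model(shifted, "speaking_rate", "PTH_vs_HC")
        c1, _ = fit1.fixed_effects["group[PTH]"]
        c2, _ = fit2.fixed_effects["group[PTH]"]
        i1, _ = fit1.fixed_effects["Intercept"]
        i2, _ = fit2.fixed_effects["Intercept"]
        assert c2 == pytest.approx(c1, abs=1e-4)
        assert i2 - i1 == pytest.approx(100.0, abs=1e-3)
        red1 = fit_random_intercept_model(df, "speaking_rate", None)
        red2 = fit_random_intercept_model(shifted, "speaking_rate", None)
        assert lrt_pvalue(fit2, red2) == pytest.approx(lrt_pvalue(fit1, red1), abs=1e-4)


class TestRandomSlopeModel:
    def test_headache_effect_recovered_within_3se(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 1.0, 1.0, headache_effect=0.8, slope_sd=0.5)}
        df = _cohort_frame(eff, seed=12, n_pth=50, n_hc=0, headache_probability=0.4)
        fit = fit_random_slope_model(df, "speaking_rate")
        assert fit.converged
        coef, se = fit.fixed_effects["headache"]
        assert abs(coef - 0.8) <= 3 * se
        assert fit.random_effect_variances["headache_slope"] > 0

    def test_zero_slope_variance_recovered_at_boundary(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 1.0, 1.0, headache_effect=0.5, slope_sd=0.0)}
        df = _cohort_frame(eff, seed=13, n_pth=50, n_hc=0, headache_probability=0.4)
        fit = fit_random_slope_model(df, "speaking_rate")
        assert fit.random_effect_variances["headache_slope"] <= 0.05

    def test_single_state_subjects_rejected(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 1.0, 1.0)}
        df = _cohort_frame(eff, seed=14, n_pth=10, n_hc=0, headache_probability=0.0)
        with pytest.raises(ValueError):
            fit_random_slope_model(df, "speaking_rate")


class TestLrt:
    def _fit(self, ll, n_params, converged=True):
        return MixedModelFit(
            fixed_effects={}, random_effect_variances={}, residual_variance=1.0,
            log_likelihood=ll, converged=converged, n_obs=100, n_subjects=10,
            n_params=n_params,
        )

    def test_identical_likelihoods_give_p_one(self):
        assert lrt_pvalue(self._fit(-50.0, 6), self._fit(-50.0, 5)) == pytest.approx(1.0)

    def test_chi2_tail_oracle(self):
        # 2*delta = 3.8415 at df=1 -> p ~ 0.0500
        p = lrt_pvalue(self._fit(-48.07925, 6), self._fit(-50.0, 5))
        assert p == pytest.approx(0.05, abs=0.0005)
        assert p == pytest.approx(stats.chi2.sf(3.8415, 1), abs=1e-6)

    def test_p_in_unit_interval(self):
        for delta in (0.0, 0.5, 3.0, 30.0):
            p = lrt_pvalue(self._fit(-50.0 + delta, 6), self._fit(-50.0, 5))
            assert 0.0 <= p <= 1.0

    def test_reduced_beating_full_raises(self):
        with pytest.raises(FittingInconsistencyError):
            lrt_pvalue(self._fit(-51.0, 6), self._fit(-50.0, 5))

    def test_nonconverged_models_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(self._fit(-50.0, 6, converged=False), self._fit(-50.0, 5))


class TestDirectionSummary:
    def test_identical_groups_have_zero_diff(self):
        eff = {"speaking_rate": FeatureEffect(4.0, 0.0, 0.0)}
        df = _cohort_frame(eff, seed=3, n_pth=3, n_hc=3)
        df["age"] = 40.0
        df["sex"] = "female"
        # no effects at all: every value equals the deterministic mean
        _, _, diff = group_direction_summary(df, "speaking_rate", by="group")
        assert diff == pytest.approx(0.0)

    def test_hand_computed_diff(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "group": ["HC"] * 3 + ["PTH"] * 3,
                "headache": [0] * 6,
                "speaking_rate": [1, 2, 3, 2, 3, 4],
            }
        )
        mean_a, mean_b, diff = group_direction_summary(frame, "speaking_rate", by="group")
        assert (mean_a, mean_b, diff) == (2.0, 3.0, 1.0)

    def test_diff_sign_matches_simulated_effect(self):
        eff = {"pause_rate": FeatureEffect(0.2, 0.02, 0.02, group_effect=0.08)}
        df = _cohort_frame(eff, seed=9, n_pth=20, n_hc=20)
        _, _, diff = group_direction_summary(df, "pause_rate", by="group")
        assert diff > 0

    def test_empty_group_errors(self):
        import pandas as pd

        frame = pd.DataFrame({"group": ["HC"], "headache": [0], "speaking_rate": [1.0]})
        with pytest.raises(ValueError):
            group_direction_summary(frame, "speaking_rate", by="group")


def test_full_loglik_dominates_reduced():
    eff = {"speaking_rate": FeatureEffect(4.0, 0.7, 0.5, group_effect=0.3)}
    for seed in range(5):
        df = _cohort_frame(eff, seed=100 + seed, n_pth=10, n_hc=10, duration_weeks=6)
        full = fit_random_intercept_model(df, "speaking_rate", "PTH_vs_HC")
        reduced = fit_random_intercept_model(df, "speaking_rate", None)
        if full.converged and reduced.converged:
            assert full.log_likelihood >= reduced.log_likelihood - 1e-4
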