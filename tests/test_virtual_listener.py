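"""Synthetic cohorts: PTA, psychometric observers, planted structure."""

import math

import numpy as np
import pandas as pd
import pytest

from audbattery import virtual_listener as vl
from audbattery.speech_task import compute_srm


def _audiogram(values) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(vl.AUDIOGRAM_FREQS_KHZ), columns=["left", "right"])


class TestComputePTA:
    def test_flat_audiogram(self):
        assert vl.compute_pta(_audiogram(np.full((6, 2), 10.0))) == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        values = np.zeros((6, 2))
        values[:4] = np.array([[10, 10], [10, 10], [20, 20], [20, 20]])
        values[4:] = 60.0  # high frequencies are excluded from the PTA
        assert vl.compute_pta(_audiogram(values)) == pytest.approx(15.0)

    def test_asymmetric_ears_average(self):
        values = np.zeros((6, 2))
        values[:4, 1] = 20.0
        assert vl.compute_pta(_audiogram(values)) == pytest.approx(10.0)

    def test_missing_frequency_is_usage_error(self):
        aud = _audiogram(np.zeros((6, 2))).drop(index=0.5)
        with pytest.raises(vl.UsageError):
            vl.compute_pta(aud)


class TestPsychometricFunction:
    def test_guess_rate_floor(self):
        pf = vl.PsychometricFunction.for_detection(alpha=0.0, beta=0.5)
        assert pf.p_correct(-1e6) == pytest.approx(0.5)
        pf_speech = vl.PsychometricFunction.for_speech(alpha=0.0, beta=2.0)
        assert pf_speech.p_correct(-1e6) == pytest.approx(1.0 / 32.0)

    def test_unanchored_midpoint_value(self):
        # gamma 0.5, lapse 0: p(alpha) = 0.5 + 0.5 * F(0) = 0.75
        pf = vl.PsychometricFunction(alpha=0.0, beta=1.0, gamma=0.5, lapse=0.0)
        assert pf.p_correct(0.0) == pytest.approx(0.75)

    def test_anchors_pin_the_tracked_percent_points(self):
        pf = vl.PsychometricFunction.for_detection(alpha=1.0, beta=0.5)
        assert pf.p_correct(1.0) == pytest.approx(1.0 / math.sqrt(2))
        pf_speech = vl.PsychometricFunction.for_speech(alpha=-3.0, beta=2.0)
        assert pf_speech.p_correct(-3.0) == pytest.approx(0.5)

    def test_monotone_in_level(self):
        pf = vl.PsychometricFunction.for_detection(alpha=0.0, beta=0.5)
        levels = np.linspace(-4, 4, 50)
        assert np.all(np.diff(pf.p_correct(levels)) > 0)

    @pytest.mark.parametrize("responder", [vl.respond_2c2afc, vl.respond_speech])
    def test_empirical_rate_matches_formula(self, responder):
        pf = (vl.PsychometricFunction.for_detection(alpha=0.0, beta=0.5)
              if responder is vl.respond_2c2afc
              else vl.PsychometricFunction.for_speech(alpha=0.0, beta=2.0))
        level = 0.8
        rng = np.random.default_rng(1234)
        n = 10_000
        hits = sum(responder(pf, level, rng) for _ in range(n))
        p = pf.p_correct(level)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(vl.UsageError):
            vl.PsychometricFunction(alpha=0, beta=0.0)
        with pytest.raises(vl.UsageError):
            vl.PsychometricFunction(alpha=0, beta=1.0, lapse=0.5)


class TestGenerateCohort:
    def test_same_seed_identical_cohort(self):
        cfg = vl.CohortConfig(n=10)
        a = vl.cohort_frame(vl.generate_cohort(cfg, seed=3))
        b = vl.cohort_frame(vl.generate_cohort(cfg, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_age_pta_correlation_recovers_target(self):
        cfg = vl.CohortConfig(n=1000)
        frame = vl.cohort_frame(vl.generate_cohort(cfg, seed=42))
        r = np.corrcoef(frame.Age, frame.PTA)[0, 1]
        assert r == pytest.approx(0.476, abs=0.06)

    def test_profile_invariants_hold(self):
        for p in vl.generate_cohort(vl.CohortConfig(n=41), seed=11):
            assert p.pta == pytest.approx(vl.compute_pta(p.audiogram))
            assert 23.0 <= p.age <= 80.0
            co, sep = p.true_speech
            assert sep <= co + 15.0
            # interaural asymmetry kept within the recruitment criterion
            gap = (p.audiogram.left - p.audiogram.right).abs().max()
            assert gap <= 10.0 + 1e-9

    def test_zero_noise_speech_model_is_exactly_linear(self):
        sm = vl.SpeechModel(noise_sd=0.0)
        cfg = vl.CohortConfig(n=30, speech_model=sm)
        frame = vl.cohort_frame(vl.generate_cohort(cfg, seed=5))
        predicted = sm.intercept + sm.beta_age * frame.Age + sm.beta_diofm * frame.DioFM_true
        assert np.allclose(frame.SEP_true, predicted)

    def test_cohort_moments_approach_configured_values(self):
        frame = vl.cohort_frame(vl.generate_cohort(vl.CohortConfig(n=4000), seed=8))
        assert frame.TGap_true.mean() == pytest.approx(2.96, abs=0.1)
        assert frame.TGap_true.std() == pytest.approx(0.66, abs=0.05)
        assert frame.DioFM_true.std() == pytest.approx(1.43, abs=0.1)
        assert frame.Age.mean() == pytest.approx(51.5, abs=1.0)
        assert frame.SEP_true.std() == pytest.approx(3.64, abs=0.25)

    def test_asymmetric_correlation_matrix_rejected(self):
        corr = vl.CohortConfig().correlations
        corr.iloc[0, 1] = 0.9
        with pytest.raises(vl.UsageError):
            vl.CohortConfig(correlations=corr)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(vl.UsageError):
            vl.CohortConfig(n=2)


@pytest.fixture(scope="module")
def study():
    cohort = vl.generate_cohort(vl.CohortConfig(n=20), seed=77)
    return cohort, vl.run_study(cohort, seed=77)


class TestRunStudy:
    def test_schema_matches_reporting_table(self, study):
        _, results = study
        for col in vl.RESULT_COLUMNS:
            assert col in results.columns
        assert len(results) == 20

    def test_srm_column_is_co_minus_sep(self, study):
        _, results = study
        for _, row in results.iterrows():
            assert row.SRM == pytest.approx(compute_srm(row.CO, row.SEP))

    def test_deterministic_given_seed(self, study):
        cohort, results = study
        again = vl.run_study(cohort, seed=77)
        pd.testing.assert_frame_equal(results, again)

    def test_estimated_thresholds_track_planted_alphas(self, study):
        cohort, results = study
        truth = vl.cohort_frame(cohort)
        for task in ("TGap", "DioFM"):
            err = results[task].to_numpy() - truth[f"{task}_true"].to_numpy()
            assert abs(np.mean(err)) < 0.25, task  # log2-unit bias bound
            assert np.corrcoef(results[task], truth[f"{task}_true"])[0, 1] > 0.7

    def test_clone_cohort_recovery_is_unbiased_away_from_floor(self):
        # clones with a mid-range planted alpha: estimate spread is pure
        # measurement noise and the mean recovers the planted value
        import dataclasses

        base = vl.generate_cohort(vl.CohortConfig(n=3), seed=13)[0]
        clones = [
            dataclasses.replace(
                base,
                listener_id=i,
                true_thresholds={**base.true_thresholds, "STM": 3.0, "DioFM": 0.5},
            )
            for i in range(40)
        ]
        results = vl.run_study(clones, seed=99)
        assert results.STM.mean() == pytest.approx(3.0, abs=0.5)
        assert results.DioFM.mean() == pytest.approx(0.5, abs=0.25)
        # between-"listener" SD here is measurement noise only: well below
        # the cohort's planted between-listener SD
        assert results.DioFM.std() < 1.43 / 2

    def test_speech_estimates_track_planted_thetas(self, study):
        cohort, results = study
        truth = vl.cohort_frame(cohort)
        err = results.SEP.to_numpy() - truth.SEP_true.to_numpy()
        assert abs(np.mean(err) + 1.3) < 1.0  # known ~-1.3 dB score bias
        assert np.corrcoef(results.SEP, truth.SEP_true)[0, 1] > 0.85

    def test_worse_planted_ability_never_improves_estimate(self):
        # monotone fidelity: shift one listener's DioFM alpha upward and the
        # expected estimated threshold moves up as well
        cohort = vl.generate_cohort(vl.CohortConfig(n=3), seed=9)
        profile = cohort[0]
        import dataclasses

        worse = dataclasses.replace(
            profile,
            true_thresholds={**profile.true_thresholds,
                             "DioFM": profile.true_thresholds["DioFM"] + 1.5},
        )
        base = np.mean([vl.run_study([profile], seed=s).DioFM[0] for s in range(25)])
        shifted = np.mean([vl.run_study([worse], seed=s).DioFM[0] for s in range(25)])
        assert shifted > base

    def test_empty_cohort_rejected(self):
        with pytest.raises(vl.UsageError):
            vl.run_study([], seed=0)
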