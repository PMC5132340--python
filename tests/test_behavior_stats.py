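"""Bias estimation, fixation analyses and debriefing consistency."""

import numpy as np
import pandas as pd
import pytest

from priorddm import behavior_stats as bs
from priorddm import synthetic_data as sd


def _symmetric_trials(n=2000, seed=0):
    """Choices driven only by the value difference; no default bias."""
    rng = np.random.default_rng(seed)
    v_def = rng.uniform(30, 70, n)
    v_alt = rng.uniform(30, 70, n)
    dv = v_def - v_alt
    p = 1 / (1 + np.exp(-0.1 * dv))
    choice = (rng.random(n) < p).astype(int)
    rt = 0.8 + 0.5 * np.exp(-0.05 * np.abs(dv)) + rng.normal(0, 0.1, n)
    return pd.DataFrame(
        {
            "subject_id": 0,
            "opposition_id": rng.integers(1, 13, n),
            "v_def": v_def,
            "v_alt": v_alt,
            "dv_it": dv,
            "dv_cat": 10.0,
            "choice": choice,
            "rt": rt,
        }
    )


class TestChoiceBias:
    def test_symmetric_generator_yields_no_bias(self):
        est = bs.choice_bias_logistic(_symmetric_trials())
        assert abs(est.choice_bias) < 3.0
        assert est.coefficients["v_def"] == pytest.approx(0.1, rel=0.2)
        assert est.coefficients["v_alt"] == pytest.approx(-0.1, rel=0.2)
        assert not est.separated

    def test_bias_detected_on_start_biased_data(self, small_experiment):
        _, _, trials = small_experiment
        biases = [bs.choice_bias_logistic(sub).choice_bias for _, sub in trials.groupby("subject_id")]
        assert np.mean(biases) > 5.0

    def test_dv_cat_covariate_attenuates_the_constant(self, small_experiment):
        _, _, trials = small_experiment
        plain, with_cat = [], []
        for _, sub in trials.groupby("subject_id"):
            plain.append(bs.choice_bias_logistic(sub).coefficients["const"])
            with_cat.append(bs.choice_bias_logistic(sub, include_dv_cat=True).coefficients["const"])
        assert np.mean(with_cat) < np.mean(plain)

    def test_all_default_choices_flagged_as_separated(self):
        t = _symmetric_trials(200, seed=1)
        t["choice"] = 1
        est = bs.choice_bias_logistic(t)
        assert est.separated
        assert est.choice_bias > 0

    def test_logistic_bias_matches_binned_rate_near_null_value(self):
        t = _symmetric_trials(20000, seed=2)
        est = bs.choice_bias_logistic(t)
        near = t[np.abs(t.dv_it) < 2.0]
        raw = 100 * (near["choice"].mean() - 0.5)
        assert abs(est.choice_bias - raw) < 2.0


class TestRtBias:
    def test_unbiased_data_has_null_rt_bias(self):
        est = bs.rt_bias_glm(_symmetric_trials())
        assert abs(est.rt_bias) < 0.05
        assert est.coefficients["abs_dv"] < 0  # harder choices are slower

    def test_bias_detected_on_start_biased_data(self, small_experiment):
        _, _, trials = small_experiment
        rbs = [bs.rt_bias_glm(sub).rt_bias for _, sub in trials.groupby("subject_id")]
        assert np.mean(rbs) > 0.1

    def test_requires_both_choice_types(self):
        t = _symmetric_trials(100, seed=3)
        t["choice"] = 1
        with pytest.raises(ValueError):
            bs.rt_bias_glm(t)


class TestBlockwise:
    def test_positive_bias_correlation_under_start_truth(self):
        cfg = sd.GeneratorConfig(n_subjects=8, seed=2)
        _, trials = sd.generate_experiment(cfg)
        res = bs.blockwise_bias_correlation(trials)
        assert res["group"]["n"] >= 6
        assert np.isfinite(res["group"]["t"])

    def test_permuting_rt_biases_destroys_correlation(self, small_experiment):
        _, _, trials = small_experiment
        rng = np.random.default_rng(0)
        rs_perm = []
        for _, sub in trials.groupby("subject_id"):
            blocks = bs.blockwise_biases(sub)
            for _ in range(20):
                perm = rng.permutation(blocks["rt_bias"].to_numpy())
                rs_perm.append(np.corrcoef(blocks["choice_bias"], perm)[0, 1])
        assert abs(np.mean(rs_perm)) < 0.1


class TestBiasByRtBins:
    def test_single_bin_equals_overall_bias(self, small_experiment):
        _, _, trials = small_experiment
        sub = trials[trials.subject_id == 0]
        one = bs.bias_by_rt_bins(sub, n_bins=1)
        overall = bs.choice_bias_logistic(sub)
        assert len(one) == 1
        assert one["choice_bias"].iloc[0] == pytest.approx(overall.choice_bias, abs=1e-9)

    def test_start_bias_decays_over_rt_bins(self, small_experiment):
        _, _, trials = small_experiment
        binned = bs.bias_by_rt_bins(trials, n_bins=4)
        means = binned.groupby("rt_bin")["choice_bias"].mean()
        assert means.iloc[0] > means.iloc[-1]

    def test_bin_count_validation(self, small_experiment):
        _, _, trials = small_experiment
        with pytest.raises(ValueError):
            bs.bias_by_rt_bins(trials, n_bins=0)


class TestChoiceCurve:
    def test_monotone_choice_curve(self, small_experiment):
        _, _, trials = small_experiment
        curve = bs.choice_curve(trials, n_bins=10)
        # increasing in dv_it: any local inversion must be within binomial
        # noise of the bin estimates (the generating curve is strictly
        # monotone; the empirical one saturates near 1)
        p = curve["p_default"].to_numpy()
        se = np.sqrt(np.clip(p * (1 - p), 1e-4, None) / curve["n"].to_numpy())
        diffs = np.diff(p)
        tol = 2.5 * np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
        assert np.all(diffs > -tol)
        assert p[-1] > p[0] + 0.3


class TestFixations:
    def test_choice_independent_streams_show_no_last_fixation_effect(self):
        cfg = sd.GeneratorConfig(n_subjects=3, seed=10, fixations=True)
        _, trials = sd.generate_experiment(cfg)
        res = bs.fixation_summaries(trials)
        assert abs(res["per_subject"]["p_choose_last_fixated"].mean() - 0.5) < 0.05

    def test_accumulator_coupled_fixations_predict_choice(self, fixation_experiment):
        _, _, trials = fixation_experiment
        res = bs.fixation_summaries(trials)
        assert res["per_subject"]["p_choose_last_fixated"].mean() > 0.5
        assert res["per_subject"]["p_choose_most_fixated"].mean() > 0.5

    def test_fixation_proportions_never_exceed_one(self, fixation_experiment):
        _, _, trials = fixation_experiment
        tc = bs.fixation_summaries(trials)["time_courses"]
        total_on = tc["onset_default"] + tc["onset_alternative"]
        total_resp = tc["response_default"] + tc["response_alternative"]
        assert np.all(total_on <= 1.0 + 1e-9)
        assert np.all(total_resp <= 1.0 + 1e-9)

    def test_missing_fixation_streams_rejected(self, small_experiment):
        _, _, trials = small_experiment
        with pytest.raises(ValueError):
            bs.fixation_summaries(trials)


class TestGazeClassification:
    WIN_L = (0.0, 0.0, 0.4, 1.0)
    WIN_R = (0.6, 0.0, 1.0, 1.0)

    def test_all_left_samples_merge_to_single_fixation(self):
        t = np.arange(0, 1.0, 1 / 60)
        samples = pd.DataFrame({"t": t, "x": 0.2, "y": 0.5})
        fx = bs.gaze_to_fixations(samples, self.WIN_L, self.WIN_R, side_of_default="left")
        assert len(fx) == 1
        assert fx["target"].iloc[0] == "default"
        assert fx["duration"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_round_trip_recovers_known_sequence(self):
        seq = [("left", 0.3), ("right", 0.25), ("left", 0.1), ("right", 0.4)]
        rows = []
        t = 0.0
        step = 1 / 60
        for side, dur in seq:
            n = int(round(dur / step))
            x = 0.2 if side == "left" else 0.8
            for _ in range(n):
                rows.append((t, x, 0.5))
                t += step
        samples = pd.DataFrame(rows, columns=["t", "x", "y"])
        fx = bs.gaze_to_fixations(samples, self.WIN_L, self.WIN_R, side_of_default="right")
        expect_targets = ["alternative", "default", "alternative", "default"]
        assert fx["target"].tolist() == expect_targets
        np.testing.assert_allclose(fx["duration"], [d for _, d in seq], atol=0.02)

    def test_off_window_samples_become_none(self):
        samples = pd.DataFrame({"t": [0.0, 0.016, 0.033], "x": 0.5, "y": 0.5})
        fx = bs.gaze_to_fixations(samples, self.WIN_L, self.WIN_R)
        assert (fx["target"] == "none").all()

    def test_nonmonotone_timestamps_rejected(self):
        samples = pd.DataFrame({"t": [0.0, 0.2, 0.1], "x": 0.2, "y": 0.5})
        with pytest.raises(ValueError):
            bs.gaze_to_fixations(samples, self.WIN_L, self.WIN_R)


class TestDebrief:
    def test_deterministic_debrief_matches_perfectly(self, small_experiment):
        _, ratings, _ = small_experiment
        debrief = sd.generate_debrief(ratings, temperature=0.0, conf_noise_sd=0.0, seed=0)
        res = bs.debrief_consistency(ratings, debrief)
        assert res["mean_match_rate"] == 1.0

    def test_match_rate_decreases_with_choice_noise(self, small_experiment):
        _, ratings, _ = small_experiment
        rates = []
        for temp in (0.0, 5.0, 20.0):
            debrief = sd.generate_debrief(ratings, temperature=temp, seed=1)
            rates.append(bs.debrief_consistency(ratings, debrief)["mean_match_rate"])
        assert rates[0] >= rates[1] >= rates[2]
        assert 0.5 < rates[2] < 1.0

    def test_confidence_tracks_category_preference(self, small_experiment):
        _, ratings, _ = small_experiment
        debrief = sd.generate_debrief(ratings, conf_noise_sd=2.0, seed=2)
        res = bs.debrief_consistency(ratings, debrief)
        assert res["group_confidence_r"]["mean"] > 0.3
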