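"""Structure, determinism and calibration of the synthetic experiments."""

import io

import numpy as np
import pandas as pd
import pytest

from priorddm import model_space
from priorddm import synthetic_data as sd


def _table_bytes(df: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue().encode()


class TestRatings:
    def test_counts_and_range(self, small_experiment):
        _, ratings, _ = small_experiment
        for _, sub in ratings.groupby("subject_id"):
            assert len(sub) == 432
            assert sub.groupby("category").size().eq(36).all()
            assert sub["category"].nunique() == 12
            assert sub["domain"].nunique() == 3
        assert ratings["rating"].between(0, 100).all()

    def test_zero_noise_collapses_to_category_means(self):
        cfg = sd.GeneratorConfig(n_subjects=1, rating_noise_sd=0.0, seed=3)
        ratings = sd.generate_ratings(cfg)
        assert ratings.groupby("category")["rating"].std().max() == 0.0

    def test_within_category_spread_matches_configured_sd(self):
        # pooled across many categories, the empirical SD estimates the
        # configured (2.5-SD-truncated) noise SD; tolerance = 3 SE
        cfg = sd.GeneratorConfig(n_subjects=24, rating_noise_sd=8.0, seed=17)
        ratings = sd.generate_ratings(cfg)
        sds = ratings.groupby(["subject_id", "category"])["rating"].std()
        trunc_factor = 0.9823  # SD shrinkage of a +-2.5 sigma truncated normal
        expect = 8.0 * trunc_factor
        se = sds.std() / np.sqrt(len(sds))
        assert abs(sds.mean() - expect) < 3 * se

    def test_seed_determinism_byte_identical(self):
        cfg = sd.GeneratorConfig(n_subjects=2, seed=11)
        a = sd.generate_ratings(cfg)
        b = sd.generate_ratings(cfg)
        assert _table_bytes(a) == _table_bytes(b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.GeneratorConfig(n_subjects=0)
        with pytest.raises(ValueError):
            sd.GeneratorConfig(rating_noise_sd=-1.0)
        with pytest.raises(ValueError):
            sd.GeneratorConfig(category_mean_levels=(1.0, 2.0))


class TestChoiceDesign:
    def test_structure(self, small_experiment):
        _, ratings, _ = small_experiment
        sub = ratings[ratings["subject_id"] == 0]
        design = sd.build_choice_design(sub)
        assert len(design) == 432
        assert design["opposition_id"].nunique() == 12
        per_opp = design.groupby("opposition_id")
        assert per_opp.size().eq(36).all()
        # 4 blocks of 9 trials per opposition
        for _, grp in per_opp:
            assert grp.groupby("block").size().eq(9).all()
        # each item appears exactly twice across the design
        items = pd.concat([design["item_left"], design["item_right"]])
        assert items.value_counts().eq(2).all()

    def test_one_item_per_category_per_trial(self, small_experiment):
        _, ratings, _ = small_experiment
        sub = ratings[ratings["subject_id"] == 1]
        design = sd.build_choice_design(sub)
        cat_of = sub.set_index("item_id")["category"]
        left = cat_of.loc[design["item_left"]].to_numpy()
        right = cat_of.loc[design["item_right"]].to_numpy()
        is_def_left = design["side_of_default"] == "left"
        def_cat = np.where(is_def_left, left, right)
        alt_cat = np.where(is_def_left, right, left)
        assert (def_cat == design["cat_default"]).all()
        assert (alt_cat == design["cat_alternative"]).all()

    def test_mean_and_relative_value_orthogonalized(self, small_experiment):
        _, ratings, trials = small_experiment
        rs = [
            abs(np.corrcoef((g["v_def"] + g["v_alt"]) / 2, g["dv_it"].abs())[0, 1])
            for _, g in trials.groupby(["subject_id", "opposition_id"])
        ]
        rs = np.array(rs)
        assert rs.mean() < 0.1
        assert np.percentile(rs, 90) < 0.2

    def test_degenerate_constant_ratings_give_zero_decision_values(self):
        cfg = sd.GeneratorConfig(n_subjects=1, rating_noise_sd=0.0, seed=2)
        ratings = sd.generate_ratings(cfg)
        ratings["rating"] = 50.0
        design = sd.build_choice_design(ratings)
        vals = ratings.set_index("item_id")["rating"]
        dv = vals.loc[design["item_left"]].to_numpy() - vals.loc[design["item_right"]].to_numpy()
        assert np.all(dv == 0.0)

    def test_requires_single_complete_subject(self, small_experiment):
        _, ratings, _ = small_experiment
        with pytest.raises(ValueError):
            sd.build_choice_design(ratings)  # several subjects
        with pytest.raises(ValueError):
            sd.build_choice_design(ratings.head(100))


class TestSimulatedBehavior:
    def test_trial_record_invariants(self, small_experiment):
        cfg, ratings, trials = small_experiment
        assert (trials["rt"] > cfg.tnd).all()
        assert (trials["dv_cat"] >= 0).all()
        np.testing.assert_allclose(trials["dv_it"], trials["v_def"] - trials["v_alt"])

    def test_dv_cat_recomputable_from_ratings(self, small_experiment):
        _, ratings, trials = small_experiment
        sub_r = ratings[ratings["subject_id"] == 0]
        means = sub_r.groupby("category")["rating"].mean()
        sub_t = trials[trials["subject_id"] == 0]
        design = sd.build_choice_design(sub_r)
        cats = design.groupby("opposition_id")[["cat_default", "cat_alternative"]].first()
        for opp, grp in sub_t.groupby("opposition_id"):
            expect = means[cats.loc[opp, "cat_default"]] - means[cats.loc[opp, "cat_alternative"]]
            np.testing.assert_allclose(grp["dv_cat"], expect)

    def test_full_determinism(self):
        cfg = sd.GeneratorConfig(n_subjects=1, seed=21)
        a = sd.generate_experiment(cfg)[1]
        b = sd.generate_experiment(cfg)[1]
        assert _table_bytes(a) == _table_bytes(b)

    def test_unbiased_generator_is_at_chance_on_null_value_trials(self):
        # flat ratings => dv_it = dv_cat = 0 on every trial; with the null
        # model truth the default rate must be at chance up to MC error
        cfg = sd.GeneratorConfig(
            n_subjects=4, rating_noise_sd=0.0, category_mean_jitter_sd=0.0,
            model="null", rt_noise_sd=0.0, seed=31,
        )
        ratings = sd.generate_ratings(cfg)
        ratings["rating"] = 50.0
        trials = []
        for s, sub in ratings.groupby("subject_id"):
            trials.append(sd.simulate_behavior(sd.build_choice_design(sub), sub, cfg))
        trials = pd.concat(trials)
        n = len(trials)
        assert abs(trials["choice"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_start_bias_shifts_choices_and_speeds_default(self):
        # flat ratings (dv_it = 0 everywhere) + a planted constant start
        # shift: choices must favor the default and default choices be faster
        cfg = sd.GeneratorConfig(
            n_subjects=4, rating_noise_sd=0.0, category_mean_jitter_sd=0.0,
            model="s_free", extra_params={"s0": 0.4}, rt_noise_sd=0.0, seed=33,
        )
        ratings = sd.generate_ratings(cfg)
        ratings["rating"] = 50.0
        trials = pd.concat(
            sd.simulate_behavior(sd.build_choice_design(sub), sub, cfg)
            for _, sub in ratings.groupby("subject_id")
        )
        assert (trials["dv_it"] == 0).all()
        assert trials["choice"].mean() > 0.55
        assert trials.loc[trials.choice == 1, "rt"].mean() < trials.loc[trials.choice == 0, "rt"].mean()

    def test_choice_bias_monotone_in_start_coefficient(self):
        from priorddm import behavior_stats as bs

        biases = []
        for a in (0.0, 0.01, 0.03):
            cfg = sd.GeneratorConfig(n_subjects=2, start_coef=a, seed=37)
            _, trials = sd.generate_experiment(cfg)
            biases.append(
                np.mean([bs.choice_bias_logistic(s).choice_bias for _, s in trials.groupby("subject_id")])
            )
        assert biases[0] < biases[1] < biases[2]

    def test_simulated_choice_rates_match_closed_form_by_value_bin(self):
        from priorddm.ddm_core import p_upper

        cfg = sd.GeneratorConfig(n_subjects=6, seed=41, rt_noise_sd=0.0)
        _, trials = sd.generate_experiment(cfg)
        spec = model_space.get_model("s_dvcat")
        theta = np.array(
            [cfg.alpha, np.log(cfg.boundary), np.log(cfg.tnd), np.log(0.1), cfg.start_coef]
        )
        mu, z, a, _, _ = model_space.trial_params_vec(spec, theta, trials)
        p = p_upper(z, a, mu, cfg.sigma**2)
        bins = pd.qcut(trials["dv_it"], 8, labels=False)
        for b in range(8):
            m = bins == b
            n = int(m.sum())
            expect = p[m.to_numpy()].mean()
            se = np.sqrt(max(expect * (1 - expect), 1e-4) / n)
            assert abs(trials.loc[m, "choice"].mean() - expect) < 3.5 * se

    def test_attentional_generator_requires_fixations(self):
        cfg = sd.GeneratorConfig(n_subjects=1, model="asddm", fixations=False, seed=1)
        ratings = sd.generate_ratings(cfg)
        sub = ratings[ratings["subject_id"] == 0]
        with pytest.raises(ValueError):
            sd.simulate_behavior(sd.build_choice_design(sub), sub, cfg)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = sd.GeneratorConfig(n_subjects=3, seed=8, theta=0.9)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = sd.GeneratorConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_write_tables(self, tmp_path, small_experiment):
        cfg, ratings, trials = small_experiment
        sd.write_tables(tmp_path, ratings, trials, cfg)
        assert (tmp_path / "ratings.tsv").exists()
        got = pd.read_csv(tmp_path / "trials.tsv", sep="\t")
        assert len(got) == len(trials)
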