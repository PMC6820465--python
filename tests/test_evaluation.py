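"""Posterior predictive checks, behavioral regressions (coding, null
calibration, power) and the parameter-recovery study."""

import numpy as np
import pandas as pd
import pytest

from rlddm.design import BanditDesign
from rlddm.evaluation import (RegressionLikelihood, default_generating_group,
                              fit_accuracy_regression, fit_rt_regression,
                              observed_pair_bin_summary,
                              parameter_recovery_study,
                              posterior_predictive_check)
from rlddm.inference import SamplerConfig
from rlddm.models import ModelSpec, RLDDMParameters, simulate_experiment
from tests.conftest import null_behavior_table


class TestPPC:
    def test_exact_number_of_predictive_datasets_and_bins(self, rlddm1_fit):
        ppc = posterior_predictive_check(rlddm1_fit, n_draws=100, seed=0)
        assert ppc.n_draws == 100
        # 4 pairs x 8 bins of 10 within-block trials
        assert len(ppc.table) == 32
        assert sorted(ppc.table["bin"].unique()) == list(range(1, 9))

    def test_quantiles_ordered_and_cover_mean(self, rlddm1_fit):
        t = posterior_predictive_check(rlddm1_fit, n_draws=100, seed=1).table
        assert (t["predicted_accuracy_lo"] <= t["predicted_accuracy_hi"]).all()
        assert (t["predicted_accuracy_lo"] <= t["predicted_accuracy"]).all()
        assert (t["predicted_rt_lo"] <= t["predicted_rt_hi"]).all()

    def test_requesting_more_draws_than_retained_fails(self, rlddm1_fit):
        with pytest.raises(ValueError, match="exceeds"):
            posterior_predictive_check(rlddm1_fit, n_draws=10 ** 7)

    def test_observed_columns_reproduce_recorded_data(self, rlddm1_fit,
                                                      design, rlddm1_table):
        """Self-check path: observed summaries in the PPC table are exactly
        the recorded data's summaries."""
        ppc = posterior_predictive_check(rlddm1_fit, n_draws=50, seed=2)
        obs = observed_pair_bin_summary(rlddm1_table, design)
        merged = ppc.table.merge(obs, on=["pair", "bin"])
        assert np.allclose(merged["observed_accuracy_x"],
                           merged["observed_accuracy_y"])
        assert np.allclose(merged["observed_rt_x"], merged["observed_rt_y"])

    def test_predictions_track_observed_learning_curve(self, rlddm1_fit):
        """The fitted model's predictive band should contain most observed
        per-(pair, bin) accuracies (the data were generated by this model)."""
        t = posterior_predictive_check(rlddm1_fit, n_draws=200, seed=3).table
        inside = ((t["observed_accuracy"] >= t["predicted_accuracy_lo"]) &
                  (t["observed_accuracy"] <= t["predicted_accuracy_hi"]))
        assert inside.mean() >= 0.8


class TestRegressionCoding:
    def test_difficulty_coded_plus_minus_one(self, design, rlddm1_table):
        like = RegressionLikelihood(rlddm1_table, design, "logistic")
        X = np.vstack(like._X)
        assert set(np.unique(X[:, 2])) == {-1.0, 1.0}
        # standardized magnitude: mean 0, sd 1
        assert abs(X[:, 1].mean()) < 1e-9
        assert X[:, 1].std() == pytest.approx(1.0)
        assert np.allclose(X[:, 3], X[:, 1] * X[:, 2])

    def test_affine_magnitude_recoding_is_invariant(self, rlddm1_table):
        """Standardization makes the design matrix invariant to affine
        recoding of the pair magnitudes."""
        d1 = BanditDesign()
        d2 = BanditDesign(option_means=tuple(2.0 * m + 7 for m in d1.option_means))
        x1 = np.vstack(RegressionLikelihood(rlddm1_table, d1, "logistic")._X)
        x2 = np.vstack(RegressionLikelihood(rlddm1_table, d2, "logistic")._X)
        assert np.allclose(x1, x2)

    def test_nonpositive_rt_rejected(self, design, rlddm1_table):
        bad = rlddm1_table.copy()
        bad.loc[bad.index[0], "rt"] = -0.5
        with pytest.raises(ValueError, match="log"):
            RegressionLikelihood(bad, design, "linear")

    def test_single_subject_rejected(self, design, rlddm1_table):
        solo = rlddm1_table[rlddm1_table["subject"] == 1]
        with pytest.raises(ValueError, match="2 subjects"):
            RegressionLikelihood(solo, design, "logistic")


class TestRegressionCalibrationAndPower:
    def test_null_data_effects_contain_zero(self, null_calibration_accuracy):
        """With no true effects, all three effect BCIs contain 0 in at least
        18 of 20 replications."""
        all_three = null_calibration_accuracy.all(axis=1)
        assert all_three.sum() >= 18

    def test_null_rt_interaction_contains_zero(self, design):
        cfg = SamplerConfig(n_iter_start=400, n_iter_max=400,
                            max_pointwise_draws=100)
        hits = 0
        for rep in range(5):
            tab = null_behavior_table(design, n_subjects=6, seed=2000 + rep)
            res = fit_rt_regression(tab, design, config=cfg, seed=rep)
            lo, hi = res.bci("interaction")
            hits += int(lo <= 0 <= hi)
        assert hits >= 4

    def test_injected_difficulty_effect_detected(self, design):
        """Accuracy strongly dependent on difficulty class: the difficulty
        BCI must exclude 0."""
        rng = np.random.default_rng(7)
        tab = null_behavior_table(design, n_subjects=10, seed=77)
        from rlddm.design import pair_statistics
        easy_pairs = set(pair_statistics(design).query(
            "difficulty_class == 'easy'")["pair"])
        easy = tab["pair"].isin(easy_pairs).to_numpy()
        acc = np.where(easy, rng.random(len(tab)) < 0.88,
                       rng.random(len(tab)) < 0.62).astype(int)
        tab["accuracy"] = acc
        higher = tab["pair"].map(design.higher_mean_option)
        lower = [p[0] if p[1] == h else p[1]
                 for p, h in zip(tab["pair"], higher)]
        tab["chosen_option"] = np.where(acc == 1, higher, lower)
        cfg = SamplerConfig(n_iter_start=600, n_iter_max=600,
                            max_pointwise_draws=100)
        res = fit_accuracy_regression(tab, design, config=cfg, seed=3)
        lo, hi = res.bci("difficulty")
        assert lo > 0

    def test_threshold_modulation_produces_negative_magnitude_effect(self, design):
        """Data simulated with a_mod < 0 (lower thresholds for richer pairs)
        must show a negative magnitude coefficient on log RT."""
        spec = ModelSpec("RLDDM", 8)
        p = RLDDMParameters(eta_plus=0.14, eta_minus=0.10, v_mod=0.3,
                            v_max=2.5, a_fix=np.log(2.0) , a_mod=-0.02,
                            t_er=0.4)
        tab = simulate_experiment(design, spec, p, n_subjects=15, seed=41)
        cfg = SamplerConfig(n_iter_start=600, n_iter_max=600,
                            max_pointwise_draws=100)
        res = fit_rt_regression(tab, design, config=cfg, seed=4)
        lo, hi = res.bci("magnitude")
        assert hi < 0


class TestParameterRecovery:
    def test_coverage_at_study_scale(self, recovery_rlddm1):
        """Pooled group-mean 95% BCI coverage across 5 replications of the
        12-subject study must reach 80%."""
        assert recovery_rlddm1.coverage() >= 0.8

    def test_subject_rank_correlations_positive(self, recovery_rlddm1):
        med = recovery_rlddm1.table.groupby("parameter")["rank_corr"].median()
        assert (med > 0.5).drop("eta", errors="ignore").all()

    def test_report_reproducible_under_fixed_seed(self, design):
        cfg = SamplerConfig(n_iter_start=100, n_iter_max=100,
                            max_pointwise_draws=50)
        a = parameter_recovery_study(ModelSpec("RL", 1), design, n_subjects=4,
                                     n_replications=1, seed=5, config=cfg)
        b = parameter_recovery_study(ModelSpec("RL", 1), design, n_subjects=4,
                                     n_replications=1, seed=5, config=cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_degenerate_zero_sd_flags_rank_correlation(self, design):
        cfg = SamplerConfig(n_iter_start=100, n_iter_max=100,
                            max_pointwise_draws=50)
        gen = {"eta": (0.2, 0.0), "theta": (0.12, 0.0)}
        rep = parameter_recovery_study(ModelSpec("RL", 1), design,
                                       generating=gen, n_subjects=4,
                                       n_replications=1, seed=6, config=cfg)
        assert rep.table["rank_corr"].isna().all()

    def test_more_trials_do_not_worsen_group_estimates(self, design):
        """Mean absolute error of group-mean estimates with doubled trials
        per subject should not exceed the short-design error by more than
        the replication spread."""
        cfg = SamplerConfig(n_iter_start=300, n_iter_max=300,
                            max_pointwise_draws=50)
        d6 = BanditDesign(n_blocks=6)
        maes = {}
        for name, d in [("short", design), ("long", d6)]:
            rep = parameter_recovery_study(ModelSpec("RL", 1), d,
                                           n_subjects=6, n_replications=2,
                                           seed=9, config=cfg)
            t = rep.table
            maes[name] = (t["estimate"] - t["generating"]).abs().mean()
        assert maes["long"] <= maes["short"] + 0.05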