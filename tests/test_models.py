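"""Combined-model assembly: drift/threshold mappings, trialwise parameters,
joint likelihood against loop oracles, nesting identities, forward simulation
properties (learning, magnitude and null effects)."""

import numpy as np
import pandas as pd
import pytest

from rlddm.design import BanditDesign
from rlddm.learning import RLParameters, q_trajectory
from rlddm.models import (ModelSpec, RLDDMParameters, build_trialwise_parameters,
                          drift_linear, drift_sigmoid, make_params,
                          pedersen_trial_modulators, rlddm_log_likelihood,
                          simulate_experiment, threshold_value_modulated)
from rlddm.wfpt import DDMParameters, wfpt_log_density
from tests.conftest import toy_trials


class TestModelSpace:
    @pytest.mark.parametrize("cls,n", [("RL", 4), ("DDM", 3), ("RLDDM", 8),
                                       ("PedersenRLDDM", 4)])
    def test_all_named_variants_constructible(self, cls, n, design):
        for v in range(1, n + 1):
            spec = ModelSpec(cls, v)
            assert spec.param_names(design)

    @pytest.mark.parametrize("cls,v", [("RL", 5), ("DDM", 4), ("RLDDM", 9),
                                       ("PedersenRLDDM", 0), ("XYZ", 1)])
    def test_unlisted_combinations_rejected(self, cls, v):
        with pytest.raises(ValueError):
            ModelSpec(cls, v)

    def test_rlddm8_parameter_names(self, design):
        assert ModelSpec("RLDDM", 8).param_names(design) == [
            "eta_plus", "eta_minus", "v_mod", "v_max", "a_fix", "a_mod", "t_er"]

    def test_sigmoid_spec_without_vmax_rejected(self):
        spec = ModelSpec("RLDDM", 5)
        with pytest.raises(ValueError, match="v_max"):
            RLDDMParameters(eta_plus=0.1, v_mod=0.2, a=2.0)._vector(spec)


class TestMappings:
    def test_linear_drift(self):
        assert drift_linear(40.0, 40.0, 0.5) == 0.0
        assert drift_linear(50.0, 36.0, 0.1) == pytest.approx(1.4)
        assert drift_linear(36.0, 50.0, 0.1) == -drift_linear(50.0, 36.0, 0.1)

    def test_sigmoid_drift(self):
        assert drift_sigmoid(40.0, 40.0, 0.5, 3.0) == 0.0
        assert drift_sigmoid(1e6, 0.0, 1.0, 3.0) == pytest.approx(3.0)
        assert drift_sigmoid(0.0, 1e6, 1.0, 3.0) == pytest.approx(-3.0)
        val = drift_sigmoid(42.0, 40.0, 0.5, 3.0)  # z = 1
        assert val == pytest.approx(6 / (1 + np.exp(-1)) - 3)
        assert val == pytest.approx(1.3863, abs=1e-3)
        assert drift_sigmoid(40.0, 42.0, 0.5, 3.0) == pytest.approx(-val)

    def test_value_modulated_threshold(self):
        assert threshold_value_modulated(0.7, 0.0, 10.0) == \
            threshold_value_modulated(0.7, 0.0, 50.0) == pytest.approx(np.exp(0.7))
        assert threshold_value_modulated(0.5, -0.02, 50.0) == \
            pytest.approx(np.exp(-0.5))
        a_vals = [threshold_value_modulated(0.5, -0.02, q) for q in (38, 43, 47, 52)]
        assert np.all(np.diff(a_vals) < 0)
        assert min(a_vals) > 0

    def test_pedersen_modulators(self):
        assert pedersen_trial_modulators(5, 2.0, 0.3, 0.0, 0.0) == (2.0, 0.3)
        a_t, _ = pedersen_trial_modulators(4, 2.0, 0.3, 0.5, 0.0)
        assert a_t == pytest.approx(1.0)
        a_series = [pedersen_trial_modulators(t, 2.0, 0.3, 0.3, 0.2)[0]
                    for t in range(1, 11)]
        m_series = [pedersen_trial_modulators(t, 2.0, 0.3, 0.3, 0.2)[1]
                    for t in range(1, 11)]
        assert np.all(np.diff(a_series) <= 0)
        assert np.all(np.diff(m_series) >= 0)
        with pytest.raises(ValueError):
            pedersen_trial_modulators(0, 2.0, 0.3, 0.1, 0.1)


class TestTrialwiseParameters:
    def test_modulated_with_amod0_reduces_to_fixed(self, design, toy_table_10):
        p_mod = RLDDMParameters(eta_plus=0.2, v_mod=0.3, a_fix=np.log(2.0),
                                a_mod=0.0, t_er=0.3)
        p_fix = RLDDMParameters(eta_plus=0.2, v_mod=0.3, a=2.0, t_er=0.3)
        t_mod = build_trialwise_parameters(toy_table_10, ModelSpec("RLDDM", 3),
                                           p_mod, design)
        t_fix = build_trialwise_parameters(toy_table_10, ModelSpec("RLDDM", 1),
                                           p_fix, design)
        assert np.array_equal(t_mod["v_t"], t_fix["v_t"])
        assert np.array_equal(t_mod["a_t"], t_fix["a_t"])

    def test_sigmoid_with_huge_vmax_approaches_linear(self, design, toy_table_10):
        """The S-shaped map resembles the linear one only in the limit: for
        large v_max, S(v_mod dq) ~ (v_max v_mod / 2) dq, so a sigmoid with
        v_mod = 2 v_lin / v_max reproduces a linear model with slope v_lin."""
        v_lin, v_max = 0.05, 1e6
        p_lin = RLDDMParameters(eta_plus=0.2, v_mod=v_lin, a=2.0, t_er=0.3)
        p_sig = RLDDMParameters(eta_plus=0.2, v_mod=2 * v_lin / v_max,
                                v_max=v_max, a=2.0, t_er=0.3)
        t_lin = build_trialwise_parameters(toy_table_10, ModelSpec("RLDDM", 1),
                                           p_lin, design)
        t_sig = build_trialwise_parameters(toy_table_10, ModelSpec("RLDDM", 5),
                                           p_sig, design)
        assert np.abs(t_lin["v_t"] - t_sig["v_t"]).max() < 1e-3

    def test_no_learning_equal_values_gives_zero_drift(self, design, toy_table_10):
        p = RLDDMParameters(eta_plus=0.0, v_mod=0.3, a=2.0, t_er=0.3)
        t = build_trialwise_parameters(toy_table_10, ModelSpec("RLDDM", 1),
                                       p, design)
        assert (t["v_t"] == 0.0).all()
        assert (t["a_t"] == 2.0).all()

    def test_q_values_enter_before_update(self, design, toy_table_10):
        """Trialwise q_cor matches the learning module's entering-values
        trajectory."""
        p = RLDDMParameters(eta_plus=0.3, v_mod=0.2, a=2.0, t_er=0.3)
        tw = build_trialwise_parameters(toy_table_10, ModelSpec("RLDDM", 1),
                                        p, design)
        traj = q_trajectory(toy_table_10, RLParameters(eta_plus=0.3), design)
        for i, row in toy_table_10.iterrows():
            cor = design.higher_mean_option(row["pair"])
            assert tw.loc[i, "q_cor"] == pytest.approx(traj.loc[i, f"q_{cor}"])

    def test_rl_spec_has_no_trialwise_parameters(self, design, toy_table_10):
        with pytest.raises(ValueError):
            build_trialwise_parameters(toy_table_10, ModelSpec("RL", 1),
                                       RLDDMParameters(eta_plus=0.1), design)


class TestJointLikelihood:
    def test_matches_loop_oracle(self, design, toy_table_10):
        """Brute-force recomputation: trialwise (v, a) from the mapping
        functions plus scalar density calls."""
        spec = ModelSpec("RLDDM", 3)
        p = RLDDMParameters(eta_plus=0.25, v_mod=0.2, a_fix=0.8, a_mod=-0.01,
                            t_er=0.2)
        tw = build_trialwise_parameters(toy_table_10, spec, p, design)
        expected = 0.0
        for i, row in toy_table_10.iterrows():
            dp = DDMParameters(v=tw.loc[i, "v_t"], a=tw.loc[i, "a_t"], t_er=0.2)
            expected += wfpt_log_density(
                row["rt"], "upper" if row["accuracy"] == 1 else "lower", dp)
        assert rlddm_log_likelihood(toy_table_10, spec, p, design) == \
            pytest.approx(expected, rel=1e-9)

    def test_dual_rate_equal_rates_bitwise_single(self, design, toy_table_10):
        p1 = RLDDMParameters(eta_plus=0.2, v_mod=0.25, a=2.0, t_er=0.2)
        p2 = RLDDMParameters(eta_plus=0.2, eta_minus=0.2, v_mod=0.25, a=2.0,
                             t_er=0.2)
        assert rlddm_log_likelihood(toy_table_10, ModelSpec("RLDDM", 1), p1, design) == \
            rlddm_log_likelihood(toy_table_10, ModelSpec("RLDDM", 2), p2, design)

    def test_no_learning_reduces_to_static_ddm(self, design, toy_table_10):
        from rlddm.wfpt import ddm_log_likelihood
        p = RLDDMParameters(eta_plus=0.0, v_mod=0.5, a=2.0, t_er=0.2)
        ll_rlddm = rlddm_log_likelihood(toy_table_10, ModelSpec("RLDDM", 1),
                                        p, design)
        # eta = 0 with equal initial Qs: v_t = 0 and a constant
        ll_ddm = ddm_log_likelihood(toy_table_10, design, 1,
                                    {"easy": 0.0, "difficult": 0.0},
                                    {"all": 2.0}, 0.2)
        assert ll_rlddm == pytest.approx(ll_ddm, rel=1e-9)

    def test_nondecision_time_above_min_rt_gives_neg_inf(self, design,
                                                         toy_table_10):
        p = RLDDMParameters(eta_plus=0.2, v_mod=0.25, a=2.0,
                            t_er=float(toy_table_10["rt"].min() + 0.01))
        assert rlddm_log_likelihood(toy_table_10, ModelSpec("RLDDM", 1),
                                    p, design) == -np.inf

    @pytest.mark.parametrize("cls,variant", [("RLDDM", v) for v in range(1, 9)] +
                             [("PedersenRLDDM", v) for v in range(1, 5)])
    def test_all_combined_variants_finite_on_simulated_data(self, design, cls,
                                                            variant):
        from rlddm.evaluation import default_generating_group
        spec = ModelSpec(cls, variant)
        gen = default_generating_group(spec, design)
        params = make_params(spec, {k: v[0] for k, v in gen.items()})
        tab = simulate_experiment(design, spec, params, n_subjects=2, seed=variant)
        ll = rlddm_log_likelihood(tab, spec, params, design)
        assert np.isfinite(ll)


class TestSimulation:
    def test_learning_effect_in_simulated_accuracy(self, design):
        """Positive learning rate and drift scaling: accuracy rises from the
        first to the last 20 trials of a block (averaged over subjects)."""
        spec = ModelSpec("RLDDM", 1)
        p = RLDDMParameters(eta_plus=0.12, v_mod=0.25, a=2.0, t_er=0.4)
        tab = simulate_experiment(design, spec, p, n_subjects=50, seed=9)
        tab = tab[~tab["excluded"]]
        early = tab[tab["trial"] <= 20]["accuracy"].mean()
        late = tab[tab["trial"] > 60]["accuracy"].mean()
        assert late > early + 0.05

    def test_magnitude_effect_with_negative_threshold_modulation(self, design):
        """a_mod < 0: the higher-valued pair CD is answered faster than AB
        while accuracy stays near-equal."""
        spec = ModelSpec("RLDDM", 3)
        p = RLDDMParameters(eta_plus=0.12, v_mod=0.25, a_fix=np.log(2.0),
                            a_mod=-0.02, t_er=0.4)
        tab = simulate_experiment(design, spec, p, n_subjects=50, seed=10)
        tab = tab[~tab["excluded"]]
        rt_cd = tab[tab["pair"] == "CD"]["rt"].mean()
        rt_ab = tab[tab["pair"] == "AB"]["rt"].mean()
        assert rt_cd < rt_ab
        acc_cd = tab[tab["pair"] == "CD"]["accuracy"].mean()
        acc_ab = tab[tab["pair"] == "AB"]["accuracy"].mean()
        assert abs(acc_cd - acc_ab) < 0.1

    def test_no_learning_gives_chance_accuracy(self, design):
        spec = ModelSpec("RLDDM", 1)
        p = RLDDMParameters(eta_plus=0.0, v_mod=0.25, a=2.0, t_er=0.4)
        tab = simulate_experiment(design, spec, p, n_subjects=30, seed=11)
        tab = tab[~tab["excluded"]]
        n = len(tab)
        assert abs(tab["accuracy"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_simulated_table_validates_and_round_trips(self, design, tmp_path):
        from rlddm.io import read_trials, validate_trials, write_trials
        spec = ModelSpec("RLDDM", 1)
        p = RLDDMParameters(eta_plus=0.1, v_mod=0.25, a=2.0, t_er=0.35)
        tab = simulate_experiment(design, spec, p, n_subjects=3, seed=12)
        validate_trials(tab, design)
        path = tmp_path / "trials.csv"
        write_trials(tab, path)
        back = read_trials(path, design)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True),
            tab.reset_index(drop=True), check_dtype=False)

    def test_shared_payoff_multiset_across_subjects(self, design):
        spec = ModelSpec("RLDDM", 1)
        p = RLDDMParameters(eta_plus=0.1, v_mod=0.25, a=2.0, t_er=0.35)
        tab = simulate_experiment(design, spec, p, n_subjects=3, seed=13)
        # every subject experienced the same multiset of feedback per option
        def multiset(sub, block):
            t = tab[(tab["subject"] == sub) & (tab["block"] == block)]
            out = {}
            for lab in design.option_labels:
                chosen = t[t["chosen_option"] == lab]["feedback_chosen"]
                pair_has = t["pair"].str.contains(lab)
                unchosen = t[pair_has & (t["chosen_option"] != lab)]["feedback_unchosen"]
                out[lab] = sorted(chosen.tolist() + unchosen.tolist())
            return out
        assert multiset(1, 1) == multiset(2, 1) == multiset(3, 1)

    def test_deterministic_in_seed(self, design):
        spec = ModelSpec("RLDDM", 1)
        p = RLDDMParameters(eta_plus=0.1, v_mod=0.25, a=2.0, t_er=0.35)
        a = simulate_experiment(design, spec, p, n_subjects=2, seed=21)
        b = simulate_experiment(design, spec, p, n_subjects=2, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_rl_simulation_has_choices_only(self, design):
        spec = ModelSpec("RL", 1)
        p = RLParameters(eta_plus=0.2, theta=0.1)
        tab = simulate_experiment(design, spec, p, n_subjects=2, seed=14)
        assert tab["rt"].isna().all()
        assert tab["accuracy"].isin([0, 1]).all()
        assert tab["accuracy"].mean() > 0.6  # value-sensitive choices
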