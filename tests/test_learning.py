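"""Delta-rule updating, power sensitivity, soft-max choice and the RL
likelihood, checked against direct arithmetic and brute-force loop oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rlddm.design import BanditDesign
from rlddm.learning import (RLParameters, choice_probability_softmax,
                            q_trajectory, rl_log_likelihood, sensitivity_power,
                            update_q)
from tests.conftest import toy_trials


class TestUpdateQ:
    def test_zero_learning_rate_keeps_q(self):
        p = RLParameters(eta_plus=0.0)
        assert update_q(27.5, 100.0, p) == 27.5

    def test_full_learning_rate_jumps_to_feedback(self):
        p = RLParameters(eta_plus=1.0)
        assert update_q(27.5, 36.0, p) == 36.0

    def test_direct_arithmetic(self):
        p = RLParameters(eta_plus=0.2)
        assert update_q(27.5, 36.0, p) == pytest.approx(29.2)

    def test_negative_prediction_error_selects_eta_minus(self):
        p = RLParameters(eta_plus=0.3, eta_minus=0.1)
        assert update_q(50.0, 45.0, p) == pytest.approx(49.5)
        # positive PE uses eta_plus
        assert update_q(45.0, 50.0, p) == pytest.approx(46.5)

    @pytest.mark.parametrize("kw", [dict(eta_plus=-0.1), dict(eta_plus=1.1),
                                    dict(eta_plus=0.5, eta_minus=2.0),
                                    dict(eta_plus=0.5, b=-1.0),
                                    dict(eta_plus=0.5, c=-0.1)])
    def test_parameter_bounds_enforced(self, kw):
        with pytest.raises(ValueError):
            RLParameters(**kw)

    @given(q=st.floats(0, 60), f=st.floats(0, 60),
           eta=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_convex_combination_bound(self, q, f, eta):
        new = update_q(q, f, RLParameters(eta_plus=eta, eta_minus=eta))
        assert min(q, f) - 1e-9 <= new <= max(q, f) + 1e-9


class TestQTrajectory:
    def test_zero_eta_trajectory_constant(self, design, toy_table_10):
        traj = q_trajectory(toy_table_10, RLParameters(eta_plus=0.0), design)
        for lab in design.option_labels:
            assert (traj[f"q_{lab}"] == design.initial_q).all()

    def test_both_presented_options_updated(self, design):
        t = toy_trials(design, [(1, 1, "AB", "B", 1.0, 40.0, 36.0),
                                (1, 2, "AB", "A", 1.0, 36.0, 40.0)])
        traj = q_trajectory(t, RLParameters(eta_plus=0.5), design)
        # values entering trial 2 reflect updates from trial 1 feedback
        assert traj.loc[1, "q_A"] == pytest.approx(31.75)  # 27.5 + .5(36-27.5)
        assert traj.loc[1, "q_B"] == pytest.approx(33.75)  # 27.5 + .5(40-27.5)

    def test_block2_initialized_at_grand_mean(self, design):
        rows = [(1, i + 1, "AB", "B", 1.0, 40.0, 36.0) for i in range(3)]
        rows += [(2, 1, "CD", "D", 1.0, 54.0, 50.0)]
        t = toy_trials(design, rows)
        p = RLParameters(eta_plus=0.5)
        traj = q_trajectory(t, p, design)
        # end of block 1: apply three updates by hand
        qa, qb = 27.5, 27.5
        for _ in range(3):
            qa += 0.5 * (36.0 - qa)
            qb += 0.5 * (40.0 - qb)
        gm = (qa + qb + 27.5 + 27.5) / 4.0
        assert traj.loc[3, "q_C"] == pytest.approx(gm)
        assert traj.loc[3, "q_A"] == pytest.approx(gm)

    def test_per_option_rule_carries_values(self, design):
        rows = [(1, 1, "AB", "B", 1.0, 40.0, 36.0), (2, 1, "AB", "A", 1.0, 36.0, 40.0)]
        t = toy_trials(design, rows)
        traj = q_trajectory(t, RLParameters(eta_plus=0.5), design,
                            init_rule="per_option")
        assert traj.loc[1, "q_B"] == pytest.approx(33.75)

    def test_presentation_counts_reset_per_block(self, design):
        rows = [(1, 1, "AB", "B", 1.0, 40.0, 36.0), (2, 1, "AB", "A", 1.0, 36.0, 40.0)]
        traj = q_trajectory(toy_trials(design, rows), RLParameters(eta_plus=0.1), design)
        assert traj.loc[0, "n_A"] == 1 and traj.loc[1, "n_A"] == 1

    def test_missing_feedback_raises(self, design):
        t = toy_trials(design, [(1, 1, "AB", "B", 1.0, 40.0, 36.0)])
        t.loc[0, "feedback_unchosen"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            q_trajectory(t, RLParameters(eta_plus=0.5), design)


class TestSensitivityPower:
    def test_zero_consistency_is_unit_sensitivity(self):
        p = RLParameters(eta_plus=0.5, b=3.0, c=0.0)
        for n in (1, 5, 40):
            assert sensitivity_power(n, p) == 1.0

    def test_n_equals_b_is_one(self):
        p = RLParameters(eta_plus=0.5, b=7.0, c=2.3)
        assert sensitivity_power(7, p) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        p = RLParameters(eta_plus=0.5, b=2.0, c=2.0)
        assert sensitivity_power(4, p) == pytest.approx(4.0)

    def test_unseen_option_rejected(self):
        p = RLParameters(eta_plus=0.5, b=2.0, c=2.0)
        with pytest.raises(ValueError):
            sensitivity_power(0, p)


class TestSoftmax:
    def test_equal_values_give_half(self):
        assert choice_probability_softmax(40.0, 40.0, 3.0) == 0.5

    def test_zero_sensitivity_gives_half(self):
        assert choice_probability_softmax(54.0, 36.0, 0.0) == 0.5

    def test_direct_evaluation(self):
        p = choice_probability_softmax(50.0, 36.0, 0.1)
        assert p == pytest.approx(1 / (1 + np.exp(-1.4)))
        assert p == pytest.approx(0.8022, abs=1e-4)

    @given(qc=st.floats(-100, 100), qi=st.floats(-100, 100),
           theta=st.floats(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_probabilities_complementary_and_bounded(self, qc, qi, theta):
        p = choice_probability_softmax(qc, qi, theta)
        q = choice_probability_softmax(qi, qc, theta)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0)

    def test_overflow_safe(self):
        assert choice_probability_softmax(1e4, -1e4, 10.0) == 1.0
        assert choice_probability_softmax(-1e4, 1e4, 10.0) == pytest.approx(0.0)


class TestRLLogLikelihood:
    def test_zero_sensitivity_gives_chance_likelihood(self, design, toy_table_10):
        p = RLParameters(eta_plus=0.3, theta=0.0)
        ll = rl_log_likelihood(toy_table_10, p, 1, design)
        assert ll == pytest.approx(10 * np.log(0.5))

    def test_matches_brute_force_loop(self, design, toy_table_10):
        """Independent oracle: explicit per-trial recomputation with its own
        Q bookkeeping, no shared code path."""
        p = RLParameters(eta_plus=0.3, eta_minus=0.15, theta=0.07)
        q = {lab: 27.5 for lab in design.option_labels}
        ll = 0.0
        for _, row in toy_table_10.iterrows():
            pair = row["pair"]
            cor = design.higher_mean_option(pair)
            inc = pair[0] if pair[1] == cor else pair[1]
            p_cor = 1 / (1 + np.exp(-0.07 * (q[cor] - q[inc])))
            ll += np.log(p_cor if row["accuracy"] == 1 else 1 - p_cor)
            for opt, f in [(row["chosen_option"], row["feedback_chosen"]),
                           (inc if row["chosen_option"] == cor else cor,
                            row["feedback_unchosen"])]:
                pe = f - q[opt]
                q[opt] += (0.3 if pe >= 0 else 0.15) * pe
        assert rl_log_likelihood(toy_table_10, p, 3, design) == pytest.approx(ll)

    def test_dual_rate_with_equal_rates_matches_single_bitwise(self, design,
                                                               toy_table_10):
        single = rl_log_likelihood(toy_table_10,
                                   RLParameters(eta_plus=0.25, theta=0.1),
                                   1, design)
        dual = rl_log_likelihood(toy_table_10,
                                 RLParameters(eta_plus=0.25, eta_minus=0.25,
                                              theta=0.1), 3, design)
        assert single == dual

    def test_likelihood_increases_with_theta_for_consistent_choices(self, design):
        # all choices correct and Q_cor > Q_inc throughout: larger theta fits
        # strictly better
        rows = [(1, i + 1, "AC", "C", 1.0, 50.0, 36.0) for i in range(8)]
        t = toy_trials(design, rows)
        t.loc[0, "accuracy"] = 1
        lls = [rl_log_likelihood(t, RLParameters(eta_plus=0.3, theta=th), 1, design)
               for th in (0.02, 0.05, 0.1, 0.2)]
        assert np.all(np.diff(lls) > 0)

    def test_invalid_variant_rejected(self, design, toy_table_10):
        with pytest.raises(ValueError):
            rl_log_likelihood(toy_table_10, RLParameters(eta_plus=0.1, theta=1.0),
                              5, design)
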