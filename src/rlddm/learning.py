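"""Delta-rule value learning and soft-max choice models.

Subjective option values Q are updated after every trial with the reward
prediction error f - Q weighted by a learning rate, optionally split by
prediction-error sign (eta_plus for f >= Q, eta_minus otherwise). Both
presented options are updated every trial (full feedback). Choice models map
the value difference to choice probability through a soft-max whose
sensitivity is either a free constant or grows as a power function of how
often the options have been encountered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RLParameters",
    "update_q",
    "q_trajectory",
    "sensitivity_power",
    "choice_probability_softmax",
    "rl_log_likelihood",
    "RL_VARIANTS",
]

# variant id -> (n learning rates, sensitivity rule)
RL_VARIANTS = {
    1: (1, "fixed"),
    2: (1, "power"),
    3: (2, "fixed"),
    4: (2, "power"),
}


@dataclass(frozen=True)
class RLParameters:
    """Learning and choice parameters.

    eta_plus, eta_minus : learning rates in [0, 1] for positive / negative
        prediction errors (pass only ``eta_plus`` for single-rate models).
    theta : fixed soft-max sensitivity (>= 0).
    b, c : scaling (> 0) and consistency (>= 0) of the power sensitivity rule
        theta_t = (n / b) ** c, with n the option presentation count.
    """

    eta_plus: float
    eta_minus: float | None = None
    theta: float | None = None
    b: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_plus <= 1.0):
            raise ValueError("eta_plus must lie in [0, 1]")
        if self.eta_minus is None:
            object.__setattr__(self, "eta_minus", self.eta_plus)
        elif not (0.0 <= self.eta_minus <= 1.0):
            raise ValueError("eta_minus must lie in [0, 1]")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.b is not None and self.b <= 0:
            raise ValueError("b must be > 0")
        if self.c is not None and self.c < 0:
            raise ValueError("c must be >= 0")


def update_q(q_prev: float, feedback: float, params: RLParameters) -> float:
    """One delta-rule update: Q + eta * (f - Q).

    The learning rate is ``eta_plus`` for non-negative prediction errors and
    ``eta_minus`` for negative ones (ties use ``eta_plus``).
    """
    pe = feedback - q_prev
    eta = params.eta_plus if pe >= 0 else params.eta_minus
    return q_prev + eta * pe


def q_trajectory(trials: pd.DataFrame, params: RLParameters, design,
                 init_rule: str = "grand_mean") -> pd.DataFrame:
    """Per-trial subjective values and presentation counts for one subject.

    ``trials`` must be ordered by block then trial and carry the TrialTable
    columns (pair, chosen_option, feedback_chosen, feedback_unchosen). Q
    values are carried across trials within a block; at a block boundary all
    options restart either at the grand mean of the previous block's final Q
    values (``init_rule='grand_mean'``, the default: new stimuli prevent
    option-specific transfer) or at their own final values
    (``init_rule='per_option'``). Block 1 starts at ``design.initial_q``, the
    average value shown in the task instructions. Presentation counts reset
    each block. Returned Q columns are the values *entering* each trial.
    """
    if init_rule not in ("grand_mean", "per_option"):
        raise ValueError(f"unknown init_rule {init_rule!r}")
    labels = design.option_labels
    q = {lab: float(design.initial_q) for lab in labels}
    counts = {lab: 0 for lab in labels}
    rows = []
    current_block = None
    for idx, row in trials.iterrows():
        if current_block is None:
            current_block = row["block"]
        elif row["block"] != current_block:
            if init_rule == "grand_mean":
                gm = float(np.mean(list(q.values())))
                q = {lab: gm for lab in labels}
            counts = {lab: 0 for lab in labels}
            current_block = row["block"]
        pair = row["pair"]
        chosen = row["chosen_option"]
        unchosen = pair[0] if pair[1] == chosen else pair[1]
        if chosen not in pair:
            raise ValueError(f"trial {idx}: chosen option {chosen!r} not in pair {pair!r}")
        for col in ("feedback_chosen", "feedback_unchosen"):
            if pd.isna(row[col]):
                raise ValueError(f"trial {idx}: missing {col}")
        counts[pair[0]] += 1
        counts[pair[1]] += 1
        rec = {"block": row["block"], "trial": row["trial"], "pair": pair}
        rec.update({f"q_{lab}": q[lab] for lab in labels})
        rec.update({f"n_{lab}": counts[lab] for lab in labels})
        rows.append(rec)
        q[chosen] = update_q(q[chosen], row["feedback_chosen"], params)
        q[unchosen] = update_q(q[unchosen], row["feedback_unchosen"], params)
    out = pd.DataFrame(rows)
    return out


def sensitivity_power(n: float, params: RLParameters) -> float:
    """Power-growth sensitivity theta = (n / b) ** c.

    ``n`` is the number of times the option(s) have been presented (for a
    pair, the mean of the two options' counts). When c = 0 the sensitivity
    is 1 for any n and b, i.e. fixed over learning.
    """
    if n <= 0:
        raise ValueError("option never presented (n must be >= 1)")
    if params.b is None or params.c is None:
        raise ValueError("power sensitivity requires parameters b and c")
    return (n / params.b) ** params.c


def choice_probability_softmax(q_cor: float, q_inc: float, theta: float) -> float:
    """Soft-max probability of choosing the higher-mean ("correct") option.

    p = exp(theta q_cor) / (exp(theta q_cor) + exp(theta q_inc)), evaluated
    overflow-safely as a logistic of theta * (q_cor - q_inc).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    z = theta * (q_cor - q_inc)
    # logistic, stable for large |z|
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


def rl_log_likelihood(trials: pd.DataFrame, params: RLParameters, variant: int,
                      design, init_rule: str = "grand_mean") -> float:
    """Summed log soft-max probability of the observed choices of one subject.

    ``variant`` selects the model: 1 = single eta / fixed theta, 2 = single
    eta / power theta, 3 = dual eta / fixed theta, 4 = dual eta / power
    theta. Trials flagged ``excluded`` contribute no likelihood but their
    feedback still drives the value updates.
    """
    if variant not in RL_VARIANTS:
        raise ValueError(f"unknown RL variant {variant}; choose from {sorted(RL_VARIANTS)}")
    _, sens_rule = RL_VARIANTS[variant]
    if sens_rule == "fixed" and params.theta is None:
        raise ValueError("fixed-sensitivity variant requires theta")
    traj = q_trajectory(trials, params, design, init_rule=init_rule)
    excluded = trials["excluded"].to_numpy() if "excluded" in trials else np.zeros(len(trials), bool)
    ll = 0.0
    for (_, trial), (_, state), exc in zip(trials.iterrows(), traj.iterrows(), excluded):
        if exc:
            continue
        pair = trial["pair"]
        cor = design.higher_mean_option(pair)
        inc = pair[0] if pair[1] == cor else pair[1]
        if sens_rule == "power":
            n = (state[f"n_{pair[0]}"] + state[f"n_{pair[1]}"]) / 2.0
            theta = sensitivity_power(n, params)
        else:
            theta = params.theta
        p_cor = choice_probability_softmax(state[f"q_{cor}"], state[f"q_{inc}"], theta)
        p_obs = p_cor if trial["accuracy"] == 1 else 1.0 - p_cor
        ll += np.log(max(p_obs, 1e-300))
    return float(ll)
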