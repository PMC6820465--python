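"""Shared fixtures: designs, toy tables, and the expensive simulation-based
fits reused across test modules (session-scoped so they run once)."""

import numpy as np
import pandas as pd
import pytest

from rlddm.design import BanditDesign
from rlddm.inference import SamplerConfig
from rlddm.models import ModelSpec, make_params, simulate_experiment


@pytest.fixture(scope="session")
def design():
    return BanditDesign()


def toy_trials(design, rows, subject=1):
    """Build a small TrialTable from (block, trial, pair, chosen, rt,
    f_chosen, f_unchosen) tuples."""
    recs = []
    for block, trial, pair, chosen, rt, f_ch, f_un in rows:
        higher = design.higher_mean_option(pair)
        left, right = pair[0], pair[1]
        recs.append(dict(subject=subject, block=block, trial=trial, pair=pair,
                         option_left=left, option_right=right,
                         choice_side="left" if chosen == left else "right",
                         chosen_option=chosen,
                         accuracy=int(chosen == higher), rt=rt,
                         feedback_chosen=f_ch, feedback_unchosen=f_un,
                         excluded=False, excluded_reason=""))
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def toy_table_10(design):
    """Ten trials, one subject, deterministic hand-written feedback."""
    rng = np.random.default_rng(123)
    pairs = ["AB", "AC", "BD", "CD", "AB", "CD", "AC", "BD", "AB", "CD"]
    rows = []
    for i, pair in enumerate(pairs):
        chosen = pair[rng.integers(2)]
        rows.append((1, i + 1, pair, chosen, float(0.5 + 0.15 * i),
                     float(rng.integers(25, 60)), float(rng.integers(25, 60))))
    return toy_trials(design, rows)


@pytest.fixture(scope="session")
def rlddm1_table(design):
    """A 12-subject dataset simulated from RLDDM 1 at the default generating
    group parameters (the package's study conditions)."""
    spec = ModelSpec("RLDDM", 1)
    rng = np.random.default_rng(2024)
    subs = [make_params(spec, {
        "eta": float(np.clip(rng.normal(0.12, 0.04), 0.01, 0.95)),
        "v_mod": float(rng.normal(0.25, 0.05)),
        "a": float(np.clip(rng.normal(2.0, 0.3), 0.5, None)),
        "t_er": float(np.clip(rng.normal(0.40, 0.05), 0.05, None)),
    }) for _ in range(12)]
    return simulate_experiment(design, spec, subs, seed=77)


@pytest.fixture(scope="session")
def reduced_sampler_config():
    """Reduced ensemble budget used by simulation-based fits in the suite."""
    return SamplerConfig(n_iter_start=300, n_iter_max=300,
                         max_pointwise_draws=200)


@pytest.fixture(scope="session")
def rlddm1_fit(rlddm1_table, design, reduced_sampler_config):
    from rlddm.model import RLDDMModel

    model = RLDDMModel(rlddm1_table, design=design, variant=1)
    return model.fit(config=reduced_sampler_config, seed=5)


@pytest.fixture(scope="session")
def recovery_rlddm1(design):
    """Simulate-and-refit study: RLDDM 1, 12 subjects x 240 trials, 5
    replications at the package's reduced recovery budget."""
    from rlddm.evaluation import parameter_recovery_study

    return parameter_recovery_study(
        ModelSpec("RLDDM", 1), design, n_subjects=12, n_replications=5,
        seed=31)


def null_behavior_table(design, n_subjects, seed):
    """Trial table with NO difficulty/magnitude/interaction effects:
    accuracy is Bernoulli per subject and log RT is normal, independent of
    the presented pair."""
    from rlddm.design import generate_pair_sequence

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subjects + 1):
        p_cor = rng.uniform(0.65, 0.8)
        mu_rt = rng.normal(0.0, 0.1)
        seq = generate_pair_sequence(design, seed=int(rng.integers(2 ** 31)))
        for b, pairs_b in enumerate(seq.pairs_by_block):
            for t, pair in enumerate(pairs_b):
                cor = design.higher_mean_option(pair)
                inc = pair[0] if pair[1] == cor else pair[1]
                acc = int(rng.random() < p_cor)
                chosen = cor if acc else inc
                rt = float(np.clip(np.exp(rng.normal(mu_rt, 0.3)), 0.16, 2.9))
                rows.append(dict(subject=s, block=b + 1, trial=t + 1, pair=pair,
                                 option_left=pair[0], option_right=pair[1],
                                 choice_side="left" if chosen == pair[0] else "right",
                                 chosen_option=chosen, accuracy=acc, rt=rt,
                                 feedback_chosen=45.0, feedback_unchosen=38.0,
                                 excluded=False, excluded_reason=""))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_calibration_accuracy(design):
    """20 hierarchical logistic fits on null data; per replication, whether
    each of the three effect BCIs contains 0."""
    from rlddm.evaluation import fit_accuracy_regression
    from rlddm.inference import SamplerConfig

    cfg = SamplerConfig(n_iter_start=400, n_iter_max=400,
                        max_pointwise_draws=100)
    outcomes = []
    for rep in range(20):
        tab = null_behavior_table(design, n_subjects=6, seed=1000 + rep)
        res = fit_accuracy_regression(tab, design, config=cfg, seed=rep)
        coef = res.coefficients.set_index("term")
        outcomes.append({
            term: bool(coef.loc[term, "bci_2.5"] <= 0 <= coef.loc[term, "bci_97.5"])
            for term in ("magnitude", "difficulty", "interaction")})
    return pd.DataFrame(outcomes)
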