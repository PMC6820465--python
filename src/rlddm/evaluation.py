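"""Posterior predictive checks, behavioral regressions, parameter recovery.

Three complementary ways of judging a fitted (or proposed) model:

* posterior predictive checks simulate full datasets from posterior draws —
  with each subject's own feedback streams — and compare predicted and
  observed learning curves (mean accuracy and RT per option pair and
  trial bin);
* hierarchical regressions quantify the difficulty and magnitude effects
  directly on the behavioral data (logistic on accuracy, linear on log RT);
* parameter recovery simulates data from known group-level parameters,
  refits, and reports credible-interval coverage and subject-level rank
  correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .design import BanditDesign, pair_statistics
from .inference import (CognitiveLikelihood, PosteriorDraws, PriorSpec,
                        ParamPrior, SamplerConfig, fit_hierarchical, _inv_link)
from .models import (ModelSpec, _INIT_RULE_CODE, _simulate_subject_kernel,
                     _simulate_subject_rl_kernel, _simulate_static_kernel,
                     make_params, simulate_experiment, trial_arrays)
from . import learning as _learning

__all__ = [
    "PPCSummary",
    "RegressionResult",
    "RecoveryReport",
    "posterior_predictive_check",
    "observed_pair_bin_summary",
    "fit_accuracy_regression",
    "fit_rt_regression",
    "parameter_recovery_study",
    "default_generating_group",
]


# ---------------------------------------------------------------------------
# posterior predictive checks


@dataclass
class PPCSummary:
    """Observed vs. predicted per-(pair, trial-bin) means with 95% BCIs."""

    table: pd.DataFrame
    n_draws: int
    bin_size: int


def _bin_index(tib: np.ndarray, bin_size: int) -> np.ndarray:
    return (tib - 1) // bin_size


def observed_pair_bin_summary(trials: pd.DataFrame, design: BanditDesign,
                              bin_size: int = 10) -> pd.DataFrame:
    """Mean accuracy and RT per (pair, within-block trial bin), pooled over
    blocks and subjects, retained trials only."""
    t = trials.copy()
    if "excluded" in t:
        t = t[~t["excluded"].astype(bool)]
    t["bin"] = _bin_index(t["trial"].to_numpy(), bin_size) + 1
    g = t.groupby(["pair", "bin"])
    out = g.agg(observed_accuracy=("accuracy", "mean"),
                observed_rt=("rt", "mean"),
                n_trials=("accuracy", "size")).reset_index()
    return out


def posterior_predictive_check(results, n_draws: int = 500, seed: int = 0,
                               bin_size: int = 10,
                               trials: pd.DataFrame | None = None,
                               design: BanditDesign | None = None,
                               spec: ModelSpec | None = None,
                               draws: PosteriorDraws | None = None,
                               init_rule: str = "grand_mean",
                               dt: float = 0.001) -> PPCSummary:
    """Simulate ``n_draws`` predictive datasets and summarize learning curves.

    Each predictive dataset reuses the subjects' own pair sequences and
    feedback streams (recoverable from the full-feedback trial table) and
    one joint posterior draw of all subject-level parameters. Summaries are
    per (pair, trial bin) means; the 2.5% and 97.5% quantiles across
    datasets form the predictive 95% BCI.
    """
    if results is not None:
        trials = results.model.data
        design = results.model.design
        spec = results.model.spec
        draws = results.draws
        init_rule = results.model.init_rule
    if spec.model_class == "DDM" and draws is None:
        raise ValueError("this spec has no forward simulator without draws")
    retained = draws.subject_param_draws()
    if n_draws > retained.shape[0]:
        raise ValueError(f"n_draws={n_draws} exceeds retained draws "
                         f"({retained.shape[0]})")
    rng = np.random.default_rng(seed)
    pick = rng.choice(retained.shape[0], size=n_draws, replace=False)

    arrays = trial_arrays(trials, design)
    like = CognitiveLikelihood(trials, spec, design, init_rule=init_rule)
    pairs = list(design.pairs)
    n_bins = int(np.ceil(design.trials_per_block / bin_size))
    pair_idx = [np.array([pairs.index(p) for p in a.pair]) for a in arrays]
    bins = [_bin_index(a.tib, bin_size) for a in arrays]
    max_steps = int(np.ceil(5.0 / dt))

    is_rl = spec.model_class == "RL"
    acc_stats = np.empty((n_draws, len(pairs), n_bins))
    rt_stats = np.full((n_draws, len(pairs), n_bins), np.nan)
    for d in range(n_draws):
        nat = retained[pick[d]]
        acc_sum = np.zeros((len(pairs), n_bins))
        rt_sum = np.zeros((len(pairs), n_bins))
        cnt = np.zeros((len(pairs), n_bins))
        for s, a in enumerate(arrays):
            n = a.n_trials
            acc = np.empty(n, dtype=np.int64)
            sim_seed = int(rng.integers(2 ** 31))
            if is_rl:
                n_eta, sens = _learning.RL_VARIANTS[spec.variant]
                p = nat[s]
                eta_p = p[0]
                eta_m = p[1] if n_eta == 2 else p[0]
                k = n_eta
                theta = p[k] if sens == "fixed" else 1.0
                b = p[k] if sens == "power" else 1.0
                c = p[k + 1] if sens == "power" else 0.0
                _simulate_subject_rl_kernel(
                    a.cor, a.inc, a.f_cor, a.f_inc, a.block,
                    design.n_options, float(design.initial_q), eta_p, eta_m,
                    theta, b, c, 1 if sens == "power" else 0,
                    _INIT_RULE_CODE[init_rule], sim_seed, acc)
                keep = np.ones(n, dtype=bool)
                rt = np.full(n, np.nan)
            elif spec.model_class == "DDM":
                vidx, aidx, n_v = like._cond[s]
                p = nat[s]
                v_arr = p[:n_v][vidx]
                n_a = len(like.param_names) - n_v - 1
                a_arr = p[n_v:n_v + n_a][aidx]
                steps = np.empty(n, dtype=np.int64)
                cens = np.empty(n, dtype=np.bool_)
                _simulate_static_kernel(v_arr, a_arr, dt, max_steps, sim_seed,
                                        acc, steps, cens)
                rt = steps * dt + p[-1]
                keep = (~cens) & (rt >= design.rt_floor) & (rt <= design.rt_ceiling)
            else:
                p = like._kernel_vector(nat[s])
                dk, tk = spec._codes
                steps = np.empty(n, dtype=np.int64)
                cens = np.empty(n, dtype=np.bool_)
                v_out = np.empty(n)
                a_out = np.empty(n)
                _simulate_subject_kernel(
                    a.cor, a.inc, a.f_cor, a.f_inc, a.block, a.tib,
                    design.n_options, float(design.initial_q), p, dk, tk,
                    _INIT_RULE_CODE[init_rule], dt, max_steps, sim_seed,
                    acc, steps, cens, v_out, a_out)
                rt = steps * dt + p[6]
                keep = (~cens) & (rt >= design.rt_floor) & (rt <= design.rt_ceiling)
            pi, bi = pair_idx[s][keep], bins[s][keep]
            np.add.at(acc_sum, (pi, bi), acc[keep])
            if not is_rl:
                np.add.at(rt_sum, (pi, bi), rt[keep])
            np.add.at(cnt, (pi, bi), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc_stats[d] = acc_sum / cnt
            if not is_rl:
                rt_stats[d] = rt_sum / cnt

    obs = observed_pair_bin_summary(trials, design, bin_size)
    rows = []
    for i, pair in enumerate(pairs):
        for b in range(n_bins):
            o = obs[(obs["pair"] == pair) & (obs["bin"] == b + 1)]
            acc_d = acc_stats[:, i, b]
            rt_d = rt_stats[:, i, b]
            rows.append({
                "pair": pair, "bin": b + 1,
                "observed_accuracy": float(o["observed_accuracy"].iloc[0]) if len(o) else np.nan,
                "observed_rt": float(o["observed_rt"].iloc[0]) if len(o) else np.nan,
                "predicted_accuracy": float(np.nanmean(acc_d)),
                "predicted_accuracy_lo": float(np.nanpercentile(acc_d, 2.5)),
                "predicted_accuracy_hi": float(np.nanpercentile(acc_d, 97.5)),
                "predicted_rt": float(np.nanmean(rt_d)) if not is_rl else np.nan,
                "predicted_rt_lo": float(np.nanpercentile(rt_d, 2.5)) if not is_rl else np.nan,
                "predicted_rt_hi": float(np.nanpercentile(rt_d, 97.5)) if not is_rl else np.nan,
            })
    return PPCSummary(pd.DataFrame(rows), n_draws=n_draws, bin_size=bin_size)


# ---------------------------------------------------------------------------
# behavioral regressions


class RegressionLikelihood:
    """Hierarchical regression adapter (logistic on accuracy or linear on
    log RT) for the generic fitting machinery. Subject-level coefficient
    vectors are drawn from group-level normals; predictors are standardized
    magnitude, difficulty coded +1 (easy) / -1 (difficult), and their
    interaction."""

    def __init__(self, trials: pd.DataFrame, design: BanditDesign, kind: str):
        if kind not in ("logistic", "linear"):
            raise ValueError("kind must be 'logistic' or 'linear'")
        self.kind = kind
        t = trials.copy()
        if "excluded" in t:
            t = t[~t["excluded"].astype(bool)]
        t = t.dropna(subset=["rt"]) if kind == "linear" else t
        stats = pair_statistics(design).set_index("pair")
        mag = stats.loc[t["pair"], "magnitude"].to_numpy(dtype=float)
        mag_std = np.std(mag)
        mag = (mag - np.mean(mag)) / (mag_std if mag_std > 0 else 1.0)
        diff = np.where(stats.loc[t["pair"], "difficulty_class"] == "easy", 1.0, -1.0)
        X = np.column_stack([np.ones(len(t)), mag, diff, mag * diff])
        if kind == "linear":
            rt = t["rt"].to_numpy(dtype=float)
            if np.any(rt <= 0):
                raise ValueError("non-positive RTs cannot be log-transformed")
            y = np.log(rt)
        else:
            y = t["accuracy"].to_numpy(dtype=float)
        self.subject_ids = sorted(t["subject"].unique())
        if len(self.subject_ids) < 2:
            raise ValueError("hierarchical regression requires >= 2 subjects")
        self._X = []
        self._y = []
        for s in self.subject_ids:
            m = (t["subject"] == s).to_numpy()
            self._X.append(X[m])
            self._y.append(y[m])
        self.param_names = ["b_intercept", "b_magnitude", "b_difficulty",
                           "b_interaction"] + (["sigma"] if kind == "linear" else [])
        self.n_subjects = len(self.subject_ids)
        self.t_er_hi = np.ones(self.n_subjects)

    def n_points(self, s: int) -> int:
        return len(self._y[s])

    def _pointwise(self, s: int, params: np.ndarray) -> np.ndarray:
        X, y = self._X[s], self._y[s]
        z = X @ params[:4]
        if self.kind == "logistic":
            return y * z - np.logaddexp(0.0, z)
        sigma = params[4]
        if sigma <= 0:
            return np.full(len(y), -np.inf)
        with np.errstate(over="ignore"):
            r = (y - z) / sigma
            return -0.5 * r * r - np.log(sigma) - 0.5 * np.log(2 * np.pi)

    def loglike(self, s: int, params: np.ndarray) -> float:
        return float(np.sum(self._pointwise(s, params)))

    def pointwise(self, s: int, params: np.ndarray) -> np.ndarray:
        return self._pointwise(s, params)


@dataclass
class RegressionResult:
    """Group-level coefficient posteriors with 95% BCIs.

    ``effect`` flags are derived (BCI excludes 0), never stored separately.
    """

    draws: PosteriorDraws
    kind: str

    @property
    def coefficients(self) -> pd.DataFrame:
        gm = self.draws.group_mean_draws()
        rows = []
        for name in self.draws.param_names:
            if not name.startswith("b_"):
                continue
            d = gm[name].to_numpy()
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append((name[2:], float(d.mean()), float(lo), float(hi),
                         bool(lo > 0 or hi < 0)))
        return pd.DataFrame(rows, columns=["term", "mean", "bci_2.5",
                                           "bci_97.5", "effect"])

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def bci(self, term: str) -> tuple[float, float]:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["bci_2.5"]), float(row["bci_97.5"])


_REGRESSION_CONFIG = SamplerConfig(n_iter_start=600, n_iter_max=1200,
                                   max_pointwise_draws=400)


def fit_accuracy_regression(trials: pd.DataFrame, design: BanditDesign,
                            priors: PriorSpec | None = None,
                            config: SamplerConfig | None = None,
                            seed: int = 0) -> RegressionResult:
    """Hierarchical logistic regression of accuracy on standardized
    magnitude, difficulty (+1 easy / -1 difficult) and their interaction."""
    like = RegressionLikelihood(trials, design, "logistic")
    draws = fit_hierarchical(likelihood=like, priors=priors,
                             config=config or _REGRESSION_CONFIG, seed=seed,
                             model_name="accuracy ~ magnitude * difficulty")
    return RegressionResult(draws, "logistic")


def fit_rt_regression(trials: pd.DataFrame, design: BanditDesign,
                      priors: PriorSpec | None = None,
                      config: SamplerConfig | None = None,
                      seed: int = 0) -> RegressionResult:
    """Hierarchical linear regression of log RT on the same predictors and
    coding as the accuracy regression."""
    like = RegressionLikelihood(trials, design, "linear")
    draws = fit_hierarchical(likelihood=like, priors=priors,
                             config=config or _REGRESSION_CONFIG, seed=seed,
                             model_name="log RT ~ magnitude * difficulty")
    return RegressionResult(draws, "linear")


# ---------------------------------------------------------------------------
# parameter recovery


def default_generating_group(spec: ModelSpec, design: BanditDesign | None = None
                             ) -> dict[str, tuple[float, float]]:
    """Realistic group-level generating distributions (natural-scale mean, SD)
    for each parameter of a spec, emulating behavior in the reference
    paradigm (asymptotic accuracy in the .8s, mean RT near 1 s)."""
    base = {
        "eta": (0.12, 0.04), "eta_plus": (0.14, 0.04), "eta_minus": (0.10, 0.03),
        "theta": (0.12, 0.04), "b": (5.0, 1.0), "c": (0.6, 0.15),
        "v_mod": (0.25, 0.05), "v_max": (2.5, 0.4),
        "a": (2.0, 0.3), "a_fix": (0.7, 0.1), "a_mod": (-0.010, 0.003),
        "t_er": (0.40, 0.05),
        "m_base": (0.20, 0.04), "d_m": (0.15, 0.05),
        "a_base": (2.2, 0.3), "d_a": (0.15, 0.05),
        "v_easy": (2.5, 0.5), "v_difficult": (1.0, 0.3),
    }
    out = {}
    for name in spec.param_names(design):
        if name in base:
            out[name] = base[name]
        elif name.startswith("v_"):
            out[name] = (1.5, 0.4)
        elif name.startswith("a_"):
            out[name] = (2.0, 0.3)
        else:
            raise KeyError(name)
    return out


_SUPPORT_CLIP = {
    "logit": (1e-3, 1 - 1e-3),
    "log": (1e-3, np.inf),
}


def _draw_subject_values(generating: dict, names: list, rng, n_subjects: int):
    """Subject-level natural parameter draws.

    Subjects are normal on the unconstrained (link) scale — matching the
    hierarchical model's population assumption — centered at link(mean) with
    the delta-method SD, so the generating group location on the natural
    scale is exactly the stated mean. The non-decision time (whose link
    bound is data-dependent) is drawn on the natural scale instead.
    """
    from scipy.special import logit as _logit

    from .inference import default_link
    vals = np.empty((n_subjects, len(names)))
    for j, name in enumerate(names):
        mean, sd = generating[name]
        link = default_link(name)
        if link == "log":
            draw = np.exp(rng.normal(np.log(mean), sd / mean, n_subjects))
        elif link == "logit":
            draw = 1.0 / (1.0 + np.exp(-rng.normal(
                _logit(mean), sd / (mean * (1 - mean)), n_subjects)))
        elif link == "scaled_logit":
            draw = np.clip(rng.normal(mean, sd, n_subjects), 0.05, np.inf)
        else:
            draw = rng.normal(mean, sd, n_subjects)
        if link in _SUPPORT_CLIP:
            lo, hi = _SUPPORT_CLIP[link]
            draw = np.clip(draw, lo, hi)
        vals[:, j] = draw
    return vals


@dataclass
class RecoveryReport:
    """Per (replication, parameter) recovery outcomes."""

    table: pd.DataFrame
    spec_name: str

    def coverage(self) -> float:
        """Fraction of group-mean 95% BCIs containing the generating value,
        pooled over parameters and replications."""
        ok = self.table["covered"].dropna()
        return float(ok.mean()) if len(ok) else np.nan

    def mean_abs_error(self) -> pd.Series:
        t = self.table
        return (t["estimate"] - t["generating"]).abs().groupby(t["parameter"]).mean()


def parameter_recovery_study(spec: ModelSpec, design: BanditDesign,
                             generating: dict | None = None,
                             n_subjects: int = 12, n_replications: int = 5,
                             seed: int = 0,
                             config: SamplerConfig | None = None,
                             init_rule: str = "grand_mean") -> RecoveryReport:
    """Simulate-and-refit study for one model spec.

    Each replication draws subject parameters from the generating group
    distributions, simulates a full experiment, fits the hierarchical model,
    and records whether each group-mean 95% BCI covers the generating group
    mean plus the Spearman rank correlation between true and recovered
    subject-level parameters (NaN-flagged when the generating SD is 0). Fit
    failures are recorded per replication, not raised.
    """
    generating = generating or default_generating_group(spec, design)
    names = ModelSpec(spec.model_class, spec.variant).param_names(design)
    rng = np.random.default_rng(seed)
    config = config or SamplerConfig(n_iter_start=1600, n_iter_max=1600,
                                     max_pointwise_draws=200)
    rows = []
    for rep in range(n_replications):
        vals = _draw_subject_values(generating, names, rng, n_subjects)
        if spec.model_class == "DDM":
            params = [make_params(spec, dict(zip(names, vals[s])))
                      for s in range(n_subjects)]
            # condition-parameterized simulation: one triple per subject
            frames = []
            for s in range(n_subjects):
                f = simulate_experiment(design, spec, [None],
                                        seed=int(rng.integers(2 ** 31)),
                                        params_by_condition=params[s])
                f["subject"] = s + 1
                frames.append(f)
            tab = pd.concat(frames, ignore_index=True)
        else:
            params = [make_params(spec, dict(zip(names, vals[s])))
                      for s in range(n_subjects)]
            tab = simulate_experiment(design, spec, params,
                                      seed=int(rng.integers(2 ** 31)),
                                      init_rule=init_rule)
        try:
            fit = fit_hierarchical(tab, spec, design, config=config,
                                   seed=int(rng.integers(2 ** 31)),
                                   init_rule=init_rule)
        except Exception as exc:  # recorded, not fatal
            for j, name in enumerate(names):
                rows.append((rep + 1, name, generating[name][0], np.nan,
                             np.nan, np.nan, np.nan, np.nan, False, str(exc)))
            continue
        gm = fit.group_mean_draws()
        sub_est = fit.subject_param_draws(thin=10).mean(axis=0)
        for j, name in enumerate(names):
            d = gm[name].to_numpy()
            lo, hi = np.percentile(d, [2.5, 97.5])
            gen = generating[name][0]
            true_sub = vals[:, j]
            if np.std(true_sub) == 0:
                rho = np.nan
            else:
                rho = float(sp_stats.spearmanr(true_sub, sub_est[:, j]).statistic)
            rows.append((rep + 1, name, gen, float(d.mean()), float(lo),
                         float(hi), bool(lo <= gen <= hi), rho,
                         fit.converged, ""))
    table = pd.DataFrame(rows, columns=[
        "replication", "parameter", "generating", "estimate", "bci_2.5",
        "bci_97.5", "covered", "rank_corr", "converged", "error"])
    return RecoveryReport(table, spec.name)
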