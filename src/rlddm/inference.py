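"""Hierarchical Bayesian estimation, diagnostics, WAIC and model comparison.

Subject-level parameters are drawn from group-level normal distributions on
an unconstrained scale (non-centered parameterization): for parameter j and
subject s, the sampled quantities are the group mean mu_j, the group SD
sigma_j (sampled as log sigma, half-normal prior) and a standardized offset
z_{sj} ~ N(0, 1); the subject's natural-scale parameter is
link^{-1}(mu_j + sigma_j z_{sj}). Links map the unconstrained space onto
each parameter's support: identity, log (positive parameters), logit
(learning rates) and a scaled logit for the non-decision time, bounded per
subject by a fraction of that subject's minimum retained RT.

Sampling uses an affine-invariant ensemble sampler (emcee). The ensemble is
initialized around per-subject penalized maximum-likelihood estimates, run
with an iteration-doubling schedule, and the first half of every chain is
discarded as warm-up. For convergence diagnostics the walker ensemble is
partitioned into four groups of equal size (walkers are exchangeable), each
group acting as one chain for the rank-normalized R-hat; a fit is flagged
converged when every R-hat <= 1.01.

Predictive accuracy is summarized by the widely applicable information
criterion computed from the pointwise log predictive density matrix with the
variance-based complexity penalty: lppd = sum_i log mean_s p(y_i | theta_s),
p_waic = sum_i var_s log p(y_i | theta_s), waic = -2 (lppd - p_waic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .design import BanditDesign
from .models import (ModelSpec, _INIT_RULE_CODE, _rl_loglik_kernel,
                     _rlddm_loglik_kernel, trial_arrays)
from .wfpt import DDM_VARIANTS, _wfpt_loglik_pointwise, _wfpt_loglik_sum
from . import learning as _learning

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "ModelComparisonRow",
    "CognitiveLikelihood",
    "fit_hierarchical",
    "compute_waic",
    "compare_models",
    "comparison_table",
]


# ---------------------------------------------------------------------------
# links and priors


def _inv_link(link: str, u, hi=1.0):
    if link == "identity":
        return u
    if link == "log":
        with np.errstate(over="ignore"):
            return np.exp(u)
    if link == "logit":
        return expit(u)
    if link == "scaled_logit":
        return hi * expit(u)
    raise ValueError(f"unknown link {link!r}")


@dataclass(frozen=True)
class ParamPrior:
    """Group-level prior and link for one model parameter.

    ``mu_loc``/``mu_scale``: normal prior on the group mean (unconstrained
    scale). ``sd_scale``: half-normal scale of the group SD. ``link`` maps
    the unconstrained space to the parameter's support.
    """

    name: str
    link: str = "identity"
    mu_loc: float = 0.0
    mu_scale: float = 2.0
    sd_scale: float = 1.0


def default_link(name: str) -> str:
    """Default link per parameter name.

    The non-decision time uses a plain log link: its hard upper bound (each
    subject's minimum retained RT) is enforced through the likelihood, which
    returns -inf beyond it, rather than through a subject-specific
    scaled-logit bound — a data-dependent bound absorbs the between-subject
    variance and collapses the group-level uncertainty.
    """
    if name.startswith("eta"):
        return "logit"
    if name in ("theta", "b", "c", "v_max", "d_a", "d_m", "sigma", "t_er") \
            or name == "a" \
            or (name.startswith("a_") and name not in ("a_fix", "a_mod")):
        return "log"
    return "identity"


@dataclass
class PriorSpec:
    """Weakly informative priors, one :class:`ParamPrior` per parameter."""

    priors: dict[str, ParamPrior]
    t_er_fraction: float = 0.95  # subject bound: fraction of min retained RT

    @classmethod
    def default(cls, param_names) -> "PriorSpec":
        return cls({n: ParamPrior(n, default_link(n)) for n in param_names})

    def __getitem__(self, name: str) -> ParamPrior:
        return self.priors[name]


@dataclass
class SamplerConfig:
    """Ensemble-sampler budget and schedule.

    The sampler starts at ``n_iter_start`` iterations and doubles the total
    until all R-hat <= ``rhat_threshold`` or ``n_iter_max`` is reached
    (the result is then flagged non-converged). ``n_walkers`` defaults to
    2 x ndim + 2 rounded up to a multiple of ``n_chains``.
    """

    n_iter_start: int = 1000
    n_iter_max: int = 16000
    n_walkers: int | None = None
    n_chains: int = 4
    rhat_threshold: float = 1.01
    max_pointwise_draws: int = 1000
    likelihood_tol: float = 1e-8
    map_init: bool = True
    progress: bool = False


# ---------------------------------------------------------------------------
# likelihood adapters


class CognitiveLikelihood:
    """Per-subject likelihood adapter for every cognitive model class.

    Packs the TrialTable once into numeric arrays and exposes
    ``loglike(s, params)`` and ``pointwise(s, params)`` on the natural
    parameter scale, in the order of ``param_names``.
    """

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec,
                 design: BanditDesign, init_rule: str = "grand_mean",
                 tol: float = 1e-8):
        self.spec = spec
        self.design = design
        self.tol = tol
        self.init_code = _INIT_RULE_CODE[init_rule]
        self.arrays = trial_arrays(trials, design)
        self.subject_ids = [a.subject for a in self.arrays]
        self.param_names = spec.param_names(design)
        self.n_subjects = len(self.arrays)
        self._scratch = [np.empty(a.n_trials) for a in self.arrays]
        # subject-wise upper bound for the non-decision time link
        self.t_er_hi = np.array([
            a.rt[a.include].min() if np.any(a.include) else 1.0
            for a in self.arrays])
        if spec.model_class == "DDM":
            drift_rule, thresh_rule = DDM_VARIANTS[spec.variant]
            self._cond = []
            for a in self.arrays:
                if drift_rule == "difficulty":
                    vidx = np.where(a.easy, 0, 1)
                    n_v = 2
                else:
                    vidx = np.array([design.pairs.index(p) for p in a.pair])
                    n_v = len(design.pairs)
                if thresh_rule == "single":
                    aidx = np.zeros(a.n_trials, dtype=np.int64)
                else:
                    aidx = np.array([design.pairs.index(p) for p in a.pair])
                self._cond.append((vidx, aidx, n_v))

    def n_points(self, s: int) -> int:
        return int(self.arrays[s].include.sum())

    def _eval(self, s: int, params: np.ndarray, pointwise: bool):
        a = self.arrays[s]
        spec = self.spec
        scratch = self._scratch[s]
        if spec.model_class in ("RLDDM", "PedersenRLDDM"):
            p = self._kernel_vector(params)
            dk, tk = spec._codes
            total = _rlddm_loglik_kernel(
                a.cor, a.inc, a.f_cor, a.f_inc, a.acc, a.rt, a.block, a.tib,
                a.include, self.design.n_options, float(self.design.initial_q),
                p, dk, tk, self.init_code, self.tol, scratch)
        elif spec.model_class == "RL":
            n_eta, sens = _learning.RL_VARIANTS[spec.variant]
            names = self.param_names
            eta_p = params[0]
            eta_m = params[1] if n_eta == 2 else params[0]
            k = n_eta
            if sens == "fixed":
                theta, b, c = params[k], 1.0, 0.0
            else:
                theta, b, c = 1.0, params[k], params[k + 1]
            total = _rl_loglik_kernel(
                a.cor, a.inc, a.f_cor, a.f_inc, a.acc, a.block, a.include,
                self.design.n_options, float(self.design.initial_q),
                eta_p, eta_m, theta, b, c, 1 if sens == "power" else 0,
                self.init_code, scratch)
        else:  # DDM
            vidx, aidx, n_v = self._cond[s]
            v = params[:n_v][vidx]
            n_a = len(self.param_names) - n_v - 1
            a_vals = params[n_v:n_v + n_a][aidx]
            t_er = np.full(a.n_trials, params[-1])
            if pointwise:
                _wfpt_loglik_pointwise(a.rt, a.acc == 1, v, a_vals, t_er,
                                       a.include, self.tol, scratch)
                return scratch[a.include].copy()
            return _wfpt_loglik_sum(a.rt, a.acc == 1, v, a_vals, t_er,
                                    a.include, self.tol)
        if pointwise:
            return scratch[a.include].copy()
        return total

    def _kernel_vector(self, params: np.ndarray) -> np.ndarray:
        """Map the named natural-scale vector onto the 9-slot kernel layout."""
        spec = self.spec
        names = self.param_names
        p = np.zeros(9)
        i = 0
        if spec.n_learning_rates == 1:
            p[0] = p[1] = params[0]
            i = 1
        else:
            p[0], p[1] = params[0], params[1]
            i = 2
        if spec.model_class == "PedersenRLDDM":
            p[2] = params[i]  # m_base
            i += 1
            if "d_m" in names:
                p[8] = params[i]
                i += 1
            p[4] = params[i]      # a_base
            p[7] = params[i + 1]  # d_a
            p[6] = params[i + 2]  # t_er
            return p
        p[2] = params[i]  # v_mod
        i += 1
        if spec.drift_mapping == "sigmoid":
            p[3] = params[i]
            i += 1
        if spec.threshold_rule == "fixed":
            p[4] = params[i]
            i += 1
        else:
            p[4], p[5] = params[i], params[i + 1]
            i += 2
        p[6] = params[i]  # t_er
        return p

    def loglike(self, s: int, params: np.ndarray) -> float:
        return float(self._eval(s, params, pointwise=False))

    def pointwise(self, s: int, params: np.ndarray) -> np.ndarray:
        return self._eval(s, params, pointwise=True)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class ModelComparisonRow:
    """One row of a WAIC comparison table.

    The identity waic = 2 (neg_lppd + p_waic) holds exactly before any
    rounding for display.
    """

    model: str
    p_waic: float
    neg_lppd: float
    flagged: bool = False

    @property
    def waic(self) -> float:
        return 2.0 * (self.neg_lppd + self.p_waic)


@dataclass
class PosteriorDraws:
    """Posterior draws plus pointwise predictive densities and diagnostics.

    ``draws`` is (chain, draw, dim) on the unconstrained sampling scale with
    layout [mu (P), log_sigma (P), z (S x P row-major)]; warm-up is already
    discarded and chains have equal length.
    """

    param_names: list
    subject_ids: list
    draws: np.ndarray
    links: list
    t_er_hi: np.ndarray  # per-subject scaled-logit bound (1.0 where unused)
    pointwise: np.ndarray  # (n_pw_draws, n_points)
    rhat: np.ndarray       # per sampled dimension
    ess: np.ndarray
    converged: bool
    divergence_fraction: float
    n_iterations: int
    model_name: str = ""
    point_subject: np.ndarray | None = None  # subject index per data point

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def group_mean_draws(self) -> pd.DataFrame:
        """Natural-scale group location draws (flattened over chains).

        For each parameter this is link^{-1}(mu), i.e. the group median on
        the natural scale; the scaled-logit bound uses the mean subject
        bound for reporting.
        """
        P = self.n_params
        mu = self.draws[:, :, :P].reshape(-1, P)
        out = {}
        for j, (name, link) in enumerate(zip(self.param_names, self.links)):
            hi = float(np.mean(self.t_er_hi)) if link == "scaled_logit" else 1.0
            out[name] = _inv_link(link, mu[:, j], hi)
        return pd.DataFrame(out)

    def subject_param_draws(self, thin: int = 1) -> np.ndarray:
        """Natural-scale subject parameters, (n_draws, S, P)."""
        P, S = self.n_params, self.n_subjects
        flat = self.draws.reshape(-1, self.draws.shape[-1])[::thin]
        mu = flat[:, :P]
        sigma = np.exp(flat[:, P:2 * P])
        z = flat[:, 2 * P:].reshape(-1, S, P)
        uncon = mu[:, None, :] + sigma[:, None, :] * z
        nat = np.empty_like(uncon)
        for j, link in enumerate(self.links):
            hi = self.t_er_hi[None, :] if link == "scaled_logit" else 1.0
            nat[:, :, j] = _inv_link(link, uncon[:, :, j], hi)
        return nat

    def save(self, path) -> None:
        """Persist draws, pointwise densities and diagnostics (.npz)."""
        np.savez_compressed(
            path, draws=self.draws, pointwise=self.pointwise,
            rhat=self.rhat, ess=self.ess, t_er_hi=self.t_er_hi,
            point_subject=self.point_subject if self.point_subject is not None
            else np.array([]),
            param_names=np.array(self.param_names, dtype=object),
            subject_ids=np.array(self.subject_ids, dtype=object),
            links=np.array(self.links, dtype=object),
            meta=np.array([self.model_name, str(self.converged),
                           str(self.divergence_fraction),
                           str(self.n_iterations)], dtype=object),
            allow_pickle=True)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        z = np.load(path, allow_pickle=True)
        meta = z["meta"]
        return cls(
            param_names=list(z["param_names"]),
            subject_ids=list(z["subject_ids"]),
            draws=z["draws"], links=list(z["links"]), t_er_hi=z["t_er_hi"],
            pointwise=z["pointwise"], rhat=z["rhat"], ess=z["ess"],
            converged=meta[1] == "True", divergence_fraction=float(meta[2]),
            n_iterations=int(meta[3]), model_name=str(meta[0]),
            point_subject=z["point_subject"] if z["point_subject"].size else None)

    def summary(self) -> pd.DataFrame:
        """Group-level natural-scale posterior summary with 95% BCIs."""
        gm = self.group_mean_draws()
        P = self.n_params
        rows = []
        for j, name in enumerate(self.param_names):
            d = gm[name].to_numpy()
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append((name, d.mean(), d.std(), lo, hi,
                         self.rhat[j], self.ess[j]))
        return pd.DataFrame(rows, columns=[
            "parameter", "mean", "sd", "bci_2.5", "bci_97.5", "rhat", "ess"])


# ---------------------------------------------------------------------------
# fitting


def _make_logpost(like, prior: PriorSpec, links):
    P = like.n_subjects and len(like.param_names)
    P = len(like.param_names)
    S = like.n_subjects
    mu_loc = np.array([prior[n].mu_loc for n in like.param_names])
    mu_scale = np.array([prior[n].mu_scale for n in like.param_names])
    sd_scale = np.array([prior[n].sd_scale for n in like.param_names])
    hi = np.asarray(getattr(like, "t_er_hi", np.ones(S)), dtype=float) * \
        prior.t_er_fraction
    link_codes = links

    def natural(theta):
        mu = theta[:P]
        sigma = np.exp(theta[P:2 * P])
        z = theta[2 * P:].reshape(S, P)
        uncon = mu[None, :] + sigma[None, :] * z
        nat = np.empty_like(uncon)
        for j, link in enumerate(link_codes):
            if link == "scaled_logit":
                nat[:, j] = hi * expit(uncon[:, j])
            else:
                nat[:, j] = _inv_link(link, uncon[:, j])
        return nat

    def logpost(theta):
        mu = theta[:P]
        log_sigma = theta[P:2 * P]
        sigma = np.exp(log_sigma)
        z = theta[2 * P:]
        lp = -0.5 * np.sum(((mu - mu_loc) / mu_scale) ** 2)
        lp += np.sum(-0.5 * (sigma / sd_scale) ** 2 + log_sigma)
        lp += -0.5 * np.sum(z ** 2)
        nat = natural(theta)
        if not np.all(np.isfinite(nat)):
            return -np.inf
        for s in range(S):
            ll = like.loglike(s, nat[s])
            if not np.isfinite(ll):
                return -np.inf
            lp += ll
        return lp if np.isfinite(lp) else -np.inf

    return logpost, natural, hi


def _map_init(like, links, hi, seed):
    """Per-subject penalized ML on the unconstrained scale; returns the
    (S, P) matrix of unconstrained estimates."""
    P = len(like.param_names)
    rng = np.random.default_rng(seed)
    out = np.zeros((like.n_subjects, P))
    for s in range(like.n_subjects):
        # start each parameter at a feasible interior point; the
        # non-decision time must begin well below the subject's minimum RT
        loc = np.zeros(P)
        for j, name in enumerate(like.param_names):
            if name == "t_er" and links[j] == "log":
                loc[j] = np.log(0.5 * hi[s])
            elif name == "a" and links[j] == "log":
                loc[j] = np.log(1.5)

        def neg(u):
            nat = np.empty(P)
            for j, link in enumerate(links):
                nat[j] = _inv_link(link, u[j], hi[s]) if link == "scaled_logit" \
                    else _inv_link(link, u[j])
            ll = like.loglike(s, nat)
            if not np.isfinite(ll):
                return 1e12
            return -(ll - 0.5 * np.sum(((u - loc) / 2.0) ** 2))
        best = None
        for attempt in range(5):
            u0 = loc + rng.normal(0, 0.3, P)
            res = minimize(neg, u0, method="Nelder-Mead",
                           options={"maxiter": 400 * P, "xatol": 1e-3,
                                    "fatol": 1e-3})
            if best is None or res.fun < best.fun:
                best = res
            if np.isfinite(best.fun) and best.fun < 1e11:
                break
        out[s] = best.x
    return out


def _split_chains(chain: np.ndarray, n_chains: int) -> np.ndarray:
    """(steps, walkers, dim) -> (n_chains, steps * walkers/n_chains, dim) by
    partitioning the exchangeable walker ensemble."""
    steps, walkers, dim = chain.shape
    per = walkers // n_chains
    groups = chain[:, :per * n_chains, :].reshape(steps, n_chains, per, dim)
    return groups.transpose(1, 0, 2, 3).reshape(n_chains, steps * per, dim)


def fit_hierarchical(trials=None, spec=None, design=None, priors=None,
                     config: SamplerConfig | None = None, seed: int = 0,
                     likelihood=None, init_rule: str = "grand_mean",
                     model_name: str | None = None) -> PosteriorDraws:
    """Fit a hierarchical Bayesian model and return posterior draws.

    Either supply (``trials``, ``spec``, ``design``) for a cognitive model,
    or a prebuilt ``likelihood`` adapter. Requires at least two subjects.
    Non-convergence (R-hat > threshold at the iteration cap) flags the
    result; it is not an exception.
    """
    import emcee

    config = config or SamplerConfig()
    if likelihood is None:
        if trials is None or spec is None or design is None:
            raise ValueError("supply either a likelihood adapter or "
                             "(trials, spec, design)")
        likelihood = CognitiveLikelihood(trials, spec, design,
                                         init_rule=init_rule,
                                         tol=config.likelihood_tol)
    if likelihood.n_subjects == 0:
        raise ValueError("empty data")
    if likelihood.n_subjects < 2:
        raise ValueError("hierarchical estimation requires >= 2 subjects")
    names = list(likelihood.param_names)
    priors = priors or PriorSpec.default(names)
    links = [priors[n].link for n in names]
    P, S = len(names), likelihood.n_subjects
    ndim = 2 * P + S * P

    logpost, natural, hi = _make_logpost(likelihood, priors, links)

    rng = np.random.default_rng(seed)
    if config.map_init:
        uncon = _map_init(likelihood, links, hi, seed)
        mu0 = uncon.mean(axis=0)
        sigma0 = np.clip(uncon.std(axis=0), 0.05, 1.5)
        z0 = np.clip((uncon - mu0) / sigma0, -3, 3)
    else:
        mu0 = np.zeros(P)
        sigma0 = np.full(P, 0.5)
        z0 = np.zeros((S, P))
    theta0 = np.concatenate([mu0, np.log(sigma0), z0.ravel()])

    n_walkers = config.n_walkers or (2 * ndim + 2)
    n_walkers += (-n_walkers) % config.n_chains
    if n_walkers < 2 * ndim + 2:
        n_walkers = 2 * ndim + 2 + ((-(2 * ndim + 2)) % config.n_chains)

    # overdispersed, structure-aware initial ensemble: group means scattered
    # at their expected posterior scale (sigma/sqrt(S)), group log-SDs and
    # standardized offsets at O(0.4) — a near-degenerate ensemble makes
    # differential-evolution proposals tiny and the chain under-disperses
    scale = np.concatenate([sigma0 / np.sqrt(S) + 0.05,
                            np.full(P, 0.4),
                            np.full(S * P, 0.4)])
    p0 = theta0[None, :] + scale[None, :] * rng.standard_normal((n_walkers, ndim))
    # make sure every walker starts at finite posterior density
    for w in range(n_walkers):
        for attempt in range(50):
            if np.isfinite(logpost(p0[w])):
                break
            shrink = 0.5 ** (1 + attempt // 10)
            p0[w] = theta0 + shrink * scale * rng.standard_normal(ndim)

    # differential-evolution moves traverse the hierarchical (sigma, z)
    # funnel far better than the default stretch move
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, logpost, moves=moves)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2 ** 31))).get_state()
    state = p0
    total = 0
    target = config.n_iter_start
    rhat = np.full(ndim, np.inf)
    converged = False
    while True:
        state = sampler.run_mcmc(state, target - total, progress=config.progress,
                                 skip_initial_state_check=True)
        total = target
        chain = sampler.get_chain()  # (steps, walkers, ndim)
        retained = chain[total // 2:]
        grouped = _split_chains(retained, config.n_chains)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(grouped)
            rhat = az.rhat(ds)["x"].to_numpy()
            ess = az.ess(ds)["x"].to_numpy()
        converged = bool(np.all(rhat <= config.rhat_threshold))
        if converged or target >= config.n_iter_max:
            break
        target = min(2 * target, config.n_iter_max)

    draws = grouped  # (n_chains, draws_per_chain, ndim)

    # pointwise log predictive densities on a thinned draw set
    flat = retained.reshape(-1, ndim)
    n_pw = min(config.max_pointwise_draws, flat.shape[0])
    idx = np.linspace(0, flat.shape[0] - 1, n_pw).astype(int)
    n_points = sum(likelihood.n_points(s) for s in range(S))
    pw = np.empty((n_pw, n_points))
    point_subject = np.concatenate([
        np.full(likelihood.n_points(s), s) for s in range(S)])
    for k, i in enumerate(idx):
        nat = natural(flat[i])
        off = 0
        for s in range(S):
            vals = likelihood.pointwise(s, nat[s])
            pw[k, off:off + len(vals)] = vals
            off += len(vals)

    lp = sampler.get_log_prob()[total // 2:]
    div_frac = float(np.mean(~np.isfinite(lp)))

    # per-parameter diagnostics: worst R-hat across (mu, log_sigma, z_j)
    rhat_param = np.array([
        max(rhat[j], rhat[P + j], rhat[2 * P + j::P].max())
        for j in range(P)])
    ess_param = np.array([min(ess[j], ess[P + j]) for j in range(P)])

    return PosteriorDraws(
        param_names=names,
        subject_ids=list(likelihood.subject_ids),
        draws=draws,
        links=links,
        t_er_hi=hi,
        pointwise=pw,
        rhat=rhat_param,
        ess=ess_param,
        converged=converged,
        divergence_fraction=div_frac,
        n_iterations=total,
        model_name=model_name or getattr(getattr(likelihood, "spec", None),
                                         "name", ""),
        point_subject=point_subject,
    )


# ---------------------------------------------------------------------------
# WAIC and comparison


def compute_waic(pointwise: np.ndarray, model: str = "") -> ModelComparisonRow:
    """WAIC from a (draws x points) pointwise log predictive density matrix.

    lppd sums the log of the draw-averaged density per point; the complexity
    penalty p_waic sums the per-point variance of the log density. Points
    whose density is zero under every draw yield -inf lppd and flag the row.
    """
    pointwise = np.asarray(pointwise, dtype=float)
    if pointwise.ndim != 2 or pointwise.shape[0] < 2:
        raise ValueError("need a (draws >= 2) x points matrix")
    n_draws = pointwise.shape[0]
    lppd_i = logsumexp(pointwise, axis=0) - np.log(n_draws)
    flagged = bool(np.any(~np.isfinite(lppd_i)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var_i = np.var(pointwise, axis=0, ddof=1)
    lppd = float(np.sum(lppd_i))
    p_waic = float(np.sum(var_i[np.isfinite(lppd_i)]))
    return ModelComparisonRow(model=model, p_waic=p_waic, neg_lppd=-lppd,
                              flagged=flagged)


def _pointwise_of(x) -> np.ndarray:
    return x.pointwise if isinstance(x, PosteriorDraws) else np.asarray(x)


def compare_models(a, b) -> tuple[float, float]:
    """Difference in expected log predictive density, a - b, with its SE.

    Per-point elpd contributions are differenced; the standard error is
    sqrt(n var) of the per-point differences. Requires identical data-point
    ordering in both pointwise matrices.
    """
    pa, pb = _pointwise_of(a), _pointwise_of(b)
    if pa.shape[1] != pb.shape[1]:
        raise ValueError("models were evaluated on different numbers of points")
    ea = logsumexp(pa, axis=0) - np.log(pa.shape[0])
    eb = logsumexp(pb, axis=0) - np.log(pb.shape[0])
    d = ea - eb
    elpd_diff = float(np.sum(d))
    se_diff = float(np.sqrt(d.shape[0] * np.var(d, ddof=1))) if d.shape[0] > 1 else 0.0
    return elpd_diff, se_diff


def comparison_table(rows) -> pd.DataFrame:
    """Delimited-text-ready WAIC table (model, p_WAIC, -lppd, WAIC)."""
    return pd.DataFrame(
        [(r.model, r.p_waic, r.neg_lppd, r.waic) for r in rows],
        columns=["model", "p_WAIC", "-lppd", "WAIC"]).sort_values("WAIC")
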