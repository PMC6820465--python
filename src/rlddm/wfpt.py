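"""Wiener diffusion first-passage machinery.

Within a trial, evidence x accumulates from a/2 between absorbing boundaries
at 0 and a with drift v and unit diffusion coefficient (the scaling
convention); the boundary hit determines the choice and the hitting time plus
the non-decision time t_er determines the response time. This module provides
the Euler-Maruyama simulator of that process, the first-passage-time density
(small-time and large-time series expansions with automatic switching), the
closed-form absorption probability and mean decision time used as oracles,
and the likelihood of the three static diffusion model variants
(condition-wise drifts and thresholds, no learning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DDMParameters",
    "FirstPassageSample",
    "simulate_first_passage",
    "simulate_first_passage_batch",
    "upper_hit_probability",
    "mean_decision_time",
    "wfpt_log_density",
    "ddm_log_likelihood",
    "DDM_VARIANTS",
]


@dataclass(frozen=True)
class DDMParameters:
    """Core diffusion parameters: drift v, threshold separation a > 0,
    non-decision time t_er >= 0. Starting point is fixed at a/2 (unbiased)
    and the diffusion coefficient at 1."""

    v: float
    a: float
    t_er: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError("drift must be finite")
        if not (self.a > 0):
            raise ValueError("threshold separation a must be > 0")
        if self.t_er < 0:
            raise ValueError("non-decision time must be >= 0")


@dataclass(frozen=True)
class FirstPassageSample:
    boundary: str  # "upper" | "lower"
    rt: float  # seconds, decision time + t_er
    censored: bool = False


# ---------------------------------------------------------------------------
# density: Navarro-Fuss style small-time / large-time series


@njit(cache=True)
def _f_standardized(u: float, w: float, tol: float) -> float:
    """First-passage density at the lower boundary of the driftless unit
    process (a = 1) at scaled time u, start w in (0, 1)."""
    # number of terms needed by each expansion for truncation error < tol
    if 2.0 * math.sqrt(2.0 * math.pi * u) * tol < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * tol * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    if math.pi * u * tol < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * tol) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if ks < kl:  # small-time expansion cheaper
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-K, K + 1):
            z = w + 2.0 * k
            acc += z * math.exp(-z * z / (2.0 * u))
        return acc / math.sqrt(2.0 * math.pi * u ** 3)
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@njit(cache=True)
def _wfpt_logpdf_lower(t: float, v: float, a: float, w: float, tol: float) -> float:
    """Log density of hitting the LOWER boundary at decision time t."""
    if t <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return -np.inf
    u = t / (a * a)
    f = _f_standardized(u, w, tol)
    if f <= 0.0:
        return -np.inf
    return math.log(f) - math.log(a * a) - v * a * w - v * v * t / 2.0


@njit(cache=True)
def _wfpt_logpdf(t_dec: float, upper: bool, v: float, a: float,
                 w: float, tol: float) -> float:
    """Log first-passage density at either boundary (drift-reflection for
    the upper boundary: v -> -v, w -> 1 - w)."""
    if upper:
        return _wfpt_logpdf_lower(t_dec, -v, a, 1.0 - w, tol)
    return _wfpt_logpdf_lower(t_dec, v, a, w, tol)


@njit(cache=True)
def _wfpt_loglik_sum(rt, upper, v, a, t_er, include, tol):
    """Summed log-likelihood over trial arrays; -inf if any included trial
    has rt <= t_er (samplers reject such draws)."""
    total = 0.0
    for i in range(rt.shape[0]):
        if not include[i]:
            continue
        t_dec = rt[i] - t_er[i]
        if t_dec <= 0.0:
            return -np.inf
        total += _wfpt_logpdf(t_dec, upper[i], v[i], a[i], 0.5, tol)
    return total


@njit(cache=True)
def _wfpt_loglik_pointwise(rt, upper, v, a, t_er, include, tol, out):
    for i in range(rt.shape[0]):
        if not include[i]:
            out[i] = 0.0
            continue
        t_dec = rt[i] - t_er[i]
        out[i] = -np.inf if t_dec <= 0.0 else _wfpt_logpdf(t_dec, upper[i], v[i], a[i], 0.5, tol)


def wfpt_log_density(rt: float, boundary: str, params: DDMParameters,
                     tol: float = 1e-10) -> float:
    """Log of the Wiener first-passage density at the stated boundary.

    Evaluated at decision time ``rt - t_er`` with unbiased start; returns
    -inf for rt <= t_er. The series truncation error is below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t_dec = rt - params.t_er
    if t_dec <= 0:
        return -np.inf
    return float(_wfpt_logpdf(t_dec, boundary == "upper",
                              params.v, params.a, 0.5, tol))


# ---------------------------------------------------------------------------
# closed-form oracles (unbiased start, unit diffusion)


def upper_hit_probability(v: float, a: float) -> float:
    """Probability of absorption at the upper boundary from a/2: a logistic
    of the drift-threshold product, 1 / (1 + exp(-v a)); 0.5 at v = 0."""
    if not (a > 0):
        raise ValueError("a must be > 0")
    return float(1.0 / (1.0 + np.exp(-v * a)))


def mean_decision_time(v: float, a: float) -> float:
    """Expected first-passage time from a/2: (a / 2v) tanh(v a / 2),
    with the driftless limit a^2 / 4."""
    if not (a > 0):
        raise ValueError("a must be > 0")
    if v == 0:
        return a * a / 4.0
    return float(a / (2.0 * v) * np.tanh(v * a / 2.0))


# ---------------------------------------------------------------------------
# Euler-Maruyama simulation


@njit(cache=True)
def _sim_one(v: float, a: float, dt: float, max_steps: int, noise: float) -> tuple:
    """Single path from a/2; returns (hit_upper, n_steps, censored).

    A Brownian-bridge crossing check between grid points removes the
    leading-order boundary-overshoot bias of the plain Euler scheme.
    """
    x = a / 2.0
    sq = noise * math.sqrt(dt)
    s2dt = noise * noise * dt
    for i in range(1, max_steps + 1):
        x_new = x + v * dt + sq * np.random.normal()
        if x_new >= a:
            return True, i, False
        if x_new <= 0.0:
            return False, i, False
        # probability the continuous bridge crossed a boundary within the step
        p_up = math.exp(-2.0 * (a - x) * (a - x_new) / s2dt)
        p_lo = math.exp(-2.0 * x * x_new / s2dt)
        u = np.random.random()
        if u < p_up:
            return True, i, False
        if u < p_up + p_lo:
            return False, i, False
        x = x_new
    return x >= a / 2.0, max_steps, True


@njit(cache=True)
def _sim_batch(v, a, dt, max_steps, noise, seed, hit_upper, n_steps, censored):
    np.random.seed(seed)
    for j in range(hit_upper.shape[0]):
        up, n, cens = _sim_one(v[j], a[j], dt, max_steps, noise)
        hit_upper[j] = up
        n_steps[j] = n
        censored[j] = cens


def simulate_first_passage(params: DDMParameters, dt: float = 0.001,
                           max_time: float = 5.0, seed: int = 0,
                           noise: float = 1.0) -> FirstPassageSample:
    """Simulate one trial by Euler-Maruyama: x_{i+1} = x_i + N(v dt, sqrt(dt)),
    x_0 = a/2, absorbing at 0 and a. Paths still unabsorbed at ``max_time``
    are returned censored (rt = max_time + t_er), not raised."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if max_time <= params.t_er:
        raise ValueError("max_time must exceed t_er")
    up, n, cens = simulate_first_passage_batch(
        np.array([params.v]), np.array([params.a]), dt=dt,
        max_time=max_time, seed=seed, noise=noise)
    return FirstPassageSample("upper" if up[0] else "lower",
                              float(n[0] * dt + params.t_er), bool(cens[0]))


def simulate_first_passage_batch(v: np.ndarray, a: np.ndarray, dt: float = 0.001,
                                 max_time: float = 5.0, seed: int = 0,
                                 noise: float = 1.0):
    """Vectorized simulation; returns (hit_upper, n_steps, censored) arrays."""
    v = np.ascontiguousarray(v, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    n = v.shape[0]
    hit_upper = np.empty(n, dtype=np.bool_)
    n_steps = np.empty(n, dtype=np.int64)
    censored = np.empty(n, dtype=np.bool_)
    max_steps = int(np.ceil(max_time / dt))
    _sim_batch(v, a, dt, max_steps, noise, seed % (2 ** 31), hit_upper, n_steps, censored)
    return hit_upper, n_steps, censored


# ---------------------------------------------------------------------------
# static DDM variants

# variant id -> (drift rule, threshold rule)
DDM_VARIANTS = {
    1: ("difficulty", "single"),
    2: ("difficulty", "per_pair"),
    3: ("per_pair", "per_pair"),
}


def ddm_condition_map(trials: pd.DataFrame, design, variant: int) -> pd.DataFrame:
    """Per-trial drift and threshold condition labels for a static variant."""
    if variant not in DDM_VARIANTS:
        raise ValueError(f"unknown DDM variant {variant}")
    drift_rule, thresh_rule = DDM_VARIANTS[variant]
    stats_df = pair_stats_lookup(design)
    pair = trials["pair"]
    unknown = set(pair) - set(stats_df.index)
    if unknown:
        raise ValueError(f"trials reference unmapped pairs: {sorted(unknown)}")
    drift_cond = (stats_df.loc[pair, "difficulty_class"].to_numpy()
                  if drift_rule == "difficulty" else pair.to_numpy())
    thresh_cond = (np.repeat("all", len(trials))
                   if thresh_rule == "single" else pair.to_numpy())
    return pd.DataFrame({"drift_condition": drift_cond,
                         "threshold_condition": thresh_cond}, index=trials.index)


def pair_stats_lookup(design) -> pd.DataFrame:
    from .design import pair_statistics
    return pair_statistics(design).set_index("pair")


def ddm_log_likelihood(trials: pd.DataFrame, design, variant: int,
                       v_by_condition: dict, a_by_condition: dict,
                       t_er: float, tol: float = 1e-10) -> float:
    """Static diffusion log-likelihood for one subject.

    Each trial's drift condition (difficulty class or pair) and threshold
    condition (shared or pair) select (v, a) from the supplied dictionaries;
    the observed boundary is upper when the higher-mean option was chosen.
    Trials flagged excluded are skipped.
    """
    cmap = ddm_condition_map(trials, design, variant)
    missing_v = set(cmap["drift_condition"]) - set(v_by_condition)
    missing_a = set(cmap["threshold_condition"]) - set(a_by_condition)
    if missing_v or missing_a:
        raise ValueError(f"unmapped conditions: v={sorted(missing_v)}, a={sorted(missing_a)}")
    v = np.array([v_by_condition[c] for c in cmap["drift_condition"]])
    a = np.array([a_by_condition[c] for c in cmap["threshold_condition"]])
    rt = trials["rt"].to_numpy(dtype=np.float64)
    upper = trials["accuracy"].to_numpy() == 1
    include = (~trials["excluded"].to_numpy() if "excluded" in trials
               else np.ones(len(trials), dtype=bool))
    t_er_arr = np.full(len(trials), t_er)
    return float(_wfpt_loglik_sum(rt, upper, v, a, t_er_arr,
                                  include.astype(np.bool_), tol))
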