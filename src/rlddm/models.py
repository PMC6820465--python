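"""Combined reinforcement-learning diffusion models (and their competitors).

A model here is a point in a small model space. Four families are
constructible, mirroring the variants compared in the accompanying analyses:

* RL 1-4: delta-rule learning + soft-max choice (choices only); single or
  dual learning rate, fixed or power-growing sensitivity.
* DDM 1-3: static diffusion models with condition-wise drifts (difficulty
  class or pair) and thresholds (shared or per pair); no learning.
* RLDDM 1-8: delta-rule values drive the diffusion trialwise; drift is a
  linear or sigmoidal function of the value difference, the threshold is
  fixed or modulated by the mean value of the presented pair
  (a_t = exp(a_fix + a_mod * Qbar)), one or two learning rates.
* Pedersen RLDDM 1-4: reconstructions of an earlier combined model family
  with a threshold decaying and (optionally) a drift scale growing as power
  functions of the within-block trial number.

The module holds the per-trial parameter mappings, fast numba kernels for
the joint choice/RT likelihood, and the forward simulator that doubles as
the package's synthetic-data generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from . import learning
from .design import BanditDesign, generate_pair_sequence, generate_payoffs
from .wfpt import _sim_one, _wfpt_logpdf, ddm_condition_map

__all__ = [
    "ModelSpec",
    "RLDDMParameters",
    "make_params",
    "drift_linear",
    "drift_sigmoid",
    "threshold_value_modulated",
    "pedersen_trial_modulators",
    "build_trialwise_parameters",
    "rlddm_log_likelihood",
    "simulate_experiment",
    "trial_arrays",
]

# ---------------------------------------------------------------------------
# model space

_RLDDM_VARIANTS = {
    # variant: (n_eta, drift_mapping, threshold_rule)
    1: (1, "linear", "fixed"),
    2: (2, "linear", "fixed"),
    3: (1, "linear", "value-modulated"),
    4: (2, "linear", "value-modulated"),
    5: (1, "sigmoid", "fixed"),
    6: (2, "sigmoid", "fixed"),
    7: (1, "sigmoid", "value-modulated"),
    8: (2, "sigmoid", "value-modulated"),
}

_PEDERSEN_VARIANTS = {
    # variant: (n_eta, drift scale rule, threshold rule)
    1: (1, "fixed", "power-decay"),
    2: (1, "power", "power-decay"),
    3: (2, "fixed", "power-decay"),
    4: (2, "power", "power-decay"),
}

_N_VARIANTS = {"RL": 4, "DDM": 3, "RLDDM": 8, "PedersenRLDDM": 4}


@dataclass(frozen=True)
class ModelSpec:
    """A constructible point in the model space.

    Only the named variants of each class can be built; attempting any other
    combination raises at construction.
    """

    model_class: str  # RL | DDM | RLDDM | PedersenRLDDM
    variant: int

    def __post_init__(self) -> None:
        if self.model_class not in _N_VARIANTS:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if not (1 <= self.variant <= _N_VARIANTS[self.model_class]):
            raise ValueError(
                f"{self.model_class} has variants 1..{_N_VARIANTS[self.model_class]}, "
                f"got {self.variant}")

    @property
    def name(self) -> str:
        pretty = {"RL": "RL", "DDM": "DDM", "RLDDM": "RLDDM",
                  "PedersenRLDDM": "Pedersen RLDDM"}[self.model_class]
        return f"{pretty} {self.variant}"

    @property
    def n_learning_rates(self) -> int:
        if self.model_class == "RL":
            return learning.RL_VARIANTS[self.variant][0]
        if self.model_class == "RLDDM":
            return _RLDDM_VARIANTS[self.variant][0]
        if self.model_class == "PedersenRLDDM":
            return _PEDERSEN_VARIANTS[self.variant][0]
        return 0

    @property
    def sensitivity_rule(self) -> str | None:
        if self.model_class == "RL":
            return learning.RL_VARIANTS[self.variant][1]
        return None

    @property
    def drift_mapping(self) -> str | None:
        if self.model_class == "RLDDM":
            return _RLDDM_VARIANTS[self.variant][1]
        if self.model_class == "PedersenRLDDM":
            return "power-scaled" if _PEDERSEN_VARIANTS[self.variant][1] == "power" \
                else "linear"
        if self.model_class == "DDM":
            from .wfpt import DDM_VARIANTS
            return {"difficulty": "per-condition", "per_pair": "per-condition"}[
                DDM_VARIANTS[self.variant][0]]
        return None

    @property
    def threshold_rule(self) -> str | None:
        if self.model_class == "RLDDM":
            return _RLDDM_VARIANTS[self.variant][2]
        if self.model_class == "PedersenRLDDM":
            return "power-decay"
        if self.model_class == "DDM":
            from .wfpt import DDM_VARIANTS
            return {"single": "fixed", "per_pair": "per-pair"}[
                DDM_VARIANTS[self.variant][1]]
        return None

    def param_names(self, design: BanditDesign | None = None) -> list[str]:
        """Free parameters of the variant, in canonical order."""
        cls, var = self.model_class, self.variant
        if cls == "RL":
            n_eta, sens = learning.RL_VARIANTS[var]
            names = ["eta"] if n_eta == 1 else ["eta_plus", "eta_minus"]
            names += ["theta"] if sens == "fixed" else ["b", "c"]
            return names
        if cls == "DDM":
            from .wfpt import DDM_VARIANTS
            drift_rule, thresh_rule = DDM_VARIANTS[var]
            if design is None:
                raise ValueError("DDM parameter names depend on the design's pairs")
            if drift_rule == "difficulty":
                names = ["v_easy", "v_difficult"]
            else:
                names = [f"v_{p}" for p in design.pairs]
            if thresh_rule == "single":
                names += ["a"]
            else:
                names += [f"a_{p}" for p in design.pairs]
            return names + ["t_er"]
        if cls == "RLDDM":
            n_eta, drift, thresh = _RLDDM_VARIANTS[var]
            names = ["eta"] if n_eta == 1 else ["eta_plus", "eta_minus"]
            names += ["v_mod"]
            if drift == "sigmoid":
                names += ["v_max"]
            if thresh == "fixed":
                names += ["a"]
            else:
                names += ["a_fix", "a_mod"]
            return names + ["t_er"]
        n_eta, scale_rule, _ = _PEDERSEN_VARIANTS[var]
        names = ["eta"] if n_eta == 1 else ["eta_plus", "eta_minus"]
        names += ["m_base"]
        if scale_rule == "power":
            names += ["d_m"]
        names += ["a_base", "d_a", "t_er"]
        return names

    # integer codes consumed by the numba kernels
    @property
    def _codes(self) -> tuple[int, int]:
        if self.model_class == "RLDDM":
            _, drift, thresh = _RLDDM_VARIANTS[self.variant]
            return ({"linear": 0, "sigmoid": 1}[drift],
                    {"fixed": 0, "value-modulated": 1}[thresh])
        if self.model_class == "PedersenRLDDM":
            return 2, 2
        raise ValueError(f"{self.name} has no trialwise diffusion mapping")


@dataclass(frozen=True)
class RLDDMParameters:
    """Parameter container for the combined models.

    Learning rates live in [0, 1]; thresholds generated by any rule must be
    strictly positive; v_max > 0; non-decision time t_er >= 0; the Pedersen
    power exponents d_a (threshold decay) and d_m (drift-scale growth) are
    >= 0. Unused fields may stay None.
    """

    eta_plus: float = 0.0
    eta_minus: float | None = None
    v_mod: float | None = None
    v_max: float | None = None
    a: float | None = None
    a_fix: float | None = None
    a_mod: float | None = None
    t_er: float = 0.0
    d_a: float | None = None
    d_m: float | None = None
    m_base: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_plus <= 1.0):
            raise ValueError("eta_plus must lie in [0, 1]")
        if self.eta_minus is None:
            object.__setattr__(self, "eta_minus", self.eta_plus)
        elif not (0.0 <= self.eta_minus <= 1.0):
            raise ValueError("eta_minus must lie in [0, 1]")
        if self.v_max is not None and self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if self.a is not None and self.a <= 0:
            raise ValueError("a must be > 0")
        if self.t_er < 0:
            raise ValueError("t_er must be >= 0")
        for name in ("d_a", "d_m"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict, spec: ModelSpec | None = None) -> "RLDDMParameters":
        d = dict(d)
        if "eta" in d:
            d["eta_plus"] = d.pop("eta")
        return cls(**d)

    def _vector(self, spec: ModelSpec) -> np.ndarray:
        """Pack into the 9-slot kernel layout, validating spec/parameter fit."""
        drift_kind, thresh_kind = spec._codes
        p = np.zeros(9)
        p[0], p[1] = self.eta_plus, self.eta_minus
        if drift_kind == 2:
            if self.m_base is None:
                raise ValueError(f"{spec.name} requires m_base")
            p[2] = self.m_base
            p[8] = self.d_m if self.d_m is not None else 0.0
        else:
            if self.v_mod is None:
                raise ValueError(f"{spec.name} requires v_mod")
            p[2] = self.v_mod
        if drift_kind == 1:
            if self.v_max is None:
                raise ValueError(f"sigmoid variant {spec.name} requires v_max")
            p[3] = self.v_max
        if thresh_kind == 0:
            if self.a is None:
                raise ValueError(f"{spec.name} requires a")
            p[4] = self.a
        elif thresh_kind == 1:
            if self.a_fix is None or self.a_mod is None:
                raise ValueError(f"{spec.name} requires a_fix and a_mod")
            p[4], p[5] = self.a_fix, self.a_mod
        else:
            if self.a_base is None or self.d_a is None:
                raise ValueError(f"{spec.name} requires a_base and d_a")
            p[4], p[7] = self.a_base, self.d_a
        p[6] = self.t_er
        return p

    @property
    def a_base(self):
        # Pedersen threshold base reuses the fixed-threshold slot
        return self.a


def make_params(spec: ModelSpec, values: dict):
    """Build the parameter object a spec's simulator/likelihood expects from
    a flat {name: value} mapping using the spec's canonical names.

    RL specs return :class:`learning.RLParameters`; combined specs return
    :class:`RLDDMParameters`; DDM specs return the
    ``(v_by_condition, a_by_condition, t_er)`` triple used by
    condition-parameterized operations.
    """
    v = dict(values)
    if spec.model_class == "RL":
        kw = {"eta_plus": v.get("eta", v.get("eta_plus"))}
        if "eta_minus" in v:
            kw["eta_minus"] = v["eta_minus"]
        for k in ("theta", "b", "c"):
            if k in v:
                kw[k] = v[k]
        return learning.RLParameters(**kw)
    if spec.model_class == "DDM":
        v_by = {}
        a_by = {}
        for name, val in v.items():
            if name == "t_er":
                continue
            if name == "a":
                a_by["all"] = val
            elif name.startswith("v_"):
                v_by[name[2:]] = val
            elif name.startswith("a_"):
                a_by[name[2:]] = val
        return v_by, a_by, v["t_er"]
    kw = {"eta_plus": v.get("eta", v.get("eta_plus")), "t_er": v.get("t_er", 0.0)}
    if "eta_minus" in v:
        kw["eta_minus"] = v["eta_minus"]
    if spec.model_class == "PedersenRLDDM":
        kw["m_base"] = v["m_base"]
        kw["a"] = v["a_base"]  # Pedersen threshold base reuses the a slot
        kw["d_a"] = v["d_a"]
        if "d_m" in v:
            kw["d_m"] = v["d_m"]
    else:
        kw["v_mod"] = v["v_mod"]
        for k in ("v_max", "a", "a_fix", "a_mod"):
            if k in v:
                kw[k] = v[k]
    return RLDDMParameters(**kw)


# ---------------------------------------------------------------------------
# trialwise parameter mappings (pure functions)


def drift_linear(q_cor: float, q_inc: float, v_mod: float) -> float:
    """Linear value-difference drift: v = v_mod * (q_cor - q_inc)."""
    return v_mod * (q_cor - q_inc)


def drift_sigmoid(q_cor: float, q_inc: float, v_mod: float, v_max: float) -> float:
    """Sigmoidal drift S(v_mod (q_cor - q_inc)) with
    S(z) = 2 v_max / (1 + exp(-z)) - v_max, an odd S-shape saturating at
    +/- v_max."""
    if v_max <= 0:
        raise ValueError("v_max must be > 0")
    z = v_mod * (q_cor - q_inc)
    if z >= 0:
        return v_max * (2.0 / (1.0 + math.exp(-z)) - 1.0)
    ez = math.exp(z)
    return v_max * (2.0 * ez / (1.0 + ez) - 1.0)


def threshold_value_modulated(a_fix: float, a_mod: float, q_bar_pres: float) -> float:
    """Value-modulated threshold exp(a_fix + a_mod * Qbar_pres) (> 0 by
    construction; a_mod = 0 recovers a constant threshold)."""
    return math.exp(a_fix + a_mod * q_bar_pres)


def pedersen_trial_modulators(t: int, a_base: float, m_base: float,
                              d_a: float, d_m: float) -> tuple[float, float]:
    """Within-block power modulators: threshold a_base * t^-d_a (decay) and
    drift scale m_base * t^d_m (growth), t the 1-based trial-in-block."""
    if t < 1:
        raise ValueError("trial-in-block index starts at 1")
    if d_a < 0 or d_m < 0:
        raise ValueError("decay/growth exponents must be >= 0")
    return a_base * t ** (-d_a), m_base * t ** d_m


# ---------------------------------------------------------------------------
# packed trial arrays (the kernels' data format)


@dataclass
class SubjectArrays:
    subject: object
    cor: np.ndarray      # option index of the higher-mean option, per trial
    inc: np.ndarray
    f_cor: np.ndarray    # feedback delivered by the higher-mean option
    f_inc: np.ndarray
    acc: np.ndarray      # 1 if the higher-mean option was chosen
    rt: np.ndarray
    block: np.ndarray
    tib: np.ndarray      # 1-based trial within block
    include: np.ndarray  # retained (non-excluded) trials
    pair: np.ndarray
    easy: np.ndarray     # difficulty class per trial

    @property
    def n_trials(self) -> int:
        return len(self.rt)


def trial_arrays(trials: pd.DataFrame, design: BanditDesign) -> list[SubjectArrays]:
    """Pack a TrialTable into per-subject numeric arrays for the kernels."""
    from .design import pair_statistics
    stats = pair_statistics(design).set_index("pair")
    out = []
    for subject, sub in trials.groupby("subject", sort=True):
        sub = sub.sort_values(["block", "trial"])
        pair = sub["pair"].to_numpy()
        cor_lab = np.array([design.higher_mean_option(p) for p in pair])
        inc_lab = np.array([p[0] if p[1] == c else p[1] for p, c in zip(pair, cor_lab)])
        chosen = sub["chosen_option"].to_numpy()
        f_ch = sub["feedback_chosen"].to_numpy(dtype=np.float64)
        f_un = sub["feedback_unchosen"].to_numpy(dtype=np.float64)
        chose_cor = chosen == cor_lab
        f_cor = np.where(chose_cor, f_ch, f_un)
        f_inc = np.where(chose_cor, f_un, f_ch)
        excluded = (sub["excluded"].to_numpy(dtype=bool)
                    if "excluded" in sub else np.zeros(len(sub), dtype=bool))
        out.append(SubjectArrays(
            subject=subject,
            cor=np.array([design.option_index(c) for c in cor_lab], dtype=np.int64),
            inc=np.array([design.option_index(c) for c in inc_lab], dtype=np.int64),
            f_cor=f_cor, f_inc=f_inc,
            acc=sub["accuracy"].to_numpy(dtype=np.int64),
            rt=sub["rt"].to_numpy(dtype=np.float64),
            block=sub["block"].to_numpy(dtype=np.int64),
            tib=sub.groupby("block").cumcount().to_numpy(dtype=np.int64) + 1,
            include=(~excluded).astype(np.bool_),
            pair=pair,
            easy=(stats.loc[pair, "difficulty_class"] == "easy").to_numpy(),
        ))
    return out


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _q_step(q, cor, inc, f_cor, f_inc, eta_plus, eta_minus):
    pe = f_cor - q[cor]
    q[cor] = q[cor] + (eta_plus if pe >= 0.0 else eta_minus) * pe
    pe = f_inc - q[inc]
    q[inc] = q[inc] + (eta_plus if pe >= 0.0 else eta_minus) * pe


@njit(cache=True)
def _trial_va(qc, qi, tib_t, p, drift_kind, thresh_kind):
    dq = qc - qi
    if drift_kind == 0:
        v = p[2] * dq
    elif drift_kind == 1:
        z = p[2] * dq
        if z >= 0.0:
            v = p[3] * (2.0 / (1.0 + math.exp(-z)) - 1.0)
        else:
            ez = math.exp(z)
            v = p[3] * (2.0 * ez / (1.0 + ez) - 1.0)
    else:
        v = p[2] * tib_t ** p[8] * dq
    if thresh_kind == 0:
        a = p[4]
    elif thresh_kind == 1:
        a = math.exp(p[4] + p[5] * (qc + qi) / 2.0)
    else:
        a = p[4] * tib_t ** (-p[7])
    return v, a


@njit(cache=True)
def _rlddm_loglik_kernel(cor, inc, f_cor, f_inc, acc, rt, block, tib, include,
                         n_options, init_q, p, drift_kind, thresh_kind,
                         init_rule, tol, pointwise):
    """Joint choice/RT log-likelihood of one subject; fills ``pointwise``
    (0 for excluded trials) and returns the sum (-inf if any retained trial
    has rt <= t_er)."""
    q = np.full(n_options, init_q)
    total = 0.0
    for t in range(rt.shape[0]):
        if t > 0 and block[t] != block[t - 1]:
            if init_rule == 0:
                gm = q.mean()
                for j in range(n_options):
                    q[j] = gm
        v, a = _trial_va(q[cor[t]], q[inc[t]], tib[t], p, drift_kind, thresh_kind)
        if include[t]:
            t_dec = rt[t] - p[6]
            if t_dec <= 0.0 or a <= 0.0:
                pointwise[t] = -np.inf
                total = -np.inf
            else:
                ll = _wfpt_logpdf(t_dec, acc[t] == 1, v, a, 0.5, tol)
                pointwise[t] = ll
                total += ll
        else:
            pointwise[t] = 0.0
        _q_step(q, cor[t], inc[t], f_cor[t], f_inc[t], p[0], p[1])
    return total


@njit(cache=True)
def _rl_loglik_kernel(cor, inc, f_cor, f_inc, acc, block, include,
                      n_options, init_q, eta_plus, eta_minus, theta_fix,
                      b, c, sens_kind, init_rule, pointwise):
    """Soft-max choice log-likelihood of one subject (RL family)."""
    q = np.full(n_options, init_q)
    counts = np.zeros(n_options, dtype=np.int64)
    total = 0.0
    for t in range(acc.shape[0]):
        if t > 0 and block[t] != block[t - 1]:
            if init_rule == 0:
                gm = q.mean()
                for j in range(n_options):
                    q[j] = gm
            for j in range(n_options):
                counts[j] = 0
        counts[cor[t]] += 1
        counts[inc[t]] += 1
        if sens_kind == 1:
            n = (counts[cor[t]] + counts[inc[t]]) / 2.0
            theta = (n / b) ** c
        else:
            theta = theta_fix
        z = theta * (q[cor[t]] - q[inc[t]])
        # log p(correct) = -log1p(exp(-z)), stable both ways
        if z >= 0.0:
            log_p_cor = -math.log1p(math.exp(-z))
        else:
            log_p_cor = z - math.log1p(math.exp(z))
        if include[t]:
            ll = log_p_cor if acc[t] == 1 else log_p_cor - z
            pointwise[t] = ll
            total += ll
        else:
            pointwise[t] = 0.0
        _q_step(q, cor[t], inc[t], f_cor[t], f_inc[t], eta_plus, eta_minus)
    return total


@njit(cache=True)
def _simulate_subject_kernel(cor, inc, f_cor, f_inc, block, tib,
                             n_options, init_q, p, drift_kind, thresh_kind,
                             init_rule, dt, max_steps, seed,
                             acc_out, steps_out, cens_out, v_out, a_out):
    """Forward-simulate one subject's choices and decision times given the
    feedback streams; Q is updated with both options' feedback each trial."""
    np.random.seed(seed)
    q = np.full(n_options, init_q)
    for t in range(cor.shape[0]):
        if t > 0 and block[t] != block[t - 1]:
            if init_rule == 0:
                gm = q.mean()
                for j in range(n_options):
                    q[j] = gm
        v, a = _trial_va(q[cor[t]], q[inc[t]], tib[t], p, drift_kind, thresh_kind)
        up, nst, cens = _sim_one(v, a, dt, max_steps, 1.0)
        acc_out[t] = 1 if up else 0
        steps_out[t] = nst
        cens_out[t] = cens
        v_out[t] = v
        a_out[t] = a
        _q_step(q, cor[t], inc[t], f_cor[t], f_inc[t], p[0], p[1])


@njit(cache=True)
def _simulate_subject_rl_kernel(cor, inc, f_cor, f_inc, block,
                                n_options, init_q, eta_plus, eta_minus,
                                theta_fix, b, c, sens_kind, init_rule, seed,
                                acc_out):
    np.random.seed(seed)
    q = np.full(n_options, init_q)
    counts = np.zeros(n_options, dtype=np.int64)
    for t in range(cor.shape[0]):
        if t > 0 and block[t] != block[t - 1]:
            if init_rule == 0:
                gm = q.mean()
                for j in range(n_options):
                    q[j] = gm
            for j in range(n_options):
                counts[j] = 0
        counts[cor[t]] += 1
        counts[inc[t]] += 1
        if sens_kind == 1:
            n = (counts[cor[t]] + counts[inc[t]]) / 2.0
            theta = (n / b) ** c
        else:
            theta = theta_fix
        z = theta * (q[cor[t]] - q[inc[t]])
        p_cor = 1.0 / (1.0 + math.exp(-z)) if z >= 0 else \
            math.exp(z) / (1.0 + math.exp(z))
        acc_out[t] = 1 if np.random.random() < p_cor else 0
        _q_step(q, cor[t], inc[t], f_cor[t], f_inc[t], eta_plus, eta_minus)


@njit(cache=True)
def _simulate_static_kernel(v_arr, a_arr, dt, max_steps, seed,
                            acc_out, steps_out, cens_out):
    np.random.seed(seed)
    for t in range(v_arr.shape[0]):
        up, nst, cens = _sim_one(v_arr[t], a_arr[t], dt, max_steps, 1.0)
        acc_out[t] = 1 if up else 0
        steps_out[t] = nst
        cens_out[t] = cens


# ---------------------------------------------------------------------------
# user-facing operations

_INIT_RULE_CODE = {"grand_mean": 0, "per_option": 1}


def build_trialwise_parameters(trials: pd.DataFrame, spec: ModelSpec,
                               params: RLDDMParameters, design: BanditDesign,
                               init_rule: str = "grand_mean") -> pd.DataFrame:
    """Per-trial drift and threshold implied by the learning trajectory.

    Q values entering trial t are those updated through trial t-1 (feedback
    arrives after the response). Returns one row per trial with columns
    v_t, a_t, q_cor, q_inc and q_bar_pres = (q_cor + q_inc) / 2.
    """
    if spec.model_class not in ("RLDDM", "PedersenRLDDM"):
        raise ValueError(f"{spec.name} has no trialwise diffusion parameters")
    drift_kind, thresh_kind = spec._codes
    p = params._vector(spec)
    frames = []
    for arrs in trial_arrays(trials, design):
        n = arrs.n_trials
        q = np.full(design.n_options, float(design.initial_q))
        v_t = np.empty(n)
        a_t = np.empty(n)
        qc_arr = np.empty(n)
        qi_arr = np.empty(n)
        for t in range(n):
            if t > 0 and arrs.block[t] != arrs.block[t - 1]:
                if init_rule == "grand_mean":
                    q[:] = q.mean()
            qc_arr[t], qi_arr[t] = q[arrs.cor[t]], q[arrs.inc[t]]
            v_t[t], a_t[t] = _trial_va(q[arrs.cor[t]], q[arrs.inc[t]],
                                       arrs.tib[t], p, drift_kind, thresh_kind)
            _q_step(q, arrs.cor[t], arrs.inc[t], arrs.f_cor[t], arrs.f_inc[t],
                    p[0], p[1])
        frames.append(pd.DataFrame({
            "subject": arrs.subject, "block": arrs.block, "trial": arrs.tib,
            "pair": arrs.pair, "v_t": v_t, "a_t": a_t,
            "q_cor": qc_arr, "q_inc": qi_arr,
            "q_bar_pres": (qc_arr + qi_arr) / 2.0,
        }))
    return pd.concat(frames, ignore_index=True)


def rlddm_log_likelihood(trials: pd.DataFrame, spec: ModelSpec,
                         params: RLDDMParameters, design: BanditDesign,
                         init_rule: str = "grand_mean", tol: float = 1e-10) -> float:
    """Summed joint choice/RT log-likelihood over subjects and retained
    trials; returns -inf (not an exception) when t_er >= some retained RT so
    samplers can reject the draw."""
    drift_kind, thresh_kind = spec._codes
    p = params._vector(spec)
    total = 0.0
    for arrs in trial_arrays(trials, design):
        scratch = np.empty(arrs.n_trials)
        ll = _rlddm_loglik_kernel(
            arrs.cor, arrs.inc, arrs.f_cor, arrs.f_inc, arrs.acc, arrs.rt,
            arrs.block, arrs.tib, arrs.include, design.n_options,
            float(design.initial_q), p, drift_kind, thresh_kind,
            _INIT_RULE_CODE[init_rule], tol, scratch)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return float(total)


def simulate_experiment(design: BanditDesign, spec: ModelSpec,
                        params_per_subject, n_subjects: int | None = None,
                        seed: int = 0, dt: float = 0.001, max_time: float = 5.0,
                        init_rule: str = "grand_mean",
                        params_by_condition=None) -> pd.DataFrame:
    """Forward-simulate a full experiment and return a TrialTable.

    Every subject observes the same representative payoff multisets in a
    subject-specific order and a subject-specific pair sequence. Per trial
    the current Q values set (v_t, a_t), a first-passage sample gives choice
    and RT, both options' feedback is recorded, and Q is updated. Simulated
    RTs outside [rt_floor, rt_ceiling] (or censored at ``max_time``) are
    flagged excluded but stay in the table, preserving the feedback stream.

    ``params_per_subject`` is a single :class:`RLDDMParameters` /
    ``learning.RLParameters`` (shared by all ``n_subjects``) or a list, one
    per subject. For DDM specs pass ``params_by_condition`` as
    ``(v_by_condition, a_by_condition, t_er)`` instead.
    """
    if isinstance(params_per_subject, (list, tuple)):
        subject_params = list(params_per_subject)
        if n_subjects is not None and n_subjects != len(subject_params):
            raise ValueError("n_subjects disagrees with the parameter list")
    else:
        subject_params = [params_per_subject] * (n_subjects or 1)
    n_subjects = len(subject_params)

    rng = np.random.default_rng(seed)
    base_payoffs = generate_payoffs(design, seed=int(rng.integers(2 ** 31)))
    max_steps = int(np.ceil(max_time / dt))
    rows = []
    for s in range(n_subjects):
        sub_seed = int(rng.integers(2 ** 31))
        payoffs = base_payoffs.reordered(sub_seed)
        seq = generate_pair_sequence(design, seed=sub_seed + 1)
        cor = []
        inc = []
        f_cor = []
        f_inc = []
        block_arr = []
        tib_arr = []
        pair_list = []
        left_first = []
        pos = {(b, lab): 0 for b in range(design.n_blocks)
               for lab in design.option_labels}
        for b, (pairs_b, sides_b) in enumerate(zip(seq.pairs_by_block, seq.left_is_first)):
            for t, (pair, first_left) in enumerate(zip(pairs_b, sides_b)):
                c_lab = design.higher_mean_option(pair)
                i_lab = pair[0] if pair[1] == c_lab else pair[1]
                cor.append(design.option_index(c_lab))
                inc.append(design.option_index(i_lab))
                f_cor.append(payoffs.payoffs[b][c_lab][pos[(b, c_lab)]])
                f_inc.append(payoffs.payoffs[b][i_lab][pos[(b, i_lab)]])
                pos[(b, c_lab)] += 1
                pos[(b, i_lab)] += 1
                block_arr.append(b + 1)
                tib_arr.append(t + 1)
                pair_list.append(pair)
                left_first.append(first_left)
        cor = np.array(cor, dtype=np.int64)
        inc = np.array(inc, dtype=np.int64)
        f_cor = np.array(f_cor, dtype=np.float64)
        f_inc = np.array(f_inc, dtype=np.float64)
        block_arr = np.array(block_arr, dtype=np.int64)
        tib_arr = np.array(tib_arr, dtype=np.int64)
        n = len(cor)
        acc = np.empty(n, dtype=np.int64)
        pars = subject_params[s]
        sim_seed = int(rng.integers(2 ** 31))
        if spec.model_class == "RL":
            n_eta, sens = learning.RL_VARIANTS[spec.variant]
            _simulate_subject_rl_kernel(
                cor, inc, f_cor, f_inc, block_arr, design.n_options,
                float(design.initial_q), pars.eta_plus, pars.eta_minus,
                pars.theta if pars.theta is not None else 1.0,
                pars.b if pars.b is not None else 1.0,
                pars.c if pars.c is not None else 0.0,
                1 if sens == "power" else 0, _INIT_RULE_CODE[init_rule],
                sim_seed, acc)
            rt = np.full(n, np.nan)
            cens = np.zeros(n, dtype=np.bool_)
            t_er = 0.0
        elif spec.model_class == "DDM":
            if params_by_condition is None:
                raise ValueError("DDM simulation requires params_by_condition")
            v_by, a_by, t_er = params_by_condition
            tmp = pd.DataFrame({"pair": pair_list})
            cmap = ddm_condition_map(tmp, design, spec.variant)
            v_arr = np.array([v_by[c] for c in cmap["drift_condition"]])
            a_arr = np.array([a_by[c] for c in cmap["threshold_condition"]])
            steps = np.empty(n, dtype=np.int64)
            cens = np.empty(n, dtype=np.bool_)
            _simulate_static_kernel(v_arr, a_arr, dt, max_steps, sim_seed,
                                    acc, steps, cens)
            rt = steps * dt + t_er
        else:
            drift_kind, thresh_kind = spec._codes
            p = pars._vector(spec)
            t_er = p[6]
            steps = np.empty(n, dtype=np.int64)
            cens = np.empty(n, dtype=np.bool_)
            v_out = np.empty(n)
            a_out = np.empty(n)
            _simulate_subject_kernel(
                cor, inc, f_cor, f_inc, block_arr, tib_arr, design.n_options,
                float(design.initial_q), p, drift_kind, thresh_kind,
                _INIT_RULE_CODE[init_rule], dt, max_steps, sim_seed,
                acc, steps, cens, v_out, a_out)
            rt = steps * dt + t_er

        labels = design.option_labels
        for t in range(n):
            pair = pair_list[t]
            c_lab, i_lab = labels[cor[t]], labels[inc[t]]
            chosen = c_lab if acc[t] == 1 else i_lab
            f_ch = f_cor[t] if acc[t] == 1 else f_inc[t]
            f_un = f_inc[t] if acc[t] == 1 else f_cor[t]
            left = pair[0] if left_first[t] else pair[1]
            right = pair[1] if left_first[t] else pair[0]
            rt_t = rt[t]
            if np.isnan(rt_t):
                excluded, reason = False, ""
            elif cens[t] or rt_t > design.rt_ceiling:
                excluded, reason = True, "too_slow"
            elif rt_t < design.rt_floor:
                excluded, reason = True, "too_fast"
            else:
                excluded, reason = False, ""
            rows.append((s + 1, block_arr[t], tib_arr[t], pair, left, right,
                         "left" if chosen == left else "right", chosen,
                         int(acc[t]), rt_t, float(f_ch), float(f_un),
                         excluded, reason))
    return pd.DataFrame(rows, columns=[
        "subject", "block", "trial", "pair", "option_left", "option_right",
        "choice_side", "chosen_option", "accuracy", "rt",
        "feedback_chosen", "feedback_unchosen", "excluded", "excluded_reason"])
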