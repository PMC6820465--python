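"""Model / Results API.

The user-facing surface follows the fit-object convention of statistical
modelling packages: a model object is built from a trial table plus a task
design, its ``fit()`` runs the hierarchical Bayesian estimation and returns
a results object carrying draws, diagnostics, ``summary()``, WAIC and
posterior-predictive simulation.

>>> design = BanditDesign()
>>> m = RLDDMModel(trials, design=design, variant=8)
>>> res = m.fit(seed=1)
>>> res.summary()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BanditDesign
from .inference import (CognitiveLikelihood, PosteriorDraws, PriorSpec,
                        SamplerConfig, compare_models, compute_waic,
                        fit_hierarchical)
from .models import ModelSpec, RLDDMParameters, simulate_experiment
from . import io as _io

__all__ = ["BanditModel", "RLModel", "DiffusionModel", "RLDDMModel",
           "PedersenRLDDMModel", "HierarchicalResults"]


class BanditModel:
    """Base class binding a TrialTable, a task design and a model variant."""

    model_class: str = ""

    def __init__(self, data: pd.DataFrame, design: BanditDesign | None = None,
                 variant: int = 1, init_rule: str = "grand_mean",
                 validate: bool = True):
        self.design = design or BanditDesign()
        self.data = _io.validate_trials(data, self.design) if validate else data
        self.spec = ModelSpec(self.model_class, variant)
        self.init_rule = init_rule

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, design: BanditDesign | None = None,
                       **kw) -> "BanditModel":
        return cls(data, design=design, **kw)

    @classmethod
    def from_csv(cls, path, design: BanditDesign | None = None, **kw) -> "BanditModel":
        design = design or BanditDesign()
        return cls(_io.read_trials(path, design), design=design, **kw)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params, subject=None) -> float:
        """Log-likelihood of shared parameters (one :class:`RLDDMParameters`
        or RL parameters applied to every subject, or restricted to one
        ``subject``)."""
        from .models import rlddm_log_likelihood
        from .learning import rl_log_likelihood
        data = self.data if subject is None else \
            self.data[self.data["subject"] == subject]
        if self.spec.model_class in ("RLDDM", "PedersenRLDDM"):
            return rlddm_log_likelihood(data, self.spec, params, self.design,
                                        init_rule=self.init_rule)
        if self.spec.model_class == "RL":
            total = 0.0
            for _, sub in data.groupby("subject"):
                total += rl_log_likelihood(sub.sort_values(["block", "trial"]),
                                           params, self.spec.variant,
                                           self.design, init_rule=self.init_rule)
            return total
        raise NotImplementedError(
            "use wfpt.ddm_log_likelihood for condition-parameterized DDMs")

    # -- estimation ---------------------------------------------------------

    def fit(self, priors: PriorSpec | None = None,
            config: SamplerConfig | None = None, seed: int = 0) -> "HierarchicalResults":
        """Hierarchical Bayesian fit; returns a results object."""
        draws = fit_hierarchical(self.data, self.spec, self.design,
                                 priors=priors, config=config, seed=seed,
                                 init_rule=self.init_rule)
        return HierarchicalResults(self, draws)

    # -- simulation ---------------------------------------------------------

    @classmethod
    def simulate(cls, design: BanditDesign, params, n_subjects: int | None = None,
                 seed: int = 0, variant: int = 1, **kw) -> pd.DataFrame:
        """Forward-simulate a synthetic experiment under this model class."""
        spec = ModelSpec(cls.model_class, variant)
        return simulate_experiment(design, spec, params, n_subjects=n_subjects,
                                   seed=seed, **kw)


class RLModel(BanditModel):
    """Delta-rule learning + soft-max choice (choices only)."""

    model_class = "RL"


class DiffusionModel(BanditModel):
    """Static diffusion decision model with condition-wise parameters."""

    model_class = "DDM"


class RLDDMModel(BanditModel):
    """Combined reinforcement-learning diffusion decision model."""

    model_class = "RLDDM"


class PedersenRLDDMModel(BanditModel):
    """Earlier combined model family with power-law trial modulators
    (reconstruction)."""

    model_class = "PedersenRLDDM"


class HierarchicalResults:
    """Posterior draws plus diagnostics for a fitted bandit model.

    Attributes
    ----------
    model : BanditModel
    draws : PosteriorDraws
    """

    def __init__(self, model: BanditModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # convenient passthroughs
    @property
    def converged(self) -> bool:
        return self.draws.converged

    @property
    def rhat(self) -> pd.Series:
        return pd.Series(self.draws.rhat, index=self.draws.param_names)

    @property
    def param_names(self):
        return self.draws.param_names

    def summary(self) -> pd.DataFrame:
        """Group-level posterior summary (natural scale, 95% BCIs,
        diagnostics)."""
        s = self.draws.summary()
        s.attrs["model"] = self.model.spec.name
        s.attrs["converged"] = self.converged
        return s

    def __str__(self) -> str:
        s = self.summary()
        head = (f"{self.model.spec.name}: {self.draws.n_subjects} subjects, "
                f"{self.draws.n_iterations} iterations, "
                f"{'converged' if self.converged else 'NOT converged'}")
        return head + "\n" + s.to_string(index=False)

    def bci(self, param: str, level: float = 95.0) -> tuple[float, float]:
        d = self.draws.group_mean_draws()[param]
        lo, hi = np.percentile(d, [(100 - level) / 2, 100 - (100 - level) / 2])
        return float(lo), float(hi)

    def subject_estimates(self) -> pd.DataFrame:
        """Posterior-mean subject-level parameters (natural scale)."""
        nat = self.draws.subject_param_draws(thin=10).mean(axis=0)
        return pd.DataFrame(nat, index=self.draws.subject_ids,
                            columns=self.draws.param_names)

    def waic(self):
        """WAIC row for this fit (variance-based penalty)."""
        return compute_waic(self.draws.pointwise, model=self.model.spec.name)

    def compare(self, other: "HierarchicalResults") -> tuple[float, float]:
        """(elpd difference self - other, SE of the difference)."""
        return compare_models(self.draws, other.draws)

    def posterior_predictive(self, n_draws: int = 500, seed: int = 0,
                             **kw):
        """Posterior predictive check against the observed data."""
        from .evaluation import posterior_predictive_check
        return posterior_predictive_check(self, n_draws=n_draws, seed=seed, **kw)

    def plot_ppc(self, ppc=None, ax=None, measure: str = "accuracy"):
        """Plot observed vs. predicted per-pair learning curves."""
        import matplotlib.pyplot as plt

        if ppc is None:
            ppc = self.posterior_predictive()
        table = ppc.table
        if ax is None:
            _, ax = plt.subplots()
        for pair, sub in table.groupby("pair"):
            line, = ax.plot(sub["bin"], sub[f"observed_{measure}"], "o--",
                            label=f"{pair} observed")
            ax.fill_between(sub["bin"], sub[f"predicted_{measure}_lo"],
                            sub[f"predicted_{measure}_hi"], alpha=0.2,
                            color=line.get_color())
        ax.set_xlabel("trial bin")
        ax.set_ylabel(measure)
        ax.legend(fontsize="small")
        return ax
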