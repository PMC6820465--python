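# Methods

## The modelling problem

In reward-guided decision-making, people repeatedly choose between options
whose values they only learn through feedback, and both *what* they choose
and *how long* they take carry information about the underlying process.
This package implements a family of combined reinforcement-learning
diffusion decision models (RLDDMs) for two-alternative bandit tasks with
full feedback, together with the task generator, the competing model
families usually compared against (soft-max RL models, static diffusion
models, and power-law-modulated combined models), hierarchical Bayesian
estimation, WAIC model comparison, posterior predictive checks, behavioral
regressions and parameter recovery.

## Task model

The default `BanditDesign` is a four-option bandit: options A–D pay
approximately normal integer rewards with means 36, 40, 50, 54 points and
SD 5, presented as the four fixed pairs AB, AC, BD, CD. Each of three
80-trial blocks shows every pair 20 times in a pseudo-random order with no
pair more than three times in a row. Accumulated points divide by 1400 to
give a bonus in francs.

*Representative sampling.* Payoffs are drawn per (block, option), rounded
to the unit, and then minimally adjusted so that each option's block sample
mean equals its generating mean exactly: the integer residual between the
target sum and the realized sum is spread as ±1 corrections over the draws
closest to the mean. This is the smallest-perturbation scheme consistent
with integer payoffs and exact means (achievable whenever N × mean is an
integer, as in the default design). Every simulated participant observes
the same payoff multisets in a participant-specific order.

*Pair sequences* are rejection-sampled uniformly from the permutations of
the pair multiset until the run-length constraint holds (bounded retries),
which makes the sampler exactly uniform over valid sequences. Left/right
placement is an independent fair coin per trial.

Two design-level statistics follow: the *magnitude* of a pair is the mean
of its two generating means (38, 43, 47, 52 for the default pairs) and its
*difficulty class* splits the pairs at the midpoint of the observed mean
differences (14 → easy for AC and BD, 4 → difficult for AB and CD). The
chance-accuracy exclusion threshold is the smallest k/n with a one-sided
exact binomial tail below α; for 240 trials at α = .05 this is 134/240 ≈
55.8%, i.e. 56% to the nearest percent.

## Learning model

Subjective values Q update by the delta rule Q ← Q + η (f − Q), applied to
*both* presented options each trial (full feedback), with the learning rate
optionally split by prediction-error sign (η⁺ for f ≥ Q, η⁻ otherwise; ties
use η⁺, a measure-zero event for continuous Q). Q starts at 27.5 — the
average value shown in task instructions — in block 1. Because each block
introduces new stimuli, presentation counts reset at block boundaries and
Q restarts at the *grand mean* of the previous block's final values
(option-specific transfer is impossible with new stimuli); a `per_option`
carry-over rule is available behind `init_rule` for users who prefer the
other reading.

RL-only choice models map values to choice through a soft-max with
sensitivity θ, either a free constant or growing as θ_t = (n/b)^c with n
the option presentation count (inclusive of the current trial, so n ≥ 1
from the first presentation; for a pair, the mean of the two options'
counts, which equals the common count whenever they agree).

## Decision model

Within a trial, evidence x accumulates between absorbing boundaries 0 and
a from the unbiased start a/2 with drift v and unit diffusion coefficient
(the scaling convention); RT = first-passage time + non-decision time t_er.
The first-passage density uses the standard small-time and large-time
series expansions with the term-count rule that picks whichever expansion
needs fewer terms for a truncation error below `tol` (default 1e-10); the
upper-boundary density follows from the lower-boundary expression by drift
reflection. The density was validated against quadrature (integrals match
the closed-form absorption probability 1/(1 + e^{−va}) to 1e-4 and sum to
1) and against large Euler-simulation samples.

The simulator is Euler–Maruyama with a Brownian-bridge crossing check
between grid points, which removes the leading-order boundary-overshoot
bias of the plain scheme (without it, mean first-passage times at
dt = 0.001 are ~3% long). Defaults: dt = 0.001 s, response window 5 s
(censored paths are flagged, mirroring the task's response deadline).

A note on scaling: the correct scale family of this process is
(v, a, s) ≡ (kv, ka, ks) with the time axis *unchanged* (divide the state
by k); the tests assert exactly this identity. All parameters are reported
in the unit-noise scale.

## Model space

* **RL 1–4**: one or two learning rates × fixed or power sensitivity.
* **DDM 1–3**: static diffusion; drift by difficulty class (1, 2) or per
  pair (3), threshold shared (1) or per pair (2, 3); one t_er.
* **RLDDM 1–8**: drift from the value difference, linearly
  (v_t = v_mod (Q_cor − Q_inc)) or through the odd sigmoid
  S(z) = 2 v_max/(1+e^{−z}) − v_max; threshold fixed or value-modulated,
  a_t = exp(a_fix + a_mod Q̄_pres) with Q̄_pres the mean value of the
  presented pair (negative a_mod lowers the threshold for richer pairs —
  the magnitude effect); one or two learning rates.
* **Pedersen-style RLDDM 1–4** (reconstructions; the original functional
  forms live in an external report, so the parameterization here is the
  package's own): threshold decays as a_t = a_base t^{−d_a} and the drift
  scale optionally grows as m_t = m_base t^{+d_m}, with t the 1-based
  within-block trial index.

Drift and threshold for trial t use the Q values *entering* the trial
(feedback arrives after the response). Nesting identities (single-rate ⊂
dual-rate, fixed ⊂ modulated threshold, linear as the large-v_max sigmoid
limit, DDM 2 ⊂ DDM 3) hold bit-exactly in the likelihood code and are
tested.

Simulated trials with RTs outside the 150–3000 ms window stay in the table
with an exclusion flag: they contribute no likelihood but their feedback
still drives learning, preserving the feedback stream.

## Hierarchical estimation

Subject parameters are population-normal on an unconstrained scale
(non-centered: subject value = link⁻¹(μ + σ z), z ~ N(0,1)). Links: logit
for learning rates; log for thresholds, sensitivities, power exponents,
v_max and t_er; identity for v_mod, a_fix, a_mod and drift-scale
parameters. Priors are weakly informative: μ ~ N(0, 2) on the link scale,
σ ~ half-normal(1).

The non-decision time deserves a remark. Its natural hard bound is each
subject's minimum retained RT, and an early design bounded t_er by a
subject-specific scaled logit at 95% of that minimum. That bound is
data-dependent and approximately proportional to the subject's true t_er,
so it absorbs the between-subject variance: the group SD collapses and
group-level credible intervals become several-fold too narrow (recovery
coverage for t_er dropped to ~20%). The released parameterization therefore
uses a plain hierarchical log link and enforces the bound through the
likelihood, which returns −inf whenever t_er ≥ some retained RT so samplers
simply reject such proposals.

Sampling uses the emcee affine-invariant ensemble with
differential-evolution moves (80% DEMove, 20% DESnookerMove); the default
stretch move fails to traverse the hierarchical funnel (R-hat > 1.05 after
8000 iterations where DE moves converge). Walkers start in a Gaussian ball
around per-subject penalized maximum-likelihood estimates. The schedule
starts at 1000 iterations and doubles until every rank-normalized R-hat is
≤ 1.01 or the 16,000-iteration cap is hit, in which case the result is
flagged non-converged (not an exception). The first half of every chain is
always discarded. For R-hat/ESS the exchangeable walker ensemble is
partitioned into four groups, each acting as one chain. The ensemble has no
divergent transitions in the Hamiltonian sense; the reported divergence
fraction counts non-finite retained log-posterior values and is expected to
be 0.

WAIC uses the variance-based penalty: lppd = Σ_i log mean_s p(y_i|θ_s),
p_waic = Σ_i var_s log p(y_i|θ_s), waic = −2(lppd − p_waic), so that
waic = 2(−lppd + p_waic) holds exactly before display rounding. Pairwise
comparison reports the summed per-point elpd difference and its standard
error √(n · var) of per-point differences.

## Evaluation machinery

*Posterior predictive checks* draw joint posterior parameter sets, simulate
full datasets re-using each subject's own pair sequence and feedback
streams (recoverable from the full-feedback table), and summarize mean
accuracy and RT per pair × trial bin (8 bins of 10 within-block trials with
the default design; per-pair bin means pool each pair's trials falling in
each bin across blocks and subjects), with 2.5/97.5% predictive quantiles.

*Regressions* are hierarchical (logistic on accuracy, linear on log RT)
with standardized magnitude, difficulty coded +1 (easy) / −1 (difficult)
and their interaction; trial number is deliberately absent. Standardization
makes results invariant to affine recoding of magnitude. An effect is
flagged when the 95% BCI of a group coefficient excludes 0.

*Parameter recovery* draws subjects normal on the link scale with
delta-method SDs (so the generating natural-scale group location is exactly
the stated mean — generating on the natural scale instead injects a
spurious transformation bias into coverage checks), simulates, refits, and
records group-mean BCI coverage and Spearman correlations between true and
recovered subject parameters (flagged NaN when the generating SD is 0).

## Synthetic-data conditions and problem sizes

The default generating group for the simplest combined model is
η = 0.12 (SD 0.04), v_mod = 0.25 (0.05), a = 2.0 (0.3), t_er = 0.40 s
(0.05) — chosen once to emulate the behavior the paradigm elicits
(asymptotic accuracy in the .8s, mean RTs near a second, a few-fold drift
increase over a block). The test suite runs recovery at 12 subjects × 240
trials × 5 replications with a reduced sampler budget of 1600 iterations
per fit (flagged non-converged by the strict R-hat rule but calibrated
enough for interval coverage), and regression calibration on 20 null
datasets of 6 subjects. These sizes are the package's default desk-scale
study; scale them up through `SamplerConfig` and the study arguments for
production analyses.

What passing these tests shows — and what it does not: the synthetic
generator *is* the fitted model, so recovery and predictive checks validate
the estimation machinery, not the model's adequacy for human data. Real
data bring contaminant RTs, lapses, non-stationary learning rates and
sequential dependencies the generator does not emulate.

## Known limitations and numerical notes

* The likelihood does not renormalize for the 150–3000 ms retention
  window; with ~1% of simulated trials excluded this truncation biases the
  recovered threshold a low by roughly 3%. The original analyses share this
  choice; accounting for it would require dividing by the per-trial
  probability of landing in the window.
* Recovered group intervals at the reduced sampler budget are slightly
  narrow (under-converged ensembles under-disperse); the iteration-doubling
  schedule removes this when allowed to run to convergence.
* Soft-max and density evaluations are overflow-safe; prediction-error
  ties use η⁺; densities below the series floor return −inf rather than
  raising.
* The RL family has no RT model: simulated RL tables carry NaN RTs and
  choice-only summaries.
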