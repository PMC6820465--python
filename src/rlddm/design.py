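"""Multi-armed bandit task design: payoff schedules, pair sequences, design statistics.

The paradigm is a four-option bandit presented in fixed pairs. Within each
learning block every option pair appears a fixed number of times in a
pseudo-random order, and each option's payoffs are drawn from a normal
distribution, rounded to integer points, and constrained so that the sample
mean of every option within every block equals its generating mean exactly
("representative sampling"). Accumulated points convert to a monetary bonus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BanditDesign",
    "PayoffSchedule",
    "PairSequence",
    "InvalidDesignError",
    "SchedulingError",
    "generate_payoffs",
    "generate_pair_sequence",
    "schedule_table",
    "pair_statistics",
    "min_accuracy_threshold",
    "points_to_francs",
    "DEFAULT_PAIRS",
]

DEFAULT_PAIRS = ("AB", "AC", "BD", "CD")


class InvalidDesignError(ValueError):
    """Raised when a BanditDesign violates its structural constraints."""


class SchedulingError(RuntimeError):
    """Raised when no pair sequence satisfying the constraints is found."""


@dataclass(frozen=True)
class BanditDesign:
    """The generating experiment: payoff distributions and block/pair structure.

    Defaults reproduce the reference paradigm: four options A-D with mean
    rewards 36, 40, 50, 54 points (SD 5), three blocks of 80 trials formed by
    presenting each of the pairs AB, AC, BD, CD twenty times per block, with
    no pair repeated more than three times in a row. 1400 points = 1 franc.
    """

    option_means: tuple[float, ...] = (36.0, 40.0, 50.0, 54.0)
    option_sd: float = 5.0
    n_blocks: int = 3
    trials_per_block: int = 80
    pairs: tuple[str, ...] = DEFAULT_PAIRS
    presentations_per_pair_per_block: int = 20
    max_run_length: int = 3
    points_per_franc: float = 1400.0
    rt_floor: float = 0.150
    rt_ceiling: float = 3.000
    initial_q: float = 27.5
    option_labels: tuple[str, ...] = field(default=("A", "B", "C", "D"))

    def __post_init__(self) -> None:
        if len(self.option_means) != len(self.option_labels):
            raise InvalidDesignError("one generating mean per option label required")
        if self.option_sd <= 0:
            raise InvalidDesignError("option_sd must be strictly positive")
        for name in ("n_blocks", "trials_per_block",
                     "presentations_per_pair_per_block", "max_run_length"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise InvalidDesignError(f"{name} must be a positive integer")
        if self.trials_per_block != self.presentations_per_pair_per_block * len(self.pairs):
            raise InvalidDesignError(
                "trials_per_block must equal presentations_per_pair_per_block x n_pairs")
        for pair in self.pairs:
            if len(pair) != 2 or any(o not in self.option_labels for o in pair):
                raise InvalidDesignError(f"pair {pair!r} references unknown option")
        if self.points_per_franc <= 0:
            raise InvalidDesignError("points_per_franc must be positive")
        if not (0 <= self.rt_floor < self.rt_ceiling):
            raise InvalidDesignError("need 0 <= rt_floor < rt_ceiling")

    @property
    def n_options(self) -> int:
        return len(self.option_labels)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def option_index(self, label: str) -> int:
        return self.option_labels.index(label)

    def presentations_per_option_per_block(self, label: str) -> int:
        n_in_pairs = sum(label in p for p in self.pairs)
        return n_in_pairs * self.presentations_per_pair_per_block

    def mean_of(self, label: str) -> float:
        return self.option_means[self.option_index(label)]

    def higher_mean_option(self, pair: str) -> str:
        a, b = pair
        return a if self.mean_of(a) >= self.mean_of(b) else b

    def to_config(self) -> dict[str, str]:
        """Flat key-value serialization (text config)."""
        return {
            "option_labels": ",".join(self.option_labels),
            "option_means": ",".join(str(m) for m in self.option_means),
            "option_sd": str(self.option_sd),
            "n_blocks": str(self.n_blocks),
            "trials_per_block": str(self.trials_per_block),
            "pairs": ",".join(self.pairs),
            "presentations_per_pair_per_block": str(self.presentations_per_pair_per_block),
            "max_run_length": str(self.max_run_length),
            "points_per_franc": str(self.points_per_franc),
            "rt_floor": str(self.rt_floor),
            "rt_ceiling": str(self.rt_ceiling),
            "initial_q": str(self.initial_q),
        }

    @classmethod
    def from_config(cls, cfg: dict[str, str]) -> "BanditDesign":
        kw: dict = {}
        if "option_labels" in cfg:
            kw["option_labels"] = tuple(cfg["option_labels"].split(","))
        if "option_means" in cfg:
            kw["option_means"] = tuple(float(x) for x in cfg["option_means"].split(","))
        if "pairs" in cfg:
            kw["pairs"] = tuple(cfg["pairs"].split(","))
        for k, cast in [("option_sd", float), ("n_blocks", int), ("trials_per_block", int),
                        ("presentations_per_pair_per_block", int), ("max_run_length", int),
                        ("points_per_franc", float), ("rt_floor", float),
                        ("rt_ceiling", float), ("initial_q", float)]:
            if k in cfg:
                kw[k] = cast(cfg[k])
        return cls(**kw)


@dataclass(frozen=True)
class PayoffSchedule:
    """Ordered integer payoffs per (block, option), one entry per presentation.

    ``payoffs[b][label]`` is the ordered list of rewards option ``label``
    delivers in block ``b`` (0-based), consumed one value per presentation.
    """

    design: BanditDesign
    payoffs: tuple  # nested: block -> {label: tuple[int, ...]}

    def block_option(self, block: int, label: str) -> np.ndarray:
        return np.asarray(self.payoffs[block][label])

    def reordered(self, seed: int) -> "PayoffSchedule":
        """Same payoff multisets, a fresh per-(block, option) ordering.

        Used to give each simulated participant the same observations in a
        different order.
        """
        rng = np.random.default_rng(seed)
        out = []
        for block in self.payoffs:
            out.append({lab: tuple(rng.permutation(vals)) for lab, vals in block.items()})
        return PayoffSchedule(self.design, tuple(out))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, block in enumerate(self.payoffs):
            for lab, vals in block.items():
                for i, v in enumerate(vals):
                    rows.append((b + 1, lab, i + 1, int(v)))
        return pd.DataFrame(rows, columns=["block", "option", "presentation", "payoff"])


@dataclass(frozen=True)
class PairSequence:
    """Per-block ordered pair labels plus left/right side assignment."""

    design: BanditDesign
    pairs_by_block: tuple  # block -> tuple[str, ...] length trials_per_block
    left_is_first: tuple  # block -> tuple[bool, ...]; True => pair[0] shown left

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, (seq, sides) in enumerate(zip(self.pairs_by_block, self.left_is_first)):
            for t, (pair, first_left) in enumerate(zip(seq, sides)):
                left, right = (pair[0], pair[1]) if first_left else (pair[1], pair[0])
                rows.append((b + 1, t + 1, pair, left, right))
        return pd.DataFrame(rows, columns=["block", "trial", "pair",
                                           "option_left", "option_right"])


def _representative_sample(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Integer draws from N(mean, sd) whose sample mean equals ``mean`` exactly.

    Draws are rounded to the unit and the integer residual between the target
    sum and the realized sum is distributed as +/-1 corrections applied to the
    draws closest to the mean, cycling if the residual exceeds n. Requires
    n * mean to be an integer (true for the default design: 40 x integer mean).
    """
    target_sum = mean * n
    if abs(target_sum - round(target_sum)) > 1e-9:
        raise InvalidDesignError(
            "n x mean must be an integer for exact representative sampling")
    target_sum = int(round(target_sum))
    draws = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    residual = target_sum - int(draws.sum())
    if residual != 0:
        step = 1 if residual > 0 else -1
        order = np.argsort(np.abs(draws - mean), kind="stable")
        for k in range(abs(residual)):
            draws[order[k % n]] += step
    return draws


def generate_payoffs(design: BanditDesign, seed: int) -> PayoffSchedule:
    """Generate the representative payoff schedule for every block and option.

    For each (block, option), N = presentations-per-option draws from the
    option's normal distribution are rounded to integers and minimally
    adjusted so the block sample mean equals the generating mean exactly;
    the stored order is a seeded permutation of the adjusted multiset.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(design.n_blocks):
        block = {}
        for lab in design.option_labels:
            n = design.presentations_per_option_per_block(lab)
            if n == 0:
                block[lab] = ()
                continue
            vals = _representative_sample(design.mean_of(lab), design.option_sd, n, rng)
            block[lab] = tuple(int(v) for v in rng.permutation(vals))
        blocks.append(block)
    return PayoffSchedule(design, tuple(blocks))


def _longest_run(seq) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def generate_pair_sequence(design: BanditDesign, seed: int,
                           max_retries: int = 10_000) -> PairSequence:
    """Seeded pair order per block with the run-length constraint.

    Rejection-samples uniform permutations of the pair multiset until no pair
    occurs more than ``max_run_length`` times consecutively (uniform over
    valid sequences). Side assignment is an independent fair coin per trial.
    """
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(len(design.pairs)),
                     design.presentations_per_pair_per_block)
    pair_arr = np.asarray(design.pairs)
    seqs, sides = [], []
    for _ in range(design.n_blocks):
        for attempt in range(max_retries):
            perm = rng.permutation(base)
            if _longest_run(perm) <= design.max_run_length:
                break
        else:
            raise SchedulingError(
                f"no sequence with max run length {design.max_run_length} "
                f"found in {max_retries} retries")
        seqs.append(tuple(pair_arr[perm]))
        sides.append(tuple(rng.random(design.trials_per_block) < 0.5))
    return PairSequence(design, tuple(seqs), tuple(sides))


def schedule_table(payoffs: PayoffSchedule, sequence: PairSequence) -> pd.DataFrame:
    """Merge a payoff schedule and a pair sequence into one trial-wise table
    (block, trial, pair, option_left, option_right, payoff_left,
    payoff_right), consuming each option's payoff stream in presentation
    order; exportable as delimited text."""
    design = sequence.design
    pos = {(b, lab): 0 for b in range(design.n_blocks)
           for lab in design.option_labels}
    rows = []
    for b, (seq, sides) in enumerate(zip(sequence.pairs_by_block,
                                         sequence.left_is_first)):
        for t, (pair, first_left) in enumerate(zip(seq, sides)):
            left, right = (pair[0], pair[1]) if first_left else (pair[1], pair[0])
            pl = payoffs.payoffs[b][left][pos[(b, left)]]
            pr = payoffs.payoffs[b][right][pos[(b, right)]]
            pos[(b, left)] += 1
            pos[(b, right)] += 1
            rows.append((b + 1, t + 1, pair, left, right, int(pl), int(pr)))
    return pd.DataFrame(rows, columns=["block", "trial", "pair", "option_left",
                                       "option_right", "payoff_left",
                                       "payoff_right"])


def pair_statistics(design: BanditDesign) -> pd.DataFrame:
    """Magnitude, mean difference and difficulty class for each pair.

    Magnitude is the mean of the two generating means; difficulty splits the
    pairs at the midpoint of the observed mean differences (above = easy).
    """
    rows = []
    for pair in design.pairs:
        a, b = pair
        ma, mb = design.mean_of(a), design.mean_of(b)
        rows.append((pair, (ma + mb) / 2.0, abs(ma - mb)))
    df = pd.DataFrame(rows, columns=["pair", "magnitude", "mean_difference"])
    diffs = df["mean_difference"]
    midpoint = (diffs.min() + diffs.max()) / 2.0
    if diffs.min() == diffs.max():
        df["difficulty_class"] = "difficult"
    else:
        df["difficulty_class"] = np.where(diffs > midpoint, "easy", "difficult")
    return df


def min_accuracy_threshold(n_trials: int, chance: float = 0.5,
                           alpha: float = 0.05) -> tuple[float, bool]:
    """Smallest accuracy not attributable to chance by a one-sided binomial test.

    Returns ``(k*/n_trials, warning)`` where k* is the smallest integer with
    P(X >= k* | n_trials, chance) < alpha. ``warning`` is True when even
    k* = n_trials does not reach significance (threshold returned as 1.0).
    """
    if not (0 < chance < 1) or not (0 < alpha < 1) or n_trials < 1:
        raise ValueError("require 0 < chance < 1, 0 < alpha < 1, n_trials >= 1")
    ks = np.arange(n_trials + 1)
    tails = stats.binom.sf(ks - 1, n_trials, chance)
    hit = np.nonzero(tails < alpha)[0]
    if len(hit) == 0:
        return 1.0, True
    return float(ks[hit[0]]) / n_trials, False


def points_to_francs(points: float, design: BanditDesign | None = None) -> float:
    """Convert accumulated reward points to the monetary bonus in francs."""
    if points < 0:
        raise ValueError("accumulated points cannot be negative")
    divisor = design.points_per_franc if design is not None else 1400.0
    return points / divisor
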