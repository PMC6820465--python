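"""TrialTable schema, validation, filtering and subject exclusion.

The universal interchange object is a tidy per-trial table (one row per
trial) with both options' feedback, stored as delimited text (CSV, UTF-8,
decimal point). RT is in seconds. Block and trial indices are 1-based.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import BanditDesign, min_accuracy_threshold

__all__ = [
    "SCHEMA_COLUMNS",
    "TrialTableError",
    "validate_trials",
    "read_trials",
    "write_trials",
    "filter_trials",
    "exclude_subjects",
]

SCHEMA_COLUMNS = [
    "subject", "block", "trial", "pair", "option_left", "option_right",
    "choice_side", "chosen_option", "accuracy", "rt",
    "feedback_chosen", "feedback_unchosen", "excluded", "excluded_reason",
]

_REQUIRED = [c for c in SCHEMA_COLUMNS if c not in ("excluded", "excluded_reason")]


class TrialTableError(ValueError):
    """Validation failure; ``rows`` lists the offending row labels."""

    def __init__(self, message: str, rows=None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows[:10]}{'...' if len(self.rows) > 10 else ''})"
        super().__init__(message)


def validate_trials(table: pd.DataFrame, design: BanditDesign) -> pd.DataFrame:
    """Validate a TrialTable against the schema and the design.

    Checks required columns, (subject, block, trial) uniqueness, positive
    RTs (NaN allowed for choice-only data), and that the accuracy code is
    consistent with the chosen option and the design's generating means.
    A median RT above 100 triggers a unit-suspicion warning (milliseconds
    in a column declared as seconds). Returns the table with the exclusion
    columns guaranteed present.
    """
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing schema columns: {missing}")
    table = table.copy()
    if "excluded" not in table:
        table["excluded"] = False
    if "excluded_reason" not in table:
        table["excluded_reason"] = ""
    table["excluded"] = table["excluded"].fillna(False).astype(bool)
    table["excluded_reason"] = table["excluded_reason"].fillna("")

    dup = table.duplicated(subset=["subject", "block", "trial"], keep=False)
    if dup.any():
        raise TrialTableError("duplicate (subject, block, trial) keys",
                              rows=table.index[dup])

    rt = table["rt"].to_numpy(dtype=float)
    bad_rt = ~np.isnan(rt) & (rt <= 0)
    if bad_rt.any():
        raise TrialTableError("non-positive RTs", rows=table.index[bad_rt])
    finite = rt[~np.isnan(rt)]
    if finite.size and np.median(finite) > 100:
        warnings.warn("median RT exceeds 100: values look like milliseconds "
                      "but the schema declares seconds", stacklevel=2)

    chosen = table["chosen_option"].astype(str)
    in_pair = [c in p for c, p in zip(chosen, table["pair"].astype(str))]
    if not all(in_pair):
        raise TrialTableError("chosen_option not in the presented pair",
                              rows=table.index[~np.asarray(in_pair)])
    higher = table["pair"].map(design.higher_mean_option)
    expect_acc = (chosen == higher).astype(int)
    bad_acc = table["accuracy"].astype(int) != expect_acc
    if bad_acc.any():
        raise TrialTableError(
            "accuracy inconsistent with chosen_option and generating means",
            rows=table.index[bad_acc])
    return table


def read_trials(path, design: BanditDesign) -> pd.DataFrame:
    """Read and validate a TrialTable from delimited text."""
    table = pd.read_csv(path)
    return validate_trials(table, design)


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a TrialTable as CSV; write -> read is the identity."""
    cols = [c for c in SCHEMA_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def filter_trials(table: pd.DataFrame, design: BanditDesign) -> pd.DataFrame:
    """Flag RTs outside [rt_floor, rt_ceiling] as excluded.

    Too-fast rows are flagged ``too_fast``, too-slow rows ``too_slow``;
    flagged rows stay in the table but are skipped by likelihoods and
    summaries downstream.
    """
    table = table.copy()
    if "excluded" not in table:
        table["excluded"] = False
    if "excluded_reason" not in table:
        table["excluded_reason"] = ""
    rt = table["rt"].to_numpy(dtype=float)
    fast = ~np.isnan(rt) & (rt < design.rt_floor)
    slow = ~np.isnan(rt) & (rt > design.rt_ceiling)
    table.loc[fast, ["excluded", "excluded_reason"]] = [True, "too_fast"]
    table.loc[slow, ["excluded", "excluded_reason"]] = [True, "too_slow"]
    return table


def exclude_subjects(table: pd.DataFrame, design: BanditDesign,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Subjects whose overall accuracy is attributable to chance.

    For each subject the exact one-sided binomial threshold is computed on
    that subject's retained trials; subjects at or below it are listed for
    exclusion. Returns a frame with per-subject accuracy, threshold and
    status ('retained' | 'excluded' | 'indeterminate' for subjects with no
    retained trials).
    """
    rows = []
    for subject, sub in table.groupby("subject", sort=True):
        kept = sub.loc[~sub["excluded"].astype(bool)] if "excluded" in sub else sub
        n = len(kept)
        if n == 0:
            rows.append((subject, np.nan, np.nan, "indeterminate"))
            continue
        acc = kept["accuracy"].mean()
        thr, _ = min_accuracy_threshold(n, 0.5, alpha)
        status = "excluded" if acc <= thr else "retained"
        rows.append((subject, float(acc), float(thr), status))
    return pd.DataFrame(rows, columns=["subject", "accuracy", "threshold", "status"])
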