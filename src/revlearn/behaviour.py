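"""Behavioural measures and the two experiments' preprocessing rules.

Accuracy is the percentage of responses matching the currently-correct option
(regardless of the received outcome), collapsed across the mini-blocks between
reversals.  Win-stay is the percentage of rewarded trials on which the next
response repeats the choice; lose-shift the percentage of punished trials on
which the next response switches.  Stay/shift chains never cross block
boundaries, the last trial of a block has no successor and is excluded, and a
missing response breaks the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "accuracy",
    "win_stay",
    "lose_shift",
    "summarize",
    "PreprocessResult",
    "preprocess_exp1",
    "preprocess_exp2",
    "trait_association",
    "min_n_correlation",
]


def _block_groups(data: pd.DataFrame):
    if "block" in data.columns:
        for _, grp in data.groupby("block", sort=True):
            yield grp.sort_values("trial") if "trial" in grp.columns else grp
    else:
        yield data.sort_values("trial") if "trial" in data.columns else data


def accuracy(data: pd.DataFrame, schedule) -> float:
    """Percent of non-missing choices equal to the schedule's correct option.

    ``data`` holds one subject x condition (columns choice, trial 1-based);
    undefined (nan) when every response is missing.
    """
    d = data.sort_values("trial") if "trial" in data.columns else data
    choices = d["choice"].to_numpy(dtype=int)
    if len(choices) != schedule.n_trials:
        raise ValueError(
            f"data has {len(choices)} trials but the schedule has {schedule.n_trials}"
        )
    observed = choices != 0
    if not observed.any():
        return float("nan")
    correct = choices[observed] == schedule.correct_option[observed]
    return 100.0 * correct.mean()


def _stay_shift(data: pd.DataFrame, outcome_value: int, want_stay: bool) -> float:
    hits = 0
    eligible = 0
    for grp in _block_groups(data):
        ch = grp["choice"].to_numpy(dtype=int)
        oc = grp["outcome"].to_numpy(dtype=int)
        for t in range(len(ch) - 1):
            if ch[t] == 0 or ch[t + 1] == 0 or oc[t] != outcome_value:
                continue
            eligible += 1
            stayed = ch[t + 1] == ch[t]
            if stayed == want_stay:
                hits += 1
    if eligible == 0:
        return float("nan")
    return 100.0 * hits / eligible


def win_stay(data: pd.DataFrame) -> float:
    """Percent of rewarded, non-terminal trials followed by the same choice."""
    return _stay_shift(data, outcome_value=1, want_stay=True)


def lose_shift(data: pd.DataFrame) -> float:
    """Percent of punished, non-terminal trials followed by the other choice."""
    return _stay_shift(data, outcome_value=-1, want_stay=False)


def summarize(trials: pd.DataFrame, schedules: dict) -> pd.DataFrame:
    """Per subject x condition behavioural summary plus per-subject overall
    accuracy.

    ``schedules`` maps condition label to its TrialSchedule.  Returns columns
    subjID, condition, accuracy, win_stay, lose_shift (and mean_rt when an
    rt_ms column is present), plus an ``overall_accuracy`` column repeated per
    subject.
    """
    rows = []
    for (sid, cond), grp in trials.groupby(["subjID", "condition"], sort=False):
        row = {
            "subjID": sid,
            "condition": cond,
            "accuracy": accuracy(grp, schedules[cond]),
            "win_stay": win_stay(grp),
            "lose_shift": lose_shift(grp),
        }
        if "rt_ms" in grp.columns:
            row["mean_rt"] = grp["rt_ms"].mean()
        rows.append(row)
    out = pd.DataFrame(rows)
    overall = out.groupby("subjID")["accuracy"].mean().rename("overall_accuracy")
    return out.merge(overall, on="subjID")


@dataclass
class PreprocessResult:
    kept: list
    excluded: pd.DataFrame  # one row per (subjID, reason)
    details: dict

    @property
    def excluded_subjects(self) -> list:
        return sorted(self.excluded["subjID"].unique())


def preprocess_exp1(
    summaries: pd.DataFrame,
    rt_cutoff_ms: float = 4000.0,
    accuracy_sd_factor: float = 2.5,
) -> PreprocessResult:
    """Experiment-1 exclusion rules on per-subject summaries.

    Excludes mean RT above 4,000 ms, and overall accuracy below
    ``mean - 2.5 x SD`` of the sample's overall accuracies (threshold computed
    on the full sample, reported both unrounded and to the nearest integer
    percent; exclusions use the unrounded value).
    """
    if "mean_rt" not in summaries.columns:
        raise ValueError("summaries need a mean_rt column for the RT cut-off")
    per_subj = (
        summaries.groupby("subjID", sort=False)
        .agg(overall_accuracy=("overall_accuracy", "first"), mean_rt=("mean_rt", "mean"))
        .reset_index()
    )
    acc = per_subj["overall_accuracy"].to_numpy(dtype=float)
    if len(acc) < 2:
        raise ValueError("accuracy threshold needs at least 2 subjects (SD undefined)")
    mean, sd = acc.mean(), acc.std(ddof=1)
    threshold = mean - accuracy_sd_factor * sd
    rows = []
    for _, row in per_subj.iterrows():
        if row.get("mean_rt", 0.0) > rt_cutoff_ms:
            rows.append({"subjID": row["subjID"], "reason": "rt_cutoff"})
        if row["overall_accuracy"] < threshold:
            rows.append({"subjID": row["subjID"], "reason": "accuracy_cutoff"})
    excluded = pd.DataFrame(rows, columns=["subjID", "reason"])
    kept = [s for s in per_subj["subjID"] if s not in set(excluded["subjID"])]
    return PreprocessResult(
        kept=kept,
        excluded=excluded,
        details={
            "accuracy_mean": mean,
            "accuracy_sd": sd,
            "accuracy_threshold": threshold,
            "accuracy_threshold_rounded": int(round(threshold)),
            "rt_cutoff_ms": rt_cutoff_ms,
        },
    )


_EXP2_CRITERIA = ("too_slow", "too_fast", "colour_bias", "side_bias")


def preprocess_exp2(
    trials: pd.DataFrame,
    criteria: tuple = _EXP2_CRITERIA,
    slow_ms: float = 10_000.0,
    fast_ms: float = 150.0,
    slow_fast_frac: float = 0.05,
    choice_frac: float = 0.10,
) -> PreprocessResult:
    """Experiment-2 preregistered trial-level exclusion rules.

    Per subject over all trials: (i) responses slower than 10 s on more than
    5% of trials; (ii) faster than 150 ms on more than 5%; (iii) either colour
    chosen on less than 10% of trials; (iv) either screen side chosen on less
    than 10%.  All inequalities are strict: a subject exactly at a boundary
    (e.g. 27 slow trials of 540, or 54 choices of one colour) is retained.
    Every failed criterion is reported.
    """
    unknown = set(criteria) - set(_EXP2_CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria {sorted(unknown)}")
    if "side_bias" in criteria and "side" not in trials.columns:
        raise ValueError(
            "criterion 'side_bias' requested but trials carry no 'side' column"
        )
    if ("too_slow" in criteria or "too_fast" in criteria) and "rt_ms" not in trials.columns:
        raise ValueError("RT criteria requested but trials carry no 'rt_ms' column")
    rows = []
    kept = []
    for sid, grp in trials.groupby("subjID", sort=False):
        n = len(grp)
        failed = []
        if "too_slow" in criteria and (grp["rt_ms"] > slow_ms).sum() > slow_fast_frac * n:
            failed.append("too_slow")
        if "too_fast" in criteria and (grp["rt_ms"] < fast_ms).sum() > slow_fast_frac * n:
            failed.append("too_fast")
        if "colour_bias" in criteria:
            observed = grp["choice"].to_numpy(dtype=int)
            for opt in (1, 2):
                if (observed == opt).sum() < choice_frac * n:
                    failed.append("colour_bias")
                    break
        if "side_bias" in criteria:
            values, counts = np.unique(grp["side"].to_numpy(), return_counts=True)
            if len(values) < 2 or counts.min() < choice_frac * n:
                failed.append("side_bias")
        if failed:
            rows.extend({"subjID": sid, "reason": r} for r in failed)
        else:
            kept.append(sid)
    excluded = pd.DataFrame(rows, columns=["subjID", "reason"])
    return PreprocessResult(kept=kept, excluded=excluded, details={"n_trials_seen": len(trials)})


def trait_association(x, y):
    """Pearson correlation with a Fisher-z two-sided p value.

    Missing pairs are deleted listwise; needs at least 4 complete pairs and
    non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    p = 2.0 * norm.sf(abs(z))
    return r, float(p)


def _correlation_power(r: float, n: int, alpha: float, alternative: str) -> float:
    """Achieved power of the Fisher-z test of a correlation against zero,
    with the small-sample bias correction zr = atanh(r) + r / (2(n-1))."""
    if n < 4:
        return 0.0
    sides = 2.0 if alternative == "two-sided" else 1.0
    crit = norm.isf(alpha / sides)
    zr = np.arctanh(r) + r / (2.0 * (n - 1))
    return float(norm.cdf(abs(zr) * np.sqrt(n - 3) - crit))


def min_n_correlation(
    r: float,
    alpha: float = 0.05,
    power: float = 0.8,
    alternative: str = "two-sided",
    n_max: int = 1_000_000,
) -> int:
    """Smallest sample size whose Fisher-z correlation test reaches the target
    power for expected correlation ``r``."""
    if not 0.0 < abs(r) < 1.0:
        raise ValueError("expected correlation must satisfy 0 < |r| < 1")
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError("alternative must be 'two-sided' or 'one-sided'")
    for n in range(4, n_max + 1):
        if _correlation_power(r, n, alpha, alternative) >= power:
            return n
    raise ValueError("no sample size below n_max reaches the requested power")
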