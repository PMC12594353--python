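"""Probabilistic reversal-learning environment with orthogonal volatility and noise.

The environment is a two-option bandit in which one option is "correct" at any
moment and the identity of the correct option reverses at unsignalled points.
Volatility controls how often reversals occur (segment lengths of 30-40 trials
for low volatility, 15-20 for high, over 135-trial blocks, giving exactly 3 vs 7
reversals); noise controls the reward contingency of the correct option (75:25
for low noise, 65:35 for high).  Outcomes of the two options are perfectly
anti-correlated: on every trial exactly one option hides the reward.

Contingencies are constructed, not sampled i.i.d.: within each inter-reversal
segment exactly ``round(reward_prob * length)`` trials (round-half-to-even)
assign the reward to the correct option, at uniformly shuffled positions.  This
mirrors a fixed trial sequence shared by all participants.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "BLOCK_ORDERS_EXP1",
    "BLOCK_ORDERS_EXP2",
    "TaskConfig",
    "TrialSchedule",
    "ScheduleConfigError",
    "generate_schedule",
    "assign_rewards",
    "outcome_for_choice",
    "build_session",
    "schedule_to_frame",
    "session_to_frame",
    "frame_to_schedules",
]

CONDITIONS = ("LVLN", "LVHN", "HVLN", "HVHN")

#: Experiment-1 counterbalancing: volatility level fixed for two blocks in a
#: row, noise level alternating block-to-block; half of participants see the
#: low-volatility pair first.
BLOCK_ORDERS_EXP1 = (
    ("LVLN", "LVHN", "HVLN", "HVHN"),
    ("LVHN", "LVLN", "HVHN", "HVLN"),
    ("HVLN", "HVHN", "LVLN", "LVHN"),
    ("HVHN", "HVLN", "LVHN", "LVLN"),
)

#: Experiment-2 adds the opposite scheme: noise fixed for two blocks in a row,
#: volatility alternating, for eight admissible orders in total.
BLOCK_ORDERS_EXP2 = BLOCK_ORDERS_EXP1 + (
    ("LVLN", "HVLN", "LVHN", "HVHN"),
    ("HVLN", "LVLN", "HVHN", "LVHN"),
    ("LVHN", "HVHN", "LVLN", "HVLN"),
    ("HVHN", "LVHN", "HVLN", "LVLN"),
)

_VOLATILITY_SEGMENTS = {"low": (4, (30, 40)), "high": (8, (15, 20))}
_NOISE_PROB = {"low": 0.75, "high": 0.65}


class ScheduleConfigError(ValueError):
    """Raised when a (segment range, segment count, trial count) triple is infeasible."""


@dataclass(frozen=True)
class TaskConfig:
    """Design of one 135-trial block.

    ``n_segments``, ``segment_length_range`` and ``reward_prob`` are derived
    from the volatility / noise levels when not given explicitly.
    """

    volatility: str = "low"
    noise: str = "low"
    n_trials: int = 135
    n_segments: int | None = None
    segment_length_range: tuple[int, int] | None = None
    reward_prob: float | None = None
    first_correct: int | None = None  # fix initial correct option; None = random
    seed: int | None = None

    def __post_init__(self):
        if self.volatility not in _VOLATILITY_SEGMENTS:
            raise ValueError(f"unknown volatility level {self.volatility!r}")
        if self.noise not in _NOISE_PROB:
            raise ValueError(f"unknown noise level {self.noise!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        n_seg, rng_ = _VOLATILITY_SEGMENTS[self.volatility]
        if self.n_segments is None:
            object.__setattr__(self, "n_segments", n_seg)
        if self.segment_length_range is None:
            object.__setattr__(self, "segment_length_range", rng_)
        if self.reward_prob is None:
            object.__setattr__(self, "reward_prob", _NOISE_PROB[self.noise])
        if not 0.5 < self.reward_prob <= 1.0:
            raise ValueError("reward_prob must lie in (0.5, 1.0]")
        lo, hi = self.segment_length_range
        if lo > hi or lo < 1:
            raise ScheduleConfigError(f"bad segment length range [{lo}, {hi}]")
        if not self.n_segments * lo <= self.n_trials <= self.n_segments * hi:
            raise ScheduleConfigError(
                f"{self.n_segments} segments of length {lo}-{hi} cannot sum to "
                f"{self.n_trials} trials"
            )
        if self.first_correct not in (None, 1, 2):
            raise ValueError("first_correct must be 1, 2 or None")

    @property
    def condition(self) -> str:
        return f"{'L' if self.volatility == 'low' else 'H'}V" \
               f"{'L' if self.noise == 'low' else 'H'}N"

    @classmethod
    def from_condition(cls, condition: str, **kwargs) -> "TaskConfig":
        cond = condition.upper()
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition label {condition!r}")
        return cls(
            volatility="low" if cond[0] == "L" else "high",
            noise="low" if cond[2] == "L" else "high",
            **kwargs,
        )


@dataclass
class TrialSchedule:
    """Realized environment for one block.

    ``correct_option`` gives the currently-correct option (1 or 2) per trial;
    ``reward_assigned_to_correct`` flags the trials on which the reward sits
    under the correct option.  Both options' outcomes on every trial follow
    deterministically from these two arrays.
    """

    correct_option: np.ndarray
    reward_assigned_to_correct: np.ndarray
    reversal_trials: np.ndarray  # 0-based trial indices where correct_option flips
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.correct_option)

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_trials)

    @property
    def segment_lengths(self) -> np.ndarray:
        bounds = np.concatenate([[0], self.reversal_trials, [self.n_trials]])
        return np.diff(bounds)

    def outcome_for(self, trial: int, choice: int) -> int:
        return outcome_for_choice(self, trial, choice)


@lru_cache(maxsize=32)
def _composition_counts(n_parts: int, total: int, lo: int, hi: int) -> tuple:
    """count[i][s] = number of ways i segments with lengths in [lo, hi] sum to s."""
    count = [[0] * (total + 1) for _ in range(n_parts + 1)]
    count[0][0] = 1
    for i in range(1, n_parts + 1):
        for s in range(total + 1):
            count[i][s] = sum(
                count[i - 1][s - l] for l in range(lo, min(hi, s) + 1)
            )
    return tuple(tuple(row) for row in count)


def _sample_segment_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact uniform draw over integer compositions of n_trials into n_segments
    parts constrained to segment_length_range, via sequential DP sampling."""
    lo, hi = config.segment_length_range
    count = _composition_counts(config.n_segments, config.n_trials, lo, hi)
    lengths = []
    remaining = config.n_trials
    for i in range(config.n_segments, 0, -1):
        weights = np.array(
            [count[i - 1][remaining - l] if remaining - l >= 0 else 0
             for l in range(lo, hi + 1)],
            dtype=float,
        )
        total = weights.sum()
        if total == 0:  # unreachable for feasible configs
            raise ScheduleConfigError("no admissible segment composition")
        l = lo + rng.choice(len(weights), p=weights / total)
        lengths.append(l)
        remaining -= l
    return np.asarray(lengths, dtype=int)


def generate_schedule(config: TaskConfig, rng: np.random.Generator | int | None = None) -> TrialSchedule:
    """Generate one block: segment composition, correct-option sequence and
    per-segment reward assignment.

    The number of reversals is exactly ``config.n_segments - 1``; within each
    segment exactly ``round(reward_prob * length)`` trials (half-to-even)
    assign the reward to the correct option.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lengths = _sample_segment_lengths(config, rng)
    first = config.first_correct
    if first is None:
        first = int(rng.integers(1, 3))
    correct = np.empty(config.n_trials, dtype=np.int8)
    pos = 0
    option = first
    reversals = []
    for k, length in enumerate(lengths):
        correct[pos: pos + length] = option
        pos += length
        if k < len(lengths) - 1:
            reversals.append(pos)
            option = 3 - option
    schedule = TrialSchedule(
        correct_option=correct,
        reward_assigned_to_correct=np.zeros(config.n_trials, dtype=np.int8),
        reversal_trials=np.asarray(reversals, dtype=int),
        config=config,
    )
    return assign_rewards(schedule, rng)


def assign_rewards(schedule: TrialSchedule, rng: np.random.Generator | int | None = None) -> TrialSchedule:
    """(Re)assign rewards segment-wise: a counted number of rewarded-correct
    trials per segment at uniformly shuffled positions."""
    rng = np.random.default_rng(rng)
    p = schedule.config.reward_prob
    flags = np.zeros(schedule.n_trials, dtype=np.int8)
    pos = 0
    for length in schedule.segment_lengths:
        n_rewarded = round(p * int(length))  # round-half-to-even
        idx = rng.permutation(int(length))[:n_rewarded]
        flags[pos + idx] = 1
        pos += int(length)
    return replace(schedule, reward_assigned_to_correct=flags)


def outcome_for_choice(schedule: TrialSchedule, trial: int, choice: int) -> int:
    """Outcome (+1 coin / -1 cross) of choosing ``choice`` on ``trial``.

    The two options' outcomes are anti-correlated: the outcome of one option is
    always the negation of the other's.
    """
    if not 0 <= trial < schedule.n_trials:
        raise IndexError(f"trial {trial} outside schedule of {schedule.n_trials} trials")
    if choice not in (1, 2):
        raise ValueError(f"choice must be 1 or 2, got {choice!r}")
    on_correct = choice == schedule.correct_option[trial]
    rewarded = bool(schedule.reward_assigned_to_correct[trial])
    return 1 if on_correct == rewarded else -1


def build_session(
    block_order: tuple[str, ...] | list[str],
    shared_seed: int = 0,
    order_set: tuple = BLOCK_ORDERS_EXP2,
) -> list[TrialSchedule]:
    """Build the four blocks of one session in presentation order.

    Schedules are a function of (condition, shared_seed) only, so every subject
    given the same ``shared_seed`` faces identical trial sequences regardless of
    block order (a same-sequence-for-all-participants protocol).
    """
    block_order = tuple(str(c).upper() for c in block_order)
    for cond in block_order:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition label {cond!r}")
    if block_order not in order_set:
        raise ValueError(f"{block_order} is not one of the admissible block orders")
    schedules = []
    for cond in block_order:
        # child seed depends on the condition, never on its position in the order
        ss = np.random.SeedSequence((int(shared_seed), CONDITIONS.index(cond)))
        rng = np.random.default_rng(ss)
        schedules.append(generate_schedule(TaskConfig.from_condition(cond), rng))
    return schedules


# ---------------------------------------------------------------------------
# serialization

def schedule_to_frame(schedule: TrialSchedule, block: int = 1) -> pd.DataFrame:
    """Flat representation; trials are 1-based in files."""
    n = schedule.n_trials
    reversal = np.zeros(n, dtype=np.int8)
    reversal[schedule.reversal_trials] = 1
    return pd.DataFrame(
        {
            "block": np.full(n, block, dtype=int),
            "condition": schedule.config.condition,
            "trial": np.arange(1, n + 1),
            "correct_option": schedule.correct_option.astype(int),
            "reward_assigned_to_correct": schedule.reward_assigned_to_correct.astype(int),
            "reversal": reversal.astype(int),
        }
    )


def session_to_frame(schedules: list[TrialSchedule]) -> pd.DataFrame:
    return pd.concat(
        [schedule_to_frame(s, block=i + 1) for i, s in enumerate(schedules)],
        ignore_index=True,
    )


def frame_to_schedules(frame: pd.DataFrame) -> dict[str, TrialSchedule]:
    """Rebuild schedules (keyed by condition) from the flat CSV representation."""
    out: dict[str, TrialSchedule] = {}
    for cond, grp in frame.groupby("condition", sort=False):
        grp = grp.sort_values("trial")
        correct = grp["correct_option"].to_numpy(dtype=np.int8)
        flags = grp["reward_assigned_to_correct"].to_numpy(dtype=np.int8)
        reversals = np.flatnonzero(grp["reversal"].to_numpy(dtype=np.int8))
        cfg = TaskConfig.from_condition(
            str(cond),
            n_trials=len(grp),
            n_segments=len(reversals) + 1,
            segment_length_range=(1, len(grp)),  # realized lengths, unconstrained
            first_correct=int(correct[0]),
        )
        out[str(cond)] = TrialSchedule(correct, flags, reversals, cfg)
    return out


def serialize_schedule(schedule: TrialSchedule, block: int = 1) -> bytes:
    """Canonical CSV bytes; identical (config, seed) pairs serialize identically."""
    buf = _io.StringIO()
    schedule_to_frame(schedule, block=block).to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode()
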