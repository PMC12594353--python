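import numpy as np
import pandas as pd
import pytest

from revlearn.behaviour import (
    accuracy,
    lose_shift,
    min_n_correlation,
    preprocess_exp1,
    preprocess_exp2,
    summarize,
    trait_association,
    win_stay,
)
from revlearn.models import simulate_agent
from revlearn.task import TaskConfig, generate_schedule


def _frame(choices, outcomes, block=None):
    d = pd.DataFrame(
        {"choice": choices, "outcome": outcomes, "trial": np.arange(1, len(choices) + 1)}
    )
    if block is not None:
        d["block"] = block
    return d


class TestAccuracy:
    def test_perfect_and_alternating(self, hvln_schedule):
        perfect = _frame(hvln_schedule.correct_option.tolist(),
                         [1] * hvln_schedule.n_trials)
        assert accuracy(perfect, hvln_schedule) == 100.0

        cfg = TaskConfig(volatility="low", n_trials=10, n_segments=1,
                         segment_length_range=(10, 10), first_correct=1)
        sched = generate_schedule(cfg, np.random.default_rng(0))
        alternating = _frame([1, 2] * 5, [1] * 10)
        assert accuracy(alternating, sched) == 50.0

    def test_missing_trials_drop_from_both_sides(self, hvln_schedule):
        choices = hvln_schedule.correct_option.astype(int).copy()
        choices[::2] = 0  # half missing, the rest all correct
        d = _frame(choices.tolist(), [1] * len(choices))
        assert accuracy(d, hvln_schedule) == 100.0

    def test_all_missing_is_undefined(self, hvln_schedule):
        d = _frame([0] * hvln_schedule.n_trials, [0] * hvln_schedule.n_trials)
        assert np.isnan(accuracy(d, hvln_schedule))

    def test_misaligned_lengths_raise(self, hvln_schedule):
        with pytest.raises(ValueError):
            accuracy(_frame([1, 2], [1, -1]), hvln_schedule)

    def test_random_agent_is_at_chance(self):
        cfg = TaskConfig(volatility="low", n_trials=10_000, n_segments=1,
                         segment_length_range=(10_000, 10_000))
        sched = generate_schedule(cfg, np.random.default_rng(5))
        sim = simulate_agent("RW", {"eta": 0.3, "beta": 0.0}, sched,
                             np.random.default_rng(6))
        assert accuracy(sim, sched) == pytest.approx(50.0, abs=2.0)


class TestStaySwitch:
    def test_hand_enumeration(self):
        # wins at t1 (stay at t2 -> hit) and t4 (terminal, excluded);
        # losses at t2 (shift) and t3 (stay)
        d = _frame([1, 1, 2, 2], [1, -1, -1, 1])
        assert win_stay(d) == 100.0
        assert lose_shift(d) == 50.0

    def test_no_eligible_trials_is_missing(self):
        assert np.isnan(win_stay(_frame([1, 2], [-1, -1])))
        assert np.isnan(lose_shift(_frame([1, 2], [1, 1])))

    def test_pure_strategies(self):
        repeat = _frame([1] * 10, [1, -1] * 5)
        assert win_stay(repeat) == 100.0
        assert lose_shift(repeat) == 0.0
        alternate = _frame([1, 2] * 5, [-1] * 10)
        assert lose_shift(alternate) == 100.0

    def test_block_boundaries_break_chains(self):
        # a win on the last trial of block 1 must not pair with block 2
        d = _frame([1, 1, 1, 1], [1, 1, 1, 1], block=[1, 1, 2, 2])
        assert win_stay(d) == 100.0  # 2 eligible wins, not 3

    def test_missing_next_response_breaks_chain(self):
        d = _frame([1, 0, 1], [1, 0, 1])
        assert np.isnan(win_stay(d))  # the only win precedes a missing response

    def test_convergence_to_generating_probabilities(self):
        """An agent built with stay-after-win probability w and shift-after-loss
        probability l measures ~100w / ~100l at large n."""
        rng = np.random.default_rng(12)
        w, l, t = 0.7, 0.4, 10_000
        choices = np.empty(t, dtype=int)
        outcomes = rng.choice([-1, 1], t)
        choices[0] = 1
        for i in range(1, t):
            if outcomes[i - 1] == 1:
                stay = rng.random() < w
            else:
                stay = not (rng.random() < l)
            choices[i] = choices[i - 1] if stay else 3 - choices[i - 1]
        d = _frame(choices, outcomes)
        assert win_stay(d) == pytest.approx(100 * w, abs=2.0)
        assert lose_shift(d) == pytest.approx(100 * l, abs=2.0)


class TestPreprocessExp1:
    def _summaries(self, accuracies, rts):
        return pd.DataFrame(
            {
                "subjID": [f"s{i}" for i in range(len(accuracies))],
                "overall_accuracy": accuracies,
                "mean_rt": rts,
            }
        )

    def test_threshold_worked_example(self):
        # sample mean 62.24, SD 8.43 -> threshold 41.165, reported as 41%
        d = 8.43 / np.sqrt(2)
        s = self._summaries([62.24 - d, 62.24 + d], [800, 900])
        result = preprocess_exp1(s)
        assert result.details["accuracy_threshold"] == pytest.approx(41.165, abs=0.01)
        assert result.details["accuracy_threshold_rounded"] == 41
        assert not len(result.excluded)

    def test_rt_cutoff(self):
        s = self._summaries([60, 62, 64], [800, 4500, 900])
        result = preprocess_exp1(s)
        assert list(result.excluded["reason"]) == ["rt_cutoff"]
        assert result.excluded["subjID"].iloc[0] == "s1"
        assert "s1" not in result.kept

    def test_accuracy_cutoff_uses_unrounded_threshold(self):
        s = self._summaries([70, 70, 70, 70, 70, 70, 70, 70, 70, 30], [800] * 10)
        result = preprocess_exp1(s)
        assert set(result.excluded["reason"]) == {"accuracy_cutoff"}
        assert result.excluded["subjID"].iloc[0] == "s9"

    def test_identical_accuracies_exclude_nobody(self):
        s = self._summaries([60.0, 60.0, 60.0], [800, 900, 1000])
        result = preprocess_exp1(s)
        assert not len(result.excluded)
        assert result.details["accuracy_threshold"] == pytest.approx(60.0)

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        s = self._summaries(rng.uniform(40, 90, 30), rng.uniform(500, 5000, 30))
        result = preprocess_exp1(s)
        assert sorted(result.kept + result.excluded_subjects) == sorted(s["subjID"])

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            preprocess_exp1(self._summaries([60.0], [800]))


class TestPreprocessExp2:
    def _trials(self, slow=0, fast=0, n_blue=270, n=540, sides=None):
        rt = np.full(n, 700.0)
        rt[:slow] = 11_000.0
        rt[slow: slow + fast] = 100.0
        choice = np.concatenate([np.ones(n_blue, int), np.full(n - n_blue, 2, int)])
        d = pd.DataFrame({"subjID": "s0", "choice": choice, "outcome": 1, "rt_ms": rt})
        if sides is not None:
            d["side"] = sides
        return d

    def test_boundary_is_retained_strictly(self):
        # exactly 27 slow trials of 540 (5%) is retained; 28 is excluded
        at_boundary = self._trials(slow=27)
        over = self._trials(slow=28)
        criteria = ("too_slow", "too_fast", "colour_bias")
        assert preprocess_exp2(at_boundary, criteria=criteria).kept == ["s0"]
        res = preprocess_exp2(over, criteria=criteria)
        assert list(res.excluded["reason"]) == ["too_slow"]

    def test_colour_bias_boundary(self):
        criteria = ("colour_bias",)
        assert preprocess_exp2(self._trials(n_blue=54), criteria=criteria).kept == ["s0"]
        res = preprocess_exp2(self._trials(n_blue=53), criteria=criteria)
        assert list(res.excluded["reason"]) == ["colour_bias"]

    def test_all_failed_criteria_reported(self):
        bad = self._trials(slow=30, fast=30, n_blue=10)
        res = preprocess_exp2(bad, criteria=("too_slow", "too_fast", "colour_bias"))
        assert sorted(res.excluded["reason"]) == ["colour_bias", "too_fast", "too_slow"]

    def test_side_criterion_requires_side_column(self):
        with pytest.raises(ValueError, match="side"):
            preprocess_exp2(self._trials())
        sides = np.array(["L"] * 520 + ["R"] * 20)
        res = preprocess_exp2(self._trials(sides=sides))
        assert list(res.excluded["reason"]) == ["side_bias"]


class TestTraitAssociation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = trait_association(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_independent_draws_are_uncorrelated(self):
        rng = np.random.default_rng(8)
        r, _ = trait_association(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert abs(r) < 0.05

    def test_listwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [1.1, 1.9, 3.0, 4.2, np.nan, 6.3]
        r, _ = trait_association(x, y)  # four complete pairs survive deletion
        assert r > 0.99
        with pytest.raises(ValueError):
            # deletion leaves only three pairs
            trait_association([1.0, 2.0, np.nan, 4.0, 5.0],
                              [1.1, 1.9, 3.0, 4.2, np.nan])

    def test_small_or_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            trait_association([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            trait_association([1, 1, 1, 1], [1, 2, 3, 4])


class TestPowerAnalysis:
    def test_fisher_z_worked_example(self):
        assert min_n_correlation(0.5, alpha=0.05, power=0.8) == 29

    def test_floor_at_tiny_power(self):
        assert min_n_correlation(0.5, power=1e-9) == 4

    def test_monotone_in_effect_size(self):
        ns = [min_n_correlation(r) for r in (0.2, 0.3, 0.5, 0.7)]
        assert ns == sorted(ns, reverse=True)

    def test_against_closed_form(self):
        # bias-corrected Fisher z solved directly, then refined by the search
        from scipy.stats import norm

        r, alpha, power = 0.3, 0.05, 0.9
        n = min_n_correlation(r, alpha, power)
        za, zb = norm.isf(alpha / 2), norm.ppf(power)
        approx = ((za + zb) / np.arctanh(r)) ** 2 + 3
        assert abs(n - approx) <= 2

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            min_n_correlation(1.0)


def test_summarize_shapes(hvln_schedule, rng):
    frames = []
    for sid in ("a", "b"):
        sim = simulate_agent("RW", {"eta": 0.3, "beta": 2.0}, hvln_schedule, rng)
        sim.insert(0, "subjID", sid)
        sim.insert(1, "condition", "HVLN")
        frames.append(sim)
    out = summarize(pd.concat(frames), {"HVLN": hvln_schedule})
    assert set(out.columns) >= {"subjID", "condition", "accuracy", "win_stay",
                                "lose_shift", "overall_accuracy"}
    assert len(out) == 2
    assert ((out["accuracy"] >= 0) & (out["accuracy"] <= 100)).all()
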