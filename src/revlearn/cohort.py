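"""Synthetic participant cohorts with the statistical structure the analysis
assumes.

Each cohort carries trait-anxiety scores (truncated normal on the STAI-T range
[20, 80]), a low / middle / high anxiety grouping, balanced block orders,
per-condition true model parameters, and choices simulated by the generative
models on the shared task schedules.  Group- and condition-specific generating
parameters are supplied on the natural scale and mapped to the unconstrained
(probit) scale for sampling, so draws always respect the parameter bounds;
optional trait couplings shift parameters linearly on that scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .inference import transform_to_natural
from .models import get_model, simulate_agent
from .task import BLOCK_ORDERS_EXP1, BLOCK_ORDERS_EXP2, CONDITIONS, build_session
from .validation import natural_map_to_hyperparams

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "split_groups",
           "default_group_param_map"]

_ORDER_SETS = {"exp1": BLOCK_ORDERS_EXP1, "exp2": BLOCK_ORDERS_EXP2}


def default_group_param_map(model: str = "FU_RP_IP") -> dict:
    """Demonstration generating values (natural scale, (mean, sd) per entry).

    These are this package's choices: they reproduce the qualitative condition
    structure the task is built to elicit — volatility-driven increases in both
    learning rates under low noise, and higher value sensitivity under low
    noise — with a slightly more exploitative high-anxiety group.  They carry
    no provenance beyond face plausibility for this task class.
    """
    spec = get_model(model)
    base = {
        "eta_pos": {"LVLN": 0.25, "LVHN": 0.33, "HVLN": 0.40, "HVHN": 0.35},
        "eta_neg": {"LVLN": 0.20, "LVHN": 0.24, "HVLN": 0.31, "HVHN": 0.28},
        "eta": {"LVLN": 0.22, "LVHN": 0.28, "HVLN": 0.35, "HVHN": 0.31},
        "phi": {c: 0.6 for c in CONDITIONS},
        "rho": {c: 0.3 for c in CONDITIONS},
        "beta": {"LVLN": 2.4, "LVHN": 2.1, "HVLN": 2.6, "HVHN": 2.1},
        "alpha": {c: 0.05 for c in CONDITIONS},
    }
    sd = {"eta_pos": 0.10, "eta_neg": 0.10, "eta": 0.10, "phi": 0.10, "rho": 0.10,
          "beta": 0.8, "alpha": 0.15}
    beta_shift = {"low": -0.15, "mid": 0.0, "high": 0.15}  # exploitation gradient
    out = {}
    for group in ("low", "mid", "high"):
        for cond in CONDITIONS:
            entry = {}
            for name in spec.param_names:
                mean = base[name][cond] + (beta_shift[group] if name == "beta" else 0.0)
                entry[name] = (mean, sd[name])
            out[(group, cond)] = entry
    return out


@dataclass
class CohortSpec:
    """Generating description of a synthetic cohort.

    ``group_param_map`` maps (anxiety group, condition) to
    ``{param: (mean, sd)}`` on the natural scale; ``trait_effect_map`` maps
    (condition, param) to a slope per trait z-score, applied on the
    unconstrained scale.
    """

    n_subjects: int = 80
    trait_mean: float = 50.75
    trait_sd: float = 10.21
    trait_bounds: tuple[float, float] = (20.0, 80.0)
    model: str = "FU_RP_IP"
    block_orders: str | Sequence = "exp1"
    group_param_map: Mapping | None = None
    trait_effect_map: Mapping | None = None
    split_method: str = "tertile"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        spec = get_model(self.model)
        if self.group_param_map is None:
            self.group_param_map = default_group_param_map(self.model)
        for key, entry in self.group_param_map.items():
            for name, (mean, sd) in entry.items():
                j = spec.param_names.index(name)
                lo, hi = spec.bounds[j]
                if (lo is not None and mean <= lo) or (hi is not None and mean >= hi):
                    raise ValueError(
                        f"group_param_map[{key}][{name}]: generating mean {mean} "
                        f"outside open bounds ({lo}, {hi})"
                    )
                if sd <= 0:
                    raise ValueError(f"group_param_map[{key}][{name}]: sd must be > 0")

    @property
    def order_set(self):
        if isinstance(self.block_orders, str):
            try:
                return _ORDER_SETS[self.block_orders]
            except KeyError:
                raise ValueError("block_orders must be 'exp1', 'exp2' or an explicit list")
        return tuple(tuple(o) for o in self.block_orders)


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame          # subjID, trait_score, group, block_order
    trials: pd.DataFrame            # subjID, condition, block, trial, choice, outcome
    true_params: pd.DataFrame       # subjID, condition, param, value
    schedules: dict                 # condition -> TrialSchedule (shared by all subjects)
    spec: CohortSpec = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def split_groups(traits, method: str = "tertile") -> np.ndarray:
    """Label trait scores low / mid / high (tertile) or low / high (median).

    Tertile: thresholds at the inclusive-rank 1/3 and 2/3 quantiles; scores at
    or below the lower threshold are low, at or above the upper are high, the
    middle third is excluded (labelled "mid").  Median: scores at or below the
    median are low, above are high; a degenerate split (everyone equal) leaves
    the high group empty with a warning.
    """
    traits = np.asarray(traits, dtype=float)
    if traits.size == 0:
        raise ValueError("no trait scores to split")
    if method == "tertile":
        if traits.size < 3:
            raise ValueError("tertile split needs at least 3 subjects")
        lo_thr = np.quantile(traits, 1 / 3, method="lower")
        hi_thr = np.quantile(traits, 2 / 3, method="higher")
        labels = np.where(
            traits <= lo_thr, "low", np.where(traits >= hi_thr, "high", "mid")
        )
    elif method == "median":
        if traits.size < 2:
            raise ValueError("median split needs at least 2 subjects")
        med = np.median(traits)
        labels = np.where(traits <= med, "low", "high")
        if not (labels == "high").any():
            warnings.warn("degenerate median split: no score above the median")
    else:
        raise ValueError("method must be 'tertile' or 'median'")
    return labels


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | int | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort: traits, groups, parameters and choices.

    Every subject faces the identical trial sequences (schedules derive from
    ``spec.seed`` alone); block orders are assigned round-robin over the
    admissible order set.
    """
    mspec = get_model(spec.model)
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_subjects
    lo, hi = spec.trait_bounds
    a, b = (lo - spec.trait_mean) / spec.trait_sd, (hi - spec.trait_mean) / spec.trait_sd
    traits = truncnorm.rvs(a, b, loc=spec.trait_mean, scale=spec.trait_sd,
                           size=n, random_state=rng)
    groups = split_groups(traits, spec.split_method)
    order_set = spec.order_set
    orders = [order_set[i % len(order_set)] for i in range(n)]

    schedules = {}
    session = build_session(order_set[0], shared_seed=spec.seed, order_set=order_set)
    for cond, sched in zip(order_set[0], session):
        schedules[cond] = sched

    trait_z = (traits - spec.trait_mean) / spec.trait_sd
    effect_map = spec.trait_effect_map or {}

    subj_rows, trial_rows, param_rows = [], [], []
    for i in range(n):
        sid = f"sub{i + 1:03d}"
        subj_rows.append(
            {"subjID": sid, "trait_score": traits[i], "group": groups[i],
             "block_order": "-".join(orders[i])}
        )
        for block, cond in enumerate(orders[i], start=1):
            try:
                entry = spec.group_param_map[(groups[i], cond)]
            except KeyError:
                raise ValueError(
                    f"group_param_map lacks an entry for ({groups[i]!r}, {cond!r})"
                )
            hp = natural_map_to_hyperparams(mspec.model_id, entry)
            slopes = np.array(
                [effect_map.get((cond, name), 0.0) for name in mspec.param_names]
            )
            u = hp.mu_pr + slopes * trait_z[i] + hp.sigma * rng.standard_normal(mspec.n_params)
            theta = transform_to_natural(mspec, u)
            for j, name in enumerate(mspec.param_names):
                param_rows.append(
                    {"subjID": sid, "condition": cond, "param": name, "value": theta[j]}
                )
            sim = simulate_agent(mspec, theta, schedules[cond], rng)
            sim.insert(0, "subjID", sid)
            sim.insert(1, "condition", cond)
            sim.insert(2, "block", block)
            trial_rows.append(sim[["subjID", "condition", "block", "trial", "choice", "outcome"]])

    return SyntheticCohort(
        subjects=pd.DataFrame(subj_rows),
        trials=pd.concat(trial_rows, ignore_index=True),
        true_params=pd.DataFrame(param_rows),
        schedules=schedules,
        spec=spec,
    )


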