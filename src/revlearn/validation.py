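"""Model validation: posterior predictive checks and parameter recovery.

The posterior predictive check re-simulates every subject's choices on their
actual trial schedules from draws of the fitted posterior and asks whether the
observed behavioural statistics (trial-aligned choice proportions, accuracy,
win-stay, lose-shift) fall inside the simulated distribution.

Parameter recovery runs the generative loop end to end by two routes: either
each synthetic subject is simulated at the fitted subject-level posterior
medians (``from_individual_medians``), or fresh subjects are drawn from the
group-level distributions (``from_group_hyperparams``); refitting then
quantifies true-versus-recovered agreement and the hierarchical shrinkage of
subject-level estimates toward the group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behaviour
from .inference import HierarchicalModel, natural_to_unconstrained, transform_to_natural
from .models import get_model, simulate_agent

__all__ = [
    "PPCResult",
    "RecoveryResult",
    "GroupHyperparams",
    "posterior_predictive_check",
    "parameter_recovery",
]


@dataclass
class PPCResult:
    """Observed-versus-simulated summaries for one fitted condition."""

    observed_curve: np.ndarray          # per-trial fraction choosing option 1
    sim_curve_mean: np.ndarray
    sim_curve_low: np.ndarray           # central-band bounds over simulations
    sim_curve_high: np.ndarray
    observed_stats: dict                # accuracy / win_stay / lose_shift
    sim_stats: dict                     # name -> array over simulations
    coverage: dict                      # name -> observed inside central band?
    n_sims: int
    band: float

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for name, obs in self.observed_stats.items():
            sims = self.sim_stats[name]
            rows.append(
                {
                    "statistic": name,
                    "observed": obs,
                    "sim_mean": float(np.mean(sims)),
                    "sim_low": float(np.quantile(sims, (1 - self.band) / 2)),
                    "sim_high": float(np.quantile(sims, 1 - (1 - self.band) / 2)),
                    "covered": self.coverage[name],
                }
            )
        return pd.DataFrame(rows)


def _behav_stats(frame: pd.DataFrame, schedule) -> dict:
    return {
        "accuracy": behaviour.accuracy(frame, schedule),
        "win_stay": behaviour.win_stay(frame),
        "lose_shift": behaviour.lose_shift(frame),
    }


def posterior_predictive_check(
    fit: HierarchicalModel,
    data: pd.DataFrame,
    schedule,
    n_sims: int = 100,
    rng: np.random.Generator | int | None = None,
    band: float = 0.95,
    force: bool = False,
) -> PPCResult:
    """Simulate the fitted cohort ``n_sims`` times from posterior draws.

    Each simulation takes one joint posterior draw (all subjects' parameters
    from the same draw, preserving their correlation) and replays every
    subject on the shared schedule.  Refuses unconverged fits unless
    ``force``.
    """
    if not fit.converged_ and not force:
        raise RuntimeError(
            f"fit did not pass the R-hat gate (max {fit.max_rhat_:.3f}); "
            "pass force=True to check it anyway"
        )
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    rng = np.random.default_rng(rng)
    spec = fit.spec_
    subjects = fit.subjects_
    t_len = schedule.n_trials

    obs_curve = np.zeros(t_len)
    obs_stats_acc = []
    for sid in subjects:
        grp = data[data["subjID"] == sid].sort_values("trial")
        obs_curve += (grp["choice"].to_numpy(dtype=int) == 1)
        obs_stats_acc.append(_behav_stats(grp, schedule))
    obs_curve /= len(subjects)
    observed_stats = {
        k: float(np.nanmean([s[k] for s in obs_stats_acc])) for k in obs_stats_acc[0]
    }

    draw_idx = rng.integers(0, fit.subject_draws_.shape[0], size=n_sims)
    sim_curves = np.zeros((n_sims, t_len))
    sim_stats = {k: np.empty(n_sims) for k in observed_stats}
    for s, d in enumerate(draw_idx):
        stats_acc = []
        for i, _ in enumerate(subjects):
            theta = fit.subject_draws_[d, i]
            sim = simulate_agent(spec, theta, schedule, rng)
            sim_curves[s] += (sim["choice"].to_numpy() == 1)
            stats_acc.append(_behav_stats(sim, schedule))
        sim_curves[s] /= len(subjects)
        for k in sim_stats:
            sim_stats[k][s] = np.nanmean([st[k] for st in stats_acc])

    lo_q, hi_q = (1 - band) / 2, 1 - (1 - band) / 2
    coverage = {}
    for k, obs in observed_stats.items():
        lo, hi = np.quantile(sim_stats[k], [lo_q, hi_q])
        coverage[k] = bool(lo <= obs <= hi) if n_sims > 1 else None
    return PPCResult(
        observed_curve=obs_curve,
        sim_curve_mean=sim_curves.mean(axis=0),
        sim_curve_low=np.quantile(sim_curves, lo_q, axis=0),
        sim_curve_high=np.quantile(sim_curves, hi_q, axis=0),
        observed_stats=observed_stats,
        sim_stats=sim_stats,
        coverage=coverage,
        n_sims=n_sims,
        band=band,
    )


@dataclass
class GroupHyperparams:
    """Group-level generating distribution on the unconstrained scale."""

    model: str
    mu_pr: np.ndarray
    sigma: np.ndarray

    def draw_subjects(self, n: int, rng: np.random.Generator) -> np.ndarray:
        spec = get_model(self.model)
        z = rng.standard_normal((n, spec.n_params))
        return transform_to_natural(spec, self.mu_pr + self.sigma * z)


def natural_map_to_hyperparams(model: str, entry: dict) -> GroupHyperparams:
    """Convert ``{param: (mean, sd)}`` on the natural scale to unconstrained
    group hyperparameters (probit mean; delta-method SD)."""
    from scipy.stats import norm

    spec = get_model(model)
    mu_nat = np.array([entry[p][0] for p in spec.param_names])
    sd_nat = np.array([entry[p][1] for p in spec.param_names])
    mu_pr = natural_to_unconstrained(spec, mu_nat)
    sigma = np.empty(spec.n_params)
    for j, (_, ub) in enumerate(spec.bounds):
        if ub is None:
            sigma[j] = sd_nat[j]
        else:
            sigma[j] = sd_nat[j] / (ub * norm.pdf(mu_pr[j]))
    return GroupHyperparams(model=spec.model_id, mu_pr=mu_pr, sigma=sigma)


@dataclass
class RecoveryResult:
    """True-versus-recovered agreement for one recovery run."""

    method: str
    param_names: tuple
    true_group_means: np.ndarray        # natural scale, (replicates, K)
    recovered_group_means: np.ndarray   # posterior means, (replicates, K)
    group_hdi: np.ndarray               # (replicates, K, 2), 89% by default
    group_covered: np.ndarray           # (replicates, K) bool
    subject_correlations: np.ndarray    # (replicates, K)
    shrinkage_ratio: np.ndarray         # recovered SD / generating SD, (replicates, K)
    max_rhat: np.ndarray                # per replicate
    fits: list = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.true_group_means.shape[0]):
            for j, name in enumerate(self.param_names):
                rows.append(
                    {
                        "replicate": r,
                        "param": name,
                        "true_group_mean": self.true_group_means[r, j],
                        "recovered_group_mean": self.recovered_group_means[r, j],
                        "hdi_low": self.group_hdi[r, j, 0],
                        "hdi_high": self.group_hdi[r, j, 1],
                        "covered": self.group_covered[r, j],
                        "subject_correlation": self.subject_correlations[r, j],
                        "shrinkage_ratio": self.shrinkage_ratio[r, j],
                        "max_rhat": self.max_rhat[r],
                    }
                )
        return pd.DataFrame(rows)


def parameter_recovery(
    model: str,
    source,
    schedule,
    method: str = "from_group_hyperparams",
    n_subjects: int | None = None,
    n_replicates: int = 1,
    rng: np.random.Generator | int | None = None,
    hdi_mass: float = 0.89,
    **fit_kwargs,
) -> RecoveryResult:
    """Simulate-and-refit recovery of group- and subject-level parameters.

    ``source`` is a :class:`GroupHyperparams` (method ``from_group_hyperparams``,
    fresh subjects drawn from the group distribution each replicate) or a
    fitted :class:`HierarchicalModel` (method ``from_individual_medians``,
    subjects fixed at their fitted posterior medians).  ``schedule`` may be a
    single block or a list of blocks played in sequence (values reset per
    block).  Coverage is scored on the unconstrained group means, where the
    generating values live; summaries are reported on the natural scale.
    """
    from .comparison import hdi as _hdi

    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if method not in ("from_group_hyperparams", "from_individual_medians"):
        raise ValueError(f"unknown recovery method {method!r}")
    spec = get_model(model)
    rng = np.random.default_rng(rng)
    schedules = schedule if isinstance(schedule, (list, tuple)) else [schedule]

    if method == "from_individual_medians":
        if not hasattr(source, "subject_params_"):
            raise TypeError("from_individual_medians needs a fitted HierarchicalModel")
        true_subjects_fixed = np.asarray(source.subject_params_)
        true_mu_pr = np.median(source.group_mu_pr_, axis=0)
    else:
        if not isinstance(source, GroupHyperparams):
            raise TypeError("from_group_hyperparams needs a GroupHyperparams source")
        true_mu_pr = np.asarray(source.mu_pr, dtype=float)

    k = spec.n_params
    shape = (n_replicates, k)
    out = {
        "true": np.empty(shape), "rec": np.empty(shape),
        "hdi": np.empty((n_replicates, k, 2)), "cov": np.zeros(shape, dtype=bool),
        "corr": np.empty(shape), "shrink": np.empty(shape),
        "rhat": np.empty(n_replicates),
    }
    fits = []
    true_mu_nat = transform_to_natural(spec, true_mu_pr)
    for r in range(n_replicates):
        if method == "from_group_hyperparams":
            n = n_subjects or 40
            thetas = source.draw_subjects(n, rng)
        else:
            thetas = true_subjects_fixed
            n = thetas.shape[0]
        rows = []
        for i in range(n):
            for b, sched in enumerate(schedules, start=1):
                sim = simulate_agent(spec, thetas[i], sched, rng)
                sim.insert(0, "subjID", f"rec{i:03d}")
                sim.insert(1, "block", b)
                rows.append(sim)
        data = pd.concat(rows, ignore_index=True)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        fit = HierarchicalModel(model=spec.model_id, seed=fit_seed, **fit_kwargs).fit(data)
        fits.append(fit)
        out["rhat"][r] = fit.max_rhat_
        for j in range(k):
            draws_pr = fit.group_mu_pr_[:, j]
            lo, hi = _hdi(draws_pr, hdi_mass)
            out["true"][r, j] = true_mu_nat[j]
            out["rec"][r, j] = float(fit.group_means_[:, j].mean())
            out["hdi"][r, j] = (lo, hi)
            out["cov"][r, j] = bool(lo <= true_mu_pr[j] <= hi)
            rec_subj = fit.subject_params_[:, j]
            true_subj = thetas[:, j]
            if np.std(true_subj) > 0 and np.std(rec_subj) > 0:
                out["corr"][r, j] = float(np.corrcoef(true_subj, rec_subj)[0, 1])
                out["shrink"][r, j] = float(np.std(rec_subj) / np.std(true_subj))
            else:
                out["corr"][r, j] = np.nan
                out["shrink"][r, j] = np.nan
    return RecoveryResult(
        method=method,
        param_names=spec.param_names,
        true_group_means=out["true"],
        recovered_group_means=out["rec"],
        group_hdi=out["hdi"],
        group_covered=out["cov"],
        subject_correlations=out["corr"],
        shrinkage_ratio=out["shrink"],
        max_rhat=out["rhat"],
        fits=fits,
    )
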