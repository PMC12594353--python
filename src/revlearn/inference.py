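"""Hierarchical Bayesian estimation of the reinforcement-learning models.

One fit covers one (model, condition, participant-group) cell: models are
fit separately per task condition and participant group.  Group-level means
and SDs and subject-level parameters are estimated simultaneously with a
non-centered parameterization: subject raw effects are
standard normal, the subject parameter is ``transform(mu + sigma * z)`` where
``transform`` maps the unconstrained scale through the standard-normal CDF onto
(0, 1) — scaled by 10 for the value-sensitivity parameter beta — and is the
identity for the unbounded indecision point alpha.

Priors follow the convention of the hierarchical model-fitting packages this
design mirrors: ``mu ~ Normal(0, 1)``; ``sigma ~ half-Normal(0, 0.2)`` for
bounded parameters and ``half-Normal(0, 1)`` for alpha; all configurable.

Sampling uses the in-package Hamiltonian Monte Carlo engine
(:mod:`revlearn._hmc`) with analytic likelihood gradients
(:mod:`revlearn._kernels`).  Convergence is gated on the split-chain potential
scale reduction statistic (R-hat < 1.1); model comparison uses Pareto-smoothed
importance-sampling leave-one-out cross-validation (LOOIC = -2 * elpd_loo).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import logsumexp, ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator

from . import _kernels
from ._hmc import sample_hmc
from .models import MODELS, ModelSpec, get_model

__all__ = [
    "MCMC_PROFILES",
    "HierarchicalModel",
    "ConvergenceWarning",
    "LooResult",
    "fit_hierarchical",
    "compute_rhat",
    "compute_looic",
    "compare_models",
    "transform_to_natural",
    "natural_to_unconstrained",
]

#: chains, warmup, retained draws per chain.  "full" is the reference
#: profile (3 chains x 4,000 samples with the first 2,000 discarded); "desk"
#: is the reduced profile used throughout the test suite.
MCMC_PROFILES = {"full": (3, 2000, 2000), "desk": (3, 1000, 1000)}

_SIGMA_SCALE_BOUNDED = 0.2
_SIGMA_SCALE_FREE = 1.0


class ConvergenceWarning(UserWarning):
    """Sampler diagnostics exceeded their gate; the fit is flagged, never hidden."""


def _upper_bounds(spec: ModelSpec) -> np.ndarray:
    """Per-parameter scale of the CDF transform; nan marks an identity
    (unbounded) parameter."""
    ub = np.empty(spec.n_params)
    for j, (lo, hi) in enumerate(spec.bounds):
        ub[j] = np.nan if hi is None else hi
    return ub


def transform_to_natural(spec: ModelSpec | str, u: np.ndarray) -> np.ndarray:
    """Map unconstrained values (..., K) to the natural parameter scale."""
    spec = get_model(spec)
    u = np.asarray(u, dtype=float)
    ub = _upper_bounds(spec)
    out = np.where(np.isnan(ub), u, np.nan_to_num(ub) * ndtr(u))
    return out


def natural_to_unconstrained(spec: ModelSpec | str, theta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transform_to_natural` (probit on bounded parameters)."""
    spec = get_model(spec)
    theta = np.asarray(theta, dtype=float)
    ub = _upper_bounds(spec)
    with np.errstate(divide="ignore"):
        out = np.where(np.isnan(ub), theta, norm.ppf(theta / np.where(np.isnan(ub), 1.0, ub)))
    return out


def _data_fingerprint(choices: np.ndarray, outcomes: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(choices.tobytes())
    h.update(outcomes.tobytes())
    return h.hexdigest()[:16]


def _frame_to_arrays(data: pd.DataFrame):
    """(subjects x trials) choice/outcome/reset matrices from the flat trial
    table.

    Rows must carry subjID, choice, outcome; trial order is taken from the
    (block, trial) columns when present, otherwise row order.  Subjects with
    fewer trials are right-padded with missing (0) entries.  The reset matrix
    flags the first trial of every block: agent values start at zero per block
    and never carry across block boundaries.
    """
    required = {"subjID", "choice", "outcome"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns {sorted(missing)}")
    if "condition" in data.columns and data["condition"].nunique() > 1:
        raise ValueError(
            "fit one condition at a time; got "
            f"{sorted(data['condition'].unique())}"
        )
    sort_cols = [c for c in ("block", "trial") if c in data.columns]
    subjects = list(pd.unique(data["subjID"]))
    t_max = int(data.groupby("subjID").size().max())
    choices = np.zeros((len(subjects), t_max), dtype=np.int8)
    outcomes = np.zeros((len(subjects), t_max), dtype=np.int8)
    resets = np.zeros((len(subjects), t_max), dtype=np.int8)
    for i, sid in enumerate(subjects):
        grp = data[data["subjID"] == sid]
        if sort_cols:
            grp = grp.sort_values(sort_cols)
        ch = grp["choice"].to_numpy(dtype=np.int8)
        oc = grp["outcome"].to_numpy(dtype=np.int8)
        resets[i, 0] = 1
        if "block" in grp.columns:
            blocks = grp["block"].to_numpy()
            resets[i, np.flatnonzero(blocks[1:] != blocks[:-1]) + 1] = 1
        bad = set(np.unique(ch)) - {0, 1, 2}
        if bad:
            raise ValueError(f"subject {sid}: choices must be 0/1/2, found {sorted(bad)}")
        if np.any((ch != 0) & ~np.isin(oc, (1, -1))):
            raise ValueError(f"subject {sid}: outcomes on observed trials must be +1/-1")
        choices[i, : len(ch)] = ch
        outcomes[i, : len(oc)] = oc
    return subjects, choices, outcomes, resets


class HierarchicalModel(BaseEstimator):
    """Hierarchical Bayesian fit of one RL model to one condition x group.

    Parameters
    ----------
    model:
        One of ``RW, RP, EWA, FU, FU_RP, FU_RP_IP``.
    chains, warmup, draws:
        MCMC schedule per chain; ``profile`` ("full" or "desk") overrides all
        three.
    target_accept:
        Dual-averaging acceptance target for the HMC step size.
    sigma_scale, sigma_scale_free:
        Half-normal prior scales for group SDs of bounded / unbounded
        parameters.
    loo_draws:
        Posterior draws (thinned evenly over chains) used for the pointwise
        log-likelihood matrix; caps the memory of PSIS-LOO on long datasets.
    fictitious_pe, rate_select:
        Update-rule switches, see :func:`revlearn.models.update_state`.
    rhat_threshold:
        Convergence gate; exceeding it raises :class:`ConvergenceWarning` and
        sets ``converged_ = False``.

    Attributes (after ``fit``)
    --------------------------
    idata_ : arviz.InferenceData with posterior and log_likelihood groups
    rhat_ : per-parameter split-chain R-hat (pandas Series)
    max_rhat_ : float, over group- and subject-level parameters
    looic_, elpd_loo_, looic_se_, pareto_k_ : PSIS-LOO summaries
    group_means_ : posterior draws of natural-scale group means, (draws, K)
    subject_params_ : posterior median subject-level parameters, (N, K)
    converged_ : bool
    """

    def __init__(
        self,
        model: str = "FU_RP_IP",
        chains: int = 3,
        warmup: int = 2000,
        draws: int = 2000,
        profile: str | None = None,
        target_accept: float = 0.8,
        sigma_scale: float = _SIGMA_SCALE_BOUNDED,
        sigma_scale_free: float = _SIGMA_SCALE_FREE,
        loo_draws: int = 1000,
        fictitious_pe: str = "unchosen",
        rate_select: str = "factual",
        rhat_threshold: float = 1.1,
        seed: int | None = None,
    ):
        self.model = model
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.profile = profile
        self.target_accept = target_accept
        self.sigma_scale = sigma_scale
        self.sigma_scale_free = sigma_scale_free
        self.loo_draws = loo_draws
        self.fictitious_pe = fictitious_pe
        self.rate_select = rate_select
        self.rhat_threshold = rhat_threshold
        self.seed = seed

    # ------------------------------------------------------------------
    def _schedule(self):
        if self.profile is not None:
            if self.profile not in MCMC_PROFILES:
                raise ValueError(f"unknown MCMC profile {self.profile!r}")
            return MCMC_PROFILES[self.profile]
        return self.chains, self.warmup, self.draws

    def _logp_and_grad_factory(self, spec, choices, outcomes, resets):
        n_subj = choices.shape[0]
        k = spec.n_params
        ub = _upper_bounds(spec)
        bounded = ~np.isnan(ub)
        ub_num = np.where(bounded, np.nan_to_num(ub, nan=1.0), 1.0)
        w2 = np.where(bounded, self.sigma_scale, self.sigma_scale_free) ** 2
        fic = 1 if self.fictitious_pe == "chosen" else 0
        rpo = 1 if self.rate_select == "per-option" else 0
        code = spec.code
        ll_buf = np.empty(n_subj)
        grad_buf = np.empty((n_subj, _kernels.MAX_PARAMS))
        theta_buf = np.zeros((n_subj, _kernels.MAX_PARAMS))

        def logp_and_grad(q):
            mu = q[:k]
            # wild warmup proposals can push log-sigma far out; the clip keeps
            # the density finite (the move is rejected on energy anyway)
            s = np.clip(q[k: 2 * k], -200.0, 200.0)
            sigma = np.exp(s)
            z = q[2 * k:].reshape(n_subj, k)
            u = mu + sigma * z
            theta_buf[:, :k] = np.where(bounded, ub_num * ndtr(u), u)
            _kernels.cohort_loglik_grad(
                code, theta_buf, choices, outcomes, resets, fic, rpo, ll_buf, grad_buf
            )
            dtheta_du = np.where(bounded, ub_num * norm.pdf(u), 1.0)
            g_u = grad_buf[:, :k] * dtheta_du
            logp = (
                ll_buf.sum()
                - 0.5 * np.sum(mu**2)
                - np.sum(sigma**2 / (2.0 * w2)) + np.sum(s)
                - 0.5 * np.sum(z**2)
            )
            d_mu = g_u.sum(axis=0) - mu
            d_s = (g_u * z).sum(axis=0) * sigma - sigma**2 / w2 + 1.0
            d_z = g_u * sigma - z
            return logp, np.concatenate([d_mu, d_s, d_z.ravel()])

        return logp_and_grad

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        """Fit the hierarchical model to one condition's trial table."""
        spec = get_model(self.model)
        subjects, choices, outcomes, resets = _frame_to_arrays(X)
        n_subj = len(subjects)
        if n_subj < 2:
            raise ValueError("hierarchical estimation needs at least 2 subjects")
        observed = choices != 0
        if np.any(observed.sum(axis=1) == 0):
            raise ValueError("every subject needs at least one non-missing trial")
        for i, sid in enumerate(subjects):
            seen = np.unique(choices[i][observed[i]])
            if len(seen) == 1:
                warnings.warn(
                    f"subject {sid} made a single unique choice; "
                    "its parameters are weakly identified"
                )
        n_chains, n_warmup, n_draws = self._schedule()
        k = spec.n_params
        dim = 2 * k + n_subj * k
        q0 = np.zeros(dim)
        q0[k: 2 * k] = np.log(0.1)
        logp_and_grad = self._logp_and_grad_factory(spec, choices, outcomes, resets)
        result = sample_hmc(
            logp_and_grad,
            q0,
            n_chains=n_chains,
            n_warmup=n_warmup,
            n_draws=n_draws,
            seed=self.seed,
            target_accept=self.target_accept,
            init_jitter=0.1,
        )
        self._assemble(spec, subjects, choices, outcomes, resets, result)
        return self

    # ------------------------------------------------------------------
    def _assemble(self, spec, subjects, choices, outcomes, resets, result):
        k = spec.n_params
        n_subj = len(subjects)
        n_chains, n_draws, _ = result.draws.shape
        names = spec.param_names
        mu_pr = result.draws[:, :, :k]
        sigma = np.exp(result.draws[:, :, k: 2 * k])
        z = result.draws[:, :, 2 * k:].reshape(n_chains, n_draws, n_subj, k)
        u_subj = mu_pr[:, :, None, :] + sigma[:, :, None, :] * z
        theta_subj = transform_to_natural(spec, u_subj)
        mu_nat = transform_to_natural(spec, mu_pr)

        coords = {
            "chain": np.arange(n_chains),
            "draw": np.arange(n_draws),
            "subject": list(subjects),
        }
        posterior = {}
        for j, name in enumerate(names):
            posterior[f"mu_{name}"] = (("chain", "draw"), mu_nat[:, :, j])
            posterior[f"mu_pr_{name}"] = (("chain", "draw"), mu_pr[:, :, j])
            posterior[f"sigma_{name}"] = (("chain", "draw"), sigma[:, :, j])
            posterior[f"{name}"] = (("chain", "draw", "subject"), theta_subj[:, :, :, j])
        post_ds = xr.Dataset(posterior, coords=coords)

        # pointwise log-likelihood on a thinned, chain-balanced subset of draws
        total = n_chains * n_draws
        n_loo = min(self.loo_draws, total)
        per_chain = max(1, n_loo // n_chains)
        idx = np.unique(np.linspace(0, n_draws - 1, per_chain).astype(int))
        fic = 1 if self.fictitious_pe == "chosen" else 0
        rpo = 1 if self.rate_select == "per-option" else 0
        t_len = choices.shape[1]
        loglik = np.empty((n_chains, len(idx), n_subj, t_len))
        theta_buf = np.zeros((n_subj, _kernels.MAX_PARAMS))
        pw = np.empty((n_subj, t_len))
        for c in range(n_chains):
            for a, d in enumerate(idx):
                theta_buf[:, :k] = theta_subj[c, d]
                _kernels.cohort_pointwise(
                    spec.code, theta_buf, choices, outcomes, resets, fic, rpo, pw
                )
                loglik[c, a] = pw
        observed = (choices != 0)
        # keep only observed trials as LOO observations
        obs_idx = np.flatnonzero(observed.ravel())
        ll_flat = loglik.reshape(n_chains, len(idx), -1)[:, :, obs_idx]
        ll_ds = xr.Dataset(
            {"choice": (("chain", "draw", "obs"), ll_flat)},
            coords={"chain": np.arange(n_chains), "draw": idx, "obs": obs_idx},
        )
        self.idata_ = az.InferenceData(posterior=post_ds, log_likelihood=ll_ds)

        # convergence diagnostics over every sampled dimension
        flat = result.draws  # (chains, draws, dim)
        rhats = compute_rhat(flat)
        dim_names = (
            [f"mu_pr_{n}" for n in names]
            + [f"log_sigma_{n}" for n in names]
            + [f"z_{n}[{s}]" for s in subjects for n in names]
        )
        self.rhat_ = pd.Series(rhats, index=dim_names)
        self.max_rhat_ = float(np.nanmax(rhats))
        self.divergences_ = int(result.divergences.sum())
        self.accept_rate_ = result.accept_rate
        self.step_size_ = result.step_size
        self.converged_ = bool(self.max_rhat_ < self.rhat_threshold)
        if not self.converged_:
            warnings.warn(
                f"max R-hat {self.max_rhat_:.3f} >= {self.rhat_threshold}; "
                "inspect the chains before using this fit",
                ConvergenceWarning,
            )

        loo = compute_looic(ll_flat)
        self.looic_ = loo.looic
        self.looic_se_ = loo.looic_se
        self.elpd_loo_ = loo.elpd_loo
        self.pareto_k_ = loo.pareto_k
        self.n_high_pareto_k_ = loo.n_high_k
        self.pointwise_elpd_ = loo.pointwise_elpd
        if loo.n_high_k:
            warnings.warn(
                f"{loo.n_high_k} observations with Pareto k > 0.7; "
                "LOOIC may be unreliable for this fit"
            )

        self.spec_ = spec
        self.subjects_ = list(subjects)
        self.group_means_ = mu_nat.reshape(-1, k)
        self.group_mu_pr_ = mu_pr.reshape(-1, k)
        self.group_sigma_ = sigma.reshape(-1, k)
        self.subject_draws_ = theta_subj.reshape(-1, n_subj, k)
        self.subject_params_ = np.median(self.subject_draws_, axis=0)
        self.data_fingerprint_ = _data_fingerprint(choices, outcomes)
        self.mcmc_config_ = {
            "chains": flat.shape[0],
            "draws": flat.shape[1],
            "warmup": self._schedule()[1],
            "seed": self.seed,
            "target_accept": self.target_accept,
        }

    # ------------------------------------------------------------------
    def group_posterior(self, param: str, scale: str = "natural") -> np.ndarray:
        """Flattened posterior draws of a group-level mean."""
        if param not in self.spec_.param_names:
            raise KeyError(f"{param!r} is not a parameter of {self.spec_.model_id}")
        j = self.spec_.param_names.index(param)
        if scale == "natural":
            return self.group_means_[:, j]
        if scale == "unconstrained":
            return self.group_mu_pr_[:, j]
        raise ValueError("scale must be 'natural' or 'unconstrained'")

    def score(self, X=None, y=None) -> float:
        """Expected log pointwise predictive density (higher is better)."""
        return float(self.elpd_loo_)


def fit_hierarchical(model, data: pd.DataFrame, **mcmc_config) -> HierarchicalModel:
    """Functional wrapper: fit ``model`` to one condition x group trial table."""
    spec = get_model(model)
    return HierarchicalModel(model=spec.model_id, **mcmc_config).fit(data)


# ---------------------------------------------------------------------------
# diagnostics

def compute_rhat(draws) -> np.ndarray | float:
    """Split-chain potential scale reduction statistic.

    ``draws`` is (chains, n) for one parameter or (chains, n, p).  Each chain
    is split in half; R-hat = sqrt(((n-1)/n * W + B/n) / W) over the split
    chains.  Zero within-chain variance yields nan (diagnostic undefined).
    """
    a = np.asarray(draws, dtype=float)
    scalar = a.ndim == 2
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise ValueError("draws must be (chains, n) or (chains, n, params)")
    m, n, p = a.shape
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 4:
        raise ValueError("R-hat needs at least 4 draws per chain")
    half = n // 2
    split = np.concatenate([a[:, :half], a[:, half: 2 * half]], axis=0)
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (half - 1) / half * w + b / half
        rhat = np.sqrt(var_hat / w)
    rhat = np.where(w <= 0, np.nan, rhat)
    return float(rhat[0]) if scalar else rhat


@dataclass
class LooResult:
    """PSIS-LOO summary; ``looic = -2 * elpd_loo`` exactly."""

    elpd_loo: float
    elpd_se: float
    looic: float
    looic_se: float
    pareto_k: np.ndarray
    n_high_k: int
    pointwise_elpd: np.ndarray = field(repr=False, default=None)


def compute_looic(pointwise_loglik, high_k: float = 0.7) -> LooResult:
    """Pareto-smoothed importance-sampling LOO from a pointwise log-likelihood
    array of shape (chains, draws, obs) or (draws, obs)."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None]
    if ll.ndim != 3:
        raise ValueError("pointwise log-likelihood must be (chains, draws, obs)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    flat = ll.reshape(-1, ll.shape[-1])  # (samples, obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short chains: smoothing may be skipped
        log_weights, pareto_k = az.psislw(xr.DataArray(-flat.T, dims=("obs", "__sample__")))
    lw = np.asarray(log_weights)  # (obs, samples), normalized to logsumexp 0
    elpd_i = logsumexp(lw + flat.T, axis=1)
    n = elpd_i.size
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(n * np.var(elpd_i, ddof=0)))
    k_arr = np.asarray(pareto_k)
    return LooResult(
        elpd_loo=elpd,
        elpd_se=se,
        looic=-2.0 * elpd,
        looic_se=2.0 * se,
        pareto_k=k_arr,
        n_high_k=int(np.sum(k_arr > high_k)),
        pointwise_elpd=elpd_i,
    )


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted models by LOOIC (ascending; lowest = best predictive fit).

    All fits must be of the same data (checked by fingerprint).  The standard
    error of each LOOIC difference to the winner is computed from the paired
    pointwise elpd contributions.  Ties order alphabetically by model id.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.data_fingerprint_ for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were made on different datasets; refusing to rank")
    order = sorted(fits, key=lambda f: (f.looic_, f.spec_.model_id))
    best = order[0]
    rows = []
    for f in order:
        if f is best:
            d, d_se = 0.0, 0.0
        else:
            diff = f.pointwise_elpd_ - best.pointwise_elpd_
            d = -2.0 * float(diff.sum())
            d_se = 2.0 * float(np.sqrt(diff.size * np.var(diff, ddof=0)))
        rows.append(
            {
                "model": f.spec_.model_id,
                "looic": f.looic_,
                "looic_se": f.looic_se_,
                "elpd_loo": f.elpd_loo_,
                "d_looic": d,
                "d_se": d_se,
                "n_high_k": f.n_high_pareto_k_,
                "max_rhat": f.max_rhat_,
                "winner": f is best,
            }
        )
    return pd.DataFrame(rows)
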