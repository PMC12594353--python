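"""A small Hamiltonian Monte Carlo engine.

Adaptive gradient-based MCMC meeting the fitting contract of
:mod:`revlearn.inference`: seeded and reproducible, dual-averaging step-size
adaptation to a target acceptance statistic (default 0.8), diagonal mass-matrix
adaptation from a mid-warmup window, and jittered trajectory lengths to avoid
periodic orbits.  The model supplies ``logp_and_grad(q) -> (float, ndarray)``
for the log posterior density; everything here is model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]


@dataclass
class HMCResult:
    draws: np.ndarray          # (chains, n_draws, dim)
    accept_rate: np.ndarray    # per chain, post-warmup mean acceptance statistic
    step_size: np.ndarray      # per chain, adapted step size
    divergences: np.ndarray    # per chain, post-warmup divergent transitions
    inv_mass: np.ndarray       # (chains, dim)


def _leapfrog(logp_and_grad, q, p, grad, eps, n_steps, inv_mass):
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        q = q + eps * inv_mass * p
        logp, grad = logp_and_grad(q)
        if not np.isfinite(logp):
            return q, p, logp, grad
        p = p + (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return q, p, logp, grad


def _find_initial_step(logp_and_grad, q, rng, inv_mass):
    """Double/halve the step size until one leapfrog step has acceptance ~0.5."""
    eps = 0.1
    logp0, grad0 = logp_and_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = -logp0 + 0.5 * np.sum(p * p * inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad0, eps, 1, inv_mass)
    h1 = -logp1 + 0.5 * np.sum(p1 * p1 * inv_mass) if np.isfinite(logp1) else np.inf
    direction = 1 if (h0 - h1) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad0, eps, 1, inv_mass)
        h1 = -logp1 + 0.5 * np.sum(p1 * p1 * inv_mass) if np.isfinite(logp1) else np.inf
        accept = h0 - h1
        if (direction == 1 and accept <= np.log(0.5)) or (
            direction == -1 and accept >= np.log(0.5)
        ):
            break
    return eps


def _sample_chain(logp_and_grad, q0, n_warmup, n_draws, rng, target_accept,
                  traj_length, max_leapfrog, divergence_threshold=1000.0):
    dim = q0.size
    inv_mass = np.ones(dim)
    q = q0.copy()
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise FloatingPointError("non-finite log posterior at the initial point")

    # dual averaging state (Hoffman & Gelman defaults)
    eps = _find_initial_step(logp_and_grad, q, rng, inv_mass)
    mu_da, log_eps_bar, h_bar = np.log(10.0 * eps), 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    window_lo, window_hi = int(0.25 * n_warmup), int(0.75 * n_warmup)
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_accept_stat = 0.0
    divergences = 0
    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -logp + 0.5 * np.sum(p * p * inv_mass)
        traj = traj_length * rng.uniform(0.8, 1.2)
        # before the mass matrix is adapted the metric is poorly scaled and the
        # step size tiny; cap trajectories there to keep warmup cheap
        cap = 24 if (warming and it < window_hi) else max_leapfrog
        n_steps = int(min(cap, max(1, round(traj / eps))))
        q_new, p_new, logp_new, grad_new = _leapfrog(
            logp_and_grad, q, p, grad, eps, n_steps, inv_mass
        )
        if np.isfinite(logp_new):
            h1 = -logp_new + 0.5 * np.sum(p_new * p_new * inv_mass)
            energy_error = h1 - h0
        else:
            energy_error = np.inf
        divergent = not np.isfinite(energy_error) or energy_error > divergence_threshold
        alpha = 0.0 if divergent else min(1.0, np.exp(-max(energy_error, -700.0)))
        if not divergent and rng.random() < alpha:
            q, logp, grad = q_new, logp_new, grad_new

        if warming:
            da_iter += 1
            frac = 1.0 / (da_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu_da - np.sqrt(da_iter) / gamma * h_bar
            eta = da_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if window_lo <= it < window_hi:
                window.append(q.copy())
            if it == window_hi - 1 and len(window) >= 10:
                w = np.asarray(window)
                var = w.var(axis=0, ddof=1)
                n_w = len(window)
                inv_mass = (n_w * var + 1e-3 * 5.0) / (n_w + 5.0)  # shrink toward 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                # re-tune the step size for the new metric
                eps = _find_initial_step(logp_and_grad, q, rng, inv_mass)
                mu_da, log_eps_bar, h_bar, da_iter = np.log(10.0 * eps), 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            if divergent:
                divergences += 1
            n_accept_stat += alpha
            draws[it - n_warmup] = q
    return draws, n_accept_stat / n_draws, eps, divergences, inv_mass


def sample_hmc(
    logp_and_grad,
    q0: np.ndarray,
    *,
    n_chains: int = 3,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int | None = None,
    target_accept: float = 0.8,
    traj_length: float = 1.2,
    max_leapfrog: int = 128,
    init_jitter: float = 0.5,
) -> HMCResult:
    """Run ``n_chains`` independent HMC chains from jittered copies of ``q0``.

    Reproducible: identical arguments and seed give identical draws.
    """
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    draws = np.empty((n_chains, n_draws, q0.size))
    accept = np.empty(n_chains)
    step = np.empty(n_chains)
    div = np.empty(n_chains, dtype=int)
    inv_mass = np.empty((n_chains, q0.size))
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        start = q0 + init_jitter * rng.standard_normal(q0.size)
        draws[c], accept[c], step[c], div[c], inv_mass[c] = _sample_chain(
            logp_and_grad, start, n_warmup, n_draws, rng, target_accept,
            traj_length, max_leapfrog,
        )
    return HMCResult(draws, accept, step, div, inv_mass)
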