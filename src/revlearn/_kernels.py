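"""Numba kernels: per-trial log-likelihoods and their analytic parameter
gradients for all six models.

These power the Hamiltonian Monte Carlo sampler, where a likelihood gradient is
evaluated at every leapfrog step.  The gradients are exact forward-mode
recursions: alongside the option values V we carry dV/dtheta through each
learning step, then accumulate d log p(choice) / dtheta at every observed
trial.  Each model family gets its own specialized scalar loop (this is the
inference hot path); a finite-difference agreement test pins every gradient
against the reference implementation in :mod:`revlearn.models`.

Parameter vectors are padded to length 4 in the canonical order of
``models.MODELS``; choices use 0 = missing, 1, 2; outcomes are +1/-1.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# model codes (match models.MODELS[...].code)
RW, RP, EWA, FU, FU_RP, FU_RP_IP = 0, 1, 2, 3, 4, 5

MAX_PARAMS = 4


@njit(cache=False, fastmath=True)
def _log_sigmoid(m):
    if m >= 0.0:
        return -math.log1p(math.exp(-m))
    return m - math.log1p(math.exp(m))


@njit(cache=False, fastmath=True)
def _sigmoid(m):
    if m >= 0.0:
        return 1.0 / (1.0 + math.exp(-m))
    e = math.exp(m)
    return e / (1.0 + e)


@njit(cache=False, fastmath=True)
def _logsig_and_weight(m):
    """(log sigmoid(m), sigmoid(-m)) from a single exponential."""
    if m >= 0.0:
        e = math.exp(-m)
        return -math.log1p(e), e / (1.0 + e)
    e = math.exp(m)
    return m - math.log1p(e), 1.0 / (1.0 + e)


@njit(cache=False, fastmath=True)
def subject_loglik_pointwise(code, theta, choices, outcomes, resets, fic_chosen, rate_per_option, out):
    """Fill ``out`` with per-trial log p(choice); returns the sum.

    Missing trials (choice 0) contribute 0.0 and do not update the state.
    ``resets[t] == 1`` re-initializes the agent state before trial t (block
    boundaries: values carry over within a block, never across blocks).
    """
    v0 = 0.0
    v1 = 0.0
    n0 = 1.0
    n1 = 1.0
    if code == RW or code == FU:
        beta = theta[1]
    else:
        beta = theta[2]
    alpha = theta[3] if code == FU_RP_IP else 0.0
    total = 0.0
    for t in range(choices.shape[0]):
        if resets[t] == 1:
            v0 = 0.0
            v1 = 0.0
            n0 = 1.0
            n1 = 1.0
        c = choices[t]
        if c == 0:
            out[t] = 0.0
            continue
        d = v0 - v1
        s = 1.0 if c == 1 else -1.0
        m = beta * s * (d - alpha)
        lp = _log_sigmoid(m)
        out[t] = lp
        total += lp
        o = float(outcomes[t])
        if c == 1:
            vc = v0
            vnc = v1
        else:
            vc = v1
            vnc = v0
        if code == RW:
            vc = vc + theta[0] * (o - vc)
        elif code == RP:
            rate = theta[0] if o > 0.0 else theta[1]
            vc = vc + rate * (o - vc)
        elif code == EWA:
            phi = theta[0]
            rho = theta[1]
            nprev = n0 if c == 1 else n1
            nnew = nprev * rho + 1.0
            vc = (vc * phi * nprev + o) / nnew
            if c == 1:
                n0 = nnew
            else:
                n1 = nnew
        elif code == FU:
            eta = theta[0]
            vc_prev = vc
            vc = vc + eta * (o - vc)
            ref = vc_prev if fic_chosen == 1 else vnc
            vnc = vnc + eta * (-o - ref)
        else:  # FU_RP, FU_RP_IP
            rate_c = theta[0] if o > 0.0 else theta[1]
            if rate_per_option == 1:
                rate_o = theta[0] if -o > 0.0 else theta[1]
            else:
                rate_o = rate_c
            vc_prev = vc
            vc = vc + rate_c * (o - vc)
            ref = vc_prev if fic_chosen == 1 else vnc
            vnc = vnc + rate_o * (-o - ref)
        if c == 1:
            v0 = vc
            v1 = vnc
        else:
            v1 = vc
            v0 = vnc
    return total


@njit(cache=False, fastmath=True)
def _grad_rw_fu(theta, choices, outcomes, resets, is_fu, fic_chosen, grad):
    """RW and FU: one learning rate (slot 0), beta in slot 1."""
    eta = theta[0]
    beta = theta[1]
    v0 = 0.0
    v1 = 0.0
    g0 = 0.0  # dV0/deta
    g1 = 0.0  # dV1/deta
    total = 0.0
    for t in range(choices.shape[0]):
        if resets[t] == 1:
            v0 = 0.0
            v1 = 0.0
            g0 = 0.0
            g1 = 0.0
        c = choices[t]
        if c == 0:
            continue
        s = 1.0 if c == 1 else -1.0
        md = s * (v0 - v1)
        m = beta * md
        lp, w = _logsig_and_weight(m)
        total += lp
        grad[1] += w * md
        grad[0] += w * beta * s * (g0 - g1)
        o = float(outcomes[t])
        if c == 1:
            vc, vo, gc, go = v0, v1, g0, g1
        else:
            vc, vo, gc, go = v1, v0, g1, g0
        pe = o - vc
        vc_prev = vc
        gc_prev = gc
        vc = vc + eta * pe
        gc = (1.0 - eta) * gc + pe
        if is_fu == 1:
            if fic_chosen == 1:
                pe_o = -o - vc_prev
                vo = vo + eta * pe_o
                go = go + pe_o - eta * gc_prev
            else:
                pe_o = -o - vo
                vo = vo + eta * pe_o
                go = (1.0 - eta) * go + pe_o
        if c == 1:
            v0, v1, g0, g1 = vc, vo, gc, go
        else:
            v1, v0, g1, g0 = vc, vo, gc, go
    return total


@njit(cache=False, fastmath=True)
def _grad_rp_family(theta, choices, outcomes, resets, fictitious, has_ip, fic_chosen,
                    rate_per_option, grad):
    """RP, FU_RP, FU_RP_IP: rates in slots 0-1, beta slot 2, alpha slot 3."""
    beta = theta[2]
    alpha = theta[3] if has_ip == 1 else 0.0
    v0 = 0.0
    v1 = 0.0
    # dV{0,1}/d{eta_pos, eta_neg}
    g00 = 0.0
    g01 = 0.0
    g10 = 0.0
    g11 = 0.0
    total = 0.0
    for t in range(choices.shape[0]):
        if resets[t] == 1:
            v0 = 0.0
            v1 = 0.0
            g00 = 0.0
            g01 = 0.0
            g10 = 0.0
            g11 = 0.0
        c = choices[t]
        if c == 0:
            continue
        s = 1.0 if c == 1 else -1.0
        md = s * (v0 - v1 - alpha)
        m = beta * md
        lp, w = _logsig_and_weight(m)
        total += lp
        grad[2] += w * md
        if has_ip == 1:
            grad[3] -= w * beta * s
        ws = w * beta * s
        grad[0] += ws * (g00 - g10)
        grad[1] += ws * (g01 - g11)
        o = float(outcomes[t])
        if c == 1:
            vc, vo = v0, v1
            gc0, gc1, go0, go1 = g00, g01, g10, g11
        else:
            vc, vo = v1, v0
            gc0, gc1, go0, go1 = g10, g11, g00, g01
        ri_c = 0 if o > 0.0 else 1
        rate_c = theta[ri_c]
        pe = o - vc
        vc_prev = vc
        gc0_prev = gc0
        gc1_prev = gc1
        vc = vc + rate_c * pe
        gc0 = (1.0 - rate_c) * gc0
        gc1 = (1.0 - rate_c) * gc1
        if ri_c == 0:
            gc0 += pe
        else:
            gc1 += pe
        if fictitious == 1:
            if rate_per_option == 1:
                ri_o = 0 if -o > 0.0 else 1
            else:
                ri_o = ri_c
            rate_o = theta[ri_o]
            if fic_chosen == 1:
                pe_o = -o - vc_prev
                vo = vo + rate_o * pe_o
                go0 = go0 - rate_o * gc0_prev
                go1 = go1 - rate_o * gc1_prev
            else:
                pe_o = -o - vo
                vo = vo + rate_o * pe_o
                go0 = (1.0 - rate_o) * go0
                go1 = (1.0 - rate_o) * go1
            if ri_o == 0:
                go0 += pe_o
            else:
                go1 += pe_o
        if c == 1:
            v0, v1 = vc, vo
            g00, g01, g10, g11 = gc0, gc1, go0, go1
        else:
            v1, v0 = vc, vo
            g10, g11, g00, g01 = gc0, gc1, go0, go1
    return total


@njit(cache=False, fastmath=True)
def _grad_ewa(theta, choices, outcomes, resets, grad):
    """EWA: phi slot 0, rho slot 1, beta slot 2."""
    phi = theta[0]
    rho = theta[1]
    beta = theta[2]
    v0 = 0.0
    v1 = 0.0
    n0 = 1.0
    n1 = 1.0
    dn0 = 0.0  # dn/drho
    dn1 = 0.0
    g0p = 0.0  # dV0/dphi
    g0r = 0.0  # dV0/drho
    g1p = 0.0
    g1r = 0.0
    total = 0.0
    for t in range(choices.shape[0]):
        if resets[t] == 1:
            v0 = 0.0
            v1 = 0.0
            n0 = 1.0
            n1 = 1.0
            dn0 = 0.0
            dn1 = 0.0
            g0p = 0.0
            g0r = 0.0
            g1p = 0.0
            g1r = 0.0
        c = choices[t]
        if c == 0:
            continue
        s = 1.0 if c == 1 else -1.0
        md = s * (v0 - v1)
        m = beta * md
        lp, w = _logsig_and_weight(m)
        total += lp
        grad[2] += w * md
        ws = w * beta * s
        grad[0] += ws * (g0p - g1p)
        grad[1] += ws * (g0r - g1r)
        o = float(outcomes[t])
        if c == 1:
            vc, nprev, dnprev, gp, gr = v0, n0, dn0, g0p, g0r
        else:
            vc, nprev, dnprev, gp, gr = v1, n1, dn1, g1p, g1r
        nnew = nprev * rho + 1.0
        dnnew = dnprev * rho + nprev
        a = vc * phi * nprev + o
        da_dphi = gp * phi * nprev + vc * nprev
        da_drho = gr * phi * nprev + vc * phi * dnprev
        vnew = a / nnew
        gp = da_dphi / nnew
        gr = da_drho / nnew - vnew * dnnew / nnew
        if c == 1:
            v0, n0, dn0, g0p, g0r = vnew, nnew, dnnew, gp, gr
        else:
            v1, n1, dn1, g1p, g1r = vnew, nnew, dnnew, gp, gr
    return total


@njit(cache=False, fastmath=True)
def subject_loglik_grad(code, theta, choices, outcomes, resets, fic_chosen, rate_per_option, grad):
    """Log-likelihood and its gradient w.r.t. the natural parameters.

    ``grad`` (length MAX_PARAMS) is overwritten; entries beyond the model's
    parameter count stay 0.
    """
    for k in range(MAX_PARAMS):
        grad[k] = 0.0
    if code == RW:
        return _grad_rw_fu(theta, choices, outcomes, resets, 0, fic_chosen, grad)
    if code == FU:
        return _grad_rw_fu(theta, choices, outcomes, resets, 1, fic_chosen, grad)
    if code == RP:
        return _grad_rp_family(theta, choices, outcomes, resets, 0, 0, fic_chosen,
                               rate_per_option, grad)
    if code == FU_RP:
        return _grad_rp_family(theta, choices, outcomes, resets, 1, 0, fic_chosen,
                               rate_per_option, grad)
    if code == FU_RP_IP:
        return _grad_rp_family(theta, choices, outcomes, resets, 1, 1, fic_chosen,
                               rate_per_option, grad)
    return _grad_ewa(theta, choices, outcomes, resets, grad)


@njit(cache=False, fastmath=True)
def cohort_loglik_grad(code, thetas, choices, outcomes, resets, fic_chosen,
                       rate_per_option, ll_out, grads_out):
    """Batched per-subject log-likelihoods and gradients (one kernel call per
    potential evaluation inside HMC)."""
    for i in range(thetas.shape[0]):
        ll_out[i] = subject_loglik_grad(
            code, thetas[i], choices[i], outcomes[i], resets[i], fic_chosen,
            rate_per_option, grads_out[i],
        )


@njit(cache=False, fastmath=True)
def cohort_pointwise(code, thetas, choices, outcomes, resets, fic_chosen,
                     rate_per_option, out):
    """Per-subject, per-trial log-likelihoods for one parameter draw."""
    for i in range(thetas.shape[0]):
        subject_loglik_pointwise(
            code, thetas[i], choices[i], outcomes[i], resets[i], fic_chosen,
            rate_per_option, out[i],
        )
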