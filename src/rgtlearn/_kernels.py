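"""Numba-compiled likelihood and gradient kernels.

All kernels operate on a flat trial representation: ``choices`` (int64
option index 0-3), ``is_win`` (int64 flag), ``rewards`` (pellets on
wins), ``penalties`` (time-out seconds on losses), with per-subject
contiguous blocks delimited by ``offsets``.

Model codes and constrained-parameter layouts (fixed order):

====  =============   =========================================
code  model           parameter vector
====  =============   =========================================
0     basic           [beta, eta+, eta-]
1     scaled          [beta, eta+, eta-, m]
2     scaled_offset   [beta, eta+, eta-, m, b]
3     nonlinear       [beta, eta+, eta-, b, r]
4     reward_scaled   [beta, eta+, eta-, m, mRew]
====  =============   =========================================

Unconstrained-to-constrained transform codes: 0 = exp (positive
parameters), 1 = standard-normal CDF (learning rates in [0, 1]),
2 = identity (the offset b).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)

MODEL_CODES = {
    "basic": 0,
    "scaled": 1,
    "scaled_offset": 2,
    "nonlinear": 3,
    "reward_scaled": 4,
}

#: number of parameters per model code
MODEL_K = np.array([3, 4, 5, 5, 5], dtype=np.int64)

#: transform code per parameter position, per model code (padded with -1)
MODEL_TRANSFORMS = np.array(
    [
        [0, 1, 1, -1, -1],  # basic
        [0, 1, 1, 0, -1],  # scaled
        [0, 1, 1, 0, 2],  # scaled_offset
        [0, 1, 1, 2, 0],  # nonlinear
        [0, 1, 1, 0, 0],  # reward_scaled
    ],
    dtype=np.int64,
)

#: constrained-parameter names per model code
MODEL_PARAM_NAMES = {
    0: ("beta", "eta_plus", "eta_minus"),
    1: ("beta", "eta_plus", "eta_minus", "m"),
    2: ("beta", "eta_plus", "eta_minus", "m", "b"),
    3: ("beta", "eta_plus", "eta_minus", "b", "r"),
    4: ("beta", "eta_plus", "eta_minus", "m", "m_rew"),
}


@njit(cache=True, inline="always")
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True, inline="always")
def _loss_target(model, p, t):
    """Pellet-equivalent target value of a loss of duration ``t`` seconds."""
    if model == 0:
        return 0.0
    elif model == 1 or model == 4:
        return -p[3] * t
    elif model == 2:
        return p[4] - p[3] * t
    else:  # nonlinear
        return p[3] - t ** p[4]


@njit(cache=True)
def _subject_pointwise(p, model, choices, is_win, rewards, penalties, out):
    """Per-trial log-likelihoods for one subject; Q starts at zero."""
    beta = p[0]
    ep = p[1]
    em = p[2]
    q = np.zeros(4)
    n = choices.shape[0]
    for t in range(n):
        c = choices[t]
        vmax = beta * q[0]
        for x in range(1, 4):
            v = beta * q[x]
            if v > vmax:
                vmax = v
        z = 0.0
        for x in range(4):
            z += math.exp(beta * q[x] - vmax)
        out[t] = beta * q[c] - vmax - math.log(z)
        if is_win[t] == 1:
            tgt = rewards[t]
            if model == 4:
                tgt = p[4] * rewards[t]
            q[c] += ep * (tgt - q[c])
        else:
            tgt = _loss_target(model, p, penalties[t])
            q[c] += em * (tgt - q[c])
    return out


@njit(cache=True)
def _subject_ll_grad(p, K, model, choices, is_win, rewards, penalties, grad):
    """Total log-likelihood and gradient w.r.t. constrained parameters.

    ``grad`` (length K) is overwritten.  Gradients are propagated through
    the Q recursion: dQ holds dQ[x]/dp[j] for j >= 1 (beta does not enter
    the updates).
    """
    beta = p[0]
    ep = p[1]
    em = p[2]
    q = np.zeros(4)
    dq = np.zeros((4, K))
    for j in range(K):
        grad[j] = 0.0
    ll = 0.0
    n = choices.shape[0]
    probs = np.empty(4)
    for t in range(n):
        c = choices[t]
        vmax = beta * q[0]
        for x in range(1, 4):
            v = beta * q[x]
            if v > vmax:
                vmax = v
        z = 0.0
        for x in range(4):
            probs[x] = math.exp(beta * q[x] - vmax)
            z += probs[x]
        ll += beta * q[c] - vmax - math.log(z)
        pq = 0.0
        for x in range(4):
            probs[x] /= z
            pq += probs[x] * q[x]
        grad[0] += q[c] - pq
        for j in range(1, K):
            pd = 0.0
            for x in range(4):
                pd += probs[x] * dq[x, j]
            grad[j] += beta * (dq[c, j] - pd)
        # delta-rule update of the chosen option only
        q_old = q[c]
        if is_win[t] == 1:
            tgt = rewards[t]
            if model == 4:
                tgt = p[4] * rewards[t]
            q[c] = q_old + ep * (tgt - q_old)
            for j in range(1, K):
                nd = (1.0 - ep) * dq[c, j]
                if j == 1:
                    nd += tgt - q_old
                if model == 4 and j == 4:
                    nd += ep * rewards[t]
                dq[c, j] = nd
        else:
            tt = penalties[t]
            tgt = _loss_target(model, p, tt)
            q[c] = q_old + em * (tgt - q_old)
            for j in range(1, K):
                nd = (1.0 - em) * dq[c, j]
                if j == 2:
                    nd += tgt - q_old
                # d target / d p[j]
                if model == 1 or model == 4:
                    if j == 3:
                        nd += em * (-tt)
                elif model == 2:
                    if j == 3:
                        nd += em * (-tt)
                    elif j == 4:
                        nd += em
                elif model == 3:
                    if j == 3:
                        nd += em
                    elif j == 4:
                        nd += em * (-(tt ** p[4]) * math.log(tt))
                dq[c, j] = nd
    return ll


@njit(cache=True)
def _hier_logp_grad_mixed(
    theta,
    model,
    K,
    n_sub,
    offsets,
    choices,
    is_win,
    rewards,
    penalties,
    tcodes,
    mu_prior_sd,
    sigma_prior_sd,
    cent,
):
    """Hierarchical posterior with per-parameter centering.

    ``cent[k] == 1``: the subject block stores u_sk directly with prior
    Normal(mu_k, sigma_k) (centered; best when the data pin u_sk).
    ``cent[k] == 0``: the block stores z_sk ~ Normal(0, 1) and
    u_sk = mu_k + sigma_k * z_sk (noncentered; best when u_sk is weakly
    identified and the group SD can approach zero).  Both express the
    same posterior.
    """
    dim = theta.shape[0]
    grad = np.zeros(dim)
    logp = 0.0
    mu = theta[:K]
    sigma = np.empty(K)
    for k in range(K):
        ls = theta[K + k]
        if ls > 40.0:  # keep exp() finite; such points are rejected anyway
            ls = 40.0
        elif ls < -40.0:
            ls = -40.0
        s = math.exp(ls)
        sigma[k] = s
        sp = sigma_prior_sd[k]
        logp += -0.5 * (s / sp) ** 2 + ls
        grad[K + k] += -(s / sp) ** 2 + 1.0
        logp += -0.5 * (mu[k] / mu_prior_sd[k]) ** 2
        grad[k] += -mu[k] / (mu_prior_sd[k] ** 2)

    cpar = np.empty(K)
    dcdu = np.empty(K)
    gc = np.empty(K)
    for s_i in range(n_sub):
        base = 2 * K + s_i * K
        for k in range(K):
            x = theta[base + k]
            if cent[k] == 1:
                u = x
                dev = (u - mu[k]) / sigma[k]
                logp += -0.5 * dev * dev - math.log(sigma[k])
                grad[base + k] += -dev / sigma[k]
                grad[k] += dev / sigma[k]
                grad[K + k] += dev * dev - 1.0
            else:
                logp += -0.5 * x * x
                grad[base + k] += -x
                u = mu[k] + sigma[k] * x
            tc = tcodes[k]
            if tc == 0:
                c = math.exp(u)
                cpar[k] = c
                dcdu[k] = c
            elif tc == 1:
                cpar[k] = _norm_cdf(u)
                dcdu[k] = INV_SQRT_2PI * math.exp(-0.5 * u * u)
            else:
                cpar[k] = u
                dcdu[k] = 1.0
        lo = offsets[s_i]
        hi = offsets[s_i + 1]
        ll = _subject_ll_grad(
            cpar, K, model, choices[lo:hi], is_win[lo:hi],
            rewards[lo:hi], penalties[lo:hi], gc,
        )
        logp += ll
        for k in range(K):
            gu = gc[k] * dcdu[k]
            if cent[k] == 1:
                grad[base + k] += gu
            else:
                z = theta[base + k]
                grad[base + k] += gu * sigma[k]
                grad[k] += gu
                grad[K + k] += gu * sigma[k] * z
    return logp, grad


@njit(cache=True)
def _pointwise_matrix(cdraws, model, n_sub, offsets, choices, is_win, rewards, penalties):
    """Pointwise log-likelihood matrix over posterior draws.

    cdraws: (n_draws, n_sub, K) constrained subject parameters.
    Returns (n_draws, n_trials).
    """
    n_draws = cdraws.shape[0]
    n_trials = choices.shape[0]
    out = np.empty((n_draws, n_trials))
    for d in range(n_draws):
        for s_i in range(n_sub):
            lo = offsets[s_i]
            hi = offsets[s_i + 1]
            _subject_pointwise(
                cdraws[d, s_i], model, choices[lo:hi], is_win[lo:hi],
                rewards[lo:hi], penalties[lo:hi], out[d, lo:hi],
            )
    return out
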