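"""Per-trial likelihood/gradient kernels for the hierarchical model.

Two interchangeable implementations of the same computation: a vectorised
numpy reference and a numba-compiled single-pass loop used when numba is
available.  Both take the full (6, n_subjects) subject-value matrix in the
fixed row layout below (inactive rows are zero) and return the summed
Bernoulli log-likelihood and its gradient with respect to every entry.

Row layout: 0 log k, 1 S_k, 2 beta, 3 S_beta, 4 logit omega, 5 S_logit_omega.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

EXP_CLIP = 30.0

ROW_LOG_K, ROW_S_K, ROW_BETA, ROW_S_BETA, ROW_LAM, ROW_S_LAM = range(6)


def loglik_grad_numpy(val, ll_amount, delay, i_ero, sign, ss, subj,
                      has_offset, has_shifts):
    """Reference implementation: summed log-lik and (6, n) gradient."""
    n = val.shape[1]
    logk_t = val[ROW_LOG_K][subj]
    beta_t = val[ROW_BETA][subj]
    if has_shifts:
        logk_t = logk_t + i_ero * val[ROW_S_K][subj]
        beta_t = beta_t + i_ero * val[ROW_S_BETA][subj]
    arg = np.clip(logk_t, -EXP_CLIP, EXP_CLIP)
    clip_mask = np.abs(logk_t) < EXP_CLIP
    k = np.exp(arg)
    denom = 1.0 + k * delay
    h = ll_amount / denom
    if has_offset:
        lam_t = val[ROW_LAM][subj]
        if has_shifts:
            lam_t = lam_t + i_ero * val[ROW_S_LAM][subj]
        w = expit(lam_t)
        sv = w * h
    else:
        sv = h
    delta = sv - ss
    x = sign * beta_t * delta
    logp = float(-np.logaddexp(0.0, -x).sum())

    g_x = expit(-x)
    g_beta_t = g_x * sign * delta
    g_delta = g_x * sign * beta_t
    if has_offset:
        g_w = g_delta * h
        g_lam_t = g_w * w * (1.0 - w)
        g_h = g_delta * w
    else:
        g_h = g_delta
    g_k = -g_h * h * delay / denom
    g_arg = g_k * k * clip_mask

    g = np.zeros_like(val)
    g[ROW_LOG_K] = np.bincount(subj, g_arg, minlength=n)
    g[ROW_BETA] = np.bincount(subj, g_beta_t, minlength=n)
    if has_shifts:
        g[ROW_S_K] = np.bincount(subj, g_arg * i_ero, minlength=n)
        g[ROW_S_BETA] = np.bincount(subj, g_beta_t * i_ero, minlength=n)
    if has_offset:
        g[ROW_LAM] = np.bincount(subj, g_lam_t, minlength=n)
        if has_shifts:
            g[ROW_S_LAM] = np.bincount(subj, g_lam_t * i_ero, minlength=n)
    return logp, g


def _make_numba_kernel():
    from numba import njit

    # the condition-modulated parameters take only 2 values per subject, so
    # all exp/logistic transforms except the choice rule are hoisted out of
    # the trial loop; fastmath stays off so draws are reproducible across
    # machines (reassociation would make results depend on SIMD width)
    @njit(cache=True, fastmath=False)
    def kernel(val, ll_amount, delay, i_ero, sign, ss, subj,
               has_offset, has_shifts):
        T = ll_amount.size
        n = val.shape[1]
        k2 = np.empty((2, n))
        beta2 = np.empty((2, n))
        w2 = np.ones((2, n))
        clip2 = np.zeros((2, n), np.bool_)
        for j in range(n):
            for i in range(2):
                fi = float(i) if has_shifts else 0.0
                logk = val[0, j] + fi * val[1, j]
                clip2[i, j] = abs(logk) >= EXP_CLIP
                k2[i, j] = np.exp(min(max(logk, -EXP_CLIP), EXP_CLIP))
                beta2[i, j] = val[2, j] + fi * val[3, j]
                if has_offset:
                    lam = val[4, j] + fi * val[5, j]
                    w2[i, j] = 1.0 / (1.0 + np.exp(-lam))
        g_karg = np.zeros((2, n))
        g_beta = np.zeros((2, n))
        g_lam = np.zeros((2, n))
        logp = 0.0
        for t in range(T):
            j = subj[t]
            i = 1 if i_ero[t] > 0.0 else 0
            k = k2[i, j]
            beta = beta2[i, j]
            w = w2[i, j]
            denom = 1.0 + k * delay[t]
            h = ll_amount[t] / denom
            delta = w * h - ss[t]
            x = sign[t] * beta * delta
            if x >= 0.0:
                e = np.exp(-x)
                logp += -np.log1p(e)
                g_x = e / (1.0 + e)
            else:
                e = np.exp(x)
                logp += x - np.log1p(e)
                g_x = 1.0 / (1.0 + e)
            g_beta[i, j] += g_x * sign[t] * delta
            g_delta = g_x * sign[t] * beta
            if has_offset:
                g_lam[i, j] += g_delta * h * w * (1.0 - w)
                g_h = g_delta * w
            else:
                g_h = g_delta
            if not clip2[i, j]:
                g_karg[i, j] += -g_h * h * delay[t] / denom * k
        g = np.zeros_like(val)
        for j in range(n):
            g[0, j] = g_karg[0, j] + g_karg[1, j]
            g[2, j] = g_beta[0, j] + g_beta[1, j]
            if has_shifts:
                g[1, j] = g_karg[1, j]
                g[3, j] = g_beta[1, j]
            if has_offset:
                g[4, j] = g_lam[0, j] + g_lam[1, j]
                if has_shifts:
                    g[5, j] = g_lam[1, j]
        return logp, g

    return kernel


try:
    loglik_grad_fast = _make_numba_kernel()
except ImportError:  # pragma: no cover - numba is an expected dependency
    loglik_grad_fast = loglik_grad_numpy
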