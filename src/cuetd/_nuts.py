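"""No-U-turn sampler with dual-averaging step-size and diagonal mass adaptation.

A generic gradient-based MCMC backend: the caller supplies a callable
returning the unnormalised log density and its gradient at a point in the
unconstrained parameter space.  The sampler is the dynamic-trajectory
Hamiltonian Monte Carlo variant that doubles the trajectory until the path
starts to double back on itself (the "no-U-turn" criterion), with slice
sampling across the trajectory, dual averaging of the step size towards a
target acceptance statistic, and a diagonal mass matrix estimated from the
warmup draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsStats", "sample_nuts"]

DELTA_MAX = 1000.0  # slice divergence threshold


@dataclass
class NutsStats:
    step_size: float = np.nan
    n_divergent: int = 0
    mean_accept: float = np.nan
    mean_treedepth: float = np.nan
    inv_mass: np.ndarray = None
    divergent: np.ndarray = field(default=None)  # per retained draw


def _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = logp_and_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, grad, logp


def _kinetic(r, inv_mass):
    return 0.5 * np.dot(r * r, inv_mass)


def _find_initial_step(logp_and_grad, theta, rng, inv_mass):
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    logp, grad = logp_and_grad(theta)
    h0 = logp - _kinetic(r, inv_mass)
    _, r1, _, logp1 = _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** a
        _, r1, _, logp1 = _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


class _Tree:
    """State bundle for the recursive trajectory doubling."""

    __slots__ = ("minus", "plus", "proposal", "n", "keep_going", "sum_accept",
                 "n_accept", "divergent")

    def __init__(self, minus, plus, proposal, n, keep_going, sum_accept,
                 n_accept, divergent):
        self.minus = minus          # (theta, r, grad) at backward end
        self.plus = plus            # (theta, r, grad) at forward end
        self.proposal = proposal    # (theta, logp)
        self.n = n                  # slice-acceptable states in subtree
        self.keep_going = keep_going
        self.sum_accept = sum_accept
        self.n_accept = n_accept
        self.divergent = divergent


def _no_uturn(minus, plus, inv_mass):
    dtheta = plus[0] - minus[0]
    return (np.dot(dtheta, inv_mass * minus[1]) >= 0.0
            and np.dot(dtheta, inv_mass * plus[1]) >= 0.0)


def _build_tree(logp_and_grad, state, logu, direction, depth, eps, h0,
                inv_mass, rng):
    if depth == 0:
        theta, r, grad, logp = _leapfrog(
            logp_and_grad, state[0], state[1], state[2], direction * eps,
            inv_mass)
        h = logp - _kinetic(r, inv_mass)
        if not np.isfinite(h):
            h = -np.inf
        n = int(logu <= h)
        divergent = logu - DELTA_MAX >= h
        accept = min(1.0, np.exp(min(h - h0, 0.0)))
        end = (theta, r, grad)
        return _Tree(end, end, (theta, logp, grad), n, not divergent, accept,
                     1, divergent)
    inner = _build_tree(logp_and_grad, state, logu, direction, depth - 1, eps,
                        h0, inv_mass, rng)
    if not inner.keep_going:
        return inner
    start = inner.minus if direction < 0 else inner.plus
    outer = _build_tree(logp_and_grad, start, logu, direction, depth - 1, eps,
                        h0, inv_mass, rng)
    if direction < 0:
        minus, plus = outer.minus, inner.plus
    else:
        minus, plus = inner.minus, outer.plus
    n = inner.n + outer.n
    proposal = inner.proposal
    if outer.n > 0 and rng.random() < outer.n / max(n, 1):
        proposal = outer.proposal
    keep_going = (outer.keep_going and _no_uturn(minus, plus, inv_mass))
    return _Tree(minus, plus, proposal, n, keep_going,
                 inner.sum_accept + outer.sum_accept,
                 inner.n_accept + outer.n_accept,
                 inner.divergent or outer.divergent)


def _adaptation_windows(n_warmup, init_buffer=75, term_buffer=50, base=25):
    """Iteration indices at which the mass matrix is (re-)estimated.

    Doubling memory windows: a step-size-only initial buffer, variance
    windows of doubling length (the last expanded to fill), and a final
    step-size-only buffer.
    """
    if n_warmup < init_buffer + term_buffer + 2 * base:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.1 * n_warmup))
        base = max(1, n_warmup - init_buffer - term_buffer)
    ends = []
    start, size = init_buffer, base
    while True:
        end = start + size
        if end + 2 * size > n_warmup - term_buffer:
            ends.append(n_warmup - term_buffer)
            break
        ends.append(end)
        start, size = end, 2 * size
    return init_buffer, ends


def sample_nuts(logp_and_grad, theta0, n_warmup, n_draws, rng,
                max_treedepth=10, target_accept=0.8):
    """Run one chain; returns (draws array (n_draws, dim), NutsStats).

    Warmup adapts the step size by dual averaging throughout and estimates
    the diagonal inverse mass from the warmup draws over doubling memory
    windows; each window end triggers a mass update and a step-size reset.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")

    # dual averaging state
    gamma, t0, kappa = 0.05, 10.0, 0.75
    eps = _find_initial_step(logp_and_grad, theta, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0

    # Welford accumulators for the mass matrix
    w_n, w_mean, w_m2 = 0, np.zeros(dim), np.zeros(dim)

    init_buffer, window_ends = _adaptation_windows(n_warmup)
    window_ends = set(window_ends)

    draws = np.empty((n_draws, dim))
    divergent_flags = np.zeros(n_draws, dtype=bool)
    accept_hist, depth_hist, n_div = [], [], 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(r0, inv_mass)
        logu = h0 - rng.exponential()
        minus = plus = (theta, r0, grad)
        prop_theta, prop_logp, prop_grad = theta, logp, grad
        n, depth, keep_going, divergent = 1, 0, True, False
        sum_accept, n_accept = 0.0, 0
        while keep_going and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            state = minus if direction < 0 else plus
            tree = _build_tree(logp_and_grad, state, logu, direction, depth,
                               eps, h0, inv_mass, rng)
            if direction < 0:
                minus = tree.minus
            else:
                plus = tree.plus
            sum_accept += tree.sum_accept
            n_accept += tree.n_accept
            divergent = divergent or tree.divergent
            if tree.keep_going and tree.n > 0:
                if rng.random() < min(1.0, tree.n / n):
                    prop_theta, prop_logp, prop_grad = tree.proposal
            n += tree.n
            keep_going = tree.keep_going and _no_uturn(minus, plus, inv_mass)
            depth += 1
        theta, logp, grad = prop_theta, prop_logp, prop_grad
        alpha = sum_accept / max(n_accept, 1)

        if warming:
            m_adapt += 1
            h_bar = ((1 - 1 / (m_adapt + t0)) * h_bar
                     + (target_accept - alpha) / (m_adapt + t0))
            log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
            eta = m_adapt ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if it >= init_buffer:
                w_n += 1
                delta = theta - w_mean
                w_mean += delta / w_n
                w_m2 += delta * (theta - w_mean)
            if (it + 1) in window_ends and w_n > 1:
                var = w_m2 / (w_n - 1)
                # regularise towards unit, as a guard against noisy estimates
                inv_mass = (w_n / (w_n + 5.0)) * var + 1e-3 * (5.0 / (w_n + 5.0))
                inv_mass = np.clip(inv_mass, 1e-10, None)
                w_n, w_mean, w_m2 = 0, np.zeros(dim), np.zeros(dim)
                eps = _find_initial_step(logp_and_grad, theta, rng, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            i = it - n_warmup
            draws[i] = theta
            divergent_flags[i] = divergent
            accept_hist.append(alpha)
            depth_hist.append(depth)
            n_div += int(divergent)

    stats = NutsStats(step_size=float(eps), n_divergent=n_div,
                      mean_accept=float(np.mean(accept_hist)),
                      mean_treedepth=float(np.mean(depth_hist)),
                      inv_mass=inv_mass, divergent=divergent_flags)
    return draws, stats
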