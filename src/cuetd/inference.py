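"""Hierarchical Bayesian estimation of the discounting models.

Both model variants share the same hierarchy: each subject-level parameter
family (log k, beta, their erotic shifts, and — for the offset model —
logit-omega and its shift) gets a group-level Gaussian with a Normal prior
on the group mean and a half-Normal(1) prior on the group SD.  Subject
effects use a non-centered parameterisation (subject value = mu + sigma * z,
z ~ N(0,1)), which removes the funnel geometry from the posterior.

The omega offset and its condition shift are composed on the logit scale and
mapped through the logistic function, so the effective per-condition offset
always lies in (0, 1) regardless of the shift draw.  The group-mean prior for
omega is Uniform(0,1) on the omega scale (a standard-logistic density after
the transform); the shift prior is Normal on the logit scale.

Sampling is by the in-package no-U-turn sampler with hand-derived analytic
gradients of the joint log posterior; convergence is gated on the
split-chain potential scale reduction factor (R-hat < 1.05 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _kernels
from ._nuts import sample_nuts
from .models import EXP_CLIP, ModelVariant
from .task import LL_CHOICE, SS_CHOICE

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "fit_model",
    "compute_rhat",
    "exclude_degenerate_subjects",
    "stack_datasets",
]

log = logging.getLogger(__name__)

# family order in the unconstrained parameter vector
FAMILIES = ("log_k_neut", "s_ero_k", "beta_neut", "s_ero_beta",
            "logit_omega_neut", "s_ero_logit_omega")
SHIFT_FAMILIES = {"s_ero_k", "s_ero_beta", "s_ero_logit_omega"}
OMEGA_FAMILIES = {"logit_omega_neut", "s_ero_logit_omega"}


@dataclass
class PriorSpec:
    """Group-level priors.  Each normal entry is (mean, sd).

    ``omega`` is the Uniform bound pair for the group-mean offset (only
    (0, 1) is supported); ``s_ero_omega`` is Normal on the logit-shift
    scale.  ``group_sd_scale`` is the half-Normal scale shared by all
    group-SD priors.
    """

    log_k: tuple = (-4.2, 2.01)
    s_ero_k: tuple = (0.15, 0.64)
    beta: tuple = (0.51, 0.3)
    s_ero_beta: tuple = (0.02, 0.11)
    omega: tuple = (0.0, 1.0)
    s_ero_omega: tuple = (0.0, 0.4)
    group_sd_scale: float = 1.0

    def mean_prior(self, family: str):
        """(mean, sd) of the Normal prior on the group mean, or None for omega."""
        return {
            "log_k_neut": self.log_k,
            "s_ero_k": self.s_ero_k,
            "beta_neut": self.beta,
            "s_ero_beta": self.s_ero_beta,
            "logit_omega_neut": None,  # uniform(0,1) via logistic transform
            "s_ero_logit_omega": self.s_ero_omega,
        }[family]


@dataclass
class SamplerConfig:
    """MCMC settings.  ``n_retained`` is the total post-warmup draw count
    across chains (4 chains x 1000 = 4000 by default)."""

    n_chains: int = 4
    n_warmup: int = 1500
    n_retained: int = 4000
    seed: int = 0
    rhat_threshold: float = 1.05
    max_treedepth: int = 10
    # 0.9 rather than the generic 0.8: hierarchical posteriors with group-SD
    # parameters mix noticeably better at a higher acceptance target
    target_accept: float = 0.9
    divergence_warn_frac: float = 0.02

    @property
    def draws_per_chain(self) -> int:
        return self.n_retained // self.n_chains

    @classmethod
    def reduced(cls, seed: int = 0) -> "SamplerConfig":
        """Desk-scale config: 2 chains, 400 warmup, 400 draws per chain."""
        return cls(n_chains=2, n_warmup=400, n_retained=800, seed=seed)


@dataclass
class ConvergenceReport:
    rhat: dict
    ess: dict
    passed: bool
    rhat_threshold: float
    zero_variance: list = field(default_factory=list)
    n_divergent: int = 0
    divergence_frac: float = 0.0

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["max_rhat"] = self.max_rhat
        return d


@dataclass
class PosteriorDraws:
    """Posterior draws plus everything needed downstream.

    ``params``: name -> (chain, draw) array, covering group means/SDs and
    per-subject parameters (named e.g. ``log_k_neut[s03]``).
    ``subject_params``: family -> (chain, draw, subject) array.
    ``pointwise_loglik``: (chain, draw, trial) per-trial log-likelihoods
    for WAIC.  ``trial_info`` describes the trials in the same order.
    """

    params: dict
    subject_params: dict
    subject_ids: list
    variant: ModelVariant
    trial_info: pd.DataFrame
    pointwise_loglik: np.ndarray
    config: SamplerConfig
    priors: PriorSpec
    sampler_stats: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        return self.params[name].reshape(-1)

    def loglik_matrix(self) -> np.ndarray:
        """(total draws, trials) pointwise log-likelihood matrix."""
        c, d, t = self.pointwise_loglik.shape
        return self.pointwise_loglik.reshape(c * d, t)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.params.items():
            c, d = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "iteration": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# data stacking

@dataclass
class _StackedData:
    ll_amount: np.ndarray
    delay: np.ndarray
    i_ero: np.ndarray
    sign: np.ndarray       # +1 for LL choice, -1 for SS
    subj: np.ndarray
    ss_amount: np.ndarray
    subject_ids: list
    trial_info: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def stack_datasets(datasets) -> _StackedData:
    """Flatten a ChoiceDataset collection into trial arrays (INVALID dropped)."""
    subject_ids = sorted({d.subject_id for d in datasets})
    sindex = {s: i for i, s in enumerate(subject_ids)}
    rows = []
    for d in datasets:
        for i in d.valid_indices():
            t = d.trials[i]
            rows.append((d.subject_id, sindex[d.subject_id], d.condition_label,
                         t.i_ero, t.ll_amount, t.delay_days, d.ss_amount,
                         1.0 if d.choices[i] == LL_CHOICE else -1.0))
    if not rows:
        raise ValueError("no valid trials in any dataset")
    info = pd.DataFrame(rows, columns=[
        "subject_id", "subject_index", "condition", "i_ero", "ll_amount",
        "delay_days", "ss_amount", "choice_sign"])
    return _StackedData(
        ll_amount=info["ll_amount"].to_numpy(float),
        delay=info["delay_days"].to_numpy(float),
        i_ero=info["i_ero"].to_numpy(float),
        sign=info["choice_sign"].to_numpy(float),
        subj=info["subject_index"].to_numpy(np.int64),
        ss_amount=info["ss_amount"].to_numpy(float),
        subject_ids=subject_ids,
        trial_info=info,
    )


# ---------------------------------------------------------------------------
# joint log posterior with analytic gradient

class _HierarchicalPosterior:
    """Unconstrained-space log posterior of the hierarchical model.

    Parameter vector layout: [mu_f] + [log sigma_f] + [z_f,subject]
    with families in FAMILIES order restricted to those active for the
    variant (base drops the omega families) and the data (shift families
    are dropped when the data contain a single condition — their draws are
    then exactly zero by construction).
    """

    def __init__(self, data: _StackedData, variant: ModelVariant,
                 priors: PriorSpec, kernel=None):
        if tuple(priors.omega) != (0.0, 1.0):
            raise NotImplementedError("only Uniform(0,1) omega prior supported")
        self.data = data
        self.variant = variant
        self.priors = priors
        self.has_shifts = bool(np.any(data.i_ero > 0) and np.any(data.i_ero == 0))
        fams = [f for f in FAMILIES
                if (variant.has_offset or f not in OMEGA_FAMILIES)
                and (self.has_shifts or f not in SHIFT_FAMILIES)]
        self.families = fams
        self.F = len(fams)
        self.n = data.n_subjects
        self.dim = 2 * self.F + self.F * self.n
        self._fi = {f: i for i, f in enumerate(fams)}
        # row indices of the active families in the fixed 6-row kernel layout
        self._rows = np.array([FAMILIES.index(f) for f in fams])
        self._kernel = kernel if kernel is not None else _kernels.loglik_grad_fast
        norm = [(i, *priors.mean_prior(f)) for i, f in enumerate(fams)
                if priors.mean_prior(f) is not None]
        self._norm_idx = np.array([i for i, _, _ in norm], dtype=int)
        self._norm_m = np.array([m for _, m, _ in norm])
        self._norm_s = np.array([s for _, _, s in norm])
        self._logistic_idx = (fams.index("logit_omega_neut")
                              if "logit_omega_neut" in fams else -1)

    def unpack(self, q):
        F, n = self.F, self.n
        mu = q[:F]
        logsig = q[F:2 * F]
        z = q[2 * F:].reshape(F, n)
        return mu, logsig, z

    def initial_point(self, rng) -> np.ndarray:
        mu0 = []
        for f in self.families:
            pr = self.priors.mean_prior(f)
            mu0.append(0.0 if pr is None else pr[0])
        q = np.concatenate([
            np.asarray(mu0),
            np.full(self.F, np.log(0.3)),
            np.zeros(self.F * self.n),
        ])
        return q + 0.1 * rng.standard_normal(q.size)

    def subject_values(self, mu, logsig, z):
        return mu[:, None] + np.exp(logsig)[:, None] * z  # (F, n)

    def logp_and_grad(self, q):
        d = self.data
        mu, logsig, z = self.unpack(q)
        sigma = np.exp(logsig)
        val = mu[:, None] + sigma[:, None] * z          # (F, n)
        full = np.zeros((6, self.n))
        full[self._rows] = val
        logp, g_full = self._kernel(
            full, d.ll_amount, d.delay, d.i_ero, d.sign, d.ss_amount, d.subj,
            self.variant.has_offset, self.has_shifts)
        g_val = g_full[self._rows]

        # chain rule through the non-centered parameterisation
        g_mu = g_val.sum(axis=1)
        g_logsig = (g_val * z).sum(axis=1) * sigma
        g_z = g_val * sigma[:, None]

        # priors
        sd_scale = self.priors.group_sd_scale
        zscore = (mu[self._norm_idx] - self._norm_m) / self._norm_s
        logp += float(-0.5 * np.sum(zscore ** 2))
        g_mu[self._norm_idx] += -zscore / self._norm_s
        li = self._logistic_idx
        if li >= 0:  # uniform(0,1) on expit(mu): standard-logistic in mu
            logp += -np.logaddexp(0.0, mu[li]) - np.logaddexp(0.0, -mu[li])
            g_mu[li] += 1.0 - 2.0 * expit(mu[li])
        logp += float(np.sum(-0.5 * (sigma / sd_scale) ** 2 + logsig))
        g_logsig += -(sigma / sd_scale) ** 2 + 1.0
        logp += float(np.sum(-0.5 * z * z))
        g_z += -z

        grad = np.concatenate([g_mu, g_logsig, g_z.reshape(-1)])
        return logp, grad

    # ------------------------------------------------------------------
    def pointwise_loglik(self, subject_values_by_family):
        """(S, T) log-lik for a stack of S subject-parameter draws.

        ``subject_values_by_family``: family -> (S, n) array on the
        sampler's native scales (missing families treated as absent).
        """
        d = self.data
        sv = subject_values_by_family
        subj = d.subj
        I = d.i_ero
        logk_t = sv["log_k_neut"][:, subj]
        beta_t = sv["beta_neut"][:, subj]
        if "s_ero_k" in sv:
            logk_t = logk_t + I * sv["s_ero_k"][:, subj]
            beta_t = beta_t + I * sv["s_ero_beta"][:, subj]
        k = np.exp(np.clip(logk_t, -EXP_CLIP, EXP_CLIP))
        h = d.ll_amount / (1.0 + k * d.delay)
        if "logit_omega_neut" in sv:
            lam_t = sv["logit_omega_neut"][:, subj]
            if "s_ero_logit_omega" in sv:
                lam_t = lam_t + I * sv["s_ero_logit_omega"][:, subj]
            svll = expit(lam_t) * h
        else:
            svll = h
        x = d.sign * beta_t * (svll - d.ss_amount)
        return -np.logaddexp(0.0, -x)


# ---------------------------------------------------------------------------

def fit_model(datasets, variant, priors: PriorSpec = None,
              config: SamplerConfig = None):
    """Fit one model variant to a ChoiceDataset collection.

    Returns ``(PosteriorDraws, ConvergenceReport)``.  A convergence failure
    (any split-chain R-hat at or above the threshold) flags the report but
    the draws are still returned.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    data = stack_datasets(datasets)
    if data.n_subjects < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    post = _HierarchicalPosterior(data, variant, priors)

    seed_seq = np.random.SeedSequence(config.seed)
    chain_draws, stats_list = [], []
    for c, child in enumerate(seed_seq.spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        q0 = post.initial_point(rng)
        draws, stats = sample_nuts(
            post.logp_and_grad, q0, config.n_warmup, config.draws_per_chain,
            rng, max_treedepth=config.max_treedepth,
            target_accept=config.target_accept)
        chain_draws.append(draws)
        stats_list.append(stats)
        log.info("chain %d: step=%.4g accept=%.2f depth=%.1f divergent=%d",
                 c, stats.step_size, stats.mean_accept, stats.mean_treedepth,
                 stats.n_divergent)
    raw = np.stack(chain_draws)            # (C, D, dim)
    C, D, _ = raw.shape
    F, n = post.F, post.n

    mu = raw[:, :, :F]
    sigma = np.exp(raw[:, :, F:2 * F])
    z = raw[:, :, 2 * F:].reshape(C, D, F, n)
    subj_vals = mu[:, :, :, None] + sigma[:, :, :, None] * z   # (C, D, F, n)

    params, subject_params = {}, {}
    for i, f in enumerate(post.families):
        params[f"mu_{f}"] = mu[:, :, i]
        params[f"sigma_{f}"] = sigma[:, :, i]
        subject_params[f] = subj_vals[:, :, i, :]
    # inactive families: draws exactly zero by construction
    active = set(post.families)
    for f in FAMILIES:
        if f in active:
            continue
        if f in OMEGA_FAMILIES and not variant.has_offset:
            continue
        params[f"mu_{f}"] = np.zeros((C, D))
        params[f"sigma_{f}"] = np.zeros((C, D))
        subject_params[f] = np.zeros((C, D, n))
    if variant.has_offset:
        params["mu_omega"] = expit(params["mu_logit_omega_neut"])
    for i, f in enumerate(post.families):
        for j, sid in enumerate(data.subject_ids):
            params[f"{f}[{sid}]"] = subj_vals[:, :, i, j]

    # pointwise log-likelihood, chunked over draws to bound memory
    T = data.subj.size
    pointwise = np.empty((C, D, T))
    flat = {f: a.reshape(C * D, n) for f, a in subject_params.items()
            if f in active}
    out = pointwise.reshape(C * D, T)
    step = max(1, 2_000_000 // max(T, 1))
    for s0 in range(0, C * D, step):
        s1 = min(C * D, s0 + step)
        out[s0:s1] = post.pointwise_loglik(
            {f: a[s0:s1] for f, a in flat.items()})

    draws_obj = PosteriorDraws(
        params=params, subject_params=subject_params,
        subject_ids=data.subject_ids, variant=variant,
        trial_info=data.trial_info, pointwise_loglik=pointwise,
        config=config, priors=priors, sampler_stats=stats_list)
    report = compute_rhat(draws_obj, threshold=config.rhat_threshold)
    n_div = sum(s.n_divergent for s in stats_list)
    report.n_divergent = n_div
    report.divergence_frac = n_div / (C * D)
    if report.divergence_frac > config.divergence_warn_frac:
        log.warning("divergence rate %.1f%% exceeds %.1f%% cap",
                    100 * report.divergence_frac,
                    100 * config.divergence_warn_frac)
    if not report.passed:
        log.warning("convergence gate failed: max R-hat %.3f", report.max_rhat)
    return draws_obj, report


def compute_rhat(draws, threshold: float = 1.05) -> ConvergenceReport:
    """Split-chain potential scale reduction factor and effective sample size.

    Accepts a PosteriorDraws or a plain dict of name -> (chain, draw)
    arrays.  Zero-variance parameters (all chains constant) are reported as
    R-hat 1.0 and flagged rather than left undefined.
    """
    import arviz as az

    params = draws.params if isinstance(draws, PosteriorDraws) else dict(draws)
    first = next(iter(params.values()))
    if first.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    varying = {k: v for k, v in params.items() if np.ptp(v) > 0}
    constant = [k for k in params if k not in varying]
    rhat, ess = {}, {}
    if varying:
        idata = az.from_dict(posterior={k: v for k, v in varying.items()})
        r = az.rhat(idata, method="split")
        e = az.ess(idata, method="bulk")
        for k in varying:
            rv = float(r[k].values)
            rhat[k] = 1.0 if np.isnan(rv) else rv
            ess[k] = float(e[k].values)
    total = first.shape[0] * first.shape[1]
    for k in constant:
        rhat[k] = 1.0
        ess[k] = float(total)
    passed = all(v < threshold for v in rhat.values())
    return ConvergenceReport(rhat=rhat, ess=ess, passed=passed,
                             rhat_threshold=threshold, zero_variance=constant)


def exclude_degenerate_subjects(datasets, min_minority_choices: int = 2):
    """Drop subjects with an extreme one-sided choice pattern.

    A subject whose minority-option count, pooled over both conditions, is
    below ``min_minority_choices`` (e.g. a single SS choice in 256 trials)
    carries almost no information about the trade-off and cannot be
    captured by the discounting model; such subjects are excluded and
    logged.  Returns ``(kept_datasets, excluded_subject_ids)``.
    """
    if min_minority_choices < 0:
        raise ValueError("min_minority_choices must be >= 0")
    counts = {}
    for d in datasets:
        ss = sum(1 for c in d.choices if c == SS_CHOICE)
        ll = sum(1 for c in d.choices if c == LL_CHOICE)
        a, b = counts.get(d.subject_id, (0, 0))
        counts[d.subject_id] = (a + ss, b + ll)
    excluded = sorted(s for s, (ss, ll) in counts.items()
                      if min(ss, ll) < min_minority_choices)
    kept = [d for d in datasets if d.subject_id not in excluded]
    if excluded:
        log.info("excluded %d degenerate subject(s): %s",
                 len(excluded), ", ".join(excluded))
    if not kept:
        raise ValueError("all subjects excluded as degenerate")
    return kept, excluded
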