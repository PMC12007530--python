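"""Model comparison (WAIC) and posterior predictive checks.

WAIC is reported on the deviance scale, waic = -2 (lppd - p_waic), so lower
values indicate better estimated out-of-sample fit.  The pointwise unit is
the trial.  Posterior predictive checks simulate full datasets from retained
posterior draws and compare the group-mean fraction of larger-later choices
per delay bin with the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .inference import PosteriorDraws
from .models import EXP_CLIP
from .task import DELAY_SETS

__all__ = [
    "WaicResult",
    "PosteriorPredictive",
    "waic",
    "rank_models",
    "posterior_predictive_simulate",
    "ll_proportion_by_delay",
    "ppc_summary",
    "ppc_coverage",
    "choice_prediction_accuracy",
    "delay_bin_map",
]


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    se: float
    n_trials: int
    name: str = ""
    n_params: int = 0
    rank: int = 0

    def to_dict(self) -> dict:
        return {"name": self.name, "waic": self.waic, "lppd": self.lppd,
                "p_waic": self.p_waic, "se": self.se,
                "n_trials": self.n_trials, "rank": self.rank}


def waic(pointwise_loglik) -> WaicResult:
    """Widely applicable information criterion from a (draws x trials) matrix.

    lppd_i = log mean_s exp(loglik_si), p_waic_i = var_s loglik_si; both are
    summed over trials and combined as waic = -2 (lppd - p_waic).  The
    standard error comes from the across-trial spread of the pointwise
    deviance contributions.
    """
    m = np.asarray(pointwise_loglik, dtype=float)
    if m.ndim == 3:  # (chain, draw, trial)
        m = m.reshape(-1, m.shape[-1])
    if m.ndim != 2:
        raise ValueError("expected a (draws, trials) matrix")
    s, t = m.shape
    if s < 2:
        raise ValueError("WAIC needs at least 2 draws (variance undefined)")
    if t < 1 or not np.all(np.isfinite(m)):
        raise ValueError("pointwise log-likelihoods must be finite, >=1 trial")
    lppd_i = logsumexp(m, axis=0) - np.log(s)
    p_i = m.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    return WaicResult(
        waic=float(waic_i.sum()),
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        se=float(np.sqrt(t * waic_i.var(ddof=1))) if t > 1 else 0.0,
        n_trials=t,
    )


def rank_models(results) -> list:
    """Rank WaicResults ascending by WAIC (rank 1 = best fit).

    ``results`` is a mapping name -> WaicResult or an iterable of named
    results.  Ties break by fewer parameters, then by name.
    """
    if isinstance(results, dict):
        items = []
        for name, r in results.items():
            r.name = r.name or name
            items.append(r)
    else:
        items = list(results)
    if len(items) < 2:
        raise ValueError("model ranking needs at least 2 results")
    items.sort(key=lambda r: (r.waic, r.n_params, r.name))
    for i, r in enumerate(items, start=1):
        r.rank = i
    return items


@dataclass
class PosteriorPredictive:
    """Simulated choice indicators: (n_datasets, n_trials), 1 = LL chosen."""

    sim_ll: np.ndarray
    trial_info: pd.DataFrame
    seed: int = 0


def posterior_predictive_simulate(draws: PosteriorDraws, n_datasets: int = 4000,
                                  seed: int = 0) -> PosteriorPredictive:
    """Simulate one dataset per selected posterior draw.

    Each simulated dataset re-uses every subject's own trials and condition
    indicators, with choices drawn Bernoulli from that draw's subject-level
    parameters.  Draws are selected evenly across the retained sample.
    """
    total = draws.n_chains * draws.n_draws
    if n_datasets > total:
        raise ValueError(
            f"n_datasets={n_datasets} exceeds retained draws ({total})")
    info = draws.trial_info
    subj = info["subject_index"].to_numpy()
    i_ero = info["i_ero"].to_numpy(float)
    amount = info["ll_amount"].to_numpy(float)
    delay = info["delay_days"].to_numpy(float)
    ss = info["ss_amount"].to_numpy(float)
    sel = np.linspace(0, total - 1, n_datasets).round().astype(int)
    sp = {f: a.reshape(total, -1)[sel] for f, a in draws.subject_params.items()}

    logk = sp["log_k_neut"][:, subj] + i_ero * sp.get(
        "s_ero_k", np.zeros_like(sp["log_k_neut"]))[:, subj]
    beta = sp["beta_neut"][:, subj] + i_ero * sp.get(
        "s_ero_beta", np.zeros_like(sp["beta_neut"]))[:, subj]
    k = np.exp(np.clip(logk, -EXP_CLIP, EXP_CLIP))
    sv = amount / (1.0 + k * delay)
    if draws.variant.has_offset:
        lam = sp["logit_omega_neut"][:, subj]
        if "s_ero_logit_omega" in sp:
            lam = lam + i_ero * sp["s_ero_logit_omega"][:, subj]
        sv = expit(lam) * sv
    p_ll = expit(np.clip(beta * (sv - ss), -EXP_CLIP, EXP_CLIP))
    rng = np.random.default_rng(seed)
    sim = rng.random(p_ll.shape) < p_ll
    return PosteriorPredictive(sim_ll=sim, trial_info=info, seed=seed)


def delay_bin_map() -> dict:
    """Map every design delay to one of the eight Set-1 delay bins.

    Set-2 delays go to the nearest Set-1 delay (ties to the smaller), which
    coincides with matching delays by rank within their set.
    """
    ref = DELAY_SETS[1]
    mapping = {d: d for d in ref}
    for d in DELAY_SETS[2]:
        mapping[d] = min(ref, key=lambda r: (abs(r - d), r))
    return mapping


def _per_subject_bin_fractions(ll_flag, subj, bins, n_subj, bin_values):
    """(n_subj, n_bins) per-subject LL fractions; NaN for empty cells."""
    n_bins = len(bin_values)
    bin_idx = np.searchsorted(bin_values, bins)
    key = subj * n_bins + bin_idx
    tot = np.bincount(key, minlength=n_subj * n_bins).astype(float)
    hit = np.bincount(key, weights=ll_flag, minlength=n_subj * n_bins)
    with np.errstate(invalid="ignore"):
        frac = (hit / tot).reshape(n_subj, n_bins)
    return frac


def ll_proportion_by_delay(trial_info: pd.DataFrame, ll_flag: np.ndarray,
                           bin_map: dict = None) -> pd.DataFrame:
    """Group-mean LL-choice fraction per delay bin with across-subject SE."""
    bin_map = bin_map or delay_bin_map()
    delays = trial_info["delay_days"].to_numpy()
    missing = set(np.unique(delays)) - set(bin_map)
    if missing:
        raise ValueError(f"delays without a bin: {sorted(missing)}")
    bins = np.array([bin_map[d] for d in delays])
    subj = trial_info["subject_index"].to_numpy()
    n_subj = subj.max() + 1
    bin_values = np.array(sorted(set(bin_map.values())))
    frac = _per_subject_bin_fractions(np.asarray(ll_flag, float), subj, bins,
                                      n_subj, bin_values)
    rows = []
    for bi, bv in enumerate(bin_values):
        col = frac[:, bi]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        se = float(col.std(ddof=1) / np.sqrt(col.size)) if col.size > 1 else 0.0
        rows.append({"delay_bin": int(bv), "mean_ll": float(col.mean()),
                     "se_ll": se, "n_subjects": int(col.size)})
    return pd.DataFrame(rows)


def ppc_summary(draws: PosteriorDraws, ppc: PosteriorPredictive,
                interval: float = 0.95, by_condition: bool = False) -> pd.DataFrame:
    """Observed vs. simulated LL fractions per delay bin.

    For each simulated dataset the group-mean LL fraction is computed per
    bin exactly as for the observed data; the simulated column reports the
    mean and the central ``interval`` across datasets.
    """
    info = draws.trial_info
    observed_ll = (info["choice_sign"].to_numpy() > 0).astype(float)
    conditions = info["condition"].unique().tolist() if by_condition else []
    groups = [("combined", np.ones(len(info), bool))] + [
        (c, (info["condition"] == c).to_numpy()) for c in conditions]

    bin_map = delay_bin_map()
    bin_values = np.array(sorted(set(bin_map.values())))
    all_bins = np.array([bin_map[d] for d in info["delay_days"].to_numpy()])
    all_subj = info["subject_index"].to_numpy()
    n_subj = all_subj.max() + 1
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    frames = []
    for label, mask in groups:
        sub = info[mask].reset_index(drop=True)
        obs = ll_proportion_by_delay(sub, observed_ll[mask], bin_map)
        subj, bins = all_subj[mask], all_bins[mask]
        sim_means = np.empty((ppc.sim_ll.shape[0], bin_values.size))
        with np.errstate(invalid="ignore"):
            for i, srow in enumerate(ppc.sim_ll[:, mask]):
                frac = _per_subject_bin_fractions(
                    srow.astype(float), subj, bins, n_subj, bin_values)
                sim_means[i] = np.nanmean(frac, axis=0)
        obs = obs.set_index("delay_bin")
        sim = pd.DataFrame(sim_means, columns=bin_values)
        obs["sim_mean"] = sim.mean()
        obs["sim_lo"] = sim.quantile(lo_q)
        obs["sim_hi"] = sim.quantile(hi_q)
        obs["condition"] = label
        obs["n_simulated"] = sim_means.shape[0]
        frames.append(obs.reset_index())
    return pd.concat(frames, ignore_index=True)


def ppc_coverage(summary: pd.DataFrame, condition: str = "combined") -> float:
    """Fraction of delay bins whose observed mean lies inside the simulated
    central interval."""
    s = summary[summary["condition"] == condition]
    inside = (s["mean_ll"] >= s["sim_lo"]) & (s["mean_ll"] <= s["sim_hi"])
    return float(inside.mean())


def choice_prediction_accuracy(draws: PosteriorDraws) -> float:
    """Fraction of trials where the model's higher-probability option at the
    posterior-mean subject parameters matches the observed choice."""
    info = draws.trial_info
    subj = info["subject_index"].to_numpy()
    i_ero = info["i_ero"].to_numpy(float)
    sp = {f: a.reshape(-1, a.shape[-1]).mean(axis=0)
          for f, a in draws.subject_params.items()}
    logk = sp["log_k_neut"][subj] + i_ero * sp.get(
        "s_ero_k", np.zeros_like(sp["log_k_neut"]))[subj]
    beta = sp["beta_neut"][subj] + i_ero * sp.get(
        "s_ero_beta", np.zeros_like(sp["beta_neut"]))[subj]
    k = np.exp(np.clip(logk, -EXP_CLIP, EXP_CLIP))
    sv = info["ll_amount"].to_numpy(float) / (1.0 + k * info["delay_days"].to_numpy(float))
    if draws.variant.has_offset:
        lam = sp["logit_omega_neut"][subj]
        if "s_ero_logit_omega" in sp:
            lam = lam + i_ero * sp["s_ero_logit_omega"][subj]
        sv = expit(lam) * sv
    p_ll = expit(beta * (sv - info["ss_amount"].to_numpy(float)))
    predicted_ll = p_ll > 0.5
    observed_ll = info["choice_sign"].to_numpy() > 0
    return float((predicted_ll == observed_ll).mean())
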