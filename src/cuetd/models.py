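"""Hyperbolic discounting model with condition shifts, offset and softmax choice.

The generative model of a single choice:

.. math::

    k(t) &= \\exp(k_{neut} + I_{Ero}(t)\\,S^k_{Ero}) \\\\
    \\beta(t) &= \\beta_{neut} + I_{Ero}(t)\\,S^\\beta_{Ero} \\\\
    SV(LL) &= \\omega(t)\\,\\frac{A}{1 + k(t) D} \\\\
    P(LL) &= \\sigma\\big(\\beta(t)\\,[SV(LL) - SV(SS)]\\big)

where :math:`I_{Ero}` is the dummy-coded cue-condition indicator (1 = erotic,
0 = neutral), :math:`SV(SS)` is the fixed immediate amount (delay 0, never
discounted and never offset-scaled) and :math:`\\omega \\in (0, 1]` is a
delay-independent multiplicative offset on the LL's subjective value.  The
*base* model fixes :math:`\\omega \\equiv 1`; the *offset* model estimates
:math:`\\omega_{neut}` and its condition shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .task import ChoiceDataset, Trial, LL_CHOICE, SS_CHOICE

__all__ = [
    "SubjectParams",
    "ModelVariant",
    "SubjectSummary",
    "modulated_k",
    "modulated_beta",
    "modulated_omega",
    "subjective_value_ll",
    "apply_offset",
    "choice_probability",
    "trial_loglik",
    "dataset_pointwise_loglik",
    "model_agnostic_td",
]

log = logging.getLogger(__name__)

# exponent clip for exp() and the logistic; avoids overflow with no
# measurable effect on probabilities (sigma(30) differs from 1 by < 1e-13)
EXP_CLIP = 30.0

BASE = "base"
OFFSET = "offset"
VARIANTS = (BASE, OFFSET)


@dataclass
class SubjectParams:
    """Subject-level parameters: neutral-condition values plus erotic shifts.

    ``log_k_neut`` is the log discount rate; ``beta_neut`` the softmax inverse
    temperature; ``omega_neut`` the multiplicative LL offset in (0, 1].  Each
    ``s_ero_*`` is the additive change of the corresponding parameter under
    erotic cue exposure (log-scale for k).
    """

    log_k_neut: float
    s_ero_k: float = 0.0
    beta_neut: float = 0.0
    s_ero_beta: float = 0.0
    omega_neut: float = 1.0
    s_ero_omega: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.omega_neut <= 1.0):
            raise ValueError("omega_neut must lie in (0, 1]")


@dataclass(frozen=True)
class ModelVariant:
    """base: pure hyperbolic (omega fixed at 1); offset: free omega + shift."""

    name: str

    def __post_init__(self):
        if self.name not in VARIANTS:
            raise ValueError(f"unknown model variant {self.name!r}")

    @property
    def has_offset(self) -> bool:
        return self.name == OFFSET

    @property
    def n_group_params(self) -> int:
        return 6 if self.has_offset else 4


@dataclass
class SubjectSummary:
    """Model-agnostic discounting summary: SS-choice proportion."""

    ss_count: int
    ll_count: int
    td_model_agnostic: float


def modulated_k(log_k_neut: float, s_ero_k: float, i_ero) -> float:
    """Condition-modulated discount rate, exp(log k_neut + I_Ero * S_Ero_k)."""
    exponent = np.clip(log_k_neut + np.asarray(i_ero) * s_ero_k, -EXP_CLIP, EXP_CLIP)
    return np.exp(exponent)


_warned_negative_beta = set()


def modulated_beta(beta_neut: float, s_ero_beta: float, i_ero) -> float:
    """Condition-modulated inverse temperature (additive shift, applied literally).

    The shift may drive beta negative; that is mathematically admissible under
    the priors and is passed through with a warning (once per distinct value)
    rather than truncated.
    """
    beta = beta_neut + np.asarray(i_ero) * s_ero_beta
    if np.any(np.asarray(beta) < 0):
        key = round(float(np.min(beta)), 12)
        if key not in _warned_negative_beta:
            _warned_negative_beta.add(key)
            log.warning("effective inverse temperature is negative (beta=%s)",
                        beta)
    return beta


def modulated_omega(omega_neut: float, s_ero_omega: float, i_ero) -> float:
    """Condition-modulated offset; must remain in (0, 1]."""
    omega = omega_neut + np.asarray(i_ero) * s_ero_omega
    if np.any(omega <= 0) or np.any(omega > 1):
        raise ValueError(f"effective offset omega={omega} outside (0, 1]")
    return omega


def subjective_value_ll(amount, delay_days, k):
    """Hyperbolic subjective value A / (1 + k D)."""
    if np.any(np.asarray(k) < 0):
        raise ValueError("discount rate k must be non-negative")
    if np.any(np.asarray(amount) <= 0):
        raise ValueError("amount must be positive")
    if np.any(np.asarray(delay_days) < 0):
        raise ValueError("delay must be non-negative")
    return amount / (1.0 + k * np.asarray(delay_days, dtype=float))


def apply_offset(sv, omega_neut: float, s_ero_omega: float = 0.0, i_ero=0):
    """Scale the LL subjective value by the effective offset.

    Applies to the LL only: the SS is immediate and its value is its face
    amount, so an offset on it would be meaningless.
    """
    return sv * modulated_omega(omega_neut, s_ero_omega, i_ero)


def choice_probability(sv_chosen, sv_other, beta):
    """Softmax (logistic) probability of the option with value ``sv_chosen``.

    Computed as sigma(beta * (sv_chosen - sv_other)) in overflow-safe form.
    """
    x = np.clip(beta * (np.asarray(sv_chosen) - np.asarray(sv_other)),
                -EXP_CLIP, EXP_CLIP)
    return 1.0 / (1.0 + np.exp(-x))


def _log_choice_probability(sv_chosen, sv_other, beta):
    x = np.clip(beta * (np.asarray(sv_chosen) - np.asarray(sv_other)),
                -EXP_CLIP, EXP_CLIP)
    return -np.logaddexp(0.0, -x)


def _effective_sv_ll(trial: Trial, params: SubjectParams, variant: ModelVariant):
    k = modulated_k(params.log_k_neut, params.s_ero_k, trial.i_ero)
    sv = subjective_value_ll(trial.ll_amount, trial.delay_days, k)
    if variant.has_offset:
        sv = apply_offset(sv, params.omega_neut, params.s_ero_omega, trial.i_ero)
    return sv


def trial_loglik(trial: Trial, choice: str, params: SubjectParams,
                 variant: ModelVariant, ss_amount: float = 20.0) -> float:
    """Log probability of the observed valid choice on one trial."""
    if choice not in (SS_CHOICE, LL_CHOICE):
        raise ValueError(f"choice must be SS or LL, got {choice!r}")
    beta = modulated_beta(params.beta_neut, params.s_ero_beta, trial.i_ero)
    sv_ll = _effective_sv_ll(trial, params, variant)
    if choice == LL_CHOICE:
        ll = _log_choice_probability(sv_ll, ss_amount, beta)
    else:
        ll = _log_choice_probability(ss_amount, sv_ll, beta)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite trial log-likelihood")
    return float(ll)


def dataset_pointwise_loglik(dataset: ChoiceDataset, params: SubjectParams,
                             variant: ModelVariant) -> np.ndarray:
    """Per-trial log-likelihoods for all valid trials, order-preserving.

    The pointwise unit is the trial; these terms feed WAIC directly.
    """
    idx = dataset.valid_indices()
    if not idx:
        raise ValueError("dataset has no valid trials")
    return np.array([
        trial_loglik(dataset.trials[i], dataset.choices[i], params, variant,
                     ss_amount=dataset.ss_amount)
        for i in idx
    ])


def model_agnostic_td(dataset: ChoiceDataset) -> SubjectSummary:
    """Relative proportion of SS choices, SS / (SS + LL), INVALID excluded.

    A model-free impulsivity measure: higher values mean more immediate
    choices, i.e. steeper discounting.
    """
    ss = sum(1 for c in dataset.choices if c == SS_CHOICE)
    ll = sum(1 for c in dataset.choices if c == LL_CHOICE)
    if ss + ll == 0:
        raise ValueError("no valid trials: model-agnostic TD undefined")
    return SubjectSummary(ss_count=ss, ll_count=ll,
                          td_model_agnostic=ss / (ss + ll))
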