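"""Synthetic cohorts from the generative discounting model.

Subjects are drawn from group-level Gaussians over log k, beta and omega
(omega on the logit scale so the hierarchy stays Gaussian while respecting
the (0, 1] constraint), each with a per-subject erotic-condition shift.
Every subject completes one neutral and one erotic 128-trial session with
the two multiplier/delay sets counterbalanced across subjects.

The generator exists so that every downstream stage — inference, model
comparison, posterior predictive checks, Bayes factors — can be exercised on
data with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import models
from .models import ModelVariant, SubjectParams, choice_probability
from .task import (
    ChoiceDataset,
    INVALID_CHOICE,
    LL_CHOICE,
    SS_AMOUNT,
    SS_CHOICE,
    build_design,
)

__all__ = ["GroupLevel", "GroundTruth", "simulate_subject", "simulate_cohort"]

# group-level means follow the neutral-condition priors of the hierarchical
# model (log k -4.2, beta 0.51, shifts 0.15 / 0.02); SDs are typical of the
# between-subject spread seen in delay-discounting cohorts
DEFAULT_MEANS = {
    "log_k_neut": -4.2,
    "s_ero_k": 0.15,
    "beta_neut": 0.51,
    "s_ero_beta": 0.02,
    "logit_omega_neut": 0.0,   # omega 0.5
    "s_ero_logit_omega": 0.0,
}
DEFAULT_SDS = {
    "log_k_neut": 1.0,
    "s_ero_k": 0.5,
    "beta_neut": 0.2,
    "s_ero_beta": 0.1,
    "logit_omega_neut": 0.5,
    "s_ero_logit_omega": 0.2,
}
PARAM_NAMES = tuple(DEFAULT_MEANS)


@dataclass
class GroupLevel:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("group-level SD must be non-negative")


@dataclass
class GroundTruth:
    """Group-level Gaussians plus (after simulation) realized subject params.

    Omega-related entries are on the logit scale; a subject's neutral offset
    is ``expit(logit_omega_neut)`` and the erotic offset is
    ``expit(logit_omega_neut + s_ero_logit_omega)``.
    """

    group: dict = field(default_factory=dict)
    subjects: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)

    @classmethod
    def default(cls, omega_mean: float = 0.5, **overrides) -> "GroundTruth":
        """Study-condition defaults; ``omega_mean`` given on the omega scale.

        ``overrides`` maps parameter name to a (mean, sd) pair.
        """
        group = {}
        for name in PARAM_NAMES:
            mean, sd = DEFAULT_MEANS[name], DEFAULT_SDS[name]
            if name == "logit_omega_neut":
                mean = float(logit(omega_mean))
            if name in overrides:
                mean, sd = overrides[name]
            group[name] = GroupLevel(mean, sd)
        return cls(group=group)

    def draw_subject(self, rng: np.random.Generator) -> SubjectParams:
        raw = {name: rng.normal(g.mean, g.sd) for name, g in self.group.items()}
        lam0 = raw["logit_omega_neut"]
        lam1 = lam0 + raw["s_ero_logit_omega"]
        omega0 = float(expit(lam0))
        return SubjectParams(
            log_k_neut=raw["log_k_neut"],
            s_ero_k=raw["s_ero_k"],
            beta_neut=raw["beta_neut"],
            s_ero_beta=raw["s_ero_beta"],
            omega_neut=omega0,
            s_ero_omega=float(expit(lam1)) - omega0,
        )


def simulate_subject(params: SubjectParams, trials, variant,
                     seed, miss_rate: float = 0.0,
                     subject_id: str = "sim", condition_label: str = None,
                     ss_amount: float = SS_AMOUNT) -> ChoiceDataset:
    """Simulate one session: Bernoulli choices from the softmax model.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  With
    ``miss_rate`` > 0 a corresponding fraction of trials is marked INVALID
    (missed response window) before any choice is drawn.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices = []
    for trial in trials:
        if miss_rate > 0 and rng.random() < miss_rate:
            choices.append(INVALID_CHOICE)
            continue
        beta = models.modulated_beta(params.beta_neut, params.s_ero_beta, trial.i_ero)
        sv_ll = models._effective_sv_ll(trial, params, variant)
        p_ll = choice_probability(sv_ll, ss_amount, beta)
        choices.append(LL_CHOICE if rng.random() < p_ll else SS_CHOICE)
    if condition_label is None:
        condition_label = "erotic" if trials and trials[0].i_ero else "neutral"
    return ChoiceDataset(subject_id=subject_id, trials=list(trials),
                         choices=choices, condition_label=condition_label,
                         ss_amount=ss_amount)


def simulate_cohort(ground_truth: GroundTruth, n_subjects: int,
                    seed: int, variant="offset", miss_rate: float = 0.0,
                    ss_amount: float = SS_AMOUNT,
                    design_assignment: str = "alternate"):
    """Simulate a full cohort: each subject runs both conditions.

    Design sets 1 and 2 are assigned to the neutral/erotic sessions
    alternately by subject index (``design_assignment="alternate"``, the
    deterministic default) or uniformly at random per subject
    (``"random"``).  Returns ``(datasets, realized_truth)`` where
    ``datasets`` is a flat list of 2 * n_subjects :class:`ChoiceDataset`
    (neutral then erotic per subject) and ``realized_truth`` carries the
    per-subject parameters actually drawn.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a cohort")
    if design_assignment not in ("alternate", "random"):
        raise ValueError(f"unknown design_assignment {design_assignment!r}")
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    rng = np.random.default_rng(seed)
    truth = GroundTruth(group=dict(ground_truth.group))
    datasets = []
    width = max(2, len(str(n_subjects)))
    for j in range(n_subjects):
        sid = f"s{j:0{width}d}"
        params = ground_truth.draw_subject(rng)
        if design_assignment == "alternate":
            neutral_set = 1 if j % 2 == 0 else 2
        else:
            neutral_set = int(rng.integers(1, 3))
        erotic_set = 3 - neutral_set
        neutral_trials = build_design(neutral_set, ss_amount, i_ero=0)
        erotic_trials = build_design(erotic_set, ss_amount, i_ero=1)
        datasets.append(simulate_subject(params, neutral_trials, variant, rng,
                                         miss_rate, sid, "neutral", ss_amount))
        datasets.append(simulate_subject(params, erotic_trials, variant, rng,
                                         miss_rate, sid, "erotic", ss_amount))
        truth.subjects.append(params)
        truth.subject_ids.append(sid)
    return datasets, truth
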