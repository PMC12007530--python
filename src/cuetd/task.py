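"""Intertemporal-choice task structure.

The task is a classical delay-discounting design: on every trial the subject
chooses between a fixed immediate reward (smaller-sooner, SS; 20 EUR) and a
larger delayed reward (larger-later, LL).  LL amounts are built by crossing a
set of 16 multipliers of the SS amount with a set of 8 delays, giving 128
trials per session.  Two slightly different multiplier/delay sets exist so
that the two experimental sessions (neutral vs. erotic cue exposure) do not
repeat identical options.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SS_AMOUNT",
    "MULTIPLIER_SETS",
    "DELAY_SETS",
    "DesignSet",
    "Trial",
    "ChoiceDataset",
    "build_design",
    "get_design_set",
]

SS_AMOUNT = 20.0

MULTIPLIER_SETS = {
    1: (1.01, 1.02, 1.05, 1.10, 1.15, 1.25, 1.35, 1.45,
        1.65, 1.85, 2.05, 2.25, 2.65, 3.05, 3.45, 3.85),
    2: (1.01, 1.03, 1.08, 1.12, 1.20, 1.30, 1.40, 1.50,
        1.60, 1.80, 2.00, 2.20, 2.60, 3.00, 3.40, 3.80),
}

DELAY_SETS = {
    1: (1, 3, 5, 8, 14, 30, 60, 122),
    2: (2, 4, 6, 9, 15, 32, 58, 119),
}

SS_CHOICE = "SS"
LL_CHOICE = "LL"
INVALID_CHOICE = "INVALID"
CHOICE_TOKENS = (SS_CHOICE, LL_CHOICE, INVALID_CHOICE)


@dataclass(frozen=True)
class DesignSet:
    """One multiplier/delay set defining a 128-trial session.

    Attributes
    ----------
    set_id : int
        1 or 2.
    ss_amount : float
        Fixed immediate (smaller-sooner) amount in euros.
    multipliers : tuple of float
        16 multipliers, each > 1, applied to ``ss_amount`` to form LL amounts.
    delays : tuple of int
        8 strictly increasing delays in days.
    """

    set_id: int
    ss_amount: float = SS_AMOUNT
    multipliers: tuple = field(default=None)
    delays: tuple = field(default=None)

    def __post_init__(self):
        if self.multipliers is None:
            object.__setattr__(self, "multipliers", MULTIPLIER_SETS[self.set_id])
        if self.delays is None:
            object.__setattr__(self, "delays", DELAY_SETS[self.set_id])
        if len(self.multipliers) != 16 or any(m <= 1 for m in self.multipliers):
            raise ValueError("need exactly 16 multipliers, all > 1")
        if len(self.delays) != 8 or any(
            b <= a for a, b in zip(self.delays, self.delays[1:])
        ):
            raise ValueError("need exactly 8 strictly increasing delays")


@dataclass(frozen=True)
class Trial:
    """A single LL option: amount (euros), delay (days), condition indicator."""

    ll_amount: float
    delay_days: int
    i_ero: int
    trial_index: int

    def __post_init__(self):
        if self.i_ero not in (0, 1):
            raise ValueError("i_ero must be 0 or 1")


@dataclass
class ChoiceDataset:
    """One subject x condition block of intertemporal choices.

    ``choices[i]`` is the response to ``trials[i]``: "SS", "LL" or "INVALID"
    (response window missed).  INVALID trials are excluded from every
    likelihood and from the model-agnostic discounting measure.
    """

    subject_id: str
    trials: list
    choices: list
    condition_label: str
    ss_amount: float = SS_AMOUNT

    def __post_init__(self):
        if len(self.trials) != len(self.choices):
            raise ValueError("one choice per trial required")
        bad = set(self.choices) - set(CHOICE_TOKENS)
        if bad:
            raise ValueError(f"unknown choice tokens: {sorted(bad)}")

    def valid_indices(self):
        return [i for i, c in enumerate(self.choices) if c != INVALID_CHOICE]

    @property
    def n_valid(self) -> int:
        return len(self.valid_indices())


def build_design(set_id: int, ss_amount: float = SS_AMOUNT, i_ero: int = 0):
    """Build the full 16 x 8 crossing of multipliers and delays.

    Returns a list of 128 :class:`Trial` objects.  LL amounts are
    ``ss_amount * multiplier`` rounded to euro cents.  Trials are ordered
    delay-major then multiplier, i.e. a fixed canonical order; presentation
    order randomisation is a per-simulation concern, not part of the design.
    """
    if set_id not in MULTIPLIER_SETS:
        raise ValueError(f"unknown design set {set_id!r}; expected 1 or 2")
    if ss_amount <= 0:
        raise ValueError("ss_amount must be positive")
    design = DesignSet(set_id=set_id, ss_amount=ss_amount)
    trials = []
    idx = 0
    for delay in design.delays:
        for mult in design.multipliers:
            trials.append(
                Trial(
                    ll_amount=round(ss_amount * mult, 2),
                    delay_days=delay,
                    i_ero=i_ero,
                    trial_index=idx,
                )
            )
            idx += 1
    return trials


def get_design_set(set_id: int, ss_amount: float = SS_AMOUNT) -> DesignSet:
    return DesignSet(set_id=set_id, ss_amount=ss_amount)
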