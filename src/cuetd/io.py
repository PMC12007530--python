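"""File formats: choice tables, ground-truth sidecars, draws, reports.

CSV is the single interchange format.  Every artifact starts with '#'
provenance comment lines (package version, seed, config hash) so a result
can always be traced to the run that produced it; readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .task import CHOICE_TOKENS, ChoiceDataset, SS_AMOUNT, Trial

__all__ = [
    "ChoiceTableError",
    "RunConfig",
    "read_choice_table",
    "write_choice_table",
    "write_truth_sidecar",
    "write_draws",
    "read_draws",
]

CHOICE_COLUMNS = ["subject_id", "condition", "i_ero", "trial_index",
                  "ll_amount", "delay_days", "choice"]
CONDITION_FOR_I = {0: "neutral", 1: "erotic"}


class ChoiceTableError(ValueError):
    """Structured parse/validation error; carries the offending row number."""

    def __init__(self, message, row=None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    n_subjects: int = 36
    variant: str = "offset"
    omega_mean: float = 0.5
    miss_rate: float = 0.0
    design_assignment: str = "alternate"
    n_chains: int = 4
    n_warmup: int = 1500
    n_retained: int = 4000
    exclusion_threshold: int = 2
    seed: int = 0
    out_dir: str = "."
    prior_overrides: dict = field(default_factory=dict)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed=None, config_hash=None, extra=None) -> list:
    lines = [f"# cuetd {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config_hash={config_hash}")
    if extra:
        lines.extend(f"# {e}" for e in extra)
    return lines


def _write_csv_with_header(df: pd.DataFrame, path, seed=None, config_hash=None,
                           extra=None, float_format=None):
    with open(path, "w", newline="") as fh:
        for line in provenance_lines(seed, config_hash, extra):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=float_format)


def write_choice_table(datasets, path, seed=None, config_hash=None):
    """Long-format choice CSV, one row per trial."""
    rows = []
    for d in datasets:
        for t, c in zip(d.trials, d.choices):
            rows.append((d.subject_id, d.condition_label, t.i_ero,
                         t.trial_index, f"{t.ll_amount:.2f}", t.delay_days, c))
    df = pd.DataFrame(rows, columns=CHOICE_COLUMNS)
    _write_csv_with_header(df, path, seed, config_hash)


def read_choice_table(path, ss_amount: float = SS_AMOUNT):
    """Read and validate a choice CSV into a ChoiceDataset collection.

    Raises :class:`ChoiceTableError` (naming the offending row where
    possible) for missing columns, unknown choice tokens, inconsistent
    condition/indicator pairs or duplicated (subject, condition,
    trial_index) keys.
    """
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:
        raise ChoiceTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ChoiceTableError(f"missing column(s): {', '.join(missing)}")
    datasets = []
    for (sid, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        trials, choices = [], []
        for row_no, row in grp.iterrows():
            line = row_no + 2  # header is line 1
            choice = row["choice"]
            if choice not in CHOICE_TOKENS:
                raise ChoiceTableError(
                    f"unknown choice token {choice!r}", row=line)
            try:
                i_ero = int(row["i_ero"])
                trial = Trial(ll_amount=float(row["ll_amount"]),
                              delay_days=int(row["delay_days"]),
                              i_ero=i_ero,
                              trial_index=int(row["trial_index"]))
            except (TypeError, ValueError) as exc:
                raise ChoiceTableError(str(exc), row=line) from exc
            if CONDITION_FOR_I.get(i_ero) != cond:
                raise ChoiceTableError(
                    f"i_ero={i_ero} inconsistent with condition {cond!r}",
                    row=line)
            if trial.ll_amount <= ss_amount:
                raise ChoiceTableError(
                    f"ll_amount {trial.ll_amount} does not exceed the "
                    f"immediate amount {ss_amount}", row=line)
            trials.append(trial)
            choices.append(choice)
        idx = [t.trial_index for t in trials]
        if len(set(idx)) != len(idx):
            raise ChoiceTableError(
                f"duplicate trial_index for subject {sid!r}, condition {cond!r}")
        datasets.append(ChoiceDataset(subject_id=sid, trials=trials,
                                      choices=choices, condition_label=cond,
                                      ss_amount=ss_amount))
    if not datasets:
        raise ChoiceTableError("empty choice table")
    return datasets


def write_truth_sidecar(truth, path, seed=None, config_hash=None):
    """Ground-truth table: per-subject true parameters plus group rows."""
    rows = []
    for name, g in truth.group.items():
        rows.append(("_group", f"mean:{name}", g.mean))
        rows.append(("_group", f"sd:{name}", g.sd))
    for sid, p in zip(truth.subject_ids, truth.subjects):
        for par in ("log_k_neut", "s_ero_k", "beta_neut", "s_ero_beta",
                    "omega_neut", "s_ero_omega"):
            rows.append((sid, par, getattr(p, par)))
    df = pd.DataFrame(rows, columns=["subject_id", "parameter", "true_value"])
    _write_csv_with_header(df, path, seed, config_hash)


def write_draws(draws, path, seed=None, config_hash=None):
    """Tidy draws CSV: chain, iteration, parameter, value."""
    _write_csv_with_header(draws.to_tidy(), path, seed, config_hash,
                           float_format="%.10g")


def read_draws(path) -> dict:
    """Read a tidy draws CSV back into name -> (chain, draw) arrays."""
    df = pd.read_csv(path, comment="#")
    out = {}
    for name, grp in df.groupby("parameter", sort=False):
        piv = grp.pivot(index="chain", columns="iteration", values="value")
        out[name] = piv.to_numpy()
    return out


def write_json(obj, path):
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default, sort_keys=True)
        fh.write("\n")
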