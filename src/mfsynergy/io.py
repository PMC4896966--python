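"""Data model and on-disk format for multi-finger force trials.

A trial is a T x 4 matrix of finger forces (newtons) sampled at a fixed
rate; columns are always ordered (index, middle, ring, little).  The
canonical on-disk format is a long-format CSV with one row per sample:

    subject, condition, trial, time_s, f_index, f_middle, f_ring, f_little

The virtual-finger (VF) force is the sum of the four finger forces; the
task in the experiment this package models is to hold the VF force at a
constant target while receiving auditory feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FINGERS = ("index", "middle", "ring", "little")
FORCE_COLUMNS = tuple(f"f_{f}" for f in FINGERS)
CONDITIONS = ("F", "I", "FI")

CSV_COLUMNS = ("subject", "condition", "trial", "time_s") + FORCE_COLUMNS


class FormatError(ValueError):
    """The file does not have the expected long-format layout."""


class DataError(ValueError):
    """The file layout is right but the contents violate the data model."""


@dataclass(frozen=True)
class TrialRecording:
    """One trial of a multi-finger constant-force task.

    Parameters
    ----------
    subject_id : str
        Subject label.
    condition : str
        Feedback condition, one of ``"F"``, ``"I"``, ``"FI"`` (frequency,
        intensity, or both modulated).
    trial_index : int
        1-based trial number within the condition.
    sample_rate : float
        Sampling rate in Hz.
    forces : ndarray, shape (T, 4)
        Finger forces in newtons, columns ordered (index, middle, ring,
        little).
    t0 : float
        Time of the first sample in seconds, relative to trial start.
    """

    subject_id: str
    condition: str
    trial_index: int
    sample_rate: float
    forces: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "forces", forces)
        if forces.ndim != 2 or forces.shape[1] != 4:
            raise ValueError(f"forces must be T x 4, got shape {forces.shape}")
        if forces.shape[0] < 2:
            raise ValueError("a trial needs at least 2 samples")
        if not np.all(np.isfinite(forces)):
            raise ValueError("forces contain non-finite values")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.condition not in CONDITIONS:
            raise DataError(f"unknown condition {self.condition!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def duration(self) -> float:
        """Trial extent in seconds: t0 plus T / sample_rate."""
        return self.t0 + self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (trial-relative)."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class ConditionSet:
    """All trials of one subject under one feedback condition.

    This is the unit of decomposition: online (within-trial) and offline
    (between-trial) variance are only defined over a set of trials with a
    common length.
    """

    subject_id: str
    condition: str
    trials: tuple[TrialRecording, ...]
    target_force: float = 18.0

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        if len(trials) < 2:
            raise ValueError("a ConditionSet needs at least 2 trials")
        n = {t.n_samples for t in trials}
        sr = {t.sample_rate for t in trials}
        if len(n) != 1 or len(sr) != 1:
            raise ValueError("all trials must share sample count and sample rate")
        if not self.target_force > 0:
            raise ValueError("target_force must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def sample_rate(self) -> float:
        return self.trials[0].sample_rate

    def force_array(self) -> np.ndarray:
        """Stack finger forces into shape (n_trials, T, 4)."""
        return np.stack([t.forces for t in self.trials])

    def vf_array(self) -> np.ndarray:
        """VF force per trial, shape (n_trials, T)."""
        return self.force_array().sum(axis=2)


def vf_force(rec: TrialRecording) -> np.ndarray:
    """Virtual-finger force: element-wise sum of the four finger forces."""
    return rec.forces.sum(axis=1)


def extract_window(rec: TrialRecording, start_s: float, end_s: float) -> TrialRecording:
    """Cut the samples whose time lies in the half-open window [start_s, end_s).

    The half-open convention makes adjacent windows disjoint and the sample
    count exactly ``round((end_s - start_s) * sample_rate)`` on aligned
    grids -- e.g. an 11 s window of a 1000 Hz trial has 11000 samples.
    """
    if not start_s < end_s:
        raise ValueError("window start must precede window end")
    if start_s < rec.t0 - 0.5 / rec.sample_rate or end_s > rec.duration + 0.5 / rec.sample_rate:
        raise ValueError(
            f"window [{start_s}, {end_s}) outside recording "
            f"[{rec.t0}, {rec.duration})"
        )
    times = rec.times
    mask = (times >= start_s - 1e-9) & (times < end_s - 1e-9)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError("window contains fewer than 2 samples")
    return replace(rec, forces=rec.forces[idx], t0=float(times[idx[0]]))


def window_condition_set(cs: ConditionSet, start_s: float, end_s: float) -> ConditionSet:
    """Apply :func:`extract_window` to every trial of a ConditionSet."""
    return replace(cs, trials=tuple(extract_window(t, start_s, end_s) for t in cs.trials))


def _trials_to_frame(sets: Sequence[ConditionSet]) -> pd.DataFrame:
    rows = []
    for cs in sets:
        for rec in cs.trials:
            df = pd.DataFrame(rec.forces, columns=list(FORCE_COLUMNS))
            df.insert(0, "time_s", rec.times)
            df.insert(0, "trial", rec.trial_index)
            df.insert(0, "condition", rec.condition)
            df.insert(0, "subject", rec.subject_id)
            rows.append(df)
    if not rows:
        return pd.DataFrame(columns=list(CSV_COLUMNS))
    return pd.concat(rows, ignore_index=True)


def write_trials(sets: Sequence[ConditionSet], path: str | Path) -> None:
    """Write ConditionSets as a long-format CSV readable by :func:`load_trials`.

    An empty list yields a header-only file.
    """
    _trials_to_frame(sets).to_csv(path, index=False, float_format="%.17g")


def load_trials(
    path: str | Path, target_force: float = 18.0, sample_rate: float | None = None
) -> list[ConditionSet]:
    """Load a long-format trial CSV into one ConditionSet per (subject, condition).

    The file must carry the columns ``subject, condition, trial, time_s,
    f_index, f_middle, f_ring, f_little``.  Times must be strictly
    increasing within each trial; the sample rate is inferred from the
    median time step unless given explicitly.  Trials are sorted by trial
    index; subjects and conditions keep file order of first appearance.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    bad = set(df["condition"].astype(str)) - set(CONDITIONS)
    if bad:
        raise DataError(f"unknown condition labels: {sorted(bad)}")

    sets: list[ConditionSet] = []
    for (subject, condition), group in df.groupby(["subject", "condition"], sort=False):
        trials = []
        for trial_index, tg in group.groupby("trial", sort=True):
            times = tg["time_s"].to_numpy(dtype=float)
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise DataError(
                    f"non-monotone time in subject {subject!r} "
                    f"condition {condition!r} trial {trial_index}"
                )
            sr = sample_rate if sample_rate is not None else 1.0 / float(np.median(dt))
            trials.append(
                TrialRecording(
                    subject_id=str(subject),
                    condition=str(condition),
                    trial_index=int(trial_index),
                    sample_rate=sr,
                    forces=tg[list(FORCE_COLUMNS)].to_numpy(dtype=float),
                    t0=float(times[0]),
                )
            )
        sets.append(
            ConditionSet(
                subject_id=str(subject),
                condition=str(condition),
                trials=tuple(trials),
                target_force=target_force,
            )
        )
    return sets
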