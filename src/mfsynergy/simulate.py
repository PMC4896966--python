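"""Synthetic multi-finger force cohorts with controlled variance structure.

The generator emulates the constant-force experiment the analysis modules
are built for: each subject presses four fingers to hold the virtual-finger
(VF) force at 18 N for 20 s, 15 trials per feedback condition (F, I, FI),
sampled at 1000 Hz.  The statistical structure is what the decomposition
and fusion models assume:

* per condition, a VF-level variance ``vf_sigma2`` split into a
  within-trial (online) and a between-trial (offline) part by the online
  fraction ``rho``,
* a constant per-condition bias (target minus mean VF force),
* online noise that is low-pass filtered Gaussian noise (physiological
  force fluctuation is slow; the default cutoff is 2 Hz),
* the VF signal allocated to the four fingers by a sharing vector, with a
  coupling parameter ``kappa`` that injects either a common noise source
  shared by all fingers (kappa > 0, positive covariance / error
  amplification) or extra zero-sum noise in the null space of the force
  sum (kappa < 0, negative covariance / error compensation),
* FI-condition variance and bias that default to the Bayes-fused values
  of the F and I parameters, so that the generated cohorts embody the
  cue-fusion hypothesis exactly.

A ramp at both trial ends connects 0 N to the plateau so that window
extraction (6-17 s of a 20 s trial) is meaningful, as in the experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal

from .fusion import fused_bias, fused_variance, fusion_weights
from .io import ConditionSet, TrialRecording, write_trials

CONDITIONS = ("F", "I", "FI")

# Feedback mapping constants of the experiment: reference tone 1000 Hz at
# 70 dB; gains of 7 Hz and 0.7 dB per newton of VF-force deviation, set at
# roughly one just-noticeable difference per newton.
REFERENCE_FREQUENCY_HZ = 1000.0
REFERENCE_INTENSITY_DB = 70.0
FREQUENCY_GAIN_HZ_PER_N = 7.0
INTENSITY_GAIN_DB_PER_N = 0.7


@dataclass(frozen=True)
class ToneSample:
    """Auditory feedback tone: frequency in Hz and intensity in dB."""

    frequency: float
    intensity: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.frequency) <= 0):
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters of a synthetic cohort.

    Condition-level dictionaries may leave the FI entry as ``None``; it
    then defaults to the Bayes-fused value of the F and I entries, which
    is the self-consistent setting used throughout.

    Variances are in N^2, biases in N (positive = undershoot).  The
    single-cue defaults (sigma ~ 0.8-0.95 N of VF-force scatter, biases of
    a few tenths of a newton) are plausible magnitudes for auditory-only
    force feedback at an 18 N target.
    """

    n_subjects: int = 10
    n_trials: int = 15
    trial_duration_s: float = 20.0
    sample_rate: float = 1000.0
    target_force: float = 18.0
    vf_sigma2: Mapping[str, float | None] = field(
        default_factory=lambda: {"F": 0.9, "I": 0.7, "FI": None}
    )
    bias: Mapping[str, float | None] = field(
        default_factory=lambda: {"F": 0.5, "I": 0.35, "FI": None}
    )
    online_fraction: float = 0.5
    sharing: tuple[float, float, float, float] = (0.30, 0.30, 0.22, 0.18)
    coupling: float = 0.3
    lowpass_cutoff_hz: float = 2.0
    ramp_s: float = 2.0
    subject_scale_sd: float = 0.25
    subject_bias_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 2:
            raise ValueError("need n_subjects >= 1 and n_trials >= 2")
        if not (0.0 < self.online_fraction < 1.0):
            raise ValueError("online_fraction must lie in (0, 1)")
        if not (-1.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [-1, 1]")
        s = np.asarray(self.sharing, dtype=float)
        if s.shape != (4,) or np.any(s <= 0) or abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("sharing must be 4 positive numbers summing to 1")
        for c in ("F", "I"):
            if not (self.vf_sigma2[c] or 0) > 0:
                raise ValueError(f"vf_sigma2[{c!r}] must be positive")
            if self.bias[c] is None:
                raise ValueError(f"bias[{c!r}] must be set")
        if self.trial_duration_s <= 2 * self.ramp_s:
            raise ValueError("trial too short for the ramps")
        if self.sample_rate <= 4 * self.lowpass_cutoff_hz:
            raise ValueError("sample_rate too low for the online-noise cutoff")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        if "sharing" in d:
            d["sharing"] = tuple(d["sharing"])
        for key in ("vf_sigma2", "bias"):
            if key in d:
                d[key] = {k: v for k, v in dict(d[key]).items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sharing"] = list(self.sharing)
        d["vf_sigma2"] = dict(self.vf_sigma2)
        d["bias"] = dict(self.bias)
        return d


def tone_map(vf: float, condition: str, cfg: SynthConfig | None = None) -> ToneSample:
    """Map a VF force to the feedback tone of a condition.

    The deviation from the target modulates frequency in condition F,
    intensity in condition I, and both in condition FI; at the target the
    tone equals the 1000 Hz / 70 dB reference.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    target = cfg.target_force if cfg is not None else 18.0
    d = vf - target
    freq = REFERENCE_FREQUENCY_HZ
    intensity = REFERENCE_INTENSITY_DB
    if condition in ("F", "FI"):
        freq = REFERENCE_FREQUENCY_HZ + FREQUENCY_GAIN_HZ_PER_N * d
    if condition in ("I", "FI"):
        intensity = REFERENCE_INTENSITY_DB + INTENSITY_GAIN_DB_PER_N * d
    return ToneSample(frequency=freq, intensity=intensity)


def _null_basis() -> np.ndarray:
    """Orthonormal basis (4 x 3) of the zero-sum subspace of finger space."""
    ones = np.ones((4, 1)) / 2.0
    # complete to an orthonormal basis and drop the force-sum direction
    q, _ = np.linalg.qr(np.hstack([ones, np.eye(4)[:, :3]]))
    return q[:, 1:]


_NULL_BASIS = _null_basis()


def _lowpass_sos(cutoff_hz: float, sample_rate: float):
    return signal.butter(2, cutoff_hz, btype="low", fs=sample_rate, output="sos")


def _filtfilt_unit_gain(sos, n: int, sample_rate: float, cutoff_hz: float) -> float:
    """Std of sosfiltfilt output for unit white-noise input (interior samples)."""
    m = min(n, max(int(20 * sample_rate / cutoff_hz), 512))
    impulse = np.zeros(2 * m + 1)
    impulse[m] = 1.0
    h = signal.sosfiltfilt(sos, impulse)
    return float(np.sqrt(np.sum(h * h)))


def _online_noise(rng, shape, sos, gain: float) -> np.ndarray:
    """Low-pass filtered standard Gaussian noise with unit stationary variance."""
    white = rng.standard_normal(shape)
    return signal.sosfiltfilt(sos, white, axis=-1) / gain


@dataclass(frozen=True)
class ConditionTruth:
    """Generating parameters of one subject x condition."""

    subject_id: str
    condition: str
    vf_sigma2: float
    bias: float
    online_var: float
    offline_var: float
    coupling: float
    expected_online_cov_sum: float
    expected_offline_cov_sum: float


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth ledger of a generated cohort."""

    config: SynthConfig
    per_condition: tuple[ConditionTruth, ...]

    def lookup(self, subject_id: str, condition: str) -> ConditionTruth:
        for ct in self.per_condition:
            if ct.subject_id == subject_id and ct.condition == condition:
                return ct
        raise KeyError((subject_id, condition))

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "per_condition": [asdict(ct) for ct in self.per_condition],
        }


def _subject_params(cfg: SynthConfig, subj_idx: int) -> dict:
    """Per-subject condition parameters with between-subject scatter.

    A common lognormal factor scales both single-cue variances (subjects
    differ in overall noisiness, not in relative cue quality) and a common
    shift moves both biases; the FI condition is fused from the subject's
    own F and I parameters unless the config pins it explicitly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + subj_idx]))
    scale = float(np.exp(rng.normal(0.0, cfg.subject_scale_sd)))
    shift = float(rng.normal(0.0, cfg.subject_bias_sd))
    sig = {c: cfg.vf_sigma2[c] * scale for c in ("F", "I") }
    b = {c: cfg.bias[c] + shift for c in ("F", "I")}
    if cfg.vf_sigma2.get("FI") is None:
        sig["FI"] = fused_variance(sig["F"], sig["I"])
    else:
        sig["FI"] = cfg.vf_sigma2["FI"] * scale
    if cfg.bias.get("FI") is None:
        b["FI"] = fused_bias(b["F"], b["I"], fusion_weights(sig["F"], sig["I"]))
    else:
        b["FI"] = cfg.bias["FI"] + shift
    return {"sigma2": sig, "bias": b}


def _generate_condition(
    cfg: SynthConfig,
    subject_id: str,
    subj_idx: int,
    cond_idx: int,
    condition: str,
    sigma2: float,
    bias: float,
    sos,
    gain: float,
) -> ConditionSet:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subj_idx, cond_idx]))
    n_tr = cfg.n_trials
    T = int(round(cfg.trial_duration_s * cfg.sample_rate))
    s = np.asarray(cfg.sharing)
    kappa = cfg.coupling
    k_pos = kappa if kappa > 0 else 0.0
    k_neg = -kappa if kappa < 0 else 0.0

    v_on = cfg.online_fraction * sigma2
    v_off = (1.0 - cfg.online_fraction) * sigma2
    plateau = cfg.target_force - bias

    # ---- offline (between-trial) parts, at finger level ------------------
    common_off = rng.normal(0.0, np.sqrt(k_pos * v_off), size=n_tr)
    indep_off = rng.normal(0.0, 1.0, size=(n_tr, 4)) * np.sqrt((1 - k_pos) * v_off * s)
    null_off = (
        rng.normal(0.0, np.sqrt(k_neg * v_off / 3.0), size=(n_tr, 3)) @ _NULL_BASIS.T
    )
    finger_means = s * (plateau + common_off[:, None]) + indep_off + null_off

    # ---- online (within-trial) parts, low-pass filtered ------------------
    common_on = _online_noise(rng, (n_tr, T), sos, gain) * np.sqrt(k_pos * v_on)
    indep_on = _online_noise(rng, (n_tr, 4, T), sos, gain) * np.sqrt(
        (1 - k_pos) * v_on * s
    )[None, :, None]
    null_on = np.einsum(
        "kf,nkt->nft",
        _NULL_BASIS.T,
        _online_noise(rng, (n_tr, 3, T), sos, gain) * np.sqrt(k_neg * v_on / 3.0),
    )

    forces = (
        finger_means[:, None, :]
        + (s[None, :] * common_on[:, :, None]).reshape(n_tr, T, 4)
        + np.transpose(indep_on, (0, 2, 1))
        + np.transpose(null_on, (0, 2, 1))
    )

    # ---- ramp envelope ---------------------------------------------------
    t = np.arange(T) / cfg.sample_rate
    env = np.ones(T)
    n_ramp = int(round(cfg.ramp_s * cfg.sample_rate))
    if n_ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = up
        env[-n_ramp:] = up[::-1]
    forces *= env[None, :, None]

    trials = tuple(
        TrialRecording(
            subject_id=subject_id,
            condition=condition,
            trial_index=i + 1,
            sample_rate=cfg.sample_rate,
            forces=forces[i],
            t0=0.0,
        )
        for i in range(n_tr)
    )
    return ConditionSet(
        subject_id=subject_id,
        condition=condition,
        trials=trials,
        target_force=cfg.target_force,
    )


def _expected_cov_sum(kappa: float, v: float, sharing) -> float:
    """Summed between-finger covariance implied by the coupling mechanism."""
    s = np.asarray(sharing)
    if kappa >= 0:
        return float(kappa * v * (1.0 - np.sum(s * s)))
    return float(kappa * v)


def generate_cohort(cfg: SynthConfig) -> tuple[list[ConditionSet], CohortTruth]:
    """Generate a full cohort and its ground-truth parameter ledger.

    Returns one ConditionSet per subject x condition (subjects S01, S02,
    ... in order, conditions in F, I, FI order) plus a :class:`CohortTruth`
    recording every generating parameter.  Deterministic in ``cfg.seed``.
    """
    sos = _lowpass_sos(cfg.lowpass_cutoff_hz, cfg.sample_rate)
    T = int(round(cfg.trial_duration_s * cfg.sample_rate))
    gain = _filtfilt_unit_gain(sos, T, cfg.sample_rate, cfg.lowpass_cutoff_hz)

    sets: list[ConditionSet] = []
    truths: list[ConditionTruth] = []
    for subj_idx in range(cfg.n_subjects):
        subject_id = f"S{subj_idx + 1:02d}"
        params = _subject_params(cfg, subj_idx)
        for cond_idx, condition in enumerate(CONDITIONS):
            sigma2 = params["sigma2"][condition]
            bias = params["bias"][condition]
            sets.append(
                _generate_condition(
                    cfg, subject_id, subj_idx, cond_idx, condition, sigma2, bias,
                    sos, gain,
                )
            )
            v_on = cfg.online_fraction * sigma2
            v_off = (1 - cfg.online_fraction) * sigma2
            truths.append(
                ConditionTruth(
                    subject_id=subject_id,
                    condition=condition,
                    vf_sigma2=sigma2,
                    bias=bias,
                    online_var=v_on,
                    offline_var=v_off,
                    coupling=cfg.coupling,
                    expected_online_cov_sum=_expected_cov_sum(
                        cfg.coupling, v_on, cfg.sharing
                    ),
                    expected_offline_cov_sum=_expected_cov_sum(
                        cfg.coupling, v_off, cfg.sharing
                    ),
                )
            )
    return sets, CohortTruth(config=cfg, per_condition=tuple(truths))


def simulate_dataset(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write it to disk in the canonical formats.

    Writes ``trials.csv`` (long-format trial table), ``truth.json``
    (ground-truth ledger) and ``synth_config.json``; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets, truth = generate_cohort(cfg)
    paths = {
        "trials": out / "trials.csv",
        "truth": out / "truth.json",
        "config": out / "synth_config.json",
    }
    write_trials(sets, paths["trials"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2))
    paths["config"].write_text(json.dumps(cfg.to_dict(), indent=2))
    return paths
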