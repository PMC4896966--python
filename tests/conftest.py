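from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfsynergy import ConditionSet, TrialRecording

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_condition_set(
    forces,
    f_t: float = 10.0,
    subject: str = "S01",
    condition: str = "F",
    sample_rate: float = 100.0,
) -> ConditionSet:
    """Build a ConditionSet from a list of T x 4 force arrays."""
    trials = tuple(
        TrialRecording(
            subject_id=subject,
            condition=condition,
            trial_index=i + 1,
            sample_rate=sample_rate,
            forces=np.asarray(f, dtype=float),
        )
        for i, f in enumerate(forces)
    )
    return ConditionSet(
        subject_id=subject, condition=condition, trials=trials, target_force=f_t
    )


def set_from_vf(vf_trials, f_t: float = 10.0, **kw) -> ConditionSet:
    """ConditionSet whose per-trial VF forces equal the given sequences
    (each finger carries a quarter of the VF force)."""
    forces = [np.column_stack([np.asarray(v, dtype=float) / 4.0] * 4) for v in vf_trials]
    return make_condition_set(forces, f_t=f_t, **kw)


def random_condition_sets(rng: np.random.Generator, n: int, **kw):
    """Random small instances spanning 2-20 trials and 10-1000 samples."""
    out = []
    for _ in range(n):
        n_trials = int(rng.integers(2, 21))
        n_samples = int(rng.integers(10, 1001))
        base = rng.normal(4.5, 1.0, size=4)
        forces = [
            base + rng.normal(0.0, rng.uniform(0.05, 1.5), size=(n_samples, 4))
            for _ in range(n_trials)
        ]
        out.append(make_condition_set(forces, f_t=float(rng.uniform(15, 21)), **kw))
    return out


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture()
def toy_set() -> ConditionSet:
    """Two-trial instance with VF forces (9,10,11,10) and (12,12,12,12)
    around a 10 N target: OMSE 2.25 = 0.25 online + 1 offline + 1 systematic."""
    return set_from_vf([[9.0, 10.0, 11.0, 10.0], [12.0, 12.0, 12.0, 12.0]], f_t=10.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small low-rate synthetic cohort shared across tests."""
    from mfsynergy import SynthConfig, generate_cohort

    cfg = SynthConfig(
        n_subjects=3,
        n_trials=8,
        trial_duration_s=10.0,
        sample_rate=100.0,
        ramp_s=1.5,
        seed=42,
    )
    sets, truth = generate_cohort(cfg)
    return cfg, sets, truth
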