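from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from mfsynergy import (
    HierarchicalVariability,
    compute_omse,
    decompose_components,
    hvd,
    ucm_split,
)

from conftest import make_condition_set, random_condition_sets, set_from_vf
from oracles import naive_hvd, naive_omse

FIELDS = (
    "omse",
    "grand_mean",
    "bias",
    "systematic_error",
    "online_var_vf",
    "offline_var_vf",
    "online_cov_sum",
    "offline_cov_sum",
    "online_task_relevant",
    "online_task_irrelevant",
    "offline_task_relevant",
    "offline_task_irrelevant",
)


class TestDecomposeComponents:
    def test_two_trial_hand_computation(self):
        cs = set_from_vf([[10.0] * 4, [12.0] * 4])
        comp = decompose_components(cs)
        assert comp.m == pytest.approx(11.0)
        assert comp.E == pytest.approx([-1.0, 1.0])

    def test_identical_constant_trials(self):
        cs = set_from_vf([[7.0] * 5] * 3)
        comp = decompose_components(cs)
        assert comp.m == pytest.approx(7.0)
        assert np.allclose(comp.E, 0.0)
        assert np.allclose(comp.X, 0.0)

    @given(st.integers(0, 2**32 - 1))
    def test_reconstruction_identity(self, seed):
        rng = np.random.default_rng(seed)
        vfs = rng.normal(10, 2, size=(3, 17))
        cs = set_from_vf(vfs)
        comp = decompose_components(cs)
        recon = comp.X + comp.E[:, None] + comp.m
        np.testing.assert_allclose(recon, cs.vf_array(), rtol=0, atol=1e-12)
        assert abs(comp.E.mean()) < 1e-12
        assert np.all(np.abs(comp.X.mean(axis=1)) < 1e-12)


class TestComputeOmse:
    def test_worked_toy_instance(self, toy_set):
        assert compute_omse(toy_set) == pytest.approx(2.25, abs=1e-12)

    def test_perfect_performance_is_zero(self):
        cs = set_from_vf([[10.0] * 6] * 2, f_t=10.0)
        assert compute_omse(cs) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for cs in random_condition_sets(rng, 5):
            expected = naive_omse([t.forces for t in cs.trials], cs.target_force)
            assert compute_omse(cs) == pytest.approx(expected, rel=1e-12)


class TestUcmSplit:
    def test_identity_covariance(self):
        rel, irr = ucm_split(np.eye(4))
        assert rel == pytest.approx(1.0)
        assert irr == pytest.approx(3.0)

    def test_perfect_positive_coupling(self):
        rel, irr = ucm_split(np.ones((4, 4)))
        assert rel == pytest.approx(4.0)
        assert irr == pytest.approx(0.0, abs=1e-12)

    def test_pure_compensation_has_zero_task_relevant(self, rng):
        # build a PSD matrix whose rows/columns sum to zero
        b = rng.normal(size=(4, 3))
        b -= b.mean(axis=0)
        sigma = b @ b.T
        rel, _ = ucm_split(sigma)
        assert rel == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_input_raises(self):
        m = np.eye(4)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ucm_split(m)


class TestHvd:
    def test_worked_toy_decomposition(self, toy_set):
        r = hvd(toy_set)
        assert r.online_var_vf == pytest.approx(0.25, abs=1e-12)
        assert r.offline_var_vf == pytest.approx(1.0, abs=1e-12)
        assert r.systematic_error == pytest.approx(1.0, abs=1e-12)
        assert r.omse == pytest.approx(2.25, abs=1e-12)
        assert r.bias == pytest.approx(-1.0)

    def test_perfect_compensation_limit(self, rng):
        # two active fingers with exactly opposite within-trial signals
        x = rng.normal(0, 1, size=40)
        forces = []
        for _ in range(3):
            f = np.zeros((40, 4))
            f[:, 0] = 5.0 + x
            f[:, 1] = 5.0 - x
            forces.append(f)
        r = hvd(make_condition_set(forces, f_t=10.0))
        assert r.online_var_vf == pytest.approx(0.0, abs=1e-12)
        assert r.online_cov_sum == pytest.approx(-2.0 * x.var(), rel=1e-10)

    def test_matches_naive_oracle_and_identities(self, rng):
        for cs in random_condition_sets(rng, 8):
            r = hvd(cs)
            ref = naive_hvd([t.forces for t in cs.trials], cs.target_force)
            for name in FIELDS:
                assert getattr(r, name) == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name
            np.testing.assert_allclose(r.online_finger_vars, ref["online_finger_vars"])
            np.testing.assert_allclose(r.offline_finger_vars, ref["offline_finger_vars"])

    def test_trial_permutation_invariance(self, rng):
        cs = random_condition_sets(rng, 1)[0]
        perm = rng.permutation(cs.n_trials)
        trials = tuple(
            type(cs.trials[0])(
                subject_id=cs.subject_id,
                condition=cs.condition,
                trial_index=i + 1,
                sample_rate=cs.sample_rate,
                forces=cs.trials[j].forces,
            )
            for i, j in enumerate(perm)
        )
        shuffled = type(cs)(cs.subject_id, cs.condition, trials, cs.target_force)
        a, b = hvd(cs), hvd(shuffled)
        for name in FIELDS:
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-10)

    @given(st.integers(0, 2**32 - 1))
    def test_additivity_identities(self, seed):
        rng = np.random.default_rng(seed)
        n_trials = int(rng.integers(2, 8))
        forces = [rng.normal(2.5, 0.8, size=(25, 4)) for _ in range(n_trials)]
        r = hvd(make_condition_set(forces, f_t=float(rng.uniform(8, 12))))
        total = r.online_var_vf + r.offline_var_vf + r.systematic_error
        assert r.omse == pytest.approx(total, rel=1e-10)
        assert r.online_var_vf == pytest.approx(
            r.online_finger_vars.sum() + r.online_cov_sum, rel=1e-9, abs=1e-12
        )
        assert r.offline_var_vf == pytest.approx(
            r.offline_finger_vars.sum() + r.offline_cov_sum, rel=1e-9, abs=1e-12
        )
        assert r.online_task_relevant == pytest.approx(r.online_var_vf / 4, rel=1e-9)
        assert r.offline_task_relevant == pytest.approx(r.offline_var_vf / 4, rel=1e-9)


class TestModelInterface:
    def test_model_fit_equals_function(self, toy_set):
        res = HierarchicalVariability(toy_set).fit()
        assert res.omse == pytest.approx(hvd(toy_set).omse)

    def test_summary_mentions_components(self, toy_set):
        text = HierarchicalVariability(toy_set).fit().summary()
        for word in ("OMSE", "online", "offline", "systematic"):
            assert word in text

    def test_from_dataframe_round_trip(self, toy_set, tmp_path):
        import pandas as pd
        from mfsynergy import write_trials

        path = tmp_path / "t.csv"
        write_trials([toy_set], path)
        df = pd.read_csv(path)
        model = HierarchicalVariability.from_dataframe(
            df, subject="S01", condition="F", target_force=10.0
        )
        assert model.fit().omse == pytest.approx(2.25, abs=1e-12)
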