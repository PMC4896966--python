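from __future__ import annotations

import numpy as np
import pytest

from mfsynergy import (
    SynthConfig,
    generate_cohort,
    hvd,
    simulate_dataset,
    tone_map,
    window_condition_set,
)
from mfsynergy.simulate import _expected_cov_sum


class TestToneMap:
    def test_target_force_gives_reference_tone(self):
        for cond in ("F", "I", "FI"):
            tone = tone_map(18.0, cond)
            assert tone.frequency == pytest.approx(1000.0)
            assert tone.intensity == pytest.approx(70.0)

    def test_frequency_gain(self):
        tone = tone_map(19.0, "F")
        assert tone.frequency == pytest.approx(1007.0)
        assert tone.intensity == pytest.approx(70.0)

    def test_both_gains_in_combined_condition(self):
        tone = tone_map(17.0, "FI")
        assert tone.frequency == pytest.approx(993.0)
        assert tone.intensity == pytest.approx(69.3)

    def test_intensity_condition_keeps_frequency(self):
        tone = tone_map(20.0, "I")
        assert tone.frequency == pytest.approx(1000.0)
        assert tone.intensity == pytest.approx(71.4)

    def test_unknown_condition_raises(self):
        with pytest.raises(ValueError):
            tone_map(18.0, "Z")


class TestSynthConfig:
    def test_rejects_bad_sharing(self):
        with pytest.raises(ValueError, match="sharing"):
            SynthConfig(sharing=(0.5, 0.5, 0.2, 0.1))

    def test_rejects_bad_online_fraction(self):
        with pytest.raises(ValueError, match="online_fraction"):
            SynthConfig(online_fraction=1.5)

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError, match="vf_sigma2"):
            SynthConfig(vf_sigma2={"F": 0.0, "I": 0.5, "FI": None})

    def test_dict_round_trip(self):
        cfg = SynthConfig(n_subjects=2, seed=7)
        assert SynthConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateCohort:
    def test_structure_and_labels(self, small_cohort):
        cfg, sets, truth = small_cohort
        assert len(sets) == cfg.n_subjects * 3
        assert {cs.condition for cs in sets} == {"F", "I", "FI"}
        assert all(cs.n_trials == cfg.n_trials for cs in sets)
        assert len(truth.per_condition) == len(sets)

    def test_same_seed_is_bit_identical(self):
        cfg = SynthConfig(n_subjects=1, n_trials=3, trial_duration_s=8.0,
                          sample_rate=100.0, ramp_s=1.0, seed=11)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.force_array(), y.force_array())

    def test_different_seeds_differ(self):
        kw = dict(n_subjects=1, n_trials=3, trial_duration_s=8.0,
                  sample_rate=100.0, ramp_s=1.0)
        a, _ = generate_cohort(SynthConfig(seed=1, **kw))
        b, _ = generate_cohort(SynthConfig(seed=2, **kw))
        assert not np.array_equal(a[0].force_array(), b[0].force_array())

    def test_noiseless_limit_is_constant_plateau(self):
        cfg = SynthConfig(
            n_subjects=1, n_trials=3, trial_duration_s=8.0, sample_rate=100.0,
            ramp_s=1.0, seed=5,
            vf_sigma2={"F": 1e-18, "I": 1e-18, "FI": None},
            bias={"F": 0.5, "I": 0.5, "FI": None},
            subject_scale_sd=0.0, subject_bias_sd=0.0, coupling=0.0,
        )
        sets, _ = generate_cohort(cfg)
        win = window_condition_set(sets[0], 2.0, 6.0)
        vf = win.vf_array()
        assert np.allclose(vf, 18.0 - 0.5, atol=1e-6)

    def test_fi_defaults_to_fused_parameters(self, small_cohort):
        from mfsynergy import fused_bias, fused_variance, fusion_weights

        cfg, _, truth = small_cohort
        f = truth.lookup("S01", "F")
        i = truth.lookup("S01", "I")
        fi = truth.lookup("S01", "FI")
        assert fi.vf_sigma2 == pytest.approx(fused_variance(f.vf_sigma2, i.vf_sigma2))
        w = fusion_weights(f.vf_sigma2, i.vf_sigma2)
        assert fi.bias == pytest.approx(fused_bias(f.bias, i.bias, w))

    def test_parameter_recovery_coarse(self):
        """Total VF variance, its online/offline split, and the bias of a
        long single-subject run recover the generating parameters."""
        cfg = SynthConfig(
            n_subjects=1, n_trials=60, trial_duration_s=15.0, sample_rate=100.0,
            ramp_s=2.0, seed=9, subject_scale_sd=0.0, subject_bias_sd=0.0,
        )
        sets, truth = generate_cohort(cfg)
        cs = window_condition_set(next(s for s in sets if s.condition == "F"), 2.0, 13.0)
        r = hvd(cs)
        t = truth.lookup("S01", "F")
        assert r.total_var_vf == pytest.approx(t.vf_sigma2, rel=0.35)
        assert r.online_var_vf / r.total_var_vf == pytest.approx(
            cfg.online_fraction, abs=0.15
        )
        se_bias = np.sqrt(r.total_var_vf / cs.n_trials)
        assert abs(r.bias - t.bias) < 3 * se_bias

    @pytest.mark.parametrize("kappa", [-0.6, 0.6])
    def test_coupling_sign_controls_covariance_sign(self, kappa):
        cfg = SynthConfig(
            n_subjects=2, n_trials=12, trial_duration_s=10.0, sample_rate=100.0,
            ramp_s=1.5, seed=13, coupling=kappa,
        )
        sets, _ = generate_cohort(cfg)
        sums = []
        for cs in sets:
            r = hvd(window_condition_set(cs, 2.0, 8.5))
            sums.append(r.online_cov_sum + r.offline_cov_sum)
        assert np.sign(np.mean(sums)) == np.sign(kappa)

    def test_expected_cov_sum_formula(self):
        s = (0.30, 0.30, 0.22, 0.18)
        assert _expected_cov_sum(0.0, 1.0, s) == 0.0
        assert _expected_cov_sum(-0.4, 2.0, s) == pytest.approx(-0.8)
        pos = _expected_cov_sum(0.4, 2.0, s)
        assert 0.0 < pos < 0.8


class TestSimulateDataset:
    def test_writes_readable_artifacts(self, tmp_path):
        from mfsynergy import load_trials

        cfg = SynthConfig(n_subjects=1, n_trials=2, trial_duration_s=6.0,
                          sample_rate=50.0, ramp_s=1.0, seed=3)
        paths = simulate_dataset(cfg, tmp_path)
        sets = load_trials(paths["trials"], target_force=cfg.target_force)
        assert len(sets) == 3
        import json

        truth = json.loads(paths["truth"].read_text())
        assert truth["config"]["seed"] == 3
        assert len(truth["per_condition"]) == 3

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = SynthConfig(n_subjects=1, n_trials=2, trial_duration_s=6.0,
                          sample_rate=50.0, ramp_s=1.0, seed=4)
        p1 = simulate_dataset(cfg, tmp_path / "a")
        p2 = simulate_dataset(cfg, tmp_path / "b")
        assert p1["trials"].read_bytes() == p2["trials"].read_bytes()
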