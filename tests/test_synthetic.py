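"""Generator determinism, template properties, forward-kinematic consistency."""

import numpy as np
import pytest
from scipy.integrate import quad

from gaitnorm import pipeline
from gaitnorm.errors import ConfigurationError, InputError
from gaitnorm.events import ForceSeries, detect_heel_contacts
from gaitnorm.kinematics import JOINTS
from gaitnorm.synthetic import (
    GeneratorConfig,
    forward_kinematics,
    joint_angle_templates,
    make_profiles,
    synthesize_dataset,
    synthesize_trial,
)


class TestProfiles:
    def test_deterministic(self, small_config):
        p1 = make_profiles(small_config)
        p2 = make_profiles(small_config)
        assert p1 == p2

    def test_zero_subject_effect_degenerates(self):
        cfg = GeneratorConfig(n_subjects=6, n_trials_per_subject=1, subject_effect_sd=0.0)
        for p in make_profiles(cfg):
            assert all(v == 1.0 for v in p.amplitude_scales.values())
            assert all(v == 0.0 for v in p.offset_shifts.values())

    def test_full_cohort_size(self):
        cfg = GeneratorConfig(n_subjects=200, n_trials_per_subject=10)
        assert len(make_profiles(cfg)) == 200

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 4},
            {"marker_rate": 0.0},
            {"grf_rate": 900.0},  # not an integer multiple of 200
            {"cycle_fraction_stance": 1.2},
            {"noise_sd_angle": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**kwargs)


class TestTemplates:
    def test_zero_amplitude_gives_constant_offsets(self, small_config):
        p = make_profiles(small_config)[0]
        p.amplitude_scales = {j: 0.0 for j in JOINTS}
        phases = np.linspace(0, 1, 17)
        vals = joint_angle_templates(p, phases)
        expect = np.array([p.offset_shifts[j] for j in JOINTS])
        np.testing.assert_allclose(vals, np.tile(expect, (17, 1)), atol=1e-12)

    def test_periodic(self, small_config):
        p = make_profiles(small_config)[0]
        np.testing.assert_allclose(
            joint_angle_templates(p, 0.0), joint_angle_templates(p, 1.0), atol=1e-12
        )

    def test_cycle_mean_equals_constant_term(self, small_config):
        from gaitnorm.synthetic import TEMPLATE_COEFFS

        p = make_profiles(small_config)[1]
        for j_idx, joint in enumerate(JOINTS):
            mean, _ = quad(lambda ph: joint_angle_templates(p, ph)[j_idx], 0, 1, limit=200)
            expect = p.offset_shifts[joint] + p.amplitude_scales[joint] * TEMPLATE_COEFFS[joint]["a0"]
            np.testing.assert_allclose(mean, expect, atol=1e-6)

    def test_phase_outside_unit_interval_rejected(self, small_config):
        p = make_profiles(small_config)[0]
        with pytest.raises(InputError):
            joint_angle_templates(p, 1.5)


class TestForwardKinematics:
    def test_foot_rigid_body_consistency(self, one_trial):
        labels = [f"L_{m}" for m in ("HEEL", "MT1", "MT5", "MML", "LML")]
        pos = [one_trial.markers[lab].positions for lab in labels]
        for i in range(len(pos)):
            for k in range(i + 1, len(pos)):
                d = np.linalg.norm(pos[i] - pos[k], axis=1)
                assert np.ptp(d) < 1e-9

    def test_frozen_angles_transport_rigidly(self, small_config):
        p = make_profiles(small_config)[0]
        t = np.arange(100) / 200.0
        const = {s: np.tile([20.0, 15.0, -5.0], (100, 1)) for s in ("left", "right")}
        markers = forward_kinematics(p, const, t)
        heel, mt1 = markers["L_HEEL"].positions, markers["L_MT1"].positions
        np.testing.assert_allclose(
            np.linalg.norm(heel - mt1, axis=1), np.linalg.norm(heel[0] - mt1[0]), atol=1e-12
        )
        # orientation constant: relative vector does not rotate
        np.testing.assert_allclose(heel - mt1, np.tile(heel[0] - mt1[0], (100, 1)), atol=1e-12)

    def test_angle_extraction_recovers_truth(self, one_trial):
        ang = pipeline.ipsilateral_joint_angles(one_trial.markers, one_trial.side).as_array()
        err = ang - one_trial.truth_angles[one_trial.side]
        rms = np.sqrt((err**2).mean(axis=0))
        assert np.all(rms < 0.5), rms

    def test_stride_length_scales_translation(self, small_config):
        p = make_profiles(small_config)[0]
        t = np.arange(50) / 200.0
        const = {s: np.zeros((50, 3)) for s in ("left", "right")}
        m1 = forward_kinematics(p, const, t)
        import copy

        p2 = copy.deepcopy(p)
        p2.stride_length *= 2.0
        m2 = forward_kinematics(p2, const, t)
        d1 = m1["PELVIS_O"].positions[-1, 1] - m1["PELVIS_O"].positions[0, 1]
        d2 = m2["PELVIS_O"].positions[-1, 1] - m2["PELVIS_O"].positions[0, 1]
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-12)

    def test_non_finite_angles_rejected(self, small_config):
        p = make_profiles(small_config)[0]
        bad = {s: np.full((10, 3), np.nan) for s in ("left", "right")}
        with pytest.raises(InputError):
            forward_kinematics(p, bad, np.arange(10) / 200.0)


class TestDataset:
    def test_trial_count(self, small_config, small_trials):
        assert len(small_trials) == small_config.n_subjects * small_config.n_trials_per_subject

    def test_byte_identical_regeneration(self, small_config, small_trials):
        again = synthesize_dataset(small_config)
        for a, b in zip(small_trials, again):
            assert a.subject_id == b.subject_id and a.side == b.side
            np.testing.assert_array_equal(a.truth_angles["left"], b.truth_angles["left"])
            np.testing.assert_array_equal(a.grf_vertical["right"], b.grf_vertical["right"])
            np.testing.assert_array_equal(
                a.markers["L_HEEL"].positions, b.markers["L_HEEL"].positions
            )

    def test_grf_nonnegative_and_zero_in_swing(self, one_trial):
        for limb in ("left", "right"):
            f = one_trial.grf_vertical[limb]
            assert np.all(f >= 0.0)
            assert np.any(f == 0.0)  # swing exists

    def test_grf_stance_fraction(self, small_config, one_trial):
        f = one_trial.grf_vertical[one_trial.side]
        frac_loaded = np.mean(f > 0.0)
        # interior cycles are fully covered; trial edges may clip stance
        assert abs(frac_loaded - small_config.cycle_fraction_stance) < 0.1

    def test_at_least_two_ipsilateral_contacts(self, small_trials):
        for tr in small_trials:
            assert len(tr.scheduled_contacts[tr.side]) >= 2

    def test_no_stochastic_terms_means_identical_targets(self):
        cfg = GeneratorConfig(
            n_subjects=5, n_trials_per_subject=1, noise_sd_angle=0.0, subject_effect_sd=0.0
        )
        profiles = make_profiles(cfg)
        phases = np.linspace(0, 1, 33)
        curves = [joint_angle_templates(p, phases) for p in profiles]
        for c in curves[1:]:
            np.testing.assert_array_equal(c, curves[0])
        # processed target rows agree too, up to cycle-boundary quantization
        # (heel contacts snap to the marker grid, shifting phase alignment by
        # up to ~0.25% of a cycle, which matters most on steep swing slopes)
        rows = [pipeline.process_trial(t).targets for t in synthesize_dataset(cfg)]
        for r in rows[1:]:
            np.testing.assert_allclose(r, rows[0], atol=1.5)

    def test_truth_and_marker_sample_counts_agree(self, one_trial):
        T = len(one_trial.markers["L_HEEL"])
        assert one_trial.truth_angles["left"].shape == (T, 3)

    def test_noise_sd_close_to_requested(self):
        cfg = GeneratorConfig(
            n_subjects=5, n_trials_per_subject=1, noise_sd_angle=2.0, subject_effect_sd=0.0
        )
        trials = synthesize_dataset(cfg)
        clean = synthesize_dataset(
            GeneratorConfig(n_subjects=5, n_trials_per_subject=1, noise_sd_angle=0.0, subject_effect_sd=0.0)
        )
        sds = [
            (t.truth_angles["left"] - c.truth_angles["left"]).std(axis=0)
            for t, c in zip(trials, clean)
        ]
        np.testing.assert_allclose(np.mean(sds), 2.0, rtol=0.15)


def test_heel_contact_detector_matches_schedule(small_trials):
    """Detected contacts on raw GRF sit within one GRF sample of the schedule."""
    for tr in small_trials[:4]:
        detected = detect_heel_contacts(ForceSeries(tr.grf_vertical[tr.side], tr.grf_rate))
        scheduled = tr.scheduled_contacts[tr.side]
        # every scheduled onset strictly inside the record should be found
        interior = scheduled[(scheduled > 0.01) & (scheduled < len(tr.grf_vertical[tr.side]) / tr.grf_rate - 0.01)]
        assert len(detected) >= len(interior)
        for s in interior:
            # continuous schedule quantized to the force sample grid
            assert np.min(np.abs(detected - s)) <= 1.001 / tr.grf_rate
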