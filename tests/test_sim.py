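"""Synthetic generator: schedules, vibration physics, sensor model, pose tracks."""

import numpy as np
import pytest

from cagevib import (
    ActivityClass,
    ConfigError,
    SimConfig,
    label_windows,
    sample_schedule,
    spectrum,
    synth_pose,
    synth_vibration,
)
from cagevib.sim import CLASS_ORDER, ActivitySchedule, Bout, ModalMode

R, S, L = CLASS_ORDER


def one_bout(cls, duration):
    return ActivitySchedule([Bout(cls, 0.0, duration)])


class TestSchedule:
    def test_absorbing_identity_chain_yields_single_bout(self):
        config = SimConfig(duration=300.0, transition=np.eye(3), start_class=R)
        schedule = sample_schedule(config, seed=0)
        assert len(schedule.bouts) == 1
        assert schedule.bouts[0].cls is R
        assert schedule.duration == pytest.approx(300.0)

    def test_symmetric_chain_dwell_fractions_near_uniform(self):
        # equal mean bout lengths + symmetric transitions -> 1/3 each
        config = SimConfig(
            duration=10 * 3600.0,
            bout_mean_s={R: 90.0, S: 90.0, L: 90.0},
        )
        fractions = sample_schedule(config, seed=7).dwell_fractions()
        for cls in CLASS_ORDER:
            assert fractions[cls] == pytest.approx(1 / 3, abs=0.05)

    def test_same_seed_same_schedule(self):
        config = SimConfig(duration=3600.0)
        a = sample_schedule(config, seed=42)
        b = sample_schedule(config, seed=42)
        assert a.bouts == b.bouts

    def test_bouts_contiguous_and_min_length(self):
        config = SimConfig(duration=1800.0)
        schedule = sample_schedule(config, seed=3)
        t = 0.0
        for bout in schedule.bouts:
            assert bout.start == pytest.approx(t)
            assert bout.duration >= config.min_bout_s - 1e-9
            t = bout.end
        assert t == pytest.approx(1800.0)

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(transition=np.full((3, 3), 0.5))

    def test_duration_shorter_than_a_bout_rejected(self):
        from cagevib.errors import ContractError

        with pytest.raises(ContractError):
            sample_schedule(SimConfig(duration=20.0, min_bout_s=30.0), seed=0)


class TestVibration:
    def test_noise_only_rms_matches_closed_form(self, spec):
        config = SimConfig(duration=60.0, amplitude_scale=0.0, gyro=True)
        stream = synth_vibration(one_bout(R, 60.0), config, seed=1)
        expected = spec.accel_noise_rms
        for axis in ("x", "y", "z"):
            rms = float(np.sqrt(np.mean(stream.accel(axis) ** 2)))
            assert rms == pytest.approx(expected, rel=0.02)
        gyro_rms = float(np.sqrt(np.mean(stream.gyro_x**2)))
        assert gyro_rms == pytest.approx(spec.gyro_noise_rms, rel=0.02)

    def test_single_mode_impulse_peaks_at_mode_frequency(self):
        config = SimConfig(
            duration=15.0,
            noise=False,
            quantize=False,
            gyro=False,
            modes=(ModalMode("z", 120.0, 120.0, 5e-3, {L: 1.0}),),
            impulse_rate={R: 0.0, S: 0.0, L: 1.0},
            strong_event_rate=0.0,
            permanent_tone=(100.0, 0.0),
        )
        stream = synth_vibration(one_bout(L, 15.0), config, seed=5)
        assert np.abs(stream.accel_z).max() > 0
        s = spectrum(stream.accel_z, config.spec.accel_rate)
        peak = s.freqs[int(np.argmax(s.magnitude))]
        assert peak == pytest.approx(120.0, abs=0.5)
        assert np.abs(stream.accel_x).max() == 0.0

    def test_silent_config_gives_zero_stream(self):
        config = SimConfig(duration=30.0, noise=False, amplitude_scale=0.0, gyro=False)
        stream = synth_vibration(one_bout(S, 30.0), config, seed=2)
        for axis in ("x", "y", "z"):
            assert np.abs(stream.accel(axis)).max() == 0.0

    def test_samples_are_lsb_multiples(self, spec):
        config = SimConfig(duration=20.0, gyro=False)
        stream = synth_vibration(one_bout(L, 20.0), config, seed=9)
        counts = stream.accel_x / spec.accel_lsb
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-6)

    def test_seeded_determinism_bit_identical(self):
        config = SimConfig(duration=30.0, gyro=True)
        schedule = sample_schedule(config, seed=0)
        a = synth_vibration(schedule, config, seed=4)
        b = synth_vibration(schedule, config, seed=4)
        np.testing.assert_array_equal(a.accel_z, b.accel_z)
        np.testing.assert_array_equal(a.gyro_x, b.gyro_x)

    def test_mode_above_nyquist_rejected(self):
        mode = ModalMode("z", 3000.0, 3000.0, 1e-3, {L: 1.0})
        config = SimConfig(duration=15.0, modes=(mode,))
        with pytest.raises(ConfigError):
            synth_vibration(one_bout(L, 15.0), config, seed=0)

    def test_gyro_channels_carry_no_activity_signal(self):
        # activity modulates accel event rates, never the gyro (noise only)
        config = SimConfig(duration=30.0, gyro=True, noise=False)
        stream = synth_vibration(one_bout(L, 30.0), config, seed=6)
        assert np.abs(stream.gyro_x).max() == 0.0
        assert np.abs(stream.accel_x).max() > 0.0


class TestPose:
    def test_resting_windows_average_published_mean(self):
        config = SimConfig(duration=1800.0)
        track = synth_pose(one_bout(R, 1800.0), config, seed=11)
        labels = label_windows(track)
        means = np.array([l.mean_velocity for l in labels if l.valid])
        assert means.mean() == pytest.approx(0.45, abs=0.02)

    def test_zero_velocity_config_freezes_positions(self):
        config = SimConfig(
            duration=60.0,
            velocity={R: (0.0, 0.0), S: (1e-9, 0.0), L: (2e-9, 0.0)},
            misdetection_rate=0.0,
        )
        track = synth_pose(one_bout(R, 60.0), config, seed=12)
        from cagevib import head_velocity, point_speeds

        speeds, valid = point_speeds(track)
        assert np.nanmax(head_velocity(speeds, valid, track.fps).speeds) == pytest.approx(0.0)

    def test_locomotion_windows_exceed_threshold(self):
        config = SimConfig(duration=1800.0)
        track = synth_pose(one_bout(L, 1800.0), config, seed=13)
        labels = label_windows(track)
        fast = [l for l in labels if l.valid and l.mean_velocity > 50.0]
        assert len(fast) / len(labels) >= 0.95

    def test_resting_roundtrip_label_recovery(self):
        # schedule -> pose -> labeler recovers resting >= 99% of the time
        config = SimConfig(duration=3600.0)
        track = synth_pose(one_bout(R, 3600.0), config, seed=14)
        labels = [l for l in label_windows(track) if l.valid]
        hit = sum(l.label is ActivityClass.RESTING for l in labels) / len(labels)
        assert hit >= 0.99

    def test_same_seed_identical_track(self):
        config = SimConfig(duration=120.0)
        schedule = sample_schedule(config, seed=1)
        a = synth_pose(schedule, config, seed=2)
        b = synth_pose(schedule, config, seed=2)
        for name in a.positions:
            np.testing.assert_array_equal(a.positions[name], b.positions[name])
            np.testing.assert_array_equal(a.likelihood[name], b.likelihood[name])


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        config = SimConfig(duration=123.0, amplitude_scale=0.7,
                           start_class=ActivityClass.STATIONARY)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back.duration == 123.0
        assert back.amplitude_scale == 0.7
        assert back.start_class is ActivityClass.STATIONARY
        assert back.modes == config.modes
        np.testing.assert_array_equal(back.transition, config.transition)
        assert back.velocity == config.velocity
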