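"""Behavioural and network read-outs against constructed trajectories."""

import numpy as np
import pytest

from bgreach import metrics as mx


def _traj(positions, target=(0.0, 0.0), dt=0.05, eps=0.1):
    p = np.asarray(positions, float)
    return mx.ReachTrajectory(times=np.arange(p.shape[0]) * dt, positions=p,
                              target=np.asarray(target), eps_reach=eps)


class TestMovementTime:
    def test_starting_at_target_is_zero(self):
        t = _traj(np.zeros((5, 2)))
        assert mx.movement_time(t) == 0.0

    def test_linear_approach_crossing(self):
        # distance 1.0 -> 0, linearly over 20 steps; first sample strictly
        # inside the 0.1 threshold is step 18 (the boundary sample rounds
        # just below 0.1 in floating point)
        xs = np.stack([np.linspace(1.0, 0.0, 21), np.zeros(21)], axis=1)
        t = _traj(xs)
        assert np.isclose(mx.movement_time(t), 18 * 0.05)

    def test_never_reaching(self):
        xs = np.tile([1.0, 0.0], (10, 1))
        assert mx.movement_time(_traj(xs)) == mx.NON_REACHABLE


class TestVelocity:
    def test_uniform_motion(self):
        xs = np.stack([np.linspace(0, 1, 21), np.zeros(21)], axis=1)
        t = _traj(xs, target=(5.0, 0.0))
        speeds, pv, tp, av = mx.velocity_profile(t)
        assert np.isclose(pv, 1.0) and np.isclose(av, 1.0)

    def test_bell_profile_peak_location(self):
        ts = np.linspace(0, 1, 21)
        x = 0.5 * (1 - np.cos(np.pi * ts))  # smooth 0 -> 1, peak speed mid
        t = _traj(np.stack([x, np.zeros(21)], axis=1), target=(5.0, 0.0))
        _, pv, tp, _ = mx.velocity_profile(t)
        assert 0.4 <= tp <= 0.6
        assert pv > 1.0

    def test_stationary_trajectory(self):
        t = _traj(np.ones((8, 2)), target=(5.0, 0.0))
        speeds, pv, tp, av = mx.velocity_profile(t)
        assert pv == 0.0 and av == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            mx.velocity_profile(_traj(np.zeros((1, 2)), target=(1, 1)))


class TestRMSAcceleration:
    def test_constant_velocity_is_zero(self):
        xs = np.stack([np.linspace(0, 2, 30), np.zeros(30)], axis=1)
        assert mx.rms_acceleration(_traj(xs, target=(9, 9))) < 1e-10

    def test_sinusoid_matches_analytic(self):
        a, w = 0.05, 2 * np.pi * 2.0  # 2 Hz, 5 cm amplitude
        ts = np.arange(0, 3, 0.01)
        xs = np.stack([a * np.sin(w * ts), np.zeros_like(ts)], axis=1)
        t = mx.ReachTrajectory(times=ts, positions=xs, target=np.array([9.0, 9.0]))
        expected = a * w**2 / np.sqrt(2)
        assert np.isclose(mx.rms_acceleration(t), expected, rtol=0.02)

    def test_single_spike_hand_computed(self):
        xs = np.zeros((5, 2))
        xs[2, 0] = 0.01  # one-sample displacement
        t = _traj(xs, target=(9, 9), dt=0.1)
        # second differences of x: [0.01, -0.02, 0.01] / dt^2
        acc = np.array([0.01, -0.02, 0.01]) / 0.01
        assert np.isclose(mx.rms_acceleration(t), np.sqrt(np.mean(acc**2)))

    def test_too_short(self):
        with pytest.raises(ValueError):
            mx.rms_acceleration(_traj(np.zeros((2, 2)), target=(1, 1)))


class TestSynchrony:
    def test_identical_sinusoids_fully_synchronous(self):
        t = np.linspace(0, 1, 500)
        traces = np.tile(np.sin(2 * np.pi * 10 * t), (8, 1))
        assert np.isclose(mx.synchrony(traces), 1.0)

    def test_antiphase_pair_is_zero(self):
        t = np.linspace(0, 1, 500)
        s = np.sin(2 * np.pi * 10 * t)
        assert mx.synchrony(np.stack([s, -s])) < 1e-20

    def test_independent_noise_is_low(self):
        rng = np.random.default_rng(0)
        traces = rng.standard_normal((64, 4000))
        assert mx.synchrony(traces) < 0.1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        traces = rng.standard_normal((10, 300))
        perm = traces[rng.permutation(10)]
        assert np.isclose(mx.synchrony(traces), mx.synchrony(perm))

    def test_constant_traces_undefined(self):
        with pytest.raises(ValueError):
            mx.synchrony(np.ones((4, 100)))


class TestSpectrogram:
    def test_pure_tone_dominant_bin(self):
        fs = 200.0
        t = np.arange(0, 5, 1 / fs)
        f, tt, s = mx.spectrogram(np.sin(2 * np.pi * 20 * t), fs)
        assert abs(f[np.argmax(s.mean(axis=1))] - 20.0) <= 1.0

    def test_zero_signal_zero_power(self):
        f, tt, s = mx.spectrogram(np.zeros(1000), 200.0)
        assert np.all(s == 0.0)

    def test_band_power_partition(self):
        fs = 200.0
        t = np.arange(0, 5, 1 / fs)
        f, tt, s = mx.spectrogram(np.sin(2 * np.pi * 20 * t), fs)
        inside = mx.band_power(f, s, 15, 25)
        outside = mx.band_power(f, s, 40, 90)
        assert inside > 100 * outside

    def test_window_longer_than_trace(self):
        with pytest.raises(ValueError):
            mx.spectrogram(np.zeros(50), 200.0, window_s=1.0)


class TestClassification:
    @pytest.mark.parametrize("mt, colour", [
        (1.0, "green"), (1.999, "green"), (2.0, "yellow"), (3.0, "yellow"),
        (4.0, "yellow"), (4.001, "red"), (mx.NON_REACHABLE, "red"),
    ])
    def test_boundaries(self, mt, colour):
        assert mx.classify_movement_time(mt) == colour

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mx.classify_movement_time(-1.0)


class TestTherapeuticWindow:
    def test_contiguous_green_interval(self):
        t = np.arange(0, 13.0, 0.5)
        mt = np.full(t.size, 3.0)
        mt[(t >= 2.5) & (t <= 6.5)] = 1.0
        assert mx.therapeutic_window(t, mt, 2.0) == 4.0

    def test_never_green(self):
        t = np.arange(0, 13.0, 0.5)
        assert mx.therapeutic_window(t, np.full(t.size, 4.5), 2.0) == 0.0

    def test_first_bout_only_vs_brute_scan(self):
        t = np.arange(0, 13.0, 0.5)
        mt = np.full(t.size, 3.0)
        mt[(t >= 3.0) & (t <= 5.0)] = 1.0   # first bout: 2 h
        mt[(t >= 8.0) & (t <= 11.0)] = 1.0  # later bout ignored
        # brute scan for the first contiguous post-dose green run
        green = (mt < 2.0) & (t >= 2.0)
        start = np.flatnonzero(green)[0]
        end = start
        while end + 1 < t.size and green[end + 1]:
            end += 1
        assert mx.therapeutic_window(t, mt, 2.0) == t[end] - t[start] == 2.0

    def test_window_bounded_by_horizon(self):
        t = np.arange(0, 13.0, 0.5)
        mt = np.full(t.size, 0.5)
        assert mx.therapeutic_window(t, mt, 2.0) <= t[-1] - 2.0
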