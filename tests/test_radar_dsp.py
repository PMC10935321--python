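"""DC-offset estimation, arc rotation, arctangent demodulation, sync."""

import numpy as np
import pytest

from bioradar import radar_dsp, synth


def _arc(center, radius, theta0, theta1, n=200):
    th = np.linspace(theta0, theta1, n)
    return center + radius * np.exp(1j * th)


class TestDecimate:
    def test_constant_series_preserved(self):
        y = radar_dsp.decimate(np.full(1000, 3.5), 1000, 100)
        assert y.size == 100
        np.testing.assert_allclose(y, 3.5, rtol=1e-6)

    def test_sinusoid_amplitude_preserved(self):
        # 0.25 Hz tone decimated 100x keeps its amplitude within 1%
        fs_in, fs_out = 10_000.0, 100.0
        t = np.arange(int(60 * fs_in)) / fs_in
        x = np.sin(2 * np.pi * 0.25 * t)
        y = radar_dsp.decimate(x, fs_in, fs_out)
        f = np.fft.rfftfreq(y.size, 1 / fs_out)
        amp = 2 * np.abs(np.fft.rfft(y)) / y.size
        peak = f[np.argmax(amp)]
        assert abs(peak - 0.25) < 0.02
        assert abs(amp.max() - 1.0) < 0.01

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            radar_dsp.decimate(np.zeros(1000), 1000, 300)


class TestDcWindowEstimate:
    def test_quarter_arc_center_recovered(self):
        z = _arc(0.5 + 0.5j, 1.0, 0.3, 0.3 + np.pi / 2)
        est = radar_dsp.estimate_dc_window(z)
        assert abs(est - (0.5 + 0.5j)) < 1e-6

    def test_full_circle_matches_algebraic_fit(self):
        z = _arc(-0.2 + 0.8j, 0.7, 0, 2 * np.pi, n=500)
        est = radar_dsp.estimate_dc_window(z)
        oracle = radar_dsp._kasa_center(z)  # closed-form LS circle fit
        assert abs(est - oracle) < 1e-6
        assert abs(est - (-0.2 + 0.8j)) < 1e-6

    def test_degenerate_cloud_raises(self):
        with pytest.raises(radar_dsp.DegenerateCloudError):
            radar_dsp.estimate_dc_window(np.full(20, 1.0 + 1.0j))

    def test_dispersed_cluster_estimate_stays_outside_cloud(self):
        rng = np.random.default_rng(4)
        z = (0.3 + 0.1j) + 0.05 * (rng.standard_normal(200)
                                   + 1j * rng.standard_normal(200))
        est = radar_dsp.estimate_dc_window(z)
        centroid = np.mean(z)
        r_rms = np.sqrt(np.mean(np.abs(z - centroid) ** 2))
        assert abs(est - centroid) >= r_rms


class TestDcTrack:
    def test_constant_offset_tracked(self, clean_session):
        _, radar, _, _, _ = clean_session
        track = radar_dsp.estimate_dc_track(radar.samples, radar.fs)
        err = np.abs(track.per_sample - radar.dc_truth)
        assert err.max() < 1e-4

    def test_drifting_offset_follows_linear_path(self):
        spec = synth.SessionSpec(
            baseline_duration=60, induction_duration=60, noise_sd=0.0,
            motion_burst_rate=0.0, dc_offset=(0.3 + 0.2j, 0.5 - 0.1j),
            rng_seed=9)
        radar, _, _, _ = synth.generate_session(spec)
        track = radar_dsp.estimate_dc_track(radar.samples, radar.fs)
        err = np.abs(track.per_sample - radar.dc_truth)
        assert np.median(err) < 0.02

    def test_short_signal_broadcasts_single_estimate(self):
        z = _arc(0.5, 1.0, 0, np.pi / 2, n=300)  # 3 s at 100 Hz
        track = radar_dsp.estimate_dc_track(z, 100.0, window_len=10.0)
        assert track.estimates.size == 1
        assert np.all(track.per_sample == track.estimates[0])

    def test_windowed_estimates_satisfy_outside_cloud_invariant(self, clean_session):
        _, radar, _, _, _ = clean_session
        track = radar_dsp.estimate_dc_track(radar.samples, radar.fs)
        wlen = int(10.0 * radar.fs)
        hop = wlen // 2
        for k, est in enumerate(track.estimates):
            w = radar.samples[k * hop:k * hop + wlen]
            if w.size < 8:
                continue
            centroid = np.mean(w)
            r_rms = np.sqrt(np.mean(np.abs(w - centroid) ** 2))
            assert abs(est - centroid) >= r_rms


class TestRotation:
    def _track_for(self, z):
        return radar_dsp.DcOffsetTrack(np.array([z.size / 200.0]),
                                       np.array([0j]), np.zeros(z.size, complex))

    def test_rotated_arc_oscillates_about_zero_angle(self):
        z = _arc(0, 1.0, np.pi / 2 - 0.3, np.pi / 2 + 0.3, n=1000)
        out = radar_dsp.remove_dc_and_rotate(z, self._track_for(z))
        mean_angle = np.angle(np.mean(out / np.abs(out)))
        assert abs(mean_angle) < 0.01

    def test_arc_already_at_zero_is_identity(self):
        z = _arc(0, 1.0, -0.4, 0.4, n=1000)
        out = radar_dsp.remove_dc_and_rotate(z, self._track_for(z))
        np.testing.assert_allclose(out, z, atol=1e-9)

    def test_arc_straddling_pi_has_no_wrap_after_rotation(self):
        z = _arc(0, 1.0, np.pi - 0.4, np.pi + 0.4, n=1000)
        out = radar_dsp.remove_dc_and_rotate(z, self._track_for(z))
        phase = np.angle(out)  # deliberately not unwrapped
        assert np.max(np.abs(np.diff(phase))) < np.pi


class TestArctangent:
    def test_constant_input_gives_zero_displacement(self):
        sig, d = radar_dsp.arctangent_demodulate(np.ones(100, complex), 0.05)
        np.testing.assert_allclose(sig.values, 0.0)
        np.testing.assert_allclose(d, 0.0)

    def test_imaginary_unit_maps_to_eighth_wavelength(self):
        lam = synth.WAVELENGTH_M
        _, d = radar_dsp.arctangent_demodulate(np.full(10, 1j), lam)
        np.testing.assert_allclose(d, lam / 8.0, rtol=1e-12)

    def test_zero_magnitude_sample_rejected(self):
        with pytest.raises(ValueError):
            radar_dsp.arctangent_demodulate(np.array([1 + 0j, 0j]), 0.05)

    def test_noiseless_session_relative_rmse_below_1pct(self, clean_recovery):
        displacement, _, truth = clean_recovery
        d = displacement - displacement.mean()
        g = truth.displacement - truth.displacement.mean()
        rel_rmse = np.sqrt(np.mean((d - g) ** 2)) / np.sqrt(np.mean(g ** 2))
        assert rel_rmse < 0.01


class TestSynchronize:
    @staticmethod
    def _pattern_plus_breathing(fs, lag_samples=0, seed=0):
        pre = synth.sync_preamble_displacement(fs)
        t = np.arange(int(60 * fs)) / fs
        breathing = 0.004 * 0.5 * (1 - np.cos(2 * np.pi * 0.25 * t))
        x = np.concatenate([pre, breathing])
        rng = np.random.default_rng(seed)
        x = x + 1e-5 * rng.standard_normal(x.size)
        return np.concatenate([np.zeros(lag_samples), x])

    def test_scripted_lag_recovered(self):
        fs = 100.0
        a = self._pattern_plus_breathing(fs, lag_samples=300, seed=1)
        b = self._pattern_plus_breathing(fs, lag_samples=0, seed=2)
        (_, _), lag = radar_dsp.synchronize(a, b, fs)
        assert abs(lag - 3.00) <= 0.05

    def test_identical_series_zero_lag(self):
        fs = 100.0
        x = self._pattern_plus_breathing(fs, seed=3)
        (_, _), lag = radar_dsp.synchronize(x, x.copy(), fs)
        assert lag == 0.0

    def test_pure_noise_warns_and_returns_zero_lag(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(4000)
        b = rng.standard_normal(4000)
        with pytest.warns(UserWarning):
            (_, _), lag = radar_dsp.synchronize(a, b, 100.0)
        assert lag == 0.0


def test_recovery_error_monotone_in_noise():
    """Recovered-displacement RMSE does not decrease as noise grows."""
    from scipy.stats import spearmanr

    levels = np.linspace(0.0, 0.5, 10)
    noise, rmse = [], []
    for sd in levels:
        for seed in range(20):
            spec = synth.SessionSpec(
                baseline_duration=20, induction_duration=20, noise_sd=float(sd),
                motion_burst_rate=0.0, rng_seed=1000 + seed)
            radar, _, truth, _ = synth.generate_session(spec)
            _, d, _ = radar_dsp.demodulate(radar)
            g = truth.displacement - truth.displacement.mean()
            e = np.sqrt(np.mean(((d - d.mean()) - g) ** 2))
            noise.append(sd)
            rmse.append(e)
    rho = spearmanr(noise, rmse).statistic
    assert rho > 0
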