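"""High-gamma feature chain: filters, envelope, framing, stacking, scaling."""

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

import neurovoc as nv
from neurovoc.errors import InvalidRateError, TooShortError
from neurovoc.framing import FrameGrid

RATE = 1024.0


def tone(freq, rate=RATE, dur=2.0, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_passband_center_zero_phase(self):
        x = tone(120.0)
        y = nv.bandpass_high_gamma(x, RATE)
        interior = slice(256, -256)
        assert 0.9 <= np.max(np.abs(y[interior])) <= 1.0
        # zero-phase: cross-correlation peaks at lag 0
        lags = range(-5, 6)
        xc = [np.dot(x[512:-512], np.roll(y, l)[512:-512]) for l in lags]
        assert list(lags)[int(np.argmax(xc))] == 0

    def test_stopband_10hz(self):
        x = tone(10.0, dur=4.0)
        assert rms(nv.bandpass_high_gamma(x, RATE)) < 0.05 * rms(x)

    def test_designed_attenuation_contract(self):
        """>= 20 dB down at 35 and 340 Hz relative to 120 Hz (filtfilt doubles dB)."""
        sos = butter(4, (70.0, 170.0), btype="bandpass", fs=RATE, output="sos")
        w, h = sosfreqz(sos, worN=[35.0, 120.0, 340.0], fs=RATE)
        gain_db = 2 * 20 * np.log10(np.abs(h))  # forward-backward
        assert gain_db[1] - gain_db[0] >= 20
        assert gain_db[1] - gain_db[2] >= 20

    def test_zeros_and_rate_guard(self):
        np.testing.assert_allclose(nv.bandpass_high_gamma(np.zeros(2048), RATE), 0.0)
        with pytest.raises(InvalidRateError):
            nv.bandpass_high_gamma(np.zeros(2048), 300.0)


class TestNotch:
    def test_line_harmonics_removed(self):
        assert rms(nv.notch_line_harmonics(tone(100.0, dur=4.0), RATE)) < 0.1
        assert rms(nv.notch_line_harmonics(tone(150.0, dur=4.0), RATE)) < 0.1

    def test_band_interior_spared(self):
        x = tone(120.0, dur=4.0)
        assert rms(nv.notch_line_harmonics(x, RATE)) > 0.7 * rms(x)

    def test_designed_3db_contract_at_120(self):
        total_db = 0.0
        for band in ((98.0, 102.0), (148.0, 152.0)):
            sos = butter(4, band, btype="bandstop", fs=RATE, output="sos")
            _, h = sosfreqz(sos, worN=[120.0], fs=RATE)
            total_db += 2 * 20 * np.log10(np.abs(h[0]))
        assert total_db >= -3.0

    def test_zeros(self):
        np.testing.assert_allclose(nv.notch_line_harmonics(np.zeros(2048), RATE), 0.0)


class TestEnvelope:
    def test_unit_sinusoid(self):
        env = nv.hilbert_envelope(tone(120.0))
        assert np.allclose(env[256:-256], 1.0, atol=0.01)

    def test_tracks_slow_amplitude(self):
        t = np.arange(int(4 * RATE)) / RATE
        a = 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        env = nv.hilbert_envelope(a * np.sin(2 * np.pi * 120.0 * t))
        interior = slice(512, -512)
        assert np.max(np.abs(env[interior] - a[interior])) < 0.05

    def test_zeros(self):
        np.testing.assert_allclose(nv.hilbert_envelope(np.zeros(1024)), 0.0)


class TestFrameAverage:
    def test_constant(self):
        frames, grid = nv.frame_average(np.full(2048, 3.5), RATE)
        np.testing.assert_allclose(frames, 3.5)
        assert grid.n_frames == frames.size

    def test_full_session_frame_count(self):
        frames, grid = nv.frame_average(np.ones(int(300 * RATE)), RATE)
        assert grid.n_frames == 29996  # floor((300 - 0.05)/0.01) + 1

    def test_single_window(self):
        frames, _ = nv.frame_average(np.ones(52), RATE)
        assert frames.size == 1

    def test_too_short(self):
        with pytest.raises(TooShortError):
            nv.frame_average(np.ones(10), RATE)

    def test_grid_matches_audio_grid(self):
        """Equal-duration neural and audio streams share one frame count."""
        dur = 12.0
        _, g_neural = nv.frame_average(np.ones(int(dur * RATE)), RATE)
        mag, g_audio = nv.stft_magnitude(np.zeros(int(dur * 16000)))
        assert g_neural.n_frames == g_audio.n_frames == mag.shape[0]


class TestStackContext:
    def test_shape_and_row_drop(self):
        out = nv.stack_context(np.random.default_rng(0).normal(size=(500, 3)))
        assert out.values.shape == (500 - 40, 27)
        assert out.n_channels == 3

    def test_ramp_offsets(self):
        f = np.arange(100, dtype=float)[:, None]
        out = nv.stack_context(f)
        np.testing.assert_allclose(
            out.values[0], [0, 5, 10, 15, 20, 25, 30, 35, 40]
        )
        np.testing.assert_allclose(out.values[7], out.values[0] + 7)

    def test_constant_rows_identical(self):
        out = nv.stack_context(np.ones((80, 2)) * 4.0)
        assert np.all(out.values == 4.0)

    def test_center_block_reproduces_input(self):
        x = np.random.default_rng(1).normal(size=(120, 4))
        out = nv.stack_context(x)
        center = out.values[:, 4 * 4 : 5 * 4]
        np.testing.assert_array_equal(center, x[20:-20])

    def test_too_few_frames(self):
        with pytest.raises(TooShortError):
            nv.stack_context(np.ones((40, 2)))


class TestNormalizer:
    def test_self_transform_standardized(self, rng):
        x = rng.normal(5.0, 3.0, size=(400, 6))
        z = nv.Normalizer().fit_transform(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.var(axis=0), 1.0, atol=1e-6)

    def test_eval_uses_train_statistics(self, rng):
        x = rng.normal(size=(300, 4))
        norm = nv.Normalizer().fit(x)
        shifted = norm.transform(x + 5.0)
        np.testing.assert_allclose(shifted.mean(axis=0), 5.0 / norm.std, atol=1e-9)

    def test_constant_column_floored_with_warning(self, rng):
        x = rng.normal(size=(100, 3))
        x[:, 1] = 7.0
        with pytest.warns(RuntimeWarning):
            z = nv.Normalizer().fit_transform(x)
        np.testing.assert_allclose(z[:, 1], 0.0)


class TestChainProperties:
    def test_time_reversal_symmetry(self):
        """Zero-phase chain: reversing the signal reverses the envelope."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=int(6 * RATE))
        fwd = nv.hilbert_envelope(
            nv.notch_line_harmonics(nv.bandpass_high_gamma(x, RATE), RATE)
        )
        rev = nv.hilbert_envelope(
            nv.notch_line_harmonics(nv.bandpass_high_gamma(x[::-1], RATE), RATE)
        )
        # FFT-based analytic signal is circular, so reversal symmetry holds
        # to small edge-driven residuals even in the interior
        interior = slice(1024, -1024)
        np.testing.assert_allclose(rev[::-1][interior], fwd[interior], atol=1e-2)
        assert np.median(np.abs(rev[::-1][interior] - fwd[interior])) < 1e-3

    def test_extract_features_full_chain_shape(self, small_session):
        feats = nv.extract_features(small_session.neural, small_session.neural_rate)
        grid = FrameGrid.from_duration(small_session.duration)
        assert feats.values.shape == (grid.n_frames - 40, 9 * small_session.n_channels)
        assert np.all(np.isfinite(feats.values))
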