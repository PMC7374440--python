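import numpy as np
import pytest

from myocoh import EnvelopeSeries, NormalizationReference, SignalRecord
from myocoh.emg import (
    bandpass,
    hilbert_envelope,
    moving_envelope,
    normalize_to_reference,
    standardize,
)

FS = 1000.0


def tone_record(freq, fs=FS, duration=4.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalRecord(amplitude * np.sin(2 * np.pi * freq * t), fs, ["ECR"])


def tone_amplitude(x, fs):
    mid = x[len(x) // 4 : -len(x) // 4]
    return np.sqrt(2) * np.std(mid)


class TestBandpass:
    def test_passband_identity(self):
        rec = tone_record(np.sqrt(20 * 50))  # geometric band centre
        out = bandpass(rec, 20, 50, order=4)
        assert tone_amplitude(out.channel("ECR"), FS) == pytest.approx(1.0, rel=0.01)

    def test_stopband_matches_analytic_butterworth_magnitude(self):
        # digital Butterworth via bilinear transform: closed-form magnitude
        # at prewarped analog frequencies, doubled in dB for filtfilt
        low, high, order, f_test = 20.0, 50.0, 4, 100.0
        warp = lambda f: 2 * FS * np.tan(np.pi * f / FS)
        wl, wh, w = warp(low), warp(high), warp(f_test)
        q = (w**2 - wl * wh) / (w * (wh - wl))
        expected = (1.0 / (1.0 + q ** (2 * order)))  # |H|^2 for forward-backward
        rec = tone_record(f_test, duration=8.0)
        out = bandpass(rec, low, high, order=order)
        measured = tone_amplitude(out.channel("ECR"), FS)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_zero_input_zero_output(self):
        rec = SignalRecord(np.zeros(2000), FS, ["ECR"])
        out = bandpass(rec, 15, 450)
        assert np.allclose(out.samples, 0.0)

    def test_invalid_corners_rejected(self):
        rec = tone_record(30)
        with pytest.raises(ValueError):
            bandpass(rec, 100, 20)
        with pytest.raises(ValueError):
            bandpass(rec, 15, 600)  # above Nyquist


def brute_force_envelope(x, fs, window, output_rate):
    """Independent trailing-window rectified mean, sample by sample."""
    w = int(round(window * fs))
    n_out = int(np.floor(len(x) / fs * output_rate + 1e-9))
    out = []
    for k in range(1, n_out + 1):
        end = min(int(np.floor(k / output_rate * fs + 1e-9)), len(x))
        start = max(end - w, 0)
        out.append(np.mean(np.abs(x[start:end])))
    return np.array(out)


class TestMovingEnvelope:
    def test_constant_signal(self):
        rec = SignalRecord(np.full(1000, -3.0), FS, ["ECR"])
        env = moving_envelope(rec, "ECR", 0.05)
        assert np.allclose(env.values, 3.0)

    def test_alternating_sign_is_flat(self):
        x = np.tile([1.0, -1.0], 500)
        env = moving_envelope(SignalRecord(x, FS, ["ECR"]), "ECR", 0.01)
        assert np.allclose(env.values, 1.0)

    def test_square_pulse_ramps_to_unit_peak(self):
        fs, w = 100.0, 0.5
        x = np.zeros(300)
        x[100:150] = 1.0  # pulse of exactly one window
        env = moving_envelope(SignalRecord(x, fs, ["ECR"]), "ECR", w)
        oracle = brute_force_envelope(x, fs, w, fs)
        np.testing.assert_allclose(env.values, oracle)
        assert env.values.max() == pytest.approx(1.0)

    def test_matches_brute_force_on_random_signals(self, rng):
        for _ in range(50):
            fs = float(rng.choice([100.0, 250.0, 1000.0]))
            n = int(rng.integers(50, 400))
            x = rng.standard_normal(n)
            window = float(rng.integers(2, min(n, 40))) / fs
            output_rate = fs / float(rng.choice([1, 2, 4]))
            env = moving_envelope(SignalRecord(x, fs, ["ECR"]), "ECR", window, output_rate)
            oracle = brute_force_envelope(x, fs, window, output_rate)
            np.testing.assert_allclose(env.values, oracle, atol=1e-12)

    def test_window_longer_than_record_rejected(self):
        rec = SignalRecord(np.zeros(100), FS, ["ECR"])
        with pytest.raises(ValueError):
            moving_envelope(rec, "ECR", 1.0)


class TestHilbertEnvelope:
    def test_sinusoid_amplitude_recovered(self):
        rec = tone_record(50, amplitude=2.5)
        env = hilbert_envelope(rec, "ECR").values
        core = env[500:-500]
        np.testing.assert_allclose(core, 2.5, rtol=0.01)

    def test_am_modulation_recovered(self):
        t = np.arange(4000) / FS
        a = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
        rec = SignalRecord(a * np.sin(2 * np.pi * 80 * t), FS, ["ECR"])
        env = hilbert_envelope(rec, "ECR").values
        np.testing.assert_allclose(env[500:-500], a[500:-500], rtol=0.02)

    def test_bandpass_then_envelope_recovers_drive_band_tone(self):
        rec = tone_record(30, amplitude=1.3, duration=6.0)  # upper beta edge
        out = bandpass(rec, 15, 450, order=4)
        env = hilbert_envelope(out, "ECR").values
        np.testing.assert_allclose(env[1000:-1000], 1.3, rtol=0.02)

    def test_zero_signal(self):
        env = hilbert_envelope(SignalRecord(np.zeros(1000), FS, ["ECR"]), "ECR")
        assert np.allclose(env.values, 0.0)


class TestStandardize:
    def test_moments_and_idempotence(self, rng):
        env = EnvelopeSeries(rng.gamma(2.0, size=500), 100.0, 0.1, "ECR")
        out = standardize(env)
        assert np.mean(out.values) == pytest.approx(0.0, abs=1e-12)
        assert np.std(out.values) == pytest.approx(1.0, rel=1e-12)
        again = standardize(out)
        np.testing.assert_allclose(again.values, out.values, atol=1e-12)

    def test_affine_invariance(self, rng):
        v = rng.standard_normal(300)
        a = standardize(EnvelopeSeries(v, 100.0, 0.1, "ECR"))
        b = standardize(EnvelopeSeries(3.0 * v + 7.0, 100.0, 0.1, "ECR"))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            standardize(EnvelopeSeries(np.ones(10), 100.0, 0.1, "ECR"))


class TestNormalization:
    def test_grip_maximum_maps_to_one(self):
        ref = NormalizationReference("power_grip_max", {"ECR": 0.8})
        env = EnvelopeSeries(np.full(10, 0.8), 100.0, 0.1, "ECR")
        assert np.allclose(normalize_to_reference(env, ref).values, 1.0)

    def test_zero_envelope_maps_to_zero(self):
        ref = NormalizationReference("power_grip_max", {"ECR": 0.8})
        env = EnvelopeSeries(np.zeros(10), 100.0, 0.1, "ECR")
        assert np.allclose(normalize_to_reference(env, ref).values, 0.0)

    def test_scale_equivariance(self, rng):
        v = rng.gamma(2.0, size=100)
        a = normalize_to_reference(
            EnvelopeSeries(v, 100.0, 0.1, "ECR"),
            NormalizationReference("power_grip_max", {"ECR": 0.5}),
        )
        b = normalize_to_reference(
            EnvelopeSeries(2 * v, 100.0, 0.1, "ECR"),
            NormalizationReference("power_grip_max", {"ECR": 1.0}),
        )
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_session_zscore_self_normalization(self, rng):
        v = rng.gamma(2.0, size=500)
        ref = NormalizationReference(
            "session_zscore", {"ECR": float(np.std(v))}, {"ECR": float(np.mean(v))}
        )
        out = normalize_to_reference(EnvelopeSeries(v, 100.0, 0.1, "ECR"), ref)
        assert np.mean(out.values) == pytest.approx(0.0, abs=1e-9)
        assert np.std(out.values) == pytest.approx(1.0, rel=1e-9)

    def test_missing_channel_rejected(self):
        ref = NormalizationReference("power_grip_max", {"FCU": 1.0})
        env = EnvelopeSeries(np.ones(5), 100.0, 0.1, "ECR")
        with pytest.raises(KeyError):
            normalize_to_reference(env, ref)
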