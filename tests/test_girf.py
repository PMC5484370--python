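"""Gradient-chain characterization: chirps, estimation, prediction."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d

import ptxverse as px

DT = px.DEFAULT_DWELL


def _delay_spectrum(n_samples, dt, delay_s):
    freqs = np.sort(np.fft.fftfreq(2 * n_samples, dt))
    h = np.exp(-2j * np.pi * freqs * delay_s)
    return px.GIRFSpectrum(freqs=freqs, h=np.tile(h, (3, 1)), df=freqs[1] - freqs[0])


class TestChirp:
    def test_linear_sweep_and_amplitude(self):
        ch = px.make_chirp(10e3, 10e-3, 5.0, DT)
        t = np.arange(ch.samples.size) * DT
        expected = 5.0 * np.sin(np.pi * (10e3 / 10e-3) * t**2)
        assert np.allclose(ch.samples, expected)
        assert np.abs(ch.samples).max() <= 5.0
        # instantaneous frequency (bandwidth/duration)*t = 5 kHz at t = 5 ms
        rate = 10e3 / 10e-3
        assert np.isclose(rate * 5e-3, 5e3)

    def test_slew_cap_scales_amplitude(self):
        ch = px.make_chirp(40e3, 10e-3, 10.0, DT, smax=180.0)
        assert ch.scale < 1.0
        assert np.abs(np.diff(ch.samples)).max() * 1e-3 / DT <= 180.0 * (1 + 1e-9)

    def test_spectrum_flat_within_3db(self):
        ch = px.make_chirp(40e3, 10e-3, 10.0, DT)
        mag = np.abs(np.fft.rfft(ch.samples, n=4 * ch.samples.size))
        freqs = np.fft.rfftfreq(4 * ch.samples.size, DT)
        smooth = uniform_filter1d(mag, 31)
        band = (freqs >= 500.0) & (freqs <= 39e3)
        db = 20 * np.log10(smooth[band] / np.median(smooth[band]))
        assert db.max() < 3.0 and db.min() > -3.0

    def test_too_short_sweep_rejected(self):
        with pytest.raises(ValueError):
            px.make_chirp(1e3, 1e-3, 5.0, DT)


class TestFrequencyResolution:
    @pytest.mark.parametrize(
        "window, expected",
        [(70e-3, 14.3), (6.4e-3, 156.0), (1.0, 1.0)],
    )
    def test_values(self, window, expected):
        df = px.girf_frequency_resolution(window)
        assert float(f"{df:.3g}") == expected


def _chirp_pairs(truth, noise_rng=None, snr_db=None):
    ins, outs = [], []
    for bw in (10e3, 20e3, 30e3, 40e3):
        ch = px.make_chirp(bw, 10e-3, 10.0, DT, smax=180.0)
        gi, go = px.measure_chirp_response(ch, truth, 70e-3)
        if snr_db is not None:
            sigma = np.sqrt(np.mean(go.samples**2)) * 10 ** (-snr_db / 20)
            go = px.GradientWaveform(
                go.samples + sigma * noise_rng.standard_normal(go.samples.shape),
                go.dt,
            )
        ins.append(gi)
        outs.append(go)
    return ins, outs


class TestEstimate:
    def test_identity_system(self):
        ch = px.make_chirp(20e3, 10e-3, 5.0, DT)
        g_one = ch.as_gradient(1)
        assert np.all(g_one.samples[0] == 0) and np.array_equal(
            g_one.samples[1], ch.samples
        )
        g3 = px.GradientWaveform(np.tile(ch.samples, (3, 1)), DT)
        spec = px.estimate_girf([g3], [g3], 20e-3, eps_rel=1e-12)
        err = np.abs(spec.h - 1.0)
        assert err[spec.confident].max() < 1e-6
        # with the default regularization the bias stays below 1e-4 in-band
        spec_d = px.estimate_girf([g3], [g3], 20e-3)
        assert np.abs(spec_d.h - 1.0)[spec_d.confident].max() < 1e-4
        assert spec.hermitian_error() < 1e-12

    def test_pure_delay_phase_slope(self):
        ch = px.make_chirp(20e3, 10e-3, 5.0, DT)
        n_win = int(round(30e-3 / DT))
        gin = np.zeros((3, n_win))
        gin[:, : ch.samples.size] = ch.samples
        gout = np.roll(gin, 5, axis=1)
        spec = px.estimate_girf(
            [px.GradientWaveform(gin, DT)], [px.GradientWaveform(gout, DT)], 30e-3
        )
        band = spec.confident[0] & (spec.freqs > 500) & (spec.freqs < 15e3)
        phase = np.unwrap(np.angle(spec.h[0][band]))
        slope = np.polyfit(spec.freqs[band], phase, 1)[0]
        delay = -slope / (2 * np.pi)
        assert np.isclose(delay, 5 * DT, rtol=0.01)

    def test_recovers_synthetic_truth_noiseless(self):
        truth = px.default_truth()
        ins, outs = _chirp_pairs(truth)
        spec = px.estimate_girf(ins, outs, 70e-3)
        h_true = truth.spectrum(DT, int(round(70e-3 / DT)))
        for axis in range(3):
            band = spec.confident[axis]
            rel = np.abs(spec.h[axis] - h_true.h[axis]) / np.abs(h_true.h[axis])
            assert rel[band].max() < 1e-3

    def test_low_confidence_bins_flagged(self):
        truth = px.default_truth()
        ins, outs = _chirp_pairs(truth)
        spec = px.estimate_girf(ins, outs, 70e-3)
        # out-of-band bins (beyond the 40 kHz sweep) must be flagged
        assert not spec.confident[0][np.abs(spec.freqs) > 60e3].any()
        assert spec.confident[0][np.abs(spec.freqs) < 5e3].all()


class TestPredict:
    def test_identity_returns_input(self):
        g = px.GradientWaveform(np.random.default_rng(0).standard_normal((3, 256)), DT)
        spec = _delay_spectrum(256, DT, 0.0)
        spec = px.GIRFSpectrum(spec.freqs, np.ones_like(spec.h), spec.df)
        out = px.predict_gradient(g, spec)
        assert np.array_equal(out.samples, g.samples)

    def test_delay_theorem(self):
        rng = np.random.default_rng(3)
        x = np.zeros((3, 300))
        x[:, 50:250] = rng.standard_normal((3, 200))
        g = px.GradientWaveform(x, DT)
        out = px.predict_gradient(g, _delay_spectrum(300, DT, 3 * DT))
        assert np.allclose(out.samples[:, 3:], x[:, :-3], atol=1e-9)
        assert np.allclose(out.samples[:, :3], 0.0, atol=1e-9)

    def test_first_order_lowpass_step_response(self):
        fc = 100.0
        tau = 1.0 / (2 * np.pi * fc)
        n = int(round(100e-3 / DT))
        g = px.GradientWaveform(
            np.vstack([np.full(n, 10.0), np.zeros(n), np.zeros(n)]), DT
        )
        freqs = np.sort(np.fft.fftfreq(2 * n, DT))
        h = 1.0 / (1.0 + 1j * freqs / fc)
        spec = px.GIRFSpectrum(freqs, np.tile(h, (3, 1)), freqs[1] - freqs[0])
        out = px.predict_gradient(g, spec)
        # the discrete step sees the sampled system half a dwell early
        t = np.arange(n) * DT + DT / 2
        expected = 10.0 * (1.0 - np.exp(-t / tau))
        rms = np.sqrt(np.mean((out.samples[0] - expected) ** 2)) / 10.0
        assert rms < 1e-4

    def test_linearity(self):
        rng = np.random.default_rng(4)
        g1 = px.GradientWaveform(rng.standard_normal((3, 200)), DT)
        g2 = px.GradientWaveform(rng.standard_normal((3, 200)), DT)
        spec = _delay_spectrum(200, DT, 2.5 * DT)
        combo = px.GradientWaveform(2.0 * g1.samples - 0.5 * g2.samples, DT)
        lhs = px.predict_gradient(combo, spec).samples
        rhs = (
            2.0 * px.predict_gradient(g1, spec).samples
            - 0.5 * px.predict_gradient(g2, spec).samples
        )
        assert np.allclose(lhs, rhs, atol=1e-9 * np.abs(lhs).max())

    def test_narrow_spectrum_rejected(self):
        g = px.GradientWaveform(np.ones((3, 256)), DT)
        freqs = np.linspace(-1e3, 1e3, 64)
        spec = px.GIRFSpectrum(
            freqs, np.full((3, 64), 0.9, complex), freqs[1] - freqs[0]
        )
        with pytest.raises(ValueError):
            px.predict_gradient(g, spec)

    def test_cascade_estimation_recovers_spectrum(self):
        """Estimating from (input, predicted-output) pairs recovers H in-band.

        The forward simulation resamples H onto the padded grid by
        linear interpolation, which smears the narrow mechanical
        resonance slightly; the tolerance reflects that, not estimator
        error (the analytically-sampled path recovers to < 1e-3).
        """
        truth = px.default_truth()
        ins, _ = _chirp_pairs(truth)
        n_fft = int(round(70e-3 / DT))
        h_true = truth.spectrum(DT, n_fft)
        outs = [px.predict_gradient(g, h_true) for g in ins]
        spec = px.estimate_girf(ins, outs, 70e-3)
        for axis in range(3):
            band = spec.confident[axis]
            rel = np.abs(spec.h[axis] - h_true.h[axis]) / np.abs(h_true.h[axis])
            assert rel[band].max() < 5e-3


class TestDeviation:
    def test_equal_waveforms(self):
        g = px.GradientWaveform(np.random.default_rng(5).standard_normal((3, 64)), DT)
        dev = px.deviation(g, g)
        assert np.all(dev.g_tilde == 0.0)
        assert np.all(dev.max_relative == 0.0)

    def test_three_percent_scale(self):
        g = px.GradientWaveform(np.random.default_rng(6).standard_normal((3, 64)), DT)
        g_act = px.GradientWaveform(0.97 * g.samples, DT)
        dev = px.deviation(g, g_act)
        assert np.allclose(dev.max_relative, 0.03, rtol=1e-9)
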