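"""Gradient-chain characterization as a linear time-invariant system.

The gradient impulse response function (GIRF) models, per axis, how the
gradient hardware maps a commanded (nominal) waveform onto the actually
played-out field: eddy currents, amplifier bandwidth, and mechanical
resonances all fold into one complex frequency response H(f).  The GIRF
is estimated from input/output pairs — linear frequency-swept (chirp)
test waveforms in practice — by least-squares deconvolution

    Ĥ(f) = Σᵢ Õᵢ(f) Ĩᵢ*(f) / (Σᵢ |Ĩᵢ(f)|² + ε),

and used to predict actual gradients by frequency-domain multiplication.
Only the self-terms (x→x, y→y, z→z) are modelled; cross-terms and the
zeroth-order (B0) response are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import GAMMA_1H
from .waveforms import GradientWaveform

__all__ = [
    "GIRFSpectrum",
    "ChirpWaveform",
    "GradientDeviation",
    "make_chirp",
    "estimate_girf",
    "girf_frequency_resolution",
    "predict_gradient",
    "deviation",
]


@dataclass
class GIRFSpectrum:
    """Per-axis complex frequency response of the gradient chain.

    Attributes
    ----------
    freqs : ndarray, shape (F,)
        Two-sided frequency grid in Hz, uniformly spaced, ascending.
    h : ndarray, shape (3, F)
        Complex response per gradient axis (self-terms only).
    df : float
        Frequency resolution in Hz (1 / record duration).
    confident : ndarray of bool, shape (3, F), optional
        False at bins where the estimation denominator fell below the
        confidence floor (out-of-band, noise-dominated bins).
    """

    freqs: np.ndarray
    h: np.ndarray
    df: float
    confident: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.h = np.atleast_2d(np.asarray(self.h, dtype=complex))
        if self.h.shape != (3, self.freqs.size):
            raise ValueError("h must have shape (3, len(freqs))")
        if not self.df > 0:
            raise ValueError("df must be positive")

    def hermitian_error(self) -> float:
        """Deviation from H(-f) = H*(f), i.e. a non-real impulse response.

        Measured as the peak imaginary part of the inverse transform
        relative to the peak magnitude.
        """
        h_fft = np.fft.ifftshift(self.h, axes=-1)
        impulse = np.fft.ifft(h_fft, axis=-1)
        peak = float(np.max(np.abs(impulse)))
        if peak == 0.0:
            return 0.0
        return float(np.max(np.abs(impulse.imag)) / peak)

    def is_identity(self) -> bool:
        return bool(np.all(self.h == 1.0))


@dataclass
class ChirpWaveform:
    """Linear frequency-swept gradient test waveform.

    g(t) = A sin(π (bandwidth/duration) t²), sweeping the instantaneous
    frequency linearly from 0 to ``bandwidth`` over ``duration``.
    """

    bandwidth: float
    duration: float
    amplitude: float
    samples: np.ndarray
    dt: float
    scale: float = 1.0  # applied amplitude scale if the slew cap bound

    def as_gradient(self, axis: int = 0) -> GradientWaveform:
        """Embed the chirp on one gradient axis (others zero)."""
        g = np.zeros((3, self.samples.size))
        g[axis] = self.samples
        return GradientWaveform(g, self.dt)


@dataclass
class GradientDeviation:
    """Difference between nominal and actual gradients, G̃ = G_nom − G_act."""

    g_tilde: np.ndarray
    dt: float
    max_relative: np.ndarray  # per axis, relative to that axis's peak

    @property
    def max_abs(self) -> np.ndarray:
        return np.max(np.abs(self.g_tilde), axis=1)


def make_chirp(
    bandwidth: float,
    duration: float,
    amplitude: float,
    dt: float,
    smax: float | None = None,
) -> ChirpWaveform:
    """Generate a linear chirp gradient waveform.

    Parameters
    ----------
    bandwidth, duration, amplitude
        Sweep bandwidth (Hz), sweep duration (s), peak amplitude (mT/m).
    dt
        Dwell time (s).
    smax
        Optional slew-rate cap (T/m/s); if the chirp exceeds it the
        amplitude is scaled down and the scale recorded.
    """
    if bandwidth <= 0 or duration <= 0 or amplitude <= 0:
        raise ValueError("bandwidth, duration and amplitude must be positive")
    if duration < 2.0 / bandwidth:
        raise ValueError("duration too short to represent the frequency sweep")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    g = amplitude * np.sin(np.pi * (bandwidth / duration) * t**2)
    scale = 1.0
    if smax is not None:
        peak_slew = float(np.max(np.abs(np.diff(g))) * 1e-3 / dt)
        if peak_slew > smax:
            scale = smax / peak_slew
            g = g * scale
    return ChirpWaveform(bandwidth, duration, amplitude * scale, g, dt, scale)


def girf_frequency_resolution(window_duration: float) -> float:
    """Frequency resolution (Hz) of a GIRF estimate from a record of given length."""
    if window_duration <= 0:
        raise ValueError("window_duration must be positive")
    return 1.0 / window_duration


def _hermitian_symmetrize(h_fft: np.ndarray) -> np.ndarray:
    """Enforce H(-f) = H*(f) on an fft-ordered spectrum (real impulse response)."""
    n = h_fft.shape[-1]
    idx = (-np.arange(n)) % n
    return 0.5 * (h_fft + np.conj(h_fft[..., idx]))


def estimate_girf(
    inputs: Sequence[GradientWaveform],
    outputs: Sequence[GradientWaveform],
    window_duration: float,
    eps_rel: float = 1e-6,
    confidence_rel: float = 1e-2,
) -> GIRFSpectrum:
    """Least-squares multi-measurement GIRF estimation.

    Each (input, output) waveform pair is zero-padded to the analysis
    window, Fourier transformed, and accumulated per axis into
    Ĥ = Σ Õ Ĩ* / (Σ|Ĩ|² + ε) with ε = ``eps_rel`` × the per-axis peak of
    the accumulated denominator.  Bins whose denominator falls below
    ``confidence_rel`` × peak are flagged low-confidence rather than
    rejected.  Hermitian symmetry is enforced so the implied impulse
    response is real.
    """
    if len(inputs) == 0 or len(inputs) != len(outputs):
        raise ValueError("need matching, non-empty input/output lists")
    dt = inputs[0].dt
    for g_in, g_out in zip(inputs, outputs):
        if g_in.dt != dt or g_out.dt != dt:
            raise ValueError("all waveforms must share the dwell time")
        if g_in.n_samples != g_out.n_samples:
            raise ValueError("each pair must share the sample grid")
    n_fft = int(round(window_duration / dt))
    for g_in in inputs:
        if g_in.n_samples > n_fft:
            raise ValueError("window_duration must cover the input duration")
    num = np.zeros((3, n_fft), dtype=complex)
    den = np.zeros((3, n_fft))
    for g_in, g_out in zip(inputs, outputs):
        i_f = np.fft.fft(g_in.samples, n=n_fft, axis=1)
        o_f = np.fft.fft(g_out.samples, n=n_fft, axis=1)
        num += o_f * np.conj(i_f)
        den += np.abs(i_f) ** 2
    eps = eps_rel * np.max(den, axis=1, keepdims=True)
    h = _hermitian_symmetrize(num / (den + eps))
    confident = den >= confidence_rel * np.max(den, axis=1, keepdims=True)
    order = np.argsort(np.fft.fftfreq(n_fft, dt))
    return GIRFSpectrum(
        freqs=np.fft.fftfreq(n_fft, dt)[order],
        h=h[:, order],
        df=1.0 / (n_fft * dt),
        confident=confident[:, order],
    )


def predict_gradient(
    g_nom: GradientWaveform, spectrum: GIRFSpectrum
) -> GradientWaveform:
    """Predict the played-out gradient by applying the GIRF to a nominal waveform.

    The input is zero-padded by a factor of two (suppressing circular
    convolution wrap-around for responses with ms-scale tails), the
    response is resampled onto the padded frequency grid by linear
    interpolation of its real and imaginary parts, and the product is
    transformed back and truncated to the input length.  An identity
    spectrum returns the input unchanged.
    """
    if spectrum.is_identity():
        return g_nom.copy()
    n = g_nom.n_samples
    n_pad = 2 * n
    f_pad = np.fft.fftfreq(n_pad, g_nom.dt)
    needed = np.max(np.abs(f_pad))
    # allow a shortfall of up to two bins at the band edge (grid rounding);
    # those bins are clamp-extrapolated by np.interp
    if spectrum.freqs[-1] < needed - 2 * spectrum.df or spectrum.freqs[0] > -(
        needed - 2 * spectrum.df
    ):
        raise ValueError(
            "GIRF frequency span (%.0f Hz) narrower than the waveform band (%.0f Hz)"
            % (spectrum.freqs[-1], needed)
        )
    g_f = np.fft.fft(g_nom.samples, n=n_pad, axis=1)
    out = np.empty_like(g_nom.samples)
    for a in range(3):
        h_a = np.interp(f_pad, spectrum.freqs, spectrum.h[a].real) + 1j * np.interp(
            f_pad, spectrum.freqs, spectrum.h[a].imag
        )
        out[a] = np.fft.ifft(g_f[a] * h_a).real[:n]
    return GradientWaveform(out, g_nom.dt)


def deviation(g_nom: GradientWaveform, g_act: GradientWaveform) -> GradientDeviation:
    """Gradient deviation G̃ = G_nom − G_act with per-axis relative summary."""
    if g_nom.n_samples != g_act.n_samples or g_nom.dt != g_act.dt:
        raise ValueError("waveforms must share the sample grid")
    g_tilde = g_nom.samples - g_act.samples
    peaks = np.max(np.abs(g_nom.samples), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        max_rel = np.where(
            peaks > 0, np.max(np.abs(g_tilde), axis=1) / peaks, 0.0
        )
    return GradientDeviation(g_tilde, g_nom.dt, max_rel)
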