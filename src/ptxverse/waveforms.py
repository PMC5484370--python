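"""Time-domain waveform containers and kinematic transforms.

The two core objects are :class:`GradientWaveform` (three-axis gradient
samples on a uniform dwell grid, mT/m) and :class:`MultiChannelRF`
(complex per-channel RF envelopes on the same grid, μT).  The excitation
k-space trajectory is obtained from the gradient waveform by

    k(t) = -γ ∫_t^T0 G(t') dt'            [rad/m]

so that k is exactly zero at the end of the pulse, and the arc length

    s(t) = γ ∫_0^t |G(τ)| dτ              [rad/m]

measures the distance traversed in excitation k-space.  Both integrals
use the trapezoidal rule on the sample grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import GAMMA_1H

__all__ = [
    "GradientWaveform",
    "MultiChannelRF",
    "Trajectory",
    "compute_k",
    "arc_length",
    "slew",
    "append_ramps",
]


@dataclass
class GradientWaveform:
    """Three-axis gradient waveform on a uniform time grid.

    Parameters
    ----------
    samples : ndarray, shape (3, N)
        Gradient amplitude per axis (x, y, z) in mT/m.
    dt : float
        Sample interval in seconds.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != 3:
            raise ValueError("gradient samples must have shape (3, N)")
        if self.samples.shape[1] < 2:
            raise ValueError("need at least two samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("gradient samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Playout duration N·dt in seconds."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample node times i·dt, i = 0..N-1."""
        return np.arange(self.n_samples) * self.dt

    def copy(self) -> "GradientWaveform":
        return GradientWaveform(self.samples.copy(), self.dt)


@dataclass
class MultiChannelRF:
    """Complex RF envelopes for C transmit channels, in μT.

    Shares the dwell grid of its paired :class:`GradientWaveform`.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=complex))
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("RF samples must have shape (C, N) with C >= 1")
        if self.samples.shape[1] < 2:
            raise ValueError("need at least two samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def peak(self) -> float:
        """Peak |B1| over all channels and time samples, μT."""
        return float(np.max(np.abs(self.samples)))

    def copy(self) -> "MultiChannelRF":
        return MultiChannelRF(self.samples.copy(), self.dt)


@dataclass
class Trajectory:
    """Excitation k-space trajectory, rad/m, ending at k = 0."""

    k: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.k = np.atleast_2d(np.asarray(self.k, dtype=float))
        if self.k.shape[0] != 3:
            raise ValueError("trajectory must have shape (3, N)")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.k.shape[1]


def compute_k(g: GradientWaveform, gamma: float = GAMMA_1H) -> Trajectory:
    """Excitation k-space trajectory of a gradient waveform.

    Integrates k(t) = -γ ∫_t^T0 G dt' with the trapezoidal rule; the
    final sample is exactly zero by construction.
    """
    g_si = g.samples * 1e-3  # mT/m -> T/m
    integral = cumulative_trapezoid(g_si, dx=g.dt, initial=0.0, axis=1)
    # integral - integral[end] = -∫_t^T0, so k = γ·(integral - integral[end])
    k = gamma * (integral - integral[:, -1:])
    k[:, -1] = 0.0
    return Trajectory(k, g.dt)


def arc_length(g: GradientWaveform, gamma: float = GAMMA_1H) -> np.ndarray:
    """Cumulative k-space arc length s(t) = γ ∫_0^t |G| dτ, rad/m.

    Non-decreasing with s(0) = 0; equals the path length of the
    excitation k-space curve.
    """
    gmag = np.linalg.norm(g.samples * 1e-3, axis=0)
    return gamma * cumulative_trapezoid(gmag, dx=g.dt, initial=0.0)


def slew(g: GradientWaveform) -> np.ndarray:
    """Per-axis slew rate by forward finite difference, T/m/s, shape (3, N-1)."""
    return np.diff(g.samples, axis=1) * 1e-3 / g.dt


def append_ramps(
    g: GradientWaveform,
    rf: MultiChannelRF,
    smax: float,
) -> tuple[GradientWaveform, MultiChannelRF]:
    """Prepend a minimal linear ramp from zero if the gradient starts non-zero.

    The ramp duration is the smallest whole number of dwells such that the
    per-axis slew stays at or below ``smax`` (T/m/s); the RF is zero-padded
    over the ramp.  A gradient already starting at zero is returned unchanged.
    """
    if smax <= 0:
        raise ValueError("smax must be positive")
    if g.n_samples != rf.n_samples or g.dt != rf.dt:
        raise ValueError("gradient and RF must share the sample grid")
    g0 = g.samples[:, 0]
    if np.all(g0 == 0.0):
        return g.copy(), rf.copy()
    ramp_duration = np.max(np.abs(g0)) * 1e-3 / smax
    n_ramp = int(np.ceil(ramp_duration / g.dt - 1e-12))
    ramp = np.outer(g0, np.arange(n_ramp) / n_ramp)
    g_out = np.concatenate([ramp, g.samples], axis=1)
    rf_out = np.concatenate(
        [np.zeros((rf.n_channels, n_ramp), dtype=complex), rf.samples], axis=1
    )
    return GradientWaveform(g_out, g.dt), MultiChannelRF(rf_out, rf.dt)
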