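"""Synthetic scanner model: field maps, targets, trajectories and a
"true" gradient chain.

Everything needed to exercise the full design-and-correct pipeline
without any measured data: an eight-channel set of smooth complex
transmit sensitivities, a smooth off-resonance map, a blurred-square
target pattern, a time-optimal 2×-undersampled spiral-in excitation
trajectory, and a per-axis gradient-chain truth model (low-pass response
with narrow mechanical-resonance features in the 600–1800 Hz band) that
stands in for the physical scanner and field camera.

The B1+ generator uses smooth deterministic spatial modes rather than
electromagnetic simulation: the small-tip design only needs smooth
complex sensitivities, and determinism matters more than physical
realism here.  The truth response is synthetic — plausible for a
whole-body gradient system but not a fit to any measured hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import DEFAULT_DWELL, GAMMA_1H
from .girf import GIRFSpectrum, predict_gradient
from .ptx import FieldMaps, TargetPattern
from .verse import time_optimal_traverse, _sample_traversal
from .waveforms import GradientWaveform, Trajectory, compute_k

__all__ = [
    "FixtureConfig",
    "ScannerTruth",
    "make_target",
    "make_maps",
    "make_spiral_in",
    "play_through",
    "measure_chirp_response",
    "default_truth",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FixtureConfig:
    """Geometry, hardware limits and seeds of the synthetic study.

    Defaults describe the phantom-style 2D experiment: a 30 × 30 mm²
    square target blurred with a 1 cm FWHM Gaussian, on a 64 × 64 grid
    over a 128 × 128 mm² field of view; an 8-channel transmit array; a
    single-shot spiral-in trajectory encoding 2 mm resolution, radially
    undersampled 2×, traversed time-optimally at 30 mT/m and 180 T/m/s;
    6.4 μs dwell.
    """

    fov: float = 0.128  # m
    grid: int = 64
    channels: int = 8
    square_side: float = 0.030  # m
    blur_fwhm: float = 0.010  # m
    spiral_res: float = 0.002  # m
    undersampling: float = 2.0
    g_max: float = 30.0  # mT/m
    s_max: float = 180.0  # T/m/s
    dwell: float = DEFAULT_DWELL
    domega_span: float = 200.0  # rad/s, peak |Δω|
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fov",
            "grid",
            "channels",
            "square_side",
            "blur_fwhm",
            "spiral_res",
            "undersampling",
            "g_max",
            "s_max",
            "dwell",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _grid_coords(cfg: FixtureConfig) -> tuple[np.ndarray, np.ndarray]:
    x = (np.arange(cfg.grid) - cfg.grid // 2) * (cfg.fov / cfg.grid)
    return np.meshgrid(x, x, indexing="ij")


def make_target(cfg: FixtureConfig, flip: float = np.pi / 2) -> TargetPattern:
    """Blurred-square target scaled to the requested flip angle (rad).

    A binary square of side ``square_side`` centred on the grid is
    convolved with a Gaussian of ``blur_fwhm`` full width at half
    maximum, softening the edges so the radially undersampled trajectory
    does not ring at the aliasing radius.
    """
    if cfg.square_side >= cfg.fov:
        raise ValueError("square must fit inside the FOV")
    xx, yy = _grid_coords(cfg)
    half = cfg.square_side / 2.0
    square = ((np.abs(xx) < half) & (np.abs(yy) < half)).astype(float)
    sigma_cells = cfg.blur_fwhm * _FWHM_TO_SIGMA / (cfg.fov / cfg.grid)
    blurred = gaussian_filter(square, sigma_cells, mode="constant")
    return TargetPattern(flip * blurred)


def make_maps(cfg: FixtureConfig) -> FieldMaps:
    """Smooth deterministic 8-channel B1+ maps and off-resonance map.

    Channel magnitudes are Gaussian lobes centred on a ring around the
    FOV (mimicking a loop transmit array) with a gentle seeded low-order
    perturbation; phases combine a per-channel offset chosen so the
    channels add constructively at the centre with a mild linear roll
    across the FOV.  The off-resonance map is a seeded sum of broad
    Gaussians scaled to the configured peak.
    """
    rng = np.random.default_rng(cfg.seed)
    xx, yy = _grid_coords(cfg)
    n_c = cfg.channels
    ring_r = 0.45 * cfg.fov
    width = 0.22 * cfg.fov
    b1 = np.empty((n_c, cfg.grid, cfg.grid), dtype=complex)
    for c in range(n_c):
        ang = 2 * np.pi * c / n_c
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        mag = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)) / (2 * width**2))
        mag *= 1.0 + 0.05 * (
            rng.standard_normal() * xx / cfg.fov + rng.standard_normal() * yy / cfg.fov
        )
        roll = (2 * np.pi / (4 * cfg.fov)) * (
            np.cos(ang) * xx + np.sin(ang) * yy
        ) * (1.0 + 0.2 * rng.standard_normal())
        phase = roll - roll[cfg.grid // 2, cfg.grid // 2]
        b1[c] = np.abs(mag) / np.max(np.abs(mag)) * np.exp(1j * phase)
    if cfg.domega_span > 0:
        dom = np.zeros_like(xx)
        for _ in range(3):
            cx, cy = rng.uniform(-0.3, 0.3, size=2) * cfg.fov
            w = rng.uniform(0.3, 0.6) * cfg.fov
            dom += rng.standard_normal() * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * w**2)
            )
        dom *= cfg.domega_span / np.max(np.abs(dom))
    else:
        dom = np.zeros_like(xx)
    mask = np.ones_like(xx, dtype=bool)
    return FieldMaps(b1=b1, domega=dom, fov=cfg.fov, mask=mask)


def make_spiral_in(
    cfg: FixtureConfig, gamma: float = GAMMA_1H
) -> tuple[GradientWaveform, Trajectory]:
    """Time-optimal single-shot spiral-in gradient waveform and trajectory.

    An Archimedean spiral from k_max = π/res inward to k = 0, with
    radial pitch ``undersampling`` × (2π/FOV), parametrized by arc
    length and traversed at the time-optimal speed profile under the
    gradient amplitude and slew limits, then sampled on the dwell grid.
    The waveform starts and ends at zero gradient and its trajectory
    ends exactly at the k-space origin.
    """
    k_max = np.pi / cfg.spiral_res
    a = cfg.undersampling / cfg.fov  # rad/m of radius per rad of angle
    theta_max = k_max / a
    ds_grid = gamma * cfg.g_max * 1e-3 * cfg.dwell / 16.0
    # dense polyline of the spiral, outer -> centre
    d_theta = ds_grid / (2.0 * k_max)
    theta = np.arange(theta_max, -d_theta / 2, -d_theta)
    theta[-1] = 0.0
    pts = np.stack([a * theta * np.cos(theta), a * theta * np.sin(theta)])
    seg = np.linalg.norm(np.diff(pts, axis=1), axis=0)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]
    k_grid = max(int(np.ceil(total / ds_grid)) + 1, 2)
    s_u = np.linspace(0.0, total, k_grid)
    ds = s_u[1] - s_u[0]
    from scipy.interpolate import CubicSpline

    from .verse import _path_tangent

    pts3 = np.vstack([pts, np.zeros(pts.shape[1])])
    keep = np.concatenate([[True], np.diff(s_dense) > 1e-12])
    spline = CubicSpline(s_dense[keep], pts3[:, keep], axis=1)
    tangent = _path_tangent(spline, s_u)
    bound = np.full(k_grid, cfg.g_max)
    v, t = time_optimal_traverse(tangent, ds, bound, cfg.s_max, gamma)
    _, _, g_samples = _sample_traversal(s_u, tangent, v, t, cfg.dwell, gamma, path=spline)
    g = GradientWaveform(g_samples, cfg.dwell)
    return g, compute_k(g, gamma)


@dataclass
class ScannerTruth:
    """Analytic per-axis "true" gradient-chain response.

    Each axis is a second-order low-pass (x and y alike, z slightly
    narrower) multiplied by one or more resonant perturbations

        1 + A·(i f f0/Q) / (f0² − f² + i f f0/Q)

    in the 600–1800 Hz band, mimicking mechanical resonances of the
    gradient coils.  DC gain is exactly 1 and the response is Hermitian
    by construction (real rational in s = i2πf).  The constant group
    delay of the causal low-pass is removed (multiplication by
    e^{+i2πfτ} with τ the DC group delay), emulating the near-zero net
    delay of a delay-calibrated gradient chain: measured responses show
    flat phase around DC, and it is the dispersive part of the response,
    not a bulk delay, that trajectory correction must handle.
    """

    corner_hz: tuple[float, float, float] = (9000.0, 9000.0, 7000.0)
    resonances: tuple[tuple[tuple[float, float, float], ...], ...] = (
        ((1100.0, 18.0, 0.10),),
        ((1100.0, 18.0, 0.10),),
        ((1100.0, 15.0, 0.10),),
    )
    noise_level: float = 0.0  # additive noise, fraction of output rms
    seed: int = 0

    def transfer(self, freqs: np.ndarray) -> np.ndarray:
        """Complex response per axis on an arbitrary frequency grid, (3, F)."""
        s = 1j * 2 * np.pi * np.asarray(freqs, dtype=float)
        h = np.empty((3, s.size), dtype=complex)
        for axis in range(3):
            wc = 2 * np.pi * self.corner_hz[axis]
            tau = np.sqrt(2.0) / wc  # DC group delay of the low-pass
            lp = np.exp(s * tau) / (1.0 + np.sqrt(2.0) * s / wc + (s / wc) ** 2)
            res = np.ones_like(s)
            for f0, q, amp in self.resonances[axis]:
                w0 = 2 * np.pi * f0
                res = res * (1.0 + amp * (s * w0 / q) / (s**2 + s * w0 / q + w0**2))
            h[axis] = lp * res
        return h

    def spectrum(self, dt: float, n_fft: int) -> GIRFSpectrum:
        """Sample the truth on the FFT grid of an ``n_fft``-point record."""
        freqs = np.fft.fftfreq(n_fft, dt)
        h = self.transfer(freqs)
        if n_fft % 2 == 0:
            # the unpaired Nyquist bin must be real for a real response
            h[:, n_fft // 2] = h[:, n_fft // 2].real
        order = np.argsort(freqs)
        return GIRFSpectrum(
            freqs=freqs[order],
            h=h[:, order],
            df=1.0 / (n_fft * dt),
        )


def default_truth(seed: int = 0, noise_level: float = 0.0) -> ScannerTruth:
    return ScannerTruth(noise_level=noise_level, seed=seed)


def measure_chirp_response(
    chirp,
    truth: "ScannerTruth",
    window_duration: float,
    rng: np.random.Generator | None = None,
) -> tuple[GradientWaveform, GradientWaveform]:
    """Simulated chirp calibration measurement for GIRF estimation.

    The chirp (applied on all three axes; only self-terms exist in the
    truth model) is zero-padded to the acquisition window before playout
    so the record captures the full decay of the chain's response —
    truncating at the chirp end would bias the estimate.  Returns the
    (input, output) waveform pair on the window grid.
    """
    n_win = int(round(window_duration / chirp.dt))
    if n_win < chirp.samples.size:
        raise ValueError("window shorter than the chirp")
    g = np.zeros((3, n_win))
    g[:, : chirp.samples.size] = chirp.samples
    g_in = GradientWaveform(g, chirp.dt)
    return g_in, play_through(g_in, truth, rng=rng)


def play_through(
    g_nom: GradientWaveform,
    truth: ScannerTruth,
    rng: np.random.Generator | None = None,
) -> GradientWaveform:
    """Played-out gradient: nominal waveform through the truth response.

    This is what the synthetic scanner "actually" plays — the monitored
    oracle and the Bloch simulator both consume it.  Optional additive
    noise emulates measurement noise at the configured level.
    """
    spec = truth.spectrum(g_nom.dt, 2 * g_nom.n_samples)
    g_act = predict_gradient(g_nom, spec)
    if truth.noise_level > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        rms = np.sqrt(np.mean(g_act.samples**2, axis=1, keepdims=True))
        g_act = GradientWaveform(
            g_act.samples
            + truth.noise_level * rms * rng.standard_normal(g_act.samples.shape),
            g_act.dt,
        )
    return g_act
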