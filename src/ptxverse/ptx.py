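"""Small-tip-angle spatial-domain parallel-transmit RF pulse design.

In the small-tip-angle regime the transverse magnetization produced by a
multi-channel pulse is linear in the per-channel RF samples:

    Mxy(r, T0) = i γ m0 Σ_c B1c(r) ∫_0^T0 e^{i k(t)·r} e^{iΔω(r)(t−T0)} b_c(t) dt,

where B1c is the complex transmit sensitivity of channel c, k(t) the
excitation k-space trajectory and Δω(r) the off-resonance map.  The
design problem is a Tikhonov-regularized least-squares fit of the RF
samples to a target pattern,

    min_b ‖A b − m_target‖² + λ‖b‖²,

solved with conjugate gradients on the normal equations; λ can be given
or chosen with the L-curve criterion.  The trajectory may be nominal,
GIRF-predicted or monitored — the operator does not care where k came
from, which is exactly the hook that the iterative reshaping loop uses.

Units: RF in μT, Mxy in units of flip angle (radians) with m0 = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_1H
from .waveforms import MultiChannelRF, Trajectory

__all__ = [
    "FieldMaps",
    "TargetPattern",
    "DesignResult",
    "PtxSystem",
    "build_system",
    "solve_tikhonov_cg",
    "lcurve_select",
    "design_pulse",
]


@dataclass
class FieldMaps:
    """Spatial maps entering the small-tip design: sensitivities, off-resonance, grid.

    Attributes
    ----------
    b1 : ndarray, shape (C, Nx, Ny)
        Complex transmit sensitivity per channel (dimensionless,
        normalized so the peak magnitude is of order 1).
    domega : ndarray, shape (Nx, Ny)
        Off-resonance map Δω = γΔB0 in rad/s.
    fov : float
        Field of view in metres (square grid assumed).
    mask : ndarray of bool, shape (Nx, Ny)
        Design/evaluation region.
    m0 : float
        Equilibrium magnetization scale (default 1; Mxy is then flip
        angle in radians).
    """

    b1: np.ndarray
    domega: np.ndarray
    fov: float
    mask: np.ndarray
    m0: float = 1.0

    def __post_init__(self) -> None:
        self.b1 = np.asarray(self.b1, dtype=complex)
        self.domega = np.asarray(self.domega, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.b1.ndim != 3:
            raise ValueError("b1 must have shape (C, Nx, Ny)")
        if self.b1.shape[1:] != self.domega.shape or self.domega.shape != self.mask.shape:
            raise ValueError("all maps must share the spatial shape")
        if not self.mask.any():
            raise ValueError("mask must be non-empty")
        if not self.fov > 0:
            raise ValueError("fov must be positive")

    @property
    def n_channels(self) -> int:
        return self.b1.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.domega.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell coordinates in metres; the FOV centre coincides with a cell."""
        nx, ny = self.shape
        x = (np.arange(nx) - nx // 2) * (self.fov / nx)
        y = (np.arange(ny) - ny // 2) * (self.fov / ny)
        return np.meshgrid(x, y, indexing="ij")

    def positions(self) -> np.ndarray:
        """Masked voxel positions, shape (M, 2), metres."""
        xx, yy = self.coords()
        return np.column_stack([xx[self.mask], yy[self.mask]])


@dataclass
class TargetPattern:
    """Desired excitation magnitude (flip angle, rad) on the map grid."""

    flip: np.ndarray

    def __post_init__(self) -> None:
        self.flip = np.asarray(self.flip, dtype=float)
        if np.any(self.flip < 0):
            raise ValueError("target magnitude must be non-negative")


@dataclass
class DesignResult:
    """Outcome of one RF design: pulse, diagnostics and small-tip prediction."""

    rf: MultiChannelRF
    residual_norm: float
    lambda_used: float
    predicted: np.ndarray  # complex small-tip Mxy map on the full grid
    nrmse: float
    peak_rf: float
    cg_iterations: int = 0
    cg_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))


class PtxSystem:
    """Linear operator of the small-tip design problem (masked space × (C·time)).

    Matrix element for voxel j, channel c, time t:

        A[j, (c,t)] = i γ m0 b1c(r_j) e^{i k(t)·r_j} e^{iΔω(r_j)(t − T0)} dt × 1e-6

    (the 1e-6 converts RF μT to Tesla).  ``apply`` and ``adjoint`` use a
    single complex matrix E of encoding phases shared by all channels.
    """

    def __init__(
        self,
        maps: FieldMaps,
        k: Trajectory,
        dt: float,
        gamma: float = GAMMA_1H,
    ) -> None:
        if not maps.mask.any():
            raise ValueError("empty mask")
        self.maps = maps
        self.dt = dt
        self.gamma = gamma
        self.n_time = k.n_samples
        self.n_channels = maps.n_channels
        r = maps.positions()  # (M, 2)
        t = np.arange(self.n_time) * dt
        t0 = t[-1]
        dom = maps.domega[maps.mask]
        phase = r @ k.k[:2] + dom[:, None] * (t - t0)[None, :]
        self.encode = np.exp(1j * phase)  # (M, N)
        self.b1m = maps.b1[:, maps.mask].T.copy()  # (M, C)
        self.coeff = 1j * gamma * maps.m0 * dt * 1e-6

    @property
    def shape(self) -> tuple[int, int]:
        return (self.encode.shape[0], self.n_channels * self.n_time)

    def apply(self, b: np.ndarray) -> np.ndarray:
        """A @ b for RF samples b of shape (C, N) (μT) -> masked Mxy (M,)."""
        return self.coeff * np.einsum(
            "mc,mc->m", self.b1m, self.encode @ b.T, optimize=True
        )

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Aᴴ @ y for masked voxel data y (M,) -> (C, N)."""
        weighted = np.conj(self.b1m) * y[:, None]  # (M, C)
        return np.conj(self.coeff) * (self.encode.conj().T @ weighted).T

    def normal_apply(self, b: np.ndarray, lam: float) -> np.ndarray:
        """(AᴴA + λI) @ b."""
        return self.adjoint(self.apply(b)) + lam * b

    def dense(self) -> np.ndarray:
        """Dense matrix, shape (M, C·N).  For small validation problems only."""
        m = self.shape[0]
        cols = self.coeff * np.einsum("cm,nm->cnm", self.b1m.T, self.encode.T)
        return cols.reshape(self.n_channels * self.n_time, m).T

    def embed(self, y: np.ndarray) -> np.ndarray:
        """Scatter masked voxel values back onto the full grid (complex)."""
        out = np.zeros(self.maps.shape, dtype=complex)
        out[self.maps.mask] = y
        return out


def build_system(
    maps: FieldMaps, k: Trajectory, dt: float, gamma: float = GAMMA_1H
) -> PtxSystem:
    """Construct the small-tip design operator for the given maps and trajectory."""
    return PtxSystem(maps, k, dt, gamma)


def solve_tikhonov_cg(
    a: PtxSystem,
    target: np.ndarray,
    lam: float,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate-gradient solution of (AᴴA + λI) b = Aᴴ m.

    Deterministic from zero initialization.  Returns the RF sample array
    (C, N) and the relative normal-equation residual history.  Aborts
    with a diagnostic if the recurrence diverges.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    b = np.zeros((a.n_channels, a.n_time), dtype=complex)
    r = a.adjoint(target)
    norm0 = float(np.linalg.norm(r))
    if norm0 == 0.0:
        return b, np.zeros(0)
    p = r.copy()
    rs_old = float(np.vdot(r, r).real)
    residuals = []
    for _ in range(max_iter):
        ap = a.normal_apply(p, lam)
        denom = float(np.vdot(p, ap).real)
        if denom <= 0:
            break  # numerically singular direction; accept current iterate
        alpha = rs_old / denom
        b += alpha * p
        r -= alpha * ap
        rs_new = float(np.vdot(r, r).real)
        rel = np.sqrt(rs_new) / norm0
        residuals.append(rel)
        if rel < tol:
            break
        if rel > 1e3 * (min(residuals) if residuals else 1.0):
            raise RuntimeError(
                "CG diverged: relative residual %.3e after %d iterations"
                % (rel, len(residuals))
            )
        p = r + (rs_new / rs_old) * p
        rs_old = rs_new
    return b, np.asarray(residuals)


def _menger_curvature(pts: np.ndarray) -> np.ndarray:
    """Three-point (circumscribed-circle) curvature of a planar polyline."""
    p1, p2, p3 = pts[:-2], pts[1:-1], pts[2:]
    cross = (p2[:, 0] - p1[:, 0]) * (p3[:, 1] - p1[:, 1]) - (
        p2[:, 1] - p1[:, 1]
    ) * (p3[:, 0] - p1[:, 0])
    d12 = np.linalg.norm(p2 - p1, axis=1)
    d23 = np.linalg.norm(p3 - p2, axis=1)
    d13 = np.linalg.norm(p3 - p1, axis=1)
    denom = d12 * d23 * d13
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return kappa


def lcurve_select(
    a: PtxSystem,
    target: np.ndarray,
    lambda_grid: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> float:
    """Pick λ at the corner (maximum curvature) of the L-curve.

    The L-curve plots log residual norm against log solution norm over a
    grid of regularization weights; its corner balances data fidelity
    against RF power.  A degenerate (cornerless) curve falls back to the
    median λ with a warning.
    """
    lams = np.sort(np.asarray(lambda_grid, dtype=float))
    if lams.size < 3:
        raise ValueError("need at least 3 lambda grid points")
    if np.any(lams <= 0):
        raise ValueError("lambda grid must be positive")
    if np.unique(lams).size != lams.size:
        raise ValueError("duplicate lambda values in grid")
    pts = np.empty((lams.size, 2))
    for i, lam in enumerate(lams):
        b, _ = solve_tikhonov_cg(a, target, lam, max_iter=max_iter, tol=tol)
        rho = float(np.linalg.norm(a.apply(b) - target))
        eta = float(np.linalg.norm(b))
        pts[i] = (np.log10(max(rho, 1e-300)), np.log10(max(eta, 1e-300)))
    # The L-curve is traversed with increasing λ: residual grows, norm
    # shrinks; the corner turns clockwise, i.e. negative Menger curvature.
    kappa = _menger_curvature(pts)
    corner = -kappa
    if not np.any(corner > 0):
        warnings.warn("L-curve has no detectable corner; using median lambda")
        return float(lams[lams.size // 2])
    return float(lams[1 + int(np.argmax(corner))])


def design_pulse(
    maps: FieldMaps,
    k: Trajectory,
    dt: float,
    target: TargetPattern,
    lam: float | str = "lcurve",
    gamma: float = GAMMA_1H,
    max_iter: int = 200,
    tol: float = 1e-6,
    lambda_grid: np.ndarray | None = None,
    lcurve_max_iter: int = 40,
) -> DesignResult:
    """Design a multi-channel small-tip pulse on an arbitrary trajectory.

    The (magnitude) target is given a spatial phase equal to the phase
    of the quadrature-mode field (sum of channel sensitivities), a
    standard choice that lets the channels add constructively.  With
    ``lam="lcurve"`` the regularization weight is selected on a
    log-spaced grid scaled by the operator's largest singular value.
    """
    a = build_system(maps, k, dt, gamma)
    quad = np.sum(maps.b1, axis=0)[maps.mask]
    phase = np.where(np.abs(quad) > 0, quad / np.where(np.abs(quad) > 0, np.abs(quad), 1.0), 1.0)
    m_target = target.flip[maps.mask] * phase
    if isinstance(lam, str):
        if lam != "lcurve":
            raise ValueError("lam must be a number or 'lcurve'")
        if lambda_grid is None:
            sigma2 = _largest_singular_value_sq(a)
            lambda_grid = sigma2 * np.logspace(-6, 0, 16)
        lam_val = lcurve_select(
            a, m_target, lambda_grid, max_iter=lcurve_max_iter, tol=tol
        )
    else:
        lam_val = float(lam)
    b, residuals = solve_tikhonov_cg(a, m_target, lam_val, max_iter=max_iter, tol=tol)
    pred_masked = a.apply(b)
    predicted = a.embed(pred_masked)
    resid = float(np.linalg.norm(pred_masked - m_target))
    tnorm = float(np.linalg.norm(np.abs(m_target)))
    nrmse = float(
        np.linalg.norm(np.abs(pred_masked) - np.abs(m_target)) / tnorm
    )
    rf = MultiChannelRF(b, dt)
    return DesignResult(
        rf=rf,
        residual_norm=resid,
        lambda_used=lam_val,
        predicted=predicted,
        nrmse=nrmse,
        peak_rf=rf.peak,
        cg_iterations=len(residuals),
        cg_residuals=residuals,
    )


def _largest_singular_value_sq(a: PtxSystem, n_iter: int = 8) -> float:
    """Power-iteration estimate of ‖A‖² (deterministic start vector)."""
    rng = np.random.default_rng(0)
    b = rng.standard_normal((a.n_channels, a.n_time)) + 1j * rng.standard_normal(
        (a.n_channels, a.n_time)
    )
    b /= np.linalg.norm(b)
    sigma2 = 1.0
    for _ in range(n_iter):
        b = a.adjoint(a.apply(b))
        sigma2 = float(np.linalg.norm(b))
        if sigma2 == 0.0:
            return 1.0
        b /= sigma2
    return sigma2
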