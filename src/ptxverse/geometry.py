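"""Path-geometry diagnostics for k-space trajectories.

VERSE reshaping must leave the traversed k-space path unchanged — only
the speed along it changes.  These helpers compare trajectories as
geometric curves: a dwell-grid waveform is first upsampled with a cubic
spline so the trapezoidal k-space integral approximates the continuous
path well below the comparison tolerance, and polylines are compared
with a symmetric Hausdorff distance using point-to-segment projection.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .constants import GAMMA_1H
from .waveforms import GradientWaveform, Trajectory, compute_k

__all__ = ["refined_k", "hausdorff_polyline"]


def refined_k(
    g: GradientWaveform, gamma: float = GAMMA_1H, refine: int = 16
) -> Trajectory:
    """k-space path of ``g`` integrated on a ``refine``-times finer grid.

    Cubic-spline resampling keeps the trapezoidal integration error far
    below the dwell-grid result, so the returned polyline can serve as a
    reference for path-geometry comparisons.
    """
    t = g.times
    t_fine = np.linspace(t[0], t[-1], (g.n_samples - 1) * refine + 1)
    samples_fine = CubicSpline(t, g.samples, axis=1)(t_fine)
    return compute_k(GradientWaveform(samples_fine, g.dt / refine), gamma)


def _directed_hausdorff(p: np.ndarray, q: np.ndarray) -> float:
    """max over points of p of the distance to the polyline through q.

    Points are matched to their nearest polyline vertex with a KD-tree
    and then projected onto the adjacent segments; this is accurate when
    q is sampled densely relative to its curvature, which `refined_k`
    guarantees for the trajectories compared here.
    """
    tree = cKDTree(q)
    _, idx = tree.query(p)
    d = np.full(p.shape[0], np.inf)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, q.shape[0] - 2)
        a = q[j]
        ab = q[j + 1] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        tproj = np.einsum("ij,ij->i", p - a, ab) / np.where(denom > 0, denom, 1.0)
        tproj = np.clip(tproj, 0.0, 1.0)
        foot = a + tproj[:, None] * ab
        d = np.minimum(d, np.linalg.norm(p - foot, axis=1))
    return float(d.max())


def hausdorff_polyline(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two polylines.

    Parameters are point arrays of shape (N, D) (or (D, N) trajectories
    transposed by the caller).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return max(_directed_hausdorff(p, q), _directed_hausdorff(q, p))
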