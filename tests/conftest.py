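"""Shared fixtures: a scaled-down synthetic study for fast unit tests.

The small configuration keeps every physical convention of the default
study (dwell, hardware limits, spiral law) but uses a 32 × 32 grid, four
transmit channels and 4 mm excitation resolution so designs run in a few
seconds.
"""

import numpy as np
import pytest

import ptxverse as px


@pytest.fixture(scope="session")
def small_cfg():
    return px.FixtureConfig(grid=32, channels=8, spiral_res=0.004, seed=3)


@pytest.fixture(scope="session")
def small_maps(small_cfg):
    return px.make_maps(small_cfg)


@pytest.fixture(scope="session")
def small_target(small_cfg):
    return px.make_target(small_cfg)


@pytest.fixture(scope="session")
def small_spiral(small_cfg):
    return px.make_spiral_in(small_cfg)


@pytest.fixture(scope="session")
def small_design(small_maps, small_target, small_spiral):
    g, k = small_spiral
    return px.design_pulse(
        small_maps, k, g.dt, small_target, lam=2e-4, max_iter=80
    )


@pytest.fixture(scope="session")
def gentle_pulse():
    """A smooth, fully dwell-resolved RF/gradient pair for VERSE property tests."""
    dt = px.DEFAULT_DWELL
    n = 1500
    t = np.arange(n) * dt
    T = n * dt
    gx = 5.0 + 0.8 * np.sin(2 * np.pi * t / T * 1.5)
    gy = 0.8 * np.cos(2 * np.pi * t / T)
    g = px.GradientWaveform(np.vstack([gx, gy, np.zeros(n)]), dt)
    rfs = (
        8.0 * np.exp(-(((t - T / 2) / (T / 5)) ** 2)) * np.exp(1j * 3 * np.pi * t / T)
    ).reshape(1, -1)
    rf = px.MultiChannelRF(rfs, dt)
    return rf, g
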