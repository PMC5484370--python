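"""Serialization: columnar plain-text waveforms and GIRF spectra, and an
HDF5 container for field maps.

The text waveform format is deliberately simple: header lines

    # dt_s=<float>
    # units=<mT/m|uT>
    # channels=<int>

followed by whitespace-separated columns, one row per time sample (time
index implicit).  Gradients use three columns (x, y, z); complex RF uses
alternating real/imaginary columns per channel.  Values are written with
17 significant digits so a read/write round trip is lossless.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .girf import GIRFSpectrum
from .ptx import FieldMaps, TargetPattern
from .waveforms import GradientWaveform, MultiChannelRF

__all__ = [
    "write_gradient",
    "read_gradient",
    "write_rf",
    "read_rf",
    "write_girf",
    "read_girf",
    "write_maps",
    "read_maps",
]

_FMT = "%.17g"


def _write_columns(path: Path, header: dict, columns: np.ndarray) -> None:
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, columns, fmt=_FMT)


def _read_columns(path: Path) -> tuple[dict, np.ndarray]:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    return header, data


def write_gradient(path: str | Path, g: GradientWaveform) -> None:
    _write_columns(
        Path(path),
        {"dt_s": repr(g.dt), "units": "mT/m", "channels": 3},
        g.samples.T,
    )


def read_gradient(path: str | Path) -> GradientWaveform:
    header, data = _read_columns(Path(path))
    if header.get("units") != "mT/m":
        raise ValueError(f"{path}: expected gradient units mT/m")
    return GradientWaveform(data.T, float(header["dt_s"]))


def write_rf(path: str | Path, rf: MultiChannelRF) -> None:
    cols = np.empty((rf.n_samples, 2 * rf.n_channels))
    cols[:, 0::2] = rf.samples.real.T
    cols[:, 1::2] = rf.samples.imag.T
    _write_columns(
        Path(path),
        {"dt_s": repr(rf.dt), "units": "uT", "channels": rf.n_channels},
        cols,
    )


def read_rf(path: str | Path) -> MultiChannelRF:
    header, data = _read_columns(Path(path))
    if header.get("units") != "uT":
        raise ValueError(f"{path}: expected RF units uT")
    n_ch = int(header["channels"])
    if data.shape[1] != 2 * n_ch:
        raise ValueError(f"{path}: column count does not match channels")
    samples = data[:, 0::2].T + 1j * data[:, 1::2].T
    return MultiChannelRF(samples, float(header["dt_s"]))


def write_girf(path: str | Path, spectrum: GIRFSpectrum) -> None:
    cols = np.empty((spectrum.freqs.size, 7))
    cols[:, 0] = spectrum.freqs
    for a in range(3):
        cols[:, 1 + 2 * a] = spectrum.h[a].real
        cols[:, 2 + 2 * a] = spectrum.h[a].imag
    _write_columns(Path(path), {"df_hz": repr(spectrum.df)}, cols)


def read_girf(path: str | Path) -> GIRFSpectrum:
    header, data = _read_columns(Path(path))
    h = np.empty((3, data.shape[0]), dtype=complex)
    for a in range(3):
        h[a] = data[:, 1 + 2 * a] + 1j * data[:, 2 + 2 * a]
    return GIRFSpectrum(freqs=data[:, 0], h=h, df=float(header["df_hz"]))


def write_maps(
    path: str | Path, maps: FieldMaps, target: TargetPattern | None = None
) -> None:
    """Store field maps (and optionally a target pattern) in an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("b1_re", data=maps.b1.real)
        f.create_dataset("b1_im", data=maps.b1.imag)
        f.create_dataset("domega", data=maps.domega)
        f.create_dataset("mask", data=maps.mask.astype(np.uint8))
        f.attrs["fov_m"] = maps.fov
        f.attrs["m0"] = maps.m0
        if target is not None:
            f.create_dataset("target_flip", data=target.flip)


def read_maps(path: str | Path) -> tuple[FieldMaps, TargetPattern | None]:
    with h5py.File(path, "r") as f:
        maps = FieldMaps(
            b1=f["b1_re"][...] + 1j * f["b1_im"][...],
            domega=f["domega"][...],
            fov=float(f.attrs["fov_m"]),
            mask=f["mask"][...].astype(bool),
            m0=float(f.attrs["m0"]),
        )
        target = (
            TargetPattern(f["target_flip"][...]) if "target_flip" in f else None
        )
    return maps, target
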