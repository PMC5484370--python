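"""Characterize the gradient chain from chirp calibration measurements.

Four linear frequency sweeps (10-40 kHz, 10 ms) are played through the
synthetic scanner truth; the per-axis impulse response spectrum is
estimated by least-squares deconvolution from the 70 ms records and
compared with the truth it should recover.
"""

import numpy as np

import ptxverse as px

truth = px.default_truth()
dwell = px.DEFAULT_DWELL

inputs, outputs = [], []
for bandwidth in (10e3, 20e3, 30e3, 40e3):
    chirp = px.make_chirp(bandwidth, 10e-3, 10.0, dwell, smax=180.0)
    g_in, g_out = px.measure_chirp_response(chirp, truth, 70e-3)
    inputs.append(g_in)
    outputs.append(g_out)

spec = px.estimate_girf(inputs, outputs, window_duration=70e-3)
h_true = truth.spectrum(dwell, int(round(70e-3 / dwell)))

print(f"frequency resolution: {px.girf_frequency_resolution(70e-3):.1f} Hz")
for axis, name in enumerate("xyz"):
    band = spec.confident[axis]
    rel = np.abs(spec.h[axis] - h_true.h[axis]) / np.abs(h_true.h[axis])
    i_res = np.argmin(np.abs(spec.freqs - 1100.0))
    print(
        f"axis {name}: in-band recovery error {rel[band].max():.2e}, "
        f"|H| at the 1.1 kHz mechanical resonance {np.abs(spec.h[axis][i_res]):.3f}"
    )
# Recovery errors ~1e-4 mean the one-time chirp calibration captures the
# chain well enough to predict played-out gradients for pulse design.
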