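"""End-to-end: iterative VERSE design with and without trajectory correction.

The synthetic scanner distorts every commanded gradient through its
low-pass + mechanical-resonance response.  The uncorrected loop designs
on the commanded (nominal) trajectory; the corrected loop estimates the
chain from chirp calibrations and redesigns on the predicted played-out
trajectory at every iteration.  Both are then evaluated by full Bloch
simulation under the true playout.
"""

import numpy as np

import ptxverse as px

cfg = px.FixtureConfig(seed=1)
g0, _ = px.make_spiral_in(cfg)
maps = px.make_maps(cfg)
target = px.make_target(cfg)
truth = px.default_truth()

inputs, outputs = [], []
for bandwidth in (10e3, 20e3, 30e3, 40e3):
    chirp = px.make_chirp(bandwidth, 10e-3, 10.0, cfg.dwell, smax=cfg.s_max)
    g_in, g_out = px.measure_chirp_response(chirp, truth, 70e-3)
    inputs.append(g_in)
    outputs.append(g_out)
spec = px.estimate_girf(inputs, outputs, window_duration=70e-3)

constraints = px.VerseConstraints(b1_max=12.0, g_max=30.0, s_max=180.0, alpha=0.95)
for mode, oracle in (
    ("nominal", px.GradientOracle("nominal")),
    ("girf-corrected", px.GradientOracle("girf", girf=spec)),
):
    history = px.reverse_design(
        maps, target, g0, constraints, oracle,
        max_iter=10, lam=2e-4, cg_max_iter=100,
    )
    peaks = ", ".join(f"{it.peak_rf:.1f}" for it in history.iterates)
    final = history.final
    played = px.play_through(final.g_nominal, truth)
    result = px.bloch_propagate(final.rf, played, maps)
    err = px.nrmse(result, target.flip, maps.mask)
    print(f"{mode}:")
    print(f"  peak RF per iteration [uT]: {peaks}")
    print(f"  converged: {history.converged} in {len(history)} iterations, "
          f"final duration {final.duration_ms:.2f} ms")
    print(f"  Bloch NRMSE under the true playout: {100 * err:.1f} %")
# The peak-RF bound is met either way, but only the corrected design
# also excites the intended pattern once the hardware distorts the
# trajectory - the uncorrected error is an order of magnitude larger.
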