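"""Build the time-optimal spiral-in excitation trajectory and inspect it.

The trajectory encodes a 128 mm field of view at 2 mm resolution,
radially undersampled 2x, traversed as fast as the 30 mT/m amplitude and
180 T/m/s slew limits allow.
"""

import numpy as np

import ptxverse as px

cfg = px.FixtureConfig(seed=1)
g, k = px.make_spiral_in(cfg)
s = px.arc_length(g)

print(f"samples            : {g.n_samples} at {g.dt * 1e6:.1f} us dwell")
print(f"duration           : {g.duration * 1e3:.2f} ms")
print(f"|k| at start       : {np.linalg.norm(k.k[:, 0]):.1f} rad/m "
      f"(pi/res = {np.pi / cfg.spiral_res:.1f})")
print(f"total arc length   : {s[-1]:.0f} rad/m")
print(f"peak gradient      : {np.linalg.norm(g.samples, axis=0).max():.2f} mT/m")
print(f"peak slew rate     : {np.abs(px.slew(g)).max():.1f} T/m/s")
# The arc length is the distance the trajectory travels through
# excitation k-space; VERSE reshaping re-times the traversal of exactly
# this path without changing its geometry.
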