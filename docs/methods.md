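# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, in the order a user meets them.

## Conventions and units

Gradients are stored in mT/m, RF envelopes in μT (complex, one row per
transmit channel), time in seconds on a uniform dwell grid (default
6.4 μs). Excitation k-space is in rad/m with γ = 2.675221×10⁸
rad·s⁻¹·T⁻¹ for ¹H, so the encoding phase is literally e^{i k·r} with r
in metres. The trajectory convention is k(t) = −γ∫_t^T0 G dt′,
integrated with the trapezoidal rule; k at the final sample is exactly
zero, which tests rely on. Equilibrium magnetization is m0 = 1 and
transverse magnetization is interpreted as flip angle in radians; a
waveform of N samples is reported with duration N·dt.

## Small-tip design

`build_system` discretizes the small-tip integral on the masked voxel
grid: element (j, c, t) is iγ m0 b1c(r_j) e^{i k_t·r_j}
e^{iΔω_j(t−T0)} dt (×10⁻⁶ for μT units). The grid is cell-based with a
cell exactly at the FOV centre (coordinates (i − N/2)·Δ), which makes a
30 mm square on a 2 mm grid exactly 15×15 cells. The solver is conjugate
gradients on the Tikhonov normal equations, zero-initialized for
determinism, tolerance 1e−6 on the relative normal-equation residual,
at most 200 iterations. The magnitude target is given the spatial phase
of the quadrature-mode field (sum of channel sensitivities), a standard
choice that lets channels add constructively.

**Regularization.** `lcurve_select` implements the L-curve criterion
(corner = maximum Menger curvature of the log-residual/log-norm curve,
clockwise bend; degenerate curves fall back to the median λ with a
warning). On the *noiseless, well-conditioned* synthetic study the
L-curve has no vertical branch — the solution norm saturates as λ → 0 —
so its corner sits in heavily regularized territory (design errors of
tens of percent). The pipeline therefore defaults to a fixed λ = 2×10⁻⁴
(≈ 4×10⁻³ of the operator's largest squared singular value), which puts
designs in the 5–8% small-tip NRMSE regime; the L-curve remains
available for noisy, measured inputs where it is appropriate. The
iterative loop selects λ once at the first iteration and freezes it
(re-selection available via a flag).

## VERSE

`to_sdomain` resamples a waveform pair onto a uniform arc-length grid
with spacing γ·max|G|·dt/16 — 16× oversampling of the fastest traversal,
needed so the finite-difference curvature of tightly wound paths (inner
spiral turns) is resolved; at 4× oversampling the reshaped waveform
overshoots the slew cap by tens of percent. The k-space path is carried
as a cubic spline of a refined integration of the input, and resampling
takes tangents from the spline derivative. RF energy where |G| is below
10⁻⁴×max|G| makes a pulse non-representable (the ratio W is unbounded)
and is rejected; the loop clears such samples first (they sit at the
stationary endpoints of time-optimal waveforms and carry negligible
flip). W below 10⁻⁶ μT counts as zero.

For multiple channels the amplitude bound uses max_c W_c(s), the
conservative extension that keeps every channel under the peak-RF bound.
The attenuation factor α = 0.95 is applied inside the bound (the
reshaping targets α·B1,max while the loop's convergence test uses
B1,max itself), damping oscillatory overshoot of the peak across
iterations.

`time_optimal_traverse` solves the phase-plane problem: pointwise caps
from the amplitude bound (v ≤ γ·bound) and the centripetal slew
component (κv²/γ ≤ s_max), then forward/backward sweeps from v = 0 at
both endpoints enforcing the tangential component of the slew
inequality. Elapsed time integrates ds/v with the harmonic-mean rule,
which is exact for constant-acceleration spans; dwell-grid sampling of
s(t) and v(t) uses the matching per-interval closed form. A small
constant (≈10⁻⁶ mT/m) is added to the resampled gradient to zero the
net-displacement bias of the integrated trajectory.

**Geometry preservation accuracy.** Reshaping preserves the k-space path
by construction, but two floors limit how precisely any *dwell-sampled*
output can be shown to retrace it: (i) where the traversal is slew- and
curvature-limited (the spiral core) the path between samples is
intrinsically ambiguous by ≈ γ·s_max·dt²/8 ≈ 0.25 rad/m, independent of
the curvature radius; (ii) on fully resolved smooth pulses the
integration-convention drift between the constructed waveform and an
independent path integrator plateaus around 10⁻³ rad/m (≈10⁻⁷ of the
path length). Geometry is therefore verified at these scales — below
0.05% of the k-space extent — rather than to an arbitrary absolute
precision.

## GIRF estimation and prediction

Chirps g(t) = A sin(π(BW/T)t²) sweep 0→BW over T; amplitudes are scaled
down when the slew cap binds and the scale is reported. Estimation
zero-pads every input/output pair to the analysis window (default
70 ms, i.e. 14.3 Hz resolution), accumulates the least-squares
deconvolution per axis with ε = 10⁻⁶ × the peak accumulated denominator,
enforces Hermitian symmetry, and flags bins whose denominator is below
10⁻² of the peak as low-confidence instead of failing. The calibration
records must cover the response's settling tail — truncating at the
chirp end biases the estimate by several percent, which is why
`measure_chirp_response` pads the playout to the acquisition window.

Prediction zero-pads the nominal waveform 2× (suppressing circular
wrap-around of ms-scale tails), resamples H onto the padded grid by
linear interpolation of its real and imaginary parts (a shortfall of up
to two edge bins is clamp-extrapolated; anything narrower is rejected),
multiplies, and truncates back to the input length. An exactly-identity
spectrum returns the input unchanged, so a unity response is a true
no-op in the loop. Only self-terms (x→x, y→y, z→z) are modelled;
cross-terms and the B0 (zeroth-order) response are out of scope.

## The iterative corrected loop

Each iteration: obtain the played-out gradient from the oracle (identity
/ GIRF prediction / monitoring callable), compute the trajectory from
it, redesign the RF on that trajectory, stop if the peak RF is within
the bound, otherwise VERSE the (RF, nominal gradient) pair toward
α×bound and continue — consulting the oracle afresh on the reshaped
command, because the played-out trajectory changes with every reshaping.
Reshaping the pair (RF, *actual* gradient) instead was tried and
diverges: the reshaped actual waveform, used as the next command, is
filtered again on playout.

Two stabilizations beyond the plain loop proved necessary once the
trajectory changes between iterations:

* **Bound accumulation.** VERSE preserves the path, so every iteration's
  amplitude bound lives on the same arc-length axis; the loop keeps the
  pointwise minimum of all bounds seen so far. Without it, regions
  slowed for one iteration's RF speed up again as soon as the next
  redesign moves its peak, and the loop limit-cycles a few μT above the
  bound.
* **Bound neighbourhood.** The bound is eroded over ±100 rad/m (running
  minimum) with a 30 rad/m Gaussian smoothing of the dip edges. The
  erosion pre-empts the small arc-position shifts of the redesigned peak
  between iterations; the smoothing keeps the reshaping from writing
  speed transients at the ~1 ms timescale of the chain's mechanical
  resonance, which would otherwise ring in the next predicted
  trajectory. Neither operation ever raises the bound, so constraint
  satisfaction is unaffected.

With both, the nominal and corrected loops converge in 2–5 iterations on
the default study, in line with how such loops behave in practice; the
unstabilized variant is available (`accumulate_bound=False`,
`bound_min_halfwidth=0`).

## Bloch simulation

`bloch_propagate` uses symmetric (Strang) split hard pulses per dwell:
half a gradient/off-resonance z-rotation, an instantaneous RF rotation
about the transverse axis of Σ_c B1c(r)·b_c(t), and another half
z-rotation, starting from (0, 0, m0) with relaxation neglected. The
split form matters: at 6.4 μs dwell the per-dwell gradient phase reaches
~3 rad at the FOV edge, so a constant-field-per-dwell propagator
disagrees with the discretized design integral by tens of percent. The
Strang form is second-order accurate for the continuous dynamics *and*
its small-tip limit coincides with the design operator's quadrature
(trapezoidal k at the sample nodes), so designer and simulator agree by
construction as the flip angle becomes small; at 10° the fixture
disagreement is ~0.01%. `small_tip` shares the design operator verbatim
(bit-for-bit equal to the designer's own prediction).

NRMSE is ‖|flip| − |target|‖₂ / ‖target‖₂ over the evaluation mask, with
flip = atan2(|Mxy|, Mz) for the Bloch result and |Mxy|/m0 for the
small-tip result. Designs are computed at the experiment's flip angle
(90°) with the linear model and evaluated with the full simulator; the
residual linearization error is part of the reported NRMSE.

## Synthetic scanner model

The generator supplies every input the method needs, at the default
study scale: 64×64 grid over 128 mm, 8 channels, 30×30 mm² square target
blurred with a 10 mm FWHM Gaussian, 2 mm-resolution spiral-in
trajectory radially undersampled 2×, 30 mT/m / 180 T/m/s limits, 6.4 μs
dwell.

* **B1+ maps** are Gaussian lobes (width 0.22×FOV) on a 0.45×FOV ring
  with constructive phase at the centre, a mild seeded low-order
  perturbation and per-channel phase roll — smooth deterministic modes,
  not electromagnetic simulation: the design only needs smooth complex
  sensitivities, and determinism beats realism for testing. The lobe
  width is chosen so the quadrature-mode sensitivity at the centre is
  ≈1 and an unconstrained 90° design peaks around 20–30 μT, i.e. 1.7–2.5×
  the 12 μT bound — the regime in which the reshaping loop actually has
  work to do. What passing tests show about real arrays is therefore the
  *mechanism*, not absolute error levels for any particular coil.
* **Off-resonance** is a seeded sum of broad Gaussians scaled to
  ±200 rad/s.
* **The gradient-chain truth** is, per axis, a second-order low-pass
  (−3 dB at 9 kHz on x/y, 7 kHz on z — the z axis deliberately narrower)
  times one resonant perturbation of ≈10% at 1.1 kHz (Q 15–18), with
  unit DC gain and Hermitian symmetry by construction. The bulk (DC
  group) delay of the causal low-pass is compensated, emulating a
  delay-calibrated chain whose measured phase is flat around DC; the
  residual response is then dispersive rather than a bulk shift, which
  is exactly what trajectory correction must handle. The model is
  synthetic — plausible for a whole-body system, not a fit to any
  measured hardware — and produces 3–8% peak relative gradient deviation
  on the study spiral. Optional seeded noise emulates measurement noise.
* **The spiral** is Archimedean with uniform radial pitch
  (undersampling × 2π/FOV per turn), arc-length parametrized and
  traversed time-optimally; it starts at rest at k_max = π/res and ends
  at rest at the k-space origin.

## Problem sizes and determinism

The default study runs a ~12.4 ms, ~1930-sample, 8-channel design on
4096 voxels; one design solve is a few seconds and a full two-mode loop
comparison with Bloch evaluation completes in under two minutes on one
CPU. Unit tests use a 32×32 / 4 mm variant of the same study. All
randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

* Magnitude-least-squares (phase-relaxed) design, explicit SAR
  constraints, cross-term and B0 GIRF components, RF-amplifier
  distortion and relaxation during excitation are out of scope.
* The L-curve criterion is unreliable on noiseless well-conditioned
  problems (documented above); the fixed-λ default encodes that.
* Hard-pulse segments (RF where the gradient is zero) are rejected
  rather than handled; the s-domain formulation cannot represent them.
* Geometry preservation can only be certified to the dwell-grid
  representation floors described in the VERSE section.
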