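# Methods

## Coordinate and phase conventions

All geometry is in cm in a right-handed isocenter frame: +y superior (the
motion axis), +z towards the source. The point source sits at
(0, 0, SAD); the detector plane at z = SAD − SID, with pixel pitch
expressed at the isocenter plane (defaults SAD = SID = 100 cm, 256×256
pixels at 0.1 cm — the paperless projective frame only has to be
self-consistent, and gamma criteria are defined in isocenter-plane
millimetres). Image rows map to −y, columns to +x.

Breathing phase runs 0–100% per cycle with 0% at the inhalation peak and
50% at the exhalation trough. A gating window is a closed cyclic interval
`cyclic_distance(phase, center) ≤ half_width`; boundary samples count as
gated (a consistent maximal-duty-cycle convention — with samples landing
exactly on window edges this admits one extra sample per cycle, visible as
duty cycle 0.209 rather than 0.200 for a 20% window at 30 Hz/4 s).

## Phase assignment

Phase is assigned retrospectively with the whole trace known. Inhalation
peaks are local maxima with minimum separation of half the estimated
period (seeded by the autocorrelation peak, then refined from the median
inter-peak interval) and minimum prominence of 10% of the trace's range.
Each interior peak is then refined to sub-sample precision by a local
quadratic least-squares fit over ±15% of a period (with concavity and
in-window guards; boundary peaks keep their sample time). The refinement
matters under measurement noise: discrete argmax jitter near a flat
inhalation peak is several samples, which would leak percent-level phase
error into the gating mask; the fit reduces it well below one percent.
Samples outside the first/last peak are extrapolated with the adjacent
cycle's period. Real-time predictive phase tracking is deliberately not
modelled — drift between real-time and retrospective phase is a
discrepancy this QA method is meant to detect.

## Stage execution-error model

The motorized stage executes a commanded trace imperfectly. Three
mechanisms, with defaults matching bench measurements of such rigs:

* **Cumulative delay** — 0.0655 s of lag per second of run time, applied
  as a uniform time stretch (the measured cumulative delay is linear in
  run time), so every breathing period grows by exactly 6.55%.
* **Positional noise** — zero-mean Gaussian, σ = 0.0359 cm, chosen so the
  expected absolute error σ√(2/π) equals the benchmarked 0.0286 cm mean
  absolute error (the hardware numbers report |error| statistics, not a
  noise distribution).
* **Turning-point overshoot** — 0.05 cm added in the motion direction
  within ±2 samples of each detected turning point; half the benchmarked
  0.1 cm maximal error, which hardware attributes to over-travel at
  velocity reversals.

The executed trace is re-phased retrospectively from its own positions.
This emulates the surrogate camera tracking the marker block the stage
actually moves: the marker lags identically with the tumor, so gating
follows the executed cycle. (Gating the executed positions by the
commanded clock would accumulate ≈46% of a cycle of phase error over a
30 s run at the default delay rate — a failure mode of open-loop gating,
not of the RPM-style tracking modelled here.) A fully zero error model
returns the input curve unchanged.

## Averaged tumor and voxelization

The sphere is voxelized by 3×3×3 supersampling on a 1 mm isotropic grid
(partial volume = occupied subcell fraction; sufficient for 2–4 cm spheres,
and the grid always spans the trace's full motion range so that every
window-conditional phantom on one curve shares a single voxelization).
Displacements are applied on the supersampled y-grid (1/3 mm) with linear
sub-bin weight splitting and the per-sample occupancies averaged — exact
for displacements on the fine grid, first-order accurate in between, and
mass-conserving by construction (verified against the analytic sphere
volume to <1%). The optional support rod (cylinder, default density 0.2
for a 20% infill print, off by default) is static and added after
averaging. Tumor default density is 1.0 (printed PLA at high infill is
water-like).

## Ray tracing

Radiological thickness is the exact Siddon line integral: all parametric
voxel-plane crossings inside the grid are collected and sorted, and each
segment is attributed to the voxel containing its midpoint (the standard
half-open convention, no double counting). The per-pixel map uses the
divergent-beam geometry with a cheap bounding-box rejection; kernels are
numba-compiled. Verified against analytic sphere chords (≤1%) and a 10 µm
dense-sampling oracle (≤0.1% on oblique rays). One caveat inherent to
piecewise-constant voxel fields: a ray at a generic lateral position
integrates values that represent each cell's center, a first-order h/2
offset; it cancels along oblique rays but not for axis-parallel or
near-tangent ones, so per-ray invariance under voxel refinement holds in
the median (<0.5%) rather than uniformly.

## Prediction vs simulated measurement

The **prediction** applies T to the thickness map of the averaged phantom
(T of the mean); the **simulated measurement** averages T over the
thickness maps of each gated instantaneous position (mean of T), which is
what an integrating EPID records. The two agree exactly for static
phantoms and differ by a Jensen gap (mean-of-T ≥ T-of-mean, since T is
convex) plus the stage's execution errors for moving ones — precisely the
discrepancy the gamma comparison quantifies. Displacing the sphere and
tracing from a fixed source equals tracing the static sphere with source
and pixel shifted oppositely, which is how the measurement simulator
avoids re-voxelizing per sample. The prediction applies all factors to
the time-integrated in-air image; gantry-angle-resolved (segmental)
computation is out of scope.

## Gamma analysis

Global normalisation to the reference (measured) maximum; evaluable mask
at 10% of that maximum; the evaluated (predicted) image is bilinearly
upsampled ×10; the search is capped at 3× the DTA, which is converged for
these smooth transit gradients (checked against an uncapped brute-force
construction in the tests); pass is γ ≤ 1 inclusive. Local normalisation
exists as an option flag only. Reference = measured and evaluated =
predicted because the QA question is "does the prediction explain the
measurement".

## Gating-window recovery

The grid search evaluates 21 centers (0–100% in 5% steps; 100 ≡ 0
evaluated once) × 4 half-widths (5, 10, 15, 20%), caching predictions for
windows that select identical gated sample sets, and maximises the
2 mm/2% GPR. Cells whose window has no dwell time score 0. Ties are
real, not an edge case: a sub-DTA perturbation (e.g. a 1 mm shift against
a 2 mm DTA) can leave dozens of windows all passing every pixel. They are
resolved in two stages: a cell whose prediction matches the measured image
to numerical identity (mean γ ≤ 1e-6; physically distinct windows differ
by ≥ ~1e-4) wins outright, making self-consistency exact; otherwise the
smallest half-width and then the center cyclically closest to 50% is
preferred — the most specific, exhalation-centered window, which is the
clinically standard gating choice. The recovered *center* is the reliable
output; width cross-sections of the GPR surface are nearly flat and the
recovered width routinely deviates from truth.

The sensitivity scan perturbs the breathing positions (±1 mm global
set-up shifts; seeded Gaussian noise at the stage-derived σ = 0.0359 cm;
phases untouched, since a set-up error moves the tumor, not the phase the
gating system sees), predicts at the true window on the perturbed curve,
and maps GPR against the unperturbed predictions over the whole grid — a
theoretical sensitivity with no measured image involved.

## Synthetic study conditions

The in-air PD stand-ins are a smooth open field (tanh penumbra at 5 cm
radius, mild radial droop) and a striped variant with smooth MLC-like
modulation; clinical VMAT fields cannot ship with a library. The
patient-like trace is two incommensurate sinusoids with baseline drift
and band-limited jitter, re-phased retrospectively. Sinusoidal studies
use 4 s period, 30 s traces at 30 Hz, peak-to-peak amplitudes 1–3 cm,
tumor diameters 2 and 4 cm, windows 30–70% and 40–60%. End-to-end
studies run on 256² images at 1 mm pitch (the perturbation study on 128²,
24 grid searches with shared prediction caches). What passing these
simulator-in-the-loop studies does **not** show: behaviour under real
EPID noise, scatter and detector lag, clinical MLC textures, phantom
alignment errors, or 3D tumor motion — the simulators model only the
error mechanisms listed above, so the GPRs here are upper bounds relative
to a physical rig.

## Numerical choices and degenerate inputs

Uniform sampling is enforced to 1e-9 s; phases live in [0, 100) with an
explicit wrap guard against floating `% 100` returning 100.0. Constant
traces and traces with <2 detectable peaks raise a degenerate-trace
error; empty gates raise an empty-gate error rather than returning empty
grids; a zero reference image raises a normalisation error; gamma with no
evaluable pixels is undefined rather than 0 or 1. Window membership uses
a 1e-9 closed-boundary epsilon. Portal images round-trip losslessly as
float64 TIFF (or to 1e-10 relative as text matrices) with a JSON geometry
sidecar; seeded runs are bit-reproducible.

## Known limitations

Spherical tumors only; 1D sup–inf motion; phase gating only (no amplitude
gating); transmission coefficients are configuration, not bundled
commissioning data; the recovered gating width is not a trustworthy
output, by construction of the method.
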