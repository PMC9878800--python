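# Methods

## The measurement

`revflow` quantifies voxel-wise retrograde flow in the thoracic aorta
from 4D flow CMR — time-resolved, three-directionally velocity-encoded
phase-contrast MRI. The quantity of interest is the volume of blood per
cardiac cycle that moves *toward* the aortic valve through a single
1 mm³ voxel.

Given a binary aorta segmentation and a co-registered velocity field
**v**(x, t) (mm/s), the method is:

1. **Centerline and planes.** A centerline is extracted between two
   user-supplied endpoint seeds, and a 2D orthogonal analysis plane is
   placed at every 1 mm arc-length station. Each plane's unit normal
   **n̂** is the local tangent, oriented away from the valve, so positive
   projected velocity is forward flow and negative is reverse flow.
2. **Assignment and projection.** Every segmented voxel is assigned to
   the Euclidean-nearest plane (ties to the lowest index), and its
   velocity is projected: s(t) = **v**(t) · **n̂**. The decomposition
   f = max(0, s), r = max(0, −s) splits each voxel-frame into forward
   and reverse contributions.
3. **Cardiac windowing.** Only the frames fully contained in a common
   600 ms window are used, n_inc = floor(600 / Δt) (a prospectively
   gated lowest-common-denominator across heart rates; at Δt = 36–42 ms
   this admits 14–16 frames). End systole k_es is the first inflection
   of the whole-aorta mean net-flow curve Q(t) after peak systole.
4. **Integration.** Per voxel, R(W) = Σ_{t∈W} max(0, −s(t)) · a · Δt,
   with face area a = 1 mm² on the isotropic analysis grid, converted to
   mL. Windows are systole = frames [0, k_es), diastole = [k_es, n_inc);
   the whole-cycle map is the elementwise sum of the two, making the
   partition identity exact by construction.
5. **Summaries.** Mean ± SD per segment (ascending aorta, arch,
   descending aorta, delineated by four landmark planes), sagittal
   mean-intensity projections, and a clinical-context estimate of total
   reverse flow through a circular mid-ascending-aorta ROI:
   total = π (d/2)² × mean per-voxel flow.

## Design choices where the procedure was open

* **End systole from the whole aorta, not the AAo.** An AAo-only
  net-flow curve can be distorted by exactly the systolic reverse flow
  being measured; the whole-aorta curve is the default, with the
  AAo-only variant available behind `PipelineConfig.es_from_aao` for
  comparison.
* **Discrete inflection rule.** Q is smoothed with a width-3 moving
  average; peak systole is the earliest global maximum k*. The sign of
  the centred second difference just after the peak is the reference;
  k_es is the first later frame where it flips (or first reaches zero).
  If no flip exists — e.g. strictly convex monotone decay — the first
  post-peak local minimum is used and a warning is logged. A curve
  peaking at the final frame is an error: the cycle cannot be split.
* **Boundary frame ownership.** The frame at k_es belongs to diastole
  (half-open split); nothing in the physiology dictates the owner, and
  the half-open choice guarantees an exact partition.
* **Frame inclusion.** floor(600/Δt) fully contained frames — the
  deterministic, conservative reading of "frames covering 600 ms".
* **Centerline algorithm.** Minimum-cost geometric path through
  1/(d + 0.5)² (d = Euclidean distance transform, mm), seeded at the
  valve and distal endpoints; Gaussian smoothing (σ = 2 mm) with odd
  (point-symmetric) end padding so a straight end is continued, not
  flattened; then a sub-voxel re-centring pass that pulls each station
  to the distance-weighted centroid of its perpendicular cross-section
  slab (axial shift component removed to preserve length); finally
  resampling at exactly 1 mm arc length with nominal arc-length
  parameterisation. The re-centring corrects the systematic half-voxel
  offset of an integer-grid path; on the default phantom the recovered
  arc length is within 0.5% of the analytic value.
* **Landmarks are config values.** The four segment-delineating planes
  (sinotubular junction, proximal to the first supra-aortic branch,
  distal to the left subclavian, proximal to the celiac artery) are
  arc-length positions in millimetres — the method's one manual step.
  Segments are half-open intervals [STJ, branch), [branch, subclavian),
  [subclavian, celiac], with voxels outside excluded (LVOT and abdominal
  run-off are never counted).

## Preprocessing

Phase-contrast velocities carry spatially smooth, temporally static
phase offsets (eddy currents, Maxwell terms), velocity wrapping beyond
the venc encoding limit, and background noise. The classical correction
chain is:

* **Antialiasing first**: per-voxel temporal unwrapping with period
  2·venc (`numpy.unwrap`), trusting the first frame. Exact whenever
  consecutive-frame jumps of the true velocity stay below venc; the
  number of adjusted voxels is logged so multi-wrap ambiguity is visible.
* **Static tissue**: voxels above the 0.6 quantile of time-averaged
  magnitude with temporal velocity-magnitude SD below 20 mm/s.
* **Eddy-current correction**: per component, an order-0 or order-1
  polynomial in world coordinates fit by least squares to the
  *time-averaged* velocity over static tissue, subtracted from every
  frame. Time-averaged fitting matches the static-offset physics and
  averages down noise; the correction is idempotent, and a
  rank-deficient order-1 fit (planar static tissue) falls back to
  order 0 with a warning. An injected linear offset is removed to a
  static-tissue residual below 1e−6 mm/s.
* **Noise mask**: voxels below the 0.1 magnitude quantile are excluded
  from all downstream statistics.

The thresholds (0.6 / 0.1 quantiles, 20 mm/s) are engineering defaults
exposed in the configuration, not literature constants.

## The synthetic phantom

The phantom emulates the geometry and flow regimes the method must
distinguish, not hemodynamic realism (no Navier–Stokes, turbulence,
wall motion, or k-space simulation):

* **Geometry**: straight ascending segment, semicircular arch, straight
  descending segment ("candy cane"), circular cross-section of radius R,
  default 10 mm lumen / 19 mm arch radius on a 64×64×96 grid at 1 mm —
  a thoracic aorta scaled down ~40% to keep the whole cane plus a
  static-tissue shell inside a compact volume.
* **Waveform**: raised-cosine ejection U(t) = ½·peak·(1 − cos 2πt/T)
  for t < T (default peak 800 mm/s, T = 360 ms), zero after. The
  waveform has an unambiguous analytic peak (T/2) and first post-peak
  inflection (3T/4), which defines the phantom's true end-systole frame
  as round(0.75·T/Δt).
* **Profile**: parabolic U(t)(1 − (ρ/R)²) by default, or plug; both
  have closed-form reverse-flow cross-section integrals.
* **Reverse components**: a near-wall systolic ring (subtract A for
  ρ/R ≥ ρ₀ during systolic frames — the flow-reversal pattern flanking
  a stenotic jet) and a uniform diastolic regurgitant plug (subtract B
  everywhere during diastolic frames). Amplitudes are free parameters:
  the defaults (A = 150 mm/s, ρ₀ = 0.7, frames 1–5; B = 100 mm/s,
  frames 9–14) produce per-voxel reverse-flow magnitudes in the
  0.005–0.03 mL/cycle range typical of in-vivo reports, but are not
  calibrated to any cohort.
* **Artifacts**: per-component linear phase offsets c₀+cₓx+c_yy+c_zz
  applied everywhere, i.i.d. Gaussian velocity noise, and optional venc
  wrapping ((v + venc) mod 2venc) − venc. A single integer seed drives
  all randomness; identical seeds give bit-identical output.
* **Static shell**: a hollow cylinder of high-magnitude, zero-velocity
  tissue at 2–2.4 lumen radii gives the eddy fit realistic support while
  leaving the background the dominant magnitude-histogram mode (a full
  2–3-radii shell would crowd out the background on this grid and break
  the 0.6-quantile static-tissue rule).

**Ground truth.** The analytic per-voxel mean reverse flow per segment
and window is the lumen cross-section average of max(0, −u(ρ, t)),
integrated in closed form (the substitution y = (ρ/R)² makes every
radial interval a linear integrand). It is computed on the acquisition
grid before interpolation; pipeline tolerances absorb interpolation and
discretisation error.

**Known discretisation bias.** Voxelising the disk at grid spacing h
overweights the ρ ≈ R rim where the ring's reverse velocity peaks; the
ring-driven systolic component is biased high by O(h/R) — about 2% at
R/h = 10 and 14% at R/h = 8 (verified by sub-voxel convergence against
quadrature). The whole-cycle segment mean on the default phantom stays
within 1% of the analytic value; recovery tests use 5% (straight
segments) / 10% (arch) noise-free and 15% at σ = 10 mm/s.

## What passing tests do and do not show

The phantom has piecewise-analytic velocities, a static lumen, exact
masks, and additive Gaussian noise. Passing recovery tests demonstrates
the pipeline's geometric and numerical correctness — projection,
assignment, timing, integration, artifact correction — not robustness
to segmentation error, wall motion, partial-volume effects at the
lumen boundary, late-diastolic truncation bias, or in-vivo flow
complexity (vortices and helices are not simulated; only their net
retrograde signature is).

## Numerical choices

* Core computations in float64; stored volumes float32.
* Cross-section ties in nearest-plane assignment break to the lowest
  plane index (deterministic, order-independent).
* Forward−reverse = net and the MIP conservation identity hold per term
  exactly; summed quantities are asserted at 1e−12 relative (independent
  float summation orders).
* Empty segments are reported as missing (NaN), never zero; MIP pixels
  with no contributing voxel are flagged empty, never zero.
* Bland–Altman: LOA reported as the half-width 1.96·SD(differences,
  ddof = 1); CoV = 100·SD(differences)/grand mean of all measurements,
  undefined (NaN) for a zero grand mean.

## Problem sizes

Default analyses run on the 64×64×96 × 15-frame phantom (~46k lumen
voxels); unit and property tests use a 48×48×72 phantom with an 8 mm
lumen. The acceptance script analyses one full-size phantom noise-free,
one at σ = 10 mm/s, and eight small phantoms twice each for the
interobserver simulation.
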