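# Methods

`thrombotrace` reconstructs time-corrected instantaneous 3D surfaces of a
growing thrombus from confocal z-stacks, quantifies surface growth, solves
the microchannel blood flow around the reconstructed surface, and computes
the Lagrangian shear-rate history platelets experience before adhesion.
This note records the models, the numerical choices and their rationale,
and what the synthetic phantoms do and do not establish about real data.

Conventions used throughout: x is the flow direction, y the channel width,
z the height; z = 0 is the capillary floor; geometry and imaging are in μm,
channel dimensions in mm in configuration, time in s, shear rates in s⁻¹,
viscosity in cP.

## Synthetic phantoms and simulated acquisition

A confocal microscope scans a z-stack bottom-up, one optical section at a
time.  With the imaging settings emulated here — 0.5 μm slices at
0.31 μm/pixel, a 1.2 s scan plus 2.3 s data transfer per stack (3.5 s stack
period) — a thrombus keeps growing *while* it is scanned, so each acquired
stack is time-skewed: slice k of stack m carries its own timestamp
t = m·3.5 + k·(1.2/n_slices).

The phantom module provides wall-attached implicit geometries with exact
ground truth at any instant:

* **Semi-ellipsoid** x²/a(t)² + y²/b(t)² + z²/c(t)² ≤ 1, z ≥ 0, with
  per-axis multiplicative growth laws (linear, exponential, logistic).
  Volume and cross-sections are closed-form, which makes this the oracle
  for all time-correction checks.  The 12 %-per-stack-period growth regime
  used in the validation tests is produced by equal exponential axis rates
  r = ln(1.12)/(3·3.5) s⁻¹.
* **Lobed phantom**: the same ellipsoid modulated by a smooth random
  azimuthal harmonic perturbation (seeded, reproducible), vanishing at the
  pole and the wall so the shape stays a single wall-attached component.
  The default preset measures ≈ 75 × 12 × 30 μm (L×W×H), a typical
  thrombus scale.  Its growth default in the pipeline and the validation
  fixtures is ~1 % volume per second, a realistic aggregate growth rate
  for the high-shear perfusion regime the package models.

Slices are rendered by point-sampling the indicator at pixel centres
(foreground = 75 % of the 12-bit range, background 0).  Optional seeded
Gaussian and salt-and-pepper noise exists but is off by default.  Two blank
guard slices below z = 0 emulate starting the scan below the
thrombus–floor interface.  12-bit data is stored in 16-bit TIFF containers
with a JSON sidecar carrying per-slice z and t.

What the phantoms do *not* emulate: the optical point-spread function,
spherical aberration near the floor, intensity falloff with depth, and
red-blood-cell clutter.  Tests passing on phantoms therefore establish the
correctness of the geometry processing chain, not the robustness of
segmentation to real microscope noise.

## Surface reconstruction

12-bit sections are mapped to 8-bit by a fixed linear scale with half-up
rounding (deterministic across platforms).  Segmentation thresholds each
slice at a single Otsu threshold computed over the whole stack's pooled
histogram — per-slice thresholds would flicker along z — and removes
connected components smaller than a 2 μm-diameter disk (the single-platelet
scale).  Sub-pixel boundaries are the 0.5-level contours of the binary
masks; border-touching components are closed along the border and flagged.

The binary slices are stacked with their metadata z-spacing and
iso-surfaced at level 0.5 (marching cubes).  The closing skirt that the
iso-surface grows below the bottom slice is flattened onto z = 0, capping
the surface exactly at the wall; degenerate faces are dropped and
watertightness is asserted.  On the r = 15 μm hemisphere fixture the
reconstructed volume is within 0.1 % of (2/3)πr³ at the default
0.5 μm/0.31 μm resolution.

**Ripple filter.**  Stacked binary slices produce stair-step ("ripple")
artefacts between z-slices.  The filter is iterated uniform graph-Laplacian
smoothing (λ = 0.5, 20 iterations) with the wall ring pinned to z = 0,
followed by an *exact* volume restore that rescales about the base-plane
point below the centroid (so the wall stays at z = 0).  Taubin λ|μ pairs
and z-weighted edge variants were evaluated on a constructed ripple fixture
(cylinder with alternating 10/10.6 μm slice radii) and attenuated the
ripple far less (1–2.5× vs 8× for the plain Laplacian at equal cost); since
shrinkage is removed exactly by the volume restore, the plain Laplacian's
only cost — shrinkage — is neutralised, and it brings the smooth-hemisphere
fixture *closer* to its analytic surface.  Volume change after the filter
is identically zero up to floating point, well inside the ≤ 1 % contract.

Surface metrics: volume by the signed-tetrahedron (divergence-theorem) sum;
L/W/H from the axis-aligned bounding box, L along flow.

## Time-correction by contour morphing

For each z-level, the segmented masks of consecutive stacks form a timeline
of (timestamp, shape) pairs.  Intermediate shapes are generated as the zero
level sets of linearly blended signed-distance fields (SDFs): the boundary
evolution that relaxes the time-1 contour onto the time-2 contour has
these blends as its fixed-point trajectory.  The SDF formulation is
symmetric in its endpoints, reproduces them exactly at blend parameters 0
and 1, handles topology changes (splits/merges) without special cases, and
turns appearance/disappearance of a component into inflation from /
deflation to a collapse point (the counterpart component's centroid), a
case the source imagery cannot disambiguate further.

SDFs are computed on the slice pixel grid (0.31 μm default) by the exact
Euclidean distance transform, signed negative inside.  Intermediate k of n
between acquired times t_a < t_b is timestamped t_a + k·(t_b − t_a)/(n+1);
n is chosen so the increment δ ≤ 60 ms by default.  An instantaneous stack
at a requested t* — which must lie inside the correctable window between
the end of the first stack's acquisition and the start of the last
stack's — selects, per z-level, the acquired-or-intermediate frame nearest
t*; the realized time spread ΔT_sample_span is reported and is ≤ 2δ by
construction.  The instantaneous stack then goes through the same
iso-surfacing and ripple filtering as a directly acquired stack.

On the 12 %-growth semi-ellipsoid the corrected volume lands within 0.5 %
of ground truth (2 % asserted), while the uncorrected direct stack shows
the characteristic skew signature — cross-sections smaller than truth near
the floor (scanned too early) and larger near the top (scanned too late) —
even though its *total* volume error largely cancels.  Morphing the outer
stacks of a growing lobed phantom to the middle stack's timepoint deviates
from the directly reconstructed middle stack by ≈ 0.3–0.4 % in volume
(1.9 % asserted).

## Growth mapping

Growth between surfaces at t₁ < t₂ is measured per vertex of the t₁
surface by casting rays along ± the outward vertex normal (area-weighted
face average) and taking the nearest intersection with the t₂ surface:
outward hits are positive (adhesion/aggregation), inward hits negative
(consolidation or embolism — geometrically indistinguishable, so not
separated).  When both directions hit, the smaller distance wins with its
sign: it reports the nearest change and avoids double counting on folded
geometry.  Rays are truncated at 20 μm (the order of inter-thrombus
spacing) so they cannot register hits on unrelated thrombi; misses are
flagged invalid, never zero-filled.  Ray casting is an in-package
Möller–Trumbore intersector with a KD-tree broad phase, chunked to bound
memory on dense meshes.

Classification uses a ±0.5 μm neutral band (a quarter platelet diameter)
by default; the band is configurable since the underlying measurement
noise scale depends on the imaging.  Summary statistics integrate
distance × lumped vertex area, with the areas evaluated on the half-offset
surface (vertices moved d/2 along their normals) — this makes the swept
volume second-order accurate on curved surfaces (−0.6 % vs the analytic
concentric-shell volume, against −10 % for the flat first-order estimate).
Vertex areas are barycentric (one third of each incident face), the
standard lumped approximation.  The exact watertight volume difference is
always reported next to the estimate as a cross-check.

## Channel flow

The perfusion channel is a 2 × 0.2 mm rectangular glass capillary run at
1.44 ml/min with blood treated as incompressible and Newtonian at 2.8 cP.
Derived characteristics: nominal (parallel-plate) wall shear
γ_w = 6Q/(wh²) = 1800 s⁻¹, hydraulic diameter 2wh/(w+h) = 0.36 mm, aspect
ratio h/w = 0.1.  The Reynolds number ρ·U_mean·D_h/μ requires a density
the user must supply (≈ 7.8 at ρ = 1000 kg/m³).

**Analytic solution.**  The fully developed rectangular-duct profile is the
standard Fourier series, normalized through the closed-form flow-rate
expression so the cross-sectional integral equals Q; cosh ratios are
computed in log space to avoid overflow at high width/height ratios, and
the series is truncated at a 10⁻⁸ relative envelope.  The wall shear
du/dz|₀ is the termwise derivative.

**Solver.**  Steady Navier–Stokes on a staggered (MAC) grid, marched to
steady state with incremental pressure-correction pseudo-timestepping:
implicit backward-Euler diffusion (pre-assembled sparse Helmholtz systems
solved by Jacobi-preconditioned CG — they are strongly diagonally
dominant), explicit first-order upwind advection (CFL-limited step), and an
exact projection each step through a pressure-Poisson solve by a direct
sparse factorisation computed once and reused.  The incremental form
(predictor includes ∇p) makes the converged state satisfy the discrete
steady equations independent of the pseudo-step size.  This is the same
pressure–velocity-coupling family as SIMPLE and converges to the identical
discrete steady state; the pseudo-transient variant was chosen because it
vectorises cleanly and its per-step cost is dominated by one pre-factorised
Poisson solve.

Boundary conditions: the inlet imposes the analytic developed profile
directly (discretely rescaled to carry exactly Q), which replaces an
explicit entrance region at an identical end state; the outlet holds a
fixed pressure; all walls and the obstacle are no-slip.  The obstacle — any
watertight reconstructed surface — is voxelized first-order by a
cell-centre inside test; all faces adjacent to solid cells are pinned to
zero and insulated in the pressure equation, so the projection is exact in
the fluid.  The convergence criterion is the normalized steady-state
residual (maximum velocity change per step, scaled by the advective time);
default tolerance 10⁻⁸ at desk scale.

Desk-scale grids used in the tests: 8 × 64 × 32 cells over a 400 μm-long
section of the full 2 mm-wide channel for the empty-channel validation
(centreline within 0.3 %, mid-width floor shear within 2 %, flux exact to
round-off, discrete divergence at machine precision, monotone error decay
under refinement), and 48 × 30 × 24 cells over a 400 × 240 × 200 μm
subsection for obstacle runs (flow rate chosen so γ_w = 1800 s⁻¹).  These
replace production-scale body-fitted meshes; the first-order staircase
obstacle limits near-surface shear accuracy to qualitative fidelity, which
is sufficient for the crown-elevation behaviour (γ_local above a 30 μm
thrombus exceeds γ_w by ≈ 2×) but not for quantitative surface-shear values
on real geometries.

**Shear rate.**  γ_local = √(2 D:D) with the rate-of-strain tensor
D = ½(∇U + (∇U)ᵀ) — the standard rheological convention, which returns the
imposed rate in simple shear and zero in rigid rotation, and is the
convention under which the channel's nominal wall value is 1800 s⁻¹.
Gradients are central in the interior and wall-aware at boundaries (the
extended difference stencil includes the no-slip wall value); the dedicated
floor-wall-shear extraction fits the quadratic through the wall and the
first two cell centres, exact for the parabolic near-wall profile.

## Lagrangian pathlines

Platelets are treated as massless tracers (steady flow ⇒ pathlines =
streamlines); finite size and inertial lift are not modelled.  Seeds sit
1 μm above the surface — the platelet-centre height at contact, which also
avoids the no-slip surface where trajectories degenerate; seeds landing
inside the voxelized obstacle, inside the mesh (concave folds) or outside
the channel are dropped and flagged.  The thrombus interaction region
(TIR) is 10 % of the thrombus length, measured upstream.

Backward integration of dX/dt = −U(X) uses an embedded Dormand–Prince
Runge–Kutta pair (4th order with 5th-order error estimate, FSAL) with
per-step error control at rtol 10⁻¹¹ / atol 10⁻⁹ μm; velocity is trilinear
over cell-centred values extended with explicit wall and inlet planes.
Termination: the inlet or a configured upstream plane (landed on by
step-size bisection), leaving the domain, a 30 s time cap, or stagnation
(|U| < 10⁻⁹ m/s, returned as a flagged pathline rather than an error —
paths that asymptote onto the no-slip floor have no finite-time upstream
history).  The tolerances were chosen so the accumulated spatial error
stays below 0.001 μm *after* amplification through near-obstacle shear;
this is validated by backward-then-forward retrace closure (measured
≈ 2×10⁻⁵ μm maximum over 100 seeds) and by the exact transverse invariance
of pathlines in the unidirectional analytic duct.

γ_local is sampled at every accepted step.  Summaries per pathline: γ at
adhesion (the seed sample), the peak over the window, and the time-weighted
(trapezoidal) mean over the final 3 s before adhesion (window truncated for
shorter paths; a TIR-bounded average can be formed by passing the TIR
extent as the window via the library).  Whether the mean should be
time-weighted or arc-length-weighted is underdetermined by the source
methodology; time-weighting is the default because the platelet's exposure
history is a time integral.  Summaries are projected onto the surface as
per-vertex channels next to the growth channel; missing pathlines stay NaN
and flagged.

## Pipeline, I/O and determinism

The pipeline chains phantom → reconstruct → timecorrect → growth → flow →
trace at demo scale, writing every stage's artifacts plus a manifest with
checksums; identical config + seed reproduce identical outputs.  Stacks are
multi-page TIFF + JSON; surfaces binary PLY (per-vertex float scalars as
named properties) or STL (geometry only, with a warning); fields legacy
ASCII VTK structured points readable by ParaView.  The VTK writer/reader
pair lives in-package; only files it wrote are read back.

All randomness (lobe shapes, optional noise, seed subsampling) flows from
explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* Segmentation is a single global threshold; real confocal data with depth-
  dependent intensity would need per-depth normalisation before it.
* The voxel (staircase) obstacle is first-order: near-surface shear on the
  obstacle is qualitatively right but grid-sensitive; production use would
  substitute a body-fitted solver behind the same `FlowField` interface.
* Growth cannot distinguish embolism from retraction, and attributes all
  volume change to the surface displacement along normals.
* Time-correction interpolates shape linearly in SDF space between stacks
  3.5 s apart; strongly non-monotone growth within one stack period is
  averaged through.
* The morphing handles growth only; advection (translation) of a thrombus
  between stacks is interpolated as shape change, not motion.
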