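# Methods

This note records the models, measurement operators, parameter choices, and
known limitations behind `liqchan`.

## Channel physics

The liquid-walled channel is treated as an aqueous strip of pinned width
*w* under an immiscible oil overlay.  The package models the interface
cross-section as a **circular arc** through the pinned contact lines at
x = ±w/2 with apex height *h*.  The arc is the constant-mean-curvature shape
of an interface at uniform pressure pinned at fixed edges, and it makes the
Law-of-Laplace treatment self-consistent; the radius is R = h/2 + w²/(8h)
(the circumcircle of the two pinned points and the apex).  Pressures follow
P = γ(1/R_xz + 1/R_yz), evaluated at the media-oil interface and documented
throughout as an *approximation* of the pressure confining cells beneath it.
No 3-D free-energy minimization, contact-line dynamics, or oil hydrodynamics
are attempted.

Units are fixed package-wide: lengths µm, tensions mN/m, pressures Pa,
migration speeds µm/min, protrusion speeds µm/s.  The single conversion
(1 mN/m ÷ 1 µm = 1000 Pa) lives in `geometry_model.laplace_pressure`.  An
infinite radius is representable (`math.inf`) and contributes exactly zero
curvature; the undeformed channel uses R_yz = ∞, which also resolves the
open question of whether an entrance-taper curvature should enter baseline
pressures (it does not, away from cells).

Key defaults: γ_OM = 41.8 mN/m (water vs. 5 cSt silicone oil), channel
widths 30–200 µm, channel length 300 µm, baseline apex heights 1–10 µm.

## Synthetic scenes

The generator exists to test the measurement pipeline, not to model cell
mechanics; every scene is a pure function of its configuration (seed
included — identical inputs are byte-identical), and all ground-truth
quantities are computed from the generation parameters in closed form,
never re-measured from pixels.

* **Z-stacks.**  Two intensity levels (media 1000, oil 100), interface at
  the analytic arc whose apex profile along the channel axis is the
  baseline height plus one Gaussian bump per cell (amplitude
  h_cell − h₀, σ = the cell's y semi-axis).  The bump is Gaussian because
  the deformation shape is not otherwise constrained; its 1–10 µm amplitude
  range matches the channel height scale.  Optics are an isotropic Gaussian
  PSF (σ = 0.3 µm default) plus additive Gaussian noise (σ = 5% of the
  media-oil contrast by default); Poisson noise adds nothing the tests
  need.  Axial step 0.2 µm, matching 200 nm confocal z-stacks.
* **Migration timelapses** (30 s frames).  The cell whose front has reached
  the furthest interface position holds the *pioneer* role and moves at
  `speed × slowdown_factor` (default 0.35 — a phenomenological factor; the
  generator's job is to test the role classifier and speed estimator, not
  to derive the slowdown).  Trailing cells move at full speed through the
  pre-deformed conduit and queue without overlap.  When a trailing cell
  makes contact (gap ≤ sum of y semi-axes by default), the pioneer yields —
  sidesteps laterally and arrests — and the catcher becomes pioneer once
  its own front reaches the interface, then slows.  The transition frame is
  recorded in ground truth and agrees with the closed-form catch-up time.
* **Protrusion movies** (≤ 1 s frames).  Blebs are near-circular lobes
  (a disc of diameter e centered e/2 outside the boundary) that reach
  maximal extension within ≤ 2 frames and retract within < 10 s lifespans;
  pseudopods are wide sheets (tangential semi-axis 1.8 × max extent, aspect
  ≈ 4:1, circularity ≈ 0.5) growing over tens of seconds.  Movies
  containing blebs require frame intervals ≤ 1 s.
* **Tissue scenes** (10 s frames).  A square tessellation of surrounding-
  cell boundaries; boundary points inside the migrating cell's footprint
  are pushed radially to its edge (so the maximal displacement equals the
  cell radius when the path crosses a boundary), then relax exponentially.
  The recovery time constant is exposed as a parameter (default 30 s); no
  value is claimed for it from experiments.

`mixture_concentration` does the protocol bookkeeping in exact rational
arithmetic before rounding (10 mg/mL collagen at 1:1:1 → 3.33 mg/mL;
80,000 cells/µL → 26,667 µL⁻¹).

## Interface height maps

Heights are measured per (x, y) column of the z-stack on the falling
(media→oil) edge at **half maximum**, with sub-voxel linear interpolation.
Numerical choices that matter:

* a 3×3×3 median prefilter (denoises without blurring the edge; lateral
  bias is negligible because the interface is smooth on the voxel scale);
* the half-max level is taken between the median of the bottom (known-
  media) voxels and the per-column oil background, floored by the global
  oil level so a noisy background estimate cannot collapse the threshold;
* the crossing is located scanning from the top, where oil noise cannot
  reach the level — scanning upward from the peak is biased low under
  noise (first-dip effect);
* columns are masked unless their bottom five voxels sit at media level
  and their peak reaches ≥ 60% of the global media brightness: sub-voxel
  contact-line films at the strip edges are optically unresolvable and are
  excluded rather than reported wrong.  Masking is monotone in the
  background factor k (default 3).  A final 3×3 neighbor-median consistency
  check drops isolated outlier columns.

On synthetic scenes this keeps every unmasked column within one axial voxel
of truth without noise and within two voxels at noise σ = 10% of contrast.

## Curvature and pressure profiles

The original measurement drew circles by hand over interface images; here
`fit_circle` uses an algebraic (Kåsa) solve of the linearized circle
equation followed by geometric Gauss–Newton refinement, reporting the RMS
orthogonal residual so fits can be audited.  Points collinear within
tolerance (smallest principal component ≤ 1e-7 of the spread) return a
flagged-infinite radius — a flat interface is a valid measurement, not an
error.  Curvature sign: interfaces bulging toward the oil (convex up,
confining) are positive; both radii enter the Laplace sum as magnitudes.

`pressure_profile_along_cell` samples stations along the cell's migration
axis: R_xz from the pinned arc with the locally measured apex height, R_yz
from a circle fit to the centerline yz profile over a window defaulting to
the cell length (the per-region hand-drawn circle, automated; the apex cap
rather than the concave flank is fitted).  Front and rear summary pressures
are evaluated at the centers of the leading and trailing 20% bands of the
cell mask — the same quantile convention the deformation metrics use.
Curvatures below 1e-4 µm⁻¹ (R > 1 cm) count as flat.

## Kinematics

Segmentation is Otsu thresholding, hole filling, and a distance-transform
watershed for touching cells, with a 20–400 µm² area gate.  Linking is
greedy nearest-neighbor with **constant-velocity prediction** (a track's
next position is extrapolated from its last step), a max-step gate
(default 15 µm/frame), and one-frame gap closing; prediction is what keeps
identities straight when a trailing cell overtakes a yielded pioneer.
Roles: per frame the pioneer is the foremost cell along the channel axis
among cells still advancing; a cell whose local (3-frame) forward speed
falls below 2 µm/min has arrested and no longer deforms the interface, so
it is not a pioneer even if still foremost.  Transition analysis reports
mean speeds over the maximal trailing and pioneer segments, excluding the
steps spanning the transition frame.

## Protrusions

Events are defined on segmented masks (so brightfield and reporter movies
share a code path).  New area between consecutive frames seeds candidate
events; a candidate is confirmed once its accumulated region reaches 1 µm²
*and* extends ≥ 1 µm beyond the pre-event boundary (the extent requirement
rejects segmentation-jitter arcs that hug the cell outline; the
accumulation catches slow sheets whose per-frame increment is small).
Candidates that fail to confirm within 15 s are discarded.  An event's
region is tracked by connected-component overlap against its onset
baseline until it regresses; radial extension is the Euclidean distance
beyond the baseline boundary.

Classification: **bleb** iff circularity (4πA/P², Crofton perimeter)
≥ 0.7 *and* lifespan < 10 s *and* time-to-max-extent ≤ 2 s; otherwise
pseudopod.  The ≤ 2 s bound operationalizes "rapid": kinetic descriptions
of blebs give an expansion-speed scale of a few µm/s and lifespans under
ten seconds, but a speed bound alone does not separate the classes cleanly,
so the rapid-rounded-short-lived signature is used and every threshold is
configurable.  The circularity
threshold is inclusive (a tie is a bleb).  Bleb rate is classified blebs
per minute of observation.

## Statistics

Two-condition comparisons are Student's t tests (paired or unpaired,
pooled variance by default, matching the experimental convention); three or
more groups get one-way ANOVA with Tukey HSD on all pairs via
`scipy.stats.tukey_hsd`.  The unadjusted pairwise p reported alongside
Tukey uses the same pooled within-group error (Fisher LSD), so the
adjusted ≥ unadjusted invariant holds by construction.  Tests run on the
displayed points (cells/channels); replicate-mean aggregation (donors,
clutches) is available via `aggregate_replicates`.  Identical inputs give
F = 0, p = 1 rather than NaN.

## What the synthetic tests do and do not show

The generators share the pipeline's geometric model of the interface (an
arc with Gaussian bumps) and an idealized two-level intensity model, so the
round-trip tests validate the *measurement operators* — edge localization,
circle fitting, unit handling, tracking, event classification — under
controlled blur and noise.  They do not probe real-data failure modes:
non-Gaussian optics, uneven dye distribution, photobleaching, cells
touching the coverslip, segmentation of irregular cell shapes, or
deviations of the true interface from a circular arc.  Problem sizes in the
tests and the acceptance script (60–70 µm fields, 16-frame timelapses,
10-event movies, 500-rep Monte Carlo, 1000-rep null simulations) were
chosen as the smallest scenes that exercise each estimator's tolerances.

## Known limitations

* The interface model is quasi-static; dynamic (viscous) contributions to
  the confining stress are not modeled.
* Pioneer identification assumes a single channel and migration along +y;
  multi-lane or reversing scenes need the role rules revisited.
* Protrusion circularity on coarse pixel grids (< ~4 px event radius) is
  noisy; the defaults assume ≤ 0.25 µm pixels for protrusion movies.
* `pre_post_passage` assumes the provided height maps are index-aligned
  with the sorted frames of the track table.
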