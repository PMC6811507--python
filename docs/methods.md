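# Methods

## Scope and model

`cvrflow` implements the quantitative core of a 4D flow MRI cerebrovascular
reactivity (CVR) analysis: from three-directional velocity-encoded volumes
to per-vessel blood flow (mL/min) and cross-sectional area (CSA, cm²),
cerebrovascular conductance (CVC = flow/MAP × 100), and CVR as the OLS slope
of CVC against end-tidal CO2 across hypercapnic conditions. All stages are
exercised on a synthetic flow phantom with analytic ground truth; no real
MRI data are required or bundled.

Coordinate convention, used everywhere: arrays are indexed (x, y, z) with
0-based voxel indices, voxel-center alignment, world position =
index × voxel_size (cm), right-handed axes. Cardiac phases occupy an
explicit trailing axis (singleton for steady flow).

## The phantom

Vessels are tubes around polyline centerlines carrying steady laminar
(Poiseuille) flow: axial velocity v(r) = 2·v̄·(1 − (r/R)²), so that the
volumetric flow is exactly Q = v̄·πR²·60 mL/min and CSA = πR². Each voxel is
supersampled 4× per axis and box-averaged, which reproduces the
partial-volume behavior of a reconstructed scan. Box-averaging a parabola
biases each interior voxel by (h²/24)·|∇²v| = (v̄/3)(h/R)²; at 8 voxels per
diameter that is ~2% of v̄ pointwise, but it redistributes rather than
destroys flux, which is why the flux integrator (below) works on a slightly
dilated domain.

Phase-contrast encoding maps velocity to phase φ = π·v/venc wrapped to
[−π, π), stored as a complex signal M·e^{iφ} per velocity axis. Decoding
returns venc·φ/π, so |v| > venc aliases exactly as in a scanner. Noise is
independent complex Gaussian per encoding with σ = 1/SNR relative to the
in-vessel magnitude (1.0); to first order the decoded-velocity noise is
venc/(π·SNR·A) per axis for a voxel of magnitude A. Background (eddy-
current-like) phase is a per-axis constant + linear field in world
coordinates, applied at encoding time. Radial k-space acquisition and
regridding are deliberately not simulated: the analysis consumes
reconstructed image-space volumes, so the phantom produces them directly.

### Study conditions

The default hypercapnia study uses the young-adult physiology of the study
protocol this package models: ETCO2 = 40/47/49 mmHg and MAP = 94/93/96 mmHg
for normocapnia / 4% CO2 / 6% CO2, venc = 80 cm/s, and an MCA caliber of
CSA = 0.069 cm² (R = 0.148 cm) dilating by 4.35% in CSA (0.069 → 0.072 cm²)
at the top condition. ICA and BA radii (0.23 and 0.16 cm) and baseline
flows (240/240/150 mL/min ICAs/BA, 120 mL/min per MCA, global 630 mL/min)
are typical young-adult values chosen once; per-vessel CVR slopes default
to 9/9/7 (ICA_L/ICA_R/BA) and 3.5 (each MCA), making the programmed global
slope 25 CVC-units/mmHg, a mid-physiological-range value. Per-vessel flow
at each condition is set so that true CVC lies *exactly* on the programmed
line — the truth ledger is analytic, not simulated. Tubes are tilted a few
degrees off the grid axes; a perfectly axis-aligned tube puts the entire
wall at one sub-voxel offset and makes any voxelized area estimate jump in
whole-shell increments, which no real vessel ever does.

The desk-scale grid is 56³ voxels of 0.0375 cm (≈8 voxels across the MCA
diameter, the regime the accuracy claims are stated for). The acceptance
runs use 20 noise seeds at SNR 20 and 2000-replicate null simulations for
the statistics calibration; these sizes make every Monte-Carlo band at
least 3 binomial standard deviations wide.

### What the phantom does not emulate

Pulsatile waveforms (a sinusoidal modulation over cardiac phases is
available but defaults off — the analysis is time-averaged), vessel wall
motion, curvature-induced secondary flow, turbulence, k-space artifacts,
coil sensitivities, and anatomy (vessels are abstract tubes; labeling is by
seed points, not atlas). Passing tests therefore demonstrate correctness of
the measurement chain under the stated flow model, not robustness to every
in-vivo confound.

## Preprocessing

**Unwrapping.** Aliasing produces ~2·venc jumps between neighbors. Each
velocity component is partitioned into maximal face-connected regions whose
internal differences stay within venc; starting from the largest region,
every other region is shifted by k·2·venc (k ∈ {−1,0,1}, single wrap) to
match its already-anchored neighbors across the jump boundaries. This
handles both isolated aliased voxels and extended aliased cores (where any
voxel-local detector fails, because the core's entire neighborhood is
aliased), is deterministic, non-iterative, and idempotent. Single-wrap
correction assumes |v| < 3·venc — safe for intracranial flow at
venc = 80 cm/s.

**Static-tissue selection.** Voxels with magnitude at or above a percentile
(default 25th) and speed below 5% of venc, where speed is measured after
subtracting the per-axis global median velocity. The median subtraction
makes the selection invariant to the background offset the mask is used to
estimate; without it, a moderate offset (≳0.15 rad) disqualifies every
static voxel.

**Background correction.** Per axis, a first-order polynomial (constant +
three linear terms; order configurable to 2) is least-squares fitted to
static-tissue velocities on the cardiac-phase average and subtracted from
all phases. Rank deficiency (degenerate masks) is an error, not a warning.

## Segmentation and centerlines

The PC-MRA angiogram is magnitude × |v| averaged over cardiac phases. A
single global Otsu cut on a Poiseuille-profile angiogram removes the
slow-flow rim (intensity → 0 at the wall) and underestimates CSA by tens of
percent, so the default is **hysteresis segmentation**: Otsu-level seeds,
each grown down to a vessel-referenced low threshold, max(0.06 × the
component's 99th-percentile intensity, 3 × the median background
intensity). The 0.06 fraction balances the parabolic-profile area deficit
against the outward partial-volume smear at ~8 voxels/diameter; the noise
floor guard prevents the grown region from percolating through noise at
low SNR. Plain Otsu, fixed, and percentile thresholds remain available.
Components below 27 voxels are removed and internal holes filled.

Centerlines are **minimum-cost paths through the distance-transform
ridge**: within each connected component the main path joins the two
geodesically farthest voxels, with edge costs divided by the squared
Euclidean distance transform so the path rides the lumen center; side
branches are back-traced from any voxel farther than max(4 voxels, 1.6 ×
the component's maximal radius) from the current centerline. This yields
ordered, spur-free paths with junction and endpoint flags by construction.
Path ends whose distance-transform value collapses below 0.8 × the path
median are trimmed: they sit inside a blind end of the mask (a phantom tube
cap), where the centerline bends toward the cap surface. Tangents come from
a smoothing spline fitted per path with a residual budget of half a voxel
per node (voxel staircases misrepresent local direction); local radius is
the distance-transform value at the node.

Labeling assigns each seeded vessel the junction-free path nearest its seed
point. Measurement nodes exclude: nodes within 3 nodes of an endpoint and
within 2 nodes of a junction (counts, not distances: "within m" covers
distances 0..m−1), plus any node closer to a junction (world distance) than
the sum of the two local radii — the junction blob, where planes are not
perpendicular tube slices.

## Quantification

At each measurement node a square plane (side 4 × local radius, pixel
half a voxel) perpendicular to the tangent is sampled by trilinear
interpolation. Lumen pixels are interpolated-mask ≥ 0.5, restricted to the
in-plane connected component containing the plane center (so a plane
slicing a neighboring vessel ignores it). CSA = lumen pixel count × pixel
area. Flux integrates v·n̂ over the lumen dilated by 2 pixels (1 voxel):
box-averaging smears part of the near-wall flux just outside the lumen
contour, and flux — unlike area — is conserved under that smearing.
Sections whose plane leaves the grid, has no lumen, or whose lumen
approaches another labeled vessel's centerline are skipped. The vessel
value is the unweighted mean over surviving sections (the along-vessel
average; length weighting would differ only for strongly curved paths).
Flux sign follows the node ordering away from the seeded end. Global flow
is ICA_L + ICA_R + BA.

Measured accuracy on noise-free phantoms at ≥8 voxels/diameter: flow within
~0.5%, CSA within ~3.5%, junction mass conservation within ~1%; the tests
assert the looser 3%/5%/5% envelopes.

## CVR statistics

CVC and CVR are computed exactly as defined above. The default fit uses all
three conditions (`all_conditions`); `hypercapnic_only` drops the
normocapnic baseline and, with two points, reduces to the difference
quotient. Both are exposed because either convention is defensible for a
three-condition protocol; the choice is logged in every output. CVC units
are kept as (mL/min/mmHg)×100 with no re-expression. MCA CSA change uses
the mean of left and right MCA between normocapnia and the top condition.

The group-statistics battery: one-way ANOVA and the split-plot
(group × repeated condition) ANOVA are implemented directly from the
classical sums of squares (they run thousands of times in calibration
loops); the two-way age × sex ANOVA delegates to statsmodels OLS with
Type-III sums of squares and sum-to-zero contrasts, which also covers
mildly unbalanced layouts. Holm–Šidák follows the step-down formula
1 − (1−p)^(m−k+1) with a running maximum for monotonicity. The unpaired t
pools variances by default so the F = t² identity with one-way ANOVA holds
exactly; Welch is a flag. Brown–Forsythe is the median-centered Levene
test. **No sphericity correction** is applied in the mixed ANOVA — a known
limitation, documented rather than silently added. Shapiro–Wilk normality
testing is out of scope.

## Numerical choices and degenerate inputs

- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning; identical seeds give byte-identical outputs.
- Empty masks, rank-deficient background fits, seeds matching no node, two
  seeds resolving to one path, missing feeding vessels, zero-variance
  paired differences, and undefined F statistics all raise `ValueError`
  with the offending name in the message.
- Velocity volumes validate shape agreement and finiteness on construction.
- The overlap check in the phantom allows vessels sharing a centerline
  endpoint (a junction) to overlap within 2 × the combined radii of that
  point and rejects any other overlap; at a junction a voxel belongs to
  whichever tube carries more flux through it.

## Known limitations

- Single-wrap unwrapping only; |v| ≥ 3·venc would need multi-wrap logic.
- CSA rests on voxel-level segmentation; sub-voxel caliber changes are
  detected statistically (averaging many sections of tilted vessels), so
  per-section CSA is quantized even though vessel-mean CSA is not.
- The mixed ANOVA uses cell-mean formulas appropriate for balanced or
  mildly unbalanced groups with complete within-subject data.
- Vessel labeling requires operator seed points; there is no atlas.
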