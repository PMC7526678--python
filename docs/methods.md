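# Methods

## Grid and world conventions

All stages share one raster convention: voxel index (i, j, k) maps to
world position `origin + index · spacing` (mm); intensities and
displacement samples live at voxel **centers**; hexahedral mesh nodes
live on the **corner** lattice offset by −spacing/2, so each element is
exactly its voxel's box and the element centroid coincides with the
voxel center where the displacement sample natively lives. Array axes
are (sagittal, coronal, axial); the axial (load) direction is z.
NIfTI headers carrying rotations or shears are rejected rather than
silently reinterpreted — the geometry throughout assumes axis-aligned
grids. Compressive normal strain is negative everywhere; reports keep
signed values.

## Phantom generator

The generator emulates the study inputs the pipeline was designed for:
a C-shaped wedge of fibrocartilage (annular sector in plan, height
tapering linearly from 8 mm at the outer rim to 2 mm at the inner
edge — the wedge that converts axial compression into hoop tension),
rasterized at 96 × 96 × 24 voxels of 0.8 × 0.8 × 0.6 mm by default
(a `paper_resolution` constructor gives the 0.4 × 0.4 × 0.6 mm
acquisition spacing). Root attachments are short angular extensions at
the C's open ends. Default radii 15–30 mm and a 280° body span give a
realistic plan-view footprint for a human meniscus.

Intensities are a smooth multi-frequency texture (~100 a.u.) inside the
tissue over a darker (~40 a.u.) but **also textured** background.
Background texture matters: in the knee the meniscus deforms together
with its neighbors, and an intensity-driven registration needs
gradients on both sides of the tissue boundary to resolve boundary
displacement; a flat background leaves the field unconstrained exactly
where surface strain is evaluated. Noise is Rician (magnitude MRI),
sd configurable, 0 in validation runs.

Ground-truth deformations are analytic (affine, uniform or confined
axial compression, radial, rigid, Gaussian bump, per-angle wedge
profile, composites). `confined_axial` — a ramp through the tissue
slab with a plateau above and zero below — is the physically motivated
compression mode: the femoral side rides down on the compressed tissue
rather than the whole space shearing indefinitely. Loaded images are
produced by backward warping (fixed-point preimage iteration, trilinear
sampling), so warp and field are exactly consistent.

The cohort generator draws characteristic strains per specimen × side ×
load × region × zone × direction from normal distributions. Group
means at 100 % BW default to the published pattern (axial −3.1/−7.3 %,
circumferential +0.35/+0.45 %, radial +0.37/+0.41 % for mild/severe);
means scale linearly with load fraction (a monotone load response with
no published functional form), and the 60/40 medial/lateral load split
scales each side about the mean so the pooled mean is preserved. Group
standard deviations are not published; the defaults (3.0 % axial, 0.5 %
otherwise) make the 12 + 12 design detect the axial contrast with
power comparable to the original post hoc estimate (~82 %) while
leaving the small tensile differences usually undetected — the
generator encodes the study's qualitative pattern, not its raw data.
Configured means are treated as per-region specimen-level means; the
region-level characteristic value of a zone-split region is the mean of
its two zone draws. All draws are reproducible from (spec, seed).

What passing tests on the phantom do **not** show: performance on real
knee MRI with partial-volume effects, intensity inhomogeneity,
surrounding bone/cartilage anatomy, or segmentation error. The phantom
isolates the computational chain, not the imaging physics.

## Registration

Rigid: 6-parameter (three Euler angles about the grid axes at the
volume center, three translations), multi-resolution Powell ascent on
global normalized cross-correlation against either the binary tibia
mask or the unloaded intensities within a dilated mask neighborhood
(config switch; the protocol's own choice between the two is unknown).

Non-rigid: greedy demons-type multi-resolution scheme (factor-2
pyramid) with the local-CC force
`∂CC²/∂m ∝ 2A/(BC) (f_c − (A/C) m_c) ∇m` computed from window sums
over the metric window (radius 2). Updates are scaled so a typical
strong force (95th percentile) moves `step_size` = 0.25 voxels, capped
per voxel at that step, Gaussian-smoothed with σ = 3 voxels, and
composed into the accumulated field. Iteration stops at the level cap
(1000/500/250/100 coarse→fine) or when the relative change of the
energy (1 − mean CC over informative voxels) drops below 1e-6. The
returned field maps unloaded positions to loaded positions, so strains
derived from it are material strains relative to the unloaded state.
No randomness anywhere: identical inputs give identical fields.

Design choice on regularization: the stated σ = 3 is applied to the
**update** field only (fluid-like, the Gauss[3,0] convention); an
optional total-field σ exists but defaults to 0. Smoothing the
accumulated field every iteration acts as repeated diffusion and
measurably dilutes strain gradients across the meniscus's thin axial
extent (a few voxels to ~13); with update-only smoothing, confined
compression up to 7.3 % is recovered to ≤ 0.5 percentage points in
every regional median at the default phantom resolution.

Known limitation: strain recovery needs several voxels across the
compressed slab. On coarse grids (slab ≤ 8 voxels, e.g. the 54 × 54 ×
14 unit-test fixture) the σ = 3 regularization under-resolves the
gradient even when endpoint errors are small; registration-based strain
checks therefore run at the full 96 × 96 × 24 phantom scale, which one
CPU handles in ~15–20 s per registration.

## Strain kinematics

The displacement gradient of the trilinear interpolant is evaluated at
the element centroid; on rectangular elements this reduces to averaged
corner differences per axis and equals the mean of the 2 × 2 × 2 Gauss
values, is exact for affine fields, and superconvergent (second order,
error ratio → 4 under halving) for smooth fields. Default measure is
infinitesimal strain — observed strains stay below ~10 % — with
Green–Lagrange available to quantify the γ²/2 rigid-rotation artifact.
Cylindrical components are quadratic forms εᵀ·e with the frame's unit
vectors at the centroid; elements on the cylinder axis (r ≈ 0) are
flagged and excluded from directional projection. No smoothing or nodal
averaging of strains precedes the median: medians are robust to
element-level noise, and voxel-sized elements make the unweighted
median equal to the volume-weighted one.

## Geometry and regions

The cylindrical origin comes from an algebraic (Kåsa) least-squares
circle fit — exact on noise-free circles — to outer-rim points supplied
manually (replicating the interactive protocol) or auto-extracted as
the outermost element centroid per angular bin. Region membership is
decided by element **centroid** angle/radius. The body arc between the
two separation lines is measured in the orientation containing the
majority of body elements (removing the wraparound ambiguity an
interactive workflow never faces) and trisected into equal angular
sectors; AH adjoins the anterior attachment. The inner/outer split uses
the **local** radial width per angular bin (default 5°; 360° recovers a
global-width variant), with the boundary at a 2/3 inner fraction; a bin
holding a single radial layer counts as inner entirely. Attachments are
never zone-split.

## Statistics

Rank tests use exact enumeration p-values whenever group sizes are at
or below `exact_threshold` (default 12) and the data are tie-free,
otherwise normal/χ² approximations with mid-ranks and tie correction.
Fully tied Mann-Whitney inputs return p = 1 (the degenerate sd → 0
cohort). "Linear Bonferroni" correction is implemented as Holm's
step-down procedure (plain Bonferroni by config) and applied within
each post hoc family — the Wilcoxon follow-ups of a significant
Friedman omnibus and the pairwise follow-ups of a significant
Kruskal-Wallis — while omnibus and single contrasts report raw
p-values; family definitions are explicit in the report so either
multiplicity reading can be reproduced. All tests are two-sided at
α = 0.05.

## Problem sizes and tolerances

Default phantom: ~25 000 elements; registration validation and the
acceptance script run at this scale (about 40 s for the full
acceptance run). Monte-Carlo calibrations use 1000 replicates for
type-I rates and 200 replicate cohorts for the power pattern. Numerical
tolerances: affine strain exactness 1e-12, circle fit 1e-9, cylindrical
projection 1e-12, field inversion residual 0.1 voxel (median), node
deduplication exact on the integer corner lattice. Tie-breaks: region
boundaries include their lower edge (ρ ≤ 2/3 is inner; centroids
exactly on a separation line belong to the body).

## Known limitations

- Registration accuracy is demonstrated on smooth synthetic warps;
  discontinuous motion (e.g. meniscal extrusion past bone) violates the
  diffeomorphic smoothness assumption.
- The rigid stage assumes substantial overlap and unambiguous tibia
  geometry; it reports, but does not recover from, low final similarity.
- The phantom's regional strain structure is piecewise-angular; real
  degeneration patterns are spatially continuous.
- Inverse material identification, loading-device mechanics, and pulse-
  sequence simulation are out of scope.
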