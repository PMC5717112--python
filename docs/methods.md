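# Methods

This note documents the models, algorithms, parameter choices and known
limitations of flow4d, in the order data flows through the pipeline.

## Synthetic phantoms

The generator emulates a 4D-flow acquisition of the ascending aorta as a
straight tube of radius R (default 10 mm) on a regular grid at
2.0 × 1.7 × 2.2 mm³ spatial and 40 ms temporal resolution (18 cardiac
phases) — the working resolution of clinical protocols. The tube spans the
full z extent by default (no end caps, so axial gradients vanish and the
steady-flow closed forms apply exactly); `tube_length` caps it inside the
grid when a pose-determining shape is needed (cohort jitter, registration).

Flow profiles:

- **poiseuille** — v = v_max (1 − r²/R²), the analytic oracle. Wall shear
  stress 2 μ v_max/R and dissipation 2 π μ L v_max² have closed forms.
- **eccentric_jet** — a parabolic core of radius R/2 displaced by
  `jet_offset` mm with zero co-flow: a one-parameter model of the
  eccentric transvalvular jet downstream of a stented prosthesis
  (offset 0 = central, stentless-like jet). No closed-form WSS/EL.
- **womersley** — the Bessel-function solution for oscillatory tube flow
  (Womersley number α = 13, aortic scale), superposed on a steady parabolic
  component and renormalized to peak v_max. Used for time-resolved realism
  only; the steady case remains the oracle.

The temporal envelope is a half-sine over the first half of the cycle
(systole) and zero in diastole, normalized to max 1 so `v_max` is attained.

Magnitude images are binary-with-floor: 1.0 inside the lumen, 0.05 outside
(static tissue). PC-MRA and noise masking only need contrast, not MR
physics, so no signal model is simulated.

Corruption applies, in order: a per-direction eddy-current offset plane
c₀ + cₓx + c_y y + c_z z (coefficients in m/s and m/s per mm), Gaussian
velocity noise (default 0.05 m/s in cohort simulations, per direction), and
phase wrapping v → v − 2·venc·round(v/(2·venc)) into [−venc, venc). All
randomness flows from a single integer seed.

Cohorts: group A ("stented-like") draws jet offsets around the planted
offset (default effect 4 mm, subject-to-subject SD 0.5 mm) and group B
around the central setting; v_max varies with SD 0.15 m/s around 2.2 m/s.
Each subject receives a rigid pose jitter (rotation ≤ 5° about a random
axis, translation ≤ 3 mm per axis) so that registration is genuinely
exercised. Default venc is 2.5 m/s in cohort simulations (no wrapping at
2.2 m/s peaks); oracle and round-trip tests lower venc deliberately to
create wraps. Clinical protocols print venc in cm/s; all values here are
m/s.

What the phantoms do **not** emulate: curved or tapering vessels, branch
arteries, turbulence, partial-volume and intravoxel dephasing, concomitant
(Maxwell) gradient phase, and anatomically realistic magnitude contrast.
Passing tests therefore demonstrate correctness of the numerics and the
statistical machinery under controlled conditions, not clinical accuracy on
patient data.

## Pre-processing

- **Eddy currents.** Static tissue = voxels with above-floor time-averaged
  magnitude (> 0.02) and temporal velocity SD < 0.05 m/s in every
  direction. A first-order polynomial (constant + linear in x, y, z) is fit
  per direction to the static-tissue velocities of the *last* frame (late
  diastole, minimal true flow) and subtracted from all frames. With fewer
  than 100 static voxels the correction is skipped with a warning. The
  model order is a package choice; a first-order fit exactly removes the
  first-order corruption the generator applies, and only removes smooth
  background from anything else.
- **Phase unwrapping.** Per direction and frame, voxels deviating from
  their 3×3×3 neighborhood median by more than venc are shifted by the
  nearest multiple of 2·venc toward the median, iterated up to 5 times so
  wrapped clusters peel from the outside in. Idempotent on wrap-free
  fields; exact on isolated single wraps in smooth fields. Large contiguous
  wrapped regions (a whole jet core beyond venc) are not recoverable by any
  local method and remain a limitation. Laplacian-based 4D unwrapping was
  considered and rejected: the neighborhood-median scheme passes the
  round-trip property and is transparent.
- **Noise mask.** Keep voxels whose time-averaged magnitude reaches
  `floor_fraction` (default 0.1) of the 99th-percentile time-averaged
  magnitude; velocities outside are zeroed before PC-MRA formation.
- **PC-MRA.** Per frame magnitude × |v|, then the *mean* over frames (the
  mean rather than the sum keeps units independent of frame count).

## Segmentation and wall geometry

The expert manual segmentation of clinical workflows is replaced by a
deterministic surrogate: threshold the time-averaged PC-MRA at
`threshold_fraction` (default 0.2) × its 99th percentile, restrict to an
axial `keep_band` when anatomical limits are wanted, keep the largest
26-connected component, and apply one closing pass (edge-padded so closing
remains extensive at volume faces). Note a fraction of the 99th percentile
can never empty a non-degenerate volume; the empty-segmentation error
arises only from band restriction or all-zero input. Externally supplied
masks are accepted everywhere a segmentation is, so hand-drawn masks remain
usable; cohort simulations use the phantom truth mask in this role, since a
zero-co-flow jet lumen is not delineable from PC-MRA alone (exactly as a
patient's aorta is contoured manually rather than thresholded).

Wall points are seeded at inside voxels with at least one outside
6-neighbor and then projected along their normals onto the 0.5-level set of
the Gaussian-smoothed (σ = 1 voxel) mask indicator — a sub-voxel surface
estimate. This projection matters: anchoring the no-slip point at a voxel
center ~δ inside the lumen biases the WSS fit by ≈ 2δ/R (tens of percent at
clinical resolution), whereas the level-set projection reduces the
placement error to a fraction of a voxel. Outward normals are the
normalized negative gradient of the smoothed indicator; the local radius is
the maximum of the Euclidean distance transform along the inward ray (the
maximal inscribed distance — robust for curved vessels and exactly the ray
length the WSS sampling needs). Points with degenerate gradients, failed
projections, or radii under ~1.5 voxels are flagged and excluded from map
means. Per-point surface area is the marching-cubes area of the smoothed
surface divided by the point count.

## Haemodynamic quantification

Peak systole is the frame with the highest mean |v| over the segmentation
(earliest frame on ties). That frame is median-filtered (3×3×3,
per-component, reflected edges) before all four metrics.

**WSS.** Per wall point an orthonormal tangent basis completes the normal;
velocity is sampled by trilinear interpolation at inward distances R/2 and
R, the wall sample is pinned to zero, and the interpolating quadratic
through the three points per tangential component yields the wall
derivative analytically: dv/dd|₀ = (4 f(R/2) − f(R))/R. A quadratic is the
unique interpolant through three points and is exact for locally parabolic
profiles; a smoothing spline is under-determined here. The resulting vector
is μ × derivative, rotated back, with any numerical normal component
discarded (shear is tangential by definition). Points whose sample ray
leaves the mask are excluded from the scalar mean. Because the no-slip
anchor sits on the estimated surface, an error in the radius estimate does
not bias the fit for parabolic profiles.

**EL.** Gradients by central differences inside the mask, one-sided where a
neighbor falls outside, never using out-of-mask values. The dissipation
function Φ (with the −⅔(∇·v)² compressibility term, included by default
because measured fields are not divergence-free; switchable off) is floored
at zero, multiplied by μ and the voxel volume, and summed over the
segmentation — totals in mW. Whether the voxel-volume factor is part of the
classical "summation over the segmentation" formulation is ambiguous; it is
included here so totals are physical energy rates (mW), and the per-voxel
density map (W/m³) is exported alongside.

Validation on the Poiseuille phantom: mean |WSS| within 2.3 % and total EL
within 2.2 % of the closed forms at the default grid, 1.4 % / 1.4 % at half
spacing, with errors decreasing monotonically under 2× refinement. Both
scale exactly linearly in μ, and EL is exactly invariant under a uniform
velocity offset.

## Cohort atlas

Registration maximizes the normalized cross-correlation of Gaussian-
smoothed (σ = 1 voxel) masks — binary masks make intensity metrics
pointless, and the smoothed-overlap objective is smooth in the pose
parameters and peaks at 1 for identical shapes. Optimization is Powell's
method over 6 rigid (or 12 affine: + scales, shears) parameters from a
centroid-aligned start plus seeded perturbation restarts; identical inputs
give identical transforms, and restarts are skipped once alignment is
essentially perfect. The metric is evaluated on the fixed mask's dilated
bounding box only. Typical recovery of jitters within the simulated range
is ≤ 0.6° axis error and ≤ 1 mm center error (the spin of a nearly
axisymmetric mask about its own axis is not identifiable, so accuracy is
stated as axis alignment).

The shared geometry is built from the pooled cohorts (never per group): the
reference is the mask of median lumen volume (ties toward the lower subject
index; one registration seed is shared by all subjects so the result is
independent of subject order), every mask is rigidly registered to it, and
the shared mask keeps voxels covered by ≥ `inclusion_fraction` (default
0.6, exposed in config) of registered masks, largest component. Subjects
then map into it by affine registration (initialized at their rigid pose)
and nearest-neighbour interpolation: each shared voxel reads the nearest
subject lumen voxel within 2 voxels (farther locations are missing); wall
values take the nearest subject wall point under the same transform, one
code path for both domains. Subjects whose registered mask overlaps the
shared mask with Dice < 0.5 are excluded and logged.

## Voxel-wise statistics

The Mann-Whitney U statistic is computed by rank summation with midrank
ties. The exact two-sided p uses the null permutation distribution obtained
by a cached dynamic program over rank sums (algebraically identical to full
enumeration and verified against it); `mann_whitney_u` takes this path for
tie-free pooled samples up to 16 by default, and the p-value map extends it
to 30 — covering the 14-vs-14 cohort case, where the exact test keeps the
achieved type-I level at 0.0497 for nominal α = 0.05 (the normal
approximation with tie and continuity correction, used beyond that or under
ties, achieves 0.0444). Locations are testable when both cohorts have at
least `min_n` = 7 non-missing subjects; identical pooled values yield
p = 1. Directions are +1 where the cohort-B median exceeds the cohort-A
median. No multiple-testing correction is applied by default — the
per-voxel map is exploratory and its calibration is reported as-is — but
Benjamini-Hochberg adjustment is available (`fdr=True`) because the voxel
family is large. Significance fractions are percentages of testable
locations (equal-volume voxels, equal-area wall points) per direction.

The conventional group table reports per-metric medians with interquartile
ranges and the two-sided Mann-Whitney p, for peak velocity, mean velocity,
mean WSS and EL.

## Problem sizes used in validation

Oracle tests run on the full default grid (80 × 94 × 46). The cohort-level
validation uses 14 + 14 subjects on a 36 × 42 × 28 grid (R = 8 mm tube,
48 mm long, 6 frames) — large enough that the shared geometry contains
~1300 testable voxels and ~550 wall points while the complete pipeline
(56 registrations included) finishes in a few minutes on one CPU. Type-I
calibration uses 50 replicates of 14-vs-14 cohorts at 1000 synthetic
locations drawn i.i.d. standard normal.

## Known limitations

- Maxwell (concomitant-gradient) phase correction is out of scope: it
  requires pulse-sequence gradient waveforms, which are not modeled; the
  generator correspondingly never applies Maxwell corruption.
- The threshold segmentation surrogate needs flow-filled lumina; eccentric
  jets with stagnant regions require an external mask.
- Median-neighborhood unwrapping cannot repair wrapped regions wider than
  its neighborhood (it peels ~1 voxel per iteration).
- WSS accuracy is stated for smooth, locally parabolic near-wall profiles;
  the 3-point quadratic underestimates sharper boundary layers.
- The EL noise floor grows with σ²/h²; with the default 3×3×3 median filter
  and 0.05 m/s noise the end-to-end summary metrics stay within ~5 % of the
  clean run, but unfiltered noisy gradients would not.
- Rigid-then-affine mask registration cannot recover rotation about a
  near-axisymmetric vessel's own axis, and no deformable registration is
  offered.
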