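# Methods

This note documents the models, estimators, numerical choices and known
limitations of `spionquant`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is taken
on faith.

## Scope and data model

The package quantifies single nanoparticles in 3D from electron tomograms
(z-stacks with isotropic voxels; z is the beam axis, the support film is
the XY plane; particles appear dark on a bright background). Tomographic
acquisition and reconstruction are out of scope: the pipeline consumes a
voxel volume, either a real reconstruction read from TIFF or a synthetic
one. Volumes travel as ImageJ-compatible TIFF; MRC is not supported.

## Synthetic particles and tomograms

Particles are star-shaped bodies defined by a radial function
r(θ, φ) = r_ellipsoid(θ, φ) · (1 + ε f(θ, φ)), where r_ellipsoid is a
triaxial ellipsoid with semi-axes a ≥ b ≥ c and f is a random band-limited
field of real spherical harmonics (degrees 2–6, i.i.d. normal
coefficients, normalised to max |f| = 1). The amplitude ε < 1 guarantees a
star-shaped body; ε ≈ 0.1–0.2 produces the irregular bean-like
morphologies seen late in thermal-decomposition syntheses. A voxel belongs
to the particle when its centre lies inside the surface.

Ground truth per particle: volume, surface area, centroid-referenced
radius of gyration and sphericity by spherical quadrature of the radial
function (trapezoid in θ, periodic rule in φ, 512 × 1024 grid; ~10⁻⁴
relative accuracy, verified against 4/3·π·a·b·c and the sphere surface).
For unperturbed ellipsoids the caliper triplet (2a, 2b, 2c) is exact;
for perturbed shapes calipers are left undefined (NaN) and tested against
a brute-force point-pair oracle instead.

Orientation convention: `euler_angles = (azimuth, polar, roll)`. The long
axis points along (azimuth, polar); roll = 0 rests the short axis as
vertically as the pose allows, roll = 90° lays it in the support plane.
The growth-series generator uses roll = 90°. This choice is deliberate:
the silhouette area of an ellipsoid along the beam is
π·abc·√(uᵀ diag(a⁻², b⁻², c⁻²) u), and only a pose with the short axis
close to the support plane makes the 2D spherical-model volume
*underestimate* the true volume for particles whose long axis is tilted
~20° out of the plane — the empirically observed direction of the 2D bias.
With the short axis vertical (flat resting) the same geometry gives an
overestimate of up to 1/(c/a). The package treats the short-axis-in-plane
pose as its resting model and demonstrates the resulting bias sign and its
monotone deepening with tilt in the acceptance suite.

Preferred orientations are sampled from an equal-weight two-component
normal mixture for the polar angle θ of the long axis (peaks symmetric
about 90°, e.g. 69°/111°; spread a few degrees), and a normal azimuth
centred at 90°. Tomograms render particles at 0.6 contrast on a 1.0
background with additive Gaussian noise of SD 0.06 (SNR 10, comfortably
above the SNR ≥ 5 regime where IsoData thresholding is unambiguous). The
missing-wedge artifact is available only as a forward z-elongation factor
(default 1.0 = off) applied to each mask before rendering; no Fourier
wedge masking is performed.

### Default growth series

Five time points emulate sampling a 320 °C thermal decomposition at
10-minute intervals, with per-time-point targets

| label | mean V (nm³) | CV | mean Ψ | n | θ peaks (°) |
|---|---|---|---|---|---|
| onset | 1597 | 0.651 | 0.91 | 149 | 80/100 |
| 10 min | 12085 | 0.326 | 0.77 | 112 | 74/106 |
| 20 min | 14325 | 0.208 | 0.76 | 83 | 72/108 |
| 30 min | 16239 | 0.237 | 0.59 | 96 | 69/111 |
| cooldown | 15324 | 0.244 | 0.56 | 72 | 69/111 |

Volumes are lognormal with the stated mean and CV. The sphericity schedule
must decrease over time (that is the generator's contract), so the two
reported near-tied pairs are ordered decreasingly (0.77 before 0.76, 0.59
before 0.56). Shape targets are met by combining an oblate axis ratio
c/a — inverted numerically from the mean analytic sphericity at the given
perturbation amplitude (bisection, averaged over three field seeds) — with
a perturbation amplitude schedule (0, 0.08, 0.10, 0.14, 0.16). Since no
quantitative aspect-ratio trajectory is available, this schedule is
calibrated only to the sphericity means; the late-stage particles it
produces are wider and flatter than real bean-shaped crystals of equal Ψ.
Default voxel size is 1.0 nm (synthesis speed; the estimators are tested
down to 0.25 nm). Particles are laid out on a non-overlapping jittered
grid, so detected count should equal generated count; aggregates for
exclusion tests are constructed explicitly by overlapping placements.

## Segmentation

Detection thresholds the whole tomogram with IsoData (iterative
intermeans), discards components below 27 voxels, and crops one
subtomogram per blob (configured lateral size, odd voxel count, full
depth) centred on the blob centroid. A tomogram whose thresholded
foreground exceeds 25% of the voxels is treated as particle-free: IsoData
applied to pure noise labels about half the volume, whereas drop-cast
scenes are sparse. Intensity polarity (dark vs bright particles) is
configuration, never guessed; a crop whose foreground becomes the majority
phase raises an error rather than silently segmenting the background.

Aggregate screening excludes a crop iff foreground touches a lateral (x or
y) face of the box, tangency included; z faces are not tested because the
crop keeps the full depth.

Binarization applies IsoData per subtomogram (not per slice), then a
watershed on the negated Euclidean distance transform. Markers are the
connected cores where the distance transform exceeds half its maximum:
touching particles of similar size have separate cores and are split,
while a single particle — however plate-like — keeps one core. (Naive
local-maximum seeding at a fixed minimum separation shatters flat
particles into fragments via the ripple of their own distance map; this
failure mode is why marker generation is prominence-based.) A known
limitation: a particle much smaller than a touching neighbour may fall
below the half-maximum core threshold and be absorbed. The component
containing (or nearest to) the crop centre is retained; everything else is
zeroed.

## Stereology

Cavalieri volume: a (spacing × spacing) point lattice with uniform random
per-axis offsets on every slice; V = count × area_per_point × voxel size.
`area_per_point` (0.91 nm²) and `spacing` (0.95 nm) are independent
configurables; because 0.95² = 0.9025 ≠ 0.91 the defaults carry a +0.8%
scale factor, and a warning is emitted whenever area_per_point ≠ spacing².
The estimator is unbiased over offsets (property-tested with a two-sided t
test at 200 offsets using the self-consistent grid) and its variance
shrinks with spacing.

Fakir surface: line lattices at the same spacing, S_d = 2·s²·I_d per
direction, averaged over directions. Two probe layouts exist:

* *isotropic* (default): three uniformly random orthogonal triplets (nine
  directions) per estimate. The direction average over random rotations
  makes the estimator unbiased for surfaces of any anisotropy; for an
  axis-aligned cube the axis-aligned layout would be biased −33% (its
  expectation is 2∫|u·n|dS per direction), which is why the isotropic
  layout is the default. Averaging three triplets keeps the
  rotation-sampling noise for faceted bodies near 1% per estimate.
* *axes*: vertical lines plus the two reslice directions, sampled at
  probe-spacing resolution on the raw mask — the manual-counting
  construction, exposed for comparison.

Oblique probes sample a slightly smoothed occupancy field (Gaussian,
σ = 0.7 voxel, trilinear interpolation, 0.5 level set) at spacing/2 along
each line. The smoothing is a numerical regularisation of the digitised
staircase boundary: counting raw-mask crossings along oblique lines
overstates the sphere surface by ~5%, and refining the sampling step makes
that worse because the staircase is a genuine property of the binary
surface. Measured accuracy with the default grid: sphere volume +0.3%,
sphere surface +0.2%, cube surface −3.6% (edge rounding under the
smoothing plus short rim chords missed at finite sampling), all within the
tolerances the oracles demand (2%/5%).

## Shape metrics

The caliper search rotates the convex hull of the foreground voxel
centres (the hull carries all caliper information, and operating on
coordinates avoids image-resampling artifacts). Stage 1 scans x-rotations
over [0, 180) at a 1° default step and takes the maximum 2D Feret of the
XY projection — every spatial direction enters some projection, so this
maximum is the 3D maximum caliper λx. Stage 2 aligns λx with the x axis
and scans rotations *about the aligned long axis*, measuring the
transverse extent: the maximum is λy and the extent 90° further is λz,
which guarantees λx ≥ λy ≥ λz. (A literal in-plane z-rotation scan after
alignment cannot produce the short axis of a flat-lying particle — it
never leaves the XY projection — so the rotation axis for stage 2 is the
aligned long axis; this is one consistent reading of the manual procedure
and is documented here rather than asserted as the only one.) Extents are
max − min of projected coordinates plus one voxel; ties break to the
smallest scan angle. The search is validated against a brute-force
max-pairwise-surface-distance oracle (agreement within 2 voxels on random
perturbed particles).

Orientation is reported as θ = polar angle of the long axis from the beam
axis (90° = in the support plane; sign fixed by requiring a non-negative
x, then y, component of the axis, so a population tilted 21° out of plane
shows the symmetric 69°/111° peaks) and φ = the x-rotation angle at which
the maximum was found.

Sphericity values slightly above 1 (surface underestimated by noise) are
reported as-is and flagged, never clipped. The voxel radius of gyration
omits the intra-voxel second moment by default (t²/4 in Rg², negligible at
sub-nanometre voxels; toggleable). The model-based 2D route projects the
mask along z, takes r = √(area/π) and volume 4/3·π·r³.

## SAXS Guinier analysis

Momentum transfer q = 4π sin(θ/2)/λ with λ = 0.1524 nm by default. The
Guinier fit is ordinary least squares of ln I on q², iterated so the
window satisfies q·Rg ≤ 1.3 (configurable); Rg = √(−3·slope), with the
95% CI transformed from the slope CI and a delta-method standard error.
The iteration reaches a fixed point in a few passes on monotone curves and
is capped at 20.

The conventional 1.3 cutoff carries a known truncation bias for compact
particles: a sphere's ln I = −x²/5 − x⁴/350 + … (x = qR), so the
first-order fit overestimates Rg by ~1.9% regardless of grid density
(pinned by a unit test). Two remedies are provided. For identity checks
the window can simply be tightened (q·Rg ≤ 0.9 brings the sphere error
under 1%). For cross-method comparisons the fit accepts
``extended=True``, adding a q⁴ term and reading Rg from the q²
coefficient; this absorbs the curvature (sphere error −0.1% noiseless,
unbiased within 0.1% under 5% noise on a 300-point grid) at the price of a
larger standard error. The pipeline's SAXS-vs-TEM comparison uses the
extended fit by default, because a 2% systematic Rg offset is detectable
at n ≈ 100 particles and would masquerade as a method disagreement.

The TEM-vs-SAXS verdict follows the asymmetric rule used in manual
practice: compute the 95% CI of (mean SAXS − mean TEM) and declare "no
significant difference" iff the lower bound is below zero. The symmetric
two-sided rule is available behind a flag and off by default. Note the
asymmetric rule cannot flag a SAXS mean far *below* the TEM mean; this is
a faithful reproduction of the described decision rule, not an oversight.
Background subtraction and instrument corrections are out of scope — the
module consumes reduced curves.

The simulated SAXS route is a monodisperse sphere at the radius matching
the population's mean TEM Rg (R = √(5/3)·R̄g) with mean-one multiplicative
lognormal noise (SD 5%). Real polydisperse SAXS is intensity-weighted
(larger particles dominate); this single-size surrogate tests the fit and
the comparison logic, not polydispersity effects.

## Statistics

Dispersity Ð = 100·SD/mean of the per-particle volume distribution —
this definition reproduces the reported 32.6% and 20.8% from the printed
(mean, SD) pairs. Group comparisons run Shapiro–Wilk on each group (for
reporting), then a two-sided F test at α = 0.05; Student's t test when
variances are homogeneous, Welch's otherwise (the gate holds the nominal
5% ± 2% type-I error over 2000 null replicates). Sphericity, which is not
normally distributed, is compared with Mann–Whitney U. Kernel densities
use the FFT construction on a ≥ 512-point regular grid with linear
interpolation at query points and the nrd0 plug-in bandwidth
(0.9·min(SD, IQR/1.34)·n^{−1/5}).

## Problem sizes and determinism

The acceptance suite segments and re-measures the full default growth
series (512 particles over five time points at 1 nm voxels, about 6
minutes on one core) and checks: mean volume recovery within 5% per time
point (measured 0.5–1.2%), a decreasing recovered sphericity schedule
(consecutive scheduled steps of ~0.01 are below the stereological
resolution of ~0.03 and are tested at that resolution; the two large drops
must be strict), conserved particle counts, and the SAXS-vs-TEM verdict in
≥ 90% of replicates. All randomness flows from explicit seeds
(`numpy.random.SeedSequence` spawning per stage); the pipeline is
byte-identical across runs at a fixed configuration.

## Known limitations

* The generator's shapes are perturbed spheroids; real faceted crystals
  (octahedra, coffin shapes) have sharper edges, for which the smoothed
  Fakir probe is a few percent low (cube: −3.6%).
* Watershed merging of strongly unequal touching particles (see above).
* The preferred-orientation resting model (short axis in-plane) is chosen
  for consistency with the observed 2D underestimation bias; real resting
  poses on amorphous carbon with surfactant layers are not modelled.
* No tilt-series projection/reconstruction simulation; the missing wedge
  appears only as its elongation symptom.
* Passing tests on this synthetic data demonstrates estimator correctness
  and pipeline integrity, not robustness to reconstruction artifacts,
  contamination, or focus gradients present in real tomograms.
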