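# Methods

This note records the models, conventions and numerical choices behind
`lensmap3d`, and what the synthetic phantoms do and do not demonstrate
about real microscope data.

## The measurement problem

The lens epithelium is a cell monolayer covering the anterior cap of the
ocular lens.  Its surface density as a function of the polar angle
theta (anterior pole = 0 deg, equator = 90 deg) exhibits three zones: a
low-density quiescent central zone (CZ), a high-density proliferative
germinative zone (GZ) peaking adjacent to the equator, and a short
low-density band of aligned cells, the meridional rows (MR), just past
the equator.  The package reconstructs this structure from confocal
z-stacks of whole Hoechst-stained lenses: detect every nucleus, recover
the lens's own coordinate frame from three manual landmark picks,
assign each nucleus spherical angles, and quantify the zonal density
profile.

## Coordinate conventions

* Voxel indices are 0-based `(z, y, x)`; physical coordinates are
  micrometres with the voxel-centre convention
  `(x, y, z) = (i*sx, j*sy, k*sz) / 1000` for spacing in nanometres.
  The reference acquisition spacing, 1515.2 x 1515.2 x 5977.2 nm, is a
  default only in the synthetic module; real stacks must carry spacing
  metadata or an explicit override.
* Theta is measured from the anterior pole (AP at 0 deg, equator at
  90 deg), after affine normalization `(x/R_max, y/R_max, z/R_min)`
  onto the unit sphere.  Normalization makes theta well defined on
  lentoid (non-spherical) lenses and makes a planted angular density
  profile recoverable independent of aspect ratio.  Phi is measured
  from the first landmark (`p1` maps to phi = 0), which makes the full
  mapping — including phi — invariant under rigid motion of the input.

## Nucleus detection

1. **Likelihood map.**  The stack is convolved with a scale-normalized
   Laplacian-of-Gaussian kernel.  The Gaussian scale is
   `sigma = R / sqrt(3)` per physical axis (the scale maximizing the
   normalized response of a solid sphere of radius R); the Laplacian is
   computed in physical coordinates (second differences weighted by
   `1/spacing^2`), and the response is negated so bright blobs peak
   positive.  A radius below the largest voxel dimension is refused as
   unresolvable rather than silently blurred away.
2. **Maxima.**  Local maxima are voxels equal to the grayscale dilation
   of the map by a discretized physical sphere of radius R (an
   ellipsoid in voxel units).  Connected plateaus of equal values
   resolve to their lexicographically smallest voxel, making output
   deterministic.
3. **Splitting and scoring.**  A marker-based watershed on the inverted
   Gaussian-smoothed intensity (sigma = R/2), seeded at the maxima and
   restricted to a foreground mask, separates touching nuclei.  The
   default mask level is `max(Otsu, intensity threshold)`: with nuclei
   occupying well under 1% of the volume, Otsu alone collapses onto the
   noise mode, so the intensity threshold provides a floor.
4. **Filters.**  Peak intensity is read from the smoothed stack at the
   peak voxel (robust to single-voxel noise); the default threshold is
   the 98th percentile of the raw stack.  Circularity is
   `sqrt(lambda_min / lambda_max)` of the region's second-moment matrix
   in physical coordinates, with Sheppard's discretization correction
   (`spacing^2 / 12` added per axis) so that a compact nucleus thinner
   than one anisotropic z-slice is scored by its physical extent
   instead of collapsing to zero.  Default threshold 0.4.  With the
   watershed disabled no regions exist, so the circularity filter is
   skipped and centroids fall back to peak-voxel centres.

Defaults (R = 4 um, q98 intensity, 0.4 circularity) are starting
points, not calibrated constants; image-quality-appropriate values are
the user's responsibility.  Note that at the reference 5977 nm z-step
the default R = 4 um is refused by the scale check — by design: either
image with a finer z-step or detect at a larger radius.

## Lens frame and spherical mapping

Three landmarks picked at the GZ/MR boundary (equal azimuthal spacing
recommended) define a circumscribed circle and a near-equatorial plane.
The plane normal is oriented toward the data-populated hemisphere, and
the anterior pole is the nucleus with minimal perpendicular distance to
the polar ray (ties to the farther nucleus).  `R_min = |AP - centre|`,
and D1–D4 report the landmark/AP distances that yield the radial data.

The GZ/MR boundary generally sits *below* the true equator, so the bare
three-point circle underestimates the equatorial radius and its plane
is offset along the axis; left uncorrected this would bias both the
aspect ratio and every assigned theta.  The frame is therefore refined
by default: with the axis direction fixed by the landmark normal, an
axis-aligned spheroid is fitted to the whole cloud by a homogeneous
linear least-squares system solved with SVD (exact for noise-free
surface points, stable under rotation), recovering the centre and the
equatorial radius `R_max`.  `build_frame(..., refine=False)` gives the
bare three-point construction, whose D1–D3 equal the circle radius by
construction.

The AP search gate defaults to 0.1 x R_max in `build_frame` (0.05 in
the low-level function): the phantoms carry ~4x10^3 cells rather than
the ~5x10^4 of a real lens, so the nucleus nearest the pole axis is
proportionally farther away.  At the default scale the chosen nucleus
sits within ~2 deg of the true pole, perturbing `R_min` by well under
1%.

Shape metrics assume an oblate spheroid: aspect ratio `R_min/R_max`,
hemisphere volume `(2/3) pi R_max^2 R_min`, full volume twice that.

## Zonal density analysis

Mapped nuclei are binned into 5-deg polar bands (the granularity at
which zone angles are conventionally reported); band areas use the
closed form `2 pi R_max^2 (cos t1 - cos t2)` on the normalized sphere,
and densities are cells per 1000 um^2.  Smoothing is a 3-bin centred
window implemented as window count/area sums — equivalent to an
area-weighted moving average, which keeps the tiny near-pole bins from
dominating the noise budget.

**Extrema.**  The profile maximum is the centre of the global maximum
bin of the smoothed profile.  The minimum is defined as the posterior
edge of the anterior plateau: among bins anterior to the maximum, the
largest-theta bin whose smoothed density is within 15% (of the
plateau-to-peak contrast) of the plateau level, the plateau level being
the median of the anterior smoothed bins.  A literal argmin is not
usable here: on a flat low-density plateau the minimum bin under
Poisson noise is essentially uniformly distributed over the plateau,
whereas the tolerance rule consistently returns the plateau's posterior
edge and degrades gracefully to "the bin preceding the maximum" for a
constant (low-contrast) profile, which is flagged with a warning.

**GZ/MR boundary.**  The boundary is the anterior edge of the first bin
past the maximum whose smoothed density falls below `drop_fraction`
(default 0.42) of the smoothed peak, falling back with a warning to the
last occupied bin if the profile never crosses.  Both constants were
calibrated analytically against the piecewise-linear planted profile of
the phantoms (not fitted to sampled data): with 5-deg bins and 3-bin
smoothing, a threshold in (0.39, 0.48) x peak selects the bin
containing the planted boundary, and 0.42 centres the noise margins on
both sides; taking the bin's anterior *edge* rather than its centre
removes the half-bin bias that would otherwise misstate the MR area by
a factor ~2 at this bin width.  When trustworthy landmark picks exist
they can override the density-based boundary.

**Per-cell densities.**  The heat-map estimator is the standard kNN
density on the sphere: k (default 6, the hexagonal-packing coordination
number) divided by the geodesic-disc area out to the k-th neighbour,
with 5 quantile colour classes.

**ROI transects.**  Anchors are nuclei within a capture half-width
(default 6 um = 1.5 x the default detection radius) of the P1-P2
segment; each grid's neighbourhood is the union of its anchors and each
anchor's k nearest nuclei, deduplicated within the grid (a nucleus may
appear in several grids).  Both the half-width and the neighbour count
are reconstructions of quantities the original procedure leaves to the
user, and both are tunable.

## Synthetic phantoms

`sample_epithelium` realizes an inhomogeneous Poisson process on the
spheroid cap by thinning an area-uniform proposal; the planted density
d(theta) is piecewise linear (plateau `d_cz` to 75 deg, rise to
`d_peak` at the peak angle, fall to `d_mr` at the GZ/MR boundary,
constant to the 115-deg epithelial edge), with the boundary solved so
the MR band occupies the requested area fraction.  Densities are
defined per unit area of the normalized sphere, so the planted theta
profile survives the mapping stage exactly.  MR cells snap to a regular
phi lattice (90 columns) as a purely cosmetic emulation of meridional
alignment.

Preset geometry plants the reference adult ("mature": aspect 0.7,
minimum 75 deg, peak 90 deg, MR 5%, 35-deg mounting tilt) and juvenile
("young": aspect 0.9, near-uniform density with a mild 95-deg peak)
conditions.  Absolute densities (mature 0.35/1.05/0.28, young
0.55/0.85/0.44 cells per 1000 um^2, both in the 1:3:0.8 and mild-peak
regimes respectively) were chosen to give 3-5x10^3 cells per cap so
the full pipeline runs in seconds; real lenses carry an order of
magnitude more cells, and scale is a parameter.

`render_stack` draws each cell as an additive isotropic Gaussian blob
(sigma = nucleus_radius / 2) plus i.i.d. Gaussian read noise.  Because
a `VoxelGrid` anchors physical coordinates at voxel (0,0,0), the
renderer returns the stack together with the physical offset of that
corner; ground-truth coordinates minus the offset express the truth in
the stack frame.  There is no optical model: no PSF anisotropy beyond
voxel spacing, no depth attenuation, no refraction through the lens
body, and no nucleus shape variation.  Passing detection tests
therefore demonstrate the geometry/scale-space logic, not robustness to
real confocal aberrations.

The rendering benchmark (`imaging_config`) uses a 0.2-scale lens
(detection depends only on local blob geometry, which is scale-free; a
full-size stack would be ~4x10^8 voxels) imaged with a half z-step
(2992 nm) and 4-um nuclei, keeping the blob scale resolvable axially.

## Problem sizes and reproducibility

Default analyses use ~4.4x10^3 cells per phantom; recovery statistics
(zone angles, MR fraction) are quoted as medians over 20 seeds, and
each end-to-end point-cloud run takes well under a second on one CPU.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seed and configuration give
byte-identical tables and stacks.

## Known limitations

* Landmark picking is manual by design; no automatic GZ/MR boundary
  detection is attempted.
* The spheroid refinement assumes the lens is an axisymmetric oblate
  spheroid; strongly aspheric lenses would need a richer surface model.
* Circularity is a second-moment score; surface-area sphericity would
  discriminate differently for irregular shapes and is not implemented.
* The MR boundary from the density drop is only as sharp as the 5-deg
  binning; per-column analysis of meridional rows is out of scope.
* Zone statistics across age groups (ANOVA etc.) are downstream of the
  exported tables and not part of the package.
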