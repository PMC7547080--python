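# lensmap3d

Whole-lens 3D mapping of the ocular lens epithelium: detect nuclei in
anisotropic confocal z-stacks, recover the lens's own spherical
coordinate frame from three landmark picks, and quantify the zonal
density structure of the epithelial cell monolayer.

The lens epithelium is organized in three zones along the polar angle
theta (anterior pole = 0 deg, equator = 90 deg): a quiescent,
low-density **central zone** (CZ), a proliferative, high-density
**germinative zone** (GZ) peaking adjacent to the equator, and the
**meridional rows** (MR), a short band of aligned cells just past the
equator where fiber differentiation begins.  `lensmap3d` turns a
z-stack of a whole Hoechst-stained lens into a table of nuclei with
per-cell spherical coordinates, a theta-density profile with its
characteristic minimum and maximum angles, CZ/GZ/MR zone assignments
and area fractions, and lens shape metrics (equatorial radius R_max,
polar radius R_min, aspect ratio R_min/R_max, volumes).

The pipeline:

1. **Detection** — LoG blob likelihood at nucleus radius R, local
   maxima by grayscale dilation with a physical-sphere structuring
   element, watershed splitting of touching nuclei, intensity and
   3D-circularity filters.  All scales in micrometres, anisotropy
   corrected throughout.
2. **Mapping** — a circle through three landmarks picked at the GZ/MR
   boundary fixes the lens axis; the anterior pole is the nucleus met
   by the polar ray; a spheroid fit refines centre and radii; the cloud
   is rigidly realigned (undoing the ~35 deg mounting tilt) and each
   nucleus gets (theta, phi) on the affinely normalized unit sphere.
3. **Zone analysis** — closed-form band areas convert counts to surface
   densities; the profile minimum/maximum, the density-drop GZ/MR
   boundary, per-zone area percentages, kNN density heat-map classes,
   and transect (ROI) density profiles.
4. **Phantoms** — a synthetic generator plants a known zone-density
   profile on a spheroid cap, renders it as a noisy stack, and provides
   the ground truth every stage is validated against.

## Worked example

```python
from lensmap3d import (boundary_landmarks, map_points, mature_config,
                       sample_epithelium, theta_density_profile,
                       zone_segmentation)

config = mature_config(seed=1)              # adult-lens phantom
truth = sample_epithelium(config)           # ~4.4e3 cells, 35 deg tilt
mapped, frame = map_points(truth.points, boundary_landmarks(config))
profile = theta_density_profile(mapped, frame)
seg = zone_segmentation(profile, mapped)
print(frame.aspect_ratio, seg.theta_min_angle, seg.theta_max_angle)
```

Running `python examples/03_map_and_zones.py` (which does exactly this)
prints:

```
R_max 1000.0 um, R_min 700.1 um, aspect ratio 0.700
hemisphere volume 1.466 mm^3
density-profile minimum at 72.5 deg (planted CZ/GZ boundary: 75.0 deg)
density-profile maximum at 92.5 deg (planted peak: 90.0 deg)
GZ/MR boundary at 110.0 deg (planted: 110.6 deg)
zone  percent_of_epithelium  n_nuclei
  CZ                  49.17      1529
  GZ                  45.19      2672
  MR                   5.65       130
```

The frame recovers the planted lentoid shape (aspect 0.7); the density
extrema land in the 5-deg bins containing the planted 75/90 deg
angles; and the meridional rows are assigned 5.6% of the epithelial
area against a planted 5%.  The other examples cover phantom
generation, rendering + detection (precision 1.00, recall 0.97 on the
benchmark stack), and ROI transects.

The same stages are available as a CLI:

```sh
lensmap3d run --preset mature --seed 1 --outdir out/
lensmap3d detect stack.tif --radius 4 --out nuclei.csv
lensmap3d map nuclei.csv --landmarks x1,y1,z1 x2,y2,z2 x3,y3,z3 --out mapped.csv
lensmap3d zones mapped.csv --frame frame.json --out out/zonal
```

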