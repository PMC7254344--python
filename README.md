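# spionquant

Model-free 3D quantification of nanoparticle size and shape from electron
tomograms, built for superparamagnetic iron-oxide nanoparticle (SPION)
growth studies and validated end-to-end against a synthetic tomogram
generator with analytic ground truth.

Conventional TEM sizing measures a 2D projection and assumes a spherical
particle; for anisotropic particles resting in a preferred orientation on
the support film this model-based route is biased. `spionquant` instead
quantifies each particle in 3D without any shape model:

* **Volume** by the Cavalieri estimator: V = P · a_p · t, with P the number
  of probe points hitting the particle across slices, a_p the area per
  point (default 0.91 nm²) and t the slice thickness.
* **Surface area** by Fakir line probes: for each probe direction d,
  S_d = 2 · s² · I_d with s the probe spacing (default 0.95 nm) and I_d the
  number of line–boundary crossings; directions are averaged (isotropic
  probe triplets by default, axis-aligned probes optionally).
* **Sphericity** Ψ = (36π V²)^{1/3} / A (1 for a sphere).
* **Anisotropy** from the three orthogonal maximum calipers λx ≥ λy ≥ λz
  found by brute-force rotation search:
  √(½[(λx−λy)² + (λy−λz)² + (λz−λx)²]) / √(λx² + λy² + λz²).
* **Radius of gyration** both from voxels (RMS distance to the centroid)
  and from SAXS curves via a windowed Guinier fit of ln I against q²
  (slope −Rg²/3, window q·Rg ≤ 1.3), allowing a model-free TEM-vs-SAXS
  consistency check via the 95% CI of the difference of means.
* **Statistics** in the reporting style of growth studies: Shapiro–Wilk
  screening, an F-test gate choosing Student vs Welch t tests, FFT-based
  Gaussian kernel densities, volume dispersity Ð = SD/mean, and per-time-
  point summary tables with growth rates.

The synthetic generator produces voxelized ellipsoids with band-limited
spherical-harmonic surface perturbations, assembles them into noisy
tomograms (dark particles, bright background, optional missing-wedge
z-elongation), and emulates a five-time-point thermal-decomposition growth
series: mean volume rising ~1.6·10³ → ~1.6·10⁴ nm³, volume CV shrinking
65% → 21%, mean sphericity declining 0.91 → 0.56, and the long axis
settling ~20° out of the support plane (θ peaks near 69°/111°).

## Worked example

```python
import numpy as np
from spionquant.types import ParticleShapeParams, ProbeGrid
from spionquant.synthetic import make_particle_mask
from spionquant.stereology import estimate
from spionquant.shape_metrics import max_caliper_search, sphericity, anisotropy

# a flat-lying oblate spheroid, semi-axes 10 x 10 x 5 nm, 0.5 nm voxels
particle, truth = make_particle_mask(
    ParticleShapeParams(semi_axes=(10, 10, 5), euler_angles=(0, 90, 0)), 0.5)

grid = ProbeGrid()                     # 0.91 nm^2 per point, 0.95 nm spacing
est = estimate(particle, grid, n_offsets=5, seed=0)
triplet, orientation = max_caliper_search(particle)

print(f"V  = {est.volume:8.1f} nm^3   (truth {truth['volume']:8.1f})")
print(f"A  = {est.surface_area:8.1f} nm^2   (truth {truth['surface_area']:8.1f})")
print(f"Psi = {sphericity(est.volume, est.surface_area):.3f}  "
      f"anisotropy = {anisotropy(triplet):.3f}")
print(f"calipers = ({triplet.lambda_x:.1f}, {triplet.lambda_y:.1f}, "
      f"{triplet.lambda_z:.1f}) nm")
```

prints

```
V  =   2095.7 nm^3   (truth   2094.4)
A  =    868.4 nm^2   (truth    867.2)
Psi = 0.912  anisotropy = 0.324
calipers = (20.5, 20.5, 10.5) nm
```

i.e. the stereological volume and surface agree with the analytic ellipsoid
values to well under 1%, the sphericity of this 2:1 oblate is ~0.91, and
the caliper triplet recovers the (20, 20, 10) nm axes to one voxel.

## Command line

```bash
spionquant all --seed 1 --out results_dir         # simulate -> report
spionquant simulate --seed 1 --out results_dir    # tomograms + ground truth
spionquant segment  --tomogram results_dir/tomograms/onset.tif --out results_dir
spionquant quantify --masks results_dir/masks --out results_dir
spionquant saxs     --curve results_dir/saxs_onset.dat --out results_dir
spionquant report   --particles results_dir/particles.csv --out results_dir
```

Tomograms travel as ImageJ-compatible TIFF stacks (voxel size in the
metadata); SAXS curves as two-column text (q in nm⁻¹, intensity); all
results as CSV/JSON with the full configuration embedded for provenance.

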