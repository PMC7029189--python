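# topofield

**3-D connective field mapping of region-to-region functional connectivity.**

`topofield` estimates, for every voxel of a *seed* brain region, where and how
broadly that voxel connects within a *mapping* region, directly from
volumetric resting-state fMRI time series — and then quantifies the
*organisation* of those connections: is the projection topographic (a smooth,
order-preserving map, like retinotopy), convergent (many seed voxels funnel
into one locus), or unorganised?  It is aimed at researchers studying
topographic organisation of cortico-cortical connectivity with standard
volumetric (NIfTI) data, without surface projection.

## The model

Each seed voxel *v*'s time course is correlated with every mapping-region
voxel and Fisher-z transformed.  The resulting connectivity profile is
summarised by a 3-D isotropic Gaussian *connective field*

```
g_v(x, y, z) = (σ³ (2π)^{3/2})⁻¹ exp( −[(x−x₀)² + (y−y₀)² + (z−z₀)²] / 2σ² )
```

with preferred locus (x₀, y₀, z₀) and spread σ (voxel units).  Parameters are
estimated by minimising the correlation distance between the z profile and
the Gaussian, under box bounds, from the profile maximum (plus coarse extra
σ starts).  The fitted field is also an encoding model: the prediction
`p_v(t) = Σ_xyz A(x, y, z, t) g_v(x, y, z)` is validated by comparing matched
against mismatched prediction–data correlations.

Organisation metrics built on the fitted fields:

* **Rank linearity** ∈ [0, 1] — complement of the normalised Procrustes SSE
  between the rank-ordered fitted centers and the rank-ordered seed voxel
  locations.  Its null expectation for a region of V voxels is 1/V; with
  spatial smoothness FWHM it is `1/resels` with `resels = V / FWHM³`, and
  inference is binomial on the effective resel count (regions with ≤ 10
  resels are flagged as unreliable).
* **Convergence** — deviance of the fitted centers from spatial uniformity
  over the mapping region, a 3-D (orthant / Peacock) Kolmogorov–Smirnov
  statistic divided by its Monte-Carlo α = 0.05 critical value, so values
  above 1 are significant for that sample size and region geometry.
* **Vector fields** — per-seed-voxel arrows toward the fitted centers
  relative to the mapping region's center of mass.
* **Gradients** — for parcellated whole-brain analyses, all-pairs rank
  linearity matrices are contrasted within/between networks, thresholded
  into topography graphs (default edge threshold 20%), and decomposed by
  nonmetric MDS on 1 − linearity distances into smooth connectivity
  gradients (mode count chosen by an elbow rule on the distance rank
  correlation curve); per-parcel task contrasts can be regressed on the
  gradients plus mean convergence with standardized OLS.

Synthetic phantoms with known connectivity (topographic / convergent / null,
controllable σ, SNR, and source smoothness) make every step testable without
any data download.

## Worked example

```python
import numpy as np
from topofield import (
    PhantomSpec, generate_phantom, fit_connective_field_map,
    rank_linearity, convergence, vector_field, estimate_fwhm, remove_region_mean,
)

spec = PhantomSpec(seed_shape=(5, 5, 5), map_shape=(9, 9, 9),
                   scheme="topographic", sigma_true=2.0,
                   n_timepoints=300, snr=10.0, seed_rng=1)
seed_ts, map_ts, truth = generate_phantom(spec)
seed_ts, map_ts = remove_region_mean(seed_ts), remove_region_mean(map_ts)

cfm = fit_connective_field_map(seed_ts, map_ts)
fwhm = estimate_fwhm(seed_ts)
lin = rank_linearity(cfm, fwhm=fwhm)
conv = convergence(cfm, n_null=999, rng=0)

print(f"estimated seed smoothness: {fwhm:.2f} voxels FWHM")
print(f"rank linearity: {lin.percent:.1f}% (null expectation {100*lin.expected:.1f}%, p = {lin.p_value:.2e})")
print(f"corrected convergence: {conv.corrected:.2f}")
```

Output:

```
estimated seed smoothness: 2.11 voxels FWHM
rank linearity: 96.5% (null expectation 7.6%, p = 4.20e-13)
corrected convergence: 1.12
```

The phantom plants a linear (identity-like) map from the 125 seed voxels onto
the 9×9×9 mapping region, so rank linearity sits near its ceiling and far
above the smoothness-adjusted null expectation of 7.6% — the planted
topography is detected.  The corrected convergence hovers near 1: a regular
topographic lattice of centers is roughly as spread out as a uniform sample.
Swapping `scheme="convergent"` reverses the picture (linearity at chance,
corrected convergence ≈ 3.5).

The same pipeline runs from the shell on NIfTI inputs:

```bash
topofield phantom --scheme topographic --out ph/
topofield fit     --data data.nii.gz --seed-mask v1d.nii.gz --map-mask v1v.nii.gz --out fit/
topofield metrics --data data.nii.gz --seed-mask v1d.nii.gz --map-mask v1v.nii.gz --out metrics/
topofield pairwise --data data.nii.gz --parcellation schaefer.nii.gz --out pairs/
topofield gradients --linearity-matrix pairs/linearity_matrix.csv --out grad/
```

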