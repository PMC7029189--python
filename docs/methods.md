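# Methods

This note documents the statistical model behind `topofield`, the estimator
conventions the package commits to, what the synthetic phantoms do and do not
emulate, and the design decisions taken where more than one reasonable
construction exists.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All model computation happens in 0-based voxel-index space.  The NIfTI
affine is carried on `VolumeGrid` for I/O and for reporting world-mm
coordinates, but the Gaussian is isotropic *per voxel*: on the
near-isotropic grids typical of resting-state acquisitions (3–4 mm cubic
voxels) index space and mm space differ only by a scale factor, and index
space avoids anisotropy bookkeeping.  Users with strongly anisotropic grids
should resample first, or fit with ``coordinate_mode='world'``, which maps
voxel centers through the affine before fitting (parameters then come out in
mm).  Mask voxel ordering is fixed — lexicographic by z,
then y, then x — so every derived quantity is reproducible across platforms.

## Connective field estimation

For each seed voxel, Pearson correlations with every mapping voxel are
computed over the non-censored frames (frames containing NaNs anywhere in
either region are dropped, and the count logged), clamped to |r| ≤ 1 − 1e−7,
and Fisher-z transformed.  Zero-variance voxel series get correlation 0 with
a warning rather than an error, because dead voxels inside anatomical masks
are common and should not abort a whole-region fit.

The 3-D isotropic Gaussian density is fitted to the z profile by minimising
`1 − Pearson(z, g)` — the correlation distance.  This objective is invariant
to the scaling of both the z values and the Gaussian's normalisation
constant, which is why no amplitude parameter is needed.  Bounds: each
location parameter within the mapping region's coordinate range; σ in
(machine ε, smallest axis range].  The optimiser starts at the location of
the maximal z value with σ = machine ε, plus coarse extra starts at
σ ∈ {0.5, 1, 2, 4} voxels, keeping the best final objective (L-BFGS-B).  The
ε-σ start alone is fragile: the objective's gradient with respect to a
near-zero σ is numerically flat, so a single start can stall on noisy
profiles; the multi-start keeps the canonical initialisation while guarding
against that basin.  A profile with zero variance (all z equal) cannot be
fitted and is returned flagged `degenerate` with parameters at the
initialisation and `fit_r2 = 0`.  `fit_r2` is the squared Pearson
correlation between the z profile and the fitted weights.

Degenerate mapping regions — fewer than 8 voxels, or any axis with a single
distinct coordinate — are rejected rather than fitted with a collapsed
bound, since a 3-D isotropic model is meaningless on a plane.

Prediction projects mapping activity through the fitted weights and
z-scores the result; fit evaluation compares the matched correlation
distribution (each voxel's data against its own prediction) with the
mismatched one (against every other voxel's prediction).

## Rank linearity and its null

The three fitted location parameters and the three seed voxel coordinates
are rank-transformed per axis (average ranks for ties), and the similarity
transform (translation + rotation/reflection + global scale) minimising the
normalised SSE between the two rank point sets is found by Procrustes
analysis; linearity is 1 − SSE.  Ranking both sides makes the statistic
invariant to any strictly monotone per-axis distortion of the fitted
centers, which is what "rank" linearity should mean; it also gives the
statistic its clean combinatorial null.  Internally linearity is a
proportion; user-facing tables report percentages.

Under the null of no spatial organisation, the probability that a voxel's
rank matches its spatial rank in a V-voxel region is 1/V, so the expected
linearity is 1/V.  Spatial smoothness reduces the number of independent
observations to the resel count `R = V / FWHM³`, giving expectation `1/R`.
Two conventions required a decision:

* **Binomial support.** Inference uses Bin(n = round(R), p = 1/R): the
  trials of the implied binomial are the *independent* spatial observations,
  which is R, not V.  At FWHM = 1 the two coincide (R = V).  Using n = V
  with p = 1/R makes the interval shrink with smoothing while the actual
  null spread grows, and Monte Carlo shows the simulated null mean falls
  outside such an interval already at FWHM 2 on a 9×9×9 region, whereas the
  resel-count binomial brackets the simulations at all smoothness levels the
  package calibrates (FWHM 1–2 on 9³ and 5³ regions).
* **Count convention.** An observed linearity L maps to the count
  `floor(L·n)` — only fully achieved successes are counted — and the
  p-value is the upper binomial tail at that count.  The floor is the
  conservative choice: on 9×9×9 permutation nulls the resulting 95%
  threshold rejects ~6% of null replicates, where rounding would reject
  ~11%.

The Procrustes complement is a continuous statistic being referred to a
discrete binomial, so the null is approximate by construction; empirically
the simulated null mean runs roughly twice 1/R (cross-terms of the
Procrustes scale absorb some chance alignment), which the binomial interval
absorbs at moderate smoothness.  Regions with R ≤ 10 resels are flagged
(`low_resel_flag`) and their p-values should not be trusted — the
approximation visibly degrades there.

**Smoothness estimation.** FWHM is estimated from the data: each time frame
is standardised over the mask, the lag-1 spatial autocorrelation ρ is pooled
from first differences between in-mask neighbours per axis, and converted to
a Gaussian-kernel FWHM via `sqrt(−2 ln 2 / ln ρ)`.  The intrinsic 1-voxel
sampling resolution is added in quadrature, so spatially independent data
report FWHM = 1 (the natural floor for resel counting on a discrete grid);
axes too thin to difference are excluded with a warning.  Smoothness is
estimated on the *seed* region, since the null concerns the assignment of
seed ranks.  The synthetic generator uses the mirrored convention — a target
effective FWHM F is produced by a kernel of `sqrt(F² − 1)` FWHM on a padded
grid that is cropped, so region edges carry interior smoothness — making
generator and estimator mutually consistent.

## Convergence

The fitted centers are compared with the uniform distribution over the
mapping region's *discrete voxel set* (not its bounding box, so irregular
region shapes do not inflate deviance) using the orthant-CDF
(Peacock-style) 3-D Kolmogorov–Smirnov statistic: the maximum absolute
difference between sample and reference cumulative fractions over all 8
orthant orderings, evaluated at the sample points.  The statistic is
reported as the ratio to its Monte-Carlo critical value at α = 0.05 for the
same sample size and mapping geometry (default 999 null draws), so
`corrected > 1` marks significant convergence on a scale comparable across
region sizes.  The ratio form was chosen over subtraction for exactly that
comparability.  The critical value can be precomputed and reused when many
maps share a geometry.

## Phantoms

`generate_phantom` builds a mapping region of independent standard-normal
source series (optionally spatially smoothed per frame), and seed voxels as
Gaussian-weighted mixtures of those sources under a planted scheme:
`topographic` (affine map of the seed lattice onto the mapping lattice),
`convergent` (one common locus with sub-voxel Gaussian scatter, SD 0.5
voxels by default — literally identical seed signals would be annihilated by
the default region-mean removal, which no real convergent region is subject
to), or `null` (uniform random centers).  White noise is added per seed
voxel with variance scaled to the realised signal variance so the SNR
(signal/noise variance ratio) is met exactly.  Source smoothness and seed
SNR are independent dials, so the smoothness-driven linearity null and the
SNR-driven fitting difficulty can be varied orthogonally.  Defaults: 818
frames (one long resting-state session); validation studies scale down to
300 frames, which keeps every study within minutes on one CPU.

The phantoms emulate the *statistical* structure the metrics assume —
linear mixing, stationary Gaussian noise, controllable spatial
correlation — and deliberately omit hemodynamics, physiological noise,
motion, and cortical folding geometry.  Passing phantom recovery therefore
validates the estimators and their nulls, not robustness to those real-data
nuisances.

## Parcel-level analyses

Pairwise linearity is directed (seed → mapping ≠ mapping → seed); matrices
are stored directed and symmetrized (mean of the two directions) only where
a method needs a distance (graphs, MDS).  Parcels below 4 voxels are kept in
the output with an error note, never dropped silently.  The topography graph
draws an undirected edge when either direction exceeds the threshold
(default 20% linearity) and lays nodes out with classical MDS.

Gradient decomposition runs nonmetric MDS (stress minimisation with
monotone regression) on 1 − symmetrized linearity, with a fixed seed and 8
random restarts per candidate mode count; the fit curve is the Spearman
correlation between embedded and observed distances.  The mode count is the
elbow of that curve — the point after which the incremental gain collapses,
located at the most negative discrete second difference — and can be
overridden by configuration.  Mode signs are fixed deterministically (the
largest-magnitude score on each mode is positive); embeddings are identified
only up to rotation within tied modes, so cross-run comparisons should use
embedded distances or absolute correlations.

Task-map regression z-scores all predictors and the response over the
analysed parcel set, so the intercept is 0 by construction and coefficients
are standardized betas; rank-deficient designs are rejected with the
offending columns named.

## Validation studies and problem sizes

`topofield.validation` packages seven self-contained studies (also run by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`):

1. permutation-null calibration of rank linearity (9×9×9, 1000 replicates);
2. the resel smoothness model at FWHM ∈ {1, 1.5, 2} on 9³ and 5³ regions
   (300 replicates each);
3. Gaussian parameter recovery at SNR 2, σ ∈ [1, 4], 216 seed voxels, 300
   frames, with a brute-force grid-search oracle on 20 profiles (center
   agreement within one voxel; σ agreement within one 0.25 grid step,
   evaluated at the optimiser's own center because the integer-center grid's
   jointly best σ compensates for sub-voxel center offsets; the optimiser's
   objective may never exceed the grid optimum);
4. topographic versus convergent phantom detection;
5. matched/mismatched prediction validity (100 seed voxels);
6. coverage of the convergence null (500 replicates against a 1999-draw
   critical value);
7. gradient machinery: elbow selection on exact 2-D latent structure, block
   separation on mode 1, and recovery of a planted standardized regression
   coefficient of 0.55 — assessed as 95%-CI *coverage* over 100 noise
   replicates, since any single draw misses its interval 5% of the time by
   construction.

## Known limitations

* Single isotropic Gaussian per seed voxel: multi-peaked or anisotropic
  connectivity profiles are summarised by their dominant blob.
* The binomial null for rank linearity is an approximation; resels ≤ 10 is
  a flag, not a correction.
* Volumetric only: topography along a folded cortical sheet is measured in
  3-D space and is influenced by folding; vector fields help visualise, but
  no surface model is used.
* Inputs are assumed fully preprocessed (motion, nuisance, filtering);
  the package performs no preprocessing beyond region-mean removal.
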