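"""Synthetic phantoms with known connectivity structure.

The generators produce volumetric time-series pairs (seed region, mapping
region) in which every seed voxel's signal is a Gaussian-weighted mixture of
mapping-region source signals under a chosen connectivity scheme:

* ``topographic`` — field centers follow an affine map of the seed lattice
  onto the mapping lattice (an idealised topographically organised
  projection, the analogue of retinotopic connectivity);
* ``convergent`` — every seed voxel connects to one common locus;
* ``null`` — centers are drawn uniformly at random over the mapping region.

Source smoothness (spatial FWHM of the mapping signals) and seed-level
noise (SNR, a variance ratio) are controlled independently, so the
smoothness-driven null of the linearity statistic and the SNR-driven
difficulty of field fitting can be varied orthogonally.  All generators are
pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .confield import gaussian_weights
from .volumes_io import RegionMask, RegionTimeSeries, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_random_volume",
    "generate_block_linearity_matrix",
]

_FWHM_PER_SD = np.sqrt(8.0 * np.log(2.0))

#: Default number of time frames: one long resting-state session.
DEFAULT_N_TIMEPOINTS = 818


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic seed/mapping region pair."""

    seed_shape: tuple[int, int, int] = (6, 6, 6)
    map_shape: tuple[int, int, int] = (9, 9, 9)
    scheme: Literal["topographic", "convergent", "null"] = "topographic"
    sigma_true: float | tuple[float, float] = 2.0
    n_timepoints: int = DEFAULT_N_TIMEPOINTS
    snr: float = 10.0
    smooth_fwhm: float = 0.0
    locus: tuple[float, float, float] | None = None
    locus_jitter: float = 0.5
    seed_rng: int = 0

    def __post_init__(self):
        for name in ("seed_shape", "map_shape"):
            shape = tuple(int(s) for s in getattr(self, name))
            if len(shape) != 3 or any(s < 4 for s in shape):
                raise ValueError(f"{name} must have >= 4 voxels per axis")
            object.__setattr__(self, name, shape)
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.smooth_fwhm < 0:
            raise ValueError("smooth_fwhm must be non-negative")
        if self.n_timepoints < 3:
            raise ValueError("need >= 3 timepoints")

    def to_dict(self) -> dict:
        return {
            "seed_shape": list(self.seed_shape),
            "map_shape": list(self.map_shape),
            "scheme": self.scheme,
            "sigma_true": list(self.sigma_true)
            if isinstance(self.sigma_true, (tuple, list))
            else self.sigma_true,
            "n_timepoints": self.n_timepoints,
            "snr": self.snr,
            "smooth_fwhm": self.smooth_fwhm,
            "locus": list(self.locus) if self.locus is not None else None,
            "locus_jitter": self.locus_jitter,
            "seed_rng": self.seed_rng,
        }


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth field parameters behind a generated phantom."""

    centers: np.ndarray  # (n_seed, 3), mapping-region voxel coordinates
    sigmas: np.ndarray  # (n_seed,)
    scheme: str


def _full_box_mask(shape: Sequence[int], label: str) -> RegionMask:
    grid = VolumeGrid.isotropic(shape)
    idx = np.indices(tuple(shape)).reshape(3, -1).T
    return RegionMask(grid, idx, label=label)


def _kernel_sd(effective_fwhm: float) -> float:
    """Gaussian kernel SD (voxels) producing the target effective smoothness.

    Effective smoothness combines the smoothing kernel with the intrinsic
    1-voxel sampling resolution in quadrature, so targets <= 1 mean no
    smoothing.
    """
    kernel_fwhm2 = effective_fwhm**2 - 1.0
    if kernel_fwhm2 <= 0:
        return 0.0
    return float(np.sqrt(kernel_fwhm2) / _FWHM_PER_SD)


def generate_random_volume(
    shape: Sequence[int],
    smooth_fwhm: float = 0.0,
    seed_rng: int | np.random.Generator | None = None,
    pad: int = 8,
) -> np.ndarray:
    """Standard-normal 3-D field with a target effective smoothness (FWHM, voxels).

    The field is generated on a padded grid, smoothed, then cropped, so the
    returned region carries the same smoothness at its edges as in its
    interior (as a region embedded in a larger brain volume would).  The
    result is re-standardised to zero mean and unit variance.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError("shape must have >= 2 voxels per axis")
    if smooth_fwhm < 0:
        raise ValueError("smoothing FWHM must be non-negative")
    rng = np.random.default_rng(seed_rng)
    sd = _kernel_sd(smooth_fwhm)
    if sd == 0.0:
        vol = rng.standard_normal(shape)
    else:
        big = tuple(s + 2 * pad for s in shape)
        vol = gaussian_filter(rng.standard_normal(big), sd, mode="constant")
        vol = vol[tuple(slice(pad, pad + s) for s in shape)]
    return (vol - vol.mean()) / vol.std()


def _true_centers(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    seed_idx = np.indices(spec.seed_shape).reshape(3, -1).T.astype(float)
    # canonical mask order (z, y, x lexicographic) must match RegionMask
    order = np.lexsort((seed_idx[:, 0], seed_idx[:, 1], seed_idx[:, 2]))
    seed_idx = seed_idx[order]
    map_hi = np.asarray(spec.map_shape, dtype=float) - 1.0
    if spec.scheme == "topographic":
        seed_hi = np.asarray(spec.seed_shape, dtype=float) - 1.0
        centers = seed_idx / seed_hi * map_hi
    elif spec.scheme == "convergent":
        locus = np.asarray(
            spec.locus if spec.locus is not None else map_hi / 2.0, dtype=float
        )
        if (locus < 0).any() or (locus > map_hi).any():
            raise ValueError(f"convergent locus {locus.tolist()} outside mapping region")
        # sub-voxel scatter around the locus: a convergent projection is
        # tightly clustered, not literally identical, and identical seed
        # signals would be annihilated by region-mean removal
        jitter = rng.normal(0.0, spec.locus_jitter, size=(seed_idx.shape[0], 3))
        centers = np.clip(locus + jitter, 0.0, map_hi)
    elif spec.scheme == "null":
        centers = rng.uniform(0.0, 1.0, size=(seed_idx.shape[0], 3)) * map_hi
    else:
        raise ValueError(f"unknown scheme {spec.scheme!r}")

    if isinstance(spec.sigma_true, (tuple, list)):
        lo, hi = spec.sigma_true
        sigmas = rng.uniform(lo, hi, size=seed_idx.shape[0])
    else:
        sigmas = np.full(seed_idx.shape[0], float(spec.sigma_true))
    if (sigmas <= 0).any():
        raise ValueError("sigma_true must be positive")
    return centers, sigmas


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[RegionTimeSeries, RegionTimeSeries, PhantomTruth]:
    """Generate one seed/mapping time-series pair with known field structure.

    Mapping voxels carry independent standard-normal series, optionally
    spatially smoothed frame by frame to ``spec.smooth_fwhm``.  Each seed
    voxel's series is the Gaussian-weighted sum of the mapping series under
    its true field, plus white noise scaled so that the signal-to-noise
    variance ratio equals ``spec.snr`` exactly on the realised signal.
    """
    rng = np.random.default_rng(spec.seed_rng)
    seed_mask = _full_box_mask(spec.seed_shape, "phantom_seed")
    map_mask = _full_box_mask(spec.map_shape, "phantom_map")
    centers, sigmas = _true_centers(spec, rng)

    n_map = len(map_mask)
    T = spec.n_timepoints
    sd = _kernel_sd(spec.smooth_fwhm)
    if sd == 0.0:
        sources = rng.standard_normal((n_map, T))
    else:
        pad = 8
        big = tuple(s + 2 * pad for s in spec.map_shape)
        frames = rng.standard_normal((T, *big))
        for t in range(T):
            frames[t] = gaussian_filter(frames[t], sd, mode="constant")
        crop = frames[(slice(None), *(slice(pad, pad + s) for s in spec.map_shape))]
        crop /= crop.std()
        idx = map_mask.voxel_indices
        sources = crop[:, idx[:, 0], idx[:, 1], idx[:, 2]].T

    map_coords = map_mask.coords
    weights = np.array(
        [gaussian_weights(c, s, map_coords) for c, s in zip(centers, sigmas)]
    )
    signal = weights @ sources
    sig_sd = signal.std(axis=1, keepdims=True)
    sig_sd[sig_sd < np.finfo(float).tiny] = 1.0
    signal = signal / sig_sd
    noise = rng.standard_normal(signal.shape)
    noise = noise - noise.mean(axis=1, keepdims=True)
    noise /= noise.std(axis=1, keepdims=True)
    seed_data = signal + noise / np.sqrt(spec.snr)

    seed_ts = RegionTimeSeries(mask=seed_mask, data=seed_data, demeaned=False)
    map_ts = RegionTimeSeries(mask=map_mask, data=sources, demeaned=False)
    truth = PhantomTruth(centers=centers, sigmas=sigmas, scheme=spec.scheme)
    return seed_ts, map_ts, truth


def generate_block_linearity_matrix(
    n_parcels: int,
    networks: dict[str, Sequence[int]],
    within: float = 0.4,
    between: float = 0.05,
    noise_sd: float = 0.02,
    seed_rng: int | np.random.Generator | None = None,
):
    """Block-structured pairwise linearity matrix with additive noise.

    ``networks`` maps network names to disjoint parcel index lists covering
    ``range(n_parcels)``.  Within-network entries are ``within``, all others
    ``between``; truncated Gaussian noise is added and the result clipped to
    [0, 1].  Diagonal entries are NaN (self-pairs are undefined).
    """
    from .netgradients import LinearityMatrix

    if n_parcels < 2:
        raise ValueError("need >= 2 parcels")
    if not 0.0 <= between < within <= 1.0:
        raise ValueError("require 0 <= between < within <= 1")
    assigned: list[int] = []
    for members in networks.values():
        assigned.extend(int(i) for i in members)
    if len(assigned) != len(set(assigned)):
        raise ValueError("networks overlap")
    if set(assigned) - set(range(n_parcels)):
        raise ValueError("network members outside parcel range")

    rng = np.random.default_rng(seed_rng)
    values = np.full((n_parcels, n_parcels), between, dtype=float)
    for members in networks.values():
        m = np.asarray(list(members), dtype=int)
        values[np.ix_(m, m)] = within
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, np.nan)
    return LinearityMatrix(parcel_ids=list(range(n_parcels)), values=values)
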