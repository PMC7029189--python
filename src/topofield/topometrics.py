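"""Topography and convergence metrics for connective field maps.

Two complementary summaries of how one region's connectivity is organised
over another:

* **Rank linearity** — how well the rank-ordered fitted field centers can be
  brought onto the rank-ordered seed voxel locations by a similarity
  transform (Procrustes: translation + rotation + global scale).  1 means a
  perfectly preserved (possibly re-oriented) topographic map, values near
  the null expectation mean no map.  Under spatial independence the expected
  linearity of a V-voxel region is 1/V; smoothness reduces the number of
  independent spatial observations to the resel count V / FWHM^3, and the
  null expectation becomes 1/resels with binomial uncertainty on the resel
  count.
* **Convergence** — deviance of the fitted centers from spatial uniformity
  over the mapping region, measured with a 3-D generalisation of the
  Kolmogorov-Smirnov statistic (orthant CDFs, Peacock's construction) and
  reported as the ratio to its Monte-Carlo 5% critical value, so values
  above 1 are significant at alpha = 0.05 for that sample size and mapping
  geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _procrustes
from scipy.stats import binom, rankdata

from .confield import ConnectiveFieldMap
from .volumes_io import RegionMask, RegionTimeSeries

__all__ = [
    "LinearityResult",
    "LinearityNull",
    "ConvergenceResult",
    "VectorField",
    "procrustes_linearity",
    "rank_linearity",
    "estimate_fwhm",
    "linearity_null",
    "ks_statistic_3d",
    "ks_critical_value",
    "convergence",
    "vector_field",
]

#: Rule-of-thumb floor: inference is flagged when the region holds
#: this many resels or fewer.
LOW_RESEL_LIMIT = 10.0

_FWHM_PER_SD = np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class LinearityNull:
    """Null model of rank linearity for a region of V voxels at a given smoothness."""

    n_voxels: int
    fwhm: float
    resels: float
    expected: float
    threshold: float
    low_resel_flag: bool

    @property
    def n_effective(self) -> int:
        """Effective number of independent spatial observations (rounded resels)."""
        return max(2, int(round(min(self.resels, self.n_voxels))))

    def p_value(self, linearity: float) -> float:
        """Upper-tail binomial probability of the observed linearity.

        The observed proportion is converted to a count of effective
        independent observations with ``floor`` (conservative: only fully
        achieved successes are counted).
        """
        n = self.n_effective
        k = int(np.floor(np.clip(linearity, 0.0, 1.0) * n + 1e-9))
        if k <= 0:
            return 1.0
        return float(binom.sf(k - 1, n, min(self.expected, 1.0)))

    def mean_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Binomial central interval for the null mean, as proportions."""
        n = self.n_effective
        a = (1.0 - level) / 2.0
        p = min(self.expected, 1.0)
        return (
            float(binom.ppf(a, n, p) / n),
            float(binom.ppf(1.0 - a, n, p) / n),
        )


def linearity_null(V: int, fwhm: float) -> LinearityNull:
    """Expected rank linearity and significance threshold for a null region.

    ``expected = min(1, fwhm^3 / V) = 1/resels``.  Inference is binomial on
    the effective independent observations: n = round(resels), success
    probability 1/resels; at fwhm = 1 this reduces to Bin(V, 1/V).  The
    threshold is the smallest proportion rejected at the one-sided 5% level.
    """
    if V < 2:
        raise ValueError("need V >= 2 voxels")
    if fwhm < 1.0:
        raise ValueError("fwhm below one voxel is not resolvable")
    resels = V / fwhm**3
    expected = min(1.0, 1.0 / resels)
    flag = resels <= LOW_RESEL_LIMIT * (1.0 + 1e-12)
    if expected >= 1.0:
        warnings.warn(
            f"fwhm^3 = {fwhm ** 3:.1f} exceeds V = {V}: expected linearity capped at 1",
            stacklevel=2,
        )
    n_eff = max(2, int(round(min(resels, V))))
    thr_count = binom.ppf(0.95, n_eff, expected) + 1
    threshold = float(min(thr_count / n_eff, 1.0))
    return LinearityNull(
        n_voxels=int(V),
        fwhm=float(fwhm),
        resels=float(resels),
        expected=float(expected),
        threshold=threshold,
        low_resel_flag=bool(flag),
    )


@dataclass(frozen=True)
class LinearityResult:
    """Rank linearity of a connective field map with its null inference."""

    linearity: float
    n_voxels: int
    fwhm: float
    resels: float
    expected: float
    threshold: float
    p_value: float
    low_resel_flag: bool

    @property
    def percent(self) -> float:
        """Linearity on the percentage scale used in reports."""
        return 100.0 * self.linearity


def _rank_columns(points: np.ndarray) -> np.ndarray:
    return np.column_stack([rankdata(points[:, d]) for d in range(points.shape[1])])


def procrustes_linearity(centers: np.ndarray, seed_coords: np.ndarray) -> float:
    """Complement of the normalised Procrustes SSE between rank-ordered
    fitted centers and rank-ordered seed locations.

    Both point sets are rank-transformed per axis (average ranks for ties),
    then the similarity transform (translation, rotation/reflection, global
    scale) minimising the normalised SSE is found; linearity = 1 - SSE.
    """
    centers = np.asarray(centers, dtype=float)
    seed_coords = np.asarray(seed_coords, dtype=float)
    if centers.shape != seed_coords.shape or centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("centers and seed coordinates must both be (n, 3)")
    if centers.shape[0] < 4:
        raise ValueError("rank linearity needs >= 4 points for a 3-D Procrustes fit")
    X = _rank_columns(seed_coords)
    Y = _rank_columns(centers)
    if np.allclose(Y, Y[0]):
        warnings.warn(
            "all fitted centers identical: Procrustes scale degenerate, linearity = 0",
            stacklevel=2,
        )
        return 0.0
    _, _, disparity = _procrustes(X, Y)
    return float(np.clip(1.0 - disparity, 0.0, 1.0))


def rank_linearity(cfm: ConnectiveFieldMap, fwhm: float = 1.0) -> LinearityResult:
    """Topography score of a fitted connective field map, with null inference.

    ``fwhm`` is the estimated spatial smoothness of the seed region's data in
    voxels (1 = spatially independent); it calibrates the null expectation
    through the resel count.
    """
    centers = cfm.centers()
    seeds = cfm.seed_coords()
    lin = procrustes_linearity(centers, seeds)
    null = linearity_null(centers.shape[0], fwhm)
    return LinearityResult(
        linearity=lin,
        n_voxels=centers.shape[0],
        fwhm=null.fwhm,
        resels=null.resels,
        expected=null.expected,
        threshold=null.threshold,
        p_value=null.p_value(lin),
        low_resel_flag=null.low_resel_flag,
    )


def _volume_with_nan(ts: RegionTimeSeries) -> np.ndarray:
    """(T, nx, ny, nz) stack of the region's data, NaN outside the mask."""
    vol = np.full((ts.n_timepoints, *ts.mask.grid.shape), np.nan)
    idx = ts.mask.voxel_indices
    vol[:, idx[:, 0], idx[:, 1], idx[:, 2]] = ts.data.T
    return vol


def estimate_fwhm(ts: RegionTimeSeries) -> float:
    """Spatial smoothness (FWHM, voxels) of a region's data.

    Random-field-style estimator: each time frame is standardised over the
    mask, the lag-1 spatial autocorrelation is pooled from first differences
    between in-mask neighbours per axis, and converted to a Gaussian-kernel
    FWHM.  The intrinsic 1-voxel sampling resolution is added in quadrature,
    so spatially independent data return 1.0.  The three axis estimates are
    combined by geometric mean.
    """
    if ts.n_timepoints < 10:
        raise ValueError("smoothness estimation needs >= 10 timepoints")
    data = ts.data
    sd = data.std(axis=1)
    if np.all(sd < np.finfo(float).tiny):
        raise ValueError("constant data: spatial variance undefined")
    vol = _volume_with_nan(ts)
    # standardise each frame over the mask
    flat = vol.reshape(vol.shape[0], -1)
    mu = np.nanmean(flat, axis=1, keepdims=True)
    s = np.nanstd(flat, axis=1, keepdims=True)
    if np.any(s < np.finfo(float).tiny):
        raise ValueError("a time frame is spatially constant; smoothness undefined")
    vol = ((flat - mu) / s).reshape(vol.shape)

    fwhms = []
    for axis in range(3):
        d = np.diff(vol, axis=axis + 1)
        d = d[np.isfinite(d)]
        if d.size < vol.shape[0]:  # too few neighbour pairs along this axis
            warnings.warn(f"axis {axis} too thin for smoothness estimation; skipped",
                          stacklevel=2)
            continue
        rho = 1.0 - d.var() / 2.0  # frames are unit variance
        if rho <= 0.0:
            kernel = 0.0
        else:
            kernel = float(np.sqrt(-2.0 * np.log(2.0) / np.log(rho)))
        fwhms.append(np.sqrt(kernel**2 + 1.0))
    if not fwhms:
        raise ValueError("no axis had enough voxels for smoothness estimation")
    return float(np.exp(np.mean(np.log(fwhms))))


# ---------------------------------------------------------------------------
# convergence: 3-D Kolmogorov-Smirnov deviance from uniformity


def _orthant_cdf_max_diff(
    evals: np.ndarray, sample: np.ndarray, reference: np.ndarray
) -> float:
    """Max |F_sample - F_reference| over all 8 orthant orderings, evaluated
    at the given points (Peacock's multidimensional KS construction)."""
    best = 0.0
    for sx in (True, False):
        for sy in (True, False):
            for sz in (True, False):
                ops = (sx, sy, sz)

                def frac(pts: np.ndarray) -> np.ndarray:
                    inside = np.ones((evals.shape[0], pts.shape[0]), dtype=bool)
                    for d, le in enumerate(ops):
                        if le:
                            inside &= pts[np.newaxis, :, d] <= evals[:, np.newaxis, d]
                        else:
                            inside &= pts[np.newaxis, :, d] >= evals[:, np.newaxis, d]
                    return inside.mean(axis=1)

                diff = np.abs(frac(sample) - frac(reference))
                best = max(best, float(diff.max()))
    return best


def ks_statistic_3d(sample: np.ndarray, reference: np.ndarray) -> float:
    """3-D KS deviance of ``sample`` from the empirical distribution of
    ``reference`` (here: the uniform distribution over a mapping region's
    voxel set), evaluated at the sample points over all 8 orthant orderings."""
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if sample.shape[1] != 3 or reference.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    return _orthant_cdf_max_diff(sample, sample, reference)


def ks_critical_value(
    map_mask: RegionMask,
    n_sample: int,
    n_null: int = 999,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo critical value of the 3-D KS statistic at the given alpha
    for samples of ``n_sample`` centers uniform on the mapping voxel set."""
    if n_null < 199:
        raise ValueError("n_null >= 199 is required for a stable 5% critical value")
    rng = np.random.default_rng(rng)
    ref = map_mask.coords
    stats = np.empty(n_null)
    for i in range(n_null):
        draw = ref[rng.integers(0, ref.shape[0], size=n_sample)]
        stats[i] = ks_statistic_3d(draw, ref)
    return float(np.quantile(stats, 1.0 - alpha))


@dataclass(frozen=True)
class ConvergenceResult:
    """3-D KS deviance from uniformity, scaled by its 5% critical value."""

    ks_stat: float
    ks_critical_05: float

    @property
    def corrected(self) -> float:
        return self.ks_stat / self.ks_critical_05


def convergence(
    cfm: ConnectiveFieldMap,
    n_null: int = 999,
    rng: np.random.Generator | int | None = None,
    critical: float | None = None,
) -> ConvergenceResult:
    """Convergence of a connective field map onto few mapping loci.

    The fitted centers are compared with the uniform distribution over the
    mapping region's voxels; the statistic is reported as the ratio to its
    Monte-Carlo alpha = 0.05 critical value (``corrected`` > 1 is significant
    convergence).  Pass ``critical`` to reuse a precomputed critical value
    for the same sample size and mapping geometry.
    """
    centers = cfm.centers()
    if centers.shape[0] < 4:
        raise ValueError("convergence needs >= 4 non-degenerate fields")
    ref = cfm.map_mask.coords
    if ref.shape[0] < centers.shape[0]:
        raise ValueError("mapping region smaller than the center sample")
    ks = ks_statistic_3d(centers, ref)
    if critical is None:
        critical = ks_critical_value(cfm.map_mask, centers.shape[0], n_null, rng)
    return ConvergenceResult(ks_stat=ks, ks_critical_05=float(critical))


@dataclass(frozen=True)
class VectorField:
    """Per-seed-voxel arrows from seed locations toward fitted centers,
    expressed relative to the mapping region's center of mass."""

    origins: np.ndarray
    vectors: np.ndarray

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            np.hstack([self.origins, self.vectors, self.norms[:, np.newaxis]]),
            columns=["i", "j", "k", "vx", "vy", "vz", "norm"],
        )
        return df


def vector_field(cfm: ConnectiveFieldMap) -> VectorField:
    """Vector-field summary of a connective field map (degenerate fits excluded)."""
    fields = cfm.valid_fields()
    if not fields:
        raise ValueError("no non-degenerate fields to summarise")
    centroid = cfm.map_mask.coords.mean(axis=0)
    origins = np.array([f.seed_voxel for f in fields], dtype=float)
    vectors = np.array([f.center for f in fields]) - centroid
    return VectorField(origins=origins, vectors=vectors)
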