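"""Parcel-level topography analysis: all-pairs linearity, network contrasts,
topography graphs, gradient decomposition, and task-map regression.

The unit of analysis moves from voxels to parcels: for every ordered pair of
parcels, connective fields are fitted seed -> mapping and summarised by rank
linearity, producing a directed parcel-by-parcel linearity matrix.  Higher
order structure is read out of that matrix three ways: block contrasts
(within- versus between-network linearity), a thresholded graph, and a
nonmetric multidimensional-scaling embedding of 1 - linearity distances
whose modes are smooth gradients of topographic connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_rel
from sklearn.manifold import MDS

from . import confield, topometrics
from .volumes_io import RegionMask, VolumeGrid, extract_region, masks_from_parcellation, remove_region_mean

__all__ = [
    "LinearityMatrix",
    "GradientSolution",
    "pairwise_linearity",
    "network_contrast",
    "topography_graph",
    "classical_mds",
    "gradient_decomposition",
    "task_map_regression",
]

logger = logging.getLogger(__name__)

#: Published default edge threshold for the topography graph (20% linearity).
GRAPH_THRESHOLD = 0.20


@dataclass
class LinearityMatrix:
    """Directed parcel-by-parcel rank linearity (seed rows -> mapping columns).

    The diagonal is NaN (self-pairs are undefined); the matrix is not assumed
    symmetric.  ``stats`` optionally carries the long-form per-pair table
    (p-values, resels, flags)."""

    parcel_ids: list[int]
    values: np.ndarray
    stats: pd.DataFrame | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.parcel_ids)
        if v.shape != (n, n):
            raise ValueError("values must be square and match parcel_ids")
        off = ~np.eye(n, dtype=bool)
        finite = v[off][np.isfinite(v[off])]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("off-diagonal linearity values must lie in [0, 1]")
        self.values = v

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def symmetrized(self) -> np.ndarray:
        """Mean of the two directed values per pair."""
        return (self.values + self.values.T) / 2.0

    def to_long_frame(self) -> pd.DataFrame:
        if self.stats is not None:
            return self.stats.copy()
        rows = []
        for a, pa in enumerate(self.parcel_ids):
            for b, pb in enumerate(self.parcel_ids):
                if a == b:
                    continue
                rows.append({"seed_id": pa, "map_id": pb, "linearity": self.values[a, b]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.parcel_ids, columns=self.parcel_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LinearityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(parcel_ids=[int(i) for i in df.index], values=df.to_numpy(dtype=float))


def pairwise_linearity(
    parcellation: np.ndarray,
    data4d: np.ndarray,
    grid: VolumeGrid,
    parcel_subset: list[int] | None = None,
    demean: bool = True,
    fwhm: float | str = "estimate",
    min_voxels: int = 4,
) -> LinearityMatrix:
    """Rank linearity of connectivity between all ordered parcel pairs.

    For each ordered pair (seed, mapping), connective fields are fitted for
    every seed voxel and summarised by rank linearity with its resel-null
    inference.  ``fwhm='estimate'`` estimates each seed parcel's spatial
    smoothness from its own data; a float fixes it.  Parcels smaller than
    ``min_voxels`` are kept in the output with NaN values and an error note
    rather than dropped silently.
    """
    masks = masks_from_parcellation(parcellation, grid, ids=parcel_subset)
    ids = sorted(masks)
    if len(ids) < 2:
        raise ValueError("need at least 2 parcels")

    ts: dict[int, object] = {}
    fwhms: dict[int, float] = {}
    too_small: set[int] = set()
    for pid in ids:
        if len(masks[pid]) < min_voxels:
            too_small.add(pid)
            logger.warning("parcel %d has %d voxels (< %d): pairs recorded as NaN",
                           pid, len(masks[pid]), min_voxels)
            continue
        t = extract_region(data4d, grid, masks[pid])
        ts[pid] = remove_region_mean(t) if demean else t
        if fwhm == "estimate":
            try:
                fwhms[pid] = topometrics.estimate_fwhm(ts[pid])
            except ValueError:
                fwhms[pid] = 1.0
        else:
            fwhms[pid] = float(fwhm)

    n = len(ids)
    values = np.full((n, n), np.nan)
    rows = []
    for a, pa in enumerate(ids):
        for b, pb in enumerate(ids):
            if a == b:
                continue
            if pa in too_small or pb in too_small:
                rows.append({"seed_id": pa, "map_id": pb, "linearity": np.nan,
                             "error": "parcel below minimum voxel count"})
                continue
            cfm = confield.fit_connective_field_map(ts[pa], ts[pb])
            res = topometrics.rank_linearity(cfm, fwhm=fwhms[pa])
            values[a, b] = res.linearity
            rows.append({
                "seed_id": pa, "map_id": pb, "linearity": res.linearity,
                "expected": res.expected, "p_value": res.p_value,
                "resels": res.resels, "fwhm": res.fwhm,
                "low_resel_flag": res.low_resel_flag, "error": "",
            })
    return LinearityMatrix(parcel_ids=ids, values=values, stats=pd.DataFrame(rows))


def network_contrast(
    lms: "LinearityMatrix | list[LinearityMatrix]",
    labels: pd.DataFrame,
    networks: list[str],
) -> pd.DataFrame:
    """Within- versus between-network linearity, with a paired test across subjects.

    ``lms`` is one matrix (single subject: means only) or one matrix per
    subject (paired t-test of within vs between means per network).
    ``labels`` maps ``parcel_id`` to ``network``.
    """
    if isinstance(lms, LinearityMatrix):
        lms = [lms]
    if not lms:
        raise ValueError("no linearity matrices given")
    assign = dict(zip(labels["parcel_id"].astype(int), labels["network"]))
    results = []
    for net in networks:
        members = [p for p, nm in assign.items() if nm == net]
        if not members:
            raise ValueError(f"network {net!r} absent from the label table")
        within_means, between_means = [], []
        for lm in lms:
            pos = {p: i for i, p in enumerate(lm.parcel_ids)}
            midx = [pos[p] for p in members if p in pos]
            if len(midx) < 2:
                raise ValueError(f"network {net!r} has < 2 parcels in the matrix")
            oidx = [i for i in range(lm.n_parcels) if i not in set(midx)]
            w = lm.values[np.ix_(midx, midx)]
            w = w[np.isfinite(w)]
            b = np.concatenate([
                lm.values[np.ix_(midx, oidx)].ravel(),
                lm.values[np.ix_(oidx, midx)].ravel(),
            ])
            b = b[np.isfinite(b)]
            within_means.append(w.mean())
            between_means.append(b.mean())
        row = {
            "network": net,
            "n_subjects": len(lms),
            "within_mean": float(np.mean(within_means)),
            "between_mean": float(np.mean(between_means)),
        }
        if len(lms) >= 2:
            diffs = np.asarray(within_means) - np.asarray(between_means)
            if np.allclose(diffs, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = ttest_rel(within_means, between_means)
            row.update(t_stat=float(t), p_value=float(p))
        else:
            logger.info("single subject: paired test skipped for network %s", net)
            row.update(t_stat=np.nan, p_value=np.nan)
        results.append(row)
    return pd.DataFrame(results)


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: eigendecomposition of the double-centered
    squared-distance matrix."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def topography_graph(
    lm: LinearityMatrix, threshold: float = GRAPH_THRESHOLD
) -> "networkx.Graph":
    """Thresholded topography graph with classical-MDS layout.

    An undirected edge joins two parcels when either directed linearity
    exceeds ``threshold`` (default 20%).  Node attributes: ``degree`` and 2-D
    ``pos`` from classical MDS of 1 - symmetrized linearity.
    """
    import networkx as nx

    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    sym = lm.symmetrized()
    g = nx.Graph()
    g.add_nodes_from(lm.parcel_ids)
    for a in range(lm.n_parcels):
        for b in range(a + 1, lm.n_parcels):
            w = np.nanmax([lm.values[a, b], lm.values[b, a]])
            if np.isfinite(w) and w > threshold:
                g.add_edge(lm.parcel_ids[a], lm.parcel_ids[b], weight=float(w))
    if g.number_of_edges() == 0:
        warnings.warn(f"no pair exceeds the {threshold:.0%} linearity threshold",
                      stacklevel=2)
    dist = 1.0 - np.nan_to_num(sym, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    pos = classical_mds(dist, 2)
    for i, pid in enumerate(lm.parcel_ids):
        g.nodes[pid]["pos"] = (float(pos[i, 0]), float(pos[i, 1]))
        g.nodes[pid]["degree"] = g.degree[pid]
    return g


@dataclass(frozen=True)
class GradientSolution:
    """Nonmetric-MDS embedding of a linearity-derived distance matrix."""

    n_modes: int
    scores: np.ndarray  # (n_parcels, n_modes), zero mean per mode
    fit_curve: np.ndarray  # Spearman(embedded dist, observed dist) per candidate m
    stress: np.ndarray  # final stress per candidate m

    @property
    def max_modes(self) -> int:
        return len(self.fit_curve)


def _embed_nmds(dist: np.ndarray, m: int, seed: int, n_init: int) -> tuple[np.ndarray, float]:
    common = dict(n_components=m, n_init=n_init, random_state=seed, max_iter=500)
    try:  # scikit-learn >= 1.9 parameter names
        mds = MDS(metric="precomputed", metric_mds=False, init="random", **common)
    except TypeError:
        mds = MDS(metric=False, dissimilarity="precomputed",
                  normalized_stress=True, **common)
    emb = mds.fit_transform(dist)
    return emb, float(mds.stress_)


def select_elbow(fit_curve: np.ndarray) -> int:
    """Elbow of a goodness-of-fit curve: the mode count after which the
    incremental gain collapses (largest-magnitude discrete second difference,
    i.e. the largest drop between successive gains)."""
    f = np.asarray(fit_curve, dtype=float)
    if f.size < 3:
        return int(f.size)
    second = f[2:] - 2.0 * f[1:-1] + f[:-2]  # index i -> mode i+2
    return int(np.argmin(second)) + 2


def gradient_decomposition(
    lm: LinearityMatrix,
    max_modes: int = 5,
    seed: int = 0,
    n_init: int = 8,
    n_modes: int | None = None,
) -> GradientSolution:
    """Gradients of topographic connectivity by nonmetric MDS.

    The directed linearity matrix is symmetrized (mean of the two
    directions) and converted to distances 1 - linearity.  For each
    candidate mode count the best nonmetric-MDS embedding over ``n_init``
    random restarts is kept; the fit curve is the Spearman correlation
    between embedded and observed distances.  The mode count is chosen by
    the elbow rule unless ``n_modes`` overrides it.
    """
    if lm.n_parcels < 5:
        raise ValueError("gradient decomposition needs >= 5 parcels")
    sym = lm.symmetrized()
    dist = 1.0 - sym
    np.fill_diagonal(dist, 0.0)
    if not np.isfinite(dist).all():
        bad = np.argwhere(~np.isfinite(dist))
        pairs = [(lm.parcel_ids[a], lm.parcel_ids[b]) for a, b in bad[:10]]
        raise ValueError(f"non-finite distances for parcel pairs {pairs}")
    tri = dist[np.triu_indices_from(dist, k=1)]
    if np.ptp(tri) < 1e-12:
        raise ValueError("all pairwise distances equal: embedding is degenerate")

    fit_curve = np.empty(max_modes)
    stresses = np.empty(max_modes)
    embeddings = []
    for m in range(1, max_modes + 1):
        emb, stress = _embed_nmds(dist, m, seed, n_init)
        emb_d = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=2)
        rho = spearmanr(tri, emb_d[np.triu_indices_from(emb_d, k=1)]).statistic
        fit_curve[m - 1] = rho
        stresses[m - 1] = stress
        embeddings.append(emb)

    chosen = int(n_modes) if n_modes is not None else select_elbow(fit_curve)
    chosen = max(1, min(chosen, max_modes))
    scores = embeddings[chosen - 1].copy()
    scores -= scores.mean(axis=0, keepdims=True)
    # deterministic sign: the largest-magnitude score on each mode is positive
    for j in range(scores.shape[1]):
        k = int(np.argmax(np.abs(scores[:, j])))
        if scores[k, j] < 0:
            scores[:, j] *= -1.0
    return GradientSolution(
        n_modes=chosen, scores=scores, fit_curve=fit_curve, stress=stresses
    )


def task_map_regression(
    gradients: GradientSolution | np.ndarray,
    convergence: np.ndarray,
    task_map: np.ndarray,
) -> dict:
    """Regress a per-parcel task contrast on topographic gradients + convergence.

    All predictors and the response are z-scored over the analysed parcel
    set, so the intercept is 0 and coefficients are standardized betas.
    Returns the coefficient table (beta, SE, t, p) and the model R^2.
    """
    import statsmodels.api as sm

    scores = gradients.scores if isinstance(gradients, GradientSolution) else np.asarray(gradients)
    scores = np.atleast_2d(scores)
    if scores.shape[0] < scores.shape[1]:
        scores = scores.T
    convergence = np.asarray(convergence, dtype=float).ravel()
    y = np.asarray(task_map, dtype=float).ravel()
    n = y.size
    if scores.shape[0] != n or convergence.size != n:
        raise ValueError("gradients, convergence, and task map must align per parcel")

    X = np.column_stack([scores, convergence])
    names = [f"gradient_{j + 1}" for j in range(scores.shape[1])] + ["convergence"]

    def z(v):
        sd = v.std(ddof=0)
        if sd < np.finfo(float).tiny:
            raise ValueError("constant column cannot be standardized")
        return (v - v.mean()) / sd

    Xz = np.column_stack([z(X[:, j]) for j in range(X.shape[1])])
    yz = z(y)
    rank = np.linalg.matrix_rank(Xz)
    if rank < Xz.shape[1]:
        corr = np.corrcoef(Xz, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        a, b = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(f"rank-deficient design: columns {names[a]!r} and {names[b]!r} "
                         "are collinear")
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    table = pd.DataFrame({
        "beta": model.params[1:],
        "se": model.bse[1:],
        "t": model.tvalues[1:],
        "p": model.pvalues[1:],
    }, index=names)
    return {
        "table": table,
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "model": model,
    }
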