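"""Parcel-pair linearity, network contrasts, graphs, gradients, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from topofield import netgradients, phantoms
from topofield.confield import gaussian_weights
from topofield.netgradients import (
    LinearityMatrix,
    gradient_decomposition,
    network_contrast,
    pairwise_linearity,
    select_elbow,
    task_map_regression,
    topography_graph,
)
from topofield.volumes_io import VolumeGrid


def _three_parcel_volume(n_t=250, seed=0):
    """Parcellation with topographic coupling 1<->2 and an independent parcel 3.

    Parcels are 5x5x5 blocks along x.  Parcel 2 holds white-noise sources;
    parcel 1 voxels mix them through an identity topographic Gaussian field
    (which also makes parcel 1 spatially smooth, exercising the resel
    correction); parcel 3 is independent noise.
    """
    rng = np.random.default_rng(seed)
    shape = (17, 5, 5)
    grid = VolumeGrid.isotropic(shape)
    labels = np.zeros(shape, dtype=int)
    labels[0:5] = 1
    labels[6:11] = 2
    labels[12:17] = 3
    data = np.zeros((*shape, n_t))

    src = rng.standard_normal((5, 5, 5, n_t))
    data[6:11] = src
    block = np.indices((5, 5, 5)).reshape(3, -1).T.astype(float)
    for v, ijk in enumerate(block):
        w = gaussian_weights(ijk, 0.9, block)
        sig = np.tensordot(w.reshape(5, 5, 5), src, axes=([0, 1, 2], [0, 1, 2]))
        sig /= sig.std()
        i, j, k = ijk.astype(int)
        data[i, j, k] = sig + rng.standard_normal(n_t) / np.sqrt(10.0)
    data[12:17] = rng.standard_normal((5, 5, 5, n_t))
    return labels, data, grid


@pytest.fixture(scope="module")
def parcel_matrix():
    labels, data, grid = _three_parcel_volume()
    return pairwise_linearity(labels, data, grid)


class TestPairwiseLinearity:
    def test_planted_pair_is_significant_and_others_are_not(self, parcel_matrix):
        lm = parcel_matrix
        stats = lm.stats.set_index(["seed_id", "map_id"])
        assert stats.loc[(1, 2), "linearity"] > stats.loc[(1, 2), "expected"]
        assert stats.loc[(1, 2), "p_value"] < 0.05
        assert stats.loc[(2, 1), "p_value"] < 0.05
        for pair in [(1, 3), (3, 1), (2, 3), (3, 2)]:
            assert stats.loc[pair, "p_value"] > 0.05

    def test_subset_gives_square_matrix(self):
        labels, data, grid = _three_parcel_volume(n_t=120, seed=1)
        lm = pairwise_linearity(labels, data, grid, parcel_subset=[1, 3], fwhm=1.0)
        assert lm.values.shape == (2, 2)
        assert lm.parcel_ids == [1, 3]

    def test_tiny_parcel_recorded_not_dropped(self):
        labels, data, grid = _three_parcel_volume(n_t=60, seed=2)
        labels[labels == 3] = 0
        labels[12, 0, 0] = 3
        labels[12, 0, 1] = 3
        labels[12, 0, 2] = 3
        lm = pairwise_linearity(labels, data, grid, fwhm=1.0)
        assert 3 in lm.parcel_ids
        i3 = lm.parcel_ids.index(3)
        assert np.isnan(lm.values[i3, :]).all()
        notes = lm.stats.query("seed_id == 3")["error"]
        assert (notes != "").all()

    def test_label_permutation_permutes_the_matrix(self):
        labels, data, grid = _three_parcel_volume(n_t=120, seed=3)
        lm = pairwise_linearity(labels, data, grid, fwhm=1.0)
        swapped = labels.copy()
        swapped[labels == 1] = 3
        swapped[labels == 3] = 1
        lm_sw = pairwise_linearity(swapped, data, grid, fwhm=1.0)
        # parcel ids are sorted, so swapping labels 1<->3 reverses the order
        assert np.allclose(lm.values[::-1, ::-1], lm_sw.values, equal_nan=True)


class TestNetworkContrast:
    def _labels(self, n):
        half = n // 2
        return pd.DataFrame({
            "parcel_id": range(n),
            "network": ["A"] * half + ["B"] * (n - half),
        })

    def test_planted_within_network_excess_detected(self):
        nets = {"A": list(range(5)), "B": list(range(5, 10))}
        lms = [
            phantoms.generate_block_linearity_matrix(
                10, nets, within=0.4, between=0.05, noise_sd=0.02, seed_rng=s
            )
            for s in range(10)
        ]
        res = network_contrast(lms, self._labels(10), ["A", "B"])
        assert (res["t_stat"] > 0).all()
        assert (res["p_value"] < 0.01).all()
        assert (res["within_mean"] > res["between_mean"]).all()

    def test_detection_power_on_planted_effect(self):
        """A 0.35 within/between contrast over 10 subjects should almost
        always reach significance."""
        nets = {"A": list(range(5)), "B": list(range(5, 10))}
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            lms = [
                phantoms.generate_block_linearity_matrix(
                    10, nets, within=0.4, between=0.05, noise_sd=0.05,
                    seed_rng=1000 * rep + s,
                )
                for s in range(10)
            ]
            res = network_contrast(lms, self._labels(10), ["A"])
            hits += bool(res["p_value"].iloc[0] < 0.05)
        assert hits / n_rep >= 0.9

    def test_identical_within_and_between_gives_zero_t(self):
        values = np.full((6, 6), 0.3)
        np.fill_diagonal(values, np.nan)
        lms = [LinearityMatrix(parcel_ids=list(range(6)), values=values)] * 3
        res = network_contrast(lms, self._labels(6), ["A"])
        assert res["t_stat"].iloc[0] == 0.0

    def test_single_subject_reports_means_without_test(self):
        lm = phantoms.generate_block_linearity_matrix(
            6, {"A": [0, 1, 2], "B": [3, 4, 5]}, seed_rng=0
        )
        res = network_contrast(lm, self._labels(6), ["A"])
        assert np.isnan(res["t_stat"].iloc[0])
        assert res["within_mean"].iloc[0] > res["between_mean"].iloc[0]

    def test_unknown_network_rejected(self):
        lm = phantoms.generate_block_linearity_matrix(
            6, {"A": [0, 1, 2], "B": [3, 4, 5]}, seed_rng=0
        )
        with pytest.raises(ValueError, match="absent"):
            network_contrast(lm, self._labels(6), ["C"])


class TestTopographyGraph:
    def test_single_suprathreshold_pair(self):
        values = np.full((4, 4), 0.05)
        values[0, 1] = values[1, 0] = 0.5
        np.fill_diagonal(values, np.nan)
        lm = LinearityMatrix(parcel_ids=[10, 11, 12, 13], values=values)
        g = topography_graph(lm, threshold=0.2)
        assert g.number_of_edges() == 1
        assert g.degree[10] == g.degree[11] == 1
        assert g.degree[12] == 0
        assert "pos" in g.nodes[10]

    def test_default_threshold_is_twenty_percent(self):
        assert netgradients.GRAPH_THRESHOLD == 0.20

    def test_uniform_suprathreshold_matrix_is_complete_with_equal_degree(self):
        values = np.full((5, 5), 0.6)
        np.fill_diagonal(values, np.nan)
        g = topography_graph(LinearityMatrix(parcel_ids=list(range(5)), values=values))
        assert g.number_of_edges() == 10
        assert len({d for _, d in g.degree}) == 1

    def test_unreachable_threshold_warns_empty_graph(self):
        values = np.full((4, 4), 0.1)
        np.fill_diagonal(values, np.nan)
        lm = LinearityMatrix(parcel_ids=list(range(4)), values=values)
        with pytest.warns(UserWarning, match="threshold"):
            g = topography_graph(lm, threshold=1.0)
        assert g.number_of_edges() == 0
        with pytest.raises(ValueError, match="threshold"):
            topography_graph(lm, threshold=0.0)


class TestGradientDecomposition:
    def _latent_matrix(self, n, dim, seed):
        rng = np.random.default_rng(seed)
        latent = rng.uniform(size=(n, dim))
        d = np.linalg.norm(latent[:, None] - latent[None, :], axis=2)
        values = np.clip(1.0 - d / d.max(), 0.0, 1.0)
        np.fill_diagonal(values, np.nan)
        return LinearityMatrix(parcel_ids=list(range(n)), values=values)

    def test_two_dimensional_latent_structure_selects_two_modes(self):
        lm = self._latent_matrix(25, 2, seed=0)
        sol = gradient_decomposition(lm, max_modes=5, seed=0)
        assert sol.n_modes == 2
        assert sol.fit_curve[1] > 0.99

    def test_two_block_matrix_separates_blocks_on_mode_one(self):
        lm = phantoms.generate_block_linearity_matrix(
            12, {"a": list(range(6)), "b": list(range(6, 12))},
            within=0.4, between=0.05, noise_sd=0.02, seed_rng=1,
        )
        sol = gradient_decomposition(lm, max_modes=3, seed=0, n_modes=2)
        mode1 = sol.scores[:, 0]
        signs = np.sign(mode1 - np.median(mode1))
        assert abs(signs[:6].sum()) == 6 and abs(signs[6:].sum()) == 6
        assert np.abs(sol.scores.mean(axis=0)).max() < 1e-9

    def test_parcel_order_invariance_up_to_rotation(self):
        """Permuting parcel order must not change the recovered geometry;
        embedded inter-parcel distances are compared, which are invariant to
        the per-mode sign and rotation ambiguity of MDS."""
        lm = self._latent_matrix(20, 2, seed=2)
        sol = gradient_decomposition(lm, max_modes=3, seed=0, n_modes=2)
        perm = np.random.default_rng(3).permutation(20)
        lm_p = LinearityMatrix(
            parcel_ids=[lm.parcel_ids[i] for i in perm],
            values=lm.values[np.ix_(perm, perm)],
        )
        sol_p = gradient_decomposition(lm_p, max_modes=3, seed=0, n_modes=2)

        def dists(scores):
            return np.linalg.norm(scores[:, None] - scores[None, :], axis=2)

        d = dists(sol.scores[perm])
        d_p = dists(sol_p.scores)
        iu = np.triu_indices(20, 1)
        rho = spearmanr(d[iu], d_p[iu]).statistic
        assert rho >= 0.99

    def test_degenerate_distances_rejected(self):
        values = np.full((6, 6), 0.5)
        np.fill_diagonal(values, np.nan)
        lm = LinearityMatrix(parcel_ids=list(range(6)), values=values)
        with pytest.raises(ValueError, match="equal"):
            gradient_decomposition(lm, max_modes=3)
        with pytest.raises(ValueError, match=">= 5 parcels"):
            gradient_decomposition(
                LinearityMatrix(parcel_ids=[0, 1], values=np.full((2, 2), np.nan)),
                max_modes=2,
            )

    def test_elbow_picks_the_gain_collapse(self):
        assert select_elbow(np.array([0.6, 0.99, 0.995, 0.996, 0.997])) == 2
        assert select_elbow(np.array([0.5, 0.8, 0.99, 0.992, 0.993])) == 3


class TestTaskMapRegression:
    def test_planted_coefficient_recovered_within_ci(self, rng):
        n = 40
        g = rng.standard_normal((n, 2))
        conv = rng.standard_normal(n)
        y = 0.55 * (g[:, 1] - g[:, 1].mean()) / g[:, 1].std() + np.sqrt(
            1 - 0.55**2
        ) * rng.standard_normal(n)
        res = task_map_regression(g, conv, y)
        b = res["table"].loc["gradient_2"]
        assert b.beta - 1.96 * b.se <= 0.55 <= b.beta + 1.96 * b.se

    def test_standardized_design_zeroes_the_intercept(self, rng):
        g = rng.standard_normal((30, 2))
        res = task_map_regression(g, rng.standard_normal(30), rng.standard_normal(30))
        assert abs(res["intercept"]) < 1e-10

    def test_null_response_is_rarely_significant(self):
        rng = np.random.default_rng(11)
        n_sig = 0
        n_rep = 60
        for _ in range(n_rep):
            g = rng.standard_normal((30, 2))
            res = task_map_regression(g, rng.standard_normal(30), rng.standard_normal(30))
            n_sig += bool((res["table"]["p"] < 0.05).any())
        # three predictors at alpha=.05 each: family-wise null rate stays moderate
        assert n_sig / n_rep <= 0.3
        assert res["r_squared"] < 0.5

    def test_collinear_design_names_offenders(self, rng):
        g = rng.standard_normal((20, 2))
        conv = g[:, 0] * 2.0 + 1.0
        with pytest.raises(ValueError, match="collinear"):
            task_map_regression(g, conv, rng.standard_normal(20))
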