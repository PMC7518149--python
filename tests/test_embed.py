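"""Distances, PCA, spectral embedding and the harmonic artifact."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import milkorder as mo
from milkorder.embed import OverlapError, gap_statistic, scaled_pairwise


def rope_qm(make_qm, n=50, d=60, noise=0.02, seed=0):
    """Herd lying on a 1-D latent line: q_ct ~ mu_c + tiny noise."""
    rng = np.random.default_rng(seed)
    mu = np.linspace(0.05, 0.95, n)
    vals = np.clip(mu[:, None] + rng.normal(0, noise, (n, d)), 1e-6, 1.0)
    return make_qm(vals), mu


class TestScaledDistance:
    def test_identical_rows_zero(self, make_qm):
        qm = make_qm(np.tile(np.linspace(0.1, 1, 12), (2, 1)))
        dm = mo.scaled_distance(qm, overlap_min=1)
        assert dm.values.iloc[0, 1] == 0.0

    def test_constant_offset_closed_form(self, make_qm):
        t = 16
        qm = make_qm(np.vstack([np.full(t, 0.4), np.full(t, 0.5)]))
        dm = mo.scaled_distance(qm, overlap_min=1)
        assert dm.values.iloc[0, 1] == pytest.approx(0.1 * np.sqrt(t))

    def test_masking_invariance(self, make_qm):
        t = 20
        a = np.vstack([np.full(t, 0.4), np.full(t, 0.5)])
        full = mo.scaled_distance(make_qm(a), overlap_min=1).values.iloc[0, 1]
        b = a.copy()
        b[0, :10] = np.nan  # half the days masked, difference unchanged
        half = mo.scaled_distance(make_qm(b), overlap_min=1).values.iloc[0, 1]
        assert half == pytest.approx(full, abs=1e-12)

    def test_insufficient_overlap_raises(self, make_qm):
        vals = np.full((2, 10), np.nan)
        vals[0, :5] = 0.5
        vals[1, 5:] = 0.5
        with pytest.raises(OverlapError):
            mo.scaled_distance(make_qm(vals), overlap_min=2)

    def test_symmetric_zero_diagonal(self, small_qm):
        dm = mo.scaled_distance(small_qm, overlap_min=1)
        v = dm.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)


class TestPCACorrelation:
    def test_first_component_recovers_latent_order(self, make_qm):
        qm, mu = rope_qm(make_qm)
        emb = mo.pca_correlation(qm)
        rho = spearmanr(emb.coordinates["pc1"], mu).statistic
        assert abs(rho) >= 0.95

    def test_pure_noise_has_no_dominant_eigenvalue(self, make_qm):
        rng = np.random.default_rng(3)
        qm = make_qm(rng.uniform(0.01, 1.0, (50, 200)))
        emb = mo.pca_correlation(qm)
        assert emb.eigenvalues[0] / emb.eigenvalues.sum() < 0.1

    def test_duplicated_cow_gets_identical_scores(self, make_qm):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.01, 1.0, (10, 15))
        vals[5] = vals[2]
        emb = mo.pca_correlation(make_qm(vals))
        assert np.allclose(
            emb.coordinates.iloc[2].to_numpy(), emb.coordinates.iloc[5].to_numpy()
        )

    def test_zero_variance_day_dropped(self, make_qm):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.01, 1.0, (8, 6))
        vals[:, 3] = 0.5
        with pytest.warns(UserWarning, match="zero-variance"):
            emb = mo.pca_correlation(make_qm(vals))
        assert len(emb.eigenvalues) == 5


class TestSimilarityInvert:
    def _dm(self, d):
        ids = pd.RangeIndex(d.shape[0])
        return mo.DistanceMatrix(
            pd.DataFrame(d, index=ids, columns=ids),
            pd.DataFrame(np.full_like(d, 10, int), index=ids, columns=ids),
            total_days=10,
        )

    def test_reciprocal(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        s = mo.similarity_invert(self._dm(d))
        assert s.iloc[0, 1] == pytest.approx(0.5)

    def test_order_reversal(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0.5, 3.0, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        s = mo.similarity_invert(self._dm(d)).to_numpy()
        off = ~np.eye(6, dtype=bool)
        order_d = np.argsort(d[off])
        order_s = np.argsort(-s[off])
        assert np.array_equal(order_d, order_s)

    def test_all_equal_distances(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        s = mo.similarity_invert(self._dm(d)).to_numpy()
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(s[off], 0.5)

    def test_zero_distance_pair_capped(self):
        d = np.array([[0, 0.0, 2.0], [0.0, 0, 2.0], [2.0, 2.0, 0]])
        s = mo.similarity_invert(self._dm(d))
        assert s.iloc[0, 1] == pytest.approx(5.0)  # 10 x max finite (0.5)


class TestKnnGraph:
    def _sim(self, n, seed=0):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.1, 1.0, (n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0.0)
        return pd.DataFrame(s)

    def test_min_degree_k(self):
        adj = mo.knn_graph(self._sim(20), k=5)
        deg = (adj.to_numpy() > 0).sum(axis=1)
        assert (deg >= 5).all()

    def test_symmetric(self):
        a = mo.knn_graph(self._sim(15), k=4).to_numpy()
        assert np.allclose(a, a.T)

    def test_three_points_k1_links_closest_pairs(self):
        # brute force over the three pairs
        s = pd.DataFrame(
            [[0.0, 0.9, 0.2], [0.9, 0.0, 0.5], [0.2, 0.5, 0.0]]
        )
        adj = mo.knn_graph(s, k=1).to_numpy()
        assert adj[0, 1] > 0 and adj[1, 2] > 0  # each node's best neighbour
        assert adj[0, 2] == 0.0

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            mo.knn_graph(self._sim(5), k=5)


class TestLaplacianEmbedding:
    def test_eigenvalues_within_spectral_bound(self, make_qm):
        qm, _ = rope_qm(make_qm, n=40)
        emb = mo.DiffusionMap(qm, k=6).fit()
        assert emb.eigenvalues.min() >= -1e-9
        assert emb.eigenvalues.max() <= 2 + 1e-9

    def test_chain_recovers_latent_order(self, make_qm):
        qm, mu = rope_qm(make_qm)
        emb = mo.DiffusionMap(qm).fit()
        rho = spearmanr(emb.coordinates["dim1"], mu).statistic
        assert abs(rho) >= 0.9

    def test_permuted_data_has_no_dominant_eigengap(self, make_qm, small_qm):
        # relative eigengap: tiny on a randomised queue, large on real structure
        perm = mo.permute_within_days(small_qm, seed=3)
        emb = mo.DiffusionMap(perm).fit()
        lead = emb.extra["nontrivial_eigenvalues"]
        assert (np.diff(lead) / lead[:-1]).max() < 0.5
        real = mo.DiffusionMap(small_qm).fit()
        lead = real.extra["nontrivial_eigenvalues"]
        assert (np.diff(lead) / lead[:-1]).max() > 1.0

    def test_non_symmetric_rejected(self):
        a = pd.DataFrame(np.arange(9.0).reshape(3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            mo.laplacian_embedding(a)

    @pytest.mark.parametrize("norm", ["unnormalized", "symmetric", "random_walk"])
    def test_geometry_robust_across_laplacians(self, make_qm, norm):
        qm, mu = rope_qm(make_qm, n=40)
        emb = mo.DiffusionMap(qm, normalization=norm).fit()
        rho = spearmanr(emb.coordinates["dim1"], mu).statistic
        assert abs(rho) >= 0.9

    def test_row_shuffle_invariance_via_procrustes(self, make_qm):
        from scipy.spatial import procrustes

        qm, _ = rope_qm(make_qm, n=40)
        emb1 = mo.DiffusionMap(qm).fit()
        rng = np.random.default_rng(1)
        order = rng.permutation(qm.n_cows)
        qm2 = mo.QuantileMatrix(
            qm.values.iloc[order], qm.subperiods.copy(), None, []
        )
        emb2 = mo.DiffusionMap(qm2).fit()
        a = emb1.coordinates.to_numpy()[:, :2]
        b = emb2.coordinates.loc[emb1.coordinates.index].to_numpy()[:, :2]
        _, _, disparity = procrustes(a, b)
        assert disparity < 1e-8


class TestHarmonicReference:
    def test_first_vector_monotone(self):
        v = mo.harmonic_reference(50, 3)
        assert (np.diff(v[:, 0]) < 0).all()

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_sign_changes(self, k):
        v = mo.harmonic_reference(60, 5)[:, k - 1]
        changes = (np.sign(v[:-1]) * np.sign(v[1:]) < 0).sum()
        assert changes == k

    def test_orthonormal_and_matches_path_laplacian(self):
        n, k = 30, 5
        v = mo.harmonic_reference(n, k)
        assert np.allclose(v.T @ v, np.eye(k), atol=1e-10)
        # independent oracle: eigendecompose the tridiagonal path Laplacian
        lap = 2 * np.eye(n) - np.eye(n, k=1) - np.eye(n, k=-1)
        lap[0, 0] = lap[-1, -1] = 1
        evals, evecs = np.linalg.eigh(lap)
        for j in range(k):
            u = evecs[:, j + 1]  # skip the constant eigenvector
            assert abs(abs(u @ v[:, j]) - 1.0) < 1e-10

    def test_embedding_axes_follow_harmonics_on_rope_data(self, make_qm):
        qm, mu = rope_qm(make_qm, n=60)
        emb = mo.DiffusionMap(qm).fit()
        order = np.argsort(emb.coordinates["dim1"].to_numpy())
        ref = mo.harmonic_reference(60, 2)
        for j in range(2):
            c = emb.coordinates.iloc[order, j].to_numpy()
            r = abs(np.corrcoef(c, ref[:, j])[0, 1])
            assert r >= 0.8


def test_gap_statistic_selects_one_cluster_on_rope(make_qm):
    qm, _ = rope_qm(make_qm, n=40)
    emb = mo.DiffusionMap(qm).fit()
    k = gap_statistic(emb.coordinates.to_numpy()[:, :3], k_max=4, seed=0)
    assert k == 1


def test_scaled_pairwise_matches_complete_euclidean(make_qm):
    rng = np.random.default_rng(2)
    x = rng.random((8, 12))
    d, ov = scaled_pairwise(x)
    from scipy.spatial.distance import squareform, pdist

    assert np.allclose(d, squareform(pdist(x)), atol=1e-10)
    assert (ov == 12).all()
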