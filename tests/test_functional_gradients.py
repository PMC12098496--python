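"""Gradient pipeline: affinity construction, embedding, alignment, dispersion."""
import numpy as np
import pytest
from scipy.stats import spearmanr, special_ortho_group

from gradstates.functional_gradients import (
    Embedding,
    build_network_fc,
    cosine_affinity,
    diffusion_embedding,
    embed_subject,
    gradient_dispersion,
    group_template,
    procrustes_align,
    sparsify_rows,
    zscore_gradients,
)
from gradstates.synthetic_cohort import GradientManifoldSpec, simulate_network_voxels


class TestBuildNetworkFC:
    def test_self_correlated_voxel_is_row_maximum_at_clip(self, rng):
        parcels = rng.standard_normal((100, 10))
        voxels = np.column_stack([parcels[:, 3], rng.standard_normal((100, 2))])
        fc = build_network_fc(voxels, parcels)
        assert fc.shape == (3, 10)
        assert fc[0, 3] == pytest.approx(np.arctanh(1 - 1e-7))
        assert fc[0, 3] == fc[0].max()

    def test_independent_noise_rows_near_zero(self, rng):
        fc = build_network_fc(rng.standard_normal((200, 20)),
                              rng.standard_normal((200, 400)))
        assert np.abs(fc.mean(axis=1)).max() < 0.05

    def test_constant_voxel_row_zeroed(self, rng):
        voxels = np.column_stack([np.ones(50), rng.standard_normal(50)])
        fc = build_network_fc(voxels, rng.standard_normal((50, 5)))
        assert np.allclose(fc[0], 0.0)

    def test_mismatched_T_rejected(self, rng):
        with pytest.raises(ValueError, match="share T"):
            build_network_fc(rng.standard_normal((50, 3)),
                             rng.standard_normal((60, 5)))


class TestSparsify:
    def test_exact_retention_count(self, rng):
        out = sparsify_rows(rng.standard_normal((30, 400)), 0.10)
        assert ((out != 0).sum(axis=1) == 40).all()

    def test_density_one_is_identity(self, rng):
        x = rng.standard_normal((5, 20))
        assert np.array_equal(sparsify_rows(x, 1.0), x)

    def test_tie_break_keeps_lowest_column_indices(self):
        out = sparsify_rows(np.ones((2, 400)), 0.10)
        expected = np.zeros((2, 400))
        expected[:, :40] = 1.0
        assert np.array_equal(out, expected)

    def test_keeps_largest_values(self, rng):
        x = rng.standard_normal((10, 100))
        out = sparsify_rows(x, 0.2)
        for i in range(10):
            kept = np.flatnonzero(out[i])
            thresh = np.sort(x[i])[::-1][19]
            assert (x[i, kept] >= thresh).all()


class TestCosineAffinity:
    def test_parallel_and_orthogonal_rows(self):
        m = np.array([[1.0, 2.0, 0.0, 0.0],
                      [2.0, 4.0, 0.0, 0.0],
                      [0.0, 0.0, 3.0, 1.0]])
        A = cosine_affinity(m)
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(A), 1.0)

    def test_matches_brute_force_double_loop(self, rng):
        m = sparsify_rows(rng.standard_normal((100, 400)), 0.10)
        A = cosine_affinity(m)
        n = len(m)
        brute = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                brute[i, j] = (m[i] @ m[j]) / (np.linalg.norm(m[i]) * np.linalg.norm(m[j]))
        np.fill_diagonal(brute, 1.0)
        assert np.max(np.abs(A - brute)) < 1e-10

    def test_zero_row_rejected_with_voxel_index(self):
        m = np.ones((4, 10))
        m[2] = 0.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            cosine_affinity(m)


class TestDiffusionEmbedding:
    def _ring_affinity(self, n=64):
        A = np.zeros((n, n))
        for i in range(n):
            A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
        return A

    def test_ring_graph_first_component_is_sinusoidal(self):
        n = 64
        emb = diffusion_embedding(self._ring_affinity(n), n_components=4)
        comp = emb.components[:, 0]
        t = 2 * np.pi * np.arange(n) / n
        basis = np.column_stack([np.sin(t), np.cos(t)])
        # cosine similarity with the best-phase unit sinusoid = norm of the
        # projection onto span{sin, cos} over the component norm
        q, _ = np.linalg.qr(basis)
        cos_sim = np.linalg.norm(q.T @ comp) / np.linalg.norm(comp)
        assert cos_sim >= 0.99

    def test_eigenvalues_sorted_in_unit_interval(self, rng):
        fc, _ = simulate_network_voxels(GradientManifoldSpec(n_voxels=80), "control", 2)
        emb = embed_subject(fc)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()
        assert (np.abs(emb.eigenvalues) <= 1.0 + 1e-12).all()

    def test_disconnected_graph_rejected_with_sizes(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embedding(A)

    def test_recovers_planted_latent_coordinate(self):
        fc, lat = simulate_network_voxels(GradientManifoldSpec(n_voxels=120),
                                          "control", seed=9)
        emb = embed_subject(fc)
        rho = spearmanr(emb.components[:, 0], lat).statistic
        assert abs(rho) >= 0.9

    def test_permutation_equivariance(self, rng):
        fc, _ = simulate_network_voxels(GradientManifoldSpec(n_voxels=60), "control", 4)
        emb = embed_subject(fc)
        perm = rng.permutation(60)
        emb_p = embed_subject(fc[perm])
        # compare up to sign per component
        for c in range(3):
            a, b = emb.components[perm, c], emb_p.components[:, c]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-6


class TestGroupTemplate:
    def test_all_identical_subjects_match_individual_embedding(self, rng):
        fc, _ = simulate_network_voxels(GradientManifoldSpec(n_voxels=60), "control", 5)
        tpl = group_template([fc, fc, fc])
        ind = embed_subject(fc)
        for c in range(2):
            a, b = tpl.components[:, c], ind.components[:, c]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8

    def test_subject_order_invariance(self):
        fcs = [simulate_network_voxels(GradientManifoldSpec(n_voxels=60),
                                       "control", s)[0] for s in range(3)]
        t1 = group_template(fcs)
        t2 = group_template(fcs[::-1])
        assert np.allclose(t1.components, t2.components)

    def test_two_subject_template_embeds_midpoint(self):
        fcs = [simulate_network_voxels(GradientManifoldSpec(n_voxels=60),
                                       "control", s)[0] for s in (7, 8)]
        tpl = group_template(fcs)
        mid = embed_subject((fcs[0] + fcs[1]) / 2.0)
        assert np.allclose(tpl.components, mid.components)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            group_template([rng.standard_normal((50, 20)),
                            rng.standard_normal((60, 20))])


class TestProcrustes:
    def _emb(self, X):
        return Embedding(X, np.linspace(0.9, 0.5, X.shape[1]), 0.5, 0.0)

    def test_self_alignment_is_identity(self, rng):
        X = rng.standard_normal((40, 4))
        tpl = self._emb(X)
        out = procrustes_align(self._emb(X.copy()), tpl)
        assert np.allclose(out.components, X - X.mean(axis=0), atol=1e-10)

    def test_recovers_sign_flips(self, rng):
        X = rng.standard_normal((40, 4))
        Xc = X - X.mean(axis=0)
        flipped = Xc * np.array([1, -1, 1, -1.0])
        out = procrustes_align(self._emb(flipped), self._emb(Xc))
        assert np.allclose(out.components, Xc, atol=1e-8)

    def test_recovers_random_orthogonal_transform(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 5))
        Xc = X - X.mean(axis=0)
        R = special_ortho_group.rvs(5, random_state=7)
        out = procrustes_align(self._emb(Xc @ R), self._emb(Xc))
        disparity = np.linalg.norm(out.components - Xc)
        assert disparity < 1e-8

    def test_never_increases_distance_to_template(self, rng):
        for _ in range(5):
            X = rng.standard_normal((30, 3))
            Y = rng.standard_normal((30, 3))
            Yc = Y - Y.mean(axis=0)
            before = np.linalg.norm((X - X.mean(axis=0)) - Yc)
            out = procrustes_align(self._emb(X), self._emb(Y))
            after = np.linalg.norm(out.components - Yc)
            assert after <= before + 1e-10


class TestZScore:
    def test_zscored_moments(self, rng):
        emb = Embedding(rng.standard_normal((50, 3)), np.ones(3), 0.5, 0.0,
                        aligned=True)
        out = zscore_gradients(emb)
        assert np.allclose(out.components.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.components.std(axis=0), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        G = rng.standard_normal((50, 3))
        a = Embedding(G, np.ones(3), 0.5, 0.0, aligned=True)
        b = Embedding(3.2 * G + 7.0, np.ones(3), 0.5, 0.0, aligned=True)
        assert np.allclose(zscore_gradients(a).components,
                           zscore_gradients(b).components, atol=1e-10)

    def test_constant_component_rejected(self):
        emb = Embedding(np.ones((20, 2)), np.ones(2), 0.5, 0.0, aligned=True)
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_gradients(emb)


class TestDispersion:
    def _emb(self, G):
        return Embedding(G, np.ones(G.shape[1]), 0.5, 0.0, aligned=True)

    def test_three_four_five_triangle(self):
        G = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        d = gradient_dispersion(self._emb(G), ["a", "a", "b", "b"])
        assert d.centroid_distances.iloc[0]["distance"] == pytest.approx(5.0)

    def test_identical_centroids_distance_zero(self):
        G = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, 1.0], [-1.0, -1.0]])
        d = gradient_dispersion(self._emb(G), ["a", "a", "b", "b"])
        assert d.centroid_distances.iloc[0]["distance"] == pytest.approx(0.0)

    def test_matches_brute_force(self, rng):
        G = rng.standard_normal((60, 2))
        labels = rng.integers(0, 4, 60)
        d = gradient_dispersion(self._emb(G), labels)
        for _, row in d.centroid_distances.iterrows():
            ca = G[labels == row["region_a"]].mean(axis=0)
            cb = G[labels == row["region_b"]].mean(axis=0)
            assert row["distance"] == pytest.approx(np.linalg.norm(ca - cb), abs=1e-10)
        for _, row in d.within_dispersion.iterrows():
            mask = labels == row["region"]
            c = G[mask].mean(axis=0)
            assert row["dispersion"] == pytest.approx(
                np.linalg.norm(G[mask] - c, axis=1).mean(), abs=1e-10)

    def test_fewer_than_two_regions_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            gradient_dispersion(self._emb(np.zeros((5, 2))), ["a"] * 5)
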