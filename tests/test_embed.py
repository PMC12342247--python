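"""Spectral embedding: ASE exactness, omnibus structure, elbow selection."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from scnvuln.data import DataValidationError
from scnvuln.embed import (
    adjacency_spectral_embedding,
    build_omnibus,
    concat_modalities,
    omni_embed_modality,
    select_dimension,
)
from scnvuln.networks import NetworkStack
from scnvuln.synth import (
    community_latent_positions,
    random_latent_positions,
    sample_weighted_network,
)


def procrustes_residual(Xhat, X):
    R, _ = orthogonal_procrustes(Xhat, X)
    return np.linalg.norm(Xhat @ R - X)


def _stack(nets, modality="volume"):
    m, n = len(nets), nets[0].shape[0]
    return NetworkStack(
        modality,
        [f"s{i:02d}" for i in range(m)],
        [f"r{j}" for j in range(n)],
        np.asarray(nets, dtype=float),
    )


class TestASE:
    def test_two_by_two_hand_eigendecomposition(self):
        X = adjacency_spectral_embedding(np.full((2, 2), 0.25), d=1)
        np.testing.assert_allclose(np.abs(X), [[0.5], [0.5]], atol=1e-12)

    def test_zero_matrix_embeds_to_zero(self):
        assert not adjacency_spectral_embedding(np.zeros((5, 5)), d=3).any()

    def test_recovers_latent_positions_on_noiseless_p(self):
        X = random_latent_positions(30, 3, seed=0)
        P = X @ X.T
        Xhat = adjacency_spectral_embedding(P, d=3)
        assert procrustes_residual(Xhat, X) <= 1e-8 * np.linalg.norm(X)

    def test_asymmetric_and_bad_d_rejected(self):
        M = np.arange(9.0).reshape(3, 3)
        with pytest.raises(DataValidationError):
            adjacency_spectral_embedding(M, d=1)
        with pytest.raises(DataValidationError):
            adjacency_spectral_embedding(np.eye(3), d=4)

    def test_residual_decreases_with_noise(self):
        """Consistency: mean Procrustes residual shrinks as edge noise -> 0."""
        X = random_latent_positions(30, 3, seed=1)
        means = []
        for sigma in (0.2, 0.1, 0.05, 0.0):
            res = []
            for seed in range(50):
                A = sample_weighted_network(X, sigma, seed=seed)
                res.append(procrustes_residual(adjacency_spectral_embedding(A, 3), X))
            means.append(np.mean(res))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestOmnibus:
    def test_single_network_is_its_own_omnibus(self):
        A = sample_weighted_network(random_latent_positions(6, 2, 0), 0.05, 0)
        O = build_omnibus(np.array([A]), mode="dense")
        np.testing.assert_array_equal(O.dense, A)

    def test_block_structure(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1, (4, 4))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        B = A[::-1, ::-1].copy()
        O = build_omnibus(np.array([A, B]), mode="dense").dense
        np.testing.assert_allclose(O[:4, :4], A)
        np.testing.assert_allclose(O[4:, 4:], B)
        np.testing.assert_allclose(O[:4, 4:], (A + B) / 2)
        np.testing.assert_allclose(O[4:, :4], (A + B) / 2)
        assert np.abs(O - O.T).max() == 0

    def test_identical_networks_give_constant_blocks(self):
        A = sample_weighted_network(random_latent_positions(5, 2, 2), 0.05, 3)
        O = build_omnibus(np.array([A, A, A]), mode="dense").dense
        for i in range(3):
            for j in range(3):
                np.testing.assert_allclose(O[5 * i : 5 * i + 5, 5 * j : 5 * j + 5], A)

    def test_implicit_matvec_matches_dense(self):
        rng = np.random.default_rng(4)
        nets = [sample_weighted_network(random_latent_positions(12, 3, s), 0.1, s) for s in range(7)]
        dense = build_omnibus(np.array(nets), mode="dense")
        implicit = build_omnibus(np.array(nets), mode="implicit")
        for _ in range(5):
            v = rng.normal(size=7 * 12)
            np.testing.assert_allclose(dense.dense @ v, implicit.matvec(v), atol=1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(DataValidationError):
            build_omnibus(np.zeros((2, 3, 4)))


class TestSelectDimension:
    def test_clear_gap_first_elbow(self):
        assert select_dimension([10, 9.8, 9.5, 1.2, 1.1, 1.0, 0.9], n_elbows=1) == 3

    def test_length_one_spectrum(self):
        assert select_dimension([5.0], n_elbows=1) == 1

    def test_matches_exhaustive_profile_loglik_oracle(self):
        rng = np.random.default_rng(12)

        def oracle_elbow(vals):
            p = len(vals)
            best, best_ll = 1, -np.inf
            for q in range(1, p + 1):
                g1, g2 = vals[:q], vals[q:]
                mu1 = np.mean(g1)
                mu2 = np.mean(g2) if len(g2) else 0.0
                ss = np.sum((g1 - mu1) ** 2) + (np.sum((g2 - mu2) ** 2) if len(g2) else 0.0)
                s2 = max(ss / p, 1e-30)
                ll = 0.0
                for v in g1:
                    ll += -0.5 * np.log(2 * np.pi * s2) - (v - mu1) ** 2 / (2 * s2)
                for v in g2:
                    ll += -0.5 * np.log(2 * np.pi * s2) - (v - mu2) ** 2 / (2 * s2)
                if ll > best_ll:
                    best_ll, best = ll, q
            return best

        for _ in range(25):
            vals = np.sort(rng.exponential(2.0, size=rng.integers(3, 30)))[::-1]
            assert select_dimension(vals, n_elbows=1) == oracle_elbow(vals)

    def test_errors_and_warning_path(self, caplog):
        with pytest.raises(DataValidationError):
            select_dimension([])
        with pytest.raises(DataValidationError):
            select_dimension([1.0, 2.0])  # not descending
        # more elbows requested than the spectrum supports -> last elbow, warning
        d = select_dimension([3.0, 1.0], n_elbows=5)
        assert d == 2

    def test_recovers_generating_rank(self):
        """Rank-3 block model, small noise: the second elbow (the pipeline
        rule: the first elbow isolates the dominant eigenvalue) lands on 3
        in >= 18/20 seeds."""
        X = community_latent_positions(30, 3, seed=7)
        hits = 0
        for seed in range(20):
            nets = np.array(
                [sample_weighted_network(X, 0.02, seed=1000 * seed + i) for i in range(4)]
            )
            O = build_omnibus(nets, mode="dense")
            w, _ = O.eigpairs(k=40)
            hits += select_dimension(np.abs(w), n_elbows=2) == 3
        assert hits >= 18


class TestOmniEmbed:
    def test_identical_networks_identical_blocks(self):
        X = random_latent_positions(20, 3, seed=5)
        A = sample_weighted_network(X, 0.05, seed=9)
        stack = _stack([A] * 4)
        lat = omni_embed_modality(stack, d=3)
        for i in range(1, 4):
            assert np.linalg.norm(lat.positions[i] - lat.positions[0]) <= 1e-8
        # the omnibus of identical networks is J (x) A, so every block is ASE(A)
        np.testing.assert_allclose(
            lat.positions[0], adjacency_spectral_embedding(A, 3), atol=1e-10
        )

    def test_planted_group_difference_separates_blocks(self):
        X = random_latent_positions(20, 3, seed=3)
        Y = X.copy()
        Y[:5] = random_latent_positions(20, 3, seed=4)[:5]
        nets = [sample_weighted_network(X, 0.02, seed=s) for s in range(4)] + [
            sample_weighted_network(Y, 0.02, seed=10 + s) for s in range(4)
        ]
        lat = omni_embed_modality(_stack(nets), d=3)
        Z = lat.positions
        within = np.linalg.norm(Z[0] - Z[1]), np.linalg.norm(Z[4] - Z[5])
        between = np.linalg.norm(Z[0] - Z[4])
        assert between > max(within)

    def test_subject_permutation_permutes_blocks(self):
        nets = [sample_weighted_network(random_latent_positions(10, 2, s), 0.05, s) for s in range(5)]
        stack = _stack(nets)
        lat = omni_embed_modality(stack, d=2)
        perm = [3, 1, 4, 0, 2]
        stack_p = NetworkStack(
            "volume",
            [stack.subjects[i] for i in perm],
            stack.regions,
            stack.data[perm],
        )
        lat_p = omni_embed_modality(stack_p, d=2)
        np.testing.assert_allclose(lat_p.positions, lat.positions[perm], atol=1e-8)

    def test_implicit_and_dense_embeddings_agree(self):
        nets = [sample_weighted_network(random_latent_positions(15, 3, s), 0.05, s) for s in range(6)]
        stack = _stack(nets)
        lat_d = omni_embed_modality(stack, d=3, mode="dense")
        lat_i = omni_embed_modality(stack, d=3, mode="implicit")
        # column signs are fixed by convention, so blocks agree directly
        assert np.linalg.norm(lat_d.positions - lat_i.positions) <= 1e-6

    def test_too_few_networks_rejected(self):
        A = np.zeros((4, 4))
        with pytest.raises(DataValidationError):
            omni_embed_modality(_stack([A]))


class TestConcat:
    def _lat(self, seed, d, modality):
        nets = [sample_weighted_network(random_latent_positions(8, 2, seed + s), 0.05, s) for s in range(3)]
        return omni_embed_modality(_stack(nets, modality), d=d)

    def test_layout_volume_then_fa(self):
        vol = self._lat(0, 3, "volume")
        fa = self._lat(5, 2, "fa")
        cat = concat_modalities(vol, fa)
        assert cat.positions.shape[2] == 5
        np.testing.assert_array_equal(cat.positions[..., :3], vol.positions)
        np.testing.assert_array_equal(cat.positions[..., 3:], fa.positions)

    def test_six_dims_when_both_select_three(self):
        vol = self._lat(0, 3, "volume")
        fa = self._lat(5, 3, "fa")
        assert concat_modalities(vol, fa).positions.shape[2] == 6

    def test_subject_mismatch_rejected(self):
        vol = self._lat(0, 2, "volume")
        fa = self._lat(5, 2, "fa")
        fa.subjects[0] = "other"
        with pytest.raises(DataValidationError):
            concat_modalities(vol, fa)
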