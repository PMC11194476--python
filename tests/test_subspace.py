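"""Deep subspace contrastive clustering: losses, training, spectral ops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omicsubtypes.evaluation import adjusted_rand_index
from omicsubtypes.subspace import (
    DsccConfig,
    affinity_from_coefficients,
    cluster_coefficients,
    contrastive_self_expression_loss,
    joint_loss,
    normalized_laplacian,
    reconstruction_loss,
    ridge_self_expression_oracle,
    self_express,
    spectral_cluster,
    train_dscc,
)


class TestSelfExpress:
    def test_zero_coefficients_give_zero(self, rng):
        Z = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(self_express(Z, np.zeros((4, 4))), 0.0)

    def test_permutation_coefficients_swap_rows(self, rng):
        Z = rng.standard_normal((2, 3))
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(self_express(Z, C), Z[::-1])

    def test_matches_double_loop_oracle(self, rng):
        Z = rng.standard_normal((6, 4))
        C = rng.standard_normal((6, 6))
        np.fill_diagonal(C, 0.0)
        expected = np.zeros((6, 4))
        for i in range(6):
            for j in range(6):
                if j != i:
                    expected[i] += C[i, j] * Z[j]
        np.testing.assert_allclose(self_express(Z, C), expected, atol=1e-12)

    def test_nonzero_diagonal_rejected(self, rng):
        Z = rng.standard_normal((3, 2))
        C = np.eye(3)
        with pytest.raises(ValueError, match="diag"):
            self_express(Z, C)


class TestReconstructionLoss:
    def test_perfect_reconstruction(self, rng):
        P = rng.standard_normal((5, 3))
        assert reconstruction_loss(P, P) == 0.0

    def test_hand_value(self):
        P = np.zeros((2, 3))
        D = np.array([[1.0, 1.0, 0.0], [0.0, 2.0, 0.0]])  # total squared = 6
        assert reconstruction_loss(P, D) == pytest.approx(3.0)

    def test_nonnegative(self, rng):
        assert reconstruction_loss(rng.standard_normal((4, 4)),
                                   rng.standard_normal((4, 4))) >= 0


class TestContrastiveLoss:
    def test_two_sample_closed_form(self):
        # s(z1, zh1) = 1, s(z1, zh2) = 0 => l_1 = -1; symmetric pair => total -2
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert contrastive_self_expression_loss(Z, Z) == pytest.approx(-2.0, abs=1e-10)

    def test_all_equal_similarities(self):
        N = 5
        Z = np.tile([1.0, 2.0, 3.0], (N, 1))
        Zh = np.tile([-1.0, 0.5, 2.0], (N, 1))
        expected = N * np.log(N - 1)
        assert contrastive_self_expression_loss(Z, Zh) == pytest.approx(
            expected, abs=1e-10
        )

    def test_monotone_in_positive_pair_similarity(self, rng):
        """Raising s(z_i, zh_i) with the negatives fixed lowers the loss."""
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        base = np.array([[0.2, 1.0], [1.0, 0.3], [0.5, 0.5]])
        better = base.copy()
        better[0] = [1.0, 0.1]  # more aligned with z_1, negatives for rows 2,3
        # only compare the i=1 term: freeze other rows' contributions by hand
        def term(Zh):
            s = lambda a, b: a @ b / np.linalg.norm(a) / np.linalg.norm(b)
            return -s(Z[0], Zh[0]) + np.log(
                np.exp(s(Z[0], Zh[1])) + np.exp(s(Z[0], Zh[2]))
            )
        assert term(better) < term(base)

    def test_zero_row_rejected(self):
        Z = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero"):
            contrastive_self_expression_loss(Z, Z)

    def test_inclusive_variant_is_nonnegative(self, rng):
        Z = rng.standard_normal((6, 4))
        Zh = rng.standard_normal((6, 4))
        assert contrastive_self_expression_loss(Z, Zh, inclusive=True) >= 0


class TestJointLoss:
    def test_two_terms_vanish(self, rng):
        P = rng.standard_normal((4, 3))
        Z = rng.standard_normal((4, 2))
        Zh = rng.standard_normal((4, 2))
        C = np.zeros((4, 4))
        total = joint_loss(P, P, Z, Zh, C, (0.01, 1.0, 1.0))
        assert total == pytest.approx(contrastive_self_expression_loss(Z, Zh))

    def test_lambda2_linearity(self, rng):
        P = rng.standard_normal((4, 3))
        Z = rng.standard_normal((4, 2))
        Zh = rng.standard_normal((4, 2))
        C = rng.standard_normal((4, 4)) * 0.1
        np.fill_diagonal(C, 0)
        a = joint_loss(P, P, Z, Zh, C, (0.01, 1.0, 1.0))
        b = joint_loss(P, P, Z, Zh, C, (0.01, 2.0, 1.0))
        assert b - a == pytest.approx(np.sum(C * C), rel=1e-10)

    def test_hand_summed_oracle(self, rng):
        P = rng.standard_normal((5, 3))
        decoded = rng.standard_normal((5, 3))
        Z = rng.standard_normal((5, 2))
        Zh = rng.standard_normal((5, 2))
        C = rng.standard_normal((5, 5)) * 0.2
        np.fill_diagonal(C, 0)
        lambdas = (0.5, 2.0, 1.5)
        expected = (
            0.5 * np.sum((P - decoded) ** 2) / 5
            + 2.0 * np.sum(C * C)
            + 1.5 * contrastive_self_expression_loss(Z, Zh)
        )
        assert joint_loss(P, decoded, Z, Zh, C, lambdas) == pytest.approx(
            expected, abs=1e-10
        )


class TestRidgeOracle:
    def test_identical_rows_large_lam(self):
        Z = np.array([[2.0, 1.0], [2.0, 1.0]])
        C = ridge_self_expression_oracle(Z, 1e6)
        assert C[0, 1] == pytest.approx(1.0, abs=1e-4)
        assert C[1, 0] == pytest.approx(1.0, abs=1e-4)

    def test_vanishing_lam_gives_zero(self, rng):
        Z = rng.standard_normal((5, 3))
        C = ridge_self_expression_oracle(Z, 1e-10)
        assert np.abs(C).max() < 1e-8

    def test_closed_form_is_optimal(self, rng):
        Z = rng.standard_normal((6, 4))
        lam = 2.0
        C = ridge_self_expression_oracle(Z, lam)

        def objective(row_i, c):
            others = np.delete(np.arange(6), row_i)
            resid = Z[row_i] - c @ Z[others]
            return c @ c + lam * resid @ resid

        for i in range(6):
            others = np.delete(np.arange(6), i)
            c_star = C[i, others]
            base = objective(i, c_star)
            for _ in range(100):
                assert base <= objective(i, c_star + rng.standard_normal(5) * 0.01) + 1e-12


class TestTrainDscc:
    def test_trained_c_matches_ridge_oracle(self, rng):
        """Contrastive term off, identity autoencoder: gradient training of C
        must find the closed-form ridge solution (lam = lambda1 / (N lambda2))."""
        Z = rng.standard_normal((20, 10))
        cfg = DsccConfig(
            identity_autoencoder=True,
            lambda1=20.0,
            lambda2=1.0,
            lambda3=0.0,
            pretrain_epochs=0,
            joint_epochs=2000,
            learning_rate=1e-2,
        )
        model = train_dscc(Z, cfg, seed=0)
        oracle = ridge_self_expression_oracle(Z, cfg.lambda1 / (20 * cfg.lambda2))
        assert np.abs(model.C - oracle).max() < 1e-3

    def test_same_seed_identical_c(self, rng):
        P = rng.standard_normal((20, 8))
        cfg = DsccConfig(pretrain_epochs=10, joint_epochs=20, encoder_dims=(16, 8))
        m1 = train_dscc(P, cfg, seed=3)
        m2 = train_dscc(P, cfg, seed=3)
        np.testing.assert_array_equal(m1.C, m2.C)

    def test_diagonal_stays_zero(self, rng):
        P = rng.standard_normal((15, 6))
        cfg = DsccConfig(pretrain_epochs=5, joint_epochs=30, encoder_dims=(12, 6))
        model = train_dscc(P, cfg, seed=1)
        np.testing.assert_array_equal(np.diag(model.C), 0.0)

    def test_pretraining_reduces_reconstruction(self, rng):
        P = rng.standard_normal((20, 8))
        cfg = DsccConfig(pretrain_epochs=100, joint_epochs=0, encoder_dims=(16, 8))
        model = train_dscc(P, cfg, seed=2)
        pre = [r["total"] for r in model.training_log if r["phase"] == "pretrain"]
        assert min(pre) < pre[0]

    def test_recovers_separated_clusters(self, rng):
        """Three well-separated latent clusters: labels recovered via the
        learned coefficients (median over 3 seeds)."""
        from omicsubtypes.synthetic import SyntheticConfig, simulate_dataset

        aris = []
        for seed in (0, 1, 2):
            _, _, truth = simulate_dataset(
                SyntheticConfig(n_samples=90, protein_noise_sd=0.1), seed=seed
            )
            P = truth.protein_full
            model = train_dscc(P, DsccConfig(n_clusters=3), seed=seed)
            labels = cluster_coefficients(model, 3, seed=seed).labels
            aris.append(adjusted_rand_index(labels, truth.true_labels))
        assert np.median(aris) >= 0.9


class TestAffinity:
    def test_symmetric_nonnegative_fixed_point(self, rng):
        C = np.abs(rng.standard_normal((5, 5)))
        C = (C + C.T) / 2
        np.testing.assert_allclose(affinity_from_coefficients(C), C)

    def test_sign_folding(self):
        C = np.array([[0.0, 1.0], [-1.0, 0.0]])
        S = affinity_from_coefficients(C)
        assert S[0, 1] == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_always_symmetric(self, seed):
        C = np.random.default_rng(seed).standard_normal((6, 6))
        S = affinity_from_coefficients(C)
        np.testing.assert_array_equal(S, S.T)
        assert np.all(S >= 0)


class TestLaplacian:
    def test_two_node_hand_value(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = normalized_laplacian(S)
        np.testing.assert_allclose(L, [[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(L)), [0.0, 2.0], atol=1e-12)

    def test_positive_semidefinite(self, rng):
        S = np.abs(rng.standard_normal((8, 8)))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        L = normalized_laplacian(S)
        assert np.linalg.eigvalsh(L).min() >= -1e-8

    def test_scaled_constant_vector_in_null_space(self, rng):
        S = np.abs(rng.standard_normal((6, 6))) + 0.1  # connected
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        L = normalized_laplacian(S)
        d = S.sum(axis=1)
        v = np.sqrt(d)
        np.testing.assert_allclose(L @ v, 0.0, atol=1e-10)

    def test_zero_degree_rows_stay_isolated(self):
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = 1.0
        L = normalized_laplacian(S)
        assert np.isfinite(L).all()
        assert L[2, 2] == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalized_laplacian(np.array([[0.0, -0.5], [-0.5, 0.0]]))


class TestSpectralCluster:
    def _block_affinity(self, sizes):
        N = sum(sizes)
        S = np.zeros((N, N))
        start = 0
        for s in sizes:
            S[start : start + s, start : start + s] = 1.0
            start += s
        np.fill_diagonal(S, 0)
        return S

    @pytest.mark.parametrize("sizes", [(5, 5), (4, 5, 6)])
    def test_disconnected_blocks_recovered(self, sizes):
        S = self._block_affinity(sizes)
        truth = np.repeat(np.arange(len(sizes)), sizes)
        result = spectral_cluster(S, len(sizes), seed=0)
        assert adjusted_rand_index(result.labels, truth) == pytest.approx(1.0)

    def test_single_cluster(self, rng):
        S = np.abs(rng.standard_normal((6, 6)))
        S = (S + S.T) / 2
        result = spectral_cluster(S, 1, seed=0)
        assert set(result.labels) == {1}

    def test_n_singletons(self, rng):
        S = np.abs(rng.standard_normal((5, 5)))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        result = spectral_cluster(S, 5, seed=0)
        assert sorted(result.labels) == [1, 2, 3, 4, 5]

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            spectral_cluster(np.eye(3) * 0, 4, seed=0)

    def test_permuted_input_gives_permuted_labels(self, rng):
        """The affinity -> Laplacian -> spectral chain is equivariant under
        sample permutation (labels agree up to renaming: ARI = 1)."""
        C = rng.standard_normal((12, 12)) * 0.2
        np.fill_diagonal(C, 0)
        C[:6, :6] += 1.0
        C[6:, 6:] += 1.0
        S = affinity_from_coefficients(C)
        labels = spectral_cluster(S, 2, seed=0).labels
        perm = rng.permutation(12)
        labels_p = spectral_cluster(S[np.ix_(perm, perm)], 2, seed=0).labels
        assert adjusted_rand_index(labels_p, labels[perm]) == pytest.approx(1.0)
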