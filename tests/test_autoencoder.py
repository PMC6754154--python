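"""Tied-weight autoencoder: algebra, training contracts, cross-validation."""

import numpy as np
import pytest

from phqtraj.autoencoder import (
    AutoencoderModel,
    ConstantTrajectoryError,
    SgdSettings,
    cross_validate,
    decode,
    encode,
    normalize_input,
    reconstruction_mse,
    train,
)
from phqtraj.cohort import ConfigurationError


def rank3_dataset(n=200, seed=11):
    """Trajectories spanned by three smooth bases, rows normalised."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 20)
    bases = np.stack([np.sin(2 * np.pi * t), t - 0.5, np.exp(-((t - 0.5) ** 2) / 0.02)])
    X = rng.normal(size=(n, 3)) @ bases
    return np.stack([normalize_input(row) for row in X])


class TestNormalizeInput:
    def test_zero_mean_unit_variance(self):
        out = normalize_input(np.arange(20.0))
        assert abs(out.mean()) < 1e-12
        assert out.var() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_on_normalised_input(self):
        once = normalize_input(np.sin(np.arange(20.0)))
        twice = normalize_input(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_matches_arithmetic_oracle(self, rng):
        x = rng.normal(5, 3, size=20)
        expected = (x - x.mean()) / x.std()
        np.testing.assert_allclose(normalize_input(x), expected, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ConstantTrajectoryError):
            normalize_input(np.full(20, 3.0))


class TestEncodeDecode:
    def test_identity_model_reconstructs_exactly(self, rng):
        model = AutoencoderModel(W=np.eye(20), b=np.zeros(20), b_prime=np.zeros(20), u="identity")
        m = rng.normal(size=20)
        np.testing.assert_allclose(decode(model, encode(model, m)), m, atol=1e-12)

    def test_zero_activation_returns_decoder_bias(self, rng):
        b_prime = rng.normal(size=20)
        model = AutoencoderModel(W=rng.normal(size=(5, 20)), b=np.zeros(5), b_prime=b_prime)
        np.testing.assert_allclose(decode(model, np.zeros(5)), b_prime, atol=1e-12)

    def test_matches_matrix_product_oracle(self, rng):
        W = rng.normal(size=(7, 20))
        b = rng.normal(size=7)
        bp = rng.normal(size=20)
        model = AutoencoderModel(W=W, b=b, b_prime=bp, u="identity")
        m = rng.normal(size=20)
        h = encode(model, m)
        np.testing.assert_allclose(h, W @ m + b, atol=1e-12)
        np.testing.assert_allclose(decode(model, h), W.T @ h + bp, atol=1e-12)

    def test_orthonormal_rows_project_onto_rowspace(self, rng):
        # with identity nonlinearity and orthonormal W rows, decode(encode(m))
        # is the orthogonal projection of m onto the rowspace of W
        A = rng.normal(size=(3, 20))
        Q, _ = np.linalg.qr(A.T)
        W = Q.T[:3]
        model = AutoencoderModel(W=W, b=np.zeros(3), b_prime=np.zeros(20), u="identity")
        m = rng.normal(size=20)
        proj = W.T @ (W @ m)
        np.testing.assert_allclose(decode(model, encode(model, m)), proj, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        model = AutoencoderModel(W=rng.normal(size=(5, 20)), b=np.zeros(5), b_prime=np.zeros(20))
        with pytest.raises(ValueError):
            encode(model, np.zeros(7))

    def test_decoder_weight_is_transpose_of_encoder(self, rng):
        # structural tie: only W is stored; feeding unit activations reads
        # the decoder columns, which must be the encoder rows
        W = rng.normal(size=(4, 20))
        model = AutoencoderModel(W=W, b=np.zeros(4), b_prime=np.zeros(20))
        for i in range(4):
            e = np.zeros(4)
            e[i] = 1.0
            np.testing.assert_allclose(decode(model, e), W[i], atol=1e-12)


class TestTraining:
    def test_loss_decreases_and_beats_mean_predictor(self):
        X = rank3_dataset(200)
        model, trace = train(X, 10, SgdSettings(epochs=60), seed=0)
        assert trace[-1] <= trace[0]
        assert trace[-1] < 1.0  # variance of normalised inputs

    def test_seed_determinism_bit_identical(self):
        X = rank3_dataset(60)
        m1, _ = train(X, 5, SgdSettings(epochs=20), seed=3)
        m2, _ = train(X, 5, SgdSettings(epochs=20), seed=3)
        assert np.array_equal(m1.W, m2.W)
        assert np.array_equal(m1.b, m2.b)
        assert np.array_equal(m1.b_prime, m2.b_prime)

    def test_rank3_data_reconstructed_below_pca_rank1_residual(self):
        X = rank3_dataset(200)
        model, trace = train(X, 10, SgdSettings(learning_rate=0.05, epochs=500), seed=1)
        # PCA residual oracle: rank-1 reconstruction error per entry
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        rank1_residual = float((s[1:] ** 2).sum() / X.size)
        assert trace[-1] < 0.05
        assert trace[-1] < rank1_residual

    def test_invalid_latent_size_rejected(self):
        with pytest.raises(ConfigurationError):
            train(rank3_dataset(20), 0)


class TestCrossValidate:
    def test_each_row_validated_exactly_once(self):
        # 10 rows, 5 folds: 2 validation rows per fold, disjoint cover
        X = rank3_dataset(10)
        rng = np.random.default_rng(4)
        order = rng.permutation(10)
        folds = np.array_split(order, 5)
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))
        assert all(len(f) == 2 for f in folds)
        res = cross_validate(X, [2], folds=5, seed=4, sgd=SgdSettings(epochs=10))
        assert len(res[2]["fold_mse"]) == 5

    def test_deterministic_under_fixed_seed(self):
        X = rank3_dataset(15)
        a = cross_validate(X, [3], folds=5, seed=9, sgd=SgdSettings(epochs=10))
        b = cross_validate(X, [3], folds=5, seed=9, sgd=SgdSettings(epochs=10))
        assert a == b

    def test_capacity_ordering_on_rank3_data(self):
        X = rank3_dataset(100)
        res = cross_validate(
            X, [1, 25], folds=5, seed=2, sgd=SgdSettings(learning_rate=0.05, epochs=150)
        )
        assert res[25]["mean_mse"] < res[1]["mean_mse"]

    def test_fewer_rows_than_folds_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_validate(rank3_dataset(4), [2], folds=5)
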