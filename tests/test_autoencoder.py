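import numpy as np
import pytest

from mrsport.autoencoder import (
    LayerSpec,
    MetaboliteAutoencoder,
    bottleneck_search,
    first_two_eigenvalue_share,
    init_autoencoder,
    sigmoid,
    train_autoencoder,
)
from mrsport.core_data import ValidationError

_BN_EPS = 1e-5


def oracle_forward(model, X, upto=None):
    """Independent layer-by-layer reference forward pass (inference mode)."""
    A = np.array(X, dtype=float)
    stop = model.n_layers_ if upto is None else upto
    for l in range(stop):
        Z = np.empty((A.shape[0], model.weights_[l].shape[1]))
        for r in range(A.shape[0]):  # deliberate naive loops
            Z[r] = A[r] @ model.weights_[l] + model.biases_[l]
        if l in model.bn_layers_:
            Z = (Z - model.bn_run_mean_[l]) / np.sqrt(model.bn_run_var_[l] + _BN_EPS)
            Z = model.bn_gamma_[l] * Z + model.bn_beta_[l]
        A = 1.0 / (1.0 + np.exp(-Z))
    return A


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    @pytest.mark.parametrize("x", [-3.0, -1.0, 2.0, 10.0])
    def test_symmetry_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_high_precision_value(self):
        assert sigmoid(1.0) == pytest.approx(0.7310585786300049, abs=1e-15)

    def test_saturates_without_overflow(self):
        assert sigmoid(1e4) == 1.0 and sigmoid(-1e4) == 0.0


class TestInit:
    def test_default_layer_shapes_are_mirrored(self):
        model = init_autoencoder(LayerSpec(), n_inputs=34, seed=0)
        dims = [w.shape for w in model.weights_]
        assert dims == [(34, 32), (32, 16), (16, 8), (8, 6),
                        (6, 8), (8, 16), (16, 32), (32, 34)]

    def test_same_seed_identical_parameters(self):
        a = init_autoencoder(seed=42)
        b = init_autoencoder(seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights_, b.weights_))

    def test_bottleneck_wider_than_last_hidden_rejected(self):
        with pytest.raises(ValidationError):
            LayerSpec(bottleneck=9)

    def test_nonmonotone_widths_rejected(self):
        with pytest.raises(ValidationError):
            LayerSpec(encoder_widths=(16, 32, 8))


class TestForward:
    def test_encode_shape_and_range(self, rng):
        model = init_autoencoder(seed=1)
        Z = model.encode(rng.random((7, 34)))
        assert Z.shape == (7, 6) and np.all((Z > 0) & (Z < 1))

    def test_zero_parameters_give_half_everywhere(self, rng):
        model = init_autoencoder(seed=1)
        model.weights_ = [np.zeros_like(w) for w in model.weights_]
        out = model.reconstruct(rng.random((3, 34)))
        assert np.allclose(out, 0.5, atol=1e-6)

    def test_matches_independent_oracle(self, rng):
        model = init_autoencoder(seed=3)
        # perturb BN stats so the oracle exercises them
        for l in model.bn_layers_:
            model.bn_run_mean_[l] = rng.normal(size=model.bn_run_mean_[l].shape)
            model.bn_run_var_[l] = 1 + rng.random(model.bn_run_var_[l].shape)
        X = rng.random((11, 34))
        assert np.allclose(model.reconstruct(X), oracle_forward(model, X),
                           atol=1e-10)
        assert np.allclose(model.encode(X),
                           oracle_forward(model, X, upto=model.bottleneck_index_ + 1),
                           atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        model = init_autoencoder(seed=1)
        with pytest.raises(ValidationError):
            model.encode(rng.random((5, 33)))


def test_backprop_matches_numerical_gradient():
    """Central-difference check of the full backward pass (BN included)."""
    model = MetaboliteAutoencoder(encoder_widths=(6, 4), bottleneck=3,
                                  dropout=0.0, batch_norm=True, random_state=7)
    model.initialize(n_inputs=7)
    rng = np.random.default_rng(0)
    X = rng.random((8, 7))

    def loss():
        A, _ = model._forward_train(X, rng)
        return np.mean((A - X) ** 2)

    A_out, caches = model._forward_train(X, rng)
    gW, gb, gg, gbe = model._backward(X, A_out, caches)
    eps = 1e-6
    for l in [0, 2, 4]:
        W = model.weights_[l]
        for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
            orig = W[idx]
            W[idx] = orig + eps
            lp = loss()
            W[idx] = orig - eps
            lm = loss()
            W[idx] = orig
            assert gW[l][idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)
    g = model.bn_gamma_[0]
    orig = g[0]
    g[0] = orig + eps
    lp = loss()
    g[0] = orig - eps
    lm = loss()
    g[0] = orig
    assert gg[0][0] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)


class TestTraining:
    def test_loss_decreases(self, rng):
        X = rng.random((60, 34))
        model = MetaboliteAutoencoder(epochs=30, random_state=0).fit(X)
        assert model.report_.train_loss[-1] <= model.report_.train_loss[0]

    def test_zero_epochs_is_noop(self, rng):
        X = rng.random((20, 34))
        a = init_autoencoder(seed=5)
        w_before = [w.copy() for w in a.weights_]
        train_autoencoder(a, X, epochs=0)
        assert all(np.array_equal(w, wb) for w, wb in zip(a.weights_, w_before))

    def test_unnormalized_input_rejected(self, rng):
        X = rng.random((20, 34)) * 5
        with pytest.raises(ValidationError):
            MetaboliteAutoencoder().fit(X)

    def test_training_is_reproducible(self, rng):
        X = rng.random((40, 34))
        a = MetaboliteAutoencoder(epochs=10, random_state=3).fit(X)
        b = MetaboliteAutoencoder(epochs=10, random_state=3).fit(X)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights_, b.weights_))
        assert a.report_.train_loss == b.report_.train_loss

    def test_rank_one_matrix_reconstructed_well(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 1)) @ rng.random((1, 34))
        X = (X - X.min(0)) / (X.max(0) - X.min(0) + 1e-12)
        model = MetaboliteAutoencoder(epochs=500, random_state=0).fit(X)
        assert model.report_.val_loss[-1] < 0.01


class TestDenoise:
    def test_shape_preserved_and_untrained_warns(self, rng):
        model = init_autoencoder(seed=2)
        X = rng.random((9, 34))
        with pytest.warns(UserWarning, match="not been trained"):
            out = model.transform(X)
        assert out.shape == X.shape

    def test_denoising_concentrates_variance(self):
        """First-two-PC share of denoised > noisy, on planted rank-2 data."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            S = rng.random((200, 2)) @ (rng.random((2, 34)) * 2)
            X = S + rng.normal(0, 0.3, S.shape)
            X = (X - X.min(0)) / (X.max(0) - X.min(0))
            model = MetaboliteAutoencoder(epochs=120, random_state=seed).fit(X)
            D = model.transform(X)
            wins += first_two_eigenvalue_share(D) > first_two_eigenvalue_share(X)
        assert wins >= 4

    def test_denoising_is_near_idempotent(self):
        rng = np.random.default_rng(1)
        S = rng.random((150, 2)) @ rng.random((2, 34))
        X = np.clip(S + rng.normal(0, 0.2, S.shape), 0, None)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        model = MetaboliteAutoencoder(epochs=150, random_state=1).fit(X)
        D = model.transform(X)
        DD = model.transform(D)
        assert np.linalg.norm(DD - D) < np.linalg.norm(D - X)


class TestBottleneckSearch:
    def test_default_grid_and_determinism(self, rng):
        X = rng.random((80, 34))
        best, bench = bottleneck_search(X, seed=0, epochs=5)
        assert set(bench) == {4, 5, 6, 7, 8, 9, 10}
        best2, bench2 = bottleneck_search(X, seed=0, epochs=5)
        assert best == best2 and bench == bench2

    def test_ties_break_toward_smaller_size(self, rng):
        X = rng.random((80, 34))
        best, bench = bottleneck_search(X, sizes=[4, 5, 6], seed=1, epochs=5)
        top = max(bench.values())
        assert best == min(s for s, v in bench.items() if v == top)

    def test_invalid_size_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            bottleneck_search(rng.random((40, 34)), sizes=[0, 5], epochs=2)
        with pytest.raises(ValidationError):
            bottleneck_search(rng.random((40, 34)), sizes=[34], epochs=2)

    def test_planted_rank_two_benchmark_is_high(self):
        rng = np.random.default_rng(4)
        S = rng.random((150, 2)) @ (rng.random((2, 34)) * 3)
        X = S + rng.normal(0, 0.2, S.shape)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        best, bench = bottleneck_search(X, sizes=[4, 6], seed=4, epochs=80)
        assert max(bench.values()) > first_two_eigenvalue_share(X)


def test_serialization_roundtrip(rng):
    X = rng.random((30, 34))
    model = MetaboliteAutoencoder(epochs=5, random_state=6).fit(X)
    clone = MetaboliteAutoencoder.from_dict(model.to_dict())
    assert np.allclose(model.transform(X), clone.transform(X), atol=1e-12)
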