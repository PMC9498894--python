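import numpy as np
import pytest

from multiconv import (
    DEFAULT_BACKGROUND,
    ConventionalConfig,
    ModelConfig,
    MPRADataset,
    build_conventional_cnn,
    build_multinomial_cnn,
    load_model,
    mse_loss,
    multinomial_transform,
    one_hot_encode,
    predict,
    reverse_complement,
    save_model,
    scan,
    train,
)
from multiconv.exceptions import (
    ConfigError,
    DataError,
    DimensionError,
    DivergenceError,
)
from multiconv.model import TrainedModel, encode_sequences


def random_sequences(rng, n, length):
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, length)]) for _ in range(n)]


class TestModelConfig:
    def test_defaults_match_reference_architecture(self):
        cfg = ModelConfig()
        assert cfg.n_filters == 512
        assert cfg.filter_length == 12
        assert cfg.activation == "relu"
        assert cfg.pooling == "max"
        assert cfg.dropout_rate == 0.4
        assert cfg.batch_size == 64
        assert cfg.learning_rate == 0.001
        assert cfg.l2_factor == 0.001

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_filters": 0},
            {"filter_length": 0},
            {"alpha": -1.0},
            {"activation": "swish"},
            {"pooling": "median"},
            {"dropout_rate": 1.0},
            {"n_dense_layers": 3},
            {"l2_factor": -0.1},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ModelConfig(**kwargs)


class TestMSELoss:
    def test_perfect_fit(self):
        assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_residuals(self):
        assert mse_loss([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_hand_computed(self):
        assert mse_loss([1, 2, 3], [2, 2, 2]) == pytest.approx(2.0 / 3.0)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            mse_loss([1, 2], [1, 2, 3])


class TestForwardPass:
    def test_single_filter_max_pool_matches_scan(self):
        """Pooled feature = max over 2*(N-L+1) activated LLRs of both strands."""
        cfg = ModelConfig(
            n_filters=1, filter_length=5, alpha=4.0, dropout_rate=0.0, seed=3
        )
        net = build_multinomial_cnn(cfg)
        sequence = "ACGTGATTACAGTACGATCA"
        kernel = multinomial_transform(net.raw_convolutions()[0], cfg.alpha)
        fwd_scores = scan(kernel, one_hot_encode(sequence))
        rc_scores = scan(kernel, reverse_complement(one_hot_encode(sequence)))
        pooled = max(np.maximum(np.concatenate([fwd_scores, rc_scores]), 0.0))
        weight, intercept = net.dense_weights()
        expected = weight[0] * pooled + intercept
        assert predict(net, [sequence])[0] == pytest.approx(expected, abs=1e-9)

    def test_background_kernel_predicts_intercept(self):
        cfg = ModelConfig(n_filters=3, filter_length=4, alpha=2.0, dropout_rate=0.0)
        net = build_multinomial_cnn(cfg)
        # X = log(B) / alpha makes every kernel row equal the background
        net.conv.params["X"][:] = np.log(DEFAULT_BACKGROUND.probs) / cfg.alpha
        _, intercept = net.dense_weights()
        out = predict(net, ["ACGTACGTAC"])
        assert out[0] == pytest.approx(intercept, abs=1e-9)

    def test_untrained_output_finite(self):
        rng = np.random.default_rng(0)
        net = build_multinomial_cnn(
            ModelConfig(n_filters=4, filter_length=6, dropout_rate=0.0)
        )
        out = predict(net, random_sequences(rng, 10, 30))
        assert np.all(np.isfinite(out))

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        net = build_multinomial_cnn(
            ModelConfig(n_filters=6, filter_length=5, dropout_rate=0.0, seed=2)
        )
        complement = str.maketrans("ACGT", "TGCA")
        seqs = random_sequences(rng, 20, 40)
        rc_seqs = [s.translate(complement)[::-1] for s in seqs]
        assert np.allclose(predict(net, seqs), predict(net, rc_seqs), atol=1e-9)

    def test_all_n_sequences_finite(self):
        net = build_multinomial_cnn(ModelConfig(n_filters=2, filter_length=4))
        assert np.all(np.isfinite(predict(net, ["N" * 12, "N" * 12])))

    def test_interpretability_correspondence(self):
        cfg = ModelConfig(n_filters=7, filter_length=5)
        net = build_multinomial_cnn(cfg)
        assert len(net.raw_convolutions()) == cfg.n_filters
        weights, _ = net.dense_weights()
        assert weights.shape == (cfg.n_filters,)


class TestConventionalCNN:
    def test_default_has_five_conv_layers(self):
        net = build_conventional_cnn()
        assert net.n_conv_layers == 5
        assert ConventionalConfig().filters_per_layer == (512, 256, 64, 64, 64)
        assert ConventionalConfig().filter_length == 5

    def test_single_layer_degenerate_config(self):
        net = build_conventional_cnn(
            ConventionalConfig(filters_per_layer=(4,), dropout_rate=0.0)
        )
        assert net.n_conv_layers == 1
        out = predict(net, ["ACGTACGTACGT"])
        assert np.isfinite(out[0])

    def test_forward_finite_on_random_input(self):
        rng = np.random.default_rng(2)
        net = build_conventional_cnn(
            ConventionalConfig(filters_per_layer=(8, 4), dropout_rate=0.0)
        )
        out = predict(net, random_sequences(rng, 5, 30))
        assert np.all(np.isfinite(out))


def numeric_gradient_check(net, n=4, length=14, seed=0, atol=2e-5):
    """Central-difference check of every parameter gradient."""
    rng = np.random.default_rng(seed)
    fwd, rc = encode_sequences(random_sequences(rng, n, length))
    y = rng.normal(size=n)

    def loss():
        pred = net.forward(fwd, rc, training=False)
        return float(np.mean((pred - y) ** 2))

    pred = net.forward(fwd, rc, training=False)
    net.backward(2.0 * (pred - y) / n)
    eps = 1e-6
    for (li, name), layer, value in net.parameters():
        grad = layer.grads.get(name)
        if grad is None:
            continue
        if name == "log_alpha" and not getattr(layer, "trainable_alpha", False):
            continue  # alpha is a frozen hyperparameter by default
        flat = value.ravel()
        for idx in rng.choice(flat.size, size=min(10, flat.size), replace=False):
            original = flat[idx]
            flat[idx] = original + eps
            up = loss()
            flat[idx] = original - eps
            down = loss()
            flat[idx] = original
            numeric = (up - down) / (2 * eps)
            assert grad.ravel()[idx] == pytest.approx(numeric, abs=atol), (
                f"layer {li} param {name} index {idx}"
            )


class TestGradients:
    def test_multinomial_network_gradients(self):
        net = build_multinomial_cnn(
            ModelConfig(
                n_filters=3, filter_length=4, alpha=5.0, dropout_rate=0.0, seed=9
            )
        )
        numeric_gradient_check(net)

    def test_multinomial_two_dense_gradients(self):
        net = build_multinomial_cnn(
            ModelConfig(
                n_filters=2,
                filter_length=3,
                alpha=3.0,
                dropout_rate=0.0,
                n_dense_layers=2,
                dense_hidden_units=5,
                seed=4,
            )
        )
        numeric_gradient_check(net)

    def test_trainable_alpha_gradient(self):
        net = build_multinomial_cnn(
            ModelConfig(
                n_filters=2,
                filter_length=3,
                alpha=4.0,
                trainable_alpha=True,
                dropout_rate=0.0,
                seed=5,
            )
        )
        numeric_gradient_check(net)

    @pytest.mark.parametrize("pooling", ["max", "sum", "average"])
    @pytest.mark.parametrize("activation", ["relu", "sigmoid", "tanh"])
    def test_poolings_and_activations(self, pooling, activation):
        net = build_multinomial_cnn(
            ModelConfig(
                n_filters=2,
                filter_length=3,
                alpha=2.0,
                activation=activation,
                pooling=pooling,
                dropout_rate=0.0,
                seed=6,
            )
        )
        numeric_gradient_check(net, n=3, length=10)

    def test_conventional_network_gradients(self):
        net = build_conventional_cnn(
            ConventionalConfig(
                filters_per_layer=(3, 2), filter_length=3, dropout_rate=0.0, seed=7
            )
        )
        numeric_gradient_check(net, n=3, length=12)


class TestTraining:
    def test_loss_decreases_on_noiseless_data(self, tiny_dataset, tiny_config):
        data, _ = tiny_dataset
        decreased = 0
        for seed in range(10):
            cfg = ModelConfig(**{**tiny_config.__dict__, "seed": seed})
            model = train(build_multinomial_cnn(cfg), data.subset(range(64)),
                          data.subset(range(64, 80)))
            losses = model.history["train_loss"]
            if all(b < a for a, b in zip(losses, losses[1:])):
                decreased += 1
        assert decreased >= 9

    def test_zero_epoch_budget_keeps_initialization(self, tiny_config):
        cfg = ModelConfig(**{**tiny_config.__dict__, "max_epochs": 0})
        net = build_multinomial_cnn(cfg)
        before = {k: v.copy() for k, v in net.get_state().items()}
        data = MPRADataset(["ACGTACGTAC"] * 4, np.arange(4.0))
        model = train(net, data)
        after = model.network.get_state()
        for key in before:
            assert np.array_equal(before[key], after[key])

    def test_constant_activities_converge_to_constant(self, tiny_config):
        rng = np.random.default_rng(3)
        seqs = random_sequences(rng, 40, 20)
        data = MPRADataset(seqs, np.full(40, 3.0))
        cfg = ModelConfig(**{**tiny_config.__dict__, "max_epochs": 30})
        init_mse = mse_loss(
            data.activities, predict(build_multinomial_cnn(cfg), seqs)
        )
        model = train(build_multinomial_cnn(cfg), data)
        final_mse = mse_loss(data.activities, predict(model, seqs))
        assert final_mse < init_mse
        assert np.allclose(predict(model, seqs), 3.0, atol=1.0)

    def test_empty_dataset_raises(self, tiny_config):
        with pytest.raises(DataError):
            MPRADataset([], np.array([]))

    def test_divergence_raises_with_epoch(self, tiny_config):
        data = MPRADataset(["ACGTACGTAC"] * 8, np.full(8, 1e200))
        with pytest.raises(DivergenceError) as excinfo:
            train(build_multinomial_cnn(tiny_config), data)
        assert excinfo.value.epoch == 0

    def test_validation_length_mismatch(self, tiny_config):
        data = MPRADataset(["ACGTACGTAC"] * 4, np.arange(4.0))
        val = MPRADataset(["ACGTACGT"] * 2, np.arange(2.0))
        with pytest.raises(DimensionError):
            train(build_multinomial_cnn(tiny_config), data, val)

    def test_training_determinism(self, tiny_dataset, tiny_config):
        data, _ = tiny_dataset
        runs = []
        for _ in range(2):
            model = train(
                build_multinomial_cnn(tiny_config),
                data.subset(range(64)),
                data.subset(range(64, 80)),
            )
            runs.append(model.history["train_loss"])
        assert runs[0] == runs[1]


class TestPredict:
    def test_repeated_calls_identical(self, tiny_config):
        net = build_multinomial_cnn(tiny_config)
        seqs = ["ACGTACGTACGTACGT", "TTTTACGTACGTACGT"]
        assert np.array_equal(predict(net, seqs), predict(net, seqs))

    def test_permutation_equivariance(self, tiny_config):
        rng = np.random.default_rng(4)
        net = build_multinomial_cnn(tiny_config)
        seqs = random_sequences(rng, 6, 20)
        out = predict(net, seqs)
        perm = [3, 1, 5, 0, 4, 2]
        assert np.allclose(predict(net, [seqs[i] for i in perm]), out[perm])

    def test_length_mismatch_after_training(self, tiny_dataset, tiny_config):
        data, _ = tiny_dataset
        cfg = ModelConfig(**{**tiny_config.__dict__, "max_epochs": 1})
        model = train(build_multinomial_cnn(cfg), data.subset(range(16)))
        with pytest.raises(DimensionError):
            predict(model, ["ACGT"])


class TestCheckpoint:
    def test_round_trip(self, tiny_dataset, tiny_config, tmp_path):
        data, _ = tiny_dataset
        cfg = ModelConfig(**{**tiny_config.__dict__, "max_epochs": 2})
        model = train(
            build_multinomial_cnn(cfg),
            data.subset(range(64)),
            data.subset(range(64, 80)),
        )
        path = tmp_path / "checkpoint.json"
        save_model(model, path)
        restored = load_model(path)
        assert np.allclose(
            predict(model, data.sequences[:5]), predict(restored, data.sequences[:5])
        )
        assert restored.history["train_loss"] == model.history["train_loss"]
        assert isinstance(restored, TrainedModel)

    def test_conventional_round_trip(self, tmp_path):
        net = build_conventional_cnn(
            ConventionalConfig(filters_per_layer=(3,), dropout_rate=0.0)
        )
        model = TrainedModel(network=net)
        path = tmp_path / "conv.json"
        save_model(model, path)
        restored = load_model(path)
        seqs = ["ACGTACGTACGT"]
        assert np.allclose(predict(net, seqs), predict(restored, seqs))
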