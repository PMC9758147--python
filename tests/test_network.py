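"""Architecture accounting, training behavior and evaluation."""

import numpy as np
import pytest

import psmdim as p
from psmdim.network import TrainingDivergenceError


def _conv(filters, kernel=(3, 3)):
    return p.LayerSpec("conv", filters=filters, kernel=kernel, activation="relu")


class TestParameterCounting:
    @pytest.mark.parametrize(
        "layer,input_size,expected",
        [
            (_conv(32), 3, 896),
            (_conv(64), 32, 18496),
            (_conv(64), 64, 36928),
            (p.LayerSpec("dense", units=64), 576, 36928),
            (p.LayerSpec("dense", units=10), 64, 650),
            (_conv(1, kernel=(1, 1)), 1, 2),  # one weight plus one bias
            (p.LayerSpec("maxpool", kernel=(2, 2)), 32, 0),
            (p.LayerSpec("flatten"), 576, 0),
        ],
    )
    def test_closed_form(self, layer, input_size, expected):
        assert p.count_parameters(layer, input_size) == expected

    def test_spec_accounting(self):
        spec = p.default_network_spec()
        assert spec.parameter_counts() == [896, 18496, 36928, 36928, 650]
        assert spec.total_parameters() == 93898

    def test_built_network_matches_analytic_counts(self, untrained_network):
        spec = untrained_network.spec
        assert untrained_network.actual_parameter_counts() == spec.parameter_counts()


class TestOutputShapes:
    @pytest.mark.parametrize(
        "layer,input_shape,expected",
        [
            (_conv(32), (28, 28, 3), (26, 26, 32)),
            (p.LayerSpec("maxpool", kernel=(2, 2)), (26, 26, 32), (13, 13, 32)),
            (_conv(64), (13, 13, 32), (11, 11, 64)),
            # odd input floors under 2x2 pooling
            (p.LayerSpec("maxpool", kernel=(2, 2)), (11, 11, 64), (5, 5, 64)),
            (p.LayerSpec("flatten"), (3, 3, 64), 576),
            (p.LayerSpec("dense", units=64), 576, 64),
        ],
    )
    def test_single_layer(self, layer, input_shape, expected):
        assert p.output_shape(layer, input_shape) == expected

    def test_kernel_larger_than_input(self):
        with pytest.raises(ValueError, match="larger than input"):
            p.output_shape(_conv(8), (2, 2, 3))

    def test_full_stack(self):
        assert p.default_network_spec().output_shapes() == [
            (26, 26, 32), (13, 13, 32), (11, 11, 64), (5, 5, 64), (3, 3, 64),
            576, 64, 10,
        ]


class TestPrediction:
    def test_outputs_are_probability_distributions(self, untrained_network,
                                                   small_colored):
        probs = untrained_network.predict_proba(small_colored.images)
        assert probs.shape == (len(small_colored), 10)
        assert np.all(probs >= 0.0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_batching_invariance(self, untrained_network, small_colored):
        whole = untrained_network.predict_proba(small_colored.images, batch_size=32)
        split = untrained_network.predict_proba(small_colored.images, batch_size=7)
        assert np.allclose(whole, split, atol=1e-10)


@pytest.fixture(scope="module")
def trained(glyph_data):
    sub = glyph_data.subset(np.arange(200))
    ds = p.build_dataset(sub, p.ColorAssignment("RC"), seed=1)
    config = p.TrainingConfig(epochs=3, batch_size=32, seed=0)
    return p.train(p.default_network_spec(), ds, config)


class TestTraining:

    def test_loss_decreases_over_early_epochs(self, trained):
        losses = trained.history["loss"].to_numpy()
        assert losses[1] <= losses[0]

    def test_history_records_all_epochs(self, trained):
        assert list(trained.history["epoch"]) == [1, 2, 3]
        assert trained.history["accuracy"].between(0, 1).all()

    def test_deterministic_given_seed(self, glyph_data):
        sub = glyph_data.subset(np.arange(64))
        ds = p.build_dataset(sub, p.ColorAssignment("RC"), seed=1)
        config = p.TrainingConfig(epochs=1, batch_size=32, seed=5)
        a = p.train(p.default_network_spec(), ds, config)
        b = p.train(p.default_network_spec(), ds, config)
        assert np.array_equal(
            a.predict_proba(ds.images[:8]), b.predict_proba(ds.images[:8])
        )

    def test_non_finite_loss_raises(self, glyph_data):
        sub = glyph_data.subset(np.arange(64))
        ds = p.build_dataset(sub, p.ColorAssignment("RC"), seed=1)
        corrupted = p.ColorDataset(
            np.where(ds.images > 0.5, np.nan, ds.images), ds.labels, ds.color_ids
        )
        config = p.TrainingConfig(epochs=1, batch_size=32, seed=0)
        with pytest.raises(TrainingDivergenceError, match="non-finite"):
            p.train(p.default_network_spec(), corrupted, config)

    def test_unsupported_compilation_rejected(self):
        with pytest.raises(ValueError, match="cross-entropy"):
            p.TrainingConfig(loss="mse")
        with pytest.raises(ValueError, match="rmsprop"):
            p.TrainingConfig(optimizer="sgd")


class _StubNetwork:
    """Predicts a fixed label sequence as one-hot probabilities."""

    def __init__(self, labels):
        self.labels = np.asarray(labels)

    def predict_proba(self, images, batch_size=256):
        out = np.zeros((len(self.labels), 10))
        out[np.arange(len(self.labels)), self.labels] = 1.0
        return out


class TestEvaluate:
    def _balanced_set(self, n_per_class=3):
        labels = np.repeat(np.arange(10), n_per_class)
        images = np.ones((labels.size, 28, 28, 3))
        return p.ColorDataset(images, labels, np.zeros(labels.size, dtype=int))

    def test_oracle_predictor(self):
        ds = self._balanced_set()
        result = p.evaluate(_StubNetwork(ds.labels), ds)
        assert result.accuracy == 1.0
        assert np.array_equal(result.confusion, np.eye(10))

    def test_constant_predictor_on_balanced_set(self):
        ds = self._balanced_set()
        result = p.evaluate(_StubNetwork(np.zeros(len(ds), dtype=int)), ds)
        assert result.accuracy == pytest.approx(0.1)

    def test_confusion_rows_sum_to_one(self, untrained_network, small_colored):
        result = p.evaluate(untrained_network, small_colored)
        present = np.bincount(small_colored.labels, minlength=10) > 0
        sums = result.confusion.sum(axis=1)
        assert np.allclose(sums[present], 1.0, atol=1e-9)
        assert np.all(sums[~present] == 0.0)

    def test_accuracy_equals_weighted_confusion_diagonal(self, untrained_network,
                                                         small_colored):
        result = p.evaluate(untrained_network, small_colored)
        freq = np.bincount(small_colored.labels, minlength=10) / len(small_colored)
        assert result.accuracy == pytest.approx(freq @ np.diag(result.confusion))

    def test_empty_test_set_rejected(self, untrained_network):
        empty = p.ColorDataset(
            np.empty((0, 28, 28, 3)), np.empty(0, dtype=int), np.empty(0, dtype=int)
        )
        with pytest.raises(ValueError, match="empty"):
            p.evaluate(untrained_network, empty)
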