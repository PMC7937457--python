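import numpy as np
import pytest

from lungcad.exceptions import TrainingDivergedError
from lungcad.network import LayerSpec, NetworkConfig, build_network
from lungcad.training import (
    LossRecord,
    TrainConfig,
    TrainState,
    cross_entropy_loss,
    gd_step,
    minibatch_iterator,
    momentum_step,
    mse_loss,
    one_hot,
    train,
)


def separable_toy(n_per_class=20, seed=0):
    """Linearly separable 2×2 'images': class 0 lights pixel (0,0), class 1
    pixel (0,1), plus small noise."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = rng.normal(0.0, 0.05, size=(2, 2))
            img[0, cls] += 1.0
            images.append(img)
            labels.append(cls)
    return np.asarray(images), np.asarray(labels)


def dense_toy_net(seed=0):
    cfg = NetworkConfig(input_side=2, seed=seed, layers=[
        LayerSpec("dense", units=4, activation="sigmoid"),
        LayerSpec("softmax_output")])
    return build_network(cfg)


class TestLosses:
    def test_mse_zero_at_perfect_prediction(self):
        t = one_hot([0, 1, 0])
        assert mse_loss(t, t) == 0.0

    def test_mse_of_a_fully_wrong_pair_is_one(self):
        assert mse_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_mse_matches_double_loop(self, rng):
        y = rng.uniform(size=(6, 2))
        t = one_hot(rng.integers(0, 2, size=6))
        expected = 0.5 * sum((t[n, k] - y[n, k]) ** 2
                             for n in range(6) for k in range(2))
        assert abs(mse_loss(y, t) - expected) < 1e-12

    def test_cross_entropy_of_confident_correct_is_small(self):
        y = np.array([[0.999, 0.001]])
        assert cross_entropy_loss(y, one_hot([0])) < 0.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros(3), np.zeros(2))


class TestMinibatches:
    def test_partition_sizes(self):
        sizes = [len(b) for b in minibatch_iterator(10, 3, seed=0)]
        assert sizes == [3, 3, 3, 1]

    def test_same_seed_same_order(self):
        a = np.concatenate(list(minibatch_iterator(20, 7, seed=5)))
        b = np.concatenate(list(minibatch_iterator(20, 7, seed=5)))
        assert np.array_equal(a, b)

    def test_distinct_seeds_give_distinct_orders(self):
        orders = {tuple(np.concatenate(list(minibatch_iterator(30, 30, seed=s))))
                  for s in range(5)}
        assert len(orders) == 5

    def test_each_index_appears_exactly_once(self):
        idx = np.sort(np.concatenate(list(minibatch_iterator(23, 4, seed=1))))
        assert np.array_equal(idx, np.arange(23))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            list(minibatch_iterator(0, 2, seed=0))


def _scalar_state(value):
    p = np.array([value])
    return TrainState(parameters=[("w", p)], velocities=[np.zeros(1)])


class TestUpdateSteps:
    def test_zero_gradient_leaves_parameters(self):
        s = _scalar_state(1.0)
        gd_step(s, [("w", np.zeros(1))], eta=0.1)
        assert s.parameters[0][1][0] == 1.0

    def test_scalar_descent_step(self):
        s = _scalar_state(1.0)
        gd_step(s, [("w", np.array([2.0]))], eta=0.1)
        np.testing.assert_allclose(s.parameters[0][1], [0.8])

    def test_momentum_zero_reduces_to_gd(self):
        a, b = _scalar_state(1.0), _scalar_state(1.0)
        for _ in range(5):
            gd_step(a, [("w", np.array([0.3]))], eta=0.1)
            momentum_step(b, [("w", np.array([0.3]))], eta=0.1, m=0.0)
        assert np.array_equal(a.parameters[0][1], b.parameters[0][1])

    def test_velocity_converges_to_geometric_limit(self):
        s = _scalar_state(0.0)
        g = np.array([2.0])
        for _ in range(200):
            momentum_step(s, [("w", g)], eta=0.01, m=0.9)
        np.testing.assert_allclose(s.velocities[0], [-0.01 * 2.0 / 0.1],
                                   rtol=1e-6)

    def test_momentum_beats_gd_on_ill_conditioned_quadratic(self):
        """Heavy-ball reaches loss 1e-6 on ½(x² + 25y²) in fewer steps."""
        def grad(p):
            return np.array([p[0], 25.0 * p[1]])

        def loss(p):
            return 0.5 * (p[0] ** 2 + 25.0 * p[1] ** 2)

        def run(m):
            s = TrainState(parameters=[("p", np.array([5.0, 5.0]))],
                           velocities=[np.zeros(2)])
            for step in range(1, 5001):
                p = s.parameters[0][1]
                if m:
                    momentum_step(s, [("p", grad(p))], eta=0.02, m=0.9)
                else:
                    gd_step(s, [("p", grad(p))], eta=0.02)
                if loss(s.parameters[0][1]) < 1e-6:
                    return step
            return 5001

        assert run(0.9) < run(0.0)

    def test_nonfinite_gradient_aborts_with_layer_name(self):
        s = _scalar_state(1.0)
        with pytest.raises(TrainingDivergedError, match="layer3.weights"):
            gd_step(s, [("layer3.weights", np.array([np.inf]))], eta=0.1)


class TestTrainLoop:
    def test_zero_iterations_change_nothing(self):
        images, labels = separable_toy()
        net = dense_toy_net()
        before = [a.copy() for _, a in net.parameter_arrays()]
        _, record = train(net, images, labels,
                          TrainConfig(iterations=0, batch_size=10))
        assert record.losses == []
        for b, (_, a) in zip(before, net.parameter_arrays()):
            assert np.array_equal(b, a)

    def test_separable_toy_reaches_full_training_accuracy(self):
        images, labels = separable_toy()
        net = dense_toy_net()
        cfg = TrainConfig(eta=0.02, batch_size=10, momentum=0.9,
                          iterations=30, seed=0)
        net, record = train(net, images, labels, cfg)
        assert np.mean(net.predict(images) == labels) == 1.0
        assert len(record.losses) == 30

    def test_fixed_seed_gives_bitwise_identical_history(self):
        images, labels = separable_toy()
        histories = []
        for _ in range(2):
            net = dense_toy_net(seed=1)
            cfg = TrainConfig(eta=0.02, batch_size=10, momentum=0.9,
                              iterations=10, seed=3)
            _, record = train(net, images, labels, cfg,
                              eval_images=images, eval_labels=labels)
            histories.append(record)
        assert histories[0].losses == histories[1].losses
        assert histories[0].accuracies == histories[1].accuracies

    def test_loss_trend_nonincreasing_after_warmup(self):
        """Windowed trend check on the separable task: over any 10-pass
        window after pass 5 the loss does not grow by more than 5%."""
        images, labels = separable_toy()
        for seed in range(3):
            net = dense_toy_net(seed=seed)
            cfg = TrainConfig(eta=0.02, batch_size=10, momentum=0.9,
                              iterations=25, seed=seed)
            _, record = train(net, images, labels, cfg)
            losses = record.losses
            for i in range(5, len(losses) - 10):
                assert losses[i + 10] <= losses[i] * 1.05

    def test_batch_larger_than_dataset_rejected(self):
        images, labels = separable_toy(n_per_class=3)
        with pytest.raises(ValueError):
            train(dense_toy_net(), images, labels, TrainConfig(batch_size=100))

    def test_history_frame_layout(self):
        images, labels = separable_toy()
        net = dense_toy_net()
        _, record = train(net, images, labels,
                          TrainConfig(iterations=3, batch_size=10),
                          eval_images=images, eval_labels=labels)
        frame = record.to_frame()
        assert list(frame.columns) == ["iteration", "loss", "accuracy"]
        assert len(frame) == 3


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"eta": 0.0}, {"momentum": 1.0}, {"batch_size": 0}, {"loss": "hinge"},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
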