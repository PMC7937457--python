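import numpy as np
import pytest

from lungcad.backprop import (
    conv_delta_from_pool,
    conv_param_grads,
    dense_backward,
    numerical_gradient_check,
    output_delta,
    pool_delta_from_conv,
    pool_param_grads,
    softmax_mse_delta,
)
from lungcad.core_layers import (
    ConvParams,
    DenseParams,
    PoolParams,
    conv_forward,
    pool_forward,
    sigmoid,
)
from lungcad.network import build_network
from lungcad.training import mse_loss, one_hot

from .conftest import toy_config
from .oracles import numeric_grad


class TestOutputDelta:
    def test_perfect_prediction_gives_zero(self):
        y = np.array([1.0, 0.0])
        assert np.all(output_delta(y, y, np.zeros(2), "sigmoid") == 0)

    def test_identity_activation_passes_residual(self):
        d = output_delta(np.array([0.2, -0.2]) + np.array([0.0, 0.0]),
                         np.zeros(2), np.zeros(2), "identity")
        np.testing.assert_allclose(d, [0.2, -0.2])

    def test_sigmoid_delta_matches_numerical(self, rng):
        u = rng.normal(size=3)
        t = np.array([1.0, 0.0, 0.0])
        d = output_delta(sigmoid(u), t, u, "sigmoid")
        numeric = numeric_grad(lambda uu: mse_loss(sigmoid(uu), t), u)
        np.testing.assert_allclose(d, numeric, atol=1e-7)

    def test_softmax_delta_matches_numerical(self, rng):
        from lungcad.core_layers import softmax

        u = rng.normal(size=2)
        t = np.array([0.0, 1.0])
        d = softmax_mse_delta(softmax(u), t)
        numeric = numeric_grad(lambda uu: mse_loss(softmax(uu), t), u)
        np.testing.assert_allclose(d, numeric, atol=1e-7)


class TestDenseBackward:
    def test_zero_delta_zero_everything(self, rng):
        p = DenseParams.initialize(rng, 5, 3)
        d_prev, grads = dense_backward(np.zeros(3), p, np.zeros(5),
                                       rng.normal(size=5), "sigmoid")
        assert np.all(d_prev == 0) and np.all(grads.weights == 0)

    def test_scalar_chain_rule(self):
        p = DenseParams(weights=np.array([[2.0]]), bias=np.zeros(1),
                        activation="identity")
        d_prev, _ = dense_backward(np.array([0.3]), p, np.zeros(1),
                                   np.ones(1), "identity")
        np.testing.assert_allclose(d_prev, [0.6])

    def test_random_layer_matches_numerical(self, rng):
        """5→3 sigmoid layer: ∂E/∂W and the propagated δ both check out."""
        w = rng.normal(size=(3, 5))
        b = rng.normal(size=3)
        u_prev = rng.normal(size=5)
        t = np.array([0.0, 1.0, 0.0])

        def loss_for(weights):
            x = sigmoid(u_prev)
            return mse_loss(x @ weights.T + b, t)

        x_prev = sigmoid(u_prev)
        p = DenseParams(weights=w, bias=b, activation="identity")
        delta = output_delta(x_prev @ w.T + b, t, x_prev @ w.T + b, "identity")
        d_prev, grads = dense_backward(delta, p, u_prev, x_prev, "sigmoid")
        np.testing.assert_allclose(grads.weights, numeric_grad(loss_for, w),
                                   atol=1e-7)
        numeric_dprev = numeric_grad(
            lambda uu: mse_loss(sigmoid(uu) @ w.T + b, t), u_prev)
        np.testing.assert_allclose(d_prev, numeric_dprev, atol=1e-7)


class TestPoolRouting:
    def test_mean_mode_shares_delta_equally(self):
        p = PoolParams.initialize(1, mode="mean", window=2)
        x = np.arange(4.0).reshape(1, 2, 2)
        _, cache = pool_forward(x, p)
        d = conv_delta_from_pool(np.full((1, 1, 1), 4.0), p,
                                 np.zeros((1, 2, 2)), cache, activation="identity")
        np.testing.assert_allclose(d, np.ones((1, 2, 2)))

    def test_max_mode_routes_to_winner_only(self):
        p = PoolParams.initialize(1, mode="max", window=2)
        x = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        _, cache = pool_forward(x, p)
        d = conv_delta_from_pool(np.full((1, 1, 1), 4.0), p,
                                 np.zeros((1, 2, 2)), cache, activation="identity")
        np.testing.assert_array_equal(d, [[[0.0, 0.0], [0.0, 4.0]]])

    @pytest.mark.parametrize("mode", ["mean", "max"])
    def test_random_stack_matches_numerical(self, rng, mode):
        """δ through pool_forward agrees with central differences on u_conv."""
        p = PoolParams(mode=mode, window=2, beta=np.array([1.5, 0.7]),
                       bias=np.array([0.1, -0.2]), activation="identity")
        u_conv = rng.normal(size=(2, 4, 4))
        t = rng.normal(size=(2, 2, 2))

        def loss_of(u):
            out, _ = pool_forward(sigmoid(u), p)
            return 0.5 * ((out - t) ** 2).sum()

        out, cache = pool_forward(sigmoid(u_conv), p)
        delta_pool = out - t                         # identity f at the pool
        d_conv = conv_delta_from_pool(delta_pool, p, u_conv, cache,
                                      activation="sigmoid")
        np.testing.assert_allclose(d_conv, numeric_grad(loss_of, u_conv),
                                   atol=1e-6)


class TestConvGrads:
    def test_zero_delta_zero_grads(self, rng):
        g = conv_param_grads(np.zeros((2, 3, 3)), rng.normal(size=(1, 5, 5)))
        assert np.all(g.kernels == 0) and np.all(g.biases == 0)

    def test_one_by_one_case_is_scalar_product(self):
        x = np.full((1, 1, 1), 3.0)
        d = np.full((1, 1, 1), 0.5)
        g = conv_param_grads(d, x)
        assert g.kernels[0, 0, 0, 0] == 1.5

    def test_random_case_matches_numerical(self, rng):
        x = rng.normal(size=(2, 8, 8))
        kern = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        t = rng.normal(size=(3, 6, 6))

        def loss_of(kk):
            p = ConvParams(kernels=kk, biases=b, activation="identity")
            return 0.5 * ((conv_forward(x, p) - p.biases[:, None, None] * 0 - t) ** 2).sum()

        p = ConvParams(kernels=kern, biases=b, activation="identity")
        delta = conv_forward(x, p) - t
        g = conv_param_grads(delta, x)
        np.testing.assert_allclose(g.kernels, numeric_grad(loss_of, kern),
                                   atol=1e-6)
        np.testing.assert_allclose(g.biases, delta.sum(axis=(1, 2)), atol=1e-12)


class TestPoolDeltaFromConv:
    def test_single_delta_paints_rotated_kernel(self):
        kern = np.arange(9.0).reshape(1, 1, 3, 3)
        p = ConvParams(kernels=kern, biases=np.zeros(1), activation="identity")
        d = pool_delta_from_conv(np.full((1, 1, 1), 2.0), p,
                                 np.zeros((1, 3, 3)), activation="identity")
        np.testing.assert_allclose(d[0], 2.0 * kern[0, 0])

    def test_zero_delta_zero_map(self, rng):
        p = ConvParams.initialize(rng, 1, 2, 3)
        d = pool_delta_from_conv(np.zeros((2, 4, 4)), p, np.zeros((1, 6, 6)))
        assert np.all(d == 0)

    def test_random_case_matches_numerical(self, rng):
        p = ConvParams(kernels=rng.normal(size=(2, 1, 3, 3)),
                       biases=rng.normal(size=2), activation="identity")
        x_pool = rng.normal(size=(1, 6, 6))
        t = rng.normal(size=(2, 4, 4))

        def loss_of(xx):
            return 0.5 * ((conv_forward(xx, p) - t) ** 2).sum()

        delta_conv = conv_forward(x_pool, p) - t
        d = pool_delta_from_conv(delta_conv, p, x_pool, activation="identity")
        np.testing.assert_allclose(d, numeric_grad(loss_of, x_pool), atol=1e-6)


class TestPoolParamGrads:
    def test_constant_field(self):
        p = PoolParams.initialize(1, mode="mean", window=2)
        x = np.full((1, 4, 4), 6.0)
        _, cache = pool_forward(x, p)
        g = pool_param_grads(np.ones((1, 2, 2)), cache)
        assert g.beta[0] == 6.0 * 4 and g.bias[0] == 4.0

    def test_max_mode_is_noop(self):
        p = PoolParams.initialize(1, mode="max", window=2)
        _, cache = pool_forward(np.arange(16.0).reshape(1, 4, 4), p)
        g = pool_param_grads(np.ones((1, 2, 2)), cache)
        assert np.all(g.beta == 0) and np.all(g.bias == 0)

    def test_random_case_matches_numerical(self, rng):
        x = rng.normal(size=(2, 4, 4))
        t = rng.normal(size=(2, 2, 2))
        beta0 = rng.normal(size=2)
        bias0 = rng.normal(size=2)

        def loss_of(bb):
            p = PoolParams(mode="mean", window=2, beta=bb, bias=bias0,
                           activation="identity")
            out, _ = pool_forward(x, p)
            return 0.5 * ((out - t) ** 2).sum()

        p = PoolParams(mode="mean", window=2, beta=beta0, bias=bias0,
                       activation="identity")
        out, cache = pool_forward(x, p)
        g = pool_param_grads(out - t, cache)
        np.testing.assert_allclose(g.beta, numeric_grad(loss_of, beta0),
                                   atol=1e-6)


class TestWholeNetworkOracle:
    def test_zero_network_zero_image_at_machine_precision(self):
        """In the all-zero configuration only central-difference truncation
        (~1e-12) separates analytic from numerical gradients."""
        net = build_network(toy_config())
        for _, arr in net.parameter_arrays():
            arr[...] = 0.0
        err = numerical_gradient_check(net, np.zeros((8, 8)), one_hot([0])[0])
        assert err < 1e-10

    @pytest.mark.parametrize("pooling", ["mean", "max"])
    @pytest.mark.parametrize("loss", ["mse", "cross_entropy"])
    def test_sigmoid_toy_net_under_1e6(self, rng, pooling, loss):
        net = build_network(toy_config(pooling=pooling, seed=11))
        err = numerical_gradient_check(net, rng.uniform(size=(8, 8)),
                                       one_hot([1])[0], loss=loss)
        assert err < 1e-6

    def test_relu_net_off_kink_under_1e4(self, rng):
        net = build_network(toy_config(activation="relu", seed=7))
        err = numerical_gradient_check(net, rng.uniform(size=(8, 8)),
                                       one_hot([0])[0])
        assert err < 1e-4

    def test_single_small_step_decreases_loss(self):
        """One η=1e-2 step on one example strictly reduces E, 20 seeds."""
        from lungcad.training import evaluate_loss

        wins = 0
        for seed in range(20):
            net = build_network(toy_config(seed=seed))
            g = np.random.default_rng(seed)
            img = g.uniform(size=(8, 8))
            t = one_hot([int(g.integers(0, 2))])[0]
            before = evaluate_loss(net, img, t)
            _, cache = net.forward(img)
            grads = net.backward(cache, t)
            for (_, p), (_, gr) in zip(net.parameter_arrays(),
                                       grads.named_arrays()):
                p -= 1e-2 * gr
            after = evaluate_loss(net, img, t)
            wins += after < before
        assert wins == 20
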