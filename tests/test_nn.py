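"""Engine checks: analytic gradients vs finite differences, losses, SGD."""

import numpy as np
import pytest

from nirsbreath.nn.layers import (
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    ConvTranspose1d,
    Linear,
    PreActBottleneck,
    ReLU,
    Sequential,
)
from nirsbreath.nn.losses import cross_entropy, mse_reconstruction, total_loss
from nirsbreath.nn.optim import SGD


def numerical_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(layer, x, rng, atol=1e-7):
    y = layer.forward(x, train=True)
    t = rng.normal(size=y.shape)  # linear probe loss sum(t * y)
    layer.zero_grad()
    gx = layer.backward(t)

    def loss():
        return float((t * layer.forward(x, train=True)).sum())

    scale = max(1.0, float(np.abs(t).max()) * 10)
    np.testing.assert_allclose(gx, numerical_grad(loss, x), atol=atol * scale,
                               rtol=1e-5)
    for p in layer.parameters():
        np.testing.assert_allclose(
            p.grad, numerical_grad(loss, p.data), atol=atol * scale, rtol=1e-5,
            err_msg=f"parameter {p.name}",
        )


LAYER_CASES = {
    "conv_k3_s1": lambda rng: Conv1d(5, 4, 3, rng=rng),
    "conv_k7_s4": lambda rng: Conv1d(5, 4, 7, stride=4, rng=rng),
    "conv_k1_s2": lambda rng: Conv1d(5, 4, 1, stride=2, rng=rng),
    "tconv_k1_s2_op1": lambda rng: ConvTranspose1d(5, 4, 1, stride=2,
                                                   output_padding=1, rng=rng),
    "tconv_k5_s3_p1": lambda rng: ConvTranspose1d(5, 4, 5, stride=3, padding=1,
                                                  rng=rng),
    "tconv_k7_s4_p2_op1": lambda rng: ConvTranspose1d(5, 4, 7, stride=4,
                                                      padding=2,
                                                      output_padding=1, rng=rng),
    "batchnorm": lambda rng: BatchNorm1d(5),
    "relu": lambda rng: ReLU(),
    "avgpool": lambda rng: AvgPool1d(),
    "unit_identity": lambda rng: PreActBottleneck(5, 3, 3, 5, rng=rng),
    "unit_projected_strided": lambda rng: PreActBottleneck(5, 3, 3, 8, stride=2,
                                                           rng=rng),
    "unit_transposed": lambda rng: PreActBottleneck(5, 6, 3, 4, stride=2,
                                                    transposed=True,
                                                    output_padding=1, rng=rng),
}


class TestGradients:
    @pytest.mark.parametrize("name", sorted(LAYER_CASES))
    def test_backward_matches_finite_differences(self, name, rng):
        layer = LAYER_CASES[name](rng)
        x = rng.normal(size=(3, 5, 12))
        assert_grads_match(layer, x, rng)

    def test_linear_gradients(self, rng):
        assert_grads_match(Linear(6, 3, rng=rng), rng.normal(size=(4, 6)), rng)

    def test_sequential_chains_gradients(self, rng):
        seq = Sequential(Conv1d(2, 3, 3, rng=rng), BatchNorm1d(3), ReLU(),
                         Conv1d(3, 2, 3, stride=2, rng=rng))
        assert_grads_match(seq, rng.normal(size=(2, 2, 10)), rng)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = BatchNorm1d(3)
        x = rng.normal(loc=2.0, scale=3.0, size=(16, 3, 20))
        for _ in range(50):
            bn.forward(x, train=True)
        y = bn.forward(x, train=False)
        assert abs(y.mean()) < 0.1
        assert abs(y.std() - 1) < 0.1


class TestGeometry:
    @pytest.mark.parametrize(
        "L_in, L_out, k, s",
        [(16, 32, 1, 2), (32, 96, 5, 3), (96, 384, 7, 4), (10, 10, 3, 1)],
    )
    def test_transposed_geometry_solves_exact_lengths(self, L_in, L_out, k, s):
        p, op = ConvTranspose1d.geometry_for(L_in, L_out, k, s)
        layer = ConvTranspose1d(2, 2, k, stride=s, padding=p, output_padding=op)
        assert layer.out_length(L_in) == L_out
        y = layer.forward(np.zeros((1, 2, L_in)))
        assert y.shape == (1, 2, L_out)

    @pytest.mark.parametrize(
        "L_in, k, s, expected", [(384, 7, 4, 96), (96, 7, 3, 32), (32, 3, 2, 16),
                                 (32, 1, 2, 16)]
    )
    def test_conv_stage_lengths(self, L_in, k, s, expected):
        assert Conv1d(1, 1, k, stride=s).out_length(L_in) == expected


class TestLosses:
    def test_reconstruction_hand_example(self):
        # N=1, X=[1,2], X_hat=[1,0]: squared distance 0^2 + 2^2 = 4
        X = np.array([[[1.0, 2.0]]])
        X_hat = np.array([[[1.0, 0.0]]])
        loss, grad = mse_reconstruction(X, X_hat)
        assert loss == pytest.approx(4.0)
        np.testing.assert_allclose(grad, [[[0.0, -4.0]]])

    def test_reconstruction_perfect_and_nonnegative(self, rng):
        X = rng.normal(size=(4, 2, 8))
        assert mse_reconstruction(X, X.copy())[0] == 0.0
        assert mse_reconstruction(X, rng.normal(size=X.shape))[0] > 0.0

    def test_reduction_scaling(self, rng):
        X = rng.normal(size=(4, 2, 8))
        Xh = rng.normal(size=X.shape)
        s, _ = mse_reconstruction(X, Xh, reduction="sample_sum")
        m, _ = mse_reconstruction(X, Xh, reduction="mean")
        assert s == pytest.approx(m * 16)

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_reconstruction(np.zeros((1, 2, 3)), np.zeros((1, 2, 4)))

    def test_total_loss_arithmetic(self):
        assert total_loss(4.0, 0.5, alpha=10.0) == pytest.approx(9.0)
        assert total_loss(4.0, 123.0, alpha=0.0) == pytest.approx(4.0)

    def test_cross_entropy_matches_closed_form(self, rng):
        logits = rng.normal(size=(5, 4))
        labels = np.array([0, 1, 2, 3, 1])
        loss, grad = cross_entropy(logits, labels)
        # independent closed form via scipy
        from scipy.special import log_softmax

        expected = -log_softmax(logits, axis=1)[np.arange(5), labels].mean()
        assert loss == pytest.approx(float(expected))
        # gradient check
        g = numerical_grad(lambda: cross_entropy(logits, labels)[0], logits)
        np.testing.assert_allclose(grad, g, atol=1e-8)

    def test_cross_entropy_perfect_prediction_low_loss(self):
        logits = np.array([[20.0, 0.0, 0.0, 0.0]])
        loss, _ = cross_entropy(logits, np.array([0]))
        assert loss < 1e-6


class TestSGD:
    def test_momentum_update_hand_computed(self):
        from nirsbreath.nn.layers import Param

        p = Param(np.array([1.0]))
        opt = SGD([p], lr=0.1, momentum=0.9)
        p.grad[:] = 2.0
        opt.step()  # v = 2 -> p = 1 - 0.2 = 0.8
        assert p.data[0] == pytest.approx(0.8)
        p.grad[:] = 0.0
        opt.step()  # v = 1.8 -> p = 0.8 - 0.18
        assert p.data[0] == pytest.approx(0.62)

    def test_single_step_descends_on_a_batch(self, rng):
        # descent sanity: at a small learning rate one step on one batch
        # strictly decreases that batch's loss
        layer = Sequential(Conv1d(2, 4, 3, rng=rng), BatchNorm1d(4), ReLU(),
                           AvgPool1d(), Linear(4, 3, rng=rng))
        x = rng.normal(size=(8, 2, 16))
        yb = rng.integers(0, 3, size=8)
        logits = layer.forward(x, train=True)
        loss0, grad = cross_entropy(logits, yb)
        layer.zero_grad()
        layer.backward(grad)
        SGD(layer.parameters(), lr=1e-3, momentum=0.0).step()
        loss1, _ = cross_entropy(layer.forward(x, train=True), yb)
        assert loss1 < loss0
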