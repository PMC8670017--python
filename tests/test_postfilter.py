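"""Convolutional post-filter: forward pass, momentum updates, training."""

import numpy as np
import pytest
from scipy.ndimage import correlate

import ctrecon as cr
from ctrecon.postfilter import loss_and_gradients


def brute_force_correlate(x, kernel):
    """Nested-loop valid correlation with edge-replicating symmetric padding."""
    k = kernel.shape[0]
    half = k // 2
    xp = np.pad(x, half, mode="symmetric")
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            acc = 0.0
            for u in range(k):
                for v in range(k):
                    acc += kernel[u, v] * xp[i + u, j + v]
            out[i, j] = acc
    return out


class TestConvForward:
    def test_identity_kernel_is_identity(self, rng):
        x = cr.ImageGrid(rng.random((16, 16)))
        out = cr.conv_forward(x, cr.KernelState.identity(3))
        np.testing.assert_array_equal(out.pixels, x.pixels)

    def test_mean_kernel_fixes_constants(self):
        ks = cr.KernelState(np.full((3, 3), 1.0 / 9.0))
        out = cr.conv_forward(np.full((8, 8), 4.0), ks)
        np.testing.assert_allclose(out, 4.0)

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.random((5, 5))
        ks = cr.KernelState(rng.standard_normal((3, 3)), bias=0.3)
        got = cr.conv_forward(x, ks)
        expected = brute_force_correlate(x, ks.kernel) + 0.3
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_relu_clamps_negative_outputs(self):
        ks = cr.KernelState.identity(3, bias=-10.0, activation="relu")
        out = cr.conv_forward(np.ones((6, 6)), ks)
        assert (out == 0.0).all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            cr.KernelState(np.ones((2, 2)))


class TestMomentumUpdate:
    def test_zero_gradient_zero_velocity_is_a_fixed_point(self):
        ks = cr.KernelState.identity(3)
        out = cr.momentum_update(ks, np.zeros((3, 3)))
        np.testing.assert_array_equal(out.kernel, ks.kernel)

    def test_beta_zero_is_plain_gradient_descent(self, rng):
        g = rng.standard_normal((3, 3))
        ks = cr.KernelState(np.zeros((3, 3)), beta=0.0, lr=0.05)
        out = cr.momentum_update(ks, g)
        np.testing.assert_array_equal(out.kernel, -0.05 * g)

    def test_two_constant_gradient_steps_unroll(self):
        # velocity: -lr*g then -(beta*lr + lr)*g -> steps of 0.1g and 0.19g
        g = np.ones((3, 3))
        ks = cr.KernelState(np.zeros((3, 3)), beta=0.9, lr=0.1)
        k1 = cr.momentum_update(ks, g)
        k2 = cr.momentum_update(k1, g)
        np.testing.assert_allclose(k1.kernel, -0.1 * g, atol=1e-15)
        np.testing.assert_allclose(k2.kernel - k1.kernel, -0.19 * g, atol=1e-15)

    def test_literal_printed_rule_feeds_on_the_kernel(self):
        # momentum applied to the kernel itself grows it even with zero
        # gradient — the reason the standard velocity form is the default
        ks = cr.KernelState(np.ones((3, 3)), beta=0.5, lr=0.1)
        out = ks
        for _ in range(10):
            out = cr.momentum_update(out, np.zeros((3, 3)), literal_update=True)
        assert np.abs(out.kernel).max() > np.abs(ks.kernel).max()

    def test_nonfinite_gradient_rejected(self):
        ks = cr.KernelState.identity(3)
        with pytest.raises(ValueError):
            cr.momentum_update(ks, np.full((3, 3), np.nan))


class TestGradients:
    @pytest.mark.parametrize("activation", ["identity", "relu"])
    def test_analytic_gradient_matches_finite_differences(self, rng, activation):
        x = rng.random((12, 12))
        y = rng.random((12, 12))
        ks = cr.KernelState.random(3, 0.3, seed=2, activation=activation, bias=0.05)
        _, grad_h, grad_b = loss_and_gradients(x, y, ks)
        eps = 1e-6
        num = np.zeros_like(grad_h)
        for u in range(3):
            for v in range(3):
                kp, km = ks.copy(), ks.copy()
                kp.kernel[u, v] += eps
                km.kernel[u, v] -= eps
                num[u, v] = (
                    loss_and_gradients(x, y, kp)[0] - loss_and_gradients(x, y, km)[0]
                ) / (2 * eps)
        assert np.abs(grad_h - num).max() / np.abs(num).max() < 1e-5
        kp, km = ks.copy(), ks.copy()
        kp.bias += eps
        km.bias -= eps
        num_b = (loss_and_gradients(x, y, kp)[0] - loss_and_gradients(x, y, km)[0]) / (2 * eps)
        assert abs(grad_b - num_b) / abs(num_b) < 1e-5


class TestTraining:
    def test_perfect_pairs_leave_identity_kernel_unchanged(self, rng):
        imgs = [rng.random((16, 16)) for _ in range(3)]
        pairs = [(im, im) for im in imgs]
        ks0 = cr.KernelState.identity(3, lr=0.1)
        ksf, trace = cr.train_postfilter(pairs, ks0, epochs=5, seed=0)
        np.testing.assert_array_equal(ksf.kernel, ks0.kernel)
        assert trace[0] == 0.0

    def test_recovers_planted_mean_kernel(self, rng):
        pairs = []
        for _ in range(8):
            d = rng.random((32, 32))
            pairs.append((d, correlate(d, np.full((3, 3), 1.0 / 9.0), mode="reflect")))
        ks0 = cr.KernelState.identity(3, beta=0.9, lr=0.25)
        ksf, _ = cr.train_postfilter(pairs, ks0, epochs=200, seed=5)
        np.testing.assert_allclose(ksf.kernel, 1.0 / 9.0, atol=1e-2)

    def test_loss_decreases_on_noisy_fbp_pairs(self):
        pairs = []
        for i in range(10):
            spec = cr.sample_lung_phantom(i, n=64, pixel_size=4.0)
            truth = cr.render_phantom(spec)
            geom = cr.default_geometry(64, 60, pixel_size=4.0)
            sino = cr.radon_forward(truth, geom)
            noisy = cr.add_sinogram_noise(sino, "poisson", 1e4, seed=100 + i)
            rec = cr.fbp_reconstruct(noisy, "ram-lak")
            pairs.append((rec.pixels, truth.pixels))
        ks0 = cr.KernelState.identity(3, beta=0.9, lr=0.5)
        _, trace = cr.train_postfilter(pairs, ks0, epochs=40, seed=7)
        assert trace[-1] < trace[0]

    def test_small_step_full_batch_loss_non_increasing(self, rng):
        # beta=0, one pair: each epoch is one exact gradient step on a
        # quadratic objective; small lr must be monotone
        d = rng.random((16, 16))
        c = correlate(d, np.full((3, 3), 1.0 / 9.0), mode="reflect")
        ks0 = cr.KernelState.identity(3, beta=0.0, lr=0.05)
        _, trace = cr.train_postfilter([(d, c)], ks0, epochs=50, seed=0)
        assert np.all(np.diff(trace) <= 1e-15)

    def test_training_is_seed_reproducible(self, rng):
        pairs = [(rng.random((12, 12)), rng.random((12, 12))) for _ in range(4)]
        ks0 = cr.KernelState.random(3, 0.1, seed=1, lr=0.05)
        a, ta = cr.train_postfilter(pairs, ks0, epochs=10, seed=3)
        b, tb = cr.train_postfilter(pairs, ks0, epochs=10, seed=3)
        assert a.kernel.tobytes() == b.kernel.tobytes()
        assert ta.tobytes() == tb.tobytes()

    def test_divergence_aborts_with_diagnostic(self, rng):
        pairs = [(100.0 * rng.random((16, 16)), rng.random((16, 16)))]
        ks0 = cr.KernelState.identity(3, beta=0.9, lr=50.0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            cr.train_postfilter(pairs, ks0, epochs=100, seed=0)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            cr.train_postfilter([], cr.KernelState.identity(3), epochs=1)


def test_kernel_state_json_round_trip():
    ks = cr.KernelState.random(5, 0.2, seed=4, beta=0.8, lr=0.01, activation="relu")
    back = cr.KernelState.from_json(ks.to_json())
    np.testing.assert_array_equal(back.kernel, ks.kernel)
    assert back.beta == ks.beta and back.activation == ks.activation
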