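"""Gradient and correctness checks for the autodiff engine."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from nodseg.nn import autodiff as ad


def numeric_grad(build, arrs, i, eps=1e-3):
    g = np.zeros_like(arrs[i], dtype=np.float64)
    for ix in np.ndindex(arrs[i].shape):
        orig = arrs[i][ix]
        arrs[i][ix] = orig + eps
        fp = float((build([ad.Tensor(a) for a in arrs]).data.astype(np.float64) ** 2).sum())
        arrs[i][ix] = orig - eps
        fm = float((build([ad.Tensor(a) for a in arrs]).data.astype(np.float64) ** 2).sum())
        arrs[i][ix] = orig
        g[ix] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(build, arrs, tol=2e-2):
    ts = [ad.Tensor(a, requires_grad=True) for a in arrs]
    out = build(ts)
    ad.sum_all(ad.mul(out, out)).backward()
    for i, t in enumerate(ts):
        ng = numeric_grad(build, arrs, i)
        denom = max(1e-6, np.abs(ng).max())
        assert np.abs(t.grad - ng).max() / denom < tol, f"arg {i}"


@pytest.mark.parametrize("kernel", [(5, 5, 5), (3, 3, 3), (1, 3, 3), (3, 1, 1), (1, 1, 1)])
def test_conv3d_gradients(kernel, rng):
    x = rng.standard_normal((2, 3, 5, 6, 6)).astype(np.float32)
    w = (rng.standard_normal((4, 3) + kernel) * 0.3).astype(np.float32)
    b = rng.standard_normal(4).astype(np.float32)
    assert_grads_match(lambda t: ad.conv3d(*t), [x, w, b])


def test_conv3d_matches_direct_correlation(rng):
    """Independent oracle: scipy.ndimage same-padding correlation."""
    x = rng.standard_normal((1, 2, 5, 7, 7)).astype(np.float32)
    w = rng.standard_normal((3, 2, 3, 3, 3)).astype(np.float32)
    y = ad.conv3d(ad.Tensor(x), ad.Tensor(w)).data
    for o in range(3):
        ref = sum(correlate(x[0, c].astype(np.float64), w[o, c].astype(np.float64),
                            mode="constant") for c in range(2))
        np.testing.assert_allclose(y[0, o], ref, atol=1e-4)


def test_fft_and_im2col_paths_agree(rng):
    """The two convolution strategies compute the same operator."""
    w = rng.standard_normal((4, 3, 3, 3, 3)).astype(np.float32) * 0.3
    big = rng.standard_normal((1, 3, 11, 40, 40)).astype(np.float32)   # FFT route
    small = big[:, :, :, :10, :10]                                     # im2col route
    y_big = ad.conv3d(ad.Tensor(big), ad.Tensor(w)).data
    y_small = ad.conv3d(ad.Tensor(small), ad.Tensor(w)).data
    # interior voxels are identical where the receptive fields match
    np.testing.assert_allclose(y_big[:, :, :, 1:9, 1:9], y_small[:, :, :, 1:9, 1:9],
                               atol=2e-4)


@pytest.mark.parametrize("op", ["down", "up", "pool2", "pool3", "prelu",
                                "linear", "gmean", "upsample"])
def test_other_op_gradients(op, rng):
    x = rng.standard_normal((2, 3, 4, 6, 6)).astype(np.float32)
    if op == "down":
        w = rng.standard_normal((6, 3, 1, 2, 2)).astype(np.float32)
        assert_grads_match(lambda t: ad.down_conv2x2(*t), [x, w])
    elif op == "up":
        w = rng.standard_normal((3, 5, 2, 2)).astype(np.float32)
        assert_grads_match(lambda t: ad.up_conv2x2(*t), [x, w])
    elif op == "pool2":
        assert_grads_match(lambda t: ad.maxpool2x2(t[0]), [x])
    elif op == "pool3":
        assert_grads_match(lambda t: ad.maxpool3x3x3_s1(t[0]),
                           [rng.standard_normal((1, 2, 4, 5, 5)).astype(np.float32)])
    elif op == "prelu":
        a = (np.abs(rng.standard_normal(3)) * 0.3).astype(np.float32)
        assert_grads_match(lambda t: ad.prelu(t[0], t[1]), [x, a])
    elif op == "linear":
        xx = rng.standard_normal((5, 3)).astype(np.float32)
        w = rng.standard_normal((4, 3)).astype(np.float32)
        b = rng.standard_normal(4).astype(np.float32)
        assert_grads_match(lambda t: ad.linear(*t), [xx, w, b])
    elif op == "gmean":
        assert_grads_match(lambda t: ad.global_mean(t[0]), [x])
    elif op == "upsample":
        assert_grads_match(lambda t: ad.upsample2x_nearest(t[0]), [x])


def test_batchnorm_gradients(rng):
    x = rng.standard_normal((2, 3, 4, 3, 3)).astype(np.float32)
    r = rng.standard_normal(x.shape).astype(np.float32)
    gamma = (np.abs(rng.standard_normal(3)) + 0.5).astype(np.float32)
    beta = rng.standard_normal(3).astype(np.float32)

    def build(ts):
        rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
        y = ad.batch_norm(ts[0], ts[1], ts[2], rm, rv, training=True)
        return ad.mul(y, ad.Tensor(r))     # break the scale invariance

    assert_grads_match(build, [x, gamma, beta])


def test_batchnorm_eval_uses_running_stats(rng):
    x = rng.standard_normal((2, 3, 2, 2, 2)).astype(np.float32)
    gamma = ad.Tensor(np.ones(3, np.float32))
    beta = ad.Tensor(np.zeros(3, np.float32))
    rm, rv = np.full(3, 0.5, np.float32), np.full(3, 4.0, np.float32)
    y = ad.batch_norm(ad.Tensor(x), gamma, beta, rm, rv, training=False)
    np.testing.assert_allclose(y.data, (x - 0.5) / np.sqrt(4.0 + 1e-5), atol=1e-5)


def test_pool_axis_windows_matches_loop(rng):
    x = rng.standard_normal((2, 3, 4, 8, 6)).astype(np.float32)
    starts, sizes = np.array([0, 3, 5, 6]), np.array([3, 2, 1, 2])
    y = ad.pool_axis_windows(ad.Tensor(x), starts, sizes, axis=3).data
    for i, (s, k) in enumerate(zip(starts, sizes)):
        np.testing.assert_array_equal(y[:, :, :, i], x[:, :, :, s:s + k].max(axis=3))
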