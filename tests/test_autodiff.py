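"""The reverse-mode engine: gradients against finite differences and an
independent convolution oracle (scipy.ndimage)."""

import numpy as np
import pytest
from scipy import ndimage

from carapace_landmarks.autodiff import (Tensor, batch_norm, concat, conv2d,
                                         gradcheck, upsample_bilinear, where)
from carapace_landmarks.nn import Adam, Parameter

RNG = np.random.default_rng(2024)


def _t(shape):
    return Tensor(RNG.normal(size=shape), requires_grad=True)


class TestElementwiseGradients:
    @pytest.mark.parametrize("name,fn,shapes", [
        ("add_broadcast", lambda a, b: (a + b).sum(), [(3, 4), (4,)]),
        ("mul_broadcast", lambda a, b: (a * b).sum(), [(3, 4), (3, 1)]),
        ("div", lambda a, b: (a / (b * b + 1.0)).sum(), [(3, 4), (3, 4)]),
        ("sub", lambda a, b: ((a - b) ** 2).sum(), [(5,), (5,)]),
        ("matmul", lambda a, b: (a @ b).sum(), [(3, 4), (4, 2)]),
        ("exp", lambda a, b: (a.exp() * b).sum(), [(3, 3), (3, 3)]),
        ("abs", lambda a, b: (a.abs() + b.abs()).sum(), [(4,), (4,)]),
        ("pow", lambda a, b: (a ** 3 + b ** 2).sum(), [(3,), (3,)]),
        ("mean_axis", lambda a, b: (a.mean(axis=0) * b).sum(),
         [(4, 3), (3,)]),
        ("reshape", lambda a, b: (a.reshape(6) * b).sum(), [(2, 3), (6,)]),
    ])
    def test_gradcheck(self, name, fn, shapes):
        inputs = [_t(s) for s in shapes]
        assert gradcheck(fn, inputs) < 1e-6, name

    def test_log_grad(self):
        x = Tensor(RNG.uniform(0.5, 2.0, (3, 3)), requires_grad=True)
        assert gradcheck(lambda x: x.log().sum(), [x]) < 1e-6

    def test_relu6_grad_away_from_kinks(self):
        x = Tensor(np.array([-2.0, 0.5, 3.0, 7.0]), requires_grad=True)
        assert gradcheck(lambda x: (x.relu6() * x.relu6()).sum(), [x]) < 1e-6

    def test_where_selects_and_routes_gradient(self):
        a, b = _t((4,)), _t((4,))
        cond = np.array([True, False, True, False])
        out = where(cond, a, b)
        out.sum().backward()
        assert np.array_equal(a.grad, cond.astype(float))
        assert np.array_equal(b.grad, (~cond).astype(float))

    def test_concat_backward_splits(self):
        a, b = _t((2, 3)), _t((2, 2))
        out = concat([a, b], axis=1)
        (out * out).sum().backward()
        assert a.grad.shape == (2, 3) and b.grad.shape == (2, 2)
        assert np.allclose(a.grad, 2 * a.data)

    def test_diamond_graph_accumulates(self):
        x = Tensor(np.array(3.0), requires_grad=True)
        y = x * x + x * x                      # two paths to x
        y.backward()
        assert x.grad == pytest.approx(4 * 3.0)

    def test_backward_requires_scalar(self):
        with pytest.raises(ValueError):
            _t((3,)).backward()


class TestConvolution:
    @pytest.mark.parametrize("cin,cout,k,stride,pad,groups", [
        (4, 7, 1, 1, 0, 1),       # pointwise fast path
        (3, 3, 3, 1, 1, 3),       # depthwise fast path
        (3, 3, 3, 2, 1, 3),       # depthwise strided
        (4, 6, 3, 1, 1, 1),       # general
        (4, 6, 3, 2, 1, 2),       # grouped strided
    ])
    def test_forward_matches_scipy(self, cin, cout, k, stride, pad, groups):
        x = RNG.normal(size=(2, cin, 8, 8))
        w = RNG.normal(size=(cout, cin // groups, k, k))
        got = conv2d(Tensor(x), Tensor(w), stride=stride, padding=pad,
                     groups=groups).data
        cg = cin // groups
        for n in range(2):
            for o in range(cout):
                g = o // (cout // groups)
                xp = np.pad(x[n], ((0, 0), (pad, pad), (pad, pad)))
                full = np.zeros((xp.shape[1] - k + 1, xp.shape[2] - k + 1))
                for c in range(cg):
                    full += ndimage.correlate(
                        xp[g * cg + c], w[o, c], mode="constant"
                    )[k // 2:xp.shape[1] - k + 1 + k // 2,
                      k // 2:xp.shape[2] - k + 1 + k // 2]
                assert np.allclose(got[n, o], full[::stride, ::stride],
                                   atol=1e-10)

    @pytest.mark.parametrize("cin,cout,k,stride,pad,groups", [
        (4, 7, 1, 1, 0, 1),
        (3, 3, 3, 2, 1, 3),
        (4, 6, 3, 2, 1, 2),
    ])
    def test_gradcheck(self, cin, cout, k, stride, pad, groups):
        x = Tensor(RNG.normal(size=(2, cin, 6, 6)), requires_grad=True)
        w = Tensor(RNG.normal(size=(cout, cin // groups, k, k)),
                   requires_grad=True)
        err = gradcheck(
            lambda x, w: (conv2d(x, w, stride=stride, padding=pad,
                                 groups=groups) ** 2).sum(), [x, w])
        assert err < 1e-5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv2d(Tensor(np.zeros((1, 4, 5, 5))),
                   Tensor(np.zeros((6, 3, 3, 3))))


class TestBatchNorm:
    def test_train_mode_gradcheck(self):
        x = Tensor(RNG.normal(size=(6, 3, 4, 4)), requires_grad=True)
        g = Tensor(RNG.normal(size=3), requires_grad=True)
        b = Tensor(RNG.normal(size=3), requires_grad=True)
        w = RNG.normal(size=(6, 3, 4, 4))
        rm, rv = np.zeros(3), np.ones(3)

        def f(x, g, b):
            return (batch_norm(x, g, b, rm.copy(), rv.copy(), True) * w).sum()

        assert gradcheck(f, [x, g, b]) < 1e-5

    def test_eval_mode_is_affine(self):
        x = Tensor(RNG.normal(size=(2, 3, 4, 4)), requires_grad=True)
        g = Tensor(np.ones(3), requires_grad=True)
        b = Tensor(np.zeros(3), requires_grad=True)
        rm = np.array([1.0, -1.0, 0.0])
        rv = np.array([4.0, 1.0, 0.25])
        out = batch_norm(x, g, b, rm, rv, False, eps=0.0)
        expected = (x.data - rm.reshape(1, 3, 1, 1)) / np.sqrt(
            rv.reshape(1, 3, 1, 1))
        assert np.allclose(out.data, expected)

    def test_running_stats_updated_in_train_mode(self):
        x = Tensor(RNG.normal(loc=2.0, size=(16, 2, 3, 3)))
        g = Tensor(np.ones(2))
        b = Tensor(np.zeros(2))
        rm, rv = np.zeros(2), np.ones(2)
        batch_norm(x, g, b, rm, rv, True, momentum=1.0)
        assert np.allclose(rm, x.data.mean(axis=(0, 2, 3)))

    def test_normalizes_batch(self):
        x = Tensor(RNG.normal(loc=5.0, scale=3.0, size=(32, 2, 4, 4)))
        out = batch_norm(x, Tensor(np.ones(2)), Tensor(np.zeros(2)),
                         np.zeros(2), np.ones(2), True)
        assert np.allclose(out.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-6)
        assert np.allclose(out.data.std(axis=(0, 2, 3)), 1.0, atol=1e-3)


class TestUpsampleBilinear:
    def test_exact_on_linear_ramp(self):
        ramp = np.arange(5.0).reshape(1, 1, 1, 5).repeat(4, axis=2)
        out = upsample_bilinear(Tensor(ramp), 4, 9).data
        assert np.allclose(out[0, 0, 0], np.linspace(0, 4, 9))

    def test_endpoints_preserved(self):
        x = RNG.normal(size=(1, 2, 3, 3))
        out = upsample_bilinear(Tensor(x), 7, 7).data
        assert np.allclose(out[..., 0, 0], x[..., 0, 0])
        assert np.allclose(out[..., -1, -1], x[..., -1, -1])

    def test_gradcheck(self):
        x = Tensor(RNG.normal(size=(1, 2, 3, 4)), requires_grad=True)
        assert gradcheck(
            lambda x: (upsample_bilinear(x, 6, 7) ** 2).sum(), [x]) < 1e-6


class TestAdam:
    def test_quadratic_loss_decreases(self):
        p = Parameter(np.array([5.0, -3.0], dtype=np.float32))
        opt = Adam([p], lr=0.1)
        losses = []
        for _ in range(200):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < 1e-2 * losses[0]
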