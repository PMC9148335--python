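"""View-network architecture, gradients, prediction, and fusion."""

import numpy as np
import pytest

from idseg.io_prep import VolumeImage
from idseg.network import (FusionWeights, ViewModel, ViewModelConfig,
                           ViewProbabilities, build_view_model, fuse_views,
                           predict_view_probs)
from idseg.network.model import DenseBlock


def closed_form_count(in_ch: int, f: int, classes: int, kernel: int = 5) -> int:
    """Independent layer-by-layer parameter tally of the architecture."""
    def block(i):
        bn = 2 * i + 2 * (i + f) + 2 * (i + 2 * f)
        convs = (kernel * kernel * i * f + f
                 + kernel * kernel * (i + f) * f + f
                 + (i + 2 * f) * f + f)
        return bn + convs + 1  # one shared single-parameter PReLU
    enc = block(in_ch) + 3 * block(f)
    bottleneck = block(f)
    dec = 4 * block(2 * f)
    classifier = f * classes + classes
    return enc + bottleneck + dec + classifier


class TestParameterCount:
    def test_published_configuration(self):
        _, n = build_view_model(ViewModelConfig())
        assert n == 3_520_871
        assert 3 * n == 10_562_613

    @pytest.mark.parametrize("f,classes,kernel", [(8, 5, 5), (4, 5, 3), (16, 3, 5)])
    def test_matches_closed_form_tally(self, f, classes, kernel):
        _, n = build_view_model(ViewModelConfig(filters=f, num_classes=classes,
                                                kernel=kernel))
        assert n == closed_form_count(1, f, classes, kernel)

    def test_pure_function_of_config(self):
        _, a = build_view_model(ViewModelConfig(filters=8, num_classes=5, seed=1))
        _, b = build_view_model(ViewModelConfig(filters=8, num_classes=5, seed=99))
        assert a == b

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ViewModelConfig(num_classes=1)
        with pytest.raises(ValueError):
            ViewModelConfig(in_channels=0)


class TestGradients:
    def test_conv_adjoint_identity(self):
        # <conv(x), g> == <x, conv_backward(g)> for the linear part
        from idseg.network.layers import Conv2d
        rng = np.random.default_rng(0)
        conv = Conv2d(3, 4, 5, rng)
        conv.bias.value[...] = 0.0
        x = rng.standard_normal((2, 3, 12, 12)).astype(np.float32)
        g = rng.standard_normal((2, 4, 12, 12)).astype(np.float32)
        y = conv.forward(x, train=True)
        dx = conv.backward(g)
        lhs = float((y * g).sum())
        rhs = float((x * dx).sum())
        assert lhs == pytest.approx(rhs, rel=1e-4)

    def test_dense_block_against_float64_reference(self):
        rng = np.random.default_rng(0)
        blk = DenseBlock(2, 3, 3, rng, "blk")
        x = rng.standard_normal((2, 2, 8, 8)).astype(np.float32)
        G = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        blk.forward(x, train=True)
        for p in blk.params():
            p.zero_grad()
        blk.backward(G.copy())

        def conv64(x, W, b):
            k = W.shape[2]
            p = k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            out = np.zeros((x.shape[0], W.shape[0], x.shape[2], x.shape[3]))
            for fo in range(W.shape[0]):
                for c in range(W.shape[1]):
                    for u in range(k):
                        for v in range(k):
                            out[:, fo] += W[fo, c, u, v] * xp[:, c, u:u + x.shape[2],
                                                              v:v + x.shape[3]]
                out[:, fo] += b[fo]
            return out

        def bn64(x, gamma, beta, eps=1e-5):
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            xh = (x - mu[None, :, None, None]) / np.sqrt(var + eps)[None, :, None, None]
            return xh * gamma[None, :, None, None] + beta[None, :, None, None]

        def fwd64():
            a = float(blk.prelu.alpha.value[0])
            pr = lambda t: np.where(t > 0, t, a * t)
            xd = x.astype(np.float64)
            x1 = conv64(pr(bn64(xd, blk.bn1.gamma.value.astype(float),
                                blk.bn1.beta.value.astype(float))),
                        blk.conv1.weight.value.astype(float),
                        blk.conv1.bias.value.astype(float))
            c1 = np.concatenate([xd, x1], 1)
            x2 = conv64(pr(bn64(c1, blk.bn2.gamma.value.astype(float),
                                blk.bn2.beta.value.astype(float))),
                        blk.conv2.weight.value.astype(float),
                        blk.conv2.bias.value.astype(float))
            c2 = np.concatenate([xd, x1, x2], 1)
            return conv64(pr(bn64(c2, blk.bn3.gamma.value.astype(float),
                                  blk.bn3.beta.value.astype(float))),
                          blk.conv3.weight.value.astype(float),
                          blk.conv3.bias.value.astype(float))

        def loss64():
            return float((fwd64() * G.astype(np.float64)).sum())

        eps = 1e-4
        for par in (blk.conv1.weight, blk.conv2.weight, blk.conv3.weight,
                    blk.bn1.gamma, blk.bn2.beta, blk.prelu.alpha):
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in par.value.shape)
                orig = par.value[idx].copy()
                par.value[idx] = np.float32(orig + eps)
                vp, lp = float(par.value[idx]), loss64()
                par.value[idx] = np.float32(orig - eps)
                vm, lm = float(par.value[idx]), loss64()
                par.value[idx] = orig
                fd = (lp - lm) / (vp - vm)
                an = float(par.grad[idx])
                assert fd == pytest.approx(an, rel=2e-3, abs=2e-3), par.name

    def test_pool_unpool_round_trip(self):
        from idseg.network.layers import MaxPool2d, MaxUnpool2d
        rng = np.random.default_rng(1)
        x = (np.abs(rng.standard_normal((2, 3, 8, 8))) + 0.1).astype(np.float32)
        pooled, idx = MaxPool2d().forward(x, train=True)
        up = MaxUnpool2d.scatter(pooled, idx, x.shape)
        # unpooled then re-pooled reproduces the pooled values
        repooled, _ = MaxPool2d().forward(up, train=True)
        assert np.array_equal(repooled, pooled)
        # gather is the adjoint of scatter
        g = rng.standard_normal(x.shape).astype(np.float32)
        back = MaxUnpool2d.gather(g, idx)
        assert float((up * g).sum()) == pytest.approx(float((pooled * back).sum()),
                                                      rel=1e-5)


@pytest.fixture(scope="module")
def model():
    return ViewModel(ViewModelConfig(filters=2, num_classes=5, kernel=3, seed=3))


class TestPredict:

    def test_probabilities_normalized(self, model):
        vol = VolumeImage(np.random.default_rng(0).random((32, 32, 32)).astype(np.float32))
        probs = predict_view_probs(model, vol, "axial")
        sums = probs.probs.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-5)
        assert np.all(probs.probs >= 0)

    def test_deterministic_in_eval_mode(self, model):
        vol = VolumeImage(np.random.default_rng(1).random((32, 32, 32)).astype(np.float32))
        a = predict_view_probs(model, vol, "coronal")
        b = predict_view_probs(model, vol, "coronal")
        assert np.array_equal(a.probs, b.probs)

    def test_non_conformed_input_rejected(self, model):
        vol = VolumeImage(np.zeros((32, 32, 40), dtype=np.float32) + 0.5)
        with pytest.raises(ValueError, match="conformed"):
            predict_view_probs(model, vol, "axial")

    def test_state_dict_round_trip(self, model):
        clone = ViewModel(ViewModelConfig(filters=2, num_classes=5, kernel=3, seed=77))
        clone.load_state_dict(model.state_dict())
        vol = VolumeImage(np.random.default_rng(2).random((32, 32, 32)).astype(np.float32))
        a = predict_view_probs(model, vol, "sagittal")
        b = predict_view_probs(clone, vol, "sagittal")
        assert np.array_equal(a.probs, b.probs)


def _rand_probs(rng, shape, c):
    p = rng.random(shape + (c,)).astype(np.float32)
    return p / p.sum(axis=-1, keepdims=True)


class TestFusion:
    def test_matches_per_voxel_brute_force(self):
        rng = np.random.default_rng(5)
        shape, c = (6, 7, 5), 4
        pa, pc, ps = (_rand_probs(rng, shape, c) for _ in range(3))
        w = FusionWeights(0.5, 0.3, 0.2)
        fused = fuse_views(ViewProbabilities(pa, "axial"),
                           ViewProbabilities(pc, "coronal"),
                           ViewProbabilities(ps, "sagittal"), w)
        for idx in np.ndindex(shape):
            scores = [0.5 * pa[idx][k] + 0.3 * pc[idx][k] + 0.2 * ps[idx][k]
                      for k in range(c)]
            best = max(range(c), key=lambda k: (scores[k], -k))
            # ties toward the lowest class index
            expect = min(k for k in range(c) if scores[k] == scores[best])
            assert fused.codes[idx] == expect

    def test_single_view_degenerate_weights(self):
        rng = np.random.default_rng(6)
        shape, c = (8, 8, 8), 5
        pa, pc, ps = (_rand_probs(rng, shape, c) for _ in range(3))
        fused = fuse_views(ViewProbabilities(pa, "axial"),
                           ViewProbabilities(pc, "coronal"),
                           ViewProbabilities(ps, "sagittal"),
                           FusionWeights(1.0, 0.0, 0.0))
        assert np.array_equal(fused.codes, pa.argmax(axis=-1))

    def test_published_weights_tie_goes_to_lowest_class(self):
        shape, c = (1, 1, 1), 4
        def onehot(k):
            p = np.zeros(shape + (c,), dtype=np.float32)
            p[..., k] = 1.0
            return p
        fused = fuse_views(ViewProbabilities(onehot(1), "axial"),
                           ViewProbabilities(onehot(2), "coronal"),
                           ViewProbabilities(onehot(3), "sagittal"),
                           FusionWeights(0.4, 0.4, 0.2))
        # scores (0, 0.4, 0.4, 0.2): classes 1 and 2 tie -> class 1
        assert fused.codes[0, 0, 0] == 1

    def test_unanimous_views(self):
        shape, c = (2, 2, 2), 5
        p = np.zeros(shape + (c,), dtype=np.float32)
        p[..., 2] = 1.0
        fused = fuse_views(ViewProbabilities(p, "axial"),
                           ViewProbabilities(p.copy(), "coronal"),
                           ViewProbabilities(p.copy(), "sagittal"))
        assert np.all(fused.codes == 2)

    def test_class_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        shape, c = (5, 5, 5), 4
        pa, pc, ps = (_rand_probs(rng, shape, c) for _ in range(3))
        perm = np.array([2, 0, 3, 1])
        base = fuse_views(ViewProbabilities(pa, "axial"),
                          ViewProbabilities(pc, "coronal"),
                          ViewProbabilities(ps, "sagittal"))
        permuted = fuse_views(ViewProbabilities(pa[..., perm], "axial"),
                              ViewProbabilities(pc[..., perm], "coronal"),
                              ViewProbabilities(ps[..., perm], "sagittal"))
        # label k in the permuted run corresponds to label perm[k] originally;
        # equivariance holds wherever the original argmax was unique
        scores = 0.4 * pa + 0.4 * pc + 0.2 * ps
        srt = np.sort(scores, axis=-1)
        unique = (srt[..., -1] - srt[..., -2]) > 1e-6
        assert np.array_equal(perm[permuted.codes][unique], base.codes[unique])

    def test_invalid_weights_and_grids(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FusionWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="non-negative"):
            FusionWeights(1.2, -0.1, -0.1)
        rng = np.random.default_rng(9)
        pa = ViewProbabilities(_rand_probs(rng, (4, 4, 4), 3), "axial")
        pc = ViewProbabilities(_rand_probs(rng, (4, 4, 4), 3), "coronal")
        ps = ViewProbabilities(_rand_probs(rng, (4, 4, 5), 3), "sagittal")
        with pytest.raises(ValueError, match="share a shape"):
            fuse_views(pa, pc, ps)
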