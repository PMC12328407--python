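"""Wavelet transforms, WTConv cascade, dense blocks and the backbone."""

import numpy as np
import pytest

from meddgtn.autodiff import Tensor
from meddgtn.nn import PointwiseConv
from meddgtn.wtbackbone import (Backbone, BackboneSpec, Transition, WTConv,
                                WTConvSpec, WTDenseBlock, WTDenseBlockSpec,
                                dwt2, dwt2_t, idwt2, idwt2_t)


class TestPlaneTransforms:
    def test_constant_plane_has_no_detail(self):
        LL, LH, HL, HH = dwt2(np.full((6, 6), 3.0))
        assert np.allclose(LL, 6.0)          # orthonormal Haar doubles
        for band in (LH, HL, HH):
            assert np.allclose(band, 0.0)

    def test_two_by_two_hand_computation(self):
        a, b, c, d = 1.0, 2.0, 3.0, 5.0
        LL, LH, HL, HH = dwt2(np.array([[a, b], [c, d]]))
        assert LL[0, 0] == pytest.approx((a + b + c + d) / 2)
        assert HH[0, 0] == pytest.approx((a - b - c + d) / 2)

    def test_energy_conservation(self, rng):
        x = rng.standard_normal((8, 8))
        bands = dwt2(x)
        assert sum((b ** 2).sum() for b in bands) == pytest.approx(
            (x ** 2).sum(), rel=1e-6)

    @pytest.mark.parametrize("shape", [(4, 4), (16, 12), (64, 64), (7, 9)])
    def test_roundtrip(self, rng, shape):
        x = rng.standard_normal(shape)
        assert np.abs(idwt2(dwt2(x), out_shape=shape) - x).max() < 1e-5

    def test_zero_subbands_give_zero_plane(self):
        z = np.zeros((3, 3))
        assert not idwt2((z, z, z, z)).any()

    def test_inverse_of_hand_example(self):
        x = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert np.allclose(idwt2(dwt2(x)), x)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dwt2(np.zeros((0, 0)))

    def test_inconsistent_subband_shapes_rejected(self):
        with pytest.raises(ValueError):
            idwt2((np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                   np.zeros((3, 3))))

    def test_differentiable_path_consistent_with_pywavelets(self, rng):
        x = rng.standard_normal((2, 3, 8, 8))
        LL, LH, HL, HH, hw = dwt2_t(Tensor(x))
        for n in range(2):
            for c in range(3):
                pLL, pLH, pHL, pHH = dwt2(x[n, c])
                assert np.allclose(LL.data[n, c], pLL)
                assert np.allclose(HH.data[n, c], pHH)
                # detail orientation conventions differ only by sign/role
                assert (LH.data[n, c] ** 2 + HL.data[n, c] ** 2).sum() == \
                    pytest.approx((pLH ** 2 + pHL ** 2).sum())
        rec = idwt2_t(LL, LH, HL, HH, hw)
        assert np.abs(rec.data - x).max() < 1e-10


class TestWTConv:
    def _dirac(self, conv):
        w = np.zeros_like(conv.weight.data)
        w[:, w.shape[1] // 2, w.shape[2] // 2] = 1.0
        conv.weight.data = w

    def test_identity_kernels_reproduce_input(self, rng):
        op = WTConv(3, WTConvSpec(levels=2), rng=rng)
        self._dirac(op.base)
        for lv in range(2):
            for band in ("ll", "lh", "hl", "hh"):
                self._dirac(getattr(op, f"conv_{band}_{lv}"))
        x = rng.random((2, 3, 16, 16))
        out = op(Tensor(x)).data
        assert np.abs(out - x).max() < 1e-4

    def test_zero_kernels_give_zero(self, rng):
        op = WTConv(2, WTConvSpec(levels=1), rng=rng)
        for _, p in op.named_parameters():
            if p is not op.gain:
                p.data = np.zeros_like(p.data)
        assert not op(Tensor(np.ones((1, 2, 8, 8)))).data.any()

    def test_single_level_matches_from_scratch_oracle(self):
        rng = np.random.default_rng(3)
        op = WTConv(1, WTConvSpec(levels=1), rng=rng)
        h = w = 8
        ramp = np.linspace(0, 1, h * w).reshape(1, 1, h, w)
        out = op(Tensor(ramp)).data

        def corr(plane, k):      # reflect-padded 3x3 correlation
            p = np.pad(plane, 1, mode="reflect")
            return sum(k[i, j] * p[i:i + plane.shape[0], j:j + plane.shape[1]]
                       for i in range(3) for j in range(3))

        def split(m, axis):      # orthonormal Haar, hi = (odd - even)/sqrt2
            ev = np.take(m, range(0, m.shape[axis], 2), axis)
            od = np.take(m, range(1, m.shape[axis], 2), axis)
            return (ev + od) / np.sqrt(2), (od - ev) / np.sqrt(2)

        def merge(lo, hi, axis):
            ev, od = (lo - hi) / np.sqrt(2), (lo + hi) / np.sqrt(2)
            shape = list(lo.shape)
            shape[axis] *= 2
            out = np.empty(shape)
            sl = [slice(None)] * lo.ndim
            sl[axis] = slice(0, None, 2)
            out[tuple(sl)] = ev
            sl[axis] = slice(1, None, 2)
            out[tuple(sl)] = od
            return out

        plane = ramp[0, 0]
        lo_h, hi_h = split(plane, 1)
        LL, LH = split(lo_h, 0)
        HL, HH = split(hi_h, 0)
        bands = {"ll": LL, "lh": LH, "hl": HL, "hh": HH}
        conv_bands = {k: corr(v, getattr(op, f"conv_{k}_0").weight.data[0])
                      for k, v in bands.items()}
        cascade = merge(merge(conv_bands["ll"], conv_bands["lh"], 0),
                        merge(conv_bands["hl"], conv_bands["hh"], 0), 1)
        base = corr(plane, op.base.weight.data[0])
        expected = 0.5 * (base + op.gain.data[0] * cascade)
        assert np.abs(out[0, 0] - expected).max() < 1e-10

    def test_preserves_shape(self, rng):
        op = WTConv(5, WTConvSpec(levels=2), rng=rng)
        x = rng.random((2, 5, 12, 20))
        assert op(Tensor(x)).shape == (2, 5, 12, 20)

    def test_too_small_spatial_dims_rejected(self, rng):
        op = WTConv(1, WTConvSpec(levels=3), rng=rng)
        with pytest.raises(ValueError):
            op(Tensor(np.ones((1, 1, 4, 4))))

    def test_non_haar_family_not_supported_in_cascade(self, rng):
        with pytest.raises(NotImplementedError):
            WTConv(1, WTConvSpec(wavelet="db2"), rng=rng)

    def test_low_frequency_sensitivity(self):
        """A broad Gaussian must put more energy into the deep LL path than
        an equal-energy checkerboard."""
        size = 32
        yy, xx = np.mgrid[0:size, 0:size]
        gauss = np.exp(-((yy - size / 2) ** 2 + (xx - size / 2) ** 2)
                       / (2 * (size / 4) ** 2))
        checker = ((yy + xx) % 2 * 2.0 - 1.0)
        checker *= np.linalg.norm(gauss) / np.linalg.norm(checker)

        def deep_ll_energy(plane):
            t = Tensor(plane[None, None])
            for _ in range(2):
                t = dwt2_t(t)[0]
            return float((t.data ** 2).sum())

        assert deep_ll_energy(gauss) > deep_ll_energy(checker)


class TestBlocksAndTransitions:
    def test_default_block_has_six_composite_layers(self, rng):
        block = WTDenseBlock(10, WTDenseBlockSpec(), WTConvSpec(), rng=rng)
        assert len(block.layers) == 6
        assert block.out_channels == 10 + 6 * 48

    def test_zero_layer_block_rejected(self):
        with pytest.raises(ValueError):
            WTDenseBlockSpec(num_layers=0)

    def test_concatenation_arithmetic(self, rng):
        block = WTDenseBlock(8, WTDenseBlockSpec(num_layers=2, growth=4),
                             WTConvSpec(levels=1), rng=rng)
        out = block(Tensor(rng.random((1, 8, 8, 8))))
        assert out.shape == (1, 16, 8, 8)

    def test_transition_halves_spatial_dims(self, rng):
        tr = Transition(8, rng=rng)
        out = tr(Tensor(rng.random((1, 8, 28, 28))))
        assert out.shape == (1, 4, 14, 14)

    def test_transition_block_means_with_identity_kernels(self, rng):
        tr = Transition(2, compression=1.0, rng=rng)
        tr.conv.weight.data = np.eye(2)
        x = rng.random((1, 2, 6, 6))
        out = tr(Tensor(x)).data
        expected = x.reshape(1, 2, 3, 2, 3, 2).mean(axis=(3, 5))
        assert np.allclose(out, expected)

    def test_constant_map_survives_pooling(self, rng):
        tr = Transition(1, compression=1.0, rng=rng)
        tr.conv.weight.data = np.eye(1)
        out = tr(Tensor(np.full((1, 1, 4, 4), 2.5))).data
        assert np.allclose(out, 2.5)


class TestBackbone:
    def test_reduced_profile_shapes(self, rng):
        bb = Backbone(BackboneSpec.reduced(), seed=0)
        bb.eval()
        fm = bb.feature_map(Tensor(rng.random((1, 3, 112, 112))))
        assert fm.shape[-2:] == (14, 14)
        x = bb(Tensor(rng.random((2, 3, 112, 112))))
        assert x.shape == (2, 64)

    def test_zero_image_gives_zero_feature(self):
        bb = Backbone(BackboneSpec.reduced(), seed=0)
        bb.eval()
        x = bb(Tensor(np.zeros((1, 3, 112, 112)))).data
        assert np.abs(x).max() < 1e-12

    def test_wrong_input_size_names_expected(self):
        bb = Backbone(BackboneSpec.reduced(), seed=0)
        with pytest.raises(ValueError, match="112"):
            bb(Tensor(np.zeros((1, 3, 64, 64))))
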