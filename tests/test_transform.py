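"""Transform codec tests against closed forms and a naive-definition oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from xraykit import (
    GrayImage,
    TransformCodecConfig,
    dct2,
    dct_compress,
    dwt_compress,
    dwt_haar_forward,
    dwt_haar_inverse,
    idct2,
    mse,
)
from xraykit.transform import zigzag_order


def naive_dct2(block: np.ndarray) -> np.ndarray:
    """O(B^4) orthonormal type-II 2-D DCT straight from the definition.

    X[u,v] = a(u) a(v) sum_x sum_y x[i,j]
             cos(pi (2i+1) u / 2B) cos(pi (2j+1) v / 2B)
    with a(0) = sqrt(1/B), a(u>0) = sqrt(2/B).
    """
    b = block.shape[0]
    out = np.zeros((b, b))
    for u in range(b):
        for v in range(b):
            total = 0.0
            for i in range(b):
                for j in range(b):
                    total += (
                        block[i, j]
                        * math.cos(math.pi * (2 * i + 1) * u / (2 * b))
                        * math.cos(math.pi * (2 * j + 1) * v / (2 * b))
                    )
            au = math.sqrt((1 if u == 0 else 2) / b)
            av = math.sqrt((1 if v == 0 else 2) / b)
            out[u, v] = au * av * total
    return out


class TestDCT2:
    def test_constant_block_concentrates_in_dc(self):
        c = dct2(np.full((8, 8), 3.25))
        assert c[0, 0] == pytest.approx(8 * 3.25, abs=1e-10)
        assert np.abs(c.ravel()[1:]).max() < 1e-10

    @pytest.mark.parametrize("size", [4, 8])
    def test_matches_naive_definition(self, rng, size):
        block = rng.uniform(0, 255, (size, size))
        assert np.abs(dct2(block) - naive_dct2(block)).max() < 1e-10

    def test_round_trip_and_parseval(self, rng):
        for _ in range(100):
            block = rng.uniform(0, 255, (8, 8))
            coeffs = dct2(block)
            assert np.abs(idct2(coeffs) - block).max() < 1e-8
            assert np.sum(coeffs**2) == pytest.approx(np.sum(block**2), rel=1e-6)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            dct2(np.zeros((4, 8)))

    def test_zigzag_ranks_are_a_permutation(self):
        zz = zigzag_order(8)
        assert sorted(zz) == list(range(64))
        # low frequencies first: DC, then the two first-diagonal entries
        rank = zz.reshape(8, 8)
        assert rank[0, 0] == 0 and {rank[0, 1], rank[1, 0]} == {1, 2}


class TestHaar:
    def test_constant_2x2_closed_form(self):
        pyr = dwt_haar_forward(GrayImage(np.full((2, 2), 5, dtype=np.int64)))
        assert pyr.approx[0, 0] == pytest.approx(2 * 5)
        for band in (pyr.detail_h, pyr.detail_v, pyr.detail_d):
            assert abs(band[0, 0]) < 1e-12

    def test_perfect_reconstruction_odd_dims(self, rng):
        img = GrayImage(rng.integers(0, 256, (33, 47)))
        back = dwt_haar_inverse(dwt_haar_forward(img))
        assert back.shape == (33, 47)
        assert np.abs(back - img.pixels).max() < 1e-8

    def test_energy_conservation(self, rng):
        img = GrayImage(rng.integers(0, 256, (32, 32)))
        pyr = dwt_haar_forward(img)
        assert pyr.energy() == pytest.approx(float(np.sum(img.pixels**2)), rel=1e-6)

    def test_matches_pywavelets_periodization(self, rng):
        pywt = pytest.importorskip("pywt")
        x = rng.integers(0, 256, (32, 48)).astype(float)
        ll, (lh, hl, hh) = pywt.dwt2(x, "haar", mode="periodization")
        mine = dwt_haar_forward(GrayImage(x.astype(np.int64)))
        for ref, band in [(ll, mine.approx), (lh, mine.detail_h),
                          (hl, mine.detail_v), (hh, mine.detail_d)]:
            assert np.abs(ref - band).max() < 1e-9

    @given(
        arr=hnp.arrays(
            np.int64,
            st.tuples(st.integers(2, 17), st.integers(2, 17)),
            elements=st.integers(0, 255),
        )
    )
    def test_round_trip_property(self, arr):
        img = GrayImage(arr)
        back = dwt_haar_inverse(dwt_haar_forward(img))
        assert np.abs(back - img.pixels).max() < 1e-8


class TestDCTCompress:
    def test_lossless_limit(self, chest_phantom):
        cfg = TransformCodecConfig(keep_fraction=1.0, downsample_factor=1)
        res = dct_compress(chest_phantom, cfg)
        assert mse(chest_phantom, res.reconstruction) <= 0.5

    def test_dc_only_exact_on_block_constant_image(self, blocky_phantom):
        cfg = TransformCodecConfig(keep_fraction=1 / 64, downsample_factor=1)
        res = dct_compress(blocky_phantom, cfg)
        assert res.reconstruction == blocky_phantom

    def test_mse_monotone_in_keep_fraction(self, chest_phantom):
        errors = [
            mse(chest_phantom, dct_compress(chest_phantom, TransformCodecConfig(keep_fraction=kf)).reconstruction)
            for kf in (0.1, 0.5)
        ]
        assert errors[0] >= errors[1]

    def test_output_shape_and_range(self, chest_phantom):
        res = dct_compress(chest_phantom, TransformCodecConfig())
        rec = res.reconstruction
        assert rec.shape == chest_phantom.shape
        assert rec.pixels.min() >= 0 and rec.pixels.max() <= chest_phantom.peak
        assert res.encoded_bits > 0 and res.compression_ratio > 0

    def test_image_smaller_than_block_rejected(self):
        tiny = GrayImage(np.zeros((4, 4), dtype=np.int64))
        with pytest.raises(ValueError):
            dct_compress(tiny, TransformCodecConfig(block_size=8))

    def test_non_multiple_shape_handled(self, rng):
        img = GrayImage(rng.integers(0, 256, (30, 45)))
        res = dct_compress(img, TransformCodecConfig(downsample_factor=2))
        assert res.reconstruction.shape == (30, 45)


class TestDWTCompress:
    def test_all_zero_image_exact(self):
        img = GrayImage(np.zeros((16, 16), dtype=np.int64))
        res = dwt_compress(img, TransformCodecConfig())
        assert res.reconstruction == img
        assert mse(img, res.reconstruction) == 0.0

    def test_quantizer_error_bounded_by_half_step(self, rng):
        from xraykit.transform import _quantize_subband

        band = rng.uniform(-100, 300, (16, 16))
        for bits in (2, 4, 6):
            delta = (band.max() - band.min()) / ((1 << bits) - 1)
            err = np.abs(_quantize_subband(band, bits) - band)
            assert err.max() <= delta / 2 + 1e-12

    def test_output_matches_input_size(self, rng):
        for shape in [(64, 64), (33, 47)]:
            img = GrayImage(rng.integers(0, 256, shape))
            res = dwt_compress(img, TransformCodecConfig())
            assert res.reconstruction.shape == shape

    def test_mse_monotone_in_coeff_bits(self, chest_phantom):
        errors = [
            mse(chest_phantom, dwt_compress(chest_phantom, TransformCodecConfig(coeff_bits=b)).reconstruction)
            for b in (2, 4, 6, 8)
        ]
        assert all(a >= b for a, b in zip(errors, errors[1:]))

    def test_invalid_coeff_bits_rejected(self):
        with pytest.raises(ValueError):
            TransformCodecConfig(coeff_bits=0)
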