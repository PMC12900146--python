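"""Wavelet decomposition, energy weighting, and local-energy fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from somfuse.fusion import (FusionConfig, dwt_decompose, dwt_reconstruct,
                            energy_weights, fuse_baseline, fuse_coefficients,
                            image_energy, lew_dwt_fuse, local_energy,
                            normalize_band)
from somfuse.quality import average_gradient


class TestNormalizeBand:
    def test_minmax_scaling(self):
        out = normalize_band(np.array([[0.0, 5.0], [10.0, 10.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.5], [1.0, 1.0]])

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_band(np.full((3, 3), 7.0)),
                                      np.zeros((3, 3)))

    def test_masked_cell_excluded_from_minmax(self, grid_factory):
        mask = np.array([[False, False], [False, True]])
        grid = grid_factory([[0.0, 5.0], [10.0, 99.0]], mask=mask)
        out = normalize_band(grid)
        np.testing.assert_allclose(out[0], [0.0, 0.5])
        assert out[1, 1] == 0.0  # masked cell neutralized

    def test_fully_masked_rejected(self, grid_factory):
        grid = grid_factory(np.ones((2, 2)), mask=np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            normalize_band(grid)


class TestEnergy:
    def test_sum_of_squares(self):
        assert image_energy(np.array([[1.0, 2.0], [3.0, 4.0]])) == 30.0
        assert image_energy(np.zeros((4, 4))) == 0.0

    def test_homogeneity(self, rng):
        x = rng.random((5, 5))
        assert image_energy(3.0 * x) == pytest.approx(9.0 * image_energy(x))

    def test_weights(self):
        np.testing.assert_allclose(energy_weights([30.0, 10.0]), [0.75, 0.25])
        np.testing.assert_allclose(energy_weights([5.0]), [1.0])
        np.testing.assert_allclose(energy_weights([2.0] * 5), [0.2] * 5)

    @given(hnp.arrays(np.float64, st.integers(1, 6),
                      elements=st.floats(0.0, 1e6)))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one_and_permute(self, energies):
        if energies.sum() == 0:
            with pytest.raises(ValueError):
                energy_weights(energies)
            return
        w = energy_weights(energies)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        perm = np.argsort(energies)
        np.testing.assert_allclose(energy_weights(energies[perm]), w[perm])


class TestDwt:
    def test_constant_block_one_level(self):
        pyr = dwt_decompose(np.full((2, 2), 4.0), FusionConfig(levels=1))
        np.testing.assert_allclose(pyr.approx, [[8.0]])
        for plane in pyr.details[0]:
            np.testing.assert_allclose(plane, 0.0, atol=1e-12)

    @pytest.mark.parametrize("shape", [(4, 4), (5, 5), (7, 9), (8, 6), (13, 13)])
    def test_perfect_reconstruction(self, rng, shape):
        img = rng.random(shape)
        pyr = dwt_decompose(img, FusionConfig(levels=2))
        rec = dwt_reconstruct(pyr)
        assert rec.shape == img.shape
        np.testing.assert_allclose(rec, img, rtol=0, atol=1e-8)

    def test_matches_haar_butterfly_oracle(self, rng):
        # one orthonormal-Haar level of a 2x2 block has the closed form
        # LL=(a+b+c+d)/2, HL=(a-b+c-d)/2, LH=(a+b-c-d)/2, HH=(a-b-c+d)/2
        # (pywt orders detail planes (cH, cV, cD) = here (LH-, HL-, HH-like))
        block = rng.random((2, 2))
        a, b, c, d = block[0, 0], block[0, 1], block[1, 0], block[1, 1]
        pyr = dwt_decompose(block, FusionConfig(levels=1))
        assert pyr.approx[0, 0] == pytest.approx((a + b + c + d) / 2)
        ch, cv, cd = (p[0, 0] for p in pyr.details[0])
        assert ch == pytest.approx((a + b - c - d) / 2)  # row difference
        assert cv == pytest.approx((a - b + c - d) / 2)  # column difference
        assert cd == pytest.approx((a - b - c + d) / 2)  # diagonal

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            dwt_decompose(np.ones((3, 3)), FusionConfig(levels=2))


class TestLocalEnergy:
    def test_ones_center(self):
        out = local_energy(np.ones((3, 3)), 3)
        assert out[1, 1] == pytest.approx(9.0)

    def test_zeros(self):
        np.testing.assert_array_equal(local_energy(np.zeros((4, 4)), 3), 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_energy(np.ones((4, 4)), 2)

    @given(hnp.arrays(np.float64, st.tuples(st.integers(3, 8), st.integers(3, 8)),
                      elements=st.floats(-10, 10)),
           st.sampled_from([3, 5]))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_bruteforce(self, arr, window):
        if window > min(arr.shape):
            return
        le = local_energy(arr, window)
        half = window // 2
        pad = np.pad(arr * arr, half, mode="symmetric")
        brute = np.array([[pad[i:i + window, j:j + window].sum()
                           for j in range(arr.shape[1])]
                          for i in range(arr.shape[0])])
        np.testing.assert_allclose(le, brute, atol=1e-10)


class TestFuseCoefficients:
    def test_weighted_ll(self):
        cfg = FusionConfig(levels=1)
        p1 = dwt_decompose(np.full((4, 4), 1.0), cfg)
        p2 = dwt_decompose(np.full((4, 4), 3.0), cfg)
        p1.approx[...] = 2.0
        p2.approx[...] = 6.0
        fused = fuse_coefficients([p1, p2], cfg, weights=[0.75, 0.25])
        np.testing.assert_allclose(fused.approx, 3.0)

    def test_idempotent_on_identical_pyramids(self, rng):
        cfg = FusionConfig(levels=2)
        img = rng.random((8, 8))
        pyrs = [dwt_decompose(img, cfg) for _ in range(3)]
        fused = fuse_coefficients(pyrs, cfg)
        np.testing.assert_allclose(fused.approx, pyrs[0].approx)
        for lev in range(2):
            for k in range(3):
                np.testing.assert_allclose(fused.details[lev][k],
                                           pyrs[0].details[lev][k])

    def test_argmax_selects_dominant_details(self, rng):
        cfg = FusionConfig(levels=1)
        small = dwt_decompose(rng.random((8, 8)) * 0.01, cfg)
        big = dwt_decompose(rng.random((8, 8)) * 10.0 + 5.0, cfg)
        # make big's detail planes strictly dominant everywhere
        for k in range(3):
            big.details[0][k][...] = np.sign(big.details[0][k] + 0.5) * 5.0
        fused = fuse_coefficients([small, big], cfg, weights=[0.5, 0.5])
        for k in range(3):
            np.testing.assert_array_equal(fused.details[0][k], big.details[0][k])

    def test_structural_mismatch_rejected(self, rng):
        cfg = FusionConfig(levels=1)
        a = dwt_decompose(rng.random((4, 4)), cfg)
        b = dwt_decompose(rng.random((8, 8)), cfg)
        with pytest.raises(ValueError):
            fuse_coefficients([a, b], cfg)


class TestLewDwtFuse:
    def test_self_fusion_identity(self, rng):
        img = rng.random((16, 16))
        fused = lew_dwt_fuse([img, img])
        np.testing.assert_allclose(fused, normalize_band(img), atol=1e-8)

    def test_constant_inputs_give_constant(self):
        fused = lew_dwt_fuse([np.full((8, 8), 2.0), np.full((8, 8), 5.0)])
        np.testing.assert_allclose(fused, fused.flat[0])

    def test_single_input_returns_normalized_self(self, rng):
        img = rng.random((8, 8))
        np.testing.assert_allclose(lew_dwt_fuse([img]), normalize_band(img))

    def test_fused_sharpness_at_least_blurred_input(self, rng):
        from scipy import ndimage
        sharp = rng.random((32, 32))
        blurred = ndimage.uniform_filter(sharp, size=5)
        fused = lew_dwt_fuse([blurred, sharp])
        assert average_gradient(fused) >= average_gradient(normalize_band(blurred))

    def test_masked_image_rejected(self, grid_factory, rng):
        good = grid_factory(rng.random((8, 8)))
        bad = grid_factory(rng.random((8, 8)), mask=np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            lew_dwt_fuse([good, bad])

    def test_mask_union_propagates(self, grid_factory, rng):
        m = np.zeros((8, 8), dtype=bool)
        m[0, 0] = True
        a = grid_factory(rng.random((8, 8)), mask=m)
        b = grid_factory(rng.random((8, 8)))
        fused = lew_dwt_fuse([a, b])
        assert fused.mask[0, 0] and fused.mask.sum() == 1


class TestBaselines:
    def test_traditional_dwt_self_fusion(self, rng):
        img = rng.random((8, 8))
        fused = fuse_baseline([img, img], "traditional_dwt")
        np.testing.assert_allclose(fused, normalize_band(img), atol=1e-8)

    def test_traditional_dwt_of_constants(self):
        fused = fuse_baseline([np.full((8, 8), 1.0), np.full((8, 8), 9.0)],
                              "traditional_dwt")
        # both normalize to all-zero planes, so the mean is zero
        np.testing.assert_allclose(fused, 0.0, atol=1e-12)

    def test_splicing_returns_all_planes(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(2)]
        planes = fuse_baseline(imgs, "simple_splicing")
        assert len(planes) == 2
        for p, src in zip(planes, imgs):
            np.testing.assert_allclose(p, normalize_band(src))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fuse_baseline([np.ones((8, 8))], "starfm")
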