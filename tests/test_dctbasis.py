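"""Masked truncated DCT basis: images, pixel-element map, K, synthesis."""

import numpy as np
import pytest

from eitdct.dctbasis import (BasisError, DctCoefficients, DctGrid,
                             basis_image_stack, build_K,
                             build_pixel_element_map, dct2_truncated_roundtrip,
                             dct_basis_image, mask_basis, reconstruct_dct,
                             synthesize_image)
from eitdct.recon import tikhonov_prior


class TestBasisImages:
    def test_dc_term_is_constant(self):
        D = dct_basis_image(0, 0, 16, 16)
        assert np.allclose(D, 1.0 / 16.0)

    @pytest.mark.parametrize("pq1,pq2", [((0, 0), (1, 0)), ((2, 3), (3, 2)),
                                         ((0, 5), (4, 5)), ((7, 7), (7, 6))])
    def test_orthogonality(self, pq1, pq2):
        D1 = dct_basis_image(*pq1, 16, 16)
        D2 = dct_basis_image(*pq2, 16, 16)
        assert abs(np.sum(D1 * D2)) < 1e-12

    @pytest.mark.parametrize("p,q", [(0, 0), (1, 0), (5, 9), (15, 15)])
    def test_unit_norm(self, p, q):
        D = dct_basis_image(p, q, 16, 16)
        assert np.sum(D**2) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_frequency(self):
        with pytest.raises(ValueError):
            dct_basis_image(16, 0, 16, 16)


class TestTruncatedRoundtrip:
    def test_full_basis_lossless(self, rng):
        A = rng.normal(size=(32, 32))
        assert np.allclose(dct2_truncated_roundtrip(A, 32), A, atol=1e-10)

    def test_constant_image_needs_only_dc(self, rng):
        A = np.full((24, 24), 3.7)
        assert np.allclose(dct2_truncated_roundtrip(A, 1), A, atol=1e-12)

    def test_truncation_discards_high_frequencies(self, rng):
        A = rng.normal(size=(64, 64))
        Ahat = dct2_truncated_roundtrip(A, 8)
        from scipy.fft import dctn

        V = dctn(Ahat, norm="ortho")
        assert np.allclose(V[8:, :], 0.0, atol=1e-12)
        assert np.allclose(V[:, 8:], 0.0, atol=1e-12)


class TestMaskedBasis:
    def test_mask_all_ones_identity(self, rng):
        D = rng.normal(size=(16, 16))
        assert np.array_equal(mask_basis(D, np.ones((16, 16))), D)

    def test_mask_all_zeros(self, rng):
        D = rng.normal(size=(16, 16))
        assert np.all(mask_basis(D, np.zeros((16, 16))) == 0)

    def test_support_is_the_mask(self, rng):
        mask = (np.indices((16, 16)).sum(axis=0) % 2).astype(np.uint8)
        D = rng.normal(size=(16, 16)) + 10.0
        C = mask_basis(D, mask)
        assert np.array_equal(C != 0, mask.astype(bool))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_basis(np.zeros((8, 8)), np.zeros((9, 8)))


class TestPixelElementMap:
    def test_matches_brute_force_scan(self, phantom, small_mesh):
        """Exact agreement with an all-triangles barycentric scan on 32x32."""
        pmap = build_pixel_element_map(small_mesh, phantom.extent, (32, 32))
        from eitdct.geometry import RasterExtent

        ext = phantom.extent
        X, Y = RasterExtent(ext.x_min, ext.x_max, ext.y_min, ext.y_max,
                            (32, 32)).pixel_centers()
        tri = small_mesh.nodes[small_mesh.elements]
        for m in range(32):
            for n in range(32):
                px, py = X[m, n], Y[m, n]
                found = -1
                for e in range(small_mesh.n_elem):
                    (x0, y0), (x1, y1), (x2, y2) = tri[e]
                    det = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
                    l0 = ((y1 - y2) * (px - x2) + (x2 - x1) * (py - y2)) / det
                    l1 = ((y2 - y0) * (px - x2) + (x0 - x2) * (py - y2)) / det
                    if l0 >= -1e-12 and l1 >= -1e-12 and 1 - l0 - l1 >= -1e-12:
                        found = e
                        break
                assert pmap.element_of[m, n] == found

    def test_centroid_maps_to_element(self, phantom, small_mesh):
        pmap = build_pixel_element_map(small_mesh, phantom.extent,
                                       phantom.raster_shape)
        # pixels containing element centroids must map into the mesh
        ext = phantom.extent
        for e in (0, small_mesh.n_elem // 2, small_mesh.n_elem - 1):
            cx, cy = small_mesh.element_centroids()[e]
            col = int((cx - ext.x_min) / ext.dx)
            row = int((ext.y_max - cy) / ext.dy)
            assert pmap.element_of[row, col] >= 0

    def test_outside_thorax_is_unmapped(self, phantom, small_mesh):
        pmap = build_pixel_element_map(small_mesh, phantom.extent,
                                       phantom.raster_shape)
        assert pmap.element_of[0, 0] == -1
        assert pmap.element_of[-1, -1] == -1


class TestBasisMatrixK:
    def test_dc_column_constant_on_lung_elements(self, suite):
        K = suite.basis.K
        col0 = K[:, 0]
        nz = col0 != 0
        assert np.all(col0[nz] > 0)
        assert np.allclose(col0[nz], col0[nz][0])
        # rows of elements without lung pixels are identically zero
        assert np.all(K[~nz].sum(axis=1) == 0)

    def test_full_rank_225(self, suite):
        assert np.linalg.matrix_rank(suite.basis.K) == 225

    def test_small_mask_raises_rank_error(self, suite):
        tiny = np.zeros((64, 64), np.uint8)
        tiny[30:34, 30:34] = 1
        with pytest.raises(BasisError):
            build_K(suite.recon_mesh, tiny, DctGrid(), suite.pixel_map)


class TestDctReconstruction:
    def test_zero_data_zero_coefficients(self, suite):
        c = reconstruct_dct(suite.J_norm, suite.basis,
                            np.zeros(suite.J_norm.shape[0]), lam=0.1)
        assert np.allclose(c.g_hat, 0.0)

    def test_recovers_coefficients_of_reduced_model(self, suite, rng):
        """Data generated by a well-posed reduced model (n_dct < n_meas) are
        recovered at tiny lambda."""
        grid = DctGrid(M=64, N=64, n_x=6, n_y=6)
        basis = build_K(suite.recon_mesh, suite.phantom.lung_mask, grid,
                        suite.pixel_map)
        g_true = rng.normal(size=grid.n_dct)
        y = (suite.J_norm @ basis.K) @ g_true
        c = reconstruct_dct(suite.J_norm, basis, y, lam=1e-8)
        err = np.linalg.norm(c.g_hat - g_true) / np.linalg.norm(g_true)
        assert err < 1e-4

    def test_trimmed_system_matches_lstsq_oracle(self, suite, rng):
        grid = DctGrid(M=64, N=64, n_x=3, n_y=3)
        basis = build_K(suite.recon_mesh, suite.phantom.lung_mask, grid,
                        suite.pixel_map)
        y = rng.normal(size=suite.J_norm.shape[0])
        lam = 0.05
        c = reconstruct_dct(suite.J_norm, basis, y, lam=lam)
        Jd = suite.J_norm @ basis.K
        ref = np.linalg.lstsq(np.vstack([Jd, lam * np.eye(9)]),
                              np.concatenate([y, np.zeros(9)]), rcond=None)[0]
        assert np.max(np.abs(c.g_hat - ref)) < 1e-8


class TestSynthesis:
    def test_dc_coefficient_constant_on_lungs(self, suite):
        g = np.zeros(225)
        g[0] = 1.0
        H = synthesize_image(DctCoefficients(g, suite.basis.grid),
                             suite.C_stack)
        lung = suite.phantom.lung_mask.astype(bool)
        assert np.allclose(H[lung], H[lung][0])
        assert np.all(H[~lung] == 0.0)

    def test_linearity(self, suite, rng):
        g1, g2 = rng.normal(size=(2, 225))
        grid = suite.basis.grid
        Ha = synthesize_image(DctCoefficients(g1, grid), suite.C_stack)
        Hb = synthesize_image(DctCoefficients(g2, grid), suite.C_stack)
        Hc = synthesize_image(DctCoefficients(2 * g1 - 3 * g2, grid),
                              suite.C_stack)
        assert np.allclose(Hc, 2 * Ha - 3 * Hb, atol=1e-12)

    def test_support_confined_to_lungs(self, suite, rng):
        g = rng.normal(size=225)
        H = synthesize_image(DctCoefficients(g, suite.basis.grid),
                             suite.C_stack)
        assert np.max(np.abs(H[suite.phantom.lung_mask == 0])) == 0.0
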