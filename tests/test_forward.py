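import numpy as np
import pytest

import cassifundus as cf
from cassifundus.dispersion import DispersionModel


def brute_force_forward(cube_data, mask_pattern, shifts):
    """Independent shift-and-add oracle with explicit python loops."""
    rows, cols, L = cube_data.shape
    out = np.zeros((rows, cols + max(shifts)))
    for r in range(rows):
        for c in range(cols):
            for k in range(L):
                out[r, c + shifts[k]] += cube_data[r, c, k] * mask_pattern[r, c]
    return out


class TestApplyMask:
    def test_all_ones_mask_is_identity(self, random_cube):
        mask = cf.CodedMask(np.ones((6, 6)), feature_px=1)
        out = cf.apply_mask(random_cube, mask)
        assert np.array_equal(out.data, random_cube.data)
        assert np.array_equal(out.wavelengths, random_cube.wavelengths)

    def test_opaque_mask_zeroes_everything(self, random_cube):
        out = cf.apply_mask(random_cube, cf.CodedMask(np.zeros((6, 6)), feature_px=1))
        assert not out.data.any()

    def test_checkerboard_matches_per_voxel_product(self):
        cube = cf.SpectralDatacube(
            np.arange(1, 9, dtype=float).reshape(2, 2, 2), [500.0, 510.0]
        )
        checker = np.array([[1, 0], [0, 1]])
        out = cf.apply_mask(cube, cf.CodedMask(checker, feature_px=1))
        expected = cube.data * checker[:, :, None]  # brute-force elementwise
        assert np.array_equal(out.data, expected)

    def test_shape_mismatch_rejected(self, random_cube):
        with pytest.raises(ValueError, match="mask shape"):
            cf.apply_mask(random_cube, cf.CodedMask(np.ones((4, 4)), feature_px=1))


class TestBandShifts:
    def test_reference_wavelength_has_zero_shift(self):
        prism = cf.default_prism()
        assert prism.band_shifts([445.0])[0] == 0

    def test_first_segment_integration_gives_21_pixels_at_480(self):
        # 35 nm at 1.67 nm/pixel -> 20.96 -> 21; cross-check by quadrature
        prism = cf.default_prism()
        assert prism.band_shifts([480.0])[0] == 21
        lam = np.linspace(445.0, 480.0, 100001)
        quad = np.trapezoid([1.0 / prism.nm_per_pixel(l) for l in lam], lam)
        assert quad == pytest.approx(35.0 / 1.67, rel=1e-6)

    def test_uniform_toy_model_is_linear(self):
        toy = DispersionModel(((500.0, 550.0, 2.0),))
        assert toy.band_shifts([510.0])[0] == 5
        assert toy.band_shifts([500.0, 510.0, 520.0]).tolist() == [0, 5, 10]

    def test_out_of_range_wavelength_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cf.default_prism().band_shifts([700.0])

    def test_shifts_nondecreasing_across_full_grid(self):
        prism = cf.default_prism()
        shifts = prism.band_shifts(np.linspace(445, 602, 35))
        assert (np.diff(shifts) >= 0).all()
        # total dispersion across the full range spans ~69 pixels
        assert shifts[-1] == 69


class TestForward:
    def test_degenerate_single_band_is_identity(self):
        cube = cf.SpectralDatacube(np.arange(9, dtype=float).reshape(3, 3, 1), [500.0])
        op = cf.SensingOperator(cf.CodedMask(np.ones((3, 3)), feature_px=1), [0])
        meas = cf.forward(cube, op)
        assert np.array_equal(meas.data, cube.data[:, :, 0])

    def test_hand_computed_shift_and_add(self):
        cube_data = np.arange(1.0, 19.0).reshape(3, 3, 2)
        mask = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0]], dtype=float)
        op = cf.SensingOperator(cf.CodedMask(mask, feature_px=1), [0, 1])
        cube = cf.SpectralDatacube(cube_data, [500.0, 510.0])
        meas = cf.forward(cube, op)
        expected = brute_force_forward(cube_data, mask, [0, 1])
        assert np.array_equal(meas.data, expected)

    def test_linearity(self, small_op, rng):
        f1 = rng.random((6, 6, 3))
        f2 = rng.random((6, 6, 3))
        a, b = 2.5, -1.25
        lhs = small_op.apply(a * f1 + b * f2)
        rhs = a * small_op.apply(f1) + b * small_op.apply(f2)
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_row_shift_equivariance(self, small_op, rng):
        f = rng.random((6, 6, 3))
        shifted = np.roll(f, 1, axis=0)
        # roll the mask too: equivariance holds for the scene relative to a
        # fixed pattern only when the pattern moves with it
        op2 = cf.SensingOperator(
            cf.CodedMask(np.roll(small_op.mask.pattern, 1, axis=0), feature_px=1),
            small_op.shifts,
        )
        assert np.allclose(op2.apply(shifted), np.roll(small_op.apply(f), 1, axis=0))

    def test_energy_conservation_with_open_mask(self, rng):
        f = rng.random((6, 6, 3))
        op = cf.SensingOperator(cf.CodedMask(np.ones((6, 6)), feature_px=1), [0, 1, 2])
        assert op.apply(f).sum() == pytest.approx(f.sum(), rel=1e-12)

    def test_gaussian_noise_is_seeded_and_additive(self, small_op, random_cube):
        noise = cf.NoiseModel("gaussian", sigma=0.1, seed=7)
        m1 = cf.forward(random_cube, small_op, noise)
        m2 = cf.forward(random_cube, small_op, noise)
        clean = cf.forward(random_cube, small_op)
        assert np.array_equal(m1.data, m2.data)
        assert not np.array_equal(m1.data, clean.data)
        assert m1.meta["noise"]["sigma"] == 0.1

    def test_shape_mismatch_rejected(self, small_op, rng):
        bad = cf.SpectralDatacube(rng.random((5, 6, 3)), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="does not match"):
            cf.forward(bad, small_op)


class TestAdjoint:
    def test_zero_measurement_gives_zero_cube(self, small_op):
        m = cf.Measurement(np.zeros(small_op.measurement_shape))
        assert not cf.adjoint(m, small_op).data.any()

    def test_adjoint_identity_random_instances(self, rng):
        for trial in range(5):
            mask = cf.random_binary_mask(8, 8, 0.5, 1, seed=trial)
            op = cf.SensingOperator(mask, [0, 1, 3, 4])
            f = rng.random((8, 8, 4))
            y = rng.random(op.measurement_shape)
            lhs = np.vdot(op.apply(f), y)
            rhs = np.vdot(f, op.adjoint_apply(y))
            assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)

    def test_open_mask_zero_shift_adjoint_is_crop(self, rng):
        op = cf.SensingOperator(cf.CodedMask(np.ones((4, 4)), feature_px=1), [0])
        y = rng.random((4, 4))
        assert np.array_equal(op.adjoint_apply(y)[:, :, 0], y)

    def test_width_mismatch_rejected(self, small_op):
        with pytest.raises(ValueError, match="measurement shape"):
            small_op.adjoint_apply(np.zeros((6, 6)))


class TestDenseOracle:
    def test_dense_action_matches_forward_and_adjoint(self, small_op, rng):
        dense = cf.dense_phi(small_op)
        f = rng.random((6, 6, 3))
        y = rng.random(small_op.measurement_shape)
        assert np.allclose(dense @ f.ravel(), small_op.apply(f).ravel(), atol=1e-12)
        assert np.allclose(
            dense.T @ y.ravel(), small_op.adjoint_apply(y).ravel(), atol=1e-12
        )

    def test_phi_phit_is_exactly_diagonal_and_matches_diag(self, small_op):
        dense = cf.dense_phi(small_op)
        gram = dense @ dense.T
        off = gram - np.diag(np.diag(gram))
        assert not off.any()
        assert np.array_equal(
            np.diag(gram), cf.phi_phit_diag(small_op).ravel()
        )

    def test_diag_counts_transmitting_features(self):
        op = cf.SensingOperator(cf.CodedMask(np.ones((4, 4)), feature_px=1), [0, 1, 2])
        d = cf.phi_phit_diag(op)
        # interior pixels see all L bands with unit weight
        assert d[:, 2].tolist() == [3.0] * 4
        zop = cf.SensingOperator(cf.CodedMask(np.zeros((4, 4)), feature_px=1), [0, 1])
        assert not cf.phi_phit_diag(zop).any()

    def test_single_band_dense_is_selection_matrix(self):
        op = cf.SensingOperator(cf.CodedMask(np.ones((2, 2)), feature_px=1), [0])
        dense = cf.dense_phi(op)
        assert np.array_equal(dense, np.eye(4))

    def test_dense_row_sums_count_mask_hits(self, small_op):
        dense = cf.dense_phi(small_op)
        assert dense.sum() == small_op.mask.pattern.sum() * small_op.n_bands

    def test_large_instance_refused(self):
        mask = cf.random_binary_mask(64, 64, 0.5, 1, seed=0)
        op = cf.SensingOperator(mask, list(range(8)))
        with pytest.raises(ValueError, match="too large"):
            cf.dense_phi(op)


class TestOperatorValidation:
    def test_decreasing_shifts_rejected(self):
        mask = cf.random_binary_mask(4, 4, 0.5, 1, seed=0)
        with pytest.raises(ValueError, match="non-decreasing"):
            cf.SensingOperator(mask, [1, 0])

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValueError, match="values"):
            cf.CodedMask(np.full((4, 4), 0.5))

    def test_measurement_width_is_cols_plus_max_shift(self, small_op):
        assert small_op.measurement_shape == (6, 8)
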