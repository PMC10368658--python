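import numpy as np
import pytest

import cassifundus as cf
from cassifundus.admm import initialize, projection_step
from cassifundus.denoise import IdentityDenoiser, TVDenoiser, tv_objective


def dense_solve(op, rhs_cube, g1, g2):
    """Dense oracle for (g2 I + g1 Phi^T Phi)^{-1} rhs."""
    dense = cf.dense_phi(op)
    n = dense.shape[1]
    A = g2 * np.eye(n) + g1 * dense.T @ dense
    return np.linalg.solve(A, rhs_cube.ravel()).reshape(rhs_cube.shape)


class TestInitialize:
    def test_matches_dense_solve(self, small_op, rng):
        y = rng.random(small_op.measurement_shape)
        f0 = initialize(y, small_op, gamma1=0.7, gamma2=1.3)
        oracle = dense_solve(small_op, small_op.adjoint_apply(y), 0.7, 1.3)
        assert np.allclose(f0, oracle, rtol=1e-8)

    def test_gamma1_zero_reduces_to_scaled_adjoint(self, small_op, rng):
        y = rng.random(small_op.measurement_shape)
        f0 = initialize(y, small_op, gamma1=0.0, gamma2=2.0)
        assert np.allclose(f0, small_op.adjoint_apply(y) / 2.0)

    def test_zero_measurement_gives_zero_cube(self, small_op):
        assert not initialize(np.zeros(small_op.measurement_shape), small_op).any()

    def test_nonpositive_gamma2_rejected(self, small_op):
        with pytest.raises(ValueError, match="penalties"):
            initialize(np.zeros(small_op.measurement_shape), small_op, 1.0, 0.0)


class TestProjectionStep:
    def test_matches_dense_solve(self, small_op, rng):
        y = rng.random(small_op.measurement_shape)
        v = rng.random((6, 6, 3))
        l1 = rng.random(small_op.measurement_shape)
        l2 = rng.random((6, 6, 3))
        g1, g2 = 0.9, 1.7
        f = projection_step(v, y, l1, l2, g1, g2, small_op)
        rhs = l2 + g2 * v + small_op.adjoint_apply(g1 * y - l1)
        assert np.allclose(f, dense_solve(small_op, rhs, g1, g2), rtol=1e-8)

    def test_gamma1_zero_and_zero_duals_returns_v(self, small_op, rng):
        v = rng.random((6, 6, 3))
        f = projection_step(
            v,
            np.zeros(small_op.measurement_shape),
            np.zeros(small_op.measurement_shape),
            np.zeros_like(v),
            0.0,
            1.0,
            small_op,
        )
        assert np.allclose(f, v)

    def test_noiseless_consistent_point_is_fixed(self, small_op, rng):
        f_star = rng.random((6, 6, 3))
        y = small_op.apply(f_star)  # verify y = Phi f*
        f = projection_step(
            f_star,
            y,
            np.zeros_like(y),
            np.zeros_like(f_star),
            1.0,
            1.0,
            small_op,
        )
        assert np.allclose(f, f_star, rtol=1e-10)


class TestDenoiseStep:
    def test_identity_denoiser_with_zero_dual_is_passthrough(self, rng):
        f = rng.random((6, 6, 3))
        v = cf.denoise_step(f, np.zeros_like(f), 1.0, IdentityDenoiser())
        assert np.array_equal(v, f)

    def test_dual_offset_is_applied_before_denoising(self, rng):
        f = rng.random((6, 6, 3))
        l2 = rng.random((6, 6, 3))
        v = cf.denoise_step(f, l2, 2.0, IdentityDenoiser())
        assert np.allclose(v, f - l2 / 2.0)

    def test_tv_denoiser_reduces_tv_objective(self, rng):
        piecewise = np.zeros((32, 32, 2))
        piecewise[8:24, 8:24, :] = 1.0
        noisy = piecewise + 0.1 * rng.standard_normal(piecewise.shape)
        out = cf.denoise_step(noisy, np.zeros_like(noisy), 1.0, TVDenoiser())
        assert tv_objective(out) < tv_objective(noisy)

    @pytest.mark.parametrize(
        "denoiser",
        [TVDenoiser(), cf.WaveletDenoiser(), cf.SpectralAttentionDenoiser(3, seed=0)],
    )
    def test_zero_strength_is_identity(self, denoiser, rng):
        x = rng.random((8, 8, 3))
        assert np.array_equal(denoiser.denoise(x, 0.0), x)


class TestMultiplierUpdates:
    def test_zero_residuals_leave_multipliers_unchanged(self, small_op, rng):
        f = rng.random((6, 6, 3))
        y = small_op.apply(f)
        state = cf.ADMMState(f, f.copy(), np.ones_like(y), np.ones_like(f), 1.0, 1.0)
        new = cf.update_multipliers(state, y, small_op)
        assert np.array_equal(new.lambda1, state.lambda1)
        assert np.array_equal(new.lambda2, state.lambda2)
        assert new.i == state.i + 1

    def test_hand_computed_two_by_two_instance(self):
        op = cf.SensingOperator(cf.CodedMask(np.ones((2, 2)), feature_px=1), [0])
        f = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])
        v = np.array([[[0.5], [2.0]], [[3.0], [5.0]]])
        y = np.array([[2.0, 2.0], [2.0, 2.0]])
        l1 = np.zeros((2, 2))
        l2 = np.zeros((2, 2, 1))
        state = cf.ADMMState(f, v, l1, l2, gamma1=2.0, gamma2=3.0)
        new = cf.update_multipliers(state, y, op)
        # lambda1 = -2 * (y - f); lambda2 = -3 * (f - v), computed by hand
        assert np.array_equal(new.lambda1, np.array([[-2.0, 0.0], [2.0, 4.0]]))
        assert np.array_equal(
            new.lambda2, np.array([[[-1.5], [0.0]], [[0.0], [3.0]]])
        )

    def test_zero_gamma_freezes_lambda1(self, small_op, rng):
        f = rng.random((6, 6, 3))
        y = rng.random(small_op.measurement_shape)
        state = cf.ADMMState(
            f, f.copy(), np.ones(small_op.measurement_shape), np.zeros_like(f), 0.0, 1.0
        )
        new = cf.update_multipliers(state, y, small_op)
        assert np.array_equal(new.lambda1, state.lambda1)


class TestGuidanceFeatures:
    def test_raw_maps_shape_is_bands_plus_two(self, small_op):
        g = cf.guidance_features(1.5, small_op)
        assert g.maps.shape == (6, 6, 5)
        assert (g.maps[:, :, 0] == 1.5).all()

    def test_open_mask_trace_constant_in_full_overlap(self):
        op = cf.SensingOperator(cf.CodedMask(np.ones((4, 4)), feature_px=1), [0, 0, 0])
        g = cf.guidance_features(1.0, op)
        assert (g.maps[:, :, -1] == 3.0).all()

    def test_trace_map_matches_dense_diagonal(self, small_op):
        dense = cf.dense_phi(small_op)
        diag = np.diag(dense @ dense.T).reshape(small_op.measurement_shape)
        rows, cols = small_op.mask.shape
        expected = np.mean(
            [diag[:, s : s + cols] for s in small_op.shifts], axis=0
        )
        assert np.allclose(cf.guidance_features(1.0, small_op).maps[:, :, -1], expected)


class TestReconstruct:
    def test_identity_operator_converges_geometrically_to_input(self):
        # with Phi = I and the identity prior, each iteration halves the
        # error at unit penalties, so the input is recovered to numerical
        # precision within a few tens of iterations
        cube = cf.SpectralDatacube(
            np.arange(16, dtype=float).reshape(4, 4, 1), [500.0]
        )
        op = cf.SensingOperator(cf.CodedMask(np.ones((4, 4)), feature_px=1), [0])
        meas = cf.forward(cube, op)
        res = cf.reconstruct(
            meas,
            op,
            cf.SolverConfig(n_iterations=40, denoiser="identity"),
            wavelengths=[500.0],
        )
        assert np.allclose(res.cube.data, cube.data, atol=1e-8)
        # error halves iteration to iteration (geometric contraction)
        assert res.residuals[5] <= 0.51 * res.residuals[4]

    def test_tv_reconstruction_beats_initialization_psnr(self, phantom8):
        cube, op, meas = phantom8
        res = cf.reconstruct(
            meas,
            op,
            cf.SolverConfig(n_iterations=50, denoiser="tv"),
            wavelengths=cube.wavelengths,
        )
        assert res.psnr(cube) > res.initialization_psnr(cube)

    def test_residual_trends_down_after_burn_in(self, phantom8):
        """After a 3-iteration burn-in the data residual ||y - Phi f|| never
        rises back above its burn-in level and ends far below the initial
        value (plug-and-play iterations show small benign oscillations, so
        strict per-iteration monotonicity is not expected)."""
        cube, op, meas = phantom8
        res = cf.reconstruct(
            meas,
            op,
            cf.SolverConfig(n_iterations=50, denoiser="tv"),
            wavelengths=cube.wavelengths,
        )
        r = res.residuals
        assert np.isfinite(r).all()
        assert r[4:].max() <= r[3] + 1e-9
        assert r[-1] < 0.01 * r[0]

    def test_two_masks_both_beat_their_initialization(self, phantom8):
        cube, _, _ = phantom8
        for seed in (2, 3):
            op = cf.SensingOperator.uniform(
                cf.random_binary_mask(64, 64, seed=seed), 8
            )
            meas = cf.forward(cube, op)
            res = cf.reconstruct(
                meas,
                op,
                cf.SolverConfig(n_iterations=30, denoiser="tv"),
                wavelengths=cube.wavelengths,
            )
            assert res.psnr(cube) > res.initialization_psnr(cube)

    def test_residual_log_and_summary_report_the_run(self, phantom8):
        cube, op, meas = phantom8
        res = cf.reconstruct(
            meas,
            op,
            cf.SolverConfig(n_iterations=4, denoiser="tv"),
            wavelengths=cube.wavelengths,
        )
        log = res.residual_log()
        assert log.splitlines()[0] == "iteration,data_residual"
        assert len(log.splitlines()) == 6  # header + init + 4 iterations
        assert "final data residual" in res.summary()

    def test_final_cube_is_nonnegative(self, phantom8):
        cube, op, meas = phantom8
        res = cf.reconstruct(
            meas,
            op,
            cf.SolverConfig(n_iterations=5, denoiser="tv"),
            wavelengths=cube.wavelengths,
        )
        assert (res.cube.data >= 0).all()

    def test_measurement_shape_mismatch_rejected(self, small_op):
        with pytest.raises(ValueError, match="does not match"):
            cf.ADMMReconstruction(np.zeros((6, 6)), small_op)

    def test_gamma_schedule_length_validated(self, small_op):
        y = np.zeros(small_op.measurement_shape)
        cfg = cf.SolverConfig(n_iterations=3, gamma1=[1.0, 1.0])
        with pytest.raises(ValueError, match="schedule length"):
            cf.ADMMReconstruction(y, small_op, cfg).fit()
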