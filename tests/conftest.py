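import numpy as np
import pytest

import cassifundus as cf


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_op():
    """6x6x3 instance with a random binary mask and shifts (0, 1, 2)."""
    mask = cf.random_binary_mask(6, 6, fill_fraction=0.5, feature_px=1, seed=0)
    return cf.SensingOperator(mask, [0, 1, 2])


@pytest.fixture
def random_cube(rng):
    """Random 6x6x3 cube matching ``small_op``."""
    return cf.SpectralDatacube(rng.random((6, 6, 3)), [500.0, 510.0, 520.0])


@pytest.fixture(scope="session")
def phantom_recovery():
    """Full 64x64x32 eye-phantom pipeline: simulate (1% noise), ADMM-TV 50
    iterations, vessel absorption spectrum via the normalized-difference
    formula.  Shared because the run takes a few seconds."""
    spec = cf.SceneSpec(seed=0)
    cube, roi, truth = cf.eye_phantom_scene(spec)
    mask = cf.random_binary_mask(spec.rows, spec.cols, 0.5, 2, seed=0)
    op = cf.SensingOperator.from_dispersion(mask, cf.default_prism(), cube.wavelengths)
    sigma = 0.01 * op.apply(cube.data).max()
    meas = cf.forward(cube, op, cf.NoiseModel("gaussian", sigma=sigma, seed=0))
    result = cf.reconstruct(
        meas,
        op,
        cf.SolverConfig(n_iterations=50, denoiser="tv"),
        wavelengths=cube.wavelengths,
    )
    s_r = cf.field_average_spectrum(result.cube, roi)
    s_i = cf.field_average_spectrum(cf.flat_scene(spec))
    s_a = cf.absorption_spectrum(s_r, s_i)
    return {
        "cube": cube,
        "roi": roi,
        "truth": truth,
        "result": result,
        "s_r": s_r,
        "s_a": s_a,
    }


@pytest.fixture(scope="session")
def phantom8():
    """Noiseless 64x64x8 eye-phantom capture: (cube, operator, measurement)."""
    spec = cf.SceneSpec(bands=8, seed=0)
    cube, _, _ = cf.eye_phantom_scene(spec)
    op = cf.SensingOperator.uniform(cf.random_binary_mask(64, 64, seed=1), 8)
    meas = cf.forward(cube, op)
    return cube, op, meas
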