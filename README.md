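# cassifundus

Coded-aperture snapshot spectral imaging (CASSI) for retinal imaging:
forward model, ADMM / deep-unfolding reconstruction, calibration, and
absorption-spectrum analysis — with synthetic scenes so the whole chain is
testable on a laptop.

## The problem

Spectral imaging of the retina must be done in a single exposure: the eye
moves too fast for scanning spectrometers. A CASSI system solves this by
placing a random binary coded aperture (mask) and a dispersive prism in
front of the camera. Every wavelength band of the scene is spatially
modulated by the same mask, sheared laterally by a wavelength-dependent
number of pixels, and summed on the detector. One 2-D frame therefore
encodes the whole 3-D datacube `f(x, y, λ)`:

```
Y_mn = Σ_k  f_(m−k') n k · T_(m−k') n  + g_mn        (shift-and-add)
y    = Φ f + g                                        (vectorized)
```

where `T` is the mask, `k'` the integer pixel shift of band `k`, and `g`
detector noise. Recovering `f` from `y` is an underdetermined inverse
problem, solved here with an augmented-Lagrangian / ADMM scheme that
alternates

1. a **denoising step** — the prior `Ψ(f)` applied to `f − λ₂/γ₂`
   (total variation, wavelets, or a trainable spectral-attention denoiser),
2. a **projection step** — the closed-form solve
   `f = (γ₂I + γ₁ΦᵀΦ)⁻¹ [λ₂ + γ₂v + Φᵀ(γ₁y − λ₁)]`, one-shot because
   `ΦΦᵀ` is diagonal, and
3. dual updates of the multipliers `λ₁, λ₂`.

The solver can also be **unfolded**: fixed at 4 stages with the per-stage
penalties `γ₁ⁱ, γ₂ⁱ` and the denoiser weights trained end to end against
simulated (cube, measurement) pairs.

The package also implements the instrument's calibration rules (band
spectral resolution = prism dispersion × mask-feature size; resolution-chart
contrast and lp/mm ↔ µm conversion; Otsu mask extraction from a
monochromatic capture) and the retinal absorption analysis
`S_a = S_i/max(S_i) − S_r/max(S_r)`, whose peaks reveal the oxyhemoglobin
signature near 540 and 575 nm.

## Worked example

Simulate an eye-phantom snapshot and reconstruct it:

```python
import cassifundus as cf

spec = cf.SceneSpec(seed=0)                       # 64×64, 32 bands, 445–600 nm
cube, vessels, truth = cf.eye_phantom_scene(spec)
mask = cf.random_binary_mask(64, 64, 0.5, feature_px=2, seed=0)
op = cf.SensingOperator.from_dispersion(mask, cf.default_prism(), cube.wavelengths)
sigma = 0.01 * op.apply(cube.data).max()          # 1% Gaussian noise
meas = cf.forward(cube, op, cf.NoiseModel("gaussian", sigma=sigma, seed=0))

model = cf.ADMMReconstruction(meas, op,
                              cf.SolverConfig(n_iterations=50, denoiser="tv"),
                              wavelengths=cube.wavelengths)
res = model.fit()
print(res.summary())
```

```
ADMM spectral reconstruction
============================================
scene shape           64 x 64 x 32
measurement shape     64 x 132
denoiser              TVDenoiser
iterations run        50
initial residual      58.0713
final data residual   2.95879
residual reduction    19.6x
gamma1 / gamma2       1.0 / 1.0
```

The snapshot is 64 × 132 because the prism spreads the 445–600 nm range over
68 pixels. The reconstruction reaches 23.68 dB PSNR against the ground
truth, versus 5.02 dB for the one-shot `Φᵀy`-based initialization. The
vessel absorption spectrum then recovers the oxyhemoglobin double peak:

```python
s_r = cf.field_average_spectrum(res.cube, vessels)       # vessel reflectance
s_i = cf.field_average_spectrum(cf.flat_scene(spec))     # lamp spectrum
s_a = cf.absorption_spectrum(s_r, s_i)
cf.find_absorption_peaks(s_a)[:2]                        # -> [540.0, 575.0]
```

Calibration figures from the packaged prism table:
`cf.average_spectral_resolution(cf.default_prism(), 2)` → `(5, 4.88…)` nm,
and `cf.lpmm_to_micron(57.0)` → `17.5` µm.

The same pipeline is available from a shell:

```sh
cassi-fundus simulate --scene phantom --seed 0 --out-dir run/
cassi-fundus reconstruct --measurement run/measurement.tif --mask run/mask.png \
    --iterations 50 --truth run/truth_cube.tif --out-dir run/out/
cassi-fundus calibrate
cassi-fundus spectra --cube run/out/reconstruction.tif --roi run/vessel_roi.png \
    --illumination run/flat.tif --out-dir run/out/
```

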