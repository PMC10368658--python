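# Methods

## Image-formation model

A scene datacube `f(r, c, k)` (rows × cols × L bands, relative radiometric
units, band centers strictly increasing in nm) is imaged through a binary
coded aperture `T(r, c)` and a dispersive wedge prism onto a monochrome
detector. The model is fully discrete: each band is multiplied by the mask,
translated along the column axis by an integer pixel shift `s_k`, and all
bands are summed, plus detector noise. Conventions:

- Arrays are `(row, col, band)`, 0-based; the column axis is the dispersion
  axis. Dispersion shifts are toward +columns and non-decreasing with
  wavelength (the opposite sign only mirrors the measurement).
- The measurement canvas is `cols + max(s_k)` wide so the full dispersed
  footprint is retained; out-of-footprint pixels are zero. This keeps the
  operator's adjoint exact (verified against a dense matrix oracle).
- Band shifts are integers; sub-pixel shear is out of scope.
- The mask is strictly binary {0, 1}; grayscale calibration captures are
  thresholded first (see calibration). `feature_px` records how many sensor
  pixels the smallest mask feature spans (2 by default, matching a mask
  sampled by ~2 × 2 camera pixels).

Pixel shifts come from a piecewise-constant dispersion table
(nm per pixel over contiguous wavelength intervals): the shift of band `k`
is `round(∫ dλ / D(λ))` from the reference wavelength to the band center.
The packaged table covers 445–602 nm in four segments (1.67 / 2.00 / 2.50 /
3.33 nm/pixel); the reference (zero-shift) wavelength is taken at the short
end, 445 nm, which the table itself does not pin down. On a 5-nm grid over
445–600 nm this spreads the scene over 68 extra columns.

Noise models: none, additive Gaussian (`sigma` in counts), or
Poisson–Gaussian (`gain` counts/photon), all seeded.

## Reconstruction

`y = Φf + g` is inverted by an augmented-Lagrangian scheme with the split
`f = v`:

- denoise: `v_i = D(f_{i−1} − λ₂/γ₂)` with prior weight `strength/γ₂`
  (base strength 0.1 by default);
- project: `f_i = (γ₂I + γ₁ΦᵀΦ)⁻¹ [λ₂ + γ₂v_i + Φᵀ(γ₁y − λ₁)]`;
- dual updates: `λ₁ ← λ₁ − γ₁(y − Φf_i)`, `λ₂ ← λ₂ − γ₂(f_i − v_i)`.

The projection is one-shot: `ΦΦᵀ` is diagonal (each measurement pixel mixes
distinct voxels), so the inverse is evaluated by the Woodbury identity
`(γ₂I + γ₁ΦᵀΦ)⁻¹ = (1/γ₂)[I − Φᵀ diag(γ₁/(γ₂ + γ₁d)) Φ]` with
`d = diag(ΦΦᵀ)`; cost is linear in voxels. The initialization uses the same
solve applied to `Φᵀy`. Both agree with dense linear solves to 1e-8
relative on small instances (test oracle).

Numerical choices and behavior:

- Multipliers are zero-initialized (standard ADMM; the formulation does not
  say otherwise) and updated after the projection with the current
  iterates. The literal mixed-index variant (λ₂ update against the previous
  v) was evaluated and diverges on the standard fixtures.
- Penalties default to constants γ₁ = γ₂ = 1 for classic priors; schedules
  (sequences per iteration) are accepted everywhere, and γ₁ = 0 is allowed
  (the data term drops out; the γ₁-weighted dual term is evaluated in the
  equivalent form `Φᵀ(γ₁y − λ₁)` so nothing is divided by zero).
- With a plug-in denoiser the data residual is not strictly monotone: small
  oscillations (a few percent of the residual scale) appear after the
  initial fast decay. This is expected for plug-and-play ADMM with constant
  penalties. Strong continuation (growing γ₂) makes the trace monotone but
  measurably degrades reconstruction quality and spectral fidelity, so it
  is not the default; the tests assert the trend (the residual never rises
  back above its burn-in level and ends ≪ its initial value).
- Iterates may go negative; nonnegativity is clipped onto the final output
  only.
- Stopping is a fixed iteration count (4 by default, matching the unfolded
  depth; classic priors typically use 50), with an optional relative-change
  tolerance for classic-prior mode.
- Divergence (non-finite residual) raises an error carrying the residual
  trace.

Priors: isotropic spatial TV band-by-band via Chambolle's dual algorithm
(20 inner iterations), per-band wavelet soft-thresholding (db4), identity,
and a trainable spectral-attention denoiser (below). With TV, strength 0.1,
50 iterations and 1% noise, the 64×64×32 phantom reconstructs at ~24 dB
PSNR from a ~5 dB initialization, and reconstruction quality is insensitive
to the mask realization (≤3 dB PSNR spread across mask seeds) because the
mask enters only through the projection.

## Deep unfolding

The solver unrolled to 4 stages forms a network whose parameters are the
per-stage penalties (softplus-parameterized, hence always positive) and the
weights of the spectral-attention denoiser shared across stages. The
denoiser treats bands as tokens: per-band (mean, std) descriptors are
projected to queries/keys (dim 4), softmax attention mixes bands, a shared
3 × 3 kernel mixes space, and the residual is gated per pixel by a linear
map of guidance features — the γ₂ constant map, the per-band mask stack,
and the band-averaged shifted-back diagonal of `ΦΦᵀ` — then scaled by the
step's prior strength, so zero strength is exactly the identity.

Training minimizes MSE between the unfolded output and the truth cube on
simulated pairs: mini-batch size 1, Adam, a stepwise learning-rate schedule
(constant for 5 warm-up epochs, then ×0.9 every 15 epochs). The
implementation is pure numpy with central finite-difference gradients over
the ~44-dimensional parameter vector — deterministic given the seed and
free of framework dependencies; the default learning rate is 1e-2, scaled
to this small parameterization. Training problem sizes default to 32×32×8
patches and a handful of epochs, which train in seconds on one CPU;
the trained network beats identity-denoiser unfolding at equal depth on
held-out patches.

## Calibration

- Band spectral resolution = local dispersion (nm/pixel) × feature size
  (pixels): the spectral span that translates the mask image by one
  feature. Values are rounded half-up to one decimal; the packaged table's
  last segment (3.33 nm/pixel) yields 6.66 → 6.7 under this convention
  (truncation would print 6.6), so exact checks use the first three
  segments.
- The system figure is the range-width-weighted mean over segments,
  reported rounded to integer nm alongside the exact value (5 nm / 4.88 nm
  for the packaged table with 2-pixel features).
- Resolution-chart analysis: Michelson contrast `(I_max − I_min)/(I_max +
  I_min)` of a line profile per bar group; the resolvable limit is the
  highest spatial frequency with contrast ≥ 0.4 (default threshold), and
  the period in µm is `1000/(lp/mm)` to one decimal.
- Mask extraction from a monochromatic flat-field capture: Otsu global
  threshold; the transmitting fraction is a sanity flag (warning outside
  [0.4, 0.6]). With 2% Gaussian noise the recovered mask agrees with truth
  on ≥99% of pixels.

## Spectra

`S_a = S_i/max(S_i) − S_r/max(S_r)` exactly as defined — a normalized
difference, not a log-ratio optical density. It is invariant to positive
rescaling of either spectrum. Reflectance spectra are per-band means over a
region of interest (vessel mask or circular ROI); the illumination spectrum
is emulated as the full-frame average of a flat-target cube, mirroring a
white-paper capture. Peak analysis smooths with a 3-point moving average
and ranks local maxima by prominence, merging peaks closer than a window
(10 nm default).

## Synthetic scenes

Generators are deterministic given a seed and produce nonnegative, finite
cubes on the default 445–600 nm / 32-band (5-nm) grid at 64 × 64, sized for
sub-minute test runs.

- **Random mask**: i.i.d. Bernoulli(fill) on the feature grid, upsampled by
  `feature_px`.
- **Rainbow**: glyph silhouettes lit per column by a Gaussian band whose
  center sweeps linearly across the range (linear-variable-filter
  behavior); FWHM 10 nm by default (the emulated filter passes 7–20 nm).
- **Bar target**: three-bar groups at stated lp/mm, horizontal and
  vertical, spectrally flat, unit contrast by construction.
- **Eye phantom**: `background(r,c) · (1 − A(λ) · vessel(r,c))` with a
  smooth (Gaussian-filtered, rescaled to [0.6, 1]) spectrally flat
  background and a branching random-walk vessel raster dilated to ~2-pixel
  width, covering 2–10% of the frame (walks are relaunched if a seed's
  raster comes out too sparse). The absorber is two Gaussians centered at
  the oxyhemoglobin peaks, 540 and 575 nm, amplitudes 0.6/0.5 and widths
  (σ) 12/10 nm — widths chosen so the *summed* absorber attains its
  discrete maxima exactly at 540 and 575 nm on the 5-nm grid (broader lobes
  let the 540-nm tail drag the second maximum to 570 nm). A user-supplied
  extinction CSV can replace the Gaussian model.

What the phantom does *not* emulate: ocular optics (lens aberrations,
scatter), wavelength-dependent fundus reflectance, realistic vascular
topology, and detector nonidealities beyond Gaussian/Poisson noise. Passing
recovery tests therefore demonstrates the correctness of the sensing model
and solver under the stated noise, not clinical-grade performance on real
retinas.

## Known limitations

- Integer band shifts only; scenes with strong sub-pixel dispersion content
  are not modeled.
- The spectral-attention denoiser is a deliberately small stand-in for a
  full spectral-transformer denoiser; it trains in seconds but its
  denoising capacity is commensurately modest.
- Finite-difference training scales linearly in parameter count; it is not
  intended for architectures beyond ~10² parameters.
- Reconstruction on the native sensor grid vs. a feature-binned grid is
  left to the caller (generate scenes at either resolution); no automatic
  binning is performed.
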