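# Methods

This note records the models, assumptions, numerical choices and known
limitations behind each `scopeqc` module.

## 1. First-order optics (`scopeqc.optics`)

All calculators use paraxial thin-lens relations on a point-scanning layout:
scanner → scan lens (focal length `f_S`) → tube lens (`f_T`) → objective
(`f_O`, numerical aperture `NA`, immersion index `n`).

- Relay magnification `M = f_T / f_S`. Angles at the scanner are demagnified
  to `θ/M` at the objective pupil; beam diameter is magnified by `M`.
- Field-of-view diameter `FOV = 2 · f_O · tan(θ/M)` with `θ` the scanner's
  mechanical-optical half-angle. The tangent form is kept (not the
  small-angle product) — at the few-degree angles typical of relays the
  difference is <0.2 %, but the tangent is the exact ray-trace result for an
  ideal f-theta-free objective.
- Effective excitation NA = `NA · beam_fill_fraction`, clipped at the full
  NA. The fill fraction is the ratio of the 1/e² beam diameter to the back
  aperture; underfilling trades resolution for a longer axial focus.
- Two-photon diffraction-limited FWHMs for a uniformly-filled pupil:
  radial `δr = 0.6·λ/NA` (nm), axial `δz = 2·λ·n/NA²` (µm). These are the
  standard Gaussian-focus two-photon expressions; they assume an
  aberration-free objective at wavelength λ.
- Collection fraction: isotropic emission into the sphere, so the captured
  fraction is the cone solid angle `Ω/4π = (1 − cos θ_max)/2` with
  `θ_max = asin(NA/n)`. Validated in tests against a Monte-Carlo oracle
  (uniform unit vectors, cone counting).

Inputs are validated (`NA < n`, positive focal lengths, fill fraction in
(0, 1]); violations raise `ValueError` at construction.

## 2. Scan models and fits (`scopeqc.models`)

### Pockels transmission

`P(V) = P0 · sin²(2π·V/V0 + φ)`. Note the period in voltage is `V0` for the
*intensity* (the half-wave voltage in the usual crystal convention is
`V0/4` between minimum and maximum). Fitted parameters: `P0` (mW), `V0`
(V), `φ` (rad). The phase is normalized to `[0, π)` after fitting — the
model is π-periodic in φ, so this canonical branch makes results
comparable across runs; `P0` is reported positive.

Initialization: `P0₀ = max(P)`; `V0₀ = 4 ×` the abscissa distance from the
smoothed scan's minimum to its maximum (a quarter intensity period),
refined by a coarse grid search over candidate periods when that estimate
leaves a large residual; `φ₀` from a 64-point phase grid at fixed
`(P0₀, V0₀)`. A regression check compares the converged residual to the
initializer's; convergence to a worse point raises `FitConvergenceError`.

### Dispersion (GDD) scan

`I(φ) = I0 · (1 + α(φ + φ0)²/Δτ⁴)^(−1/2)`, `α = 16·ln²2 ≈ 7.687`. This is
the two-photon signal of a Gaussian pulse whose width is broadened by pure
group-delay dispersion:

`Δτ(φ) = Δτ0·√(1 + (4·ln2·φ/Δτ0²)²)`, and `I ∝ 1/Δτ` for fixed pulse
energy. Both forms are implemented; their consistency (`I(φ)` with
`φ0 = 0` equals `Δτ0/Δτ(φ)`) and agreement with an independent FFT
propagation of a chirped Gaussian field are test-enforced.

Fitted parameters: `I0` (signal units), `φ0` (fs², the pre-compensation
offset; the peak sits at applied GDD `−φ0`), `Δτ` (fs, transform-limited
intensity FWHM). Initialization: `I0₀ = max(I)`, `φ0₀ = −argmax`,
`Δτ₀ = (α·x½²/3)^¼` from the observed half-maximum half-width `x½`. If the
scan's maximum sits on the first or last point the peak may lie outside
the scanned range: the fit proceeds but warns and flags
`peak_at_boundary`.

### Uncertainties

Standard errors come from the Jacobian covariance scaled by the residual
variance (`scipy.optimize.curve_fit`). Optionally a seeded residual
bootstrap (`n_bootstrap` resamples of the fitted residuals) provides a
second estimate; tests verify the two agree for well-behaved scans and
that ±2σ intervals achieve ≥90 % coverage over 200 noisy repeats.

Degenerate inputs (constant ordinate, too few points, non-finite values)
raise typed exceptions before any optimizer call.

## 3. Virtual microscope (`scopeqc.simulate`)

A deliberately small forward model whose purpose is closed-loop validation:
every parameter the analyzers estimate is a configurable input here.

Scene → optics → detection:

1. **Scene**: square grid of dark bars (pitch 100 µm, width 10 µm, 5 %
   transmission) on a bright field; uniform dye bath; or point-like beads.
2. **Geometric distortion**: radial barrel map `r' = r(1 + k·r²)` applied in
   image space (object coordinates obtained by fixed-point inversion,
   accurate to <10⁻³ px over the field). `k_for_edge_displacement(pct, R)`
   parameterizes `k` by the percent radial displacement at radius `R`
   (by default the half-diagonal).
3. **Vignetting**: Gaussian `exp(−r²/2σ²)` with σ expressed as a fraction
   of the half-diagonal (`vignette_sigma`, default 0.8).
4. **PSF**: separable 3-D Gaussian. Beads are rendered as erf-integrated
   per-voxel volumes (exact integral of the Gaussian over each voxel, not a
   point sample), truncated at ±4σ; total flux per bead is conserved to
   <10⁻⁴ and test-enforced. Default FWHMs 0.79 µm radial / 5.0 µm axial at
   0.2 µm pixels and 0.5 µm z-steps.
5. **Detection**: mean photon signal scaled by `photon_scale`, Poisson
   sampled, plus Gaussian read noise (`read_noise_sd`) and a DC `offset`;
   clipped at `saturation` (default 32768) and quantized to uint16. The
   mixed Poisson–Gaussian variance law is test-enforced.

Bead placement is rejection sampling with a minimum pairwise separation and
configurable edge margins; impossible packings raise `BeadPlacementError`
rather than looping forever. Every render derives all randomness from one
`numpy.random.default_rng(seed)`, making outputs bit-reproducible.

Scope limits: no optical aberrations beyond the Gaussian PSF, no depth-
dependent scattering, no scanner timing artifacts, beads are ideal points
(no physical bead diameter convolution).

## 4. PSF measurement (`scopeqc.psf`)

- **Detection**: the volume is matched-filtered (1-voxel Gaussian) before
  thresholding so photon noise on a bead's slowly-decaying axial shoulder
  cannot split one bead into multiple candidates. Background = median,
  noise = 1.4826·MAD (robust σ); candidates are 3³ local maxima above
  `background + threshold_sd·noise` (default 8σ). Centers are refined on
  the raw data by an intensity-weighted centroid over a 5³ neighborhood.
  Residual duplicates within `min(isolation/2, 2)` µm merge into the
  brighter candidate; remaining candidates closer than
  `isolation_radius_um` (default 5 µm) are rejected pairwise, as are beads
  whose fitting window would cross a volume face.
- **Profiles**: x/y/z line profiles through each sub-voxel center are
  sampled by cubic-spline interpolation on a local crop (order-3
  `map_coordinates`; linear interpolation biases the radial FWHM by ~3 %
  at 4 px sampling, cubic keeps the noiseless bias below 2 %). Profile
  half-lengths default to 4× the expected FWHM per axis.
- **Fitting**: each profile gets a 4-parameter Gaussian fit (amplitude,
  center, σ, baseline); FWHM = 2√(2·ln2)·σ. Radial FWHM is the mean of x
  and y. Profiles with boundary peaks, multiple separated peaks, or <7
  samples are rejected per bead without failing the run. Fitted FWHMs
  below 2 sample spacings are flagged `undersampled` (Nyquist guard).
- **Summary**: mean ± sd across beads; additionally all beads are
  peak-normalized, averaged, and the averaged image re-fit as a
  cross-check (reported, not merged into the summary).

## 5. Field calibration (`scopeqc.field`)

- **Grid scale map**: grid rotation up to ±2° is estimated first by
  maximizing the projection-profile variance over 0.25° steps on a central
  crop, and removed. For each axis, the image is cut into strips two grid
  periods wide; each strip's projection profile yields dark-bar centers by
  parabolic sub-pixel interpolation around prominence-filtered minima, and
  each adjacent line pair gives a local scale `pitch / spacing` (µm/px)
  at the cell center. Fewer than 3 detected lines per axis raises
  `GridDetectionError`; spacing coefficient of variation >20 % flags the
  map `irregular`.
- **Distortion metric**: `100·|S̄_center − S̄_edge| / S̄`, where cells belong
  to the center block when their max-norm distance from the image center is
  ≤30 % of the half-field and to the edge ring when ≥75 %. For a barrel
  map parameterized by the corner displacement percentage, this metric
  reads slightly below the nominal percentage (the edge ring averages radii
  below the corner radius); tests bound it a priori at ±2 points around a
  4 % displacement.
- **Uniformity**: percent deviation `100·sd/mean` over a centered ROI
  (default 700 µm), with pixels at/above saturation excluded and counted,
  plus full-image row/column mean profiles for plotting.
- **FOV summary**: image extent in mm from pixel counts × mean scale, with
  the optional first-order predicted diameter attached for comparison.

## 6. QC orchestration (`scopeqc.qc`, `scopeqc.cli`)

`QcConfig.from_dict` validates a nested config (`optics`, `inputs`,
`analysis`, `seed`) and names every offending key in its error message;
analysis parameters default sensibly (tolerance 10 %, saturation 32768).
`run_qc` computes optics predictions, then runs each analyzer whose input
file is configured; a stage failure is recorded under `errors` by stage
name without aborting the rest. Measured-vs-predicted comparisons (FOV
diagonal, PSF FWHMs) are tagged `pass`/`warn` at the configured tolerance.
Reports carry the package version and a 16-hex-digit SHA-256 hash of the
canonicalized config for provenance. The `scopeqc` CLI exposes all of the
above plus the simulators; every randomized command takes `--seed`.

## 7. Open decisions and limitations

- The π-periodic Pockels phase convention (`[0, π)`) is a choice; labs
  tracking the modulator sign may prefer `(−π/2, π/2]`.
- The distortion metric is scalar by design (one number for trending); the
  full cell table is retained in `ScaleMap.cells` for spatial analysis.
- PSF measurements assume sparse, well-separated beads; dense fields
  lose beads to the isolation rule rather than producing biased widths.
- The virtual microscope's noise model ignores detector excess noise
  factors (PMT multiplication noise); variance calibration against a real
  detector would need a gain parameter per instrument.
- Diffraction-limit formulas are for uniform pupil illumination; with
  strong underfilling the Gaussian-pupil expressions would be more exact.
  The package follows the uniform-pupil convention and exposes the fill
  fraction only through the effective NA.
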