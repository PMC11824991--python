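# scopeqc

Quantitative characterization toolkit for two-photon laser-scanning
microscopes. It bundles the small set of calculations and analyses needed to
commission and routinely re-verify a point-scanning two-photon system:

- **First-order optics calculators** — relay magnification, pupil scan
  half-angle, predicted field of view, effective excitation NA, two-photon
  diffraction-limited FWHMs, and solid-angle collection fraction.
- **Instrument model fits** — the sin² transmission curve of a Pockels-cell
  power modulator and the inverse-pulse-width fluorescence response of a
  group-delay-dispersion (GDD) scan, both via nonlinear least squares with
  Jacobian and optional bootstrap standard errors.
- **Image-based calibration** — local magnification maps and a center-vs-edge
  distortion metric from grid-target images, illumination uniformity from dye
  bath images, and bead-based PSF FWHM measurement from z-stacks.
- **A virtual microscope** — a seeded forward model that renders grid, bath
  and bead images with realistic optics (barrel distortion, vignetting,
  Gaussian PSF) and detection noise (Poisson + read noise), used to validate
  every analyzer against known ground truth.
- **A QC runner** — one config-driven command that executes every analyzer
  whose input is present and writes a machine- and human-readable report.

## Physics

Transmitted power of a Pockels cell driven at voltage `V`:

    P(V) = P0 · sin²(2π·V/V0 + φ)

Two-photon fluorescence of a transform-limited Gaussian pulse with FWHM
`Δτ` (fs) under applied GDD `φ` (fs²), with `α = 16·ln²2`:

    I(φ) = I0 · (1 + α(φ + φ0)² / Δτ⁴)^(−1/2)

which is the inverse of the dispersion-broadened pulse width

    Δτ(φ) = Δτ0 · √(1 + (4·ln2·φ / Δτ0²)²).

First-order scan optics: relay magnification `M = f_T/f_S`, pupil half-angle
`θ/M`, field-of-view diameter `2·f_O·tan(θ/M)`; two-photon diffraction
limits `δr = 0.6·λ/NA` and `δz = 2·λ·n/NA²`; fluorescence collection
fraction `(1 − cos θ_max)/2` with `θ_max = asin(NA/n)`.

Details, assumptions and parameter defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

Design predictions from an optical-train config (`optics.yaml` holding the
eight keys `scan_focal_length_mm`, `tube_focal_length_mm`,
`objective_focal_length_mm`, `objective_na`, `immersion_index`,
`scanner_half_angle_deg`, `beam_fill_fraction`, `wavelength_nm`):

```console
$ scopeqc optics-report optics.yaml
relay_magnification = 3.75
pupil_scan_half_angle = 2.66667 deg
predicted_fov_diameter = 1.16439 mm
effective_excitation_na = 0.7
diffraction_radial_fwhm = 788.571 nm
diffraction_axial_fwhm = 4.99429 um
collection_half_angle = 36.9777 deg
collection_sphere_fraction = 0.100565
```

Simulate a Pockels voltage scan (truth: P0 120 mW, V0 300 V, φ 0.4 rad,
2 mW additive noise) and fit it:

```console
$ scopeqc simulate pockels --seed 7 --out sim
$ scopeqc pockels-fit sim/pockels.csv
P0 = 119.541 ± 0.31 mW
V0 = 300.375 ± 0.27 V
phase = 0.404707 ± 0.0044 rad
rss = 249.747 over 81 points
```

Same for a GDD scan (truth: φ0 20200 fs², Δτ 150 fs):

```console
$ scopeqc simulate gdd --seed 7 --out sim
$ scopeqc gdd-fit sim/gdd.csv
I0 = 1.00524 ± 0.0044 au
phi0 = 20114.4 ± 55 fs^2
delta_tau (FWHM) = 148.28 ± 0.67 fs
rss = 0.0287127 over 101 points
```

Render a 100 µm grid target at 2.77 µm/px and recover the scale:

```console
$ scopeqc simulate grid --seed 7 --out sim
$ scopeqc calibrate-field grid sim/grid.tif --pitch-um 100
scale S = 2.771 ± 0.014 um/px (168 cells)
center-vs-edge distortion = 0.16 %
field diagonal = 2.007 mm
```

The same analyses are available from Python (`scopeqc.optics`,
`scopeqc.models`, `scopeqc.simulate`, `scopeqc.field`, `scopeqc.psf`,
`scopeqc.qc`), and `scopeqc qc-run --config qc.yaml --out report/` runs
everything configured in one pass.

## Reproduction

```bash
python -m pytest -q tests/                                   # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports the headline design quantity (predicted
field-of-view diameter, mm to one decimal) computed from the packaged
calculators; it is deterministic, the `--seed` argument is recorded for
interface uniformity. All simulations are seeded and bit-reproducible;
every analyzer is validated in `tests/` against synthetic ground truth and
independent oracles (Fourier pulse propagation, Monte-Carlo solid angle).

## Layout

```
src/scopeqc/
  optics.py     first-order design calculators
  models.py     Pockels and GDD-scan models + fits
  simulate.py   virtual microscope (grid/bath/bead renderers, scan simulators)
  field.py      grid scale maps, distortion metric, uniformity, FOV summary
  psf.py        bead detection and PSF FWHM measurement
  io.py         TIFF/CSV/config readers and writers
  qc.py         config-driven QC orchestration
  cli.py        `scopeqc` command-line interface
```
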