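# Methods

This note documents the models implemented in `paw`, the defaults they
ship with, the numerical choices behind them, and what the synthetic
data do and do not establish about real measurements.

## Transduction physics (`paw.physics`)

A piezophotonic film converts a nanosecond laser pulse into a pressure
pulse by rapid optical heating and thermoelastic expansion. The
efficiency of heat-to-pressure conversion is the Grüneisen parameter
Γ = c_s²β/C_p of the expanding matrix (dimensionless; c_s in m/s, β in
K⁻¹, C_p in J·kg⁻¹·K⁻¹). Peak pressure depends on the optical
penetration depth 1/µ_a relative to the acoustic transit length c_s·τ_L
during the laser pulse:

* thin absorber (1/µ_a < c_s·τ_L): p_max = Γ·E_L/(c_s·τ_L);
* thick absorber (otherwise): p_max = Γ·E_L·µ_a.

The boundary case 1/µ_a = c_s·τ_L is assigned to "thick"; the regime
definitions are strict inequalities and the choice only affects the
measure-zero boundary. The Napierian absorption coefficient is derived
from decadic absorbance as µ_a = 2.3·A/l (2.3 approximating ln 10,
the convention of the film tables this module mirrors; the Beer–Lambert
identity therefore holds to ~0.5%).

API units follow the field's reporting conventions — MPa, mJ/cm², µm,
ns, cm⁻¹ — with all arithmetic in SI internally, so formulas read as
published and unit bugs cannot hide in the middle of a computation.

The Mechanical Index is implemented as MI = p_rarefaction[MPa]/√f[MHz]
(the standard regulatory definition), with a flag at the 0.7
cavitation-risk threshold. Composite CNT+PDMS films take the Γ of the
PDMS matrix, which is the component that expands and launches the wave;
no Γ, β or C_p values are bundled for specific films — they are user
inputs.

`physics.FILM_TABLE` records the measured film properties (thickness,
absorbance at 532 nm, hydrophone peak pressure at 50 mJ/cm²) used by
the reference checks; absorbances at the spectrophotometer ceiling are
stored at the A = 10 bound, making the derived µ_a values lower bounds.

## Interferometric pressure mapping (`paw.interferometry`)

Fringe demodulation is the classical 2D Fourier-transform method:
FFT of the interferogram, selection of the carrier sideband, Hann
apodization around it, translation of the carrier to DC, inverse FFT,
and 2D phase unwrapping (reliability-sorted, via
`skimage.restoration.unwrap_phase`). Choices:

* **Carrier detection**: largest-magnitude spectral peak outside a DC
  exclusion disc of 3 cycles/image; the Hermitian twin with the lower
  angular coordinate is taken, which fixes the sign convention
  (compression → positive Δφ; a `sign=-1` flag flips it for the
  mirrored interferometer geometry). An image whose best sideband is
  below 5% of the DC magnitude is rejected as carrying no fringes.
* **Apodization**: 2D Hann window of radius half the carrier-to-DC
  distance (configurable). The radius trades noise rejection against
  attenuation of the pulse's spectral width; see "sampling" below.
* **Residual plane removal**: after subtracting pumped and reference
  phases, a tilt+offset plane fitted over a quiet ROI (default: a
  10%-wide margin on the edge opposite the acoustic source) is
  subtracted. This absorbs unwrap constants and slow drifts without
  touching the pulse region.
* **Carrier sharing**: `pressure_map` detects the carrier on the
  reference image and reuses it for the pumped image, so the acoustic
  perturbation cannot bias the carrier estimate.

The phase-to-pressure chain is Δn = (Δφ/2π)(λ/l) with λ the probe
wavelength (default 400 nm) and l the liquid path (default 2 mm, a
line-of-sight average — no Abel inversion is attempted);
Δρ = Δn/0.322 g·cm⁻³ (empirical refractivity slope of water); and the
Tait equation of state P = k₀/n[(ρ/ρ₀)ⁿ − 1] + P₀ reported as gauge
pressure in MPa. Default water EOS at 20 °C: ρ₀ = 0.9982 g/cm³,
n = 7.15, k₀ = ρ₀·c_s² with c_s = 1482 m/s, P₀ = 0.101325 MPa; all
overridable. The EOS is inverted in closed form,
ρ = ρ₀(1 + nP/k₀)^(1/n), which is exact and needs no iteration;
pressures at or below the −k₀/n bound raise an error. For
|Δρ|/ρ₀ < 10⁻³ the EOS agrees with the acoustic relation P = c_s²Δρ
to better than 1%, which is the basis of several independent test
oracles.

**Sampling.** The demodulated bandwidth is limited by the Hann window
radius (⅛ of the image side at the default 0.25 cycles/px carrier), so
pulse amplitude recovery depends on how many pixels span the pulse: a
36 µm FWHM pulse is recovered to ~1.5% at 1 µm/px on a 384² grid (the
default synthetic geometry), but only to ~10–15% when the pulse spans
≲ 25 px. Profiles report per-position mean and standard deviation
across the transverse axis; FWHM is measured between linearly
interpolated half-maximum crossings.

## Waveform metrics (`paw.waveforms`)

Hydrophone calibration divides the trace spectrum by the interpolated
sensitivity curve (V/MPa). Outside the calibrated band (typically
1–30 MHz) the sensitivity is held at its band-edge value: spectral
content beyond the calibration range is passed through unscaled rather
than extrapolated, which leaves out-of-band pressure contributions
conservatively estimated. Metrics are computed after subtracting a
baseline (median of the first 10% of samples): peak compressive
pressure, rarefaction magnitude searched from the compressive peak to
the end of the trace (photoacoustic pulses carry a trailing tail),
temporal FWHM by interpolated half-maximum crossings, and centre
frequency as the spectral centroid of the one-sided magnitude spectrum.
Metrics are computed on the calibrated trace.

## Release kinetics (`paw.guv_release`)

Segmentation is a global per-frame Otsu threshold (absolute override
available) with connected-component labelling and an equivalent-radius
filter; the interior mask is eroded by one pixel to keep the membrane
rim out of the interior mean. Tracking is greedy nearest-neighbour
linking with a distance cap and no gap closing — adequate because the
experimental vesicles are immobilised on a gel and essentially
stationary; tracks shorter than a configurable minimum (default 3
frames) are dropped. Background is the per-frame mean over a
vesicle-free ROI; an ROI is rejected when more than 2% of its pixels
(and more than two) exceed the segmentation threshold in any frame, a
criterion that catches intruding vesicles while tolerating isolated
noise excursions.

The released fraction is f(t) = 1 − I_t/I₀ on background-corrected
intensities (I₀ = first tracked frame), clipped to [0, 1] with the
clip count reported, under the assumption of complete release at
infinite time. The Ritger–Peppas law k·tⁿ is fitted by unweighted
nonlinear least squares on the untransformed pairs with t > 0 and
f < 0.6 (the model's validity bound; the mask is reported), started
from a log–log regression on the positive fractions and bounded to
k ≥ 0, n > 0; standard errors come from the Jacobian-based covariance.
Both per-vesicle and pooled-curve fits are supported and the fit report
records which was used (the pipeline default is pooled). Fitting on
untransformed data keeps small/negative noisy fractions in the loss
instead of discarding them, which is what keeps the exponent estimate
unbiased in the Monte-Carlo checks. Group comparisons are two-tailed
pooled-variance t-tests with means ± SEM.

## Synthetic data (`paw.synthetic`)

The generators define the study conditions under which the pipeline is
validated:

* **Pressure field / interferograms**: 1 MPa peak, 36 µm spatial FWHM,
  compression/rarefaction ratio 10, on a 384² grid at 1 µm/px;
  carrier 0.25 cycles/px, visibility 0.8, mean intensity 100,
  probe 400 nm over 2 mm of water. The pulse template is a
  raised-cosine compressive lobe (FWHM equals half-width exactly) with
  a wider (2×) inverted trailing lobe — the steep-rise,
  weak-rarefaction morphology of rigidly backed thermoelastic sources —
  rather than a Gaussian; the template is swappable. Rendering uses the
  exact closed-form Tait inversion, so round-trip tests probe only the
  demodulation, not the forward model.
* **Waveforms**: 7 MPa peak, 25 ns FWHM, ratio 10, 0.5 ns sampling,
  with the pulse centre on a sample and the half-maximum crossings on
  the grid, so the analysis metrics are exact rather than
  quantization-limited.
* **Movies**: five non-overlapping stationary discs (radius 6–12 µm,
  initial dye amplitude 150–250 over a background of 10) on a 96² grid
  at 1 µm/px, 900 s at 2 Hz (1800 frames); interior dye signal
  I₀(1 − k·tⁿ) with n = 0.53 and k = 0.25/900^0.53 ≈ 0.0068, i.e. 25%
  release by 900 s; per-pixel Gaussian noise σ = 10 (SNR ≈ 20 for a
  typical vesicle). Dye rides on top of the background level, so
  background subtraction recovers the release law exactly in the
  noise-free case. Photobleaching is not simulated; a k = 0
  configuration serves as the constant-intensity control.

Every generator is a pure function of (config, seed) and
bit-reproducible; independent seeded streams are derived per generator.

What passing tests show — and don't. The synthetic movies have uniform
discs, stationary geometry, additive Gaussian noise and no bleaching,
debris or focus drift; the synthetic interferograms have an ideal
monochromatic carrier and no speckle or vibration. Recovery of (k, n)
and of pressure maps under these conditions validates the algebra and
the estimators, not robustness to every artefact of real microscope or
interferometer data.

## Pipeline and CLI

`run_pipeline` chains simulate → track → fit deterministically from a
single configuration and writes a manifest (config hash, seed, tool
version, output list, timestamp). The `paw` executable exposes each
stage; results are JSON on stdout, logs on stderr, and exit codes are
0/1/2 for success/runtime error/usage error.

## Known limitations

* No acoustic propagation modelling (diffraction, attenuation,
  nonlinearity): fields are kinematic templates at the observation
  plane, and measured peak-pressure tables are carried as metadata, not
  predicted.
* The interferometric inversion treats the optical path as uniform; it
  is a line-of-sight average, biased low for waves narrower than the
  path is deep.
* Hydrophone spatial averaging and out-of-band response are not
  corrected beyond the flat extrapolation described above.
* The tracker does no gap closing or merge/split handling; it is not
  suitable for dense, fast-moving objects.
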