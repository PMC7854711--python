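# paw — photoacoustic-wave analysis

`paw` quantifies how laser-generated photoacoustic (thermoelastic)
pressure waves permeabilize giant unilamellar vesicles (GUVs). It is
aimed at groups doing optical generation of ultrasound with
piezophotonic films (CNT–PDMS, dye-doped polystyrene) who need to turn
three kinds of raw measurement into numbers:

1. **Interferograms → pressure maps.** A Mach–Zehnder interferogram of
   the wave in solution is demodulated by the 2D Fourier-transform
   method (Hann apodization of the carrier sideband, 2D phase
   unwrapping), and the phase change Δφ is converted through

   Δn = (Δφ/2π)(λ/l),  Δρ = Δn/0.322 g·cm⁻³,  P = k₀/n[(ρ/ρ₀)ⁿ − 1] + P₀

   (Tait equation of state for water) into a 2D gauge-pressure map,
   plus 1D profiles with peak pressure and spatial FWHM.
2. **Hydrophone traces → pulse metrics.** Frequency-domain calibration
   against the manufacturer's sensitivity curve, then peak compressive
   and rarefaction pressures, temporal FWHM, spectral centre frequency
   and the compression/rarefaction ratio.
3. **Fluorescence movies → release kinetics.** Vesicle segmentation and
   tracking, background-corrected interior intensity, released fraction
   f(t) = 1 − I_t/I₀, and a nonlinear least-squares fit of the
   Ritger–Peppas power law M_t/M_∞ = k·tⁿ (valid for M_t/M_∞ < 0.6),
   whose exponent n diagnoses the transport mechanism (0.43 Fickian,
   1.0 zero-order). Group contrasts use the two-tailed pooled-variance
   Student t-test with mean ± SEM.

Closed-form transduction physics (Grüneisen parameter Γ = c_s²β/C_p,
thin/thick-absorber peak pressures, interface transmission
T = 4Z₁Z₂/(Z₁+Z₂)², Mechanical Index) lives in `paw.physics`, and
seeded generators for all three input kinds live in `paw.synthetic`, so
the whole chain is testable against known ground truth.

## Worked example

Render the default synthetic experiment (a 1 MPa, 36 µm FWHM, mostly
compressive pulse seen through 2 mm of water at 400 nm) and invert it:

```python
from paw.interferometry import pressure_map, pressure_profile, profile_fwhm
from paw.synthetic import SimulationConfig, make_pressure_field, render_interferogram

cfg = SimulationConfig(seed=7)
field = make_pressure_field(cfg)            # ground truth
pair = render_interferogram(field, cfg)     # pumped + reference fringes
pmap = pressure_map(pair, cfg.eos)          # full inversion
prof = pressure_profile(pmap, axis="cols")
print(f"true peak      : {field.grid.max():.3f} MPa")
print(f"recovered peak : {pmap.grid.max():.3f} MPa")
print(f"spatial FWHM   : {profile_fwhm(prof):.2f} um")
```

prints

```
true peak      : 1.000 MPa
recovered peak : 0.985 MPa
spatial FWHM   : 36.35 um
```

i.e. the fringe-demodulation chain recovers the pulse amplitude to 1.5%
and its width to well under a pixel. The same configuration drives the
time-domain generator; `paw.waveforms.metrics` on its output returns
`p_max 7.00 MPa, FWHM 25.0 ns, ratio 10.0` — the canonical morphology
of a rigidly confined piezophotonic source.

The release pipeline runs end to end from the command line or from
Python:

```python
from paw.pipeline import run_pipeline
from paw.synthetic import SimulationConfig

run_pipeline(SimulationConfig(seed=7), "out/")   # simulate → track → fit
```

`out/fit.json` then holds the pooled Ritger–Peppas fit; for seed 7 the
900 s, 2 Hz, five-vesicle movie (25% release, per-pixel SNR ≈ 20)
yields `n = 0.535 ± 0.001, k = 0.00657` against generating values
n = 0.53, k = 0.00680.

Equivalent CLI:

```sh
paw simulate movie --seed 7 --out out/
paw release track out/movie.tif --out out/tracks.csv
paw release fit out/tracks.csv --out out/fit.json
paw physics transmission --z1 1.048e6 --z2 1.494e6
```

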