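"""Seeded generators for every input the analysis pipeline consumes.

No raw interferograms, hydrophone traces or GUV movies are deposited
with the study this package supports, so each pipeline stage is
exercised on synthetic inputs with known ground truth.  The generators
embody the measured signal structure:

* a quasi-planar, mostly compressive pressure pulse (~1 MPa peak,
  ~36 µm spatial FWHM, compression/rarefaction ratio ~10) rendered into
  carrier-fringe interferograms through the exact forward model
  (Tait EOS → refractive index → fringe phase);
* hydrophone pulses of the same morphology in time (~25 ns FWHM);
* movies of stationary fluorescent vesicles whose interior intensity
  decays as I₀·(1 − k·tⁿ), i.e. power-law release, at a 2 Hz frame
  rate over 900 s with ~25% release by the final frame.

The compressive lobe is a raised-cosine (Hann) bump — its FWHM equals
its half-width exactly — with a wider trailing inverted lobe attached,
reproducing the steep-rise / weak-rarefaction morphology of thermoelastic
pulses from rigidly backed films.  Every generator is a pure function of
its configuration (including the seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import GeometryError, InvalidParameterError, PackingError, SamplingError
from .fields import ScalarField
from .interferometry import InterferogramPair, TaitEOS, WATER_REFRACTIVITY_SLOPE
from .waveforms import Waveform

#: Default release-rate constant: 25% release at 900 s with n = 0.53.
DEFAULT_RELEASE_K = 0.25 / 900.0**0.53


@dataclass
class GeometryConfig:
    shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 1.0


@dataclass
class PulseConfig:
    """Spatial pressure pulse at the observation plane."""

    peak_pressure_MPa: float = 1.0
    spatial_fwhm_um: float = 36.0
    rarefaction_ratio: float = 10.0     # compressive peak / rarefaction magnitude
    position_um: float | None = None    # pulse centre along propagation; grid centre if None
    tail_width_factor: float = 2.0


@dataclass
class FringeConfig:
    carrier_cpp: float = 0.25           # cycles/pixel along the propagation axis
    visibility: float = 0.8
    mean_intensity: float = 100.0
    noise_sigma: float = 0.0


@dataclass
class OpticsConfig:
    wavelength_nm: float = 400.0
    path_mm: float = 2.0


@dataclass
class MovieConfig:
    shape: tuple[int, int] = (96, 96)
    pixel_size_um: float = 1.0
    n_guvs: int = 5
    radius_range_um: tuple[float, float] = (6.0, 12.0)
    intensity_range: tuple[float, float] = (150.0, 250.0)
    background: float = 10.0
    k: float = DEFAULT_RELEASE_K
    n: float = 0.53
    duration_s: float = 900.0
    frame_rate_Hz: float = 2.0
    noise_sigma: float = 10.0           # per-pixel; SNR ~ 20 for typical I0


@dataclass
class WaveformConfig:
    p_max_MPa: float = 7.0
    temporal_fwhm_ns: float = 25.0
    rarefaction_ratio: float = 10.0
    sample_interval_ns: float = 0.5
    n_samples: int = 1024
    centre_fraction: float = 0.4        # pulse centre as a fraction of the trace
    tail_width_factor: float = 2.0
    noise_sigma: float = 0.0


@dataclass
class SimulationConfig:
    """Complete description of a synthetic experiment."""

    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    pulse: PulseConfig = field(default_factory=PulseConfig)
    fringes: FringeConfig = field(default_factory=FringeConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    eos: TaitEOS = field(default_factory=TaitEOS.water)
    movie: MovieConfig = field(default_factory=MovieConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)

    def __post_init__(self) -> None:
        if not (0 < self.fringes.visibility <= 1):
            raise InvalidParameterError("fringe visibility must be in (0, 1]")
        if self.pulse.rarefaction_ratio < 1 or self.waveform.rarefaction_ratio < 1:
            raise InvalidParameterError("rarefaction ratio must be >= 1")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator."""
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


def _pulse_profile(x: np.ndarray, centre: float, fwhm: float, peak: float,
                   rarefaction_ratio: float, tail_width_factor: float) -> np.ndarray:
    """Asymmetric pulse: Hann compressive lobe + wider trailing inverted lobe.

    ``x`` increases along propagation; the rarefaction lobe trails the
    compressive lobe (smaller x, nearer the source).  The Hann lobe's
    FWHM equals ``fwhm`` exactly.
    """
    y = np.zeros_like(x, dtype=float)
    u = (x - centre) / fwhm
    lobe = np.abs(u) < 1
    y[lobe] = peak * 0.5 * (1 + np.cos(np.pi * u[lobe]))
    if np.isfinite(rarefaction_ratio):
        tail_w = tail_width_factor * fwhm
        tail_centre = centre - fwhm - tail_w
        v = (x - tail_centre) / tail_w
        tail = np.abs(v) < 1
        y[tail] -= peak / rarefaction_ratio * 0.5 * (1 + np.cos(np.pi * v[tail]))
    return y


def make_pressure_field(cfg: SimulationConfig) -> ScalarField:
    """Quasi-1D pressure band: the pulse profile along columns, constant over rows."""
    geo, pulse = cfg.geometry, cfg.pulse
    width_um = geo.shape[1] * geo.pixel_size_um
    centre = pulse.position_um if pulse.position_um is not None else width_um / 2
    extent = pulse.spatial_fwhm_um * (2 + 2 * pulse.tail_width_factor)
    if extent > width_um:
        raise GeometryError("pulse wider than the grid")
    x_um = np.arange(geo.shape[1]) * geo.pixel_size_um
    profile = _pulse_profile(x_um, centre, pulse.spatial_fwhm_um,
                             pulse.peak_pressure_MPa, pulse.rarefaction_ratio,
                             pulse.tail_width_factor)
    grid = np.broadcast_to(profile, geo.shape).copy()
    return ScalarField(grid, "pressure_MPa", geo.pixel_size_um)


def pressure_to_phase(field: ScalarField, cfg: SimulationConfig) -> np.ndarray:
    """Forward model P → Δρ → Δn → Δφ (radians), the inverse of the analysis chain."""
    drho = cfg.eos.density_change_gcm3(field.grid)      # g/cm³
    dn = WATER_REFRACTIVITY_SLOPE * drho
    return dn * 2 * np.pi * (cfg.optics.path_mm * 1e-3) / (cfg.optics.wavelength_nm * 1e-9)


def render_interferogram(field: ScalarField, cfg: SimulationConfig) -> InterferogramPair:
    """Render a pressure field into a pumped/reference fringe-image pair.

    The pumped image is I₀·(1 + V·cos(2π·f·x + Δφ)) with the phase bump
    from the forward model; the reference is the unperturbed carrier.
    Optional additive Gaussian noise (independent on both images) is
    seeded from the configuration.
    """
    dphi = pressure_to_phase(field, cfg)
    fr = cfg.fringes
    cols = np.arange(field.shape[1])[None, :]
    carrier_phase = 2 * np.pi * fr.carrier_cpp * cols
    pumped = fr.mean_intensity * (1 + fr.visibility * np.cos(carrier_phase + dphi))
    reference = fr.mean_intensity * (
        1 + fr.visibility * np.cos(np.broadcast_to(carrier_phase, field.shape)))
    reference = reference.copy()
    if fr.noise_sigma > 0:
        rng = _rng(cfg, 1)
        pumped = pumped + rng.normal(0, fr.noise_sigma, field.shape)
        reference = reference + rng.normal(0, fr.noise_sigma, field.shape)
    make = lambda g: ScalarField(g, "intensity", field.pixel_size_um)
    return InterferogramPair(make(pumped), make(reference),
                             probe_wavelength_nm=cfg.optics.wavelength_nm,
                             optical_path_mm=cfg.optics.path_mm)


def make_waveform(cfg: SimulationConfig) -> Waveform:
    """Synthetic calibrated hydrophone trace with the stated pulse morphology.

    In time the rarefaction lobe follows the compressive peak.  The
    pulse centre falls on a sample and the FWHM is an even multiple of
    the sampling interval, so the interpolated metrics are exact.
    """
    wf = cfg.waveform
    if wf.temporal_fwhm_ns < 8 * wf.sample_interval_ns:
        raise SamplingError("pulse under-resolved: need >= 8 samples across the FWHM")
    t = np.arange(wf.n_samples) * wf.sample_interval_ns
    centre = round(wf.centre_fraction * wf.n_samples) * wf.sample_interval_ns
    # time axis: mirror the spatial template so the tail comes after the peak
    y = _pulse_profile(-t, -centre, wf.temporal_fwhm_ns, wf.p_max_MPa,
                       wf.rarefaction_ratio, wf.tail_width_factor)
    if wf.noise_sigma > 0:
        y = y + _rng(cfg, 2).normal(0, wf.noise_sigma, wf.n_samples)
    return Waveform(t, y, calibrated=True)


def make_guv_movie(cfg: SimulationConfig,
                   max_retries: int = 500) -> tuple[np.ndarray, pd.DataFrame]:
    """Movie of stationary fluorescent vesicles releasing their cargo.

    Returns a (frames, rows, cols) float stack and a ground-truth table
    (guv_id, row, col, radius_um, I0, k, n).  Disc i holds interior
    intensity I₀ᵢ·(1 − k·tⁿ), floored at zero, on a constant dim
    background, with per-pixel Gaussian noise.
    """
    mv = cfg.movie
    rng = _rng(cfg, 3)
    n_r, n_c = mv.shape
    px = mv.pixel_size_um

    centres: list[tuple[float, float]] = []
    radii_um: list[float] = []
    tries = 0
    while len(centres) < mv.n_guvs:
        if tries > max_retries:
            raise PackingError(
                f"could not place {mv.n_guvs} non-overlapping discs in {mv.shape}")
        tries += 1
        r_um = rng.uniform(*mv.radius_range_um)
        r_px = r_um / px
        row = rng.uniform(r_px + 2, n_r - r_px - 2)
        col = rng.uniform(r_px + 2, n_c - r_px - 2)
        ok = all(np.hypot(row - r0, col - c0) > r_px + rr / px + 3
                 for (r0, c0), rr in zip(centres, radii_um))
        if ok:
            centres.append((row, col))
            radii_um.append(r_um)
    i0 = rng.uniform(*mv.intensity_range, size=mv.n_guvs)

    n_frames = int(round(mv.duration_s * mv.frame_rate_Hz))
    times = np.arange(n_frames) / mv.frame_rate_Hz
    released = np.clip(mv.k * times**mv.n, 0.0, 1.0)

    rows_g, cols_g = np.mgrid[0:n_r, 0:n_c]
    masks = [np.hypot(rows_g - r0, cols_g - c0) <= r_um / px
             for (r0, c0), r_um in zip(centres, radii_um)]

    # dye fluorescence rides on top of the ambient background level, so
    # background subtraction recovers I0*(1 - k t^n) exactly
    stack = np.full((n_frames, n_r, n_c), mv.background, dtype=float)
    for i, mask in enumerate(masks):
        interior = np.maximum(i0[i] * (1.0 - released), 0.0)
        stack[:, mask] = mv.background + interior[:, None]
    if mv.noise_sigma > 0:
        stack += rng.normal(0, mv.noise_sigma, stack.shape)

    truth = pd.DataFrame({
        "guv_id": np.arange(mv.n_guvs),
        "row": [c[0] for c in centres],
        "col": [c[1] for c in centres],
        "radius_um": radii_um,
        "I0": i0,
        "k": mv.k,
        "n": mv.n,
    })
    return stack, truth


def movie_to_fields(stack: np.ndarray, pixel_size_um: float) -> list[ScalarField]:
    """Wrap a (frames, rows, cols) stack as a list of intensity fields."""
    return [ScalarField(frame, "intensity", pixel_size_um) for frame in stack]


def write_movie_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.astype(np.float32))
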