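"""Interferogram pairs to quantitative pressure maps.

A pressure pulse travelling through the 2-mm liquid layer of the imaging
cuvette changes the local density, hence the refractive index, hence the
optical path of the probe beam: it appears as bends in the carrier
fringes of a Mach–Zehnder interferogram.  This module inverts that chain:

1. ``extract_phase`` — spatial-carrier fringe demodulation by the 2D
   Fourier-transform method: isolate the carrier sideband with a Hann
   window in the spectral domain, shift it to DC, inverse transform, and
   unwrap the phase of the resulting analytic signal.
2. ``phase_difference`` — pumped minus reference phase, with residual
   tilt/offset removed over a quiet region.
3. ``phase_to_index`` — Δn = (Δφ/2π)(λ/l) for probe wavelength λ and
   liquid path l.
4. ``index_to_density`` — Δρ = Δn/0.322 g/cm³ (empirical water
   refractivity slope).
5. ``density_to_pressure`` — Tait equation of state
   P = k₀/n[(ρ/ρ₀)ⁿ − 1] + P₀, reported as gauge pressure in MPa.

``pressure_map`` composes the chain; ``pressure_profile`` and
``profile_fwhm`` reduce a map to the 1D statistics used to characterise
the pulse (peak pressure, spatial FWHM).

Sign convention: compression (density increase) produces positive Δφ;
pass ``sign=-1`` for the opposite interferometer geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase

from .errors import (
    BoundsError,
    IncompatibleFieldsError,
    InvalidParameterError,
    NoCarrierError,
    UnboundedPeakError,
    UnphysicalDensityError,
    UnphysicalPressureError,
)
from .fields import Rect, ScalarField

#: Empirical slope of water refractive index with density: dn/drho in
#: (g/cm3)^-1, i.e. delta_rho = delta_n / 0.322.
WATER_REFRACTIVITY_SLOPE = 0.322

#: Radius (in cycles/image, i.e. FFT bins) of the DC exclusion disc used
#: when auto-detecting the carrier peak.
DC_EXCLUSION_BINS = 3.0

#: Minimum carrier sideband magnitude, as a fraction of the DC magnitude,
#: below which an image is considered to carry no fringes.
CARRIER_THRESHOLD = 0.05


@dataclass
class TaitEOS:
    """Tait equation-of-state parameters for a liquid.

    P = k0/n [(rho/rho0)^n - 1] + P0, with k0 the bulk modulus scale in
    Pa, n the Tait exponent, rho0 the rest density in g/cm³ and P0 the
    ambient pressure in Pa.
    """

    k0_Pa: float
    exponent_n: float
    rho0_gcm3: float
    P0_Pa: float = 101325.0

    def __post_init__(self) -> None:
        if not (self.k0_Pa > 0 and self.exponent_n > 0 and self.rho0_gcm3 > 0):
            raise InvalidParameterError("k0, n and rho0 must be positive")

    @classmethod
    def water(cls, sound_speed_ms: float = 1482.0, rho0_gcm3: float = 0.9982,
              exponent_n: float = 7.15) -> "TaitEOS":
        """Water at 20 °C with k₀ = ρ₀·cs²."""
        k0 = rho0_gcm3 * 1000.0 * sound_speed_ms**2
        return cls(k0_Pa=k0, exponent_n=exponent_n, rho0_gcm3=rho0_gcm3)

    def pressure_gauge_MPa(self, drho_gcm3: np.ndarray) -> np.ndarray:
        """Gauge pressure (MPa) for a density change (g/cm³)."""
        rho = self.rho0_gcm3 + np.asarray(drho_gcm3, dtype=float)
        if np.any(rho <= 0):
            raise UnphysicalDensityError("total density must be positive everywhere")
        ratio = rho / self.rho0_gcm3
        return self.k0_Pa / self.exponent_n * (ratio**self.exponent_n - 1.0) * 1e-6

    def density_change_gcm3(self, p_gauge_MPa: np.ndarray) -> np.ndarray:
        """Invert the EOS: density change (g/cm³) for gauge pressure (MPa).

        The Tait form inverts in closed form,
        rho = rho0 (1 + n P/k0)^(1/n); pressures at or below the
        -k0/n spinodal bound have no physical density and raise.
        """
        p = np.asarray(p_gauge_MPa, dtype=float) * 1e6
        arg = 1.0 + self.exponent_n * p / self.k0_Pa
        if np.any(arg <= 0):
            raise UnphysicalPressureError(
                "pressure below the invertible (rho > 0) branch of the Tait EOS")
        return self.rho0_gcm3 * (arg ** (1.0 / self.exponent_n) - 1.0)


@dataclass
class InterferogramPair:
    """Pumped/reference interferogram pair plus probe-beam geometry."""

    pumped: ScalarField
    reference: ScalarField
    probe_wavelength_nm: float
    optical_path_mm: float
    carrier: tuple[float, float] | None = None  # (cycles/px rows, cols); auto if None

    def __post_init__(self) -> None:
        if self.pumped.quantity != "intensity" or self.reference.quantity != "intensity":
            raise InvalidParameterError("interferograms must be intensity fields")
        if not self.pumped.same_geometry(self.reference):
            raise IncompatibleFieldsError("pumped and reference geometry differ")
        if not (self.probe_wavelength_nm > 0 and self.optical_path_mm > 0):
            raise InvalidParameterError("wavelength and optical path must be positive")


@dataclass
class PressureProfile:
    """1D pressure statistics along one image axis."""

    positions_um: np.ndarray
    mean_MPa: np.ndarray
    std_MPa: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.mean_MPa = np.asarray(self.mean_MPa, dtype=float)
        self.std_MPa = np.asarray(self.std_MPa, dtype=float)
        if not (len(self.positions_um) == len(self.mean_MPa) == len(self.std_MPa)):
            raise InvalidParameterError("profile arrays must share length")
        if np.any(self.std_MPa < -1e-12):
            raise InvalidParameterError("std must be non-negative")


# ---------------------------------------------------------------------------
# carrier detection and demodulation

def _fft_bin_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Signed FFT bin coordinates (cycles/image) for each spectral sample."""
    fr = np.fft.fftfreq(shape[0]) * shape[0]
    fc = np.fft.fftfreq(shape[1]) * shape[1]
    return np.meshgrid(fr, fc, indexing="ij")


def detect_carrier(image: ScalarField) -> tuple[float, float]:
    """Locate the spatial-carrier peak in an interferogram spectrum.

    Returns the carrier frequency (cycles/pixel along rows, cols) of the
    largest-magnitude spectral peak outside a DC exclusion disc of
    :data:`DC_EXCLUSION_BINS` cycles/image.  Of the Hermitian twin peaks
    the one with the lower angular coordinate (atan2 in [0, 2pi)) is
    returned.  Raises :class:`NoCarrierError` when the best peak is
    below :data:`CARRIER_THRESHOLD` times the DC magnitude.
    """
    grid = image.grid
    F = np.fft.fft2(grid)
    mag = np.abs(F)
    kr, kc = _fft_bin_coords(grid.shape)
    dist = np.hypot(kr, kc)
    search = mag.copy()
    search[dist <= DC_EXCLUSION_BINS] = 0.0

    peak = search.max()
    dc = mag[0, 0]
    if dc <= 0 or peak < CARRIER_THRESHOLD * dc:
        raise NoCarrierError("no spatial carrier detectable above threshold")

    # deterministic tie-break between the conjugate twins (equal magnitude)
    cand = np.argwhere(np.isclose(search, peak, rtol=1e-12))
    angles = np.mod(np.arctan2(kr[tuple(cand.T)], kc[tuple(cand.T)]), 2 * np.pi)
    i = cand[np.argmin(angles)]
    return (kr[i[0], i[1]] / grid.shape[0], kc[i[0], i[1]] / grid.shape[1])


def _sideband_window(shape: tuple[int, int], carrier_cpp: tuple[float, float],
                     radius_bins: float | None) -> np.ndarray:
    """2D Hann window centred on the carrier sideband, in the FFT domain."""
    kr, kc = _fft_bin_coords(shape)
    cr = carrier_cpp[0] * shape[0]
    cc = carrier_cpp[1] * shape[1]
    # wraparound-aware distance to the carrier bin
    dr = (kr - cr + shape[0] / 2) % shape[0] - shape[0] / 2
    dc = (kc - cc + shape[1] / 2) % shape[1] - shape[1] / 2
    d = np.hypot(dr, dc)
    if radius_bins is None:
        radius_bins = 0.5 * np.hypot(cr, cc)  # half the carrier-to-DC distance
    if radius_bins <= 0:
        raise InvalidParameterError("apodization radius must be positive")
    w = np.zeros(shape)
    inside = d < radius_bins
    w[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / radius_bins))
    return w


def extract_phase(image: ScalarField,
                  carrier: tuple[float, float] | None = None,
                  apodization_radius_bins: float | None = None) -> ScalarField:
    """Demodulate an interferogram into an unwrapped phase map (radians).

    Fourier-transform fringe analysis: the spectrum is apodized with a
    Hann window centred on the carrier sideband (default radius: half
    the carrier-to-DC distance), the sideband is translated to DC, and
    the phase of the inverse transform is unwrapped in 2D.

    Parameters
    ----------
    image
        Intensity interferogram with a dominant spatial carrier.
    carrier
        Carrier frequency (cycles/pixel along rows, cols); auto-detected
        from the spectrum when omitted.
    apodization_radius_bins
        Radius of the spectral Hann window, in cycles/image.
    """
    if image.quantity != "intensity":
        raise InvalidParameterError("extract_phase expects an intensity field")
    if carrier is None:
        carrier = detect_carrier(image)
    grid = image.grid
    F = np.fft.fft2(grid)
    W = _sideband_window(grid.shape, carrier, apodization_radius_bins)
    analytic = np.fft.ifft2(F * W)
    # remove the carrier ramp before taking the angle
    rows = np.arange(grid.shape[0])[:, None]
    cols = np.arange(grid.shape[1])[None, :]
    demod = analytic * np.exp(-2j * np.pi * (carrier[0] * rows + carrier[1] * cols))
    phase = np.asarray(unwrap_phase(np.angle(demod)), dtype=float)
    return image.with_grid(phase, quantity="phase_rad")


def remove_plane(field: ScalarField, roi: Rect | None = None) -> ScalarField:
    """Subtract the least-squares plane (tilt + offset) fitted over ``roi``.

    The plane is fitted on the ROI (whole field when omitted) and
    subtracted everywhere.
    """
    grid = field.grid
    rows, cols = np.meshgrid(np.arange(grid.shape[0]), np.arange(grid.shape[1]),
                             indexing="ij")
    if roi is None:
        sel = np.ones(grid.shape, dtype=bool)
    else:
        roi.validate_within(grid.shape)
        sel = np.zeros(grid.shape, dtype=bool)
        sel[roi.slices()] = True
    A = np.column_stack([np.ones(sel.sum()), rows[sel], cols[sel]])
    coef, *_ = np.linalg.lstsq(A, grid[sel], rcond=None)
    plane = coef[0] + coef[1] * rows + coef[2] * cols
    return field.with_grid(grid - plane)


def quiet_margin(shape: tuple[int, int], source_edge: str = "left",
                 fraction: float = 0.1) -> Rect:
    """ROI covering a ``fraction``-wide margin on the edge opposite the source."""
    n_r, n_c = shape
    w_r = max(1, int(round(fraction * n_r)))
    w_c = max(1, int(round(fraction * n_c)))
    if source_edge == "left":
        return Rect(0, n_r, n_c - w_c, n_c)
    if source_edge == "right":
        return Rect(0, n_r, 0, w_c)
    if source_edge == "top":
        return Rect(n_r - w_r, n_r, 0, n_c)
    if source_edge == "bottom":
        return Rect(0, w_r, 0, n_c)
    raise InvalidParameterError(f"unknown source edge {source_edge!r}")


def phase_difference(pumped_phase: ScalarField, reference_phase: ScalarField,
                     quiet_roi: Rect | None = None,
                     source_edge: str = "left") -> ScalarField:
    """Pumped minus reference phase, with residual tilt/offset removed.

    The residual plane (from unwrap offsets and slow drifts) is fitted
    over ``quiet_roi`` — by default a 10%-wide margin on the edge
    farthest from the acoustic source — and subtracted everywhere.
    """
    if pumped_phase.quantity != "phase_rad" or reference_phase.quantity != "phase_rad":
        raise InvalidParameterError("phase_difference expects phase fields")
    if not pumped_phase.same_geometry(reference_phase):
        raise IncompatibleFieldsError("phase fields differ in geometry")
    diff = pumped_phase.with_grid(pumped_phase.grid - reference_phase.grid)
    if quiet_roi is None:
        quiet_roi = quiet_margin(diff.shape, source_edge)
    return remove_plane(diff, quiet_roi)


# ---------------------------------------------------------------------------
# unit-conversion chain

def phase_to_index(dphi: ScalarField, wavelength_nm: float,
                   path_mm: float) -> ScalarField:
    """Refractive-index change Δn = (Δφ/2π)·(λ/l)."""
    if dphi.quantity != "phase_rad":
        raise InvalidParameterError("phase_to_index expects a phase field")
    if not (wavelength_nm > 0 and path_mm > 0):
        raise InvalidParameterError("wavelength and path must be positive")
    dn = dphi.grid / (2 * np.pi) * (wavelength_nm * 1e-9) / (path_mm * 1e-3)
    return dphi.with_grid(dn, quantity="delta_n")


def index_to_density(dn: ScalarField) -> ScalarField:
    """Density change Δρ = Δn / 0.322 in g/cm³."""
    if dn.quantity != "delta_n":
        raise InvalidParameterError("index_to_density expects a delta_n field")
    return dn.with_grid(dn.grid / WATER_REFRACTIVITY_SLOPE,
                        quantity="delta_rho_gcm3")


def density_to_pressure(drho: ScalarField, eos: TaitEOS) -> ScalarField:
    """Gauge pressure map (MPa) from a density-change map via the Tait EOS."""
    if drho.quantity != "delta_rho_gcm3":
        raise InvalidParameterError("density_to_pressure expects a delta_rho field")
    return drho.with_grid(eos.pressure_gauge_MPa(drho.grid),
                          quantity="pressure_MPa")


def pressure_map(pair: InterferogramPair, eos: TaitEOS,
                 quiet_roi: Rect | None = None, source_edge: str = "left",
                 sign: int = 1) -> ScalarField:
    """Full interferogram-pair to pressure-map inversion.

    The carrier is detected on the reference image (unless supplied on
    the pair) and the same carrier is used to demodulate both images, so
    the acoustic perturbation cannot bias the carrier estimate.
    """
    carrier = pair.carrier or detect_carrier(pair.reference)
    ref_phase = extract_phase(pair.reference, carrier=carrier)
    pump_phase = extract_phase(pair.pumped, carrier=carrier)
    dphi = phase_difference(pump_phase, ref_phase, quiet_roi=quiet_roi,
                            source_edge=source_edge)
    if sign == -1:
        dphi = dphi.with_grid(-dphi.grid)
    dn = phase_to_index(dphi, pair.probe_wavelength_nm, pair.optical_path_mm)
    return density_to_pressure(index_to_density(dn), eos)


# ---------------------------------------------------------------------------
# profiles

def pressure_profile(pmap: ScalarField, axis: str = "cols",
                     roi: Rect | None = None) -> PressureProfile:
    """Mean ± std pressure along one axis, averaged over the other.

    ``axis="cols"`` gives a profile whose positions run along columns
    (statistics taken over rows), and vice versa.
    """
    if pmap.quantity != "pressure_MPa":
        raise InvalidParameterError("pressure_profile expects a pressure field")
    if roi is None:
        sub = pmap.grid
    else:
        roi.validate_within(pmap.shape)
        sub = pmap.grid[roi.slices()]
    if axis == "cols":
        reduce_axis, offset = 0, (roi.col0 if roi else 0)
    elif axis == "rows":
        reduce_axis, offset = 1, (roi.row0 if roi else 0)
    else:
        raise InvalidParameterError("axis must be 'rows' or 'cols'")
    mean = sub.mean(axis=reduce_axis)
    std = sub.std(axis=reduce_axis, ddof=0)
    positions = (np.arange(len(mean)) + offset) * pmap.pixel_size_um
    return PressureProfile(positions, mean, std)


def profile_fwhm(profile: PressureProfile) -> float:
    """Full width at half maximum of a profile peak, in µm.

    The half-maximum crossings nearest the global maximum are located by
    linear interpolation between samples; a missing crossing on either
    side raises :class:`UnboundedPeakError`.
    """
    y = profile.mean_MPa
    x = profile.positions_um
    i_pk = int(np.argmax(y))
    peak = y[i_pk]
    if peak <= 0:
        raise UnboundedPeakError("profile has no positive peak")
    half = peak / 2.0

    def _cross(idx_range, direction):
        prev = i_pk
        for i in idx_range:
            if y[i] < half:
                # interpolate between i and the previous sample
                x0, x1 = x[prev], x[i]
                y0, y1 = y[prev], y[i]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        raise UnboundedPeakError(
            f"no half-maximum crossing on the {direction} side of the peak")

    left = _cross(range(i_pk - 1, -1, -1), "left")
    right = _cross(range(i_pk + 1, len(y)), "right")
    return float(right - left)
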