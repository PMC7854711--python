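"""Hydrophone and transducer trace analysis.

Needle-hydrophone voltage traces are converted to absolute pressure by
frequency-domain deconvolution with the manufacturer's sensitivity curve
(V/MPa over a calibrated band, typically 1–30 MHz).  Calibrated traces
are reduced to the metrics used to characterise a photoacoustic pulse:
peak compressive pressure, peak rarefaction pressure (the trailing
negative tail), temporal FWHM, spectral centre frequency, and the
compression/rarefaction ratio.  A mostly-compressive photoacoustic pulse
has a ratio around 10 — the property that keeps the Mechanical Index low
even at multi-MPa compressive peaks.

Outside the calibrated band the sensitivity is held at its band-edge
value (flat extrapolation): spectral content beyond the calibration
range is then neither amplified nor removed, which makes out-of-band
pressure estimates conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InvalidCalibrationError,
    InvalidParameterError,
    NoCompressivePeakError,
    SamplingError,
    UnboundedPeakError,
)

MIN_SAMPLES = 16
BASELINE_FRACTION = 0.1  # leading fraction of the trace used for the baseline


@dataclass
class Waveform:
    """Uniformly sampled time trace: volts (raw) or MPa (calibrated)."""

    time_ns: np.ndarray
    value: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_ns.ndim != 1 or self.time_ns.shape != self.value.shape:
            raise InvalidParameterError("time and value must be 1D arrays of equal length")
        if len(self.time_ns) < MIN_SAMPLES:
            raise SamplingError(f"waveform needs at least {MIN_SAMPLES} samples")
        dt = np.diff(self.time_ns)
        if np.any(dt <= 0):
            raise SamplingError("time axis must be strictly increasing")
        if (dt.max() - dt.min()) > 1e-9 * dt.mean():
            raise SamplingError("waveform must be uniformly sampled")

    @property
    def sample_interval_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def units(self) -> str:
        return "MPa" if self.calibrated else "V"


@dataclass
class SensitivityCurve:
    """Hydrophone sensitivity (V/MPa) versus frequency (MHz)."""

    frequency_MHz: np.ndarray
    sensitivity_V_per_MPa: np.ndarray
    valid_band_MHz: tuple[float, float]

    def __post_init__(self) -> None:
        self.frequency_MHz = np.asarray(self.frequency_MHz, dtype=float)
        self.sensitivity_V_per_MPa = np.asarray(self.sensitivity_V_per_MPa, dtype=float)
        if self.frequency_MHz.shape != self.sensitivity_V_per_MPa.shape:
            raise InvalidParameterError("frequency and sensitivity must share shape")
        if np.any(np.diff(self.frequency_MHz) <= 0):
            raise InvalidParameterError("frequencies must be strictly increasing")
        if np.any(self.sensitivity_V_per_MPa <= 0):
            raise InvalidCalibrationError("sensitivities must be positive")
        lo, hi = self.valid_band_MHz
        if not (self.frequency_MHz[0] <= lo < hi <= self.frequency_MHz[-1]):
            raise InvalidParameterError("valid band must lie within the frequency range")

    def at(self, f_MHz: np.ndarray) -> np.ndarray:
        """Sensitivity at arbitrary frequencies, flat outside the valid band."""
        lo, hi = self.valid_band_MHz
        f = np.clip(np.asarray(f_MHz, dtype=float), lo, hi)
        return np.interp(f, self.frequency_MHz, self.sensitivity_V_per_MPa)


@dataclass
class WaveformMetrics:
    """Summary metrics of a calibrated photoacoustic pulse."""

    p_max_compressive_MPa: float
    p_min_rarefaction_MPa: float  # magnitude of the trailing negative lobe
    temporal_fwhm_ns: float
    centre_frequency_MHz: float
    compression_rarefaction_ratio: float


def calibrate(raw: Waveform, sens: SensitivityCurve) -> Waveform:
    """Deconvolve the hydrophone response: V trace -> MPa trace.

    Divides the trace spectrum by the interpolated sensitivity inside
    the valid band; outside the band the sensitivity is held at its
    band-edge value.
    """
    if raw.calibrated:
        raise InvalidParameterError("waveform already calibrated")
    n = len(raw.value)
    spectrum_v = np.fft.rfft(raw.value)
    f_MHz = np.fft.rfftfreq(n, d=raw.sample_interval_ns) * 1e3  # 1/ns = GHz
    pressure = np.fft.irfft(spectrum_v / sens.at(f_MHz), n=n)
    return replace(raw, value=pressure, calibrated=True)


def _half_crossing(t: np.ndarray, y: np.ndarray, i_peak: int, half: float,
                   direction: int) -> float:
    """Interpolated time where y falls below half, walking from the peak."""
    i = i_peak
    while 0 <= i + direction < len(y):
        j = i + direction
        if y[j] < half:
            return float(t[i] + (half - y[i]) * (t[j] - t[i]) / (y[j] - y[i]))
        i = j
    raise UnboundedPeakError("pulse does not fall to half maximum within the trace")


def metrics(w: Waveform) -> WaveformMetrics:
    """Peak pressures, temporal FWHM, centre frequency of a calibrated pulse.

    The baseline (median of the first 10% of samples) is subtracted
    first, so a constant offset does not bias the metrics.  The
    rarefaction pressure is the magnitude of the minimum in the window
    from the compressive peak to the end of the trace, matching the
    trailing-tail geometry of photoacoustic pulses.
    """
    base = np.median(w.value[: max(1, int(BASELINE_FRACTION * len(w.value)))])
    y = w.value - base
    if y.max() <= 0:
        raise NoCompressivePeakError("trace has no positive compressive peak")
    i_pk = int(np.argmax(y))
    p_max = float(y[i_pk])

    tail = y[i_pk:]
    p_rare = float(max(0.0, -tail.min()))

    half = p_max / 2.0
    t_left = _half_crossing(w.time_ns, y, i_pk, half, -1)
    t_right = _half_crossing(w.time_ns, y, i_pk, half, +1)

    f_MHz, mag = spectrum(replace(w, value=y))
    centre = float((f_MHz * mag).sum() / mag.sum()) if mag.sum() > 0 else 0.0

    ratio = p_max / p_rare if p_rare > 0 else np.inf
    return WaveformMetrics(
        p_max_compressive_MPa=p_max,
        p_min_rarefaction_MPa=p_rare,
        temporal_fwhm_ns=float(t_right - t_left),
        centre_frequency_MHz=centre,
        compression_rarefaction_ratio=float(ratio),
    )


def spectrum(w: Waveform) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum: (frequency in MHz, |FFT| magnitude)."""
    mag = np.abs(np.fft.rfft(w.value))
    f_MHz = np.fft.rfftfreq(len(w.value), d=w.sample_interval_ns) * 1e3
    return f_MHz, mag


# ---------------------------------------------------------------------------
# CSV I/O (two columns with header, comma separator, decimal point)

def read_waveform_csv(path: str | Path, calibrated: bool = False) -> Waveform:
    df = pd.read_csv(path)
    return Waveform(df["time_ns"].to_numpy(), df["value"].to_numpy(),
                    calibrated=calibrated)


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    pd.DataFrame({"time_ns": w.time_ns, "value": w.value}).to_csv(path, index=False)


def read_sensitivity_csv(path: str | Path,
                         valid_band_MHz: tuple[float, float] | None = None
                         ) -> SensitivityCurve:
    df = pd.read_csv(path)
    f = df["frequency_MHz"].to_numpy()
    if valid_band_MHz is None:
        valid_band_MHz = (float(f[0]), float(f[-1]))
    return SensitivityCurve(f, df["sensitivity_V_per_MPa"].to_numpy(),
                            valid_band_MHz)
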