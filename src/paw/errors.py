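"""Exception hierarchy for the paw package."""


class PawError(Exception):
    """Base class for all paw-specific errors."""


class InvalidParameterError(PawError, ValueError):
    """A physical parameter is outside its admissible range."""


class IncompatibleFieldsError(PawError, ValueError):
    """Two fields that must share geometry do not."""


class NoCarrierError(PawError, ValueError):
    """No spatial carrier peak detectable in an interferogram spectrum."""


class UnphysicalDensityError(PawError, ValueError):
    """Total density rho0 + drho is non-positive somewhere on the grid."""


class UnphysicalPressureError(PawError, ValueError):
    """Pressure outside the invertible branch of the Tait equation."""


class BoundsError(PawError, ValueError):
    """A region of interest extends outside its parent grid."""


class UnboundedPeakError(PawError, ValueError):
    """A profile peak has no half-maximum crossing on one side."""


class InvalidCalibrationError(PawError, ValueError):
    """A hydrophone sensitivity curve is unusable (non-positive values)."""


class SamplingError(PawError, ValueError):
    """A trace is non-uniformly sampled or under-resolves its pulse."""


class NoCompressivePeakError(PawError, ValueError):
    """A waveform has no positive compressive peak."""


class IncompatibleStackError(PawError, ValueError):
    """Frames of a time-lapse stack disagree in geometry."""


class ContaminatedBackgroundError(PawError, ValueError):
    """A background ROI overlaps a detected object."""


class InvalidBaselineError(PawError, ValueError):
    """Initial corrected intensity I_0 is non-positive."""


class InsufficientDataError(PawError, ValueError):
    """Too few valid points for a fit or test."""


class FitFailureError(PawError, RuntimeError):
    """Nonlinear least squares failed to converge."""


class GeometryError(PawError, ValueError):
    """A synthetic object does not fit on the requested grid."""


class PackingError(PawError, RuntimeError):
    """Could not place the requested number of discs without overlap."""
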