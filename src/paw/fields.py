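"""2D scalar fields on a uniform pixel grid.

A :class:`ScalarField` carries a 2D array together with the physical
quantity it represents and the (isotropic) pixel size.  Every image-like
object in the pipeline — raw interferogram intensity, demodulated phase,
refractive-index change, density change, pressure — is a ScalarField, and
each conversion step retags the quantity so that unit mistakes surface as
errors instead of silently wrong numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BoundsError, InvalidParameterError

#: Admissible quantity tags, in pipeline order.
QUANTITIES = (
    "intensity",
    "phase_rad",
    "delta_n",
    "delta_rho_gcm3",
    "pressure_MPa",
)

MIN_GRID = 8  # smallest meaningful interferogram side


@dataclass
class ScalarField:
    """A 2D grid of real values tagged with its physical quantity.

    Parameters
    ----------
    grid
        2D real array, at least 8x8. Row index is the first axis.
    quantity
        One of ``intensity``, ``phase_rad``, ``delta_n``,
        ``delta_rho_gcm3``, ``pressure_MPa``.
    pixel_size_um
        Isotropic pixel pitch in micrometres.
    origin
        (row, col) index of the grid origin; purely informational.
    """

    grid: np.ndarray
    quantity: str
    pixel_size_um: float
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise InvalidParameterError("grid must be 2D")
        if min(self.grid.shape) < MIN_GRID:
            raise InvalidParameterError(
                f"grid must be at least {MIN_GRID}x{MIN_GRID}, got {self.grid.shape}"
            )
        if self.quantity not in QUANTITIES:
            raise InvalidParameterError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def with_grid(self, grid: np.ndarray, quantity: str | None = None) -> "ScalarField":
        """Return a copy carrying ``grid`` (and optionally a new quantity tag)."""
        return replace(self, grid=np.asarray(grid, dtype=float),
                       quantity=quantity or self.quantity)

    def same_geometry(self, other: "ScalarField") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_size_um, other.pixel_size_um
        )


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise InvalidParameterError("rectangle must have positive extent")

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row0 < 0 or self.col0 < 0 or self.row1 > shape[0] or self.col1 > shape[1]:
            raise BoundsError(f"rect {self} outside grid of shape {shape}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)
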