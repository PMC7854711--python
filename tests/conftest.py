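import dataclasses

import numpy as np
import pytest

from paw.fields import ScalarField
from paw.synthetic import GeometryConfig, MovieConfig, SimulationConfig


@pytest.fixture
def default_cfg() -> SimulationConfig:
    """Study-condition defaults: 1 MPa / 36 um pulse, 25 ns waveform, 900 s movie."""
    return SimulationConfig(seed=11)


@pytest.fixture
def quick_movie_cfg() -> SimulationConfig:
    """Short noiseless movie for fast tracking tests."""
    return SimulationConfig(
        seed=11,
        movie=MovieConfig(shape=(64, 64), n_guvs=3, radius_range_um=(5.0, 9.0),
                          duration_s=60.0, noise_sigma=0.0),
    )


def disc_frame(shape, centres, radii_px, value=200.0, background=10.0,
               pixel_size_um=1.0) -> ScalarField:
    """Frame of uniform bright discs on a dim background."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    grid = np.full(shape, background, dtype=float)
    vals = value if np.iterable(value) else [value] * len(centres)
    for (r0, c0), r, v in zip(centres, radii_px, vals):
        grid[np.hypot(rows - r0, cols - c0) <= r] = v
    return ScalarField(grid, "intensity", pixel_size_um)
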