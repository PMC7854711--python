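"""File I/O: TIFF fields, CSV profiles, YAML parameter files."""

from __future__ import annotations

from dataclasses import asdict, fields as dc_fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidParameterError
from .fields import ScalarField
from .interferometry import PressureProfile, TaitEOS
from . import synthetic


def read_field_tiff(path: str | Path, quantity: str,
                    pixel_size_um: float) -> ScalarField:
    """Read a single-plane TIFF as a tagged scalar field."""
    grid = tifffile.imread(str(path))
    if grid.ndim == 3 and grid.shape[0] == 1:
        grid = grid[0]
    return ScalarField(np.asarray(grid, dtype=float), quantity, pixel_size_um)


def write_field_tiff(field: ScalarField, path: str | Path) -> None:
    tifffile.imwrite(str(path), field.grid.astype(np.float32))


def write_profile_csv(profile: PressureProfile, path: str | Path) -> None:
    pd.DataFrame({
        "position_um": profile.positions_um,
        "mean_MPa": profile.mean_MPa,
        "std_MPa": profile.std_MPa,
    }).to_csv(path, index=False)


def load_eos_yaml(path: str | Path) -> TaitEOS:
    """Tait EOS from a YAML mapping; missing keys fall back to water at 20 °C."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    base = TaitEOS.water()
    kwargs = {f.name: data.get(f.name, getattr(base, f.name))
              for f in dc_fields(TaitEOS)}
    return TaitEOS(**kwargs)


def _build_dataclass(cls, data: dict):
    """Recursively build a (nested) dataclass, rejecting unknown keys."""
    names = {f.name: f for f in dc_fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise InvalidParameterError(
            f"unknown {cls.__name__} key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, value in data.items():
        target = _NESTED.get(name)
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build_dataclass(target, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "geometry": synthetic.GeometryConfig,
    "pulse": synthetic.PulseConfig,
    "fringes": synthetic.FringeConfig,
    "optics": synthetic.OpticsConfig,
    "eos": TaitEOS,
    "movie": synthetic.MovieConfig,
    "waveform": synthetic.WaveformConfig,
}


def load_sim_config(path: str | Path) -> synthetic.SimulationConfig:
    """SimulationConfig from a YAML file; absent sections take defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build_dataclass(synthetic.SimulationConfig, data)


def dump_sim_config(cfg: synthetic.SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg)))
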