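"""End-to-end pipeline orchestration with run manifests.

``run_pipeline`` chains simulation, analysis and fitting stages
deterministically from a single configuration and records every output
file in a JSON manifest, so a run can be reproduced from the manifest's
config hash and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ContaminatedBackgroundError, InvalidParameterError, PawError
from .fields import Rect, ScalarField
from .guv_release import (
    background_correct,
    fit_ritger_peppas,
    measure_background,
    pool_release_curves,
    release_curve,
    track_guvs,
    tracks_to_dataframe,
    write_fit_json,
)
from .interferometry import pressure_map, pressure_profile, profile_fwhm
from .synthetic import (
    SimulationConfig,
    make_guv_movie,
    make_pressure_field,
    make_waveform,
    movie_to_fields,
    render_interferogram,
    write_movie_tiff,
)
from .waveforms import metrics, write_waveform_csv

KNOWN_STAGES = ("simulate-movie", "track", "fit")


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    input_paths: list[str] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)
    tool_version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def config_hash(cfg: SimulationConfig) -> str:
    """Stable hex digest of a configuration (canonical YAML of its fields)."""
    canon = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def find_background_roi(frames: list[ScalarField],
                        size: tuple[int, int] = (10, 10),
                        step: int = 8) -> Rect:
    """First candidate rectangle free of above-threshold pixels in all frames."""
    n_r, n_c = frames[0].shape
    for r0 in range(0, n_r - size[0], step):
        for c0 in range(0, n_c - size[1], step):
            roi = Rect(r0, r0 + size[0], c0, c0 + size[1])
            try:
                measure_background(frames, roi)
                return roi
            except ContaminatedBackgroundError:
                continue
    raise PawError("no vesicle-free background region found")


def run_pipeline(cfg: SimulationConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = KNOWN_STAGES) -> RunManifest:
    """Run simulate-movie → track → fit and write a manifest.

    Each stage reads what the previous one produced; the whole chain is
    a deterministic function of the configuration (seed included).
    """
    for s in stages:
        if s not in KNOWN_STAGES:
            raise InvalidParameterError(
                f"unknown stage {s!r}; known stages: {', '.join(KNOWN_STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="run " + "+".join(stages),
                           config_hash=config_hash(cfg), seed=cfg.seed,
                           timestamp=datetime.now(timezone.utc).isoformat())

    fields = None
    tracks = None
    if "simulate-movie" in stages:
        stack, truth = make_guv_movie(cfg)
        write_movie_tiff(stack, out / "movie.tif")
        truth.to_csv(out / "truth.csv", index=False)
        manifest.output_paths += [str(out / "movie.tif"), str(out / "truth.csv")]
        fields = movie_to_fields(stack, cfg.movie.pixel_size_um)

    if "track" in stages:
        if fields is None:
            raise InvalidParameterError("track stage requires simulate-movie output")
        r_lo, r_hi = cfg.movie.radius_range_um
        tracks = track_guvs(fields, max_displacement_um=3 * cfg.movie.pixel_size_um,
                            min_radius_um=0.5 * r_lo, max_radius_um=2 * r_hi,
                            frame_rate_Hz=cfg.movie.frame_rate_Hz)
        roi = find_background_roi(fields)
        bg = measure_background(fields, roi)
        tracks = [background_correct(t, fields, roi, background=bg) for t in tracks]
        tracks_to_dataframe(tracks).to_csv(out / "tracks.csv", index=False)
        manifest.output_paths.append(str(out / "tracks.csv"))

    if "fit" in stages:
        if tracks is None:
            raise InvalidParameterError("fit stage requires track output")
        curves = [release_curve(t) for t in tracks]
        fit = fit_ritger_peppas(pool_release_curves(curves))
        write_fit_json(fit, out / "fit.json", mode="pooled")
        manifest.output_paths.append(str(out / "fit.json"))

    manifest.write(out / "manifest.json")
    manifest.output_paths.append(str(out / "manifest.json"))
    return manifest
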