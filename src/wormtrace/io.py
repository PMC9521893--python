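"""Image-stack and tabular I/O.

Movies travel as plain multi-page TIFF (pages = T*Z, row-major in T) with a
JSON sidecar carrying acquisition metadata (pixel size, Z spacing, frame
interval, stimulus window).  Traces are long-format CSV.  Coordinates are
0-based (row, col); time is frame index * frame_interval_s with t=0 at the
first recorded frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "ProjectedMovie",
    "read_stack",
    "write_stack",
    "max_project",
    "write_traces",
    "read_traces",
]

_REQUIRED_SIDECAR_KEYS = (
    "pixel_size_um",
    "z_step_um",
    "frame_interval_s",
    "stimulus_onset_frame",
    "stimulus_duration_frames",
    "n_z",
)


@dataclass
class MovieStack:
    """T x Z x Y x X intensity stack plus acquisition/stimulus metadata."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    frame_interval_s: float
    stimulus_onset_frame: int
    stimulus_duration_frames: int
    source_id: str = ""

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("MovieStack data must be T x Z x Y x X")
        T = self.data.shape[0]
        if not (0 <= self.stimulus_onset_frame
                and self.stimulus_onset_frame + self.stimulus_duration_frames <= T):
            raise ValueError("stimulus window must lie within [0, T)")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]


@dataclass
class ProjectedMovie:
    """T x Y x X maximum-intensity projection with the parent's metadata."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    stimulus_onset_frame: int
    stimulus_duration_frames: int
    source_id: str = ""

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("ProjectedMovie data must be T x Y x X")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray) -> "ProjectedMovie":
        return replace(self, data=data)


def write_stack(movie: MovieStack, tif_path, sidecar_path=None) -> None:
    """Write a movie as multi-page TIFF plus its JSON metadata sidecar."""
    tif_path = str(tif_path)
    if sidecar_path is None:
        sidecar_path = tif_path.rsplit(".", 1)[0] + ".json"
    T, Z, H, W = movie.data.shape
    tifffile.imwrite(tif_path, movie.data.reshape(T * Z, H, W))
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "z_step_um": movie.z_step_um,
        "frame_interval_s": movie.frame_interval_s,
        "stimulus_onset_frame": movie.stimulus_onset_frame,
        "stimulus_duration_frames": movie.stimulus_duration_frames,
        "n_z": Z,
        "source_id": movie.source_id,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_stack(tif_path, sidecar_path=None) -> MovieStack:
    """Read a multi-page TIFF movie, normalizing axes to T x Z x Y x X.

    The page count must be divisible by the sidecar's declared Z count; every
    required metadata key must be present.
    """
    tif_path = str(tif_path)
    if sidecar_path is None:
        sidecar_path = tif_path.rsplit(".", 1)[0] + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    missing = [k for k in _REQUIRED_SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar missing required metadata keys: {missing}")
    pages = tifffile.imread(tif_path)
    if pages.ndim == 2:
        pages = pages[None]
    n_z = int(meta["n_z"])
    if pages.shape[0] % n_z:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by declared Z={n_z}")
    T = pages.shape[0] // n_z
    data = pages.reshape(T, n_z, *pages.shape[1:])
    return MovieStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        stimulus_onset_frame=int(meta["stimulus_onset_frame"]),
        stimulus_duration_frames=int(meta["stimulus_duration_frames"]),
        source_id=str(meta.get("source_id", "")),
    )


def max_project(stack: MovieStack) -> ProjectedMovie:
    """Voxel-wise maximum over Z."""
    return ProjectedMovie(
        data=stack.data.max(axis=1),
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        stimulus_onset_frame=stack.stimulus_onset_frame,
        stimulus_duration_frames=stack.stimulus_duration_frames,
        source_id=stack.source_id,
    )


def write_traces(traces: pd.DataFrame, path) -> None:
    """Write a long-format trace table to CSV.

    Expected columns: movie_id, neuron_id, frame, time_s, raw, background,
    dff, gap (raw empty where gap is set).  Values are written with enough
    precision to read back to <= 1e-6 relative error.
    """
    required = {"movie_id", "neuron_id", "frame", "time_s", "raw", "background", "dff", "gap"}
    missing = required - set(traces.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    out = traces.copy()
    out.loc[out["gap"].astype(bool), "raw"] = np.nan
    out.to_csv(path, index=False, float_format="%.9g")


def read_traces(path) -> pd.DataFrame:
    return pd.read_csv(path)
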