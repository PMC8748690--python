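"""Run configuration, voxel-grid container and file I/O.

Volumes travel as multi-page TIFF files with one page per z-slice per channel,
channel-major (all slices of channel 0, then channel 1, ...).  Channel identity
is always an explicit name->index map supplied by the caller or the config;
nothing is inferred from metadata.  Tables are plain CSV with a header row.

Coordinates are 0-based voxel indices; physical positions are
``index * voxel_size`` (voxel-center convention), with z index 0 the bottom
slice of the acquisition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("spherotil")

#: channel names used throughout the spheroid pipeline
SPHEROID_CHANNELS = ("spheroid", "tcell", "dead")


@dataclass
class VoxelGrid:
    """One timepoint of a multi-channel anisotropic z-stack.

    Parameters
    ----------
    channels
        Mapping from channel name to a 3D ``(Z, Y, X)`` intensity array.
        All channels must share a shape.
    voxel_size
        ``(dx, dy, dz)`` in micrometres.
    timepoint_h
        Acquisition time of this stack in hours.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelGrid needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channels must be 3D (Z, Y, X); got shape {first}")
        for ch, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"channel {ch!r} has shape {shp}, expected {first}"
                )
        dx, dy, dz = self.voxel_size
        if dx <= 0 or dy <= 0 or dz <= 0:
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        self.channels = {ch: np.asarray(a) for ch, a in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class Config:
    """Resolved run configuration with the acquisition defaults.

    Defaults mirror the acquisition protocol: 3 um z-steps, stacks every 2 h,
    couple movies at 10 s frames for 15 min.
    """

    voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0)
    frame_interval_s: float = 10.0
    imaging_interval_h: float = 2.0
    movie_duration_min: float = 15.0

    # segmentation stage parameters
    spheroid_threshold: float | str = "otsu"   # "otsu" or absolute intensity
    alpha: float | str = "auto"                # "auto" = per-object critical alpha (um)
    min_volume_um3: float = 10_000.0
    cell_threshold: float | str = "otsu"
    min_cell_volume_um3: float = 100.0         # ~ sphere of 8 um diameter is 268 um3
    dead_threshold: float | str = "otsu"
    marker_separation_um: float = 30.0         # min watershed-seed separation

    # cytotoxicity stage
    slope_window_points: int = 8               # 2 h at 15-min sampling
    normalization: str = "difference"          # or "ratio"

    # morphodynamics stage
    spread_fraction: float = 0.95
    lamella_sector_deg: float = 90.0
    lamella_area_frac: float = 0.10

    rng_seed: int = 0

    def __post_init__(self) -> None:
        dx, dy, dz = self.voxel_size
        if min(dx, dy, dz) <= 0:
            raise ValueError("voxel sizes must be positive")
        for name in ("frame_interval_s", "imaging_interval_h", "movie_duration_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.normalization not in ("difference", "ratio"):
            raise ValueError("normalization must be 'difference' or 'ratio'")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "voxel_size" in raw:
            raw["voxel_size"] = tuple(float(v) for v in raw["voxel_size"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_size"] = list(d["voxel_size"])
        return d

    def log_resolved(self) -> None:
        """Log seed and fully-resolved configuration (every CLI run does this)."""
        logger.info("seed=%d config=%s", self.rng_seed, json.dumps(self.to_dict()))


# ---------------------------------------------------------------------------
# volumes


def write_stack(grid: VoxelGrid, path: str | Path,
                channel_order: Sequence[str] | None = None) -> None:
    """Write a VoxelGrid as a channel-major multi-page TIFF."""
    order = list(channel_order) if channel_order is not None else list(grid.channels)
    pages = np.concatenate([np.asarray(grid.channels[ch]) for ch in order], axis=0)
    tifffile.imwrite(str(path), pages)


def read_stack(path: str | Path, channel_map: Mapping[str, int],
               voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0),
               timepoint_h: float = 0.0) -> VoxelGrid:
    """Read a channel-major multi-page TIFF into a named-channel VoxelGrid.

    ``channel_map`` maps channel name -> channel index; the page count must be
    divisible by the number of channels and all pages must share a shape.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got ndim={arr.ndim}")
    n_ch = len(channel_map)
    if n_ch < 1:
        raise ValueError("channel_map must name at least one channel")
    if arr.shape[0] % n_ch:
        raise ValueError(
            f"{arr.shape[0]} pages not divisible by {n_ch} channels"
        )
    z = arr.shape[0] // n_ch
    vols = arr.reshape(n_ch, z, *arr.shape[1:])
    channels = {}
    for name, idx in channel_map.items():
        if not 0 <= idx < n_ch:
            raise KeyError(f"channel {name!r} index {idx} out of range 0..{n_ch - 1}")
        channels[name] = vols[idx]
    return VoxelGrid(channels=channels, voxel_size=tuple(voxel_size),
                     timepoint_h=timepoint_h)


# ---------------------------------------------------------------------------
# tables


def read_table(path: str | Path, schema: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a delimited table, enforcing required columns and numeric dtypes.

    ``schema`` maps column name -> python type (float, int, bool, str).
    Missing columns or non-coercible cells raise ``ValueError``.
    """
    df = pd.read_csv(path)
    if schema is None:
        return df
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if len(df) and coerced.isna().any() and not df[col].isna().any():
                bad = df[col][coerced.isna()].iloc[0]
                raise ValueError(f"non-numeric cell {bad!r} in numeric column {col!r}")
            df[col] = coerced.astype(typ)
        elif typ is bool:
            df[col] = df[col].astype(bool)
        else:
            df[col] = df[col].astype(str) if len(df) else df[col]
    return df


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV at full float precision (lossless round-trip)."""
    records.to_csv(path, index=False, float_format="%.17g")


def make_rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)
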