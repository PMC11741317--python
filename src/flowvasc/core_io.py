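"""Shared containers, TIFF/CSV readers and writers, and run configuration.

All spatial quantities are converted to micrometres at read time; pixel
units never propagate past this module.  Image coordinates follow the
raster convention (x = column index increasing rightwards, y = row index
increasing downwards) while angles follow the mathematical
counter-clockwise convention: a displacement ``(dx, dy)`` in the image
maps to ``atan2(-dy, dx)``, so 0 rad points along +x and +pi/2 points
"up" in a displayed image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

IMAGE_KINDS = ("label", "intensity", "mask")

#: canonical column order for track tables
TRACK_COLUMNS = ["condition", "replicate", "population", "track", "frame", "t", "x", "y"]


@dataclass(frozen=True)
class ImageStack:
    """A 2D or 3D pixel grid with physical calibration.

    ``kind`` is one of ``label`` (non-negative integers, background 0),
    ``mask`` (values in {0, 1}) or ``intensity`` (non-negative reals).
    ``pixel_size`` is micrometres per pixel, isotropic in-plane.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    name: str = ""
    kind: str = "intensity"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.size == 0:
            raise ValueError("zero-sized image")
        if arr.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D grid, got ndim={arr.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.kind not in IMAGE_KINDS:
            raise ValueError(f"unknown image kind {self.kind!r}")
        if self.kind in ("label", "mask"):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.mod(arr, 1) == 0):
                    raise ValueError(f"non-integer values in {self.kind} image")
                arr = arr.astype(np.int64)
            if arr.min() < 0:
                raise ValueError(f"negative values in {self.kind} image")
            if self.kind == "mask" and arr.max(initial=0) > 1:
                raise ValueError("non-binary mask: values outside {0, 1}")
        else:
            if arr.min() < 0:
                raise ValueError("negative values in intensity image")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero label values present in a label image."""
        if self.kind != "label":
            raise ValueError("labels() requires a label image")
        vals = np.unique(self.data)
        return vals[vals > 0]


def read_image(path: str | Path, kind: str = "intensity", pixel_size: float = 1.0,
               name: str = "") -> ImageStack:
    """Read a (multipage) TIFF raster into an :class:`ImageStack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    return ImageStack(arr, pixel_size=pixel_size, name=name or path.stem, kind=kind)


def write_image(stack: ImageStack, path: str | Path) -> None:
    data = stack.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


# ---------------------------------------------------------------------------
# track tables


@dataclass
class TrackSet:
    """Time-stamped 2D positions per track, labelled by condition, replicate
    and population (dye channel in mosaic experiments).

    Positions are in micrometres, time in hours.  Rows are sorted by track
    and frame; frames are strictly increasing within a track.
    """

    df: pd.DataFrame
    frame_interval: float | None = None

    GROUP_KEYS = ["condition", "replicate", "population", "track"]

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("condition", ""), ("replicate", 0), ("population", "")):
            if col not in df.columns:
                df[col] = default
            elif default == "":
                df[col] = df[col].fillna("")
        missing = [c for c in ("track", "frame", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if "t" not in df.columns:
            if self.frame_interval is None:
                raise ValueError("need either a 't' column or a frame interval")
            df["t"] = df["frame"] * self.frame_interval
        df = df[TRACK_COLUMNS].sort_values(self.GROUP_KEYS + ["frame"], kind="mergesort")
        dup = df.duplicated(subset=self.GROUP_KEYS + ["frame"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate sample: track {row['track']} frame {row['frame']}")
        self.df = df.reset_index(drop=True)

    @property
    def n_tracks(self) -> int:
        return self.df.groupby(self.GROUP_KEYS, sort=False).ngroups

    @property
    def conditions(self) -> list:
        return sorted(self.df["condition"].unique())

    def iter_tracks(self) -> Iterator[tuple[tuple, pd.DataFrame]]:
        yield from self.df.groupby(self.GROUP_KEYS, sort=False)

    def subset(self, **labels) -> "TrackSet":
        df = self.df
        for col, val in labels.items():
            df = df[df[col] == val]
        return TrackSet(df.reset_index(drop=True), frame_interval=self.frame_interval)


#: TrackMate spot-export tables carry three extra non-data header rows
#: (human-readable names, shortened names, units) below the column header.
_TRACKMATE_SKIPROWS = [1, 2, 3]
_TRACKMATE_COLS = {"TRACK_ID": "track", "FRAME": "frame",
                   "POSITION_X": "x", "POSITION_Y": "y"}


def read_tracks(path: str | Path, dialect: str = "plain", pixel_size: float = 1.0,
                frame_interval: float | None = None) -> TrackSet:
    """Read a track table (CSV) into a :class:`TrackSet`.

    ``dialect='plain'`` expects columns ``track, frame, x, y`` with optional
    ``condition, replicate, population``.  ``dialect='trackmate'`` parses a
    TrackMate spots export (``TRACK_ID, FRAME, POSITION_X, POSITION_Y``),
    skipping its three non-data header rows.  Positions are multiplied by
    ``pixel_size`` (µm per pixel; pass 1.0 for pre-calibrated exports).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain":
        df = pd.read_csv(path)
        df = df.rename(columns={"track_id": "track"})
    elif dialect == "trackmate":
        df = pd.read_csv(path, skiprows=_TRACKMATE_SKIPROWS)
        missing = [c for c in _TRACKMATE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[list(_TRACKMATE_COLS)].rename(columns=_TRACKMATE_COLS)
        df = df.apply(pd.to_numeric)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in ("x", "y"):
        if col in df.columns:
            df[col] = df[col].astype(float) * pixel_size
    return TrackSet(df, frame_interval=frame_interval)


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    ts.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports


def write_report(results, path: str | Path) -> None:
    """Write an analysis summary to CSV.

    Accepts a DataFrame, a mapping of scalars, or any result object
    exposing ``to_frame()``.  Numeric values round-trip at full float64
    precision (shortest-repr CSV encoding).
    """
    if isinstance(results, pd.DataFrame):
        df = results
    elif hasattr(results, "to_frame"):
        df = results.to_frame()
    elif isinstance(results, Mapping):
        df = pd.DataFrame([results])
    else:
        raise TypeError(f"cannot serialise {type(results).__name__}")
    # repr round-trips float64 exactly; pandas' default formatter does not
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """Declarative run configuration shared by all pipeline stages.

    flow_direction : unit vector in image coordinates (x, y-down); the
        default (1, 0) means flow towards +x so that a polarity angle of
        pi is "against flow".
    frame_interval : hours between movie frames (7.5 min default).
    pixel_size : micrometres per pixel.
    seed : every stochastic operation derives its RNG from this.
    kde_bandwidth : bandwidth rule for the retina KDE ('scott' or a float
        factor on the per-axis standard deviation).
    n_sample_pixels : labelled pixels sampled per retina for the
        arteriovenous coordinate distribution.
    n_boot : bootstrap replicate count for estimation statistics.
    quantile_rule : quantile convention for percentile statistics
        ('linear' = linear interpolation between order statistics).
    """

    flow_direction: tuple[float, float] = (1.0, 0.0)
    frame_interval: float = 0.125
    pixel_size: float = 1.0
    seed: int = 0
    kde_bandwidth: str | float = "scott"
    n_sample_pixels: int = 5000
    n_boot: int = 5000
    quantile_rule: str = "linear"
    bin_hours: float = 1.0
    min_track_frames: int = 10
    plexus_band: tuple[float, float] = (0.4, 0.8)

    def __post_init__(self) -> None:
        u = np.asarray(self.flow_direction, dtype=float)
        if u.shape != (2,) or not np.isclose(np.hypot(*u), 1.0, atol=1e-8):
            raise ValueError("flow direction must be a 2D unit vector")
        self.flow_direction = (float(u[0]), float(u[1]))
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("flow_direction", "plexus_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for key in ("flow_direction", "plexus_band"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def flow_vector_from_angle(degrees: float) -> tuple[float, float]:
    """Unit flow vector in image coordinates from a math-convention angle.

    0° points along +x; positive angles rotate counter-clockwise as
    displayed (y axis of the image points down, hence the sign flip).
    """
    a = np.deg2rad(degrees)
    return (float(np.cos(a)), float(-np.sin(a)))
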