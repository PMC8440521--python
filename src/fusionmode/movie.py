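"""Image-stack and event-table I/O.

Movies are multi-page single-channel grayscale TIFFs with unsigned 8/16-bit
counts; pixel size (um) and frame interval (s) ride along as ImageJ-style
metadata and fall back to config values when absent. Event tables are plain
CSV so that fixtures stay human-diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class MovieFormatError(ValueError):
    """Unsupported or corrupt image input."""


class SchemaError(ValueError):
    """Event table missing a required column."""


@dataclass
class MovieStack:
    """Calibrated (time, y, x) intensity stack for one channel."""

    data: np.ndarray            # (T, Y, X), unsigned integer semantics
    pixel_size: float           # um / px
    frame_interval: float       # s
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise MovieFormatError(f"movie must be 2D or 3D, got ndim={self.data.ndim}")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise MovieFormatError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def astype_float(self) -> np.ndarray:
        return self.data.astype(np.float64)


def write_movie(stack: MovieStack, path) -> None:
    """Write a MovieStack as a multi-page grayscale TIFF with metadata."""
    path = Path(path)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channel_label": stack.channel_label,
    }
    data = stack.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))


def read_movie(path, *, pixel_size: float | None = None,
               frame_interval: float | None = None,
               channel_label: str = "") -> MovieStack:
    """Read a multi-page grayscale TIFF as a MovieStack.

    Calibration is taken from the embedded metadata written by
    :func:`write_movie`; when absent, the ``pixel_size``/``frame_interval``
    arguments (typically from the run config) are required.

    Raises
    ------
    MovieFormatError
        For RGB/float inputs, unsupported bit depths, truncated files, or
        missing calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise MovieFormatError(
                    f"{path}: expected grayscale pages, got "
                    f"{page.photometric.name} with {page.samplesperpixel} "
                    "samples per pixel")
            data = tif.asarray()
            desc = page.description or ""
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise MovieFormatError(f"cannot read TIFF {path}: {exc}") from exc

    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MovieFormatError(
            f"expected single-channel grayscale pages, got array shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16):
        raise MovieFormatError(
            f"expected 8- or 16-bit grayscale data, got dtype {data.dtype}")

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    px = meta.get("pixel_size_um", pixel_size)
    dt = meta.get("frame_interval_s", frame_interval)
    label = meta.get("channel_label", channel_label)
    if px is None or dt is None:
        raise MovieFormatError(
            f"{path} carries no calibration metadata; supply pixel_size and "
            "frame_interval from the config")
    return MovieStack(data=data, pixel_size=float(px), frame_interval=float(dt),
                      channel_label=str(label))


# --- event tables ---------------------------------------------------------

#: canonical leading columns of every event table
EVENT_COLUMNS = ["event_id", "cell_id", "mode", "onset_frame", "x_px", "y_px", "dwell_s"]


def write_event_table(table: pd.DataFrame, path) -> None:
    """Write an event table as CSV, canonical columns first."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table missing required column(s): {missing}")
    extra = [c for c in table.columns if c not in EVENT_COLUMNS]
    table[EVENT_COLUMNS + extra].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    """Read an event-table CSV; unknown extra columns are preserved."""
    table = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table missing required column(s): {missing}")
    extra = [c for c in table.columns if c not in EVENT_COLUMNS]
    return table[EVENT_COLUMNS + extra]
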