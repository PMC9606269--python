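"""Containers and file I/O for TIRF movie stacks and tabular artifacts.

Movies travel as multi-page 16-bit unsigned TIFF; every table (spots,
traces, step fits, histograms, ground truth) is plain CSV so each pipeline
stage can be run and inspected independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

DEFAULT_PIXEL_SIZE_UM = 0.107  # 16 um EMCCD pixel / 150x objective
DEFAULT_FRAME_INTERVAL_MS = 50.0


@dataclass
class MovieStack:
    """A frames x rows x cols intensity stack with acquisition metadata.

    Parameters
    ----------
    data
        Non-negative intensity grid, shape ``(n_frames, rows, cols)``.
    pixel_size
        Lateral pixel size in micrometres per pixel.
    frame_interval
        Time between frames in milliseconds.
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be (n_frames, rows, cols) with >= 1 frame")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def fov_area(self) -> float:
        """Field-of-view area in square micrometres."""
        r, c = self.shape
        return r * c * self.pixel_size**2


def write_movie(path, movie: MovieStack) -> None:
    """Write a movie as a multi-page uint16 TIFF, clipping to the dtype range."""
    data = np.clip(np.rint(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_size_um": movie.pixel_size,
            "frame_interval_ms": movie.frame_interval,
        },
    )


def read_movie(path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> MovieStack:
    """Read a multi-page TIFF stack.

    Metadata written by :func:`write_movie` is recovered when present;
    explicit arguments override it.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    px = pixel_size if pixel_size is not None else float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
    dt = frame_interval if frame_interval is not None else float(meta.get("frame_interval_ms", DEFAULT_FRAME_INTERVAL_MS))
    return MovieStack(data.astype(np.float32), pixel_size=px, frame_interval=dt)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
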