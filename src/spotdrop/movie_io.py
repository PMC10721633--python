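"""Movie, trace, spot and event-table I/O.

Movies travel as multipage TIFF (one page per frame, 16-bit unsigned on
disk, ImageJ-compatible ``finterval`` metadata). Tables travel as plain
CSV with mandatory header rows, "." decimal and comma separators. All
writers are deterministic: rows are emitted in ascending ``spot_id``
order so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyMovieError, SchemaError, UnsupportedFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "read_movie",
    "write_movie",
    "write_traces",
    "read_traces",
    "write_events",
    "read_events",
    "write_truth",
    "read_truth",
    "write_spots",
    "read_spots",
]

EVENT_COLUMNS = ["spot_id", "x", "y", "verdict", "drop_frame", "initial_intensity"]
TRUTH_COLUMNS = ["spot_id", "x", "y", "event_type", "event_frame"]
TRACE_COLUMNS = ["spot_id", "frame", "raw", "normalized", "frame_valid"]
SPOT_COLUMNS = ["spot_id", "x", "y", "roi_radius", "annulus_inner", "annulus_outer"]


@dataclass
class Movie:
    """A single-channel time-lapse stack.

    Parameters
    ----------
    data
        Intensity stack shaped ``(n_frames, rows, cols)``.
    frame_interval
        Seconds between frames; ``None`` marks an unknown interval.
    pixel_size
        µm per pixel, optional.
    source
        Path or label identifying where the movie came from.
    valid
        Optional boolean mask, same shape as ``data``; ``False`` marks
        pixels filled in by drift correction rather than observed.
    """

    data: np.ndarray
    frame_interval: float | None = None
    pixel_size: float | None = None
    source: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (frame, row, col), got {self.data.ndim}-D")
        if self.data.shape[0] < 1:
            raise EmptyMovieError("movie has zero frames")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.valid is not None and self.valid.shape != self.data.shape:
            raise ValueError("validity mask shape must match data shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def duration(self) -> float | None:
        """Total acquisition span in seconds, if the interval is known."""
        if self.frame_interval is None:
            return None
        return self.frame_interval * (self.n_frames - 1)


def read_movie(path: str | Path, frame_interval: float | None = None) -> Movie:
    """Read a single-channel multipage TIFF stack.

    The frame interval is taken from ImageJ metadata when present,
    falling back to the ``frame_interval`` argument, falling back to
    ``None`` (unknown).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) == 0:
            raise EmptyMovieError(f"{path}: TIFF has zero pages")
        series = tf.series[0]
        axes = series.axes
        if "S" in axes or "C" in axes:
            raise UnsupportedFormatError(
                f"{path}: multi-channel/RGB TIFF not supported (axes={axes!r})"
            )
        data = tf.asarray()
        meta_interval = None
        if tf.imagej_metadata is not None:
            meta_interval = tf.imagej_metadata.get("finterval")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise UnsupportedFormatError(f"{path}: expected 2-D pages, got array of shape {data.shape}")
    interval = meta_interval if meta_interval else frame_interval
    return Movie(data=data, frame_interval=interval, source=str(path))


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a 16-bit unsigned multipage TIFF.

    Out-of-range values are clipped with a logged warning counting the
    affected pixels; in-range float data is rounded.
    """
    path = Path(path)
    data = np.asarray(movie.data)
    n_low = int(np.sum(data < 0))
    n_high = int(np.sum(data > 65535))
    if n_low or n_high:
        logger.warning(
            "write_movie(%s): clipping %d pixels below 0 and %d pixels above 65535",
            path, n_low, n_high,
        )
    out = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    metadata = {"axes": "TYX"}
    if movie.frame_interval is not None:
        metadata["finterval"] = float(movie.frame_interval)
    tifffile.imwrite(path, out, imagej=True, metadata=metadata)


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_traces(traces, path: str | Path) -> None:
    """Write intensity traces as long-format CSV (one row per spot per frame)."""
    rows = []
    for tr in sorted(traces, key=lambda t: t.spot_id):
        for f in range(len(tr.raw)):
            rows.append(
                (tr.spot_id, f, tr.raw[f],
                 tr.normalized[f] if tr.normalized is not None else np.nan,
                 int(tr.frame_valid[f]))
            )
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    _write_csv(df, path)


def read_traces(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write a drop-call event table (spot_id, x, y, verdict, drop_frame, initial_intensity)."""
    _require_columns(events, EVENT_COLUMNS, Path(path))
    df = events.loc[:, EVENT_COLUMNS].sort_values("spot_id").reset_index(drop=True)
    df["drop_frame"] = df["drop_frame"].astype("Int64")
    _write_csv(df, path)


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    df["drop_frame"] = df["drop_frame"].astype("Int64")
    return df


def write_truth(truth, path: str | Path) -> None:
    """Write a simulator ground-truth table.

    Accepts a list of ``GroundTruthEvent`` or an equivalent DataFrame.
    """
    if isinstance(truth, pd.DataFrame):
        df = truth.loc[:, TRUTH_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [(e.spot_id, e.x, e.y, e.event_type, e.event_frame) for e in truth],
            columns=TRUTH_COLUMNS,
        )
    df = df.sort_values("spot_id").reset_index(drop=True)
    df["event_frame"] = df["event_frame"].astype("Int64")
    _write_csv(df, path)


def read_truth(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRUTH_COLUMNS, path)
    df["event_frame"] = df["event_frame"].astype("Int64")
    return df


def write_spots(spots, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.spot_id, s.x, s.y, s.roi_radius, s.annulus_inner, s.annulus_outer) for s in spots],
        columns=SPOT_COLUMNS,
    )
    df = df.sort_values("spot_id").reset_index(drop=True)
    _write_csv(df, path)


def read_spots(path: str | Path):
    from .detect import Spot

    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SPOT_COLUMNS, path)
    return [
        Spot(
            spot_id=int(r.spot_id), x=float(r.x), y=float(r.y),
            roi_radius=float(r.roi_radius),
            annulus_inner=float(r.annulus_inner),
            annulus_outer=float(r.annulus_outer),
        )
        for r in df.itertuples()
    ]
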