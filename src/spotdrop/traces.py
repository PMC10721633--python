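"""Per-spot background-corrected intensity traces, normalized to the
initial intensity.

For each frame the raw value is the ROI pixel sum minus the per-frame
annulus-median background times the ROI area; the normalized trace
divides by the mean of the first ``n_initial_frames`` raw values. The
normalization makes downstream drop calling invariant to camera gain
and the background subtraction makes it robust to additive offsets and
slow illumination drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Spot, annulus_offsets, roi_offsets
from .movie_io import Movie

__all__ = ["IntensityTrace", "extract_trace", "normalize_trace", "extract_traces"]

# A trace whose initial intensity is within this many initial-window
# standard deviations of zero is treated as a non-spot and excluded.
MIN_INITIAL_SNR = 3.0


@dataclass
class IntensityTrace:
    """Background-corrected intensity time series for one spot."""

    spot_id: int
    raw: np.ndarray
    normalized: np.ndarray | None
    initial_intensity: float
    n_initial_frames: int
    frame_valid: np.ndarray
    usable: bool = True

    def __len__(self) -> int:
        return len(self.raw)


def extract_trace(movie: Movie, spot: Spot) -> tuple[np.ndarray, np.ndarray]:
    """Raw background-corrected trace for one spot.

    Returns ``(raw, frame_valid)``: per frame, the sum of ROI pixels
    minus the annulus median times the ROI pixel count, and a flag that
    is False wherever the ROI touches pixels invalidated by drift fill.
    """
    rows, cols = movie.frame_shape
    yc, xc = int(np.rint(spot.y)), int(np.rint(spot.x))
    rdy, rdx = roi_offsets(spot)
    ady, adx = annulus_offsets(spot)
    ry, rx = yc + rdy, xc + rdx
    ay, ax = yc + ady, xc + adx
    for yy, xx in ((ry, rx), (ay, ax)):
        if yy.min() < 0 or xx.min() < 0 or yy.max() >= rows or xx.max() >= cols:
            raise ValueError(f"spot {spot.spot_id}: ROI/annulus extends outside the field")
    data = movie.data
    roi_sum = data[:, ry, rx].sum(axis=1)
    bg = np.median(data[:, ay, ax], axis=1)
    raw = roi_sum - bg * len(ry)
    if movie.valid is not None:
        frame_valid = movie.valid[:, ry, rx].all(axis=1)
    else:
        frame_valid = np.ones(movie.n_frames, dtype=bool)
    return raw, frame_valid


def normalize_trace(
    raw: np.ndarray,
    n_initial_frames: int = 5,
    spot_id: int = 0,
    frame_valid: np.ndarray | None = None,
) -> IntensityTrace:
    """Normalize a raw trace to its mean initial intensity.

    The initial intensity is the mean of the first ``n_initial_frames``
    raw values. Traces whose initial intensity is non-positive or not
    clearly above the initial-window noise (see ``MIN_INITIAL_SNR``)
    are marked unusable and excluded from condition totals.
    """
    raw = np.asarray(raw, dtype=float)
    if n_initial_frames < 1:
        raise ValueError("n_initial_frames must be >= 1")
    if frame_valid is None:
        frame_valid = np.ones(len(raw), dtype=bool)
    window = raw[:n_initial_frames]
    initial = float(window.mean())
    noise = float(window.std(ddof=1)) if n_initial_frames > 1 else 0.0
    usable = initial > 0 and initial > MIN_INITIAL_SNR * noise
    normalized = raw / initial if usable else None
    return IntensityTrace(
        spot_id=spot_id,
        raw=raw,
        normalized=normalized,
        initial_intensity=initial,
        n_initial_frames=n_initial_frames,
        frame_valid=np.asarray(frame_valid, dtype=bool),
        usable=usable,
    )


def extract_traces(
    movie: Movie, spots: list[Spot], n_initial_frames: int = 5
) -> list[IntensityTrace]:
    """Extract and normalize traces for all spots."""
    out = []
    for spot in spots:
        raw, frame_valid = extract_trace(movie, spot)
        out.append(
            normalize_trace(raw, n_initial_frames, spot_id=spot.spot_id, frame_valid=frame_valid)
        )
    return out
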