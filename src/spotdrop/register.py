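"""Lateral stage-drift estimation and correction.

Drift is modelled as a pure per-frame translation, estimated by phase
cross-correlation with subpixel refinement and removed by linear
interpolation. The convention throughout: a trajectory entry ``(dy, dx)``
is the displacement of that frame's content relative to frame 0, so
correction translates the frame by ``-(dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .errors import ConstantImageError
from .movie_io import Movie

__all__ = ["DriftTrajectory", "estimate_pairwise_shift", "estimate_drift", "apply_drift"]


@dataclass
class DriftTrajectory:
    """Per-frame cumulative (dy, dx) shift relative to frame 0."""

    shifts: np.ndarray        # (n_frames, 2) of (dy, dx)
    mode: str = "to_reference"

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("shift at frame 0 must be (0, 0)")

    def __len__(self) -> int:
        return self.shifts.shape[0]


def estimate_pairwise_shift(
    image_a: np.ndarray, image_b: np.ndarray, upsample: int = 20
) -> tuple[float, float]:
    """Estimate the (dy, dx) displacement of ``image_b`` relative to ``image_a``.

    Positive values mean image_b's content sits down/right of image_a's;
    translating image_b by ``-(dy, dx)`` aligns it to image_a. Uses
    phase cross-correlation with subpixel refinement at ``1/upsample``
    pixel granularity.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantImageError("shift between constant images is undefined")
    # phase_cross_correlation returns the shift applied to the moving
    # image to match the reference, i.e. minus the displacement.
    # Classic (amplitude-weighted) correlation: spectral whitening is
    # counterproductive on sparse-spot images whose high frequencies
    # carry no signal, and it biases estimates on interpolated frames.
    shift, _err, _phase = phase_cross_correlation(
        a, b, upsample_factor=upsample, normalization=None
    )
    return (-float(shift[0]), -float(shift[1]))


def estimate_drift(
    movie: Movie,
    mode: str = "to_reference",
    upsample: int = 20,
    smooth_window: int | None = None,
) -> DriftTrajectory:
    """Estimate the cumulative drift trajectory of a movie.

    ``to_reference`` registers every frame directly against frame 0
    (robust for the short drifts of a fixed field of view);
    ``sequential`` accumulates frame-to-frame shifts, which tolerates
    larger total excursions at the price of summed errors. An optional
    centred moving average smooths the trajectory.
    """
    if movie.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    if mode not in ("to_reference", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = movie.data
    shifts = np.zeros((movie.n_frames, 2))
    try:
        if mode == "to_reference":
            ref = frames[0]
            for t in range(1, movie.n_frames):
                shifts[t] = estimate_pairwise_shift(ref, frames[t], upsample)
        else:
            for t in range(1, movie.n_frames):
                shifts[t] = estimate_pairwise_shift(frames[t - 1], frames[t], upsample)
            shifts = np.cumsum(shifts, axis=0)
    except ConstantImageError as exc:
        raise ConstantImageError(f"frame {t}: {exc}") from exc
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        padded = np.pad(shifts, ((smooth_window // 2, smooth_window // 2), (0, 0)), mode="edge")
        for k in range(2):
            shifts[:, k] = np.convolve(padded[:, k], kernel, mode="valid")[: movie.n_frames]
        shifts -= shifts[0]
    return DriftTrajectory(shifts=shifts, mode=mode)


def apply_drift(movie: Movie, traj: DriftTrajectory) -> Movie:
    """Translate each frame by minus its estimated drift.

    Uses linear interpolation; pixels shifted in from outside the field
    are filled with the frame's median (an unbiased stand-in for
    background) and marked ``False`` in the returned movie's validity
    mask so downstream ROI measurements can flag them.
    """
    if len(traj) != movie.n_frames:
        raise ValueError(
            f"trajectory length {len(traj)} != movie frames {movie.n_frames}"
        )
    out = np.empty_like(movie.data, dtype=float)
    valid = np.ones(movie.data.shape, dtype=bool)
    for t in range(movie.n_frames):
        d = traj.shifts[t]
        if np.all(np.abs(d) < 1e-9):
            out[t] = movie.data[t]
            continue
        fill = float(np.median(movie.data[t]))
        out[t] = ndi.shift(movie.data[t], -d, order=1, mode="constant", cval=fill)
        mask = ndi.shift(np.ones(movie.frame_shape), -d, order=1, mode="constant", cval=0.0)
        valid[t] = mask > 1.0 - 1e-6
    return Movie(
        data=out,
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        source=movie.source,
        valid=valid,
    )
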