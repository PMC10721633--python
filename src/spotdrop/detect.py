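"""Spot detection: define fixed ROIs from the start of the corrected movie.

Molecules are surface-immobilized and drift is removed first, so spots
are located once on a reference image (mean of the first few corrected
frames) and held fixed — no tracking. Detection is Gaussian smoothing
followed by local-maxima selection above a robust background threshold,
with greedy minimum-distance suppression that keeps the brighter of any
conflicting pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .movie_io import Movie

__all__ = [
    "Spot",
    "DetectionParams",
    "build_reference",
    "detect_maxima",
    "measure_local_background",
    "roi_offsets",
    "annulus_offsets",
]


@dataclass(frozen=True)
class Spot:
    """A fixed circular ROI around a detected molecule.

    ``x``/``y`` are reference-image pixel coordinates (col, row);
    intensity is integrated over pixels within ``roi_radius`` of the
    centre and local background is the median of the annulus between
    ``annulus_inner`` and ``annulus_outer``.
    """

    spot_id: int
    x: float
    y: float
    roi_radius: float = 3.0
    annulus_inner: float = 5.0
    annulus_outer: float = 7.0

    def __post_init__(self) -> None:
        if not self.roi_radius < self.annulus_inner < self.annulus_outer:
            raise ValueError("require roi_radius < annulus_inner < annulus_outer")


@dataclass(frozen=True)
class DetectionParams:
    """Detection knobs.

    ``prominence_threshold`` is either an absolute intensity above the
    image median, or ``"auto"``: ``k`` robust standard deviations
    (1.4826 × MAD) above the median. ROI geometry defaults follow
    roi_radius ≈ 2×psf_sigma with a 2-px-wide annulus 2 px beyond it.
    """

    smoothing_sigma: float = 1.0
    prominence_threshold: float | str = "auto"
    k: float = 5.0
    min_distance: float = 5.0
    n_reference_frames: int = 5
    roi_radius: float = 3.0
    annulus_gap: float = 2.0
    annulus_width: float = 2.0

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if self.n_reference_frames < 1:
            raise ValueError("n_reference_frames must be >= 1")

    @property
    def annulus_inner(self) -> float:
        return self.roi_radius + self.annulus_gap

    @property
    def annulus_outer(self) -> float:
        return self.annulus_inner + self.annulus_width


def build_reference(movie: Movie, n_reference_frames: int = 5) -> np.ndarray:
    """Mean of the first ``n_reference_frames`` frames."""
    if n_reference_frames > movie.n_frames:
        raise ValueError(
            f"n_reference_frames={n_reference_frames} exceeds movie frames {movie.n_frames}"
        )
    return movie.data[:n_reference_frames].astype(float).mean(axis=0)


def detect_maxima(image: np.ndarray, params: DetectionParams | None = None) -> list[Spot]:
    """Find spot centres as smoothed local maxima above background.

    A constant image yields zero spots. Conflicting maxima closer than
    ``min_distance`` keep the brighter one, ties broken by lower (y, x);
    maxima whose annulus would leave the field are dropped. Spot ids
    are assigned in (y, x) raster order.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_maxima expects a 2-D image")
    smoothed = ndi.gaussian_filter(img, params.smoothing_sigma)
    med = float(np.median(smoothed))
    if params.prominence_threshold == "auto":
        mad = float(np.median(np.abs(smoothed - med)))
        thresh = med + params.k * 1.4826 * mad
    else:
        thresh = med + float(params.prominence_threshold)

    is_max = smoothed == ndi.maximum_filter(smoothed, size=3)
    ys, xs = np.nonzero(is_max & (smoothed > thresh))
    if ys.size == 0:
        return []
    vals = smoothed[ys, xs]
    order = np.lexsort((xs, ys, -vals))  # brighter first, then (y, x)
    ys, xs = ys[order], xs[order]

    accepted_y: list[int] = []
    accepted_x: list[int] = []
    min_d2 = params.min_distance**2
    for y, x in zip(ys, xs):
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_d2 for ay, ax in zip(accepted_y, accepted_x)):
            accepted_y.append(int(y))
            accepted_x.append(int(x))

    rows, cols = img.shape
    m = params.annulus_outer
    spots = [
        (y, x)
        for y, x in zip(accepted_y, accepted_x)
        if m <= y <= rows - 1 - m and m <= x <= cols - 1 - m
    ]
    spots.sort()  # (y, x) raster order for stable ids
    return [
        Spot(
            spot_id=i, x=float(x), y=float(y),
            roi_radius=params.roi_radius,
            annulus_inner=params.annulus_inner,
            annulus_outer=params.annulus_outer,
        )
        for i, (y, x) in enumerate(spots)
    ]


def roi_offsets(spot: Spot) -> tuple[np.ndarray, np.ndarray]:
    """(dy, dx) integer offsets of pixels within roi_radius of the centre."""
    r = int(np.ceil(spot.roi_radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dy**2 + dx**2 <= spot.roi_radius**2
    return dy[inside], dx[inside]


def annulus_offsets(spot: Spot) -> tuple[np.ndarray, np.ndarray]:
    """(dy, dx) integer offsets of pixels in the background annulus."""
    r = int(np.ceil(spot.annulus_outer))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    inside = (d2 >= spot.annulus_inner**2) & (d2 <= spot.annulus_outer**2)
    return dy[inside], dx[inside]


def measure_local_background(image: np.ndarray, spot: Spot) -> float:
    """Median intensity per pixel in the spot's background annulus."""
    img = np.asarray(image, dtype=float)
    rows, cols = img.shape
    dy, dx = annulus_offsets(spot)
    yy = np.rint(spot.y).astype(int) + dy
    xx = np.rint(spot.x).astype(int) + dx
    if yy.min() < 0 or xx.min() < 0 or yy.max() >= rows or xx.max() >= cols:
        raise ValueError(f"spot {spot.spot_id}: annulus extends outside the field")
    return float(np.median(img[yy, xx]))
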