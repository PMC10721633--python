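"""Synthetic TIRF movie generator with per-spot event ground truth.

Forward model of the single-molecule strand-separation assay: sparse
immobile diffraction-limited spots (2-D Gaussian PSF) on a uniform
background, imaged as a time-lapse. Each spot may undergo a strand
separation event ("drop": the labelled oligonucleotide leaves the
evanescent field, its intensity falls to ``residual_fraction`` of the
original) or photobleach (intensity falls to zero); the two are
competing exponential processes and the earlier one within the
acquisition window wins. Stage drift (linear plus random walk), Poisson
shot noise, camera gain and Gaussian read noise complete the model.

Every per-condition preset encodes one of the study's end-point counts
(drops / total spots) so pipeline recovery can be checked against a
known generating probability.

Randomness uses one master seed split into independent child streams
for positions, event schedule and rendering noise, so each stage can be
varied without perturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import CrowdedFieldError
from .movie_io import Movie

__all__ = [
    "SimulationConfig",
    "GroundTruthEvent",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "condition_preset",
    "sample_spot_positions",
    "sample_event_schedule",
    "render_movie",
    "drift_path",
    "simulate_movie",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward model.

    Defaults reproduce the study's acquisition geometry: 121 frames at
    5 s intervals (10 min at one frame per 5 s, plus the initial frame),
    512×512 EMCCD field, and immobilized scaffolds kept a minimum of
    15.2 µm apart. Pixel size defaults to 0.16 µm/px (typical for a
    100× TIRF objective on a 16 µm-pixel EMCCD); amplitude and
    background defaults give a peak signal-to-noise ratio near 10.
    """

    field_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.16           # µm / pixel
    n_frames: int = 121
    frame_interval: float = 5.0        # s
    n_spots: int = 15
    min_spacing: float = 15.2          # µm, hard minimum between spot centres
    psf_sigma: float = 1.3             # px
    spot_amplitude_mean: float = 2000.0  # photons / frame, integrated over the PSF
    spot_amplitude_cv: float = 0.1
    background_level: float = 100.0    # photons / pixel / frame
    camera_gain: float = 1.0           # ADU / photon
    read_noise_sd: float = 2.0         # ADU
    drift_rate: tuple[float, float] = (0.0, 0.0)  # (dy, dx) px / frame
    drift_rw_sd: float = 0.0           # px / frame random-walk step sd
    drop_probability: float = 0.5
    drop_time_scale: float = 120.0     # s, waiting-time scale of drops that occur
    event_onset: float = 30.0          # s, protein arrival; no event can precede it
    photobleach_rate: float = 0.0      # 1 / s
    residual_fraction: float = 0.0     # relative brightness after a drop
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(s < 1 for s in self.field_shape):
            raise ValueError("field_shape must be positive")
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ValueError("drop_probability must lie in [0, 1]")
        if not 0.0 <= self.residual_fraction < 0.75:
            raise ValueError("residual_fraction must lie in [0, 0.75) to keep events callable")
        for name in ("min_spacing", "psf_sigma", "spot_amplitude_mean", "spot_amplitude_cv",
                     "background_level", "camera_gain", "read_noise_sd", "drift_rw_sd",
                     "drop_time_scale", "photobleach_rate", "pixel_size", "frame_interval",
                     "event_onset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def min_spacing_px(self) -> float:
        return self.min_spacing / self.pixel_size

    @property
    def acquisition_span(self) -> float:
        """Total modelled time window in seconds (n_frames × interval)."""
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class GroundTruthEvent:
    """Simulator truth for one spot: what happened to it and when."""

    spot_id: int
    x: float
    y: float
    event_type: str               # "drop" | "photobleach" | "none"
    event_frame: int | None

    def __post_init__(self) -> None:
        if self.event_type not in ("drop", "photobleach", "none"):
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if (self.event_frame is None) != (self.event_type == "none"):
            raise ValueError("event_frame must be None iff event_type is 'none'")


@dataclass(frozen=True)
class ConditionPreset:
    """A study condition expressed as its end-point drop count."""

    name: str
    n_drops: int
    n_spots: int

    @property
    def drop_probability(self) -> float:
        return self.n_drops / self.n_spots


# End-point counts per condition (drops, total spots observed).
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    p.name: p
    for p in [
        ConditionPreset("ATP", 255, 330),
        ConditionPreset("ADP", 48, 413),
        ConditionPreset("no_protein", 44, 340),
        ConditionPreset("boxes_scr", 61, 609),
        ConditionPreset("trios_scr", 82, 706),
        ConditionPreset("R264A", 24, 353),
        ConditionPreset("I190A", 23, 309),
        ConditionPreset("domainIII_IV", 209, 387),   # DnaA 104-446, lacking domains I-II
        ConditionPreset("dual_atto647", 194, 235),   # trio-complement strand, double-label control
        ConditionPreset("dual_atto565", 170, 413),   # distal strand; dye photobleach-sensitive
    ]
}


def condition_preset(name: str) -> ConditionPreset:
    """Look up a registered condition preset by name."""
    try:
        return CONDITION_PRESETS[name]
    except KeyError:
        available = ", ".join(sorted(CONDITION_PRESETS))
        raise KeyError(f"unknown condition preset {name!r}; available: {available}") from None


def sample_spot_positions(
    n: int,
    field_shape: tuple[int, int],
    min_spacing_px: float,
    seed: int | np.random.Generator = 0,
    margin: int = 8,
    max_attempts: int = 2000,
    max_restarts: int = 20,
) -> list[tuple[int, int]]:
    """Place ``n`` spot centres uniformly with a hard minimum spacing.

    Centres sit on integer pixel coordinates at least ``margin`` pixels
    from every border (so the measurement annulus stays inside the
    field). Placement is rejection sampling with bounded retries; an
    infeasible or overcrowded request raises :class:`CrowdedFieldError`
    rather than looping forever.

    Returns a list of ``(x, y)`` tuples (col, row).
    """
    if min_spacing_px < 0:
        raise ValueError("min_spacing_px must be non-negative")
    if n == 0:
        return []
    rows, cols = field_shape
    lo_y, hi_y = margin, rows - 1 - margin
    lo_x, hi_x = margin, cols - 1 - margin
    if hi_y < lo_y or hi_x < lo_x:
        raise CrowdedFieldError(
            f"field {field_shape} too small for border margin {margin}"
        )
    # Quick geometric infeasibility check: no two points of the usable
    # region are farther apart than its diagonal.
    diag = float(np.hypot(hi_y - lo_y, hi_x - lo_x))
    if n >= 2 and min_spacing_px > diag:
        raise CrowdedFieldError(
            f"field too crowded: min spacing {min_spacing_px:.1f} px exceeds the "
            f"usable diagonal {diag:.1f} px"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_restarts):
        pts: list[tuple[int, int]] = []
        ok = True
        for _i in range(n):
            placed = False
            for _a in range(max_attempts):
                y = int(rng.integers(lo_y, hi_y + 1))
                x = int(rng.integers(lo_x, hi_x + 1))
                if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing_px**2 for px, py in pts):
                    pts.append((x, y))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise CrowdedFieldError(
        f"field too crowded: could not place {n} spots with spacing "
        f"{min_spacing_px:.1f} px in field {field_shape} after {max_restarts} restarts"
    )


def _truncated_exponential(rng: np.random.Generator, scale: float, span: float, size: int) -> np.ndarray:
    """Waiting times from an exponential of the given scale truncated to [0, span]."""
    u = rng.random(size)
    if scale == 0:
        return np.zeros(size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))


def sample_event_schedule(
    config: SimulationConfig,
    n: int,
    seed: int | np.random.Generator = 0,
    positions: Sequence[tuple[float, float]] | None = None,
) -> list[GroundTruthEvent]:
    """Assign each spot its fate: drop, photobleach, or nothing.

    Each spot drops with probability ``drop_probability``; conditional
    on dropping, the event time is ``event_onset`` (protein arrival —
    no strand separation can precede the protein) plus an exponential
    waiting time of scale ``drop_time_scale`` truncated to the
    remaining acquisition window. Photobleaching is an independent
    competing exponential of rate ``photobleach_rate`` running from
    illumination start; whichever process fires first inside the window
    defines the recorded event.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    span = config.acquisition_span
    drops = rng.random(n) < config.drop_probability
    if config.event_onset < span:
        waits = _truncated_exponential(rng, config.drop_time_scale, span - config.event_onset, n)
        t_drop = np.where(drops, config.event_onset + waits, np.inf)
    else:
        # protein never arrives within the window: no drops possible
        t_drop = np.full(n, np.inf)
    if config.photobleach_rate > 0:
        t_bleach = rng.exponential(1.0 / config.photobleach_rate, size=n)
    else:
        t_bleach = np.full(n, np.inf)
    t_bleach = np.where(t_bleach < span, t_bleach, np.inf)

    events = []
    for i in range(n):
        x, y = positions[i] if positions is not None else (np.nan, np.nan)
        td, tb = t_drop[i], t_bleach[i]
        if np.isinf(td) and np.isinf(tb):
            events.append(GroundTruthEvent(i, x, y, "none", None))
            continue
        t = min(td, tb)
        frame = min(int(t // config.frame_interval), config.n_frames - 1)
        etype = "drop" if td <= tb else "photobleach"
        events.append(GroundTruthEvent(i, x, y, etype, frame))
    return events


def drift_path(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Cumulative (dy, dx) translation per frame, zero at frame 0."""
    t = np.arange(config.n_frames)[:, None]
    linear = t * np.asarray(config.drift_rate, dtype=float)[None, :]
    if config.drift_rw_sd > 0:
        steps = rng.normal(0.0, config.drift_rw_sd, size=(config.n_frames, 2))
        steps[0] = 0.0
        walk = np.cumsum(steps, axis=0)
    else:
        walk = np.zeros((config.n_frames, 2))
    return linear + walk


def render_movie(
    config: SimulationConfig,
    positions: Sequence[tuple[float, float]],
    events: Sequence[GroundTruthEvent],
    seed: int | np.random.Generator = 0,
    drift: np.ndarray | None = None,
) -> Movie:
    """Render the photon-to-ADU forward model into a Movie.

    ``drift`` optionally supplies a precomputed cumulative (n_frames, 2)
    drift path (see :func:`drift_path`); by default one is drawn from
    the rendering stream.

    Each frame is ``background_level`` plus one integrated-amplitude
    Gaussian per spot at its drifted position; a spot keeps its sampled
    amplitude before its event frame and ``residual_fraction`` of it
    (drop) or zero (photobleach) from the event frame onward. Pixel
    photon counts are Poisson-sampled (unless ``shot_noise`` is off),
    scaled by the camera gain, and Gaussian read noise is added.
    """
    if len(positions) != len(events):
        raise ValueError("positions and events must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = config.field_shape
    n_spots = len(positions)

    if config.spot_amplitude_cv > 0 and n_spots:
        shape = 1.0 / config.spot_amplitude_cv**2
        amps = rng.gamma(shape, config.spot_amplitude_mean / shape, size=n_spots)
    else:
        amps = np.full(n_spots, config.spot_amplitude_mean)

    if drift is None:
        drift = drift_path(config, rng)
    else:
        drift = np.asarray(drift, dtype=float)
        if drift.shape != (config.n_frames, 2):
            raise ValueError("drift must have shape (n_frames, 2)")
    sigma = config.psf_sigma
    halfwin = int(np.ceil(4 * sigma)) + 1
    norm = 1.0 / (2.0 * np.pi * sigma**2)

    photons = np.full((config.n_frames, rows, cols), config.background_level, dtype=np.float32)
    for i, ((x0, y0), ev) in enumerate(zip(positions, events)):
        amp_t = np.full(config.n_frames, amps[i])
        if ev.event_frame is not None:
            if ev.event_type == "drop":
                amp_t[ev.event_frame :] *= config.residual_fraction
            else:
                amp_t[ev.event_frame :] = 0.0
        if not amp_t.any():
            continue
        yc = y0 + drift[:, 0]
        xc = x0 + drift[:, 1]
        # one window per spot covering its whole drifted excursion,
        # evaluated for all frames at once
        ylo = max(int(np.floor(yc.min())) - halfwin, 0)
        yhi = min(int(np.ceil(yc.max())) + halfwin + 1, rows)
        xlo = max(int(np.floor(xc.min())) - halfwin, 0)
        xhi = min(int(np.ceil(xc.max())) + halfwin + 1, cols)
        if ylo >= yhi or xlo >= xhi:
            continue
        yy = np.arange(ylo, yhi)[None, :, None]
        xx = np.arange(xlo, xhi)[None, None, :]
        g = np.exp(
            -((yy - yc[:, None, None]) ** 2 + (xx - xc[:, None, None]) ** 2) / (2 * sigma**2)
        )
        photons[:, ylo:yhi, xlo:xhi] += amp_t[:, None, None] * norm * g

    if config.shot_noise:
        adu = rng.poisson(photons).astype(np.float32)
    else:
        adu = photons.copy()
    if config.camera_gain != 1.0:
        adu *= np.float32(config.camera_gain)
    if config.read_noise_sd > 0:
        adu += rng.normal(0.0, config.read_noise_sd, size=adu.shape).astype(np.float32)
    return Movie(
        data=adu,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
        source="simulated",
    )


def simulate_movie(
    config: SimulationConfig,
    margin: int = 8,
) -> tuple[Movie, list[GroundTruthEvent]]:
    """Run positions → schedule → rendering under one master seed.

    The master seed is split into three independent child streams
    (positions, event schedule, rendering noise), so changing one stage
    leaves the others' draws untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pos, rng_sched, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    positions = sample_spot_positions(
        config.n_spots, config.field_shape, config.min_spacing_px, rng_pos, margin=margin
    )
    events = sample_event_schedule(config, config.n_spots, rng_sched, positions=positions)
    movie = render_movie(config, positions, events, rng_noise)
    return movie, events
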