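"""Fluorescence-quench (BHQ) strand-separation plate kinetics.

In the plate assay a quencher-bearing strand suppresses a nearby
fluorophore; strand separation relieves the quenching, so signal rises
as DnaA unwinds the scaffold. Wells come in experimental/background
pairs measured on a shared timepoint grid (default 0–4500 s every
30 s, 151 points), in triplicate, with the first point read before
protein addition. Background subtraction is per-timepoint: each
experimental replicate minus the mean of the background replicates.

Tables use a long CSV schema: well_id, role, condition, replicate,
time_s, signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import GridMismatchError, NoTransitionError

__all__ = [
    "PLATE_COLUMNS",
    "SsaResult",
    "subtract_background",
    "initial_rate",
    "summarize_ssa",
    "simulate_plate",
    "melt_temperature",
]

PLATE_COLUMNS = ["well_id", "role", "condition", "replicate", "time_s", "signal"]

#: Default acquisition grid: a reading every 30 s for 75 min.
DEFAULT_TIMEPOINTS = np.arange(0.0, 4500.0 + 1e-9, 30.0)  # 151 points

#: Assay constants: scaffold and protein concentrations (nM).
SCAFFOLD_NM = 12.5
DNAA_NM = 650.0


@dataclass
class SsaResult:
    """Background-corrected kinetics for one condition."""

    condition: str
    time_s: np.ndarray
    mean: np.ndarray             # corrected signal averaged over replicates
    sd: np.ndarray               # replicate standard deviation (ddof=1)
    initial_rate: float          # fluorescence units / s
    rate_window: float           # seconds


def _grids(df: pd.DataFrame) -> np.ndarray:
    """Common timepoint grid of a well table; error on any mismatch."""
    grids = [g["time_s"].to_numpy(float) for _, g in df.sort_values("time_s").groupby("well_id")]
    ref = grids[0]
    for g in grids[1:]:
        if len(g) != len(ref) or not np.array_equal(g, ref):
            n = min(len(g), len(ref))
            diff = np.nonzero(g[:n] != ref[:n])[0]
            t = g[diff[0]] if len(diff) else (g[n:] + list(ref[n:]))[0]
            raise GridMismatchError(f"well timepoint grids differ, first at t={t}")
    return ref


def subtract_background(experimental: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint background subtraction.

    At each timepoint the mean of the background replicates is
    subtracted from each experimental replicate. Returns a long
    DataFrame (replicate, time_s, corrected).
    """
    grid_exp = _grids(experimental)
    grid_bg = _grids(background)
    if len(grid_exp) != len(grid_bg) or not np.array_equal(grid_exp, grid_bg):
        n = min(len(grid_exp), len(grid_bg))
        diff = np.nonzero(grid_exp[:n] != grid_bg[:n])[0]
        t = grid_exp[diff[0]] if len(diff) else max(grid_exp[-1], grid_bg[-1])
        raise GridMismatchError(
            f"experimental and background grids differ, first at t={t}"
        )
    bg_mean = background.groupby("time_s")["signal"].mean()
    out = []
    for rep, grp in experimental.sort_values("time_s").groupby("replicate"):
        corrected = grp["signal"].to_numpy(float) - bg_mean.loc[grp["time_s"]].to_numpy(float)
        out.append(pd.DataFrame({"replicate": rep, "time_s": grp["time_s"].to_numpy(float),
                                 "corrected": corrected}))
    return pd.concat(out, ignore_index=True)


def initial_rate(time_s: np.ndarray, signal: np.ndarray, rate_window: float = 600.0) -> float:
    """Early-window linear rate of a corrected trace.

    Least-squares slope of signal vs time over the first
    ``rate_window`` seconds after protein addition. The first timepoint
    is pre-protein: it anchors the window but is excluded from the fit.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    t0 = t[0]
    mask = (t > t0) & (t <= t0 + rate_window)
    if mask.sum() < 3:
        raise ValueError(f"initial_rate needs >=3 timepoints inside the {rate_window}-s window")
    return float(np.polyfit(t[mask], y[mask], 1)[0])


def summarize_ssa(
    corrected: pd.DataFrame, condition: str = "", rate_window: float = 600.0
) -> SsaResult:
    """Average corrected replicates and estimate the initial rate."""
    wide = corrected.pivot(index="time_s", columns="replicate", values="corrected").sort_index()
    time_s = wide.index.to_numpy(float)
    mean = wide.mean(axis=1).to_numpy(float)
    sd = wide.std(axis=1, ddof=1).to_numpy(float) if wide.shape[1] > 1 else np.zeros(len(wide))
    rate = initial_rate(time_s, mean, rate_window)
    return SsaResult(condition=condition, time_s=time_s, mean=mean, sd=sd,
                     initial_rate=rate, rate_window=rate_window)


def simulate_plate(
    conditions: list[tuple[str, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 500.0,
    baseline_drift: float = 0.01,
    n_replicates: int = 3,
    timepoints: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthetic plate run: saturating-exponential unwinding kinetics.

    Each condition is a tuple ``(label, A, k)``: experimental wells read
    ``baseline(t) + A(1 − e^{−k(t − t_add)})`` for t past the protein
    addition (the second timepoint), background wells read the shared
    drifting baseline only, all plus Gaussian noise. Triplicates by
    default on the 151-point 30-s grid.
    """
    rng = np.random.default_rng(seed)
    t = DEFAULT_TIMEPOINTS.copy() if timepoints is None else np.asarray(timepoints, float)
    t_add = t[1] if len(t) > 1 else 0.0
    base = baseline + baseline_drift * t
    rows = []
    well = 0
    for label, A, k in conditions:
        if k < 0:
            raise ValueError("rate constant k must be >= 0")
        signal_true = A * -np.expm1(-k * np.clip(t - t_add, 0.0, None))
        for rep in range(n_replicates):
            for role, clean in (("experimental", base + signal_true), ("background", base)):
                noisy = clean + (rng.normal(0.0, noise_sd, len(t)) if noise_sd > 0 else 0.0)
                rows.append(pd.DataFrame({
                    "well_id": f"W{well:03d}", "role": role, "condition": label,
                    "replicate": rep, "time_s": t, "signal": noisy,
                }))
                well += 1
    return pd.concat(rows, ignore_index=True)


def melt_temperature(
    temperature: np.ndarray,
    fluorescence: np.ndarray,
    smooth_sigma: float = 1.0,
    mode: str = "auto",
) -> float:
    """Melting temperature from a fluorescence melt curve.

    Tm is the temperature at the extremum of the smoothed first
    derivative dF/dT, refined by parabolic interpolation between grid
    points. ``mode`` selects the transition sign: ``"rise"`` (quencher
    release), ``"fall"`` (intercalating-dye loss) or ``"auto"``
    (largest |dF/dT|).
    """
    T = np.asarray(temperature, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if len(T) < 5:
        raise ValueError("melt curve needs at least 5 points")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    scale = max(abs(float(F.max())), abs(float(F.min())), 1.0)
    if np.ptp(F) < 1e-9 * scale:
        raise NoTransitionError("melt curve is flat: no transition detected")
    smoothed = ndi.gaussian_filter1d(F, smooth_sigma)
    dF = np.gradient(smoothed, T)
    if mode == "rise":
        obj = dF
    elif mode == "fall":
        obj = -dF
    elif mode == "auto":
        obj = np.abs(dF)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    i = int(np.argmax(obj))
    if obj[i] <= 0:
        raise NoTransitionError("melt curve shows no transition of the requested sign")
    if 0 < i < len(T) - 1:
        # parabolic vertex through the three points around the extremum
        y0, y1, y2 = obj[i - 1], obj[i], obj[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(T[i] + delta * (T[min(i + 1, len(T) - 1)] - T[max(i - 1, 0)]) / 2.0)
    return float(T[i])
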