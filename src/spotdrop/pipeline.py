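"""End-to-end convenience: register → detect → trace → call → summarize."""

from __future__ import annotations

from dataclasses import dataclass

from .detect import DetectionParams, Spot, build_reference, detect_maxima
from .dropcall import DropCall, DropRule, call_drop, summarize_condition
from .movie_io import Movie
from .register import DriftTrajectory, apply_drift, estimate_drift
from .traces import IntensityTrace, extract_traces

__all__ = ["PipelineResult", "analyze_movie"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one movie."""

    trajectory: DriftTrajectory | None
    corrected: Movie
    spots: list[Spot]
    traces: list[IntensityTrace]
    calls: list[DropCall]

    def summary(self, condition: str = "", replicate_ids=None):
        return summarize_condition(self.calls, condition, replicate_ids)


def analyze_movie(
    movie: Movie,
    rule: DropRule = DropRule(),
    detection: DetectionParams | None = None,
    register: bool = True,
    register_mode: str = "to_reference",
    upsample: int = 20,
    n_initial_frames: int = 5,
) -> PipelineResult:
    """Run the full disappearing-spot analysis on one movie."""
    detection = detection or DetectionParams()
    trajectory = None
    corrected = movie
    if register and movie.n_frames >= 2:
        trajectory = estimate_drift(movie, mode=register_mode, upsample=upsample)
        corrected = apply_drift(movie, trajectory)
    reference = build_reference(corrected, detection.n_reference_frames)
    spots = detect_maxima(reference, detection)
    traces = extract_traces(corrected, spots, n_initial_frames=n_initial_frames)
    calls = [call_drop(t, rule) for t in traces]
    return PipelineResult(
        trajectory=trajectory, corrected=corrected, spots=spots, traces=traces, calls=calls
    )
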