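"""The drop rule, per-condition aggregation and truth evaluation.

A spot is called a drop when its normalized intensity falls strictly
below a threshold fraction of the initial intensity (default 0.75) for
a run of consecutive frames (default 5). The call is a trigger, not a
state classifier: later recovery does not rescind it. Condition
summaries report the drop fraction with a Wilson 95% confidence
interval and, when replicate labels are given, the per-replicate
fractions with their mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .simulate import GroundTruthEvent
from .traces import IntensityTrace

__all__ = [
    "DropRule",
    "DropCall",
    "ConditionSummary",
    "EvaluationMetrics",
    "call_drop",
    "calls_to_frame",
    "summarize_condition",
    "control_adjusted_fraction",
    "match_spots_to_truth",
    "relabel_calls",
    "evaluate_against_truth",
]


@dataclass(frozen=True)
class DropRule:
    """Threshold fraction of initial intensity and required run length."""

    threshold: float = 0.75
    run_length: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


@dataclass(frozen=True)
class DropCall:
    """Verdict for one spot: drop / no_drop / excluded, with the first
    frame of the earliest qualifying run when dropped."""

    spot_id: int
    verdict: str
    drop_frame: int | None = None

    def __post_init__(self) -> None:
        if self.verdict not in ("drop", "no_drop", "excluded"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if (self.drop_frame is not None) != (self.verdict == "drop"):
            raise ValueError("drop_frame must be set iff verdict is 'drop'")


@dataclass
class ConditionSummary:
    condition: str
    n_drops: int
    n_total: int
    n_excluded: int
    fraction: float
    ci_low: float
    ci_high: float
    replicate_fractions: list[float] = field(default_factory=list)
    replicate_mean: float | None = None
    replicate_sd: float | None = None


@dataclass
class EvaluationMetrics:
    """Drop-caller performance against simulator truth.

    Truth events of either type (drop or photobleach) count as
    "should be called": the intensity rule cannot distinguish them on a
    single spot, mirroring the assay's reliance on no-protein/ADP
    controls. ``photobleach_call_fraction`` reports how many correct
    calls were in fact photobleaching.
    """

    recall: float
    precision: float
    n_true_events: int
    n_calls: int
    n_matched: int
    median_frame_error: float
    frac_within_tolerance: float
    photobleach_call_fraction: float


def call_drop(trace: IntensityTrace, rule: DropRule = DropRule()) -> DropCall:
    """Apply the drop rule to one normalized trace.

    Verdict is ``drop`` iff ``run_length`` consecutive frames sit
    strictly below ``threshold``; ``drop_frame`` is the first frame of
    the earliest such run. Frames flagged invalid (drift fill) are
    treated as not-below-threshold. Unusable traces, and traces shorter
    than the run length, are ``excluded``.
    """
    if not trace.usable or trace.normalized is None or len(trace) < rule.run_length:
        return DropCall(spot_id=trace.spot_id, verdict="excluded")
    below = (trace.normalized < rule.threshold) & trace.frame_valid
    run = 0
    for f, b in enumerate(below):
        run = run + 1 if b else 0
        if run == rule.run_length:
            return DropCall(spot_id=trace.spot_id, verdict="drop", drop_frame=f - rule.run_length + 1)
    return DropCall(spot_id=trace.spot_id, verdict="no_drop")


def calls_to_frame(calls: list[DropCall], traces: list[IntensityTrace] | None = None,
                   spots=None) -> pd.DataFrame:
    """Assemble calls (plus optional spot geometry and trace metadata)
    into the standard event-table DataFrame."""
    trace_by_id = {t.spot_id: t for t in traces} if traces else {}
    spot_by_id = {s.spot_id: s for s in spots} if spots else {}
    rows = []
    for c in sorted(calls, key=lambda c: c.spot_id):
        t = trace_by_id.get(c.spot_id)
        s = spot_by_id.get(c.spot_id)
        rows.append(
            (c.spot_id,
             s.x if s else np.nan, s.y if s else np.nan,
             c.verdict, c.drop_frame,
             t.initial_intensity if t else np.nan)
        )
    df = pd.DataFrame(rows, columns=["spot_id", "x", "y", "verdict", "drop_frame", "initial_intensity"])
    df["drop_frame"] = df["drop_frame"].astype("Int64")
    return df


def summarize_condition(
    calls: list[DropCall],
    condition: str = "",
    replicate_ids: dict[int, object] | None = None,
) -> ConditionSummary:
    """Aggregate drop calls into a per-condition fraction.

    Excluded calls are removed from the usable total. The fraction
    carries a Wilson 95% binomial confidence interval; when
    ``replicate_ids`` maps spot_id → replicate label, per-replicate
    fractions and their mean ± sd (ddof=1) are reported as well.
    """
    usable = [c for c in calls if c.verdict != "excluded"]
    n_excluded = len(calls) - len(usable)
    if not usable:
        raise ValueError(f"condition {condition!r}: no usable calls to summarize")
    n_total = len(usable)
    n_drops = sum(c.verdict == "drop" for c in usable)
    fraction = n_drops / n_total
    ci_low, ci_high = proportion_confint(n_drops, n_total, alpha=0.05, method="wilson")
    summary = ConditionSummary(
        condition=condition,
        n_drops=n_drops,
        n_total=n_total,
        n_excluded=n_excluded,
        fraction=fraction,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )
    if replicate_ids is not None:
        groups: dict[object, list[DropCall]] = {}
        for c in usable:
            groups.setdefault(replicate_ids[c.spot_id], []).append(c)
        fracs = [
            sum(c.verdict == "drop" for c in grp) / len(grp)
            for _, grp in sorted(groups.items(), key=lambda kv: str(kv[0]))
        ]
        summary.replicate_fractions = fracs
        summary.replicate_mean = float(np.mean(fracs))
        summary.replicate_sd = float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0
    return summary


def control_adjusted_fraction(summary: ConditionSummary, control: ConditionSummary) -> float:
    """Condition fraction minus the no-protein control fraction.

    Provided for convenience only — reported condition fractions are
    raw, never control-subtracted by default.
    """
    return summary.fraction - control.fraction


def match_spots_to_truth(spots, truth: list[GroundTruthEvent], radius: float = 2.0) -> dict[int, int]:
    """Greedy nearest-neighbour matching of detected spots to truth spots.

    Returns a mapping ``detected spot_id -> truth spot_id`` for pairs
    within ``radius`` pixels, closest pairs first, each spot used once.
    Needed because detection assigns its own ids in raster order.
    """
    from scipy.spatial import cKDTree

    if not spots or not truth:
        return {}
    t_xy = np.array([[e.x, e.y] for e in truth])
    d_xy = np.array([[s.x, s.y] for s in spots])
    tree = cKDTree(t_xy)
    pairs = []
    for i, xy in enumerate(d_xy):
        for j in tree.query_ball_point(xy, radius):
            pairs.append((float(np.hypot(*(xy - t_xy[j]))), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    mapping: dict[int, int] = {}
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        mapping[spots[i].spot_id] = truth[j].spot_id
        used_d.add(i)
        used_t.add(j)
    return mapping


def relabel_calls(calls: list[DropCall], mapping: dict[int, int]) -> list[DropCall]:
    """Rewrite call spot_ids via a detection→truth mapping, dropping unmatched calls."""
    return [
        DropCall(spot_id=mapping[c.spot_id], verdict=c.verdict, drop_frame=c.drop_frame)
        for c in calls
        if c.spot_id in mapping
    ]


def evaluate_against_truth(
    calls: list[DropCall],
    truth: list[GroundTruthEvent],
    frame_tolerance: int = 2,
) -> EvaluationMetrics:
    """Score drop calls against the simulator's ground-truth events."""
    truth_by_id = {e.spot_id: e for e in truth}
    call_ids = {c.spot_id for c in calls}
    if not call_ids <= set(truth_by_id):
        missing = sorted(call_ids - set(truth_by_id))[:5]
        raise ValueError(f"calls reference spot_ids absent from truth, e.g. {missing}")

    n_true = sum(e.event_type in ("drop", "photobleach") for e in truth)
    called = [c for c in calls if c.verdict == "drop"]
    matched = [c for c in called if truth_by_id[c.spot_id].event_type in ("drop", "photobleach")]
    frame_errors = np.array(
        [abs(c.drop_frame - truth_by_id[c.spot_id].event_frame) for c in matched], dtype=float
    )
    n_bleach = sum(truth_by_id[c.spot_id].event_type == "photobleach" for c in matched)
    return EvaluationMetrics(
        recall=len(matched) / n_true if n_true else float("nan"),
        precision=len(matched) / len(called) if called else float("nan"),
        n_true_events=n_true,
        n_calls=len(called),
        n_matched=len(matched),
        median_frame_error=float(np.median(frame_errors)) if len(frame_errors) else float("nan"),
        frac_within_tolerance=(
            float(np.mean(frame_errors <= frame_tolerance)) if len(frame_errors) else float("nan")
        ),
        photobleach_call_fraction=n_bleach / len(matched) if matched else float("nan"),
    )
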