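"""Suction-event segmentation, per-newborn suction summaries and
inter-annotator agreement.

A suction event (SE) is a maximal run of suction insertions in which no pause
between consecutive insertions exceeds ``max_pause_s`` (default 5 s); a
strictly longer pause splits the run into two events.  Suction annotation is
restricted to an analysis window (default the first 420 s after birth), so
events are clipped to that window before summarising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from neosuction.config import AnalysisConfig
from neosuction.types import EpisodeRecord, EventKind, IntervalEvent, SuctionEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SuctionSummary:
    """Per-newborn suctioning summary over the analysed window."""

    n_se: int
    total_suction_s: float
    proportion_time_suctioning: float
    n_insertions: int
    n_mouth: int
    n_nose: int
    insertions_per_se: float
    any_catheter: bool
    analyzed_window_s: float


def merge_insertions(
    insertions: Sequence[IntervalEvent], config: AnalysisConfig | None = None
) -> list[SuctionEvent]:
    """Group suction insertions into suction events by the pause rule.

    Consecutive insertions whose gap (next start minus previous stop) is at
    most ``config.max_pause_s`` belong to the same event; a strictly larger
    gap starts a new one.  Overlapping insertions (an annotation slip) are
    merged into a single insertion with a logged warning.  Output is sorted
    and non-overlapping; input order is irrelevant.
    """
    config = config or AnalysisConfig()
    bad = [e for e in insertions if e.kind is not EventKind.SUCTION_INSERTION]
    if bad:
        raise ValueError(f"merge_insertions expects suction insertions only, got {bad[0].kind}")
    if not insertions:
        return []

    ordered = sorted(insertions, key=lambda e: (e.start_s, e.stop_s))
    deduped: list[IntervalEvent] = [ordered[0]]
    for e in ordered[1:]:
        prev = deduped[-1]
        if e.start_s < prev.stop_s:  # overlap within one annotator
            logger.warning(
                "overlapping suction insertions [%s, %s) and [%s, %s); merging",
                prev.start_s, prev.stop_s, e.start_s, e.stop_s,
            )
            deduped[-1] = replace(prev, stop_s=max(prev.stop_s, e.stop_s))
        else:
            deduped.append(e)

    groups: list[list[IntervalEvent]] = [[deduped[0]]]
    for e in deduped[1:]:
        gap = e.start_s - groups[-1][-1].stop_s
        if gap > config.max_pause_s:
            groups.append([e])
        else:
            groups[-1].append(e)
    return [SuctionEvent.from_insertions(g) for g in groups]


def clip_to_window(
    ses: Sequence[SuctionEvent], config: AnalysisConfig | None = None
) -> list[SuctionEvent]:
    """Intersect suction events with ``[0, analysis_window_s)``.

    An event straddling the boundary is truncated (its insertions clipped
    likewise); events entirely outside are dropped.  An infinite window is
    the identity.
    """
    config = config or AnalysisConfig()
    w = config.analysis_window_s
    if math.isinf(w):
        return list(ses)
    out: list[SuctionEvent] = []
    for se in ses:
        if se.start_s >= w:
            continue
        if se.stop_s <= w:
            out.append(se)
            continue
        clipped = [
            replace(e, stop_s=min(e.stop_s, w))
            for e in se.insertions
            if e.start_s < w
        ]
        if clipped:
            out.append(SuctionEvent.from_insertions(clipped))
    return out


def summarize_suction(
    episode: EpisodeRecord,
    ses: Sequence[SuctionEvent],
    config: AnalysisConfig | None = None,
) -> SuctionSummary:
    """Per-newborn counts and durations over the analysed window."""
    config = config or AnalysisConfig()
    window = min(episode.duration_s, config.analysis_window_s)
    total = sum(se.duration_s for se in ses)
    n_ins = sum(len(se.insertions) for se in ses)
    return SuctionSummary(
        n_se=len(ses),
        total_suction_s=total,
        proportion_time_suctioning=total / window if window > 0 else 0.0,
        n_insertions=n_ins,
        n_mouth=sum(se.n_mouth for se in ses),
        n_nose=sum(se.n_nose for se in ses),
        insertions_per_se=n_ins / len(ses) if ses else 0.0,
        any_catheter=any(se.any_catheter for se in ses),
        analyzed_window_s=window,
    )


def _boundaries(timelines: Iterable[Sequence[IntervalEvent]], duration: float) -> list[float]:
    pts = {0.0, duration}
    for tl in timelines:
        for e in tl:
            for t in (e.start_s, e.stop_s):
                if 0.0 < t < duration:
                    pts.add(t)
    return sorted(pts)


def _labels_at(timeline: Sequence[IntervalEvent], t: float) -> frozenset[EventKind]:
    return frozenset(e.kind for e in timeline if e.start_s <= t < e.stop_s)


def agreement_score(
    timeline_a: Sequence[IntervalEvent],
    timeline_b: Sequence[IntervalEvent],
    episode_duration_s: float,
    *,
    method: str = "time",
) -> float:
    """Inter-annotator agreement over ``[0, episode_duration_s)``.

    ``method='time'`` (default): the fraction of the episode during which the
    two annotators' sets of active event kinds coincide; time when both are
    idle counts as agreement.  ``method='events'``: the fraction of events
    (of either annotator) matched by an event of the same kind in the other
    timeline with temporal overlap — an alternative event-count reading of
    "annotations matched".  Symmetric in its two arguments.
    """
    if episode_duration_s <= 0:
        raise ValueError("episode_duration_s must be positive")
    if method == "events":
        return _event_agreement(timeline_a, timeline_b)
    if method != "time":
        raise ValueError(f"unknown agreement method {method!r}")

    agreed = 0.0
    cuts = _boundaries([timeline_a, timeline_b], episode_duration_s)
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = (lo + hi) / 2.0
        if _labels_at(timeline_a, mid) == _labels_at(timeline_b, mid):
            agreed += hi - lo
    return agreed / episode_duration_s


def _event_agreement(a: Sequence[IntervalEvent], b: Sequence[IntervalEvent]) -> float:
    if not a and not b:
        return 1.0

    def matched(x: IntervalEvent, other: Sequence[IntervalEvent]) -> bool:
        return any(
            o.kind is x.kind and o.overlaps(x.start_s, x.stop_s) for o in other
        )

    hits = sum(matched(e, b) for e in a) + sum(matched(e, a) for e in b)
    return hits / (len(a) + len(b))


def flag_for_review(score: float, config: AnalysisConfig | None = None) -> bool:
    """True iff the annotator pair falls below the agreement threshold."""
    config = config or AnalysisConfig()
    return score < config.agreement_threshold
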