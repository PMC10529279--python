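"""Heart-rate response extraction and classification around suction events.

For each suction event (SE), the pre- and post-SE heart rates are the medians
of up to five monitor samples taken within 20 s before the start and after
the end of the event.  The response is then classified, in order of
precedence:

1. *Indeterminate* — pre or post HR missing and no arrhythmia detectable.
2. *Ventilation-cessation fall* — positive-pressure ventilation ended
   immediately (within ``vent_cessation_gap_s``) before the SE and HR fell
   by more than ``vent_cessation_fall_bpm`` (absolute) below the pre-SE HR.
   Treated as a change unrelated to suctioning itself.
3. *Suction-related arrhythmia* — bigeminy (alternating short/long RR
   intervals) in the beat series overlapping the event.
4. *Suction-related fall* — HR below (1 − ``fall_fraction``) of the pre-SE
   HR for at least ``fall_min_samples`` consecutive samples during the SE or
   within 20 s after it, with no ventilation bout overlapping the dip.
5. *No change* otherwise.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from neosuction.config import AnalysisConfig
from neosuction.suction_events import clip_to_window, merge_insertions
from neosuction.types import (
    BeatSeries,
    EpisodeRecord,
    EventKind,
    HRSample,
    IntervalEvent,
    ResponseLabel,
    SEResponse,
    SuctionEvent,
)


def pre_post_hr(
    hr_series: Sequence[HRSample],
    se: SuctionEvent,
    config: AnalysisConfig | None = None,
) -> tuple[Optional[float], Optional[float]]:
    """Median HR before the SE start and after the SE end.

    The pre window is ``[start − hr_window_s, start)``, the post window
    ``(stop, stop + hr_window_s]``.  When more than ``hr_samples_k`` samples
    fall in a window, the ``hr_samples_k`` nearest the event boundary are
    used; with fewer than ``min_hr_samples`` the value is missing (None).
    """
    config = config or AnalysisConfig()
    k, m, w = config.hr_samples_k, config.min_hr_samples, config.hr_window_s

    pre_pool = [s for s in hr_series if se.start_s - w <= s.t_s < se.start_s]
    post_pool = [s for s in hr_series if se.stop_s < s.t_s <= se.stop_s + w]
    pre_sel = pre_pool[-k:]  # time-sorted: last k are nearest the start
    post_sel = post_pool[:k]

    def med(sel: list[HRSample]) -> Optional[float]:
        if len(sel) < m:
            return None
        return float(statistics.median(s.hr_bpm for s in sel))

    return med(pre_sel), med(post_sel)


def _subthreshold_runs(
    samples: Sequence[HRSample], threshold: float, min_run: int
) -> list[tuple[int, int]]:
    """Index ranges [i, j] of maximal runs of consecutive samples strictly
    below ``threshold`` with length >= min_run."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(samples)
    while i < n:
        if samples[i].hr_bpm < threshold:
            j = i
            while j + 1 < n and samples[j + 1].hr_bpm < threshold:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def detect_fall(
    hr_series: Sequence[HRSample],
    se: SuctionEvent,
    pre_hr: float,
    ventilation_events: Sequence[IntervalEvent],
    config: AnalysisConfig | None = None,
) -> tuple[bool, Optional[float], Optional[tuple[float, float]]]:
    """Detect a suction-related relative HR fall.

    Returns ``(flag, max_fall_fraction, fall_interval)``.  The flag is true
    iff at least ``fall_min_samples`` consecutive samples within
    ``[start, stop + hr_window_s]`` lie strictly below
    ``pre_hr * (1 − fall_fraction)`` and no ventilation interval overlaps
    that excursion; the deepest qualifying excursion is reported.  When no
    excursion qualifies, the observed maximum fall fraction over the window
    (possibly negative if HR only rose) is still returned.
    """
    config = config or AnalysisConfig()
    window = [
        s for s in hr_series if se.start_s <= s.t_s <= se.stop_s + config.hr_window_s
    ]
    if not window:
        return False, None, None

    observed = max((pre_hr - s.hr_bpm) / pre_hr for s in window)
    threshold = pre_hr * (1.0 - config.fall_fraction)
    best: Optional[tuple[float, tuple[float, float]]] = None
    for i, j in _subthreshold_runs(window, threshold, config.fall_min_samples):
        t0, t1 = window[i].t_s, window[j].t_s
        if any(v.start_s < t1 and t0 < v.stop_s for v in ventilation_events):
            continue  # concurrent ventilation: not attributable to suction
        depth = max((pre_hr - s.hr_bpm) / pre_hr for s in window[i : j + 1])
        if best is None or depth > best[0]:
            best = (depth, (t0, t1))
    if best is None:
        return False, observed, None
    return True, best[0], best[1]


def _detect_absolute_fall(
    hr_series: Sequence[HRSample],
    se: SuctionEvent,
    pre_hr: float,
    config: AnalysisConfig,
) -> bool:
    """True iff HR drops by more than ``vent_cessation_fall_bpm`` below the
    pre-SE HR for >= fall_min_samples consecutive samples in the SE window."""
    window = [
        s for s in hr_series if se.start_s <= s.t_s <= se.stop_s + config.hr_window_s
    ]
    threshold = pre_hr - config.vent_cessation_fall_bpm
    return bool(_subthreshold_runs(window, threshold, config.fall_min_samples))


def detect_bigeminy(
    beats: Optional[BeatSeries], interval: tuple[float, float]
) -> bool:
    """Detect bigeminy: a run of >= 8 beats intersecting ``interval`` whose
    RR intervals alternate short/long with long/short ratio >= 1.5 for every
    adjacent pair.  Fewer than 8 beats in the interval means insufficient
    evidence (returns False; never raises)."""
    if beats is None:
        return False
    lo, hi = interval
    times = [t for t in beats.beat_times_s if lo <= t <= hi]
    if len(times) < 8:
        return False
    rr = [b - a for a, b in zip(times[:-1], times[1:])]
    need = 6  # 8 beats -> 7 RR intervals -> 6 adjacent pairs

    def pair_ok(a: float, b: float) -> bool:
        return max(a, b) / min(a, b) >= 1.5

    run = 0
    for i in range(len(rr) - 1):
        alternating = (rr[i] < rr[i + 1]) != (rr[i - 1] < rr[i]) if run else True
        if pair_ok(rr[i], rr[i + 1]) and alternating:
            run += 1
            if run >= need:
                return True
        else:
            run = 0
    return False


def classify_se(
    episode: EpisodeRecord,
    se: SuctionEvent,
    config: AnalysisConfig | None = None,
) -> SEResponse:
    """Classify one suction event's HR response (see module docstring)."""
    config = config or AnalysisConfig()
    w = config.hr_window_s
    vents = episode.events_of_kind(EventKind.VENTILATION)
    stims = episode.events_of_kind(EventKind.STIMULATION)

    pre, post = pre_post_hr(episode.hr_series, se, config)
    bigeminy = detect_bigeminy(episode.beats, (se.start_s, se.stop_s + w))
    vent_prior = any(v.overlaps(se.start_s - w, se.start_s) for v in vents)
    stim_prior = any(s.overlaps(se.start_s - w, se.start_s) for s in stims)
    concurrent = any(v.overlaps(se.start_s, se.stop_s + w) for v in vents)

    resp = SEResponse(
        se=se,
        label=ResponseLabel.INDETERMINATE,
        pre_hr_bpm=pre,
        post_hr_bpm=post,
        concurrent_ventilation=concurrent,
        ventilation_prior=vent_prior,
        stimulation_prior=stim_prior,
    )
    if pre is None or post is None:
        if bigeminy:
            resp.label = ResponseLabel.SUCTION_RELATED_ARRHYTHMIA
        return resp

    resp.delta_hr_bpm = post - pre
    flag, observed, _ = detect_fall(episode.hr_series, se, pre, vents, config)
    resp.fall_fraction_observed = observed

    cessation_prior = any(
        0.0 <= se.start_s - v.stop_s <= config.vent_cessation_gap_s for v in vents
    )
    if cessation_prior and _detect_absolute_fall(episode.hr_series, se, pre, config):
        resp.label = ResponseLabel.VENT_CESSATION_FALL
    elif bigeminy:
        resp.label = ResponseLabel.SUCTION_RELATED_ARRHYTHMIA
    elif flag:
        resp.label = ResponseLabel.SUCTION_RELATED_FALL
    else:
        resp.label = ResponseLabel.NO_CHANGE
    return resp


@dataclass
class ClassifiedCohort:
    """Analysis set of classified suction events plus the exclusion log."""

    responses: list[tuple[str, SEResponse]] = field(default_factory=list)
    any_change: dict[str, bool] = field(default_factory=dict)
    excluded_ids: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[ResponseLabel]:
        return [r.label for _, r in self.responses]


def episode_suction_events(
    episode: EpisodeRecord, config: AnalysisConfig | None = None
) -> list[SuctionEvent]:
    """Merge the episode's suction insertions into events and clip them to
    the analysis window."""
    config = config or AnalysisConfig()
    insertions = episode.events_of_kind(EventKind.SUCTION_INSERTION)
    return clip_to_window(merge_insertions(insertions, config), config)


def classify_cohort(
    episodes: Sequence[EpisodeRecord], config: AnalysisConfig | None = None
) -> ClassifiedCohort:
    """Classify every suction event of every episode.

    Episodes whose HR coverage is unusable — every one of their SEs comes
    out indeterminate — are excluded from the analysis set and logged,
    mirroring the restriction to complete heart-rate/ventilation data.
    """
    config = config or AnalysisConfig()
    out = ClassifiedCohort()
    for ep in episodes:
        ses = episode_suction_events(ep, config)
        if not ses:
            continue
        responses = [classify_se(ep, se, config) for se in ses]
        if all(r.label is ResponseLabel.INDETERMINATE for r in responses):
            out.excluded_ids.append(ep.newborn_id)
            out.notes.append(
                f"{ep.newborn_id}: excluded, no usable HR coverage for any of "
                f"{len(ses)} suction event(s)"
            )
            continue
        for r in responses:
            out.responses.append((ep.newborn_id, r))
        out.any_change[ep.newborn_id] = any(r.label.suction_related for r in responses)
    return out
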