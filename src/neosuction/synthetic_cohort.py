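"""Synthetic resuscitation cohorts with planted ground truth.

The study's raw delivery-room recordings cannot be shared, so this module
generates whole cohorts of episodes that emulate them: ~1 Hz heart-rate
streams with dropout, annotation timelines (suction insertions, ventilation
bouts, stimulation, covering), per-newborn covariates, and a 3-day mortality
outcome.  Every suction event carries a known truth label so detection and
classification can be scored exactly:

* *suction-related fall* — the HR trace dips by ``planted_fall_fraction`` of
  the pre-event level starting inside the event and recovering within 40 s,
  with no ventilation bout near the dip;
* *ventilation-cessation fall* — a ventilation bout ends within
  ``vent_cessation_gap_s`` before the event and the HR then drops by at
  least ``planted_vent_fall_bpm``;
* *suction-related arrhythmia* — the beat series switches to bigeminy
  (alternating short/long RR intervals) over the event;
* *no change* otherwise.

The per-event probability of a suction-related change is not flat: it is
weighted by an inverted-U (Gaussian bump) in the pre-event baseline HR,
centred in the normal range, while its cohort-wide marginal stays at the
configured rate.  Mortality is drawn from the truth labels, so the 2x2
mortality analysis downstream can be validated against a known association.

Reproducibility: one seed; each newborn gets an independent counter-derived
substream, so any single episode is identical regardless of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from neosuction.types import (
    AmnioticFluid,
    BeatSeries,
    Device,
    EpisodeRecord,
    EventKind,
    HRSample,
    IntervalEvent,
    Outcome,
    ResponseLabel,
    Sex,
    Site,
)

# Mean of the inverted-U weight over pre-event baseline HRs under default
# settings, estimated once from a large generator run; dividing by it keeps
# the marginal suction-related-change rate at the configured value.
_HR_EFFECT_MEAN_WEIGHT = 0.7168


class GenerationError(RuntimeError):
    """Raised when a scenario cannot produce a valid episode."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Cohort-level generation settings.

    Defaults encode the study conditions: 91% of newborns suctioned, a
    median of 2 suction events per baby (quartiles 1-4), lognormal event
    durations with median 14 s (quartiles 7-23), a mean of 3.6 insertions
    per event, 22% of babies seeing at least one catheter suction, a 12.6%
    marginal rate of suction-related HR changes and 8.1% of
    ventilation-cessation falls per event, and mortality of 64% given at
    least one suction-related change versus 28% otherwise.
    """

    n_newborns: int = 76
    seed: int = 0
    p_suctioned: float = 0.91
    # P(number of SEs = 1..8): median 2, quartiles 1-4
    n_se_probs: tuple[float, ...] = (0.30, 0.25, 0.15, 0.12, 0.08, 0.05, 0.03, 0.02)
    se_duration_log_median_s: float = 14.0
    se_duration_log_sigma: float = 0.88
    insertions_per_se_mean: float = 3.6
    p_catheter: float = 0.22
    p_mouth: float = 0.6
    p_suction_related_change: float = 0.126
    p_vent_cessation_change: float = 0.081
    p_arrhythmia_given_change: float = 1.0 / 17.0
    planted_fall_fraction: float = 0.25
    planted_vent_fall_bpm: float = 40.0
    p_death_given_change: float = 0.64
    p_death_given_no_change: float = 0.28
    hr_noise_sd_bpm: float = 3.0
    p_missing_hr: float = 0.05
    episode_duration_log_median_s: float = 390.0
    episode_duration_log_sigma: float = 0.40
    episode_duration_range_s: tuple[float, float] = (100.0, 1500.0)
    # First observed HR: lognormal fitted to printed quartiles (55, 139) bpm
    first_hr_log_median: float = 87.4
    first_hr_log_sigma: float = 0.687
    # Inverted-U dependence of change probability on pre-event baseline HR
    hr_effect_center_bpm: float = 135.0
    hr_effect_width_bpm: float = 40.0
    hr_effect_mean_weight: float = _HR_EFFECT_MEAN_WEIGHT
    p_female: float = 0.34
    amniotic_probs: tuple[float, float, float] = (0.52, 0.15, 0.33)
    p_stim_prior: float = 0.64
    p_vent_prior_background: float = 0.45

    def __post_init__(self) -> None:
        for name in (
            "p_suctioned", "p_catheter", "p_mouth", "p_suction_related_change",
            "p_vent_cessation_change", "p_arrhythmia_given_change",
            "p_death_given_change", "p_death_given_no_change", "p_missing_hr",
            "p_female", "p_stim_prior", "p_vent_prior_background",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.n_newborns < 1:
            raise ValueError("n_newborns must be >= 1")
        if abs(sum(self.n_se_probs) - 1.0) > 1e-9:
            raise ValueError("n_se_probs must sum to 1")
        if abs(sum(self.amniotic_probs) - 1.0) > 1e-9:
            raise ValueError("amniotic_probs must sum to 1")
        lo, hi = self.episode_duration_range_s
        if not 0 < lo < hi:
            raise ValueError("episode_duration_range_s must be increasing and positive")


@dataclass(frozen=True)
class SETruth:
    """Ground truth for one generated suction event."""

    start_s: float
    stop_s: float
    label: ResponseLabel
    planted_fall_fraction: Optional[float] = None
    planted_fall_bpm: Optional[float] = None
    arrhythmia_interval: Optional[tuple[float, float]] = None
    pre_baseline_bpm: Optional[float] = None


@dataclass
class SyntheticTruth:
    """Planted labels for one episode, for recovery testing."""

    newborn_id: str
    se_truths: list[SETruth] = field(default_factory=list)
    outcome_path: str = "no_change"  # which mortality branch was drawn

    @property
    def any_change(self) -> bool:
        return any(t.label.suction_related for t in self.se_truths)


# ---------------------------------------------------------------------------
# baseline trajectory


class _Baseline:
    """Piecewise-linear HR baseline: first-HR level recovering linearly to a
    plateau in the normal range, constant afterwards."""

    def __init__(self, first_hr: float, plateau: float, t_recover: float):
        self.first_hr = first_hr
        self.plateau = plateau
        self.t_recover = t_recover

    def __call__(self, t):
        frac = np.clip(np.asarray(t, dtype=float) / self.t_recover, 0.0, 1.0)
        return self.first_hr + (self.plateau - self.first_hr) * frac


def _change_probability(h: float, sc: ScenarioConfig) -> float:
    """Per-event suction-related-change probability at pre-event HR ``h``."""
    w = math.exp(-0.5 * ((h - sc.hr_effect_center_bpm) / sc.hr_effect_width_bpm) ** 2)
    return min(0.9, sc.p_suction_related_change * w / sc.hr_effect_mean_weight)


# ---------------------------------------------------------------------------
# episode pieces


def _draw_covariates(sc: ScenarioConfig, rng: np.random.Generator) -> dict:
    first_hr = float(
        np.clip(
            sc.first_hr_log_median * math.exp(rng.normal(0.0, sc.first_hr_log_sigma)),
            25.0, 220.0,
        )
    )
    return {
        "birthweight_g": float(np.clip(rng.normal(3060.0, 560.0), 1000.0, 6000.0)),
        "ga_weeks": float(np.clip(rng.normal(38.1, 1.6), 34.0, 43.0)),
        "sex": Sex.FEMALE if rng.random() < sc.p_female else Sex.MALE,
        "amniotic_fluid": list(AmnioticFluid)[
            int(rng.choice(3, p=sc.amniotic_probs))
        ],
        "first_hr_bpm": first_hr,
    }


def _place_suction_events(
    sc: ScenarioConfig, rng: np.random.Generator, duration: float
) -> list[tuple[float, float]]:
    """Draw SE count and durations, then place them sequentially with at
    least 50 s between events so planted responses never overlap."""
    n_target = 1 + int(rng.choice(len(sc.n_se_probs), p=sc.n_se_probs))
    durations = [
        float(
            np.clip(
                sc.se_duration_log_median_s
                * math.exp(rng.normal(0.0, sc.se_duration_log_sigma)),
                2.0, 120.0,
            )
        )
        for _ in range(n_target)
    ]
    limit_start, limit_stop = 400.0, duration - 60.0
    n = len(durations)
    # drop trailing events until the packed chain fits the usable span
    while n > 0:
        last_latest = min(limit_start, limit_stop - durations[n - 1])
        packed_last = 30.0 + sum(durations[: n - 1]) + 50.0 * (n - 1)
        if packed_last <= last_latest:
            break
        n -= 1
    if n == 0:
        return []
    durations = durations[:n]
    slack = min(limit_start, limit_stop - durations[-1]) - (
        30.0 + sum(durations[:-1]) + 50.0 * (n - 1)
    )
    w = rng.random(n) + 0.05
    extras = w / w.sum() * slack * float(rng.uniform(0.2, 1.0))
    spans: list[tuple[float, float]] = []
    t = 30.0
    for d, extra in zip(durations, extras):
        start = t + float(extra)
        spans.append((start, start + d))
        t = start + d + 50.0
    return spans


def _build_insertions(
    sc: ScenarioConfig,
    rng: np.random.Generator,
    span: tuple[float, float],
    use_catheter: bool,
) -> list[IntervalEvent]:
    """Fill one SE span with insertions separated by pauses of < 5 s."""
    start, stop = span
    d = stop - start
    n_ins = 1 + int(rng.poisson(sc.insertions_per_se_mean - 1.0))
    if n_ins == 1:
        bounds = [(start, stop)]
    else:
        gap_total = min(4.8 * (n_ins - 1), 0.5 * d)
        raw = rng.uniform(0.5, 1.0, size=n_ins - 1)
        gaps = np.minimum(raw / raw.sum() * gap_total, 4.8)
        ins_total = d - float(gaps.sum())
        raw_i = rng.uniform(0.5, 1.0, size=n_ins)
        lens = raw_i / raw_i.sum() * ins_total
        bounds = []
        t = start
        for i in range(n_ins):
            bounds.append((t, t + float(lens[i])))
            t += float(lens[i]) + (float(gaps[i]) if i < n_ins - 1 else 0.0)
        # land exactly on the drawn stop
        bounds[-1] = (bounds[-1][0], stop)
    out = []
    for lo, hi in bounds:
        out.append(
            IntervalEvent(
                kind=EventKind.SUCTION_INSERTION,
                start_s=lo,
                stop_s=hi,
                site=Site.MOUTH if rng.random() < sc.p_mouth else Site.NOSE,
                device=(
                    Device.CATHETER
                    if use_catheter and rng.random() < 0.5
                    else Device.BULB
                ),
            )
        )
    return out


@dataclass
class _Dip:
    """A planted depression of the HR trace.

    The signal blends from the baseline down to an absolute target
    ``level`` (ramp down), holds there, and blends back (ramp up), so the
    nadir is exactly ``level`` regardless of what the baseline does
    meanwhile."""

    t0: float
    level: float
    ramp_down: float
    hold: float
    ramp_up: float

    def blend(self, t: np.ndarray) -> np.ndarray:
        """Mixing weight in [0, 1]: 1 means the signal sits at ``level``."""
        dt = t - self.t0
        down = np.clip(dt / self.ramp_down, 0.0, 1.0)
        up = np.clip((dt - self.ramp_down - self.hold) / self.ramp_up, 0.0, 1.0)
        return down - up


# ---------------------------------------------------------------------------
# public API


def generate_episode(
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    newborn_id: str = "NB0000",
) -> tuple[EpisodeRecord, SyntheticTruth]:
    """Generate one episode plus its planted truth.

    Raises :class:`GenerationError` when the configured episode duration
    cannot accommodate a single suction event.
    """
    sc = scenario
    cov = _draw_covariates(sc, rng)
    lo_d, hi_d = sc.episode_duration_range_s
    duration = float(
        np.clip(
            sc.episode_duration_log_median_s
            * math.exp(rng.normal(0.0, sc.episode_duration_log_sigma)),
            lo_d, hi_d,
        )
    )
    if duration - 60.0 - 2.0 < 30.0:
        raise GenerationError(
            f"episode duration {duration:.0f} s cannot fit one suction event"
        )

    plateau = float(rng.uniform(120.0, 170.0))
    t_recover = float(rng.uniform(180.0, 330.0))
    if cov["first_hr_bpm"] > plateau:
        # tachycardic start settling down: keep the descent slow (<= 0.08
        # bpm/s) so a drifting baseline can never mimic a planted fall
        t_recover = max(t_recover, (cov["first_hr_bpm"] - plateau) / 0.08)
    baseline = _Baseline(
        first_hr=cov["first_hr_bpm"], plateau=plateau, t_recover=t_recover
    )

    suctioned = rng.random() < sc.p_suctioned
    spans = _place_suction_events(sc, rng, duration) if suctioned else []
    use_catheter = rng.random() < sc.p_catheter

    # --- truth labels ------------------------------------------------------
    truths: list[SETruth] = []
    for start, stop in spans:
        h = float(baseline(start))
        u = rng.random()
        p_vent = sc.p_vent_cessation_change
        p_chg = _change_probability(h, sc)
        if u < p_vent and h >= 90.0:
            # an absolute >30 bpm fall is only physiologically representable
            # (and detectable above the HR floor) at a sufficient baseline
            label = ResponseLabel.VENT_CESSATION_FALL
        elif p_vent <= u < p_vent + p_chg:
            label = (
                ResponseLabel.SUCTION_RELATED_ARRHYTHMIA
                if rng.random() < sc.p_arrhythmia_given_change
                else ResponseLabel.SUCTION_RELATED_FALL
            )
        else:
            label = ResponseLabel.NO_CHANGE
        truths.append(SETruth(start, stop, label, pre_baseline_bpm=h))

    # --- events timeline ---------------------------------------------------
    events: list[IntervalEvent] = []
    for (start, stop) in spans:
        events.extend(_build_insertions(sc, rng, (start, stop), use_catheter))
    if use_catheter and spans:
        suctions = [e for e in events if e.kind is EventKind.SUCTION_INSERTION]
        if not any(e.device is Device.CATHETER for e in suctions):
            idx = events.index(suctions[0])
            events[idx] = IntervalEvent(
                kind=EventKind.SUCTION_INSERTION,
                start_s=suctions[0].start_s,
                stop_s=suctions[0].stop_s,
                site=suctions[0].site,
                device=Device.CATHETER,
            )

    dips: list[_Dip] = []
    final_truths: list[SETruth] = []
    for t in truths:
        start, stop = t.start_s, t.stop_s
        if t.label is ResponseLabel.VENT_CESSATION_FALL:
            v_stop = start - float(rng.uniform(1.0, 4.5))
            v_start = v_stop - float(rng.uniform(10.0, 25.0))
            events.append(IntervalEvent(EventKind.VENTILATION, max(0.0, v_start), v_stop))
            t0 = start + float(rng.uniform(0.5, 2.0))
            depth = sc.planted_vent_fall_bpm * float(rng.uniform(1.0, 1.25))
            dips.append(
                _Dip(
                    t0=t0,
                    level=float(baseline(t0)) - depth,
                    ramp_down=3.0,
                    hold=float(rng.uniform(5.0, 9.0)),
                    ramp_up=float(rng.uniform(5.0, 10.0)),
                )
            )
            t = SETruth(start, stop, t.label, planted_fall_bpm=depth,
                        pre_baseline_bpm=t.pre_baseline_bpm)
        elif t.label is ResponseLabel.SUCTION_RELATED_FALL:
            # optional ventilation bout safely before the event (prior flag
            # without triggering the cessation rule or masking the dip)
            if rng.random() < sc.p_vent_prior_background:
                v_stop = start - float(rng.uniform(6.5, 12.0))
                v_start = v_stop - float(rng.uniform(8.0, 15.0))
                events.append(
                    IntervalEvent(EventKind.VENTILATION, max(0.0, v_start), v_stop)
                )
            t0 = start + float(rng.uniform(0.5, max(0.6, min(3.0, stop - start - 0.5))))
            depth = sc.planted_fall_fraction * float(baseline(t0))
            dips.append(
                _Dip(
                    t0=t0,
                    level=float(baseline(t0)) - depth,
                    ramp_down=3.0,
                    hold=float(rng.uniform(5.0, 9.0)),
                    ramp_up=float(rng.uniform(5.0, 10.0)),
                )
            )
            t = SETruth(start, stop, t.label,
                        planted_fall_fraction=sc.planted_fall_fraction,
                        planted_fall_bpm=depth, pre_baseline_bpm=t.pre_baseline_bpm)
        elif t.label is ResponseLabel.SUCTION_RELATED_ARRHYTHMIA:
            t = SETruth(start, stop, t.label,
                        arrhythmia_interval=(start - 1.0, stop + 8.0),
                        pre_baseline_bpm=t.pre_baseline_bpm)
        else:  # NO_CHANGE: ventilation/stimulation priors are harmless here
            if rng.random() < sc.p_vent_prior_background:
                v_stop = start - float(rng.uniform(1.0, 12.0))
                v_start = v_stop - float(rng.uniform(8.0, 15.0))
                events.append(
                    IntervalEvent(EventKind.VENTILATION, max(0.0, v_start), v_stop)
                )
        if rng.random() < sc.p_stim_prior:
            s_stop = start - float(rng.uniform(0.0, 4.0))
            s_start = s_stop - float(rng.uniform(5.0, 14.0))
            events.append(
                IntervalEvent(EventKind.STIMULATION, max(0.0, s_start), s_stop)
            )
        final_truths.append(t)

    if rng.random() < 0.5:
        c0 = float(rng.uniform(0.0, 30.0))
        events.append(IntervalEvent(EventKind.COVERING, c0, c0 + float(rng.uniform(5.0, 20.0))))
    events.sort(key=lambda e: (e.start_s, e.stop_s))

    # --- heart-rate stream -------------------------------------------------
    t_grid = np.arange(5.0, duration, 1.0)
    signal = baseline(t_grid)
    for dip in dips:
        s = dip.blend(t_grid)
        signal = (1.0 - s) * signal + s * dip.level
    noisy = signal + rng.normal(0.0, sc.hr_noise_sd_bpm, size=t_grid.shape)
    noisy = np.clip(noisy, 20.0, 250.0)
    keep = rng.random(t_grid.shape) >= sc.p_missing_hr
    hr_series = [
        HRSample(float(t), float(v)) for t, v in zip(t_grid[keep], noisy[keep])
    ]

    beats = None
    arrhythmia_intervals = [
        t.arrhythmia_interval for t in final_truths if t.arrhythmia_interval
    ]
    if arrhythmia_intervals:
        beats = _generate_beats(baseline, duration, arrhythmia_intervals)

    # --- outcome -----------------------------------------------------------
    any_change = any(t.label.suction_related for t in final_truths)
    p_death = sc.p_death_given_change if any_change else sc.p_death_given_no_change
    died = rng.random() < p_death

    episode = EpisodeRecord(
        newborn_id=newborn_id,
        outcome=Outcome.DIED_3D if died else Outcome.SURVIVED,
        ventilated_flag=True,
        events=events,
        hr_series=hr_series,
        beats=beats,
        **cov,
    )
    truth = SyntheticTruth(
        newborn_id=newborn_id,
        se_truths=final_truths,
        outcome_path="change" if any_change else "no_change",
    )
    return episode, truth


def _generate_beats(
    baseline: _Baseline, duration: float, arrhythmia: Sequence[tuple[float, float]]
) -> BeatSeries:
    """Beat times over the whole episode: RR = 60/HR from the baseline,
    switching to alternating 0.35/0.70 s RR inside arrhythmia intervals."""
    times: list[float] = []
    t = 1.0
    short = True
    while t < duration:
        times.append(t)
        in_arr = any(lo <= t <= hi for lo, hi in arrhythmia)
        if in_arr:
            t += 0.35 if short else 0.70
            short = not short
        else:
            t += 60.0 / float(baseline(t))
            short = True
    return BeatSeries(times)


def generate_cohort(
    scenario: ScenarioConfig,
) -> tuple[list[EpisodeRecord], list[SyntheticTruth]]:
    """Generate ``scenario.n_newborns`` episodes with their truths.

    Each newborn uses an independent substream seeded by
    ``(scenario.seed, index)``, so episode ``i`` is invariant to cohort size.
    """
    episodes, truths = [], []
    for i in range(scenario.n_newborns):
        rng = np.random.default_rng([scenario.seed, i])
        ep, tr = generate_episode(scenario, rng, newborn_id=f"NB{i:04d}")
        episodes.append(ep)
        truths.append(tr)
    return episodes, truths


def generate_second_annotator(
    episode: EpisodeRecord,
    jitter_sd_s: float,
    p_miss: float,
    rng: np.random.Generator,
) -> list[IntervalEvent]:
    """Perturbed copy of the episode's timeline for agreement testing.

    Each boundary is jittered by centred Gaussian noise of SD ``jitter_sd_s``
    and each event is dropped with probability ``p_miss``; at least one event
    is always retained (when the original timeline is non-empty).
    """
    if jitter_sd_s < 0:
        raise ValueError("jitter_sd_s must be >= 0")
    if not 0.0 <= p_miss <= 1.0:
        raise ValueError("p_miss must lie in [0, 1]")
    kept: list[IntervalEvent] = []
    for e in episode.events:
        if rng.random() < p_miss:
            continue
        start = max(0.0, e.start_s + float(rng.normal(0.0, jitter_sd_s)))
        stop = max(start + 0.1, e.stop_s + float(rng.normal(0.0, jitter_sd_s)))
        kept.append(
            IntervalEvent(e.kind, start, stop, site=e.site, device=e.device,
                          obscured=e.obscured)
        )
    if not kept and episode.events:
        e = episode.events[int(rng.integers(len(episode.events)))]
        kept.append(e)
    return sorted(kept, key=lambda e: (e.start_s, e.stop_s))
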