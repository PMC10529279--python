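"""Analysis configuration: every threshold of the pipeline in one place.

The defaults encode the study's fixed cutoffs: a suction event ends after a
pause of more than 5 s, pre/post heart rates are medians of five samples taken
up to 20 s before/after the event, a suction-related fall is a drop of more
than 15% of the pre-event HR, a ventilation-cessation fall is an absolute drop
of more than 30 bpm after positive-pressure ventilation stopped just before
suctioning, suction annotation is restricted to the first 420 s, and annotator
pairs must agree on at least 80% of the episode.  Operations take the config
explicitly so sensitivity analyses can vary any knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and window lengths used throughout the pipeline.

    Parameters
    ----------
    max_pause_s:
        Longest pause (s) between suction insertions that still belongs to
        one suction event; a strictly larger gap splits the event.
    hr_window_s:
        Length (s) of the pre/post windows around a suction event in which
        heart-rate samples are collected.
    hr_samples_k:
        Number of HR samples whose median defines the pre/post HR.
    fall_fraction:
        Relative fall (of pre-event HR) that must be exceeded for a
        suction-related fall; strict inequality.
    vent_cessation_fall_bpm:
        Absolute fall (bpm) that must be exceeded for a fall attributed to
        stopping ventilation immediately before suctioning.
    vent_cessation_gap_s:
        Maximum gap (s) between the end of a ventilation bout and the start
        of the suction event for the cessation rule to apply.
    analysis_window_s:
        Suction annotation window (s) from birth.
    agreement_threshold:
        Minimum inter-annotator agreement proportion; below it the pair is
        flagged for consensus review.
    min_hr_samples:
        Minimum HR samples in a window for the pre/post median to be usable;
        fewer yields a missing value.
    fall_min_samples:
        Consecutive sub-threshold samples required before a dip counts as a
        fall (a single noisy sample is not a fall).
    """

    max_pause_s: float = 5.0
    hr_window_s: float = 20.0
    hr_samples_k: int = 5
    fall_fraction: float = 0.15
    vent_cessation_fall_bpm: float = 30.0
    vent_cessation_gap_s: float = 5.0
    analysis_window_s: float = 420.0
    agreement_threshold: float = 0.80
    min_hr_samples: int = 3
    fall_min_samples: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")
        if not 0 < self.fall_fraction < 1:
            raise ValueError("fall_fraction must lie in (0, 1)")
        if not 0 < self.agreement_threshold <= 1:
            raise ValueError("agreement_threshold must lie in (0, 1]")
        if self.hr_samples_k < self.min_hr_samples:
            raise ValueError("hr_samples_k must be >= min_hr_samples")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
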