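"""Episode file I/O.

One episode is stored as three files named ``<newborn_id>_events.csv``,
``<newborn_id>_hr.csv`` and ``<newborn_id>_episode.json`` in one directory.
Events and HR samples are RFC-4180 CSV (UTF-8, '.' decimal separator);
covariates, outcome and the optional beat-time series live in the JSON file.
Round-trips are lossless: floats are written with ``repr`` precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional

from neosuction.types import (
    AmnioticFluid,
    BeatSeries,
    Device,
    EpisodeRecord,
    EventKind,
    HRSample,
    IntervalEvent,
    Outcome,
    Sex,
    Site,
)

EVENTS_HEADER = ["kind", "start_s", "stop_s", "site", "device", "obscured"]
HR_HEADER = ["t_s", "hr_bpm"]


class ParseError(ValueError):
    """Raised when an episode file cannot be parsed; names file, row, field."""


def _parse_enum(enum_cls, raw: str, *, path: Path, row: int, col: str):
    try:
        return enum_cls(raw)
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise ParseError(
            f"{path.name}, row {row}: unknown {col} {raw!r} (expected one of {valid})"
        ) from None


def _parse_float(raw: str, *, path: Path, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"{path.name}, row {row}: unparseable {col} {raw!r}") from None


def _episode_paths(directory: Path, newborn_id: str) -> dict[str, Path]:
    d = Path(directory)
    return {
        "events": d / f"{newborn_id}_events.csv",
        "hr": d / f"{newborn_id}_hr.csv",
        "episode": d / f"{newborn_id}_episode.json",
    }


def write_episode(episode: EpisodeRecord, directory: str | Path) -> dict[str, Path]:
    """Write one episode's file set; returns the paths written."""
    paths = _episode_paths(Path(directory), episode.newborn_id)
    paths["events"].parent.mkdir(parents=True, exist_ok=True)

    with open(paths["events"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENTS_HEADER)
        for e in episode.events:
            w.writerow(
                [
                    e.kind.value,
                    repr(e.start_s),
                    repr(e.stop_s),
                    e.site.value,
                    e.device.value,
                    int(e.obscured),
                ]
            )
    with open(paths["hr"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(HR_HEADER)
        for s in episode.hr_series:
            w.writerow([repr(s.t_s), repr(s.hr_bpm)])

    meta = {
        "newborn_id": episode.newborn_id,
        "outcome": episode.outcome.value,
        "birthweight_g": episode.birthweight_g,
        "ga_weeks": episode.ga_weeks,
        "sex": episode.sex.value,
        "amniotic_fluid": episode.amniotic_fluid.value,
        "first_hr_bpm": episode.first_hr_bpm,
        "ventilated_flag": episode.ventilated_flag,
        "beat_times_s": list(episode.beats.beat_times_s) if episode.beats else None,
    }
    with open(paths["episode"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return paths


def read_episode(directory: str | Path, newborn_id: str) -> EpisodeRecord:
    """Read the episode file set for ``newborn_id`` from ``directory``."""
    paths = _episode_paths(Path(directory), newborn_id)
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(p)

    events = _read_events_csv(paths["events"])
    hr_series = _read_hr_csv(paths["hr"])

    with open(paths["episode"], encoding="utf-8") as fh:
        meta = json.load(fh)
    try:
        beats = meta.get("beat_times_s")
        return EpisodeRecord(
            newborn_id=str(meta["newborn_id"]),
            outcome=Outcome(meta["outcome"]),
            birthweight_g=float(meta["birthweight_g"]),
            ga_weeks=float(meta["ga_weeks"]),
            sex=Sex(meta["sex"]),
            amniotic_fluid=AmnioticFluid(meta["amniotic_fluid"]),
            first_hr_bpm=float(meta["first_hr_bpm"]),
            ventilated_flag=bool(meta["ventilated_flag"]),
            events=events,
            hr_series=hr_series,
            beats=BeatSeries(beats) if beats else None,
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{paths['episode'].name}: {exc}") from exc


def _read_events_csv(path: Path) -> list[IntervalEvent]:
    events: list[IntervalEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c for c in EVENTS_HEADER if c not in reader.fieldnames
        ]:
            missing = sorted(set(EVENTS_HEADER) - set(reader.fieldnames or []))
            raise ParseError(f"{path.name}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            events.append(
                IntervalEvent(
                    kind=_parse_enum(EventKind, row["kind"], path=path, row=i, col="kind"),
                    start_s=_parse_float(row["start_s"], path=path, row=i, col="start_s"),
                    stop_s=_parse_float(row["stop_s"], path=path, row=i, col="stop_s"),
                    site=_parse_enum(Site, row["site"], path=path, row=i, col="site"),
                    device=_parse_enum(Device, row["device"], path=path, row=i, col="device"),
                    obscured=bool(int(row["obscured"] or 0)),
                )
            )
    return events


def _read_hr_csv(path: Path) -> list[HRSample]:
    samples: list[HRSample] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c for c in HR_HEADER if c not in reader.fieldnames
        ]:
            missing = sorted(set(HR_HEADER) - set(reader.fieldnames or []))
            raise ParseError(f"{path.name}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            samples.append(
                HRSample(
                    t_s=_parse_float(row["t_s"], path=path, row=i, col="t_s"),
                    hr_bpm=_parse_float(row["hr_bpm"], path=path, row=i, col="hr_bpm"),
                )
            )
    return samples


def write_cohort(episodes: Iterable[EpisodeRecord], directory: str | Path) -> list[str]:
    """Write every episode's file set; returns the newborn ids written."""
    ids = []
    for ep in episodes:
        write_episode(ep, directory)
        ids.append(ep.newborn_id)
    return ids


def read_cohort(directory: str | Path) -> list[EpisodeRecord]:
    """Read all episodes found in ``directory`` (by ``*_episode.json``)."""
    d = Path(directory)
    ids = sorted(p.name[: -len("_episode.json")] for p in d.glob("*_episode.json"))
    return [read_episode(d, i) for i in ids]
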