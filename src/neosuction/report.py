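"""End-to-end orchestration and reporting.

``run_pipeline`` chains the stages — synthesise or load a cohort, segment
suction events, classify HR responses, run the statistics — and writes
deterministic JSON outputs plus a Markdown report and a predicted-
probability figure.  A run manifest records config hash, inputs, seed and
exclusion counts; identical inputs reproduce identical JSON outputs byte
for byte (figures excepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import neosuction
from neosuction import resus_stats
from neosuction.config import AnalysisConfig
from neosuction.hr_response import ClassifiedCohort, classify_cohort, episode_suction_events
from neosuction.io import read_cohort, write_cohort
from neosuction.resus_stats import (
    SeparationError,
    build_se_table,
    chi2_2x2,
    fit_rcs_logit,
    mortality_table,
    percent,
    predictor_screen,
    probability_curve,
    summarize,
)
from neosuction.suction_events import summarize_suction
from neosuction.synthetic_cohort import ScenarioConfig, generate_cohort
from neosuction.types import EpisodeRecord, Outcome, ResponseLabel

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: Optional[int]
    n_episodes: int
    n_excluded: int
    input_files: dict[str, str] = field(default_factory=dict)  # name -> sha256
    versions: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value") and not isinstance(obj, (int, float)):
        return obj.value
    return obj


def suction_summaries(
    episodes: Sequence[EpisodeRecord], config: AnalysisConfig
) -> list[dict]:
    out = []
    for ep in episodes:
        ses = episode_suction_events(ep, config)
        s = summarize_suction(ep, ses, config)
        out.append({"newborn_id": ep.newborn_id,
                    "outcome": ep.outcome.value, **dataclasses.asdict(s)})
    return out


def make_report(
    summaries: list[dict],
    classified: ClassifiedCohort,
    episodes: Sequence[EpisodeRecord],
    config: AnalysisConfig,
) -> dict:
    """Assemble the analysis report as a JSON-serialisable dict.

    Sections: per-outcome-group suctioning descriptives, SE response
    classification counts with percentages, 2x2 mortality comparisons with
    Pearson chi-square, and the predictor screen.
    """
    by_group: dict[str, list[dict]] = {"died_3d": [], "survived": []}
    for s in summaries:
        by_group[s["outcome"]].append(s)

    def group_block(rows: list[dict]) -> dict:
        if not rows:
            return {"n": 0}
        suctioned = [r for r in rows if r["n_se"] > 0]
        block = {"n": len(rows),
                 "n_suctioned": len(suctioned),
                 "suctioned_pct": percent(len(suctioned), len(rows))}
        for key in ("n_se", "total_suction_s", "proportion_time_suctioning",
                    "n_insertions", "insertions_per_se"):
            vals = [r[key] for r in suctioned]
            if vals:
                sm = summarize(vals)
                block[key] = {"median": sm.median, "q1": sm.q1, "q3": sm.q3}
        return block

    n_by_label = {lab.value: 0 for lab in ResponseLabel}
    for lab in classified.labels:
        n_by_label[lab.value] += 1
    n_se_total = len(classified.responses)
    label_pct = {
        k: percent(v, n_se_total) if n_se_total else None
        for k, v in n_by_label.items()
    }

    report: dict = {
        "config": config.to_dict(),
        "groups": {g: group_block(rows) for g, rows in by_group.items()},
        "n_se_analyzed": n_se_total,
        "n_newborns_analyzed": len(classified.any_change),
        "n_excluded": len(classified.excluded_ids),
        "labels": {"counts": n_by_label, "percentages": label_pct},
    }

    # --- 2x2 mortality: suction-related change vs not ---------------------
    table = mortality_table(classified, episodes)
    if table[0].sum() == 0 or table[1].sum() == 0:
        report["mortality"] = {"note": "not estimable: a change group is empty"}
    else:
        stat, p = chi2_2x2(table)
        report["mortality"] = {
            "table": table.tolist(),
            "died_pct_with_change": percent(int(table[0, 0]), int(table[0].sum())),
            "died_pct_without_change": percent(int(table[1, 0]), int(table[1].sum())),
            "chi2": stat,
            "p": p,
        }

    # --- 2x2 mortality: ventilation-cessation fall vs not ------------------
    by_id = {ep.newborn_id: ep for ep in episodes}
    unrelated: dict[str, bool] = {nid: False for nid in classified.any_change}
    for nid, r in classified.responses:
        if r.label is ResponseLabel.VENT_CESSATION_FALL:
            unrelated[nid] = True
    t2 = np.zeros((2, 2), dtype=int)
    for nid, flag in unrelated.items():
        died = by_id[nid].outcome is Outcome.DIED_3D
        t2[0 if flag else 1, 0 if died else 1] += 1
    if t2[0].sum() == 0 or t2[1].sum() == 0:
        report["mortality_unrelated"] = {"note": "not estimable: a group is empty"}
    else:
        stat, p = chi2_2x2(t2)
        report["mortality_unrelated"] = {
            "table": t2.tolist(),
            "died_pct_with_unrelated": percent(int(t2[0, 0]), int(t2[0].sum())),
            "died_pct_without_unrelated": percent(int(t2[1, 0]), int(t2[1].sum())),
            "chi2": stat,
            "p": p,
        }

    # --- predictor screen ---------------------------------------------------
    try:
        screen = predictor_screen(classified, episodes)
        report["predictor_screen"] = [_jsonable(r) for r in screen]
    except (SeparationError, ValueError) as exc:
        report["predictor_screen"] = {"note": f"not estimable: {exc}"}
    return report


def render_markdown(report: dict) -> str:
    """Markdown rendering of the report dict."""
    lines = ["# Suction-event analysis report", ""]
    lines.append(f"Analyzed suction events: {report['n_se_analyzed']} in "
                 f"{report['n_newborns_analyzed']} newborns "
                 f"({report['n_excluded']} excluded for unusable HR data).")
    lines.append("")
    lines.append("## Response classification")
    lines.append("")
    lines.append("| label | count | % |")
    lines.append("|---|---|---|")
    for k, v in report["labels"]["counts"].items():
        pct = report["labels"]["percentages"][k]
        lines.append(f"| {k} | {v} | {pct if pct is not None else '-'} |")
    lines.append("")
    lines.append("## Mortality by suction-related HR change")
    lines.append("")
    m = report["mortality"]
    if "note" in m:
        lines.append(m["note"])
    else:
        lines.append(f"Died with change: {m['died_pct_with_change']}%; "
                     f"without change: {m['died_pct_without_change']}% "
                     f"(chi-square {m['chi2']:.2f}, p = {m['p']:.3f}).")
    lines.append("")
    lines.append("## Predictor screen")
    lines.append("")
    screen = report["predictor_screen"]
    if isinstance(screen, dict):
        lines.append(screen.get("note", ""))
    else:
        lines.append("| predictor | level | OR | 95% CI | p | p_nonlinear |")
        lines.append("|---|---|---|---|---|---|")
        for r in screen:
            or_ = f"{r['odds_ratio']:.2f}" if r.get("odds_ratio") else "-"
            ci = (f"{r['ci95'][0]:.2f}-{r['ci95'][1]:.2f}" if r.get("ci95") else "-")
            p = f"{r['p_overall']:.3f}" if r.get("p_overall") is not None else "-"
            pnl = (f"{r['p_nonlinear']:.3f}"
                   if r.get("p_nonlinear") is not None else "-")
            lines.append(f"| {r['label']} | {r.get('level') or '-'} | {or_} | "
                         f"{ci} | {p} | {pnl} |")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    out_dir: str | Path,
    input_dir: Optional[str | Path] = None,
    scenario: Optional[ScenarioConfig] = None,
    config: Optional[AnalysisConfig] = None,
    make_figures: bool = True,
) -> RunManifest:
    """Run synth/load -> events -> classify -> stats and write all outputs."""
    if (input_dir is None) == (scenario is None):
        raise ValueError("provide exactly one of input_dir or scenario")
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if scenario is not None:
        episodes, truths = generate_cohort(scenario)
        ep_dir = out / "episodes"
        write_cohort(episodes, ep_dir)
        truth_payload = [_jsonable(t) for t in truths]
        (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    else:
        episodes = read_cohort(input_dir)
        if not episodes:
            raise FileNotFoundError(f"no episodes found in {input_dir}")

    summaries = suction_summaries(episodes, config)
    classified = classify_cohort(episodes, config)
    for note in classified.notes:
        logger.info("exclusion: %s", note)

    report = make_report(summaries, classified, episodes, config)

    responses_payload = [
        {"newborn_id": nid, **_jsonable(r)} for nid, r in classified.responses
    ]
    (out / "summaries.json").write_text(json.dumps(_jsonable(summaries), indent=1))
    (out / "responses.json").write_text(json.dumps(responses_payload, indent=1))
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    (out / "report.md").write_text(render_markdown(report))

    if make_figures:
        _write_probability_figure(classified, episodes, out / "prob_curve.png")

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        seed=scenario.seed if scenario is not None else None,
        n_episodes=len(episodes),
        n_excluded=len(classified.excluded_ids),
        input_files={
            p.name: _sha256(p) for p in sorted(out.glob("*.json"))
        },
        versions={"neosuction": neosuction.__version__, "numpy": np.__version__},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    return manifest


def _write_probability_figure(
    classified: ClassifiedCohort, episodes: Sequence[EpisodeRecord], path: Path
) -> None:
    """Predicted probability of a suction-related change vs pre-SE HR,
    with the 95% confidence band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = build_se_table(classified, episodes).dropna(subset=["pre_hr_bpm"])
    if df.empty or df["y"].nunique() < 2 or df["pre_hr_bpm"].nunique() < 10:
        logger.warning("probability figure skipped: insufficient data")
        return
    try:
        fit = fit_rcs_logit(df["y"].to_numpy(), df["pre_hr_bpm"].to_numpy(),
                            df["newborn_id"].to_numpy())
    except (SeparationError, ValueError) as exc:
        logger.warning("probability figure skipped: %s", exc)
        return
    grid = np.linspace(df["pre_hr_bpm"].min(), df["pre_hr_bpm"].max(), 200)
    curve = probability_curve(fit, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(curve.x, curve.lower, curve.upper, alpha=0.3, color="grey")
    ax.plot(curve.x, curve.p, color="C0")
    ax.set_xlabel("HR prior to suction event (bpm)")
    ax.set_ylabel("P(suction-related HR change)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
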