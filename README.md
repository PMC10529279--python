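# neosuction

Analysis pipeline for **suctioning during newborn resuscitation**: it turns
delivery-room annotation timelines and monitor-derived heart-rate (HR)
streams into suction events, classifies each event's HR response, and runs
the cohort statistics used to relate those responses to 3-day mortality and
newborn characteristics.

Intended users are research teams working with delivery-room video
annotations (e.g. ELAN-style interval tiers) plus dry-electrode ECG heart
rate — typically resuscitation studies in low-resource settings — who need a
reproducible, scriptable version of the following analysis:

1. **Suction events (SE).** A suction event is a maximal run of suction
   insertions (bulb or catheter, mouth or nose) with no pause greater than
   5 s between insertions; a pause > 5 s splits the run into two events.
   Events are analysed within the first 420 s after birth. Inter-annotator
   agreement of two independent timelines is scored as time-in-agreement and
   flagged below 80%.
2. **HR response per event.** Pre- and post-event HR are medians of up to
   five ~1 Hz samples within 20 s before the start / after the end of the
   event. An event is classified, in order of precedence, as
   *ventilation-cessation fall* (positive-pressure ventilation ended ≤ 5 s
   before the event and HR fell > 30 bpm — a change unrelated to suctioning
   itself), *suction-related arrhythmia* (bigeminy: alternating short/long
   RR intervals, ratio ≥ 1.5), *suction-related fall* (HR below
   (1 − 0.15) × pre-event HR for ≥ 2 consecutive samples during the event or
   within 20 s after it, with no concurrent ventilation), *no change*, or
   *indeterminate* when HR coverage is unusable.
3. **Statistics.** Per-baby descriptives (summaries of individual means over
   repeated events), one-sample Wilcoxon signed-rank for ΔHR, Pearson
   chi-square (df = 1, no continuity correction) on 2×2 mortality tables,
   and logistic regression of suction-related change on predictors with a
   cluster-robust sandwich covariance (clusters = newborns, small-sample
   factor G/(G−1)). Continuous predictors enter as restricted cubic splines
   with 3 knots at the 0.10/0.50/0.90 quantiles,

   R(x) = [(x−t₁)₊³ − (x−t₂)₊³ (t₃−t₁)/(t₃−t₂) + (x−t₃)₊³ (t₂−t₁)/(t₃−t₂)] / (t₃−t₁)²,

   with Wald tests of the overall (2 df) and non-linear (1 df) effect;
   linearity is assumed when the non-linearity p > 0.05, in which case odds
   ratios with 95% CI are reported per conventional unit scales (per 100 g
   birthweight, per 10 bpm HR, per 10 s time). Otherwise a
   predicted-probability curve with a 95% delta-method confidence band is
   produced.

Because the underlying recordings cannot be shared, the package ships a
**synthetic-cohort generator** with planted ground truth (HR falls,
ventilation-cessation falls, bigeminy episodes, and a mortality association)
so the whole pipeline is testable end to end.

## Worked example

```bash
neosuction run --n 76 --seed 1 --out out/
```

generates a 76-newborn synthetic cohort, segments and classifies every
suction event and writes `summaries.json`, `responses.json`, `report.json`,
`report.md`, a probability-curve figure and a run manifest. The same from
Python:

```python
from neosuction import ScenarioConfig, generate_cohort, classify_cohort
from neosuction.resus_stats import build_se_table, fit_rcs_logit, wald_nonlinear

episodes, truths = generate_cohort(ScenarioConfig(n_newborns=76, seed=1))
classified = classify_cohort(episodes)
df = build_se_table(classified, episodes)
fit = fit_rcs_logit(df["y"], df["pre_hr_bpm"], df["newborn_id"])
print(round(wald_nonlinear(fit).p, 3))    # -> 0.039
```

On this cohort the run reports (`out/report.json` / `out/report.md`):

```
Analyzed suction events: 157 in 70 newborns (0 excluded for unusable HR data).
SUCTION_RELATED_FALL 11 (7.0%) | SUCTION_RELATED_ARRHYTHMIA 2 (1.3%)
VENT_CESSATION_FALL 11 (7.0%) | NO_CHANGE 133 (84.7%)
Died with change: 66.7%; without change: 19.0% (chi-square 11.44, p = 0.001)
```

i.e. about 8% of this replicate's suction events show a suction-related HR
change (fall or bigeminy), a further 7% show a fall attributable to stopping
ventilation just before suctioning, and mortality is much higher among
newborns with at least one suction-related change — the association planted
by the generator and recovered by the pipeline. In the predictor screen,
pre-event HR is the clearly significant predictor (overall Wald p = 0.019,
non-linearity p = 0.039), with the fitted probability curve peaking in the
normal HR range (~100–170 bpm).

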