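# Methods

This note documents the models, rules and numerical choices implemented in
`neosuction`, and what the synthetic-data experiments do and do not show.

## Event segmentation

Suction insertions are annotated intervals in seconds since birth; intervals
are half-open `[start, stop)` so adjacent events do not overlap. A *suction
event* (SE) is a maximal run of insertions in which every pause (next start
minus previous stop) is at most `max_pause_s` (default 5 s); a strictly
longer pause splits the run. Overlapping insertions from one annotator are
an annotation slip and are merged into one insertion with a logged warning.
Suction analysis is restricted to `[0, analysis_window_s)` (default 420 s);
an event straddling the boundary is truncated rather than dropped, because
partial visibility inside the window is the faithful reading of a windowed
annotation protocol.

Inter-annotator agreement is the fraction of the episode during which the
two annotators' sets of active event kinds coincide (both idle counts as
agreement). The 80% threshold flags a pair for consensus review. An
event-count-based alternative (`method="events"`) is exposed because the
choice of metric is a genuinely open question for interval annotations; the
time-based metric is the default since it is the only one fully determined
by the interval data.

## HR response classification

Pre/post-SE heart rates are medians of up to `hr_samples_k = 5` monitor
samples in `[start − 20 s, start)` and `(stop, stop + 20 s]`. When a window
holds more than five samples, the five nearest the event boundary are used —
the most recent physiology. With fewer than `min_hr_samples = 3` the value
is missing and the event is indeterminate unless an arrhythmia is
detectable from the beat series.

A *fall* requires at least `fall_min_samples = 2` consecutive samples below
threshold: a single noisy sample is not a fall. The suction-related rule is
relative — strictly below `(1 − 0.15) ×` pre-SE HR, within
`[start, stop + 20 s]`, with no ventilation bout overlapping the excursion —
while the ventilation-cessation rule is absolute — more than 30 bpm below
the pre-SE HR, applicable only when a ventilation bout ended within
`vent_cessation_gap_s = 5 s` before the event. Each rule uses the form
(fraction vs absolute bpm) in which its cutoff is conventionally stated.
The cessation check precedes the suction-related checks because such falls
are attributable to interrupting ventilation, not to suction, and must not
inflate the suction-related count. Arrhythmia detection is restricted to
bigeminy: a run of ≥ 8 beats whose RR intervals alternate short/long with a
ratio ≥ 1.5 for every adjacent pair; with fewer than 8 beats in the window
the evidence is insufficient and the flag stays false.

Episodes in which *every* SE is indeterminate are excluded from the
analysis set (with a logged reason), mirroring the restriction of such
analyses to episodes with complete HR/ventilation data.

## Statistics

* **Descriptives** first reduce repeated observations to per-baby means.
  Quartiles use linear interpolation (type 7); printed quartiles depend on
  this convention.
* **Wilcoxon signed-rank** (one-sample, two-sided): zeros discarded; exact
  p by enumeration of all 2ⁿ sign assignments when n ≤ 20 with no tied
  absolute differences (two-sided p = 2·min(tails), capped at 1); otherwise
  the normal approximation with midranks, tie correction and continuity
  correction.
* **2×2 chi-square**: Pearson, df = 1, *without* Yates continuity
  correction — the variant validated by recovering the printed mortality
  p-values (0.014 and 0.043) from the corresponding tables; with the
  correction both p-values are larger and do not match.
* **Restricted cubic splines**: 3 knots at the 0.10/0.50/0.90 empirical
  quantiles (the common "default location" convention for three knots;
  configurable). The restricted truncated-power basis is linear beyond the
  outer knots and C² everywhere; both properties are tested numerically.
* **Cluster-robust logistic regression** (`ClusterLogit`): maximum
  likelihood via IRLS (statsmodels GLM-Binomial, convergence checked on the
  score norm), covariance `B (Σ_g s_g s_gᵀ) B · G/(G−1)` with bread
  `B = (XᵀWX)⁻¹`. The plain G/(G−1) small-sample factor is used (documented
  choice); Stata-style implementations additionally multiply by
  (n−1)/(n−k), a ≤ 0.5% difference at this package's typical sizes. Point
  estimates are identical with and without clustering. Perfect separation
  is detected (zero deviance, diverging coefficients, or degenerate fitted
  probabilities) and raised as an explicit error rather than returning
  meaningless standard errors. CIs use z = 1.96, matching large-sample
  sandwich practice.
* **Predictor screen**: categorical predictors get a cluster-robust OR vs
  the reference level; continuous predictors get the spline fit with
  overall (2 df) and non-linearity (1 df) Wald tests, falling back to a
  linear fit with OR per conventional scale (100 g, 10 bpm, 10 s) when the
  non-linearity p > 0.05. Amniotic fluid pools thick meconium with
  blood-stained, as is conventional for sparse categories in this setting.
* **Probability curves**: inverse-logit of the linear predictor with a
  95% delta-method band on the linear predictor; grid points outside the
  fitted range are computed but flagged as extrapolation.

## Synthetic cohort generator

The generator emulates the study conditions: 91% of newborns suctioned; SE
counts per baby with median 2 (quartiles 1–4, support 1–8); lognormal SE
durations (median 14 s, σ = 0.88, matching quartiles 7–23 s); a mean of 3.6
insertions per SE with intra-event pauses < 5 s; 22% of babies with at
least one catheter insertion; episode durations lognormal with median
390 s clipped to 100–1500 s; first observed HR lognormal fitted to the
printed quartiles (55, 139) bpm — a lognormal cannot simultaneously match
the printed median 77, so the quartile fit is used; Gaussian HR noise
(SD 3 bpm, a realistic dry-electrode figure) and 5% missing samples at
random, which exercises the minimum-sample rule.

The HR baseline is piecewise linear from the first observed HR toward a
plateau in 120–170 bpm reached within 3–5.5 min. A tachycardic start
(first HR above the plateau) settles at most 0.08 bpm/s so baseline drift
can never mimic a planted fall. Planted responses are *level-blend* dips:
the trace ramps to an absolute target level (25% below the local baseline
for suction-related falls; ≥ 40 bpm below for ventilation-cessation falls),
holds 5–9 s and recovers within 40 s, guaranteeing at least two consecutive
sub-threshold samples in the noiseless signal for every admissible
parameter draw — the basis of the sensitivity-1.0 recovery test. SEs are
placed ≥ 50 s apart so responses never overlap. Bigeminy truth plants an
alternating 0.35/0.70 s RR segment over the event inside a full-episode
beat series derived from the baseline (RR = 60/HR).

The per-SE probability of a suction-related change is not flat: it is the
configured marginal rate (12.6%) times an inverted-U Gaussian weight in the
pre-SE baseline HR (centre 135 bpm, width 40 bpm), divided by the mean
weight under default settings (0.7168, estimated once from a large
generator run and frozen). This plants the "changes are most likely at
normal pre-suction HR" dependence that the spline regression is expected to
recover, while the cohort-wide marginal stays calibrated. Ventilation-
cessation truth (8.1% per SE) is only assigned when the local baseline is
≥ 90 bpm, since a > 30 bpm absolute fall is neither physiological nor
detectable above the HR floor below that; the realized cessation rate is
therefore slightly below the configured value (≈ 7%). Mortality is drawn
from the *truth* labels (64% given ≥ 1 suction-related change, 28%
otherwise), so the downstream 2×2 analysis can be validated against a known
association.

Reproducibility: one cohort seed; newborn *i* uses the counter-derived
substream `(seed, i)`, so any single episode is byte-identical regardless
of cohort size.

### What the synthetic experiments show — and don't

Passing recovery tests show the *rules are implemented correctly* and that
the statistical layer recovers planted effects at realistic noise levels.
They do not show field performance on real dry-electrode traces: real
signals have autocorrelated artifacts, HR-dependent noise, rhythm changes
other than bigeminy, and annotation errors beyond boundary jitter and
missed events. Planted falls recover within 40 s by design (to keep per-SE
truth unambiguous), so the synthetic post-pre ΔHR in changed events is
near zero rather than strongly negative as in sustained real-world falls;
signal-level summary statistics of the synthetic cohort are therefore not
comparable to observed cohort values and are not used as checks.

### Null predictors and type-I calibration

Sex, amniotic fluid, device, ventilation/stimulation priors, gestational
age, birthweight and SE duration are generated independently of the change
mechanism and serve as planted nulls. First observed HR and time from birth
to the SE are *not* null: through the recovering baseline both are
correlated with pre-SE HR (as in real physiology), so they are excluded
from the type-I calibration. The null rejection-rate band used in testing
([0.01, 0.12] at α = 0.05, fixed a priori) allows for the documented
anti-conservatism of small-G sandwich Wald tests and for correlation of
tests within a replicate, while still detecting systematic inflation.

## Problem sizes used in tests

Recovery and calibration tests run on cohorts of 100–500 newborns
(≈ 200–1200 suction events) with fixed seeds; the type-I calibration uses
50 replicates of the 76-newborn default scenario; brute-force oracles
(interval clustering, fall-window scanning, Wilcoxon sign enumeration) run
on inputs small enough for exhaustive computation. These sizes give the
binomial/oracle comparisons stated in the tests sharp expected behaviour
while keeping the default suite fast.

## Known limitations

* Agreement scoring compares event *kinds* only; site/device mismatches on
  overlapping suction annotations are not penalised.
* Bigeminy is the only arrhythmia detected; the classifier will label other
  rhythm disturbances as falls or no-change depending on the displayed HR.
* The "immediately prior" ventilation-cessation window is operationalised
  as 5 s (consistent with the pause convention); the literal reading of
  "immediately" is not defined in interval data.
* Exact Wilcoxon enumeration is O(2ⁿ) and intentionally capped at n = 20.
* The generator's outcome model is a two-level Bernoulli on the truth
  labels; it does not model confounding between covariates and mortality.
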