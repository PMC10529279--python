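"""Statistical layer for suction-event cohorts.

Implements the analyses applied to classified suction events: per-baby
descriptives (summaries of individual means over repeated events), the
one-sample Wilcoxon signed-rank test for HR changes, Pearson chi-square on
2x2 mortality tables, and logistic regression over suction events with
standard errors robust to clustering within newborns — including restricted
cubic splines (3 knots at the 0.10/0.50/0.90 quantiles) with Wald tests of
the overall and non-linear effect, odds ratios per scaled units, and
predicted-probability curves with 95% confidence bands.

The regression core is the :class:`ClusterLogit` estimator, a
scikit-learn-style class (``fit`` / ``predict_proba`` / ``get_params``)
whose fitted covariance is the cluster sandwich

    V = B (sum_g s_g s_g') B * G/(G-1),     B = (X'WX)^(-1),

with ``s_g`` the summed score contributions of cluster ``g`` and ``G`` the
number of clusters.  Point estimates are the ordinary maximum-likelihood
fit; clustering affects the covariance only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from neosuction.config import AnalysisConfig
from neosuction.hr_response import ClassifiedCohort
from neosuction.types import (
    AmnioticFluid,
    EpisodeRecord,
    Outcome,
    ResponseLabel,
    Sex,
)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


# ---------------------------------------------------------------------------
# descriptives


@dataclass(frozen=True)
class Summary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


def summarize(
    values: Sequence[float], repeated_by_id: Optional[Sequence] = None
) -> Summary:
    """Summary statistics; with grouping ids, each id is first reduced to
    its mean so repeated observations per newborn do not dominate.

    Quartiles use linear interpolation (the type-7 convention), which the
    printed quartiles depend on.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("summarize requires at least one value")
    if repeated_by_id is not None:
        if len(repeated_by_id) != x.size:
            raise ValueError("grouping ids must match values in length")
        x = pd.Series(x).groupby(list(repeated_by_id)).mean().to_numpy()
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return Summary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """Percentage of ``count`` out of ``denominator``, rounded for report
    display (one decimal by default)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / denominator, decimals)


# ---------------------------------------------------------------------------
# hypothesis tests


def wilcoxon_signed_rank(x: Sequence[float], mu0: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value against ``mu0``.

    Differences exactly equal to ``mu0`` are discarded.  With n <= 20 and no
    tied absolute differences the p-value is exact, by enumeration of all
    2^n sign assignments; otherwise the normal approximation with midranks,
    tie correction and continuity correction is used.
    """
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all values equal mu0; Wilcoxon p set to 1", stacklevel=2)
        return 1.0
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    has_ties = np.unique(absd).size < n
    w_plus = float(ranks[d > 0].sum())
    if n <= 20 and not has_ties:
        return _wilcoxon_exact_p(ranks, w_plus)
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return float(res.pvalue)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p: 2*min(P(W<=w), P(W>=w)) over all sign patterns."""
    n = ranks.size
    # distribution of W+ over 2^n equiprobable sign assignments
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    w = signs @ ranks
    p_low = float(np.mean(w <= w_plus + 1e-9))
    p_high = float(np.mean(w >= w_plus - 1e-9))
    return min(1.0, 2.0 * min(p_low, p_high))


def chi2_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Returns ``(statistic, p)``.  A zero margin makes the statistic
    undefined; an exact test is suggested instead.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table; use an exact test instead")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def likelihood_ratio_p(loglike_full: float, loglike_reduced: float, df: int) -> float:
    """Likelihood-ratio-test p-value for nested model fits."""
    lr = 2.0 * (loglike_full - loglike_reduced)
    return float(sps.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_basis(x: Sequence[float], knots: Sequence[float]) -> np.ndarray:
    """Restricted-cubic-spline basis with three knots: columns (x, R(x)).

    R uses the restricted truncated-power form, linear beyond the outer
    knots:

        R(x) = [(x-t1)+^3 - (x-t2)+^3 (t3-t1)/(t3-t2)
                + (x-t3)+^3 (t2-t1)/(t3-t2)] / (t3-t1)^2
    """
    t1, t2, t3 = (float(k) for k in knots)
    if not t1 < t2 < t3:
        raise ValueError("knots must be strictly increasing and distinct")
    xv = np.asarray(x, dtype=float)

    def p3(v):
        return np.clip(v, 0.0, None) ** 3

    r = (
        p3(xv - t1)
        - p3(xv - t2) * (t3 - t1) / (t3 - t2)
        + p3(xv - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([xv, r])


def default_knots(x: Sequence[float]) -> tuple[float, float, float]:
    """Default 3-knot locations: the 0.10, 0.50 and 0.90 quantiles."""
    xv = np.asarray(x, dtype=float)
    if np.unique(xv).size < 10:
        raise ValueError("need at least 10 distinct values to place default knots")
    q = np.quantile(xv, [0.10, 0.50, 0.90])
    return float(q[0]), float(q[1]), float(q[2])


# ---------------------------------------------------------------------------
# cluster-robust logistic regression


class ClusterLogit:
    """Logistic regression with a cluster-robust sandwich covariance.

    scikit-learn-style estimator: construct with hyper-parameters, call
    :meth:`fit` with a design matrix (intercept added automatically unless
    ``add_intercept=False``), read fitted attributes with trailing
    underscores.  With every observation its own cluster the covariance
    reduces to the heteroskedasticity-robust (HC0) form times the
    small-sample factor G/(G-1).
    """

    def __init__(self, add_intercept: bool = True, max_iter: int = 200,
                 tol: float = 1e-10):
        self.add_intercept = add_intercept
        self.max_iter = max_iter
        self.tol = tol

    # minimal get/set_params so the class composes with sklearn utilities
    def get_params(self, deep: bool = True) -> dict:
        return {"add_intercept": self.add_intercept, "max_iter": self.max_iter,
                "tol": self.tol}

    def set_params(self, **params) -> "ClusterLogit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _design(self, X) -> np.ndarray:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        if self.add_intercept:
            Xa = np.column_stack([np.ones(Xa.shape[0]), Xa])
        return Xa

    def fit(self, X, y, groups=None) -> "ClusterLogit":
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if y.min() == y.max():
            raise SeparationError("outcome is constant; model not estimable")
        Xd = self._design(X)
        n, p = Xd.shape
        if np.linalg.matrix_rank(Xd) < p:
            raise ValueError("design matrix is rank deficient")
        if groups is None:
            groups = np.arange(n)
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups must match X in length")
        uniq = np.unique(groups)
        if uniq.size < 2:
            raise ValueError("need at least 2 clusters")

        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(
                    maxiter=self.max_iter, tol=self.tol
                )
        except PerfectSeparationError as exc:
            raise SeparationError(str(exc)) from exc
        beta = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.fittedvalues, dtype=float)
        score = Xd * (y - mu)[:, None]
        grad_norm = float(np.linalg.norm(score.sum(axis=0)))
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            raise SeparationError("diverging coefficients indicate perfect separation")
        if res.deviance < 1e-6:
            raise SeparationError("zero deviance: data are perfectly separated")
        eps = np.min(np.minimum(mu, 1 - mu))
        if eps < 1e-10 and grad_norm > 1e-4:
            raise SeparationError("fitted probabilities at 0/1: perfect separation")

        bread = np.asarray(res.cov_params(), dtype=float)
        meat = np.zeros((p, p))
        for g in uniq:
            s_g = score[groups == g].sum(axis=0)
            meat += np.outer(s_g, s_g)
        g_count = uniq.size
        cov = bread @ meat @ bread * (g_count / (g_count - 1.0))
        cov = (cov + cov.T) / 2.0

        self.params_ = beta
        self.cov_params_ = cov
        self.cov_mle_ = bread
        self.n_obs_ = n
        self.n_clusters_ = int(g_count)
        self.converged_ = bool(res.converged) and grad_norm < 1e-6
        self.loglike_ = float(res.llf)
        return self

    def predict_proba(self, X) -> np.ndarray:
        eta = self._design(X) @ self.params_
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def intercept_(self) -> float:
        return float(self.params_[0]) if self.add_intercept else 0.0

    @property
    def coef_(self) -> np.ndarray:
        return self.params_[1:] if self.add_intercept else self.params_


@dataclass
class SplineLogitFit:
    """Fitted cluster-robust (spline) logistic regression."""

    coefficients: np.ndarray
    covariance: np.ndarray
    knots: Optional[tuple[float, float, float]]
    n_obs: int
    n_clusters: int
    converged: bool
    loglike: float = math.nan
    x_range: Optional[tuple[float, float]] = None
    names: tuple[str, ...] = ()


def fit_logit_cluster(y, X, cluster_ids, names: Sequence[str] = ()) -> SplineLogitFit:
    """Cluster-robust logistic fit of ``y`` on ``X`` (intercept added).

    ``X`` may be empty (n x 0) for an intercept-only model.
    """
    if X is None:
        Xa = np.zeros((len(np.asarray(y)), 0))
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
    est = ClusterLogit().fit(Xa, y, groups=cluster_ids)
    return SplineLogitFit(
        coefficients=est.params_,
        covariance=est.cov_params_,
        knots=None,
        n_obs=est.n_obs_,
        n_clusters=est.n_clusters_,
        converged=est.converged_,
        loglike=est.loglike_,
        names=("intercept", *names) if names else (),
    )


def fit_rcs_logit(
    y, x, cluster_ids, knots: Optional[Sequence[float]] = None
) -> SplineLogitFit:
    """Restricted-cubic-spline logistic fit of ``y`` on one predictor.

    Design is ``[1, x, R(x)]`` with 3 knots at the default quantile
    locations unless given.
    """
    xv = np.asarray(x, dtype=float)
    kn = tuple(knots) if knots is not None else default_knots(xv)
    fit = fit_logit_cluster(y, rcs_basis(xv, kn), cluster_ids,
                            names=("linear", "nonlinear"))
    fit.knots = (float(kn[0]), float(kn[1]), float(kn[2]))
    fit.x_range = (float(xv.min()), float(xv.max()))
    return fit


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p: float


def wald(fit: SplineLogitFit, coefficient_subset: Sequence[int]) -> WaldResult:
    """Wald chi-square test that the given coefficients are jointly zero."""
    idx = list(coefficient_subset)
    if not idx:
        raise ValueError("coefficient subset must be non-empty")
    b = fit.coefficients[idx]
    V = fit.covariance[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance for requested subset") from exc
    if stat < 0:
        raise ValueError("covariance for requested subset is not positive definite")
    df = len(idx)
    return WaldResult(statistic=stat, df=df, p=float(sps.chi2.sf(stat, df)))


def wald_overall(fit: SplineLogitFit) -> WaldResult:
    """Overall effect of the spline predictor: both spline coefficients."""
    return wald(fit, [1, 2])


def wald_nonlinear(fit: SplineLogitFit) -> WaldResult:
    """Non-linear effect: the restricted-cubic term only.  Linearity is
    assumed when this p exceeds 0.05."""
    return wald(fit, [2])


def odds_ratio(
    fit: SplineLogitFit, coefficient: int, unit_scale: float = 1.0
) -> tuple[float, tuple[float, float]]:
    """Odds ratio (with cluster-robust 95% CI) per ``unit_scale`` units for
    a linear (non-spline) coefficient."""
    if fit.knots is not None and coefficient == 2:
        raise ValueError(
            "odds ratios are not meaningful for the spline term; "
            "use probability_curve instead"
        )
    b = float(fit.coefficients[coefficient])
    se = float(np.sqrt(max(fit.covariance[coefficient, coefficient], 0.0)))
    or_ = math.exp(b * unit_scale)
    lo = math.exp((b - Z95 * se) * unit_scale)
    hi = math.exp((b + Z95 * se) * unit_scale)
    return or_, (min(lo, hi), max(lo, hi))


@dataclass
class ProbabilityCurve:
    x: np.ndarray
    p: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    extrapolated: np.ndarray  # bool mask: grid points outside the fitted range


def probability_curve(fit: SplineLogitFit, x_grid: Sequence[float]) -> ProbabilityCurve:
    """Pointwise predicted probabilities with a 95% confidence band.

    The band is the inverse logit of the linear predictor +- 1.96 times its
    delta-method standard error under the cluster-robust covariance.  Grid
    points outside the fitted data range are computed but flagged as
    extrapolation.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; curve not available")
    xg = np.asarray(x_grid, dtype=float)
    if fit.knots is not None:
        D = np.column_stack([np.ones_like(xg), rcs_basis(xg, fit.knots)])
    elif fit.coefficients.size == 1:
        D = np.ones((xg.size, 1))
    else:
        D = np.column_stack([np.ones_like(xg), xg])
    eta = D @ fit.coefficients
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", D, fit.covariance, D), 0.0, None))
    inv = lambda v: 1.0 / (1.0 + np.exp(-v))
    if fit.x_range is not None:
        extrap = (xg < fit.x_range[0]) | (xg > fit.x_range[1])
    else:
        extrap = np.zeros_like(xg, dtype=bool)
    return ProbabilityCurve(
        x=xg, p=inv(eta), lower=inv(eta - Z95 * se), upper=inv(eta + Z95 * se),
        extrapolated=extrap,
    )


# ---------------------------------------------------------------------------
# predictor screen over classified suction events


#: per-unit scales for reported odds ratios (per 100 g, per 10 bpm, per 10 s)
OR_SCALES = {
    "birthweight_g": 100.0,
    "first_hr_bpm": 10.0,
    "time_to_se_s": 10.0,
}

CATEGORICAL_PREDICTORS = [
    ("female", "Female"),
    ("amniotic_fluid", "Amniotic fluid"),
    ("catheter", "Catheter (vs. bulb)"),
    ("ventilation_prior", "Ventilation prior to SE"),
    ("stimulation_prior", "Stimulation prior to SE"),
]
CONTINUOUS_PREDICTORS = [
    ("ga_weeks", "Gestational age (weeks)"),
    ("birthweight_g", "Birthweight (g)"),
    ("first_hr_bpm", "First observed HR (bpm)"),
    ("time_to_se_s", "Time post delivery to initiation of SE (sec)"),
    ("pre_hr_bpm", "HR prior to SE (bpm)"),
    ("se_duration_s", "Duration of SE (sec)"),
]


def build_se_table(
    classified: ClassifiedCohort, episodes: Sequence[EpisodeRecord]
) -> pd.DataFrame:
    """Per-suction-event analysis table: outcome flag (suction-related HR
    change) plus every screened predictor.  Indeterminate events are
    dropped (they lack usable HR data)."""
    by_id = {ep.newborn_id: ep for ep in episodes}
    rows = []
    for nid, r in classified.responses:
        if r.label is ResponseLabel.INDETERMINATE:
            continue
        ep = by_id[nid]
        rows.append(
            {
                "newborn_id": nid,
                "y": int(r.label.suction_related),
                "female": int(ep.sex is Sex.FEMALE),
                "amniotic_fluid": ep.amniotic_fluid.value,
                "catheter": int(r.se.any_catheter),
                "ventilation_prior": int(r.ventilation_prior),
                "stimulation_prior": int(r.stimulation_prior),
                "ga_weeks": ep.ga_weeks,
                "birthweight_g": ep.birthweight_g,
                "first_hr_bpm": ep.first_hr_bpm,
                "time_to_se_s": r.se.start_s,
                "pre_hr_bpm": r.pre_hr_bpm,
                "se_duration_s": r.se.duration_s,
                "delta_hr_bpm": r.delta_hr_bpm,
                "label": r.label.value,
                "died": int(ep.outcome is Outcome.DIED_3D),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PredictorResult:
    name: str
    label: str
    kind: str  # 'categorical' | 'continuous'
    odds_ratio: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None
    p_overall: Optional[float] = None
    p_nonlinear: Optional[float] = None
    level: Optional[str] = None  # category level for multi-level predictors
    note: Optional[str] = None


def predictor_screen(
    classified: ClassifiedCohort, episodes: Sequence[EpisodeRecord]
) -> list[PredictorResult]:
    """Screen candidate predictors of suction-related HR changes.

    Categorical predictors get a cluster-robust logistic odds ratio versus
    the reference level; continuous predictors get a 3-knot restricted cubic
    spline with Wald tests of the overall and non-linear effect, falling
    back to a linear odds ratio (per the conventional unit scale) when the
    non-linearity p exceeds 0.05.  Degenerate predictors are skipped with a
    note.
    """
    df = build_se_table(classified, episodes)
    y = df["y"].to_numpy()
    groups = df["newborn_id"].to_numpy()
    out: list[PredictorResult] = []

    for name, label in CATEGORICAL_PREDICTORS:
        col = df[name]
        levels = sorted(col.unique(), key=str)
        if len(levels) < 2:
            out.append(PredictorResult(name, label, "categorical",
                                       note="skipped: single level"))
            continue
        if name == "amniotic_fluid":
            ref = AmnioticFluid.CLEAR.value
            others = [l for l in (AmnioticFluid.SLIGHT.value,
                                  AmnioticFluid.THICK_BLOOD.value) if l in levels]
            X = np.column_stack([(col == l).astype(float) for l in others])
            try:
                fit = fit_logit_cluster(y, X, groups, names=tuple(others))
            except (SeparationError, ValueError) as exc:
                out.append(PredictorResult(name, label, "categorical",
                                           note=f"skipped: {exc}"))
                continue
            p_all = wald(fit, list(range(1, 1 + len(others)))).p
            out.append(PredictorResult(name, label, "categorical",
                                       p_overall=p_all, level=f"{ref} (ref)"))
            for j, lvl in enumerate(others, start=1):
                or_, ci = odds_ratio(fit, j)
                out.append(PredictorResult(name, label, "categorical",
                                           odds_ratio=or_, ci95=ci,
                                           p_overall=wald(fit, [j]).p, level=lvl))
            continue
        x = col.astype(float).to_numpy()
        try:
            fit = fit_logit_cluster(y, x, groups, names=(name,))
        except (SeparationError, ValueError) as exc:
            out.append(PredictorResult(name, label, "categorical",
                                       note=f"skipped: {exc}"))
            continue
        or_, ci = odds_ratio(fit, 1)
        out.append(PredictorResult(name, label, "categorical", odds_ratio=or_,
                                   ci95=ci, p_overall=wald(fit, [1]).p))

    for name, label in CONTINUOUS_PREDICTORS:
        sub = df.dropna(subset=[name])
        x = sub[name].astype(float).to_numpy()
        ysub = sub["y"].to_numpy()
        gsub = sub["newborn_id"].to_numpy()
        scale = OR_SCALES.get(name, 1.0)
        try:
            fit = fit_rcs_logit(ysub, x, gsub)
        except (SeparationError, ValueError) as exc:
            out.append(PredictorResult(name, label, "continuous",
                                       note=f"skipped: {exc}"))
            continue
        p_all = wald_overall(fit).p
        p_nl = wald_nonlinear(fit).p
        res = PredictorResult(name, label, "continuous", p_overall=p_all,
                              p_nonlinear=p_nl)
        if p_nl > 0.05:
            # linearity assumed: report OR per conventional unit scale
            try:
                lin = fit_logit_cluster(ysub, x, gsub, names=(name,))
                res.odds_ratio, res.ci95 = odds_ratio(lin, 1, unit_scale=scale)
                res.p_overall = wald(lin, [1]).p
            except (SeparationError, ValueError) as exc:
                res.note = f"linear refit failed: {exc}"
        else:
            res.note = "non-linear: see probability curve"
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# cohort flow and 2x2 mortality


def cohort_flow(
    births: int,
    ga_ge34: int,
    stillborn: int,
    stabilized: int,
    suctioned: int,
    ventilated: int,
) -> dict[str, float]:
    """Cohort-flow percentages among liveborn newborns of GA >= 34 weeks.

    Each percentage is 100 * count / liveborn, to one decimal, with
    ``liveborn = ga_ge34 - stillborn``.
    """
    counts = dict(births=births, ga_ge34=ga_ge34, stillborn=stillborn,
                  stabilized=stabilized, suctioned=suctioned, ventilated=ventilated)
    for k, v in counts.items():
        if v < 0 or v != int(v):
            raise ValueError(f"{k} must be a non-negative integer")
    if stillborn > ga_ge34:
        raise ValueError("stillborn cannot exceed ga_ge34")
    liveborn = ga_ge34 - stillborn
    if liveborn == 0:
        raise ValueError("no liveborn newborns; percentages undefined")
    return {
        "liveborn": float(liveborn),
        "stabilized_pct": percent(stabilized, liveborn),
        "suctioned_pct": percent(suctioned, liveborn),
        "ventilated_pct": percent(ventilated, liveborn),
    }


def mortality_table(
    classified: ClassifiedCohort, episodes: Sequence[EpisodeRecord]
) -> np.ndarray:
    """2x2 table [[died & change, survived & change],
    [died & no change, survived & no change]] over newborns in the analysis
    set."""
    by_id = {ep.newborn_id: ep for ep in episodes}
    t = np.zeros((2, 2), dtype=int)
    for nid, change in classified.any_change.items():
        died = by_id[nid].outcome is Outcome.DIED_3D
        t[0 if change else 1, 0 if died else 1] += 1
    return t
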