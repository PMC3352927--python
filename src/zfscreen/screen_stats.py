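"""Statistics for the screening layer.

Group comparisons follow the assay conventions: heart rate is non-Gaussian
(left-skewed), so treated-versus-control cardio comparisons use the
Mann-Whitney U test; angiogenesis comparisons between two groups use
Welch's unequal-variance t test and multi-group dose series use one-way
ANOVA with Dunnett's many-to-one adjustment against the vehicle control.
Dose-response potency is summarised by a four-parameter logistic (variable
slope sigmoid) IC50 fit, and assay validation panels by a confusion summary.

A note on terminology: the validation summaries report the fraction of
known-effect compounds detected and the fraction of no-effect compounds
correctly rejected.  The source screening literature for these assays calls
the first "specificity" and the second "sensitivity" — the opposite of the
usual epidemiological convention — so :func:`confusion_summary` reports both
quantities under neutral names alongside the conventional labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .plate_model import ValidationRecord, Verdict

__all__ = [
    "GroupComparison",
    "ConfusionSummary",
    "coefficient_of_variation",
    "mann_whitney",
    "welch_t",
    "anova_dunnett",
    "fit_4pl",
    "FourPLFit",
    "roc_threshold",
    "confusion_summary",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group (or many-to-one) hypothesis test."""

    statistic: float
    p_value: float
    test_name: str
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: sample SD x 100 / mean.

    Requires at least two values and a nonzero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) * 100.0 / mean)


def mann_whitney(a: Sequence[float], b: Sequence[float], two_sided: bool = True) -> GroupComparison:
    """Mann-Whitney U test of ``a`` versus ``b``.

    Uses the exact null distribution when the smaller group has at most 8
    observations and the data are tie-free; otherwise the normal
    approximation with tie correction (and continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    alternative = "two-sided" if two_sided else "less"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test_name=f"mann-whitney ({method})",
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance t test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variability
        p = 1.0 if a.mean() == b.mean() else 0.0
        return GroupComparison(statistic=0.0 if p == 1.0 else math.inf,
                               p_value=p, test_name="welch-t (degenerate)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="welch-t",
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

_DUNNETT_DRAWS = 200_000
_DUNNETT_SEED = 0x5EED
_null_max_t_cache: dict[tuple, np.ndarray] = {}


def _dunnett_null_sample(ns: tuple[int, ...], n0: int, df: int) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    (T_1..T_k) is multivariate t with df degrees of freedom and correlation
    rho_ij = lambda_i * lambda_j where lambda_i = sqrt(n_i / (n_i + n0)).
    Sampled with a fixed internal seed so adjusted p-values are reproducible;
    the sample is cached per design (group sizes and df).
    """
    key = (ns, n0, df)
    cached = _null_max_t_cache.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(_DUNNETT_SEED)
    lam = np.sqrt(np.asarray(ns, dtype=float) / (np.asarray(ns) + n0))
    # Z_i = lam_i * Z0 + sqrt(1 - lam_i^2) * Zi gives the required correlation
    z0 = rng.standard_normal(_DUNNETT_DRAWS)
    zi = rng.standard_normal((_DUNNETT_DRAWS, len(ns)))
    z = lam * z0[:, None] + np.sqrt(1.0 - lam**2) * zi
    w = rng.chisquare(df, _DUNNETT_DRAWS) / df
    max_abs_t = np.abs(z).max(axis=1) / np.sqrt(w)
    max_abs_t.sort()
    _null_max_t_cache[key] = max_abs_t
    return max_abs_t


def anova_dunnett(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    alpha: float = 0.05,
) -> tuple[GroupComparison, list[GroupComparison]]:
    """One-way ANOVA plus Dunnett's test of every group against control.

    Returns the omnibus F comparison and one :class:`GroupComparison` per
    non-control group carrying both the raw t p-value and the Dunnett
    family-wise adjusted p (two-sided), evaluated by Monte-Carlo sampling of
    the multivariate-t max statistic with a fixed internal seed.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if not 0 <= control_index < len(arrays):
        raise ValueError(f"control index {control_index} out of range")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    control = arrays[control_index]
    others = [a for i, a in enumerate(arrays) if i != control_index]
    n0 = control.size
    n_total = sum(a.size for a in arrays)
    df = n_total - len(arrays)
    # pooled within-group variance (ANOVA mean square error)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_error = sse / df

    if ms_error == 0:
        # degenerate: no within-group variability; differing means separate
        # the groups perfectly
        means_differ = len({a.mean() for a in arrays}) > 1
        omnibus = GroupComparison(
            statistic=math.inf if means_differ else 0.0,
            p_value=0.0 if means_differ else 1.0,
            test_name="anova-F (degenerate)",
        )
        comparisons = [
            GroupComparison(
                statistic=math.inf if a.mean() != control.mean() else 0.0,
                p_value=0.0 if a.mean() != control.mean() else 1.0,
                adjusted_p=0.0 if a.mean() != control.mean() else 1.0,
                test_name="dunnett (degenerate)",
            )
            for a in others
        ]
        return omnibus, comparisons

    f_stat, f_p = stats.f_oneway(*arrays)
    omnibus = GroupComparison(statistic=float(f_stat), p_value=float(f_p),
                              test_name="anova-F")
    null_max_t = _dunnett_null_sample(tuple(a.size for a in others), n0, df)

    comparisons = []
    for a in others:
        se = math.sqrt(ms_error * (1.0 / a.size + 1.0 / n0))
        t = (a.mean() - control.mean()) / se
        raw_p = 2.0 * stats.t.sf(abs(t), df)
        # adjusted p = P(max_i |T_i| >= |t|) under the joint null
        idx = np.searchsorted(null_max_t, abs(t), side="left")
        adj_p = (null_max_t.size - idx) / null_max_t.size
        comparisons.append(
            GroupComparison(
                statistic=float(t),
                p_value=float(min(raw_p, 1.0)),
                adjusted_p=float(max(adj_p, min(raw_p, 1.0))),
                test_name="dunnett (monte-carlo)",
            )
        )
    return omnibus, comparisons


# ---------------------------------------------------------------------------
# Four-parameter logistic dose-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourPLFit:
    """Variable-slope sigmoidal dose-response fit.

    response = bottom + (top - bottom) / (1 + (dose / ic50)**hill)

    ``hill`` > 0 corresponds to a response falling with dose (an inhibition
    curve); the parameterisation is symmetric so rising curves fit with
    negative ``hill``.
    """

    ic50: float
    hill: float
    top: float
    bottom: float
    stderr: tuple[float, float, float, float]
    converged: bool


def _four_pl(log_dose: np.ndarray, log_ic50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_dose - log_ic50)))


def fit_4pl(dose: Sequence[float], response: Sequence[float]) -> FourPLFit:
    """Fit a four-parameter logistic curve on the log-dose scale.

    Starting values come from the response range and the dose at which the
    response crosses its midpoint.  Non-convergence (or an unidentifiable,
    essentially flat response) is reported through ``converged=False``
    rather than an exception.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose.size != response.size:
        raise ValueError("dose and response must be the same length")
    if np.unique(dose).size < 5:
        raise ValueError("need at least 5 distinct dose levels")
    if np.any(dose <= 0):
        raise ValueError("doses must be > 0")

    log_dose = np.log(dose)
    top0 = float(response.max())
    bottom0 = float(response.min())
    span = top0 - bottom0
    nan_se = (math.nan,) * 4
    if span <= 0 or span < 1e-12 * max(abs(top0), 1.0):
        return FourPLFit(math.nan, math.nan, top0, bottom0, nan_se, False)

    # midpoint crossing for the IC50 start; slope sign from the dose-response trend
    mid = (top0 + bottom0) / 2.0
    order = np.argsort(log_dose)
    crossing = log_dose[order][np.argmin(np.abs(response[order] - mid))]
    trend = np.corrcoef(log_dose, response)[0, 1]
    hill0 = 1.0 if trend < 0 else -1.0

    try:
        popt, pcov = optimize.curve_fit(
            _four_pl,
            log_dose,
            response,
            p0=[crossing, hill0, top0, bottom0],
            maxfev=20_000,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return FourPLFit(math.nan, math.nan, top0, bottom0, nan_se, False)

    log_ic50, hill, top, bottom = popt
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    converged = bool(np.all(np.isfinite(popt)))
    ic50 = float(np.exp(log_ic50))
    # delta method: se(ic50) = ic50 * se(log ic50)
    se = (float(ic50 * perr[0]), float(perr[1]), float(perr[2]), float(perr[3]))
    if not np.isfinite(se[0]) or abs(hill) < 1e-3:
        converged = False
    return FourPLFit(ic50, float(hill), float(top), float(bottom), se, converged)


# ---------------------------------------------------------------------------
# ROC threshold selection and confusion summaries
# ---------------------------------------------------------------------------


def roc_threshold(
    control_rates: Sequence[float], treated_rates: Sequence[float]
) -> tuple[float, float, float]:
    """Youden-optimal decision threshold between two empirical samples.

    Sweeps candidate thresholds at the midpoints between adjacent pooled
    values (plus the extremes) and returns ``(threshold, sensitivity,
    specificity)`` in percent.  The positive calling direction is inferred
    from the sample means: if treated values run lower than control (the
    bradycardia case — beats per 15 s below threshold are positive), a value
    below the threshold is a positive call; otherwise above.
    """
    control = np.asarray(control_rates, dtype=float)
    treated = np.asarray(treated_rates, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise ValueError("both samples must be non-empty")

    low_is_positive = treated.mean() <= control.mean()
    pooled = np.unique(np.concatenate([control, treated]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.array([])
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])

    best = (-np.inf, candidates[0], 0.0, 0.0)
    for thr in candidates:
        if low_is_positive:
            sens = np.mean(treated < thr)
            spec = np.mean(control >= thr)
        else:
            sens = np.mean(treated > thr)
            spec = np.mean(control <= thr)
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    return float(thr), float(100.0 * sens), float(100.0 * spec)


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/TN/FN/FP counts and the derived validation rates (percent).

    ``detection_rate_positives`` = 100 * TP / (TP + FN): the share of
    known-effect compounds the assay detected.  ``correct_rejection_rate`` =
    100 * TN / (TN + FP): the share of no-effect compounds correctly left
    uncalled.  Conventional aliases: the first is sensitivity/recall, the
    second specificity; the screening reports this package follows swap the
    two words, hence the explicit naming.  Rates are ``None`` when their
    denominator is empty (undefined, not zero).
    """

    tp: int
    tn: int
    fn: int
    fp: int
    detection_rate_positives: float | None
    correct_rejection_rate: float | None

    @property
    def n_records(self) -> int:
        return self.tp + self.tn + self.fn + self.fp

    @property
    def sensitivity_conventional(self) -> float | None:
        return self.detection_rate_positives

    @property
    def specificity_conventional(self) -> float | None:
        return self.correct_rejection_rate


def confusion_summary(records: Sequence[ValidationRecord]) -> ConfusionSummary:
    """Tally validation verdicts and compute detection/rejection rates."""
    counts = {v: 0 for v in Verdict}
    for rec in records:
        counts[rec.verdict] += 1
    tp, tn, fn, fp = counts[Verdict.TP], counts[Verdict.TN], counts[Verdict.FN], counts[Verdict.FP]
    detection = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    rejection = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return ConfusionSummary(tp=tp, tn=tn, fn=fn, fp=fp,
                            detection_rate_positives=detection,
                            correct_rejection_rate=rejection)
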