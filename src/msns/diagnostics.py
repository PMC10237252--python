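"""Diagnostic-accuracy statistics for a low-is-sick severity score.

Everything a validation study of an admission severity score reports is here:
descriptive frequency tables (with the truncation percentage convention),
Pearson chi-square association of each subscore band with the outcome, the
tie-corrected Mann-Whitney comparison of score distributions between outcome
groups (with exact enumeration at small n), the ROC curve under the
"positive = score <= cutoff predicts death" orientation, the Youden-optimal
cutoff, sensitivity/specificity/predictive values with Wilson 95% intervals,
and the single-proportion sample-size formula.

The test statistics are computed from their definitions in this module;
only the reference distributions (standard normal, chi-squared) come from
scipy.  Scores are assumed to live on the integer grid 0..16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .cohort import Cohort
from .errors import MsnsError, UnknownParameterError
from .rubric import MAX_TOTAL, PARAMETERS, MsnsResult

#: Midpoint cutpoints spanning the integer score grid: -0.5, 0.5, ..., 16.5.
CUTPOINTS = np.arange(-0.5, MAX_TOTAL + 1.0, 1.0)

PERCENT_CONVENTIONS = ("truncate", "round")


def _as_outcome_mask(outcomes) -> np.ndarray:
    """Boolean mask, True where the outcome is 'expired'."""
    arr = np.asarray(outcomes)
    if arr.dtype.kind == "b":
        return arr
    return arr == "expired"


# --------------------------------------------------------------------------
# descriptives
# --------------------------------------------------------------------------

def integer_percent(count: int, total: int, convention: str = "truncate") -> int:
    """Integer percentage under the chosen convention.

    ``truncate`` is floor(100*count/total) — the convention under which the
    reference cohort's printed percentages (e.g. 9/71 -> 12%) are internally
    consistent; ``round`` is standard half-even rounding.
    """
    if convention not in PERCENT_CONVENTIONS:
        raise ValueError(f"convention must be one of {PERCENT_CONVENTIONS}")
    pct = 100.0 * count / total
    return math.floor(pct) if convention == "truncate" else round(pct)


#: Categorical fields summarised by default, with their category order.
_DESCRIPTIVE_FIELDS = {
    "sex": ("male", "female"),
    "gestational_age_group": ("preterm", "term"),
    "mode_of_delivery": ("vaginal", "caesarean"),
    "parity": ("primi", "multi"),
    "outcome": ("discharged", "expired"),
}

TERM_THRESHOLD_WEEKS = 37.0


def descriptive_summary(cohort: Cohort, convention: str = "truncate") -> pd.DataFrame:
    """Baseline characteristics table: count and integer percent per category.

    Gestational age is summarised as a preterm/term dichotomy at
    37.0 completed weeks.  Returns a tidy frame with columns
    ``field, category, count, percent``.
    """
    if len(cohort) == 0:
        raise MsnsError("descriptive_summary requires a non-empty cohort")
    n = len(cohort)
    rows = []
    for fname, categories in _DESCRIPTIVE_FIELDS.items():
        if fname == "gestational_age_group":
            values = ["preterm" if r.gestational_age < TERM_THRESHOLD_WEEKS else "term"
                      for r in cohort]
        else:
            values = [getattr(r, fname) for r in cohort]
        for cat in categories:
            count = sum(v == cat for v in values)
            rows.append({"field": fname, "category": cat, "count": count,
                         "percent": integer_percent(count, n, convention)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Two-group rank comparison: U, tie-corrected z, p, and group summaries."""

    u_statistic: float  # U for group a (pairs where a < b, ties half)
    z_value: float
    p_value: float
    method: str  # 'normal' or 'exact'
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via midranks: counts pairs (a_i < b_j), ties 1/2."""
    n_a = len(a)
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    # rank-sum form gives U2 = #(a > b) + ties/2; U1 = n_a*n_b - U2
    u2 = r_a - n_a * (n_a + 1) / 2.0
    return n_a * len(b) - u2


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided permutation p by full enumeration of group labelings.

    U for a labeling is the pairwise win count (ties half), accumulated from
    a precomputed comparison matrix, so enumeration stays cheap at the small
    group sizes where it is used.
    """
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n_a = len(a)
    # wins[i, j] = 1 if pooled[i] < pooled[j], 1/2 on ties
    wins = (pooled[:, None] < pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    mid = n_a * len(b) / 2.0
    extreme = 0
    total = 0
    idx = np.arange(n)
    for comb in combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = wins[np.ix_(mask, ~mask)].sum()
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
    return extreme / total


def mann_whitney(values_a, values_b, method: str = "auto") -> GroupComparison:
    """Mann-Whitney U comparison of two samples.

    U counts pairs where a value from group a is below one from group b
    (ties half).  The z statistic uses the tie-corrected variance
    ``n_a n_b / 12 * ((n+1) - sum(t^3 - t) / (n (n-1)))``; the two-sided p
    comes from the normal approximation with a continuity correction of 1/2
    (the reported ``z_value`` itself is uncorrected, as conventionally
    printed).  With ``method='auto'`` an exact two-sided permutation p is
    substituted whenever both groups have at most 8 observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MsnsError("mann_whitney requires two non-empty groups")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    u = _u_statistic(a, b)

    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    mean_u = n_a * n_b / 2.0
    if var <= 0:
        z, p_normal = 0.0, 1.0
    else:
        z = (u - mean_u) / math.sqrt(var)
        z_corrected = max(abs(u - mean_u) - 0.5, 0.0) / math.sqrt(var)
        p_normal = min(1.0, 2.0 * norm.sf(z_corrected))

    if method == "exact" or (method == "auto" and n_a <= 8 and n_b <= 8):
        p, used = _exact_p(a, b, u), "exact"
    elif method in ("auto", "normal"):
        p, used = p_normal, "normal"
    else:
        raise ValueError("method must be 'auto', 'normal' or 'exact'")

    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return GroupComparison(
        u_statistic=float(u), z_value=float(z), p_value=float(p), method=used,
        median_a=float(qa[1]), iqr_a=(float(qa[0]), float(qa[2])),
        median_b=float(qb[1]), iqr_b=(float(qb[0]), float(qb[2])),
        n_a=n_a, n_b=n_b,
    )


# --------------------------------------------------------------------------
# chi-square association
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    degrees_of_freedom: int
    p_value: float
    small_expected_cells: bool  # any expected count < 5


def chi_square(observed_table) -> ContingencyResult:
    """Pearson chi-square test of independence on a contingency table.

    All-zero rows and columns are dropped before computing expected counts
    from the margins; a flag marks tables with any expected cell below 5
    (the classical validity rule of thumb), but the statistic is still
    computed.
    """
    obs = np.asarray(observed_table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise MsnsError("observed table must be a 2-D array of non-negative counts")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise MsnsError("need at least two non-empty rows and columns")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(
        observed=obs, expected=expected, statistic=statistic,
        degrees_of_freedom=df, p_value=float(chi2_dist.sf(statistic, df)),
        small_expected_cells=bool((expected < 5).any()),
    )


def band_outcome_table(
    cohort: Cohort, msns_results: Sequence[MsnsResult], parameter: str
) -> pd.DataFrame:
    """3x2 counts of one parameter's subscore {0,1,2} by outcome."""
    if parameter not in PARAMETERS:
        raise UnknownParameterError(parameter)
    if len(msns_results) != len(cohort):
        raise MsnsError(
            f"{len(msns_results)} score results for {len(cohort)} records")
    table = pd.DataFrame(0, index=[0, 1, 2], columns=["discharged", "expired"])
    for rec, res in zip(cohort, msns_results):
        table.loc[res.subscores[parameter], rec.outcome] += 1
    table.index.name = f"{parameter}_score"
    return table


# --------------------------------------------------------------------------
# ROC / cutoff / diagnostic metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """ROC of the 'positive if score <= c' classifier over midpoint cutpoints.

    ``sensitivity[i] = P(score <= cutpoints[i] | expired)`` and
    ``specificity[i] = P(score > cutpoints[i] | discharged)``; the curve
    therefore runs from (sens, spec) = (0, 1) to (1, 0) as c increases.
    """

    cutpoints: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutpoint": self.cutpoints,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def roc_curve(total_scores, outcomes) -> RocCurve:
    """ROC curve and trapezoidal AUC for integer scores where low predicts death.

    AUC integrates sensitivity over 1 - specificity and equals the
    probability that a random expired neonate scores below a random
    discharged one, counting ties one half.
    """
    scores = np.asarray(total_scores, dtype=float)
    expired = _as_outcome_mask(outcomes)
    if expired.all() or not expired.any():
        raise MsnsError("roc_curve requires both outcome classes")
    e, d = scores[expired], scores[~expired]
    sens = np.array([(e <= c).mean() for c in CUTPOINTS])
    spec = np.array([(d > c).mean() for c in CUTPOINTS])
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return RocCurve(cutpoints=CUTPOINTS.copy(), sensitivity=sens,
                    specificity=spec, auc=auc)


def optimal_cutoff(roc: RocCurve) -> int:
    """Integer cutoff (positive if score <= cutoff) maximising Youden's J.

    Ties on J are broken toward higher sensitivity, then toward the lower
    cutoff, so a run of equally perfect cutpoints reports its smallest
    member.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    cutoffs = np.floor(roc.cutpoints).astype(int)  # -1 .. 16
    best = max(range(len(cutoffs)),
               key=lambda i: (j[i], roc.sensitivity[i], -cutoffs[i]))
    return int(cutoffs[best])


def wilson_interval(successes: int, trials: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials <= 0:
        return (float("nan"), float("nan"))
    z = norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    phat = successes / trials
    denom = 1.0 + z**2 / trials
    centre = phat + z**2 / (2 * trials)
    spread = z * math.sqrt(phat * (1 - phat) / trials + z**2 / (4 * trials**2))
    # clamp away rounding noise: the interval lies in [0,1] and contains phat
    lo = min(max((centre - spread) / denom, 0.0), phat)
    hi = max(min((centre + spread) / denom, 1.0), phat)
    return (lo, hi)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Accuracy of 'score <= cutoff predicts death' at one cutoff."""

    cutoff: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    tp: int
    fn: int
    fp: int
    tn: int


def diagnostic_metrics(total_scores, outcomes, cutoff: int,
                       confidence: float = 0.95) -> DiagnosticSummary:
    """Sensitivity, specificity and predictive values at a chosen cutoff,
    each with a Wilson interval.

    Predictive values are NaN (with NaN intervals) when no record is
    predicted in the corresponding class.
    """
    scores = np.asarray(total_scores, dtype=float)
    expired = _as_outcome_mask(outcomes)
    if expired.all() or not expired.any():
        raise MsnsError("diagnostic_metrics requires both outcome classes")
    positive = scores <= cutoff
    tp = int((positive & expired).sum())
    fn = int((~positive & expired).sum())
    fp = int((positive & ~expired).sum())
    tn = int((~positive & ~expired).sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    sens, spec = ratio(tp, tp + fn), ratio(tn, tn + fp)
    return DiagnosticSummary(
        cutoff=int(cutoff),
        sensitivity=sens, specificity=spec,
        ppv=ratio(tp, tp + fp), npv=ratio(tn, tn + fn),
        youden_j=sens + spec - 1.0,
        sensitivity_ci=wilson_interval(tp, tp + fn, confidence),
        specificity_ci=wilson_interval(tn, tn + fp, confidence),
        ppv_ci=wilson_interval(tp, tp + fp, confidence),
        npv_ci=wilson_interval(tn, tn + fn, confidence),
        tp=tp, fn=fn, fp=fp, tn=tn,
    )


# --------------------------------------------------------------------------
# sample size
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the single-proportion precision formula
    ``N = Z^2 p (1-p) / d^2``."""

    p: float  # anticipated sensitivity or specificity
    d: float  # absolute precision, same scale as p
    confidence_level: float = 0.95

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must lie strictly in (0, 1)")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must lie strictly in (0, 1)")

    @property
    def z_quantile(self) -> float:
        return float(norm.ppf(1.0 - (1.0 - self.confidence_level) / 2.0))


def sample_size_sensitivity(spec: SampleSizeSpec) -> int:
    """Required N to estimate a proportion p to absolute precision d:
    ``ceil(Z^2 p (1-p) / d^2)``."""
    z = spec.z_quantile
    return math.ceil(z * z * spec.p * (1.0 - spec.p) / (spec.d * spec.d))
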