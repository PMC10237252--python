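"""Diagnostic statistics against closed forms, brute force, and scipy/sklearn."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, mannwhitneyu, norm
from sklearn.metrics import roc_auc_score

from msns import (
    MsnsError,
    SampleSizeSpec,
    band_outcome_table,
    chi_square,
    compute_msns,
    descriptive_summary,
    diagnostic_metrics,
    integer_percent,
    mann_whitney,
    optimal_cutoff,
    roc_curve,
    sample_size_sensitivity,
    wilson_interval,
)
from msns.cohort import Cohort

from conftest import make_observation


# --------------------------------------------------------------------------
# descriptives
# --------------------------------------------------------------------------

@pytest.mark.parametrize("count, expected", [
    (59, 83), (12, 16), (14, 19), (57, 80), (55, 77),
    (16, 22), (58, 81), (13, 18), (62, 87), (9, 12),
])
def test_truncation_reproduces_printed_percentages(count, expected):
    """Every integer percentage of the 71-neonate baseline table follows
    from its count under truncation toward zero."""
    assert integer_percent(count, 71, "truncate") == expected


def test_rounding_convention_differs_where_expected():
    assert integer_percent(9, 71, "round") == 13  # 12.68 rounds up


def test_descriptive_summary_single_record():
    cohort = Cohort(records=[make_observation()], provenance="test")
    table = descriptive_summary(cohort)
    male = table[(table["field"] == "sex") & (table["category"] == "male")]
    assert male["count"].item() == 1 and male["percent"].item() == 100


def test_descriptive_summary_rejects_empty_cohort():
    with pytest.raises(MsnsError):
        descriptive_summary(Cohort(records=[], provenance="empty"))


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def test_disjoint_groups_attain_extreme_u():
    gc = mann_whitney([1, 2, 3], [4, 5, 6])
    assert gc.u_statistic == 9.0  # every a below every b
    assert mann_whitney([4, 5, 6], [1, 2, 3]).u_statistic == 0.0


def test_identical_groups_give_z_zero_p_one():
    gc = mann_whitney([5, 5, 5], [5, 5, 5], method="normal")
    assert gc.z_value == 0.0 and gc.p_value == 1.0


def brute_force_two_sided_p(a, b):
    """Permutation oracle: enumerate every labeling of the pooled values and
    count those with U at least as far from n_a*n_b/2 as observed.  U is
    counted pair by pair, independently of the rank-based implementation."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(group_a, group_b):
        return sum((x < y) + 0.5 * (x == y) for x in group_a for y in group_b)

    mid = n_a * len(b) / 2
    u_obs = u_of(a, b)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        hits += abs(u_of(ga, gb) - mid) >= abs(u_obs - mid) - 1e-12
    return hits / total


def test_exact_p_matches_brute_force_enumeration():
    a, b = [12, 14, 9, 17], [8, 8, 11]
    ours = mann_whitney(a, b)  # auto -> exact at these sizes
    assert ours.method == "exact"
    assert ours.p_value == pytest.approx(brute_force_two_sided_p(a, b), abs=1e-12)
    assert ours.u_statistic == 1.0  # only 9 vs 11 has a below b


def test_exact_p_matches_scipy_without_ties():
    a, b = [12, 14, 9, 17], [8, 7, 11]
    ours = mann_whitney(a, b)
    ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    # U orientation: scipy's statistic counts a > b pairs; ours counts a < b
    assert ours.u_statistic == pytest.approx(len(a) * len(b) - ref.statistic)


def test_normal_approximation_close_to_exact_with_ties(rng):
    """Continuity-corrected normal p tracks the exact permutation p on tied
    integer data once both groups have at least 5 observations."""
    for _ in range(50):
        n_a, n_b = rng.integers(5, 9, size=2)
        a = rng.integers(0, 17, size=n_a)
        b = rng.integers(0, 17, size=n_b)
        exact = mann_whitney(a, b, method="exact").p_value
        approx = mann_whitney(a, b, method="normal").p_value
        assert abs(exact - approx) < 0.1


def test_tie_corrected_p_matches_scipy_on_tied_data(rng):
    a = rng.integers(0, 5, size=40)
    b = rng.integers(1, 6, size=35)
    ours = mann_whitney(a, b, method="normal")
    ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_u_label_swap_antisymmetry(rng):
    a = rng.integers(0, 17, size=12)
    b = rng.integers(0, 17, size=9)
    u_ab = mann_whitney(a, b).u_statistic
    u_ba = mann_whitney(b, a).u_statistic
    assert u_ab + u_ba == len(a) * len(b)


def test_group_summaries_are_median_and_iqr():
    gc = mann_whitney([1, 2, 3, 4, 100], [10, 20, 30])
    assert gc.median_a == 3 and gc.iqr_a == (2, 4)
    assert gc.median_b == 20


def test_empty_group_rejected():
    with pytest.raises(MsnsError):
        mann_whitney([], [1, 2])


# --------------------------------------------------------------------------
# chi-square
# --------------------------------------------------------------------------

def test_independent_table_has_zero_statistic():
    res = chi_square([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_perfectly_associated_table():
    res = chi_square([[20, 0], [0, 20]])
    assert res.statistic == pytest.approx(40.0)
    assert res.degrees_of_freedom == 1


def test_chi_square_matches_scipy_without_correction(rng):
    for _ in range(25):
        table = rng.integers(1, 40, size=(3, 2))
        ours = chi_square(table)
        stat, p, df, _ = chi2_contingency(table, correction=False)
        assert ours.statistic == pytest.approx(stat)
        assert ours.p_value == pytest.approx(p)
        assert ours.degrees_of_freedom == df


def test_all_zero_rows_are_dropped_before_df():
    res = chi_square([[5, 10], [0, 0], [10, 5]])
    assert res.degrees_of_freedom == 1
    assert res.observed.shape == (2, 2)


def test_small_expected_cell_sets_warning_flag():
    assert chi_square([[1, 9], [2, 8]]).small_expected_cells
    assert not chi_square([[20, 20], [20, 20]]).small_expected_cells


def test_degenerate_table_rejected():
    with pytest.raises(MsnsError):
        chi_square([[3, 4]])
    with pytest.raises(MsnsError):
        chi_square([[3, 0], [4, 0]])


def test_band_outcome_table_margins(fixture_cohort):
    results = [compute_msns(r) for r in fixture_cohort]
    table = band_outcome_table(fixture_cohort, results, "heart_rate")
    assert table.sum().tolist() == [62, 9]  # outcome margins
    subs = [r.subscores["heart_rate"] for r in results]
    assert table.sum(axis=1).tolist() == [subs.count(0), subs.count(1), subs.count(2)]


def test_band_outcome_table_unknown_parameter(fixture_cohort):
    results = [compute_msns(r) for r in fixture_cohort]
    with pytest.raises(Exception, match="lactate"):
        band_outcome_table(fixture_cohort, results, "lactate")


# --------------------------------------------------------------------------
# ROC / cutoff / metrics
# --------------------------------------------------------------------------

def pair_counting_auc(scores, expired_mask):
    """Independent O(n^2) concordance estimator: P(expired scores lower),
    ties one half."""
    e = np.asarray(scores, float)[expired_mask]
    d = np.asarray(scores, float)[~np.asarray(expired_mask)]
    wins = sum((ei < dj) + 0.5 * (ei == dj) for ei in e for dj in d)
    return wins / (len(e) * len(d))


def random_score_cohort(rng, n_max=60):
    n_e = int(rng.integers(2, 10))
    n_d = int(rng.integers(2, n_max))
    scores = np.concatenate([rng.integers(0, 17, n_e), rng.integers(0, 17, n_d)])
    expired = np.zeros(len(scores), bool)
    expired[:n_e] = True
    return scores, expired


def test_perfect_separation_gives_auc_one():
    scores = [3, 3, 13, 13, 13]
    expired = [True, True, False, False, False]
    assert roc_curve(scores, expired).auc == pytest.approx(1.0)


def test_identical_distributions_give_auc_half():
    scores = [5, 9, 12, 5, 9, 12]
    expired = [True, True, True, False, False, False]
    assert roc_curve(scores, expired).auc == pytest.approx(0.5)


def test_roc_endpoints_and_monotonicity(rng):
    scores, expired = random_score_cohort(rng)
    roc = roc_curve(scores, expired)
    assert roc.sensitivity[0] == 0.0 and roc.specificity[0] == 1.0
    assert roc.sensitivity[-1] == 1.0 and roc.specificity[-1] == 0.0
    assert (np.diff(roc.sensitivity) >= 0).all()
    assert (np.diff(roc.specificity) <= 0).all()


def test_trapezoid_auc_equals_pair_counting(rng):
    for _ in range(100):
        scores, expired = random_score_cohort(rng)
        auc = roc_curve(scores, expired).auc
        assert auc == pytest.approx(pair_counting_auc(scores, expired), abs=1e-12)


def test_auc_matches_sklearn(rng):
    scores, expired = random_score_cohort(rng)
    ours = roc_curve(scores, expired).auc
    assert ours == pytest.approx(roc_auc_score(expired, -scores), abs=1e-12)


def test_label_swap_maps_auc_to_complement(rng):
    scores, expired = random_score_cohort(rng)
    assert roc_curve(scores, expired).auc == pytest.approx(
        1.0 - roc_curve(scores, ~expired).auc, abs=1e-12)


def test_single_class_input_rejected():
    with pytest.raises(MsnsError):
        roc_curve([1, 2, 3], [True, True, True])
    with pytest.raises(MsnsError):
        diagnostic_metrics([1, 2, 3], [False, False, False], 9)


def test_optimal_cutoff_perfect_separation_tie_rule():
    scores = [3, 3, 13, 13]
    expired = [True, True, False, False]
    assert optimal_cutoff(roc_curve(scores, expired)) == 3


def test_optimal_cutoff_degenerate_returns_smallest_of_the_tie():
    scores = [7, 7, 7, 7]
    expired = [True, False, True, False]
    assert optimal_cutoff(roc_curve(scores, expired)) == 7


def test_optimal_cutoff_matches_exhaustive_argmax(rng):
    """Returned cutoff attains the exhaustively-maximised Youden J and obeys
    the (J, sensitivity, lower cutoff) tie-break."""
    for _ in range(100):
        scores, expired = random_score_cohort(rng, n_max=200)
        roc = roc_curve(scores, expired)
        got = optimal_cutoff(roc)
        e, d = scores[expired], scores[~expired]
        best = max(range(-1, 17),
                   key=lambda c: ((e <= c).mean() + (d > c).mean() - 1,
                                  (e <= c).mean(), -c))
        assert got == best


def test_wilson_interval_nine_of_nine():
    lo, hi = wilson_interval(9, 9)
    z = norm.ppf(0.975)
    expected_lo = (1 + z**2 / 18 - z * math.sqrt(z**2 / (4 * 81))) / (1 + z**2 / 9)
    assert lo == pytest.approx(expected_lo, abs=1e-12)
    assert lo == pytest.approx(0.70, abs=0.005)
    assert hi == pytest.approx(1.0)


@settings(max_examples=200, derandomize=True)
@given(k=st.integers(0, 50), extra=st.integers(0, 50))
def test_wilson_interval_contains_estimate_within_unit(k, extra):
    n = k + extra
    if n == 0:
        return
    lo, hi = wilson_interval(k, n)
    assert 0.0 <= lo <= k / n <= hi <= 1.0


def test_diagnostic_metrics_two_by_two_arithmetic():
    # TP=6, FN=3 (expired), FP=8, TN=54 (discharged) at cutoff 9
    scores = [9] * 6 + [10] * 3 + [9] * 8 + [10] * 54
    expired = [True] * 9 + [False] * 62
    m = diagnostic_metrics(scores, expired, cutoff=9)
    assert (m.tp, m.fn, m.fp, m.tn) == (6, 3, 8, 54)
    assert m.sensitivity == pytest.approx(6 / 9)
    assert m.specificity == pytest.approx(54 / 62)
    assert m.ppv == pytest.approx(6 / 14)
    assert m.npv == pytest.approx(54 / 57)
    assert m.youden_j == pytest.approx(6 / 9 + 54 / 62 - 1)
    assert m.sensitivity_ci == wilson_interval(6, 9)


def test_perfect_separation_metrics():
    m = diagnostic_metrics([3, 3, 13, 13], [True, True, False, False], cutoff=5)
    assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.youden_j == 1.0


def test_undefined_predictive_value_is_nan():
    # nothing predicted positive at cutoff -1
    m = diagnostic_metrics([5, 9], [True, False], cutoff=-1)
    assert math.isnan(m.ppv) and math.isnan(m.ppv_ci[0])


# --------------------------------------------------------------------------
# sample size
# --------------------------------------------------------------------------

def test_sample_size_collapses_to_z_squared():
    assert sample_size_sensitivity(SampleSizeSpec(p=0.5, d=0.5)) == 4


def test_sample_size_direct_evaluation():
    assert sample_size_sensitivity(SampleSizeSpec(p=0.69, d=0.11)) == 68


def test_doubling_precision_quarters_n_up_to_ceiling():
    for p, d in [(0.69, 0.05), (0.3, 0.02), (0.9, 0.01)]:
        n1 = sample_size_sensitivity(SampleSizeSpec(p=p, d=d))
        n2 = sample_size_sensitivity(SampleSizeSpec(p=p, d=2 * d))
        assert n1 <= 4 * n2 <= n1 + 3


@pytest.mark.parametrize("kwargs", [
    {"p": 0.0, "d": 0.1}, {"p": 1.0, "d": 0.1},
    {"p": 0.5, "d": 0.0}, {"p": 0.5, "d": 0.1, "confidence_level": 1.0},
])
def test_sample_size_input_validation(kwargs):
    with pytest.raises(ValueError):
        SampleSizeSpec(**kwargs)
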