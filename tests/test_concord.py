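"""Concordance statistics, exact binomial intervals, alert exclusion."""

import random

import numpy as np
import pytest
from scipy.stats import binom

from jcs2gcs import (
    Cohort,
    JCS_CODES,
    absolute_concordance,
    clopper_pearson,
    exclude_alert,
    published_table,
    relative_concordance,
    validation_report,
)
from jcs2gcs.concord import format_pct


# -- Clopper–Pearson --------------------------------------------------------

def test_zero_successes_closed_form():
    """k = 0: interval is (0, 1 − (α/2)^(1/n))."""
    low, high = clopper_pearson(0, 10)
    assert low == 0.0
    assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)


def test_all_successes_mirror_symmetry():
    low, high = clopper_pearson(10, 10)
    assert high == 1.0
    assert low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)


@pytest.mark.parametrize(
    "k,n,printed",
    [
        (659, 821, ("77.4", "82.9")),
        (765, 821, ("91.2", "94.8")),
        (123, 267, ("40.0", "52.2")),
        (215, 267, ("75.3", "85.1")),
    ],
)
def test_interval_reproduces_published_validation_cis(k, n, printed):
    """The four published validation-cohort CIs at one-decimal rounding."""
    low, high = clopper_pearson(k, n)
    assert (format_pct(low), format_pct(high)) == printed


@pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
def test_domain_errors(k, n):
    with pytest.raises(ValueError):
        clopper_pearson(k, n)


def test_alpha_domain():
    with pytest.raises(ValueError):
        clopper_pearson(1, 2, alpha=0.0)


def bruteforce_exact_interval(k, n, alpha=0.05, tol=1e-12):
    """Oracle: bisection for the extreme p with exact tail prob ≥ α/2."""
    def search(tail, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if tail(mid) >= alpha / 2:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else search(lambda p: binom.sf(k - 1, n, p), 0.0, k / n)
    if k == 0:
        high = 1.0 - (alpha / 2) ** (1 / n)
    elif k == n:
        high = 1.0
    else:
        # largest p with P(X <= k) >= alpha/2
        lo, hi = k / n, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if binom.cdf(k, n, mid) >= alpha / 2:
                lo = mid
            else:
                hi = mid
        high = (lo + hi) / 2
    if k == 0:
        low = 0.0
    return low, high


def test_interval_matches_bruteforce_tail_search_small_n():
    for n in range(1, 31):
        for k in range(n + 1):
            low, high = clopper_pearson(k, n)
            olow, ohigh = bruteforce_exact_interval(k, n)
            assert low == pytest.approx(olow, abs=1e-6), (k, n)
            assert high == pytest.approx(ohigh, abs=1e-6), (k, n)


def test_interval_matches_statsmodels_beta_method():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(0, 5), (3, 7), (659, 821), (123, 267), (50, 50)]:
        low, high = clopper_pearson(k, n)
        slow, shigh = proportion_confint(k, n, alpha=0.05, method="beta")
        assert low == pytest.approx(float(slow), abs=1e-10)
        assert high == pytest.approx(float(shigh), abs=1e-10)


def test_coverage_is_conservative():
    """Exact intervals cover the true p at ≥ nominal − MC error."""
    rng = np.random.default_rng(2024)
    n_sim = 2000
    for p in (0.1, 0.5, 0.8, 0.93):
        for n in (50, 267, 821):
            ks = rng.binomial(n, p, size=n_sim)
            covered = 0
            for k in np.unique(ks):
                low, high = clopper_pearson(int(k), n)
                if low <= p <= high:
                    covered += int(np.sum(ks == k))
            coverage = covered / n_sim
            mc_se = np.sqrt(0.95 * 0.05 / n_sim)
            assert coverage >= 0.95 - 2 * mc_se, (p, n, coverage)


# -- concordance ------------------------------------------------------------

def test_absolute_concordance_counts(tiny_cohort):
    res = absolute_concordance(tiny_cohort)
    assert (res.successes, res.n) == (3, 5)
    assert res.proportion == pytest.approx(0.6)


def test_relative_concordance_counts(tiny_cohort):
    # the (30, 8) row enters the ±1 window; (100, 12) stays out
    res = relative_concordance(tiny_cohort)
    assert (res.successes, res.n) == (4, 5)


def test_perfect_cohort_ci_upper_is_one():
    cohort = Cohort.from_pairs([(0, 15)] * 8)
    res = absolute_concordance(cohort)
    assert res.proportion == 1.0
    assert res.ci_high == 1.0


def test_offset_two_not_relatively_concordant():
    cohort = Cohort.from_pairs([(30, 11)])
    assert relative_concordance(cohort).successes == 0


def test_concordance_matches_rowwise_recount_on_random_cohorts():
    rng = random.Random(99)
    table = published_table()
    for _ in range(50):
        pairs = [(rng.choice(JCS_CODES), rng.randint(3, 15))
                 for _ in range(rng.randint(1, 60))]
        cohort = Cohort.from_pairs(pairs)
        abs_oracle = sum(1 for j, g in pairs if g == table[j])
        rel_oracle = sum(1 for j, g in pairs if abs(g - table[j]) <= 1)
        abs_res = absolute_concordance(cohort)
        rel_res = relative_concordance(cohort)
        assert abs_res.successes == abs_oracle
        assert rel_res.successes == rel_oracle
        assert rel_res.successes >= abs_res.successes
        assert abs_res.ci_low <= abs_res.proportion <= abs_res.ci_high


def test_empty_cohort_errors():
    with pytest.raises(ValueError):
        absolute_concordance(Cohort(observations=()))


def test_subcohort_cannot_raise_successes():
    rng = random.Random(4)
    pairs = [(rng.choice(JCS_CODES), rng.randint(3, 15)) for _ in range(60)]
    cohort = Cohort.from_pairs(pairs)
    full = absolute_concordance(cohort).successes
    for cut in (10, 30, 50):
        sub = Cohort(observations=cohort.observations[:cut])
        assert absolute_concordance(sub).successes <= full


# -- alert exclusion / report ------------------------------------------------

def test_exclude_alert_counts():
    cohort = Cohort.from_pairs([(0, 15), (0, 14), (30, 9)])
    sub = exclude_alert(cohort)
    assert len(sub) == 1
    assert len(sub) + 2 == len(cohort)
    assert "alert" in sub.provenance


def test_exclude_alert_identity_when_no_alert(alert_free_cohort):
    sub = exclude_alert(alert_free_cohort)
    assert sub.observations == alert_free_cohort.observations


def test_exclude_alert_validation_cohort_sizes():
    """821 rows with 554 alert leave the 267-patient sensitivity cohort."""
    pairs = [(0, 15)] * 554 + [(30, 9)] * 267
    assert len(exclude_alert(Cohort.from_pairs(pairs))) == 267


def test_validation_report_four_results_match_recounts(tiny_cohort):
    report = validation_report(tiny_cohort)
    assert (report.primary_absolute.successes, report.primary_absolute.n) == (3, 5)
    assert (report.primary_relative.successes, report.primary_relative.n) == (4, 5)
    # sensitivity drops the two alert rows
    assert report.sensitivity_absolute.n == 3
    assert report.sensitivity_absolute.successes == 1
    assert report.sensitivity_relative.successes == 2


def test_validation_report_all_alert_sensitivity_absent():
    report = validation_report(Cohort.from_pairs([(0, 15)] * 5))
    assert report.primary_absolute.proportion == 1.0
    assert report.sensitivity_absolute is None
    assert report.sensitivity_relative is None
    assert "not computable" in report.to_text()


def test_report_percent_formatting_one_decimal():
    assert format_pct(659 / 821) == "80.3"
    assert format_pct(0.125) == "12.5"  # round-half-even keeps exact halves
    assert format_pct(1.0) == "100.0"


def test_report_csv_rows_shape(tiny_cohort):
    rows = validation_report(tiny_cohort).to_csv_rows()
    assert [r["analysis"] for r in rows] == ["primary", "primary",
                                             "sensitivity", "sensitivity"]
    assert [r["kind"] for r in rows] == ["absolute", "relative"] * 2
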