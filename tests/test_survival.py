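"""Survival statistics: Kaplan-Meier, Cox, Harrell's C, correlated comparison."""

import numpy as np
import pytest

from recip import (
    CohortValidationError,
    ConvergenceError,
    SurvivalSample,
    UndefinedStatisticError,
    compare_cindex,
    cox_univariate,
    harrell_cindex,
    km_estimate,
)

from conftest import random_survival_cohort


# ---------------------------------------------------------------- Kaplan-Meier

def test_km_no_censoring_drops_by_one_nth():
    sample = SurvivalSample(np.array([1.0, 2, 3, 4, 5]), np.ones(5, int))
    curve = km_estimate(sample)
    steps = [curve.survival_at(t) for t in (1, 2, 3, 4, 5)]
    assert steps == pytest.approx([0.8, 0.6, 0.4, 0.2, 0.0])
    assert curve.median == 3.0  # earliest time with survival <= 0.5


def test_km_matches_hand_computed_product_limit_table():
    """6 subjects, censoring interleaved between deaths.

    times 1,2,3,4,5,6 with events 1,0,1,1,0,1:
    S(1) = 5/6; t=2 censored; S(3) = 5/6 * 3/4 = 5/8;
    S(4) = 5/8 * 2/3 = 5/12; t=5 censored; S(6) = 0. Median = 4.
    """
    sample = SurvivalSample(np.array([1.0, 2, 3, 4, 5, 6]),
                            np.array([1, 0, 1, 1, 0, 1]))
    curve = km_estimate(sample)
    assert curve.survival_at(1) == pytest.approx(5 / 6)
    assert curve.survival_at(2) == pytest.approx(5 / 6)
    assert curve.survival_at(3) == pytest.approx(5 / 8)
    assert curve.survival_at(4) == pytest.approx(5 / 12)
    assert curve.survival_at(5.5) == pytest.approx(5 / 12)
    assert curve.survival_at(6) == pytest.approx(0.0)
    assert curve.median == 4.0


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(2)
    times = rng.exponential(10, 200)
    sample = SurvivalSample(times, np.ones(200, int))
    curve = km_estimate(sample)
    for t in np.quantile(times, [0.1, 0.5, 0.9]):
        assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)


def test_km_exponential_median_recovery():
    rng = np.random.default_rng(7)
    times = rng.exponential(12.0 / np.log(2.0), 5000)
    curve = km_estimate(SurvivalSample(times, np.ones(5000, int)))
    assert curve.median == pytest.approx(12.0, rel=0.05)
    assert curve.median_ci[0] < curve.median < curve.median_ci[1]


def test_km_median_undefined_when_curve_stays_high():
    sample = SurvivalSample(np.array([1.0, 2, 3, 4]), np.array([1, 0, 0, 0]))
    curve = km_estimate(sample)
    assert np.isinf(curve.median)


def test_km_all_zero_times_rejected():
    with pytest.raises(CohortValidationError):
        km_estimate(SurvivalSample(np.zeros(3), np.ones(3, int)))


# ------------------------------------------------------------------------ Cox

def test_cox_identical_groups_hr_one():
    times = np.tile(np.array([3.0, 5, 7, 11, 13]), 2)
    events = np.ones(10, int)
    group = np.repeat([0.0, 1.0], 5)
    res = cox_univariate(SurvivalSample(times, events), group)
    assert res.hr == pytest.approx(1.0, abs=1e-6)
    assert res.ci_low <= res.hr <= res.ci_high


def test_cox_matches_partial_likelihood_grid_search():
    """1-D grid oracle: log partial likelihood maximized directly (no ties)."""
    times = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.7, 8.0, 9.9])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, 0.0, -0.4])

    def log_pl(beta):
        order = np.argsort(times)
        ll = 0.0
        for idx, i in enumerate(order):
            if events[i]:
                at_risk = order[idx:]
                ll += beta * x[i] - np.log(np.exp(beta * x[at_risk]).sum())
        return ll

    grid = np.arange(-3.0, 3.0, 1e-3)
    beta_grid = grid[np.argmax([log_pl(b) for b in grid])]
    res = cox_univariate(SurvivalSample(times, events), x)
    assert res.coef == pytest.approx(beta_grid, abs=2e-3)


def test_cox_two_group_hazard_ratio_recovery():
    rng = np.random.default_rng(31)
    n = 2000
    group = rng.integers(0, 2, n).astype(float)
    true_t = rng.exponential(1.0 / np.where(group == 1, 2.0, 1.0))
    censor = rng.uniform(0, np.quantile(true_t, 0.995) * 2.2, n)
    times = np.minimum(true_t, censor)
    events = (true_t <= censor).astype(int)
    res = cox_univariate(SurvivalSample(times, events), group)
    assert 1.8 <= res.hr <= 2.2
    assert res.p < 0.001


def test_cox_constant_covariate_rejected():
    with pytest.raises(CohortValidationError):
        cox_univariate(SurvivalSample(np.array([1.0, 2]), np.array([1, 1])),
                       np.array([1.0, 1.0]))


def test_cox_perfect_separation_signaled():
    # all deaths in one group far before the other group's censoring
    times = np.array([1.0, 2, 3, 100, 101, 102])
    events = np.array([1, 1, 1, 0, 0, 0])
    group = np.array([1.0, 1, 1, 0, 0, 0])
    with pytest.raises(ConvergenceError):
        cox_univariate(SurvivalSample(times, events), group)


# -------------------------------------------------------------------- C-index

def cindex_brute(times, events, risk):
    """O(n^2) all-ordered-pairs evaluation of Harrell's rules."""
    num = 0.0
    n_pairs = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not usable:
                continue
            n_pairs += 1
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    return num / n_pairs if n_pairs else None


def test_cindex_all_tied_risks_is_half():
    sample = SurvivalSample(np.array([1.0, 2, 3, 4]), np.ones(4, int))
    assert harrell_cindex(sample, np.ones(4)).c == pytest.approx(0.5)


def test_cindex_perfect_concordance():
    times = np.array([5.0, 3, 9, 1, 7])
    sample = SurvivalSample(times, np.ones(5, int))
    assert harrell_cindex(sample, -times).c == pytest.approx(1.0)


def test_cindex_equals_brute_force_on_random_cohorts():
    rng = np.random.default_rng(13)
    for _ in range(100):
        n = int(rng.integers(5, 31))
        times, events = random_survival_cohort(rng, n)
        risk = rng.integers(0, 4, n).astype(float)
        expected = cindex_brute(times, events, risk)
        if expected is None:
            with pytest.raises(UndefinedStatisticError):
                harrell_cindex(SurvivalSample(times, events), risk)
        else:
            got = harrell_cindex(SurvivalSample(times, events), risk)
            assert got.c == pytest.approx(expected, abs=1e-12)


def test_cindex_cross_checked_against_scikit_survival():
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(29)
    for _ in range(25):
        n = int(rng.integers(10, 60))
        times, events = random_survival_cohort(rng, n)
        risk = rng.normal(size=n)
        mine = harrell_cindex(SurvivalSample(times, events), risk).c
        ref = concordance_index_censored(events.astype(bool), times, risk)[0]
        assert mine == pytest.approx(ref, abs=1e-12)


def test_cindex_invariant_under_monotone_transform():
    rng = np.random.default_rng(41)
    times, events = random_survival_cohort(rng, 50)
    risk = rng.normal(size=50)
    sample = SurvivalSample(times, events)
    base = harrell_cindex(sample, risk).c
    assert harrell_cindex(sample, np.exp(risk)).c == pytest.approx(base)
    assert harrell_cindex(sample, 3 * risk - 7).c == pytest.approx(base)


def test_cindex_no_usable_pairs_signaled():
    sample = SurvivalSample(np.array([5.0, 5.0]), np.array([0, 0]))
    with pytest.raises(UndefinedStatisticError):
        harrell_cindex(sample, np.array([1.0, 2.0]))


def test_cox_and_cindex_rank_groups_consistently():
    rng = np.random.default_rng(53)
    n = 500
    group = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(1.0 / np.where(group == 1, 2.5, 1.0))
    sample = SurvivalSample(times, np.ones(n, int))
    hr = cox_univariate(sample, group).hr
    c = harrell_cindex(sample, group).c
    assert (hr > 1.0) == (c > 0.5)


# ------------------------------------------------------- correlated C-indices

def test_compare_identical_risks_degenerate():
    rng = np.random.default_rng(61)
    times, events = random_survival_cohort(rng, 40)
    risk = rng.normal(size=40)
    with pytest.warns(UserWarning, match="degenerate"):
        res = compare_cindex(SurvivalSample(times, events), risk, risk)
    assert res.delta == 0.0
    assert res.p == 1.0


def test_compare_variance_positive_and_p_in_unit_interval():
    rng = np.random.default_rng(67)
    for _ in range(20):
        times, events = random_survival_cohort(rng, 60)
        sample = SurvivalSample(times, events)
        res = compare_cindex(sample, rng.normal(size=60), rng.normal(size=60))
        assert res.se >= 0.0
        assert 0.0 <= res.p <= 1.0


def test_influence_variance_agrees_with_leave_one_out_jackknife():
    """The influence-based se should track an exact delete-one jackknife."""
    rng = np.random.default_rng(71)
    times = rng.exponential(10, 120)
    events = rng.integers(0, 2, 120)
    events[events.sum() == 0] = 1
    risk = rng.normal(size=120)
    sample = SurvivalSample(times, events)
    res = harrell_cindex(sample, risk)
    loo = []
    for k in range(120):
        keep = np.ones(120, bool)
        keep[k] = False
        loo.append(
            harrell_cindex(SurvivalSample(times[keep], events[keep]), risk[keep]).c
        )
    loo = np.asarray(loo)
    jack_se = np.sqrt((119 / 120) * ((loo - loo.mean()) ** 2).sum())
    assert res.se == pytest.approx(jack_se, rel=0.15)


def test_compare_detects_informative_vs_noise_predictor():
    rng = np.random.default_rng(73)
    hits = 0
    for _ in range(25):
        n = 500
        risk = rng.normal(size=n)
        times = rng.exponential(12 * np.exp(-0.8 * risk))
        sample = SurvivalSample(times, np.ones(n, int))
        res = compare_cindex(sample, risk, rng.normal(size=n))
        hits += res.p < 0.05
    assert hits >= 20  # power >= 80%
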