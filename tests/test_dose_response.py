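"""Cohort simulation and dose-response statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from y90dose.dose_response import (
    LesionCohort,
    logistic_fit,
    rank_sum_test,
    response_probability,
    roc_analysis,
    simulate_cohort,
)

# KL projection of the response model onto the logistic family, computed once
# with an independent scipy.optimize oracle on exact probabilities
KL_BETA0 = -3.66773
KL_BETA1 = 0.0416672
KL_ED50 = 88.024
KL_ED80 = 121.295


@pytest.mark.parametrize(
    "dose,expected",
    [(0.0, np.exp(-8.0)), (85.0, 0.533942), (199.0, 0.97336)],
)
def test_response_probability_values(dose, expected):
    assert response_probability(dose) == pytest.approx(expected, rel=1e-4)


def test_response_probability_domain():
    with pytest.raises(ValueError):
        response_probability(-1.0)
    with pytest.warns(UserWarning, match="design range"):
        response_probability(250.0)


def test_cohort_design_and_determinism():
    c1 = simulate_cohort(seed=42)
    c2 = simulate_cohort(seed=42)
    assert np.array_equal(c1.doses_gy, np.arange(1.0, 200.0, 2.0))
    assert c1.n == 100
    assert np.array_equal(c1.responses, c2.responses)
    assert not np.array_equal(c1.responses, simulate_cohort(seed=43).responses)


def test_mean_responder_fraction_matches_quadrature():
    """Empirical response rate converges to the grid mean of the response
    model (0.558 by quadrature)."""
    grid_mean = response_probability(np.arange(1.0, 200.0, 2.0)).mean()
    frac = np.mean([simulate_cohort(seed=s).responses.mean() for s in range(500)])
    assert grid_mean == pytest.approx(0.558, abs=0.001)
    assert frac == pytest.approx(grid_mean, abs=0.01)


def test_per_dose_rates_chi2_goodness_of_fit():
    """Responses per dose level over many seeds are binomial with the model
    probabilities (chi-square GOF, alpha = 0.01)."""
    doses = np.arange(1.0, 200.0, 2.0)
    p = response_probability(doses)
    n_seeds = 1000
    counts = np.zeros_like(p)
    for s in range(n_seeds):
        counts += simulate_cohort(seed=s).responses
    expected = n_seeds * p
    var = n_seeds * p * (1 - p)
    chi2 = float((((counts - expected) ** 2) / var).sum())
    crit = stats.chi2.ppf(0.99, df=len(doses))
    assert chi2 < crit


def test_rank_sum_identical_groups_p_near_one():
    res = rank_sum_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.pvalue > 0.9


def test_rank_sum_complete_separation_is_minimal_p():
    """{1,2,3} vs {101,102,103} attains the smallest p over all 20 label
    assignments (exact enumeration oracle)."""
    values = [1.0, 2.0, 3.0, 101.0, 102.0, 103.0]
    p_sep = rank_sum_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0]).pvalue
    all_p = []
    for combo in itertools.combinations(range(6), 3):
        g1 = [values[i] for i in combo]
        g0 = [values[i] for i in range(6) if i not in combo]
        all_p.append(rank_sum_test(g1, g0).pvalue)
    assert p_sep == pytest.approx(min(all_p))
    assert rank_sum_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0]).statistic == 0.0


def test_rank_sum_empty_group_raises():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


def test_roc_auc_equals_mannwhitney_u():
    """Trapezoidal AUC over the empirical ROC equals U/(n1*n0) exactly."""
    cohort = simulate_cohort(seed=5)
    roc = roc_analysis(cohort)
    u = stats.mannwhitneyu(
        cohort.responder_doses, cohort.non_responder_doses
    ).statistic
    n1 = cohort.responses.sum()
    n0 = cohort.n - n1
    assert roc.auc == pytest.approx(u / (n1 * n0), rel=1e-12)


def test_roc_against_sklearn_oracle():
    from sklearn.metrics import roc_auc_score

    cohort = simulate_cohort(seed=11)
    roc = roc_analysis(cohort)
    assert roc.auc == pytest.approx(
        roc_auc_score(cohort.responses, cohort.doses_gy), rel=1e-12
    )


def test_roc_perfect_and_null_classifiers():
    perfect = LesionCohort(doses_gy=[1, 2, 3, 10, 11, 12],
                           responses=[0, 0, 0, 1, 1, 1])
    assert roc_analysis(perfect).auc == pytest.approx(1.0)
    assert roc_analysis(perfect).youden_sensitivity == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    aucs = []
    for _ in range(200):
        doses = np.arange(1.0, 200.0, 2.0)
        responses = rng.integers(0, 2, size=100)
        if responses.min() == responses.max():
            continue
        aucs.append(roc_analysis(LesionCohort(doses, responses)).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_roc_single_class_raises():
    with pytest.raises(ValueError):
        roc_analysis(LesionCohort(doses_gy=[1.0, 2.0], responses=[1, 1]))


def test_youden_invariant_under_monotone_dose_transform():
    cohort = simulate_cohort(seed=9)
    roc = roc_analysis(cohort)
    transformed = LesionCohort(doses_gy=np.log(cohort.doses_gy),
                               responses=cohort.responses)
    roc_t = roc_analysis(transformed)
    assert roc_t.auc == pytest.approx(roc.auc, rel=1e-12)
    assert roc_t.youden_threshold == pytest.approx(np.log(roc.youden_threshold))
    assert roc_t.youden_sensitivity == pytest.approx(roc.youden_sensitivity)
    assert roc_t.youden_specificity == pytest.approx(roc.youden_specificity)


def test_logistic_parameter_recovery_large_n(rng):
    """Sampling from an exact logistic curve recovers the parameters within
    2 SE at large n."""
    beta0, beta1 = -4.0, 0.05
    doses = rng.uniform(1, 200, size=8000)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * doses)))
    responses = (rng.random(8000) < p).astype(int)
    fit = logistic_fit(doses_gy=doses, responses=responses)
    assert fit.converged
    se0 = np.sqrt(fit.cov[0, 0])
    se1 = np.sqrt(fit.cov[1, 1])
    assert abs(fit.beta0 - beta0) < 2 * se0
    assert abs(fit.beta1 - beta1) < 2 * se1
    assert fit.ed50_gy == pytest.approx(-beta0 / beta1, rel=0.05)


def test_logistic_kl_projection_regression():
    """Weighted fit to the exact response probabilities reproduces the pinned
    KL projection of the response model onto the logistic family."""
    doses = np.arange(1.0, 200.0, 2.0)
    p = np.asarray(response_probability(doses))
    fit = logistic_fit(doses_gy=doses, responses=p)
    assert fit.converged
    assert fit.beta0 == pytest.approx(KL_BETA0, abs=2e-3)
    assert fit.beta1 == pytest.approx(KL_BETA1, rel=1e-3)
    assert fit.ed50_gy == pytest.approx(KL_ED50, abs=0.1)
    assert fit.ed80_gy == pytest.approx(KL_ED80, abs=0.1)


def test_logistic_decreasing_exponent_convention():
    fit = logistic_fit(simulate_cohort(seed=2))
    assert fit.a == -fit.beta1
    assert fit.b == fit.beta0
    assert fit.predict(fit.ed50_gy) == pytest.approx(0.5, abs=1e-9)


def test_logistic_separation_flagged():
    doses = np.concatenate([np.arange(1, 51), np.arange(150, 200)]).astype(float)
    responses = (doses > 100).astype(int)
    fit = logistic_fit(doses_gy=doses, responses=responses)
    assert not fit.converged
    assert fit.ed50_gy is None


def test_logistic_single_class_raises():
    with pytest.raises(ValueError):
        logistic_fit(doses_gy=[1.0, 2.0, 3.0], responses=[1, 1, 1])


def test_logistic_profile_ci_brackets_delta_ci():
    cohort = simulate_cohort(seed=17)
    delta = logistic_fit(cohort)
    profile = logistic_fit(cohort, ci_method="profile")
    assert profile.ed50_gy == pytest.approx(delta.ed50_gy, abs=0.5)
    lo, hi = profile.ed50_ci95
    assert lo < profile.ed50_gy < hi
    # profile interval is asymmetric but of comparable width
    assert (hi - lo) == pytest.approx(delta.ed50_ci95[1] - delta.ed50_ci95[0],
                                      rel=0.5)


def test_cohort_csv_round_trip(tmp_path):
    cohort = simulate_cohort(seed=8)
    path = tmp_path / "cohort.csv"
    cohort.to_csv(path)
    back = LesionCohort.from_csv(path)
    assert np.array_equal(back.doses_gy, cohort.doses_gy)
    assert np.array_equal(back.responses, cohort.responses)
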