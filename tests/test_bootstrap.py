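"""Percentile and BCa bootstrap intervals and per-score-class statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from scoreboot.bootstrap import (
    BootstrapDistribution,
    bca_adjusted_levels,
    bca_interval,
    bias_correction,
    jackknife_acceleration,
    percentile_interval,
    score_class_cis,
)
from scoreboot.pooling import PoolingPlan
from scoreboot.simulate import (
    PredictorSpec,
    SyntheticSpec,
    generate_cohort,
    true_class_probabilities,
    true_model,
)

from conftest import make_cohort


class TestPercentileInterval:
    def test_uniform_grid_hits_stated_percentiles(self):
        grid = np.arange(1, 1001) / 1000.0
        assert percentile_interval(grid, 0.95) == (0.025, 0.975)

    def test_degenerate_distribution(self):
        low, high = percentile_interval(np.full(100, 0.4))
        assert (low, high) == (0.4, 0.4)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="40"):
            percentile_interval(np.arange(30) / 30.0)

    def test_endpoints_are_replicates(self, rng):
        est = rng.normal(size=501)
        low, high = percentile_interval(est)
        assert low in est and high in est


def reference_bca(x, B, level, seed):
    """Independently coded BCa for the sample mean, sharing the documented
    resample stream (default_rng(seed).integers(0, n, (B, n)))."""
    x = np.asarray(x, float)
    n = len(x)
    theta = x.mean()
    idx = np.random.default_rng(seed).integers(0, n, size=(B, n))
    boots = sorted(x[row].mean() for row in idx)
    boots = np.array(boots)
    below = sum(b < theta for b in boots) + 0.5 * sum(b == theta for b in boots)
    frac = below / B
    frac = min(max(frac, 1 / (2 * B)), 1 - 1 / (2 * B))
    z0 = norm.ppf(frac)
    jack = np.array([np.r_[x[:i], x[i + 1:]].mean() for i in range(n)])
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    a = 0.0 if denom == 0 else (dev**3).sum() / (6 * denom)
    ends = []
    for zk in (norm.ppf((1 - level) / 2), norm.ppf(1 - (1 - level) / 2)):
        alpha = norm.cdf(z0 + (z0 + zk) / (1 - a * (z0 + zk)))
        k = min(max(int(np.ceil(alpha * B)), 1), B)
        ends.append(boots[k - 1])
    return ends[0], ends[1]


class TestBcaInterval:
    def test_matches_independent_reference(self):
        x = np.r_[np.ones(20), np.zeros(80)]
        for seed in (1, 7, 123):
            low, high, diag = bca_interval(x, np.mean, B=1000, seed=seed)
            ref_low, ref_high = reference_bca(x, B=1000, level=0.95, seed=seed)
            assert low == pytest.approx(ref_low, abs=1e-12)
            assert high == pytest.approx(ref_high, abs=1e-12)
            assert low <= 0.2 <= high
            assert 0.0 <= low <= high <= 1.0

    def test_vectorized_path_identical(self):
        x = np.random.default_rng(5).exponential(size=60)
        loop = bca_interval(x, np.mean, B=500, seed=9)
        fast = bca_interval(x, np.mean, B=500, seed=9, vectorized=True)
        assert loop[:2] == fast[:2]
        assert loop[2] == fast[2]

    def test_flat_jackknife_gives_zero_acceleration(self):
        assert jackknife_acceleration(np.full(25, 0.3)) == 0.0

    def test_symmetric_distribution_reduces_to_percentile(self):
        # z0 = 0 (theta at the median), a = 0 (flat jackknife)
        est = np.concatenate([np.linspace(0.1, 0.49, 500),
                              np.linspace(0.51, 0.9, 500)])
        dist = BootstrapDistribution(np.sort(est), 1000, theta_hat=0.5)
        z0 = bias_correction(dist.estimates, dist.theta_hat)
        assert z0 == 0.0
        a1, a2 = bca_adjusted_levels(z0, 0.0, 0.95)
        assert (a1, a2) == pytest.approx((0.025, 0.975))

    def test_determinism(self):
        x = np.random.default_rng(3).normal(size=40)
        r1 = bca_interval(x, np.mean, B=300, seed=11)
        r2 = bca_interval(x, np.mean, B=300, seed=11)
        assert r1 == r2

    def test_monotone_in_level(self):
        x = np.r_[np.ones(30), np.zeros(70)]
        widths = []
        for level in (0.90, 0.95, 0.99):
            low, high, _ = bca_interval(x, np.mean, B=1000, level=level, seed=2)
            widths.append((low, high))
        for (l1, h1), (l2, h2) in zip(widths, widths[1:]):
            assert l2 <= l1 and h2 >= h1

    def test_undefined_statistic_on_original_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            bca_interval(np.array([1.0, 2.0]), lambda s: np.nan, B=50, seed=0)

    def test_second_order_sanity_skewed_mean(self):
        # BCa should calibrate no worse than the plain percentile interval
        # for the mean of skewed data at small n
        rng = np.random.default_rng(42)
        n, reps, B = 25, 2000, 1000
        true_mean = 1.0
        cover_bca = cover_pct = 0
        for _ in range(reps):
            x = rng.exponential(size=n)
            low, high, diag, dist = bca_interval(
                x, np.mean, B=B, seed=rng.integers(2**31),
                vectorized=True, return_distribution=True,
            )
            cover_bca += low <= true_mean <= high
            plo, phi = percentile_interval(dist)
            cover_pct += plo <= true_mean <= phi
        err_bca = abs(cover_bca / reps - 0.95)
        err_pct = abs(cover_pct / reps - 0.95)
        assert err_bca <= err_pct + 0.005


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    est=st.lists(
        st.floats(min_value=0, max_value=1, allow_nan=False), min_size=40, max_size=400
    ),
    level=st.sampled_from([0.8, 0.9, 0.95, 0.99]),
)
def test_reduction_identity_bca_equals_percentile(est, level):
    """Forcing z0 = 0, a = 0 collapses BCa onto the percentile interval."""
    est = np.sort(np.asarray(est))
    a1, a2 = bca_adjusted_levels(0.0, 0.0, level)
    tail = (1 - level) / 2
    assert a1 == pytest.approx(tail, abs=1e-12)
    assert a2 == pytest.approx(1 - tail, abs=1e-12)
    from scoreboot.bootstrap import _nearest_rank

    low, high = percentile_interval(est, level)
    assert _nearest_rank(est, a1) == low
    assert _nearest_rank(est, a2) == high


def two_predictor_spec(seed, n=545):
    preds = (
        PredictorSpec("A", prevalence=0.35, beta=1.2),
        PredictorSpec("B", prevalence=0.25, beta=1.0),
    )
    return SyntheticSpec(
        n=n, predictors=preds, n_noise=0, target_prevalence=0.207, seed=seed
    )


class TestScoreClassCis:
    def test_all_morbid_class_degenerate_upper_bound(self):
        flag = np.r_[np.ones(10), np.zeros(40)]
        y = np.r_[np.ones(10), (np.random.default_rng(0).random(40) < 0.2)]
        cohort = make_cohort({"flag": flag}, y.astype(int))
        model = true_model(
            SyntheticSpec(
                n=50,
                predictors=(PredictorSpec("flag", 0.2, 1.0),),
                n_noise=0,
                baseline_logit=-1.5,
                target_prevalence=None,
            )
        )
        stats = score_class_cis(cohort, model, B=500, seed=3)
        top = stats[-1]
        assert top.proportion == 1.0
        assert top.ci_high == 1.0

    def test_class_sizes_and_occurrence_sum(self):
        spec = two_predictor_spec(seed=21)
        cohort, _ = generate_cohort(spec)
        stats = score_class_cis(cohort, true_model(spec), B=400, seed=5)
        assert sum(s.n for s in stats) == cohort.n
        assert sum(s.pct_occurrence for s in stats) == pytest.approx(100.0)

    def test_endpoints_within_unit_interval_and_ordered(self):
        spec = two_predictor_spec(seed=22)
        cohort, _ = generate_cohort(spec)
        for s in score_class_cis(cohort, true_model(spec), B=400, seed=6):
            assert 0.0 <= s.ci_low <= s.proportion <= s.ci_high <= 1.0 or (
                0.0 <= s.ci_low <= s.ci_high <= 1.0
            )

    def test_empty_class_in_train_rejected(self):
        spec = two_predictor_spec(seed=23)
        cohort, _ = generate_cohort(spec)
        plan = PoolingPlan.identity(5)  # scores only reach 2
        with pytest.raises(ValueError, match="empty"):
            score_class_cis(cohort, true_model(spec), plan, B=200, seed=0)

    def test_tiny_class_reports_reduced_b_effective(self):
        rng = np.random.default_rng(8)
        flag = np.r_[np.ones(1), np.zeros(59)]
        y = (rng.random(60) < 0.3).astype(int)
        cohort = make_cohort({"flag": flag}, y)
        model = true_model(
            SyntheticSpec(
                n=60, predictors=(PredictorSpec("flag", 0.02, 1.0),),
                n_noise=0, baseline_logit=-1.0, target_prevalence=None,
            )
        )
        with pytest.warns(UserWarning, match="empty in"):
            stats = score_class_cis(cohort, model, B=600, seed=4)
        top = stats[-1]
        assert top.n == 1
        assert top.B_effective < 600
        # singleton class empties in ~ (1-1/n)^n ~ 37% of replicates
        assert 0.5 * 600 <= top.B_effective <= 0.75 * 600

    def test_test_cohort_proportions_attached(self):
        spec = two_predictor_spec(seed=25)
        cohort, _ = generate_cohort(spec)
        spec2 = two_predictor_spec(seed=26)
        test, _ = generate_cohort(spec2)
        stats = score_class_cis(
            cohort, true_model(spec), B=300, seed=1, test=test
        )
        for s in stats:
            assert s.test_proportion is not None
            assert 0.0 <= s.test_proportion <= 1.0

    def test_determinism_same_seed(self):
        spec = two_predictor_spec(seed=27)
        cohort, _ = generate_cohort(spec)
        a = score_class_cis(cohort, true_model(spec), B=300, seed=9)
        b = score_class_cis(cohort, true_model(spec), B=300, seed=9)
        assert a == b

    def test_coverage_of_mid_class_probability(self):
        """BCa CIs for a mid-prevalence score class cover the enumerated
        true conditional outcome probability at close to nominal rate."""
        reps = 500
        spec0 = two_predictor_spec(seed=0)
        truth = true_class_probabilities(spec0, true_model(spec0))
        # class '1' is the mid-prevalence class
        p_true = float(
            truth.set_index("class_label").loc["1", "p_outcome_given_class"]
        )
        covered = 0
        for rep in range(reps):
            spec = two_predictor_spec(seed=10_000 + rep)
            cohort, _ = generate_cohort(spec)
            stats = score_class_cis(
                cohort, true_model(spec), B=1000, seed=50_000 + rep
            )
            mid = {s.label: s for s in stats}["1"]
            covered += mid.ci_low <= p_true <= mid.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.03)
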