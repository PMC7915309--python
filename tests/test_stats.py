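"""Nonparametric tests against enumeration/permutation oracles; trend fits."""

import itertools

import numpy as np
import pytest
import scipy.stats

from octquant import (
    EyeTimepointResult,
    build_timeseries,
    compare_cohorts,
    correlate_metric_drug,
    fit_linear_trend,
    fit_log_curve,
    paired_change,
)
from octquant import test_normality as normality_test  # alias: avoid pytest collection
from octquant.errors import DegenerateInputError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mwu_exact_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of all
    C(n1+n2, n1) group assignments of the pooled sample."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(sa, sb))
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2 * min(cdf, sf))


# ---------------------------------------------------------------------------
# time series assembly
# ---------------------------------------------------------------------------

def _res(eye, week, ratio, group="treated"):
    return EyeTimepointResult(
        eye_id=eye, laterality="RE", group=group, week=week,
        vit_rpe_ratio=ratio, vit_mean=ratio * 200, rpe_mean=200.0,
        n_bscans=61, n_rejected=0, aggregate_count=0,
        total_area_um2=ratio * 1e5, mean_area_um2=0.0,
        ilm_rnfl_thickness_um=60.0,
    )


class TestBuildTimeseries:
    def test_single_eye_single_week(self):
        ts = build_timeseries([_res("a", 0, 0.3)], "vit_rpe_ratio", "treated")
        assert ts.weeks.tolist() == [0.0]
        assert ts.values.tolist() == [pytest.approx(0.3)]
        assert ts.spreads.tolist() == [0.0]

    def test_two_eyes_mean(self):
        ts = build_timeseries(
            [_res("a", 2, 0.2), _res("b", 2, 0.4)], "vit_rpe_ratio", "treated")
        assert ts.values[0] == pytest.approx(0.3)

    def test_matches_brute_force_per_week_averages(self):
        rng = np.random.default_rng(12)
        weeks = [0, 1, 2, 4, 6, 8, 12, 24]
        results = [
            _res(f"e{i}", w, float(rng.uniform(0.1, 0.4)))
            for i in range(40) for w in weeks
        ]
        ts = build_timeseries(results, "vit_rpe_ratio", "treated")
        for j, w in enumerate(weeks):
            vals = [r.vit_rpe_ratio for r in results if r.week == w]
            assert ts.values[j] == pytest.approx(np.mean(vals), rel=1e-12)
            assert ts.n_per_week[j] == 40

    def test_unknown_metric_and_empty_group(self):
        with pytest.raises(KeyError):
            build_timeseries([_res("a", 0, 0.3)], "nope", "treated")
        with pytest.raises(DegenerateInputError):
            build_timeseries([_res("a", 0, 0.3)], "vit_rpe_ratio", "healthy_control")


class TestNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(13)
        res = normality_test(rng.normal(0, 1, 1000))
        assert res.p_value > 0.05

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(14)
        res = normality_test(rng.uniform(0, 1, 1000))
        assert res.p_value < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            normality_test([1.0, 1.0, 1.0])
        with pytest.raises(DegenerateInputError):
            normality_test([1.0, 2.0])


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = compare_cohorts([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        res = compare_cohorts([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_equals_enumeration_for_small_n(self):
        """For every split with n1+n2 <= 8 the exact p matches the
        full-enumeration oracle."""
        rng = np.random.default_rng(15)
        for n1 in range(1, 5):
            for n2 in range(n1, 9 - n1):
                a = list(rng.normal(0, 1, n1))
                b = list(rng.normal(0.5, 1, n2))
                res = compare_cohorts(a, b)
                assert res.p_value == pytest.approx(
                    mwu_exact_enumeration(a, b), abs=1e-12), (n1, n2)

    def test_large_sample_p_matches_permutations(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.4, 1, 30)
        res = compare_cohorts(a, b)
        # seeded permutation oracle on the U statistic
        pooled = np.concatenate([a, b])
        ranks = scipy.stats.rankdata(pooled)
        u_obs = ranks[:30].sum() - 30 * 31 / 2
        mid = 30 * 30 / 2
        B = 100_000
        perm = rng.permuted(np.tile(ranks, (B, 1)), axis=1)
        u_perm = perm[:, :30].sum(axis=1) - 30 * 31 / 2
        p_perm = np.mean(np.abs(u_perm - mid) >= abs(u_obs - mid))
        assert res.p_value == pytest.approx(p_perm, abs=0.01)

    def test_empty_sample_raises(self):
        with pytest.raises(DegenerateInputError):
            compare_cohorts([], [1.0])


class TestWilcoxon:
    def test_no_change_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_change([1, 2, 3], [1, 2, 3])

    def test_all_positive_differences_exact_p(self):
        before = [0, 0, 0, 0, 0]
        after = [1, 2, 3, 4, 5]
        res = paired_change(before, after, alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)

    def test_large_sample_p_matches_sign_flips(self):
        rng = np.random.default_rng(17)
        before = rng.normal(0, 1, 50)
        after = before + rng.normal(0.3, 1, 50)
        res = paired_change(before, after)
        d = after - before
        ranks = scipy.stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mid = 50 * 51 / 4
        B = 100_000
        signs = rng.integers(0, 2, (B, 50))
        w_perm = (signs * ranks).sum(axis=1)
        p_perm = np.mean(np.abs(w_perm - mid) >= abs(w_obs - mid))
        assert res.p_value == pytest.approx(p_perm, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(DegenerateInputError):
            paired_change([1, 2], [1, 2, 3])


class TestFits:
    def test_exact_line_recovers_printed_coefficients(self):
        """A noiseless line with slope -0.0002 and intercept 0.2543 is
        recovered exactly with R^2 = 1."""
        x = np.array([10.0, 40.0, 80.0, 240.0])
        y = -0.0002 * x + 0.2543
        fit = fit_linear_trend(x, y)
        assert fit.slope == pytest.approx(-0.0002, rel=1e-9)
        assert fit.intercept == pytest.approx(0.2543, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_y_gives_zero_slope_and_r2(self):
        fit = fit_linear_trend([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_noisy_line_slope_within_sampling_error(self):
        rng = np.random.default_rng(18)
        x = np.linspace(0, 10, 100)
        sigma = 0.5
        y = 2.0 * x + 1.0 + rng.normal(0, sigma, 100)
        fit = fit_linear_trend(x, y)
        se = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope - 2.0) < 3 * se

    def test_degenerate_linear_inputs(self):
        with pytest.raises(DegenerateInputError):
            fit_linear_trend([1, 2], [1, 2])
        with pytest.raises(DegenerateInputError):
            fit_linear_trend([3, 3, 3], [1, 2, 3])

    def test_exact_log_curve(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = 2.0 * np.log(x) + 1.0
        fit = fit_log_curve(x, y)
        assert fit.slope == pytest.approx(2.0, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_y_log(self):
        fit = fit_log_curve([1, 2, 4], [3.0, 3.0, 3.0])
        assert fit.slope == 0.0

    def test_noisy_log_recovery_within_10pct(self):
        rng = np.random.default_rng(19)
        x = np.linspace(1, 24, 50)
        y = 5.0 * np.log(x) + 2.0 + rng.normal(0, 0.5, 50)
        fit = fit_log_curve(x, y)
        assert fit.slope == pytest.approx(5.0, rel=0.10)

    def test_log_rejects_non_positive_x(self):
        with pytest.raises(DegenerateInputError):
            fit_log_curve([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_r_squared_bounded_on_random_data(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            x = rng.uniform(0.5, 10, 10)
            y = rng.uniform(-5, 5, 10)
            assert 0.0 <= fit_linear_trend(x, y).r_squared <= 1.0
            assert 0.0 <= fit_log_curve(x, y).r_squared <= 1.0


class TestDrugCorrelation:
    def test_proportional_series_has_r_one(self):
        metric = [1.0, 2.0, 3.0, 4.0]
        drug = [2.0, 4.0, 6.0, 8.0]
        c = correlate_metric_drug(metric, drug)
        assert c.pearson_r == pytest.approx(1.0)
        assert c.fit.r_squared == pytest.approx(1.0)

    def test_independent_series_rarely_correlate(self):
        """Under the null (independent series, n=100) |r| < 0.2 in well
        over 90% of seeded replicates."""
        rng = np.random.default_rng(21)
        hits = 0
        reps = 100
        for _ in range(reps):
            m = rng.normal(0, 1, 100)
            d = rng.normal(0, 1, 100)
            if abs(correlate_metric_drug(m, d).pearson_r) < 0.2:
                hits += 1
        assert hits / reps >= 0.90

    def test_shared_latent_decay_correlates(self):
        weeks = np.array([1.0, 4.0, 8.0, 24.0])
        latent = np.exp(-0.3 * weeks)
        rng = np.random.default_rng(22)
        metric = 5e5 * latent * (1 + rng.normal(0, 0.05, 4))
        drug = 80 * latent * (1 + rng.normal(0, 0.05, 4))
        assert correlate_metric_drug(metric, drug).pearson_r > 0.9

    def test_too_few_weeks(self):
        with pytest.raises(DegenerateInputError):
            correlate_metric_drug([1.0, 2.0], [1.0, 2.0])
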