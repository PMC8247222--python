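"""z-tests, correlations and the stratified comparison, checked against
independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from smos import (
    CohortRecord,
    SMoSResult,
    normality_check,
    one_sample_z,
    pearson_correlation,
    stratified_comparison,
    summarize_scores,
    summarize_stratum,
    two_sample_z,
)
from smos.cohort_stats import StratumSummary
from smos.errors import (
    EmptyStratumError,
    InsufficientDataError,
    InsufficientPairsError,
    UndefinedCorrelationError,
    UnsupportedSampleSizeError,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_two_sided_p(z: float) -> float:
    """Two-sided normal p by numerical integration of the density."""
    density = lambda t: math.exp(-0.5 * t * t) / math.sqrt(2 * math.pi)
    tail, _ = quad(density, abs(z), 40.0)
    return 2.0 * tail


def oracle_pearson_r(x, y) -> float:
    """Pearson r straight from the covariance definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _record(score: float, **kw) -> CohortRecord:
    half = min(score / 2.0, 50.0)
    smos = SMoSResult(ws_points=half, dsc_points=score - half, total=score)
    defaults = dict(patient_id="p", age=65.0, sex="male", operative=False)
    defaults.update(kw)
    return CohortRecord(smos=smos, **defaults)


class TestSummaries:
    def test_hand_computed(self):
        s = summarize_scores([50.0, 60.0, 70.0])
        assert s.n == 3
        assert s.mean == 60.0
        assert s.sd == pytest.approx(10.0)
        assert s.se == pytest.approx(10.0 / math.sqrt(3))

    def test_single_observation_flagged(self):
        s = summarize_scores([42.0])
        assert (s.n, s.mean) == (1, 42.0)
        assert s.sd is None and s.se is None
        assert "sd-undefined" in s.flags

    def test_empty_stratum_rejected(self):
        with pytest.raises(EmptyStratumError):
            summarize_scores([])
        with pytest.raises(EmptyStratumError):
            summarize_stratum([])

    def test_matches_direct_summation_oracle(self, rng):
        values = rng.uniform(0, 100, size=100)
        s = summarize_scores(values)
        n = len(values)
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        assert s.mean == pytest.approx(mean, abs=1e-10)
        assert s.sd == pytest.approx(math.sqrt(var), abs=1e-10)
        assert s.se == pytest.approx(math.sqrt(var / n), abs=1e-10)

    def test_records_with_missing_smos_excluded(self):
        records = [_record(60.0), CohortRecord(patient_id="x", age=50, sex="male")]
        assert summarize_stratum(records).n == 1


class TestOneSampleZ:
    def test_reference_total_row(self):
        # published total stratum: mean 58.7, SE 1.68, n 182 vs population 74.3
        summary = StratumSummary(n=182, mean=58.7, sd=1.68 * math.sqrt(182), se=1.68)
        t = one_sample_z(summary, 74.3)
        assert t.mean_difference == pytest.approx(-15.6, abs=1e-12)
        assert t.ci_low == pytest.approx(-18.90, abs=0.05)
        assert t.ci_high == pytest.approx(-12.30, abs=0.05)
        assert t.p < 0.001

    def test_null_case(self):
        summary = summarize_scores([60.0, 62.0, 58.0, 60.0])
        t = one_sample_z(summary, summary.mean)
        assert t.mean_difference == 0.0
        assert t.z == 0.0
        assert t.p == 1.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            one_sample_z(summarize_scores([42.0]), 74.3)

    def test_small_n_flagged(self):
        t = one_sample_z(summarize_scores([50, 60, 70, 55.0]), 74.3)
        assert "small-n" in t.flags

    def test_p_matches_density_integration(self, rng):
        for _ in range(20):
            summary = summarize_scores(rng.uniform(30, 90, size=rng.integers(5, 40)))
            t = one_sample_z(summary, float(rng.uniform(40, 80)))
            assert t.p == pytest.approx(oracle_two_sided_p(t.z), abs=1e-10)

    def test_p_at_z_1_96(self):
        # p(z = 1.96) ~ 0.05
        summary = StratumSummary(n=100, mean=1.96, sd=10.0, se=1.0)
        t = one_sample_z(summary, 0.0)
        assert t.p == pytest.approx(0.05, abs=1e-3)

    @given(
        mean=st.floats(20, 90),
        se=st.floats(0.5, 8.0),
        ref=st.floats(10, 95),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_ci_symmetry_and_width(self, mean, se, ref, alpha):
        from scipy.stats import norm

        summary = StratumSummary(n=30, mean=mean, sd=se * math.sqrt(30), se=se)
        t = one_sample_z(summary, ref, alpha)
        assert t.ci_low <= t.mean_difference <= t.ci_high
        mid = (t.ci_low + t.ci_high) / 2.0
        assert mid == pytest.approx(t.mean_difference, abs=1e-9)
        width = 2.0 * norm.ppf(1.0 - alpha / 2.0) * se
        assert t.ci_high - t.ci_low == pytest.approx(width, rel=1e-12)

    def test_p_decreases_with_abs_z(self):
        summaries = [StratumSummary(n=50, mean=m, sd=7.07, se=1.0) for m in (1.0, 2.0, 3.0)]
        ps = [one_sample_z(s, 0.0).p for s in summaries]
        assert ps[0] > ps[1] > ps[2]


class TestTwoSampleZ:
    def test_operative_contrast_difference(self):
        op = StratumSummary(n=38, mean=50.2, sd=21.25, se=21.25 / math.sqrt(38))
        nonop = StratumSummary(n=144, mean=62.1, sd=22.97, se=22.97 / math.sqrt(144))
        t = two_sample_z(op, nonop)
        assert abs(t.mean_difference) == pytest.approx(11.9, abs=1e-9)
        assert t.p < 0.05

    def test_identical_groups(self):
        g = summarize_scores([50, 60, 70.0])
        t = two_sample_z(g, g)
        assert t.mean_difference == 0.0
        assert t.p == 1.0

    def test_insufficient_group(self):
        with pytest.raises(InsufficientDataError):
            two_sample_z(summarize_scores([42.0]), summarize_scores([50, 60.0]))

    def test_monte_carlo_difference_recovery(self, rng):
        # simulated normal groups: estimated difference within 3 SE_diff of
        # the true difference in >= 99% of replicates
        true_diff, n1, n2, sd = 8.0, 60, 45, 15.0
        hits = 0
        reps = 1000
        for _ in range(reps):
            g1 = summarize_scores(rng.normal(60.0 + true_diff, sd, size=n1))
            g2 = summarize_scores(rng.normal(60.0, sd, size=n2))
            t = two_sample_z(g1, g2)
            se_diff = math.sqrt(g1.sd**2 / n1 + g2.sd**2 / n2)
            if abs(t.mean_difference - true_diff) <= 3.0 * se_diff:
                hits += 1
        assert hits / reps >= 0.99


class TestStratifiedComparison:
    def test_layout_and_order(self, norms):
        records = [_record(60.0, age=65.0)]
        rows = stratified_comparison(records, norms)
        labels = [r.label for r in rows]
        assert labels[:3] == ["total/combined", "total/male", "total/female"]
        assert labels[3:6] == ["30-39/combined", "30-39/male", "30-39/female"]
        assert len(rows) == 18

    def test_empty_stratum_flagged_not_dropped(self, norms, rng):
        records = [
            _record(float(s), patient_id=f"m{i}", age=35.0)
            for i, s in enumerate(rng.uniform(40, 80, size=8))
        ]
        rows = {r.label: r for r in stratified_comparison(records, norms)}
        assert rows["30-39/female"].skipped
        assert rows["30-39/female"].skip_reason == "no patients"
        assert not rows["30-39/male"].skipped

    def test_single_stratum_matches_direct_test(self, norms, rng):
        scores = rng.uniform(40, 90, size=12)
        records = [_record(float(s), patient_id=f"p{i}", age=45.0) for i, s in enumerate(scores)]
        rows = {r.label: r for r in stratified_comparison(records, norms)}
        direct = one_sample_z(summarize_scores(scores), norms.get("40-49", "male").smos_mean)
        row = rows["40-49/male"]
        assert row.test.mean_difference == pytest.approx(direct.mean_difference, abs=1e-12)
        assert row.test.p == pytest.approx(direct.p, abs=1e-15)

    def test_total_counts_are_consistent(self, norms, rng):
        records = []
        i = 0
        for age, sex, k in [(35, "male", 5), (45, "female", 7), (75, "male", 4), (62, "female", 6)]:
            for _ in range(k):
                records.append(
                    _record(float(rng.uniform(30, 90)), patient_id=f"r{i}", age=float(age), sex=sex)
                )
                i += 1
        rows = {r.label: r for r in stratified_comparison(records, norms)}
        total_n = rows["total/combined"].summary.n
        band_n = sum(
            rows[f"{b}/combined"].summary.n
            for b in ("30-39", "40-49", "50-59", "60-69", "70+")
            if rows[f"{b}/combined"].summary is not None
        )
        assert total_n == len(records) == band_n
        assert total_n == rows["total/male"].summary.n + rows["total/female"].summary.n

    def test_bonferroni_adjustment(self, norms, rng):
        records = [
            _record(float(s), patient_id=f"p{i}", age=45.0)
            for i, s in enumerate(rng.uniform(40, 90, size=20))
        ]
        rows = stratified_comparison(records, norms, bonferroni=True)
        tested = [r for r in rows if r.test is not None]
        for r in tested:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.test.p * len(tested)))


class TestPearson:
    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_correlation(x, [-v for v in x])
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1, 2, 3.0], [5, 5, 5.0])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientPairsError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, None, 4.0, 5.0]
        y = [2.0, None, 6.0, 8.0, 10.0]
        res = pearson_correlation(x, y)
        assert res.n == 3  # only complete pairs used

    def test_matches_covariance_oracle(self, rng):
        x = rng.uniform(0, 100, size=20)
        y = 0.4 * x + rng.normal(0, 10, size=20)
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(oracle_pearson_r(list(x), list(y)), abs=1e-10)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance(self, a, b):
        x = [1.0, 3.0, 4.0, 7.0, 11.0, 13.0]
        y = [2.0, 1.0, 5.0, 4.0, 9.0, 8.0]
        base = pearson_correlation(x, y)
        scaled = pearson_correlation([a * v + b for v in x], y)
        assert scaled.r == pytest.approx(base.r, abs=1e-9)
        assert -1.0 <= scaled.r <= 1.0


class TestNormality:
    def test_rejection_rate_calibrated_under_null(self, rng):
        reps, n, alpha = 1000, 200, 0.05
        rejections = sum(
            normality_check(rng.normal(size=n))[1] < alpha for _ in range(reps)
        )
        assert 0.03 <= rejections / reps <= 0.075

    def test_power_against_skew(self, rng):
        reps, n = 200, 500
        rejections = sum(
            normality_check(rng.exponential(size=n))[1] < 0.05 for _ in range(reps)
        )
        assert rejections / reps > 0.95

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            normality_check([7.0] * 10)

    @pytest.mark.parametrize("n", [2, 5001])
    def test_unsupported_n(self, n):
        with pytest.raises(UnsupportedSampleSizeError):
            normality_check(list(range(n)))
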