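"""NSS scoring and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from speckleflow import (
    AreaSeries,
    NSSRecord,
    compare_groups,
    group_summary,
    nss_total,
    percent_difference,
    timepoint_comparison,
    ttest_groups,
)
from speckleflow.stats import NSS_CATEGORY_MAXIMA, NSS_MAX_TOTAL


def record(motor=0, sensory=0, beam=0, reflex=0, rat="r0", ex="e0", trial=0):
    return NSSRecord(rat, ex, motor, sensory, beam, reflex, trial)


class TestNSSTotal:
    def test_scale_bounds(self):
        assert NSS_MAX_TOTAL == 18
        assert sum(NSS_CATEGORY_MAXIMA.values()) == 18
        assert nss_total([record()]) == 0.0
        assert nss_total([record(6, 2, 6, 4)]) == 18.0

    def test_mean_over_examiners(self):
        recs = [record(motor=m, ex=f"e{m}") for m in (4, 5, 6)]
        assert nss_total(recs) == 5.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nss_total([record(motor=7)])
        with pytest.raises(ValueError):
            nss_total([record(sensory=-1)])
        with pytest.raises(ValueError):
            nss_total([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        motor=st.integers(0, 6),
        sensory=st.integers(0, 2),
        beam=st.integers(0, 6),
        reflex=st.integers(0, 4),
    )
    def test_total_bounded(self, motor, sensory, beam, reflex):
        assert 0 <= nss_total([record(motor, sensory, beam, reflex)]) <= 18


class TestGroupSummary:
    def test_constant_group(self):
        assert group_summary([1, 1, 1]) == (1.0, 0.0)

    def test_two_point_case(self):
        mean, sem = group_summary([2, 4])
        assert mean == 3.0 and sem == pytest.approx(1.0)  # sd = √2, sem = √2/√2

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            group_summary([5.0])


class TestTTest:
    def test_identical_groups_null(self):
        t, p, sig = ttest_groups([3, 3, 3], [3, 3, 3])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_hand_computed_case(self):
        t, p, _ = ttest_groups([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)

    def test_pooled_variant_available(self):
        a, b = [1.0, 2.0, 3.0, 9.0], [2.0, 3.0, 4.0]
        t_w, _, _ = ttest_groups(a, b, equal_var=False)
        t_p, _, _ = ttest_groups(a, b, equal_var=True)
        assert t_w != t_p

    def test_power_matches_noncentral_t_oracle(self):
        # group conditions: 19.5 ± 1.4·√11 vs 12.4 ± 1.5·√11, n = 11 each
        sa, sb, n = 1.4 * np.sqrt(11), 1.5 * np.sqrt(11), 11
        se = np.sqrt(sa**2 / n + sb**2 / n)
        ncp = (19.5 - 12.4) / se
        df = (sa**2 / n + sb**2 / n) ** 2 / (
            (sa**2 / n) ** 2 / (n - 1) + (sb**2 / n) ** 2 / (n - 1)
        )
        crit = sps.t.ppf(0.975, df)
        power = 1 - sps.nct.cdf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp)
        rng = np.random.default_rng(0)
        n_mc = 400
        hits = sum(
            ttest_groups(rng.normal(19.5, sa, n), rng.normal(12.4, sb, n))[2]
            for _ in range(n_mc)
        )
        # MC rejection rate within 4 binomial sd of the analytic power (~0.91)
        tol = 4 * np.sqrt(power * (1 - power) / n_mc)
        assert hits / n_mc == pytest.approx(power, abs=tol)
        assert hits / n_mc > 0.8

    def test_p_value_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.0, 1.0, 6)
        _, p_t, _ = ttest_groups(a, b)
        res = sps.permutation_test(
            (a, b),
            lambda x, y, axis=-1: sps.ttest_ind(x, y, equal_var=False, axis=axis).statistic,
            permutation_type="independent",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        assert abs(p_t - res.pvalue) < 0.02


class TestPercentDifference:
    @pytest.mark.parametrize(
        "conscious, anesthetic, expected",
        [(63.7, 40.1, 58.9), (5.9, 4.6, 28.3), (47.0, 32.0, 46.9)],
    )
    def test_headline_group_differences(self, conscious, anesthetic, expected):
        assert percent_difference(conscious, anesthetic) == expected

    def test_equal_means_zero(self):
        assert percent_difference(7.7, 7.7) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=0.1, max_value=1e3),
        b=st.floats(min_value=0.1, max_value=1e3),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariant(self, a, b, c):
        assert percent_difference(c * a, c * b) == percent_difference(a, b)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(5.0, 0.0)


class TestCompareGroups:
    def test_full_comparison_fields(self):
        gc = compare_groups([5, 6, 7, 8], [3, 4, 5, 6])
        assert gc.mean_a == 6.5 and gc.mean_b == 4.5
        assert gc.sem_a == pytest.approx(np.std([5, 6, 7, 8], ddof=1) / 2)
        assert gc.percent_diff == pytest.approx(44.4)
        assert 0 <= gc.p_value <= 1


def series(areas, times=(1.0, 8.0, 15.0)):
    return AreaSeries(np.asarray(times), np.asarray(areas, float), "CBF_50", 0.1)


class TestTimepointComparison:
    def test_identical_groups_all_null(self):
        grp = [series([1, 2, 3]), series([1, 2, 3])]
        _, p = timepoint_comparison(grp, [series([1, 2, 3]), series([1, 2, 3])])
        np.testing.assert_allclose(p, 1.0)

    def test_divergence_detected_from_planted_bin(self):
        # groups share early bins and separate cleanly from the 8-min bin on
        rng = np.random.default_rng(4)
        times = (1.0, 5.0, 8.0, 12.0, 15.0)
        base = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        boost = np.array([0.0, 0.0, 5.0, 7.0, 9.0])
        grp_a = [series(base + boost + rng.normal(0, 0.5, 5), times) for _ in range(8)]
        grp_b = [series(base + rng.normal(0, 0.5, 5), times) for _ in range(8)]
        t, p = timepoint_comparison(grp_a, grp_b)
        assert np.all(p[:2] > 0.05)
        assert np.all(p[2:] < 0.05)
        assert t[np.argmax(p < 0.05)] == 8.0

    def test_single_shared_bin(self):
        _, p = timepoint_comparison(
            [series([1.0], (15.0,)), series([2.0], (15.0,))],
            [series([5.0], (15.0,)), series([6.0], (15.0,))],
        )
        assert p.shape == (1,)

    def test_misaligned_axes_rejected(self):
        with pytest.raises(ValueError):
            timepoint_comparison(
                [series([1, 2, 3])], [series([1, 2, 3], times=(2.0, 9.0, 16.0))]
            )

    def test_bonferroni_toggle_inflates_p(self):
        grp_a = [series([1, 2, 3]), series([2, 3, 4])]
        grp_b = [series([4, 5, 6]), series([5, 6, 7])]
        _, p_raw = timepoint_comparison(grp_a, grp_b)
        _, p_bonf = timepoint_comparison(grp_a, grp_b, bonferroni=True)
        assert np.all(p_bonf >= p_raw)
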