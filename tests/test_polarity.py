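"""Degree-of-Apicality statistics and the significance-test battery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from apicobasal.polarity import (
    InvalidMeasurementError,
    PolarityExperiment,
    PolarityMeasurement,
    ab_ratio_vs_one,
    anova_tukey,
    degree_of_apicality,
    kd_wt_doa,
    null_vs_wt_doa,
    one_sample_t_vs_one,
    total_signal_ratio,
    two_sample_t,
)
from apicobasal.synthetic import SimPolarityConfig, simulate_polarity_measurements


def _t_sf_oracle(t_value: float, df: float) -> float:
    """Upper-tail t probability by numeric integration of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = quad(dens, t_value, math.inf)
    return val


def _measurement(apical, basal, bg, **kw):
    return PolarityMeasurement(group_id=kw.pop("group_id", "g1"),
                               apical_mfi=apical, basal_mfi=basal, bg_mfi=bg, **kw)


class TestDoA:
    @pytest.mark.parametrize(
        "apical,basal,bg,expected",
        [(10, 10, 2, 1.0), (8, 4, 2, 3.0), (4, 8, 2, 1.0 / 3.0)],
    )
    def test_background_corrected_ratio(self, apical, basal, bg, expected):
        assert degree_of_apicality(_measurement(apical, basal, bg)).doa == pytest.approx(expected)

    def test_signal_below_background_rejected(self):
        with pytest.raises(InvalidMeasurementError, match="denominator"):
            degree_of_apicality(_measurement(10, 1, 2))
        with pytest.raises(InvalidMeasurementError):
            degree_of_apicality(_measurement(1, 10, 2))

    @given(
        st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0, 100), st.floats(0.01, 100)
    )
    def test_scale_invariance(self, a_sig, b_sig, bg, k):
        """Scaling both background-corrected signals by k leaves DoA fixed."""
        d1 = degree_of_apicality(_measurement(bg + a_sig, bg + b_sig, bg)).doa
        d2 = degree_of_apicality(_measurement(bg + k * a_sig, bg + k * b_sig, bg)).doa
        assert d1 == pytest.approx(d2, rel=1e-9)

    @pytest.mark.parametrize("kd,wt,expected", [(2.0, 2.0, 1.0), (5.0, 2.0, 2.5)])
    def test_kd_wt_ratio(self, kd, wt, expected):
        assert kd_wt_doa(kd, wt) == pytest.approx(expected)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_kd_wt_reciprocity(self, a, b):
        assert kd_wt_doa(a, b) * kd_wt_doa(b, a) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize(
        "mut,wts,expected",
        [(2.0, [2.0, 2.0], 1.0), (3.0, [1.0, 2.0], 2.0), (4.0, [2.0], 2.0)],
    )
    def test_whole_mutant_vs_mean_wt(self, mut, wts, expected):
        assert null_vs_wt_doa(mut, wts) == pytest.approx(expected)
        if len(wts) == 1:
            assert null_vs_wt_doa(mut, wts) == kd_wt_doa(mut, wts[0])

    def test_empty_wt_list_rejected(self):
        with pytest.raises(ValueError):
            null_vs_wt_doa(2.0, [])


class TestOneSampleT:
    def test_exact_null_is_degenerate(self):
        res = one_sample_t_vs_one([1.0, 1.0, 1.0])
        assert res.degenerate and res.p_value == 1.0

    def test_degenerate_departure(self):
        res = one_sample_t_vs_one([2.0, 2.0])
        assert res.degenerate and res.p_value == 0.0

    def test_closed_form_df2(self):
        # mean 2, sd 0.2, n 3: t = 8.6603, df = 2, p = 1 - t/sqrt(t^2+2)
        res = one_sample_t_vs_one([2.0, 2.2, 1.8])
        t = res.statistic
        assert t == pytest.approx(8.6603, abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(1 - t / math.sqrt(t * t + 2), abs=1e-10)
        assert res.p_value == pytest.approx(0.01307, abs=5e-6)

    def test_one_sided_tails_complement(self):
        values = [0.8, 0.9, 1.1, 0.85, 0.7]
        less = one_sample_t_vs_one(values, "less")
        greater = one_sample_t_vs_one(values, "greater")
        assert less.p_value + greater.p_value == pytest.approx(1.0, abs=1e-12)
        assert less.p_value == pytest.approx(
            1 - _t_sf_oracle(less.statistic, less.df), abs=1e-8
        )

    def test_matches_cdf_oracle_two_sided(self):
        values = [1.3, 1.1, 0.9, 1.5, 1.2, 1.4]
        res = one_sample_t_vs_one(values)
        assert res.p_value == pytest.approx(2 * _t_sf_oracle(abs(res.statistic), res.df), abs=1e-8)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_vs_one([1.0])


class TestTotalSignal:
    def test_identity_and_halving(self):
        m = _measurement(8, 4, 0)
        assert total_signal_ratio(m, m) == pytest.approx(1.0)
        half = _measurement(4, 2, 0)
        assert total_signal_ratio(half, m) == pytest.approx(0.5)

    def test_apical_basal_sum_symmetry(self):
        kd = _measurement(9, 3, 1)
        kd_swapped = _measurement(3, 9, 1)
        wt = _measurement(6, 6, 1)
        assert total_signal_ratio(kd, wt) == pytest.approx(total_signal_ratio(kd_swapped, wt))

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            total_signal_ratio(_measurement(5, 5, 1), _measurement(1, 1, 2))


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_large_shift_significant(self):
        res = two_sample_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.01

    def test_welch_df_never_exceeds_pooled(self, rng):
        for _ in range(20):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 9))
            b = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 9))
            welch = two_sample_t(a, b, pooled=False)
            pooled = two_sample_t(a, b, pooled=True)
            assert welch.df <= pooled.df + 1e-9

    def test_welch_df_satterthwaite_oracle(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0, 3, 9)
        res = two_sample_t(a, b, pooled=False)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert res.df == pytest.approx(df, rel=1e-10)
        assert res.p_value == pytest.approx(
            2 * _t_sf_oracle(abs(res.statistic), res.df), abs=1e-8
        )


class TestAnovaTukey:
    def test_identical_constant_groups(self):
        anova, pairwise = anova_tukey([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert anova.statistic == 0.0 and anova.p_value == 1.0 and anova.degenerate
        assert all(p.p_value == 1.0 for p in pairwise)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.8, 1, 5)
        anova, pairwise = anova_tukey([a, b])
        t = two_sample_t(a, b, pooled=True)
        assert anova.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert anova.p_value == pytest.approx(t.p_value, rel=1e-10)
        # with two groups the studentized-range p equals the t-test p
        assert pairwise[0].p_value == pytest.approx(t.p_value, rel=1e-6)

    def test_sums_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 3.0], [6.0, 5.0, 7.0]]
        anova, _ = anova_tukey(groups)
        grand = np.mean(np.concatenate(groups))
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f = (ss_between / 2) / (ss_within / 6)
        assert anova.statistic == pytest.approx(f, rel=1e-12)
        assert anova.df == (2.0, 6.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 2.0], [3.0]])


class TestAbRatio:
    def test_equal_pairs_degenerate(self):
        res = ab_ratio_vs_one([2.0, 3.0], [2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_composes_with_one_sample_t(self):
        ratios = [1.1, 1.2, 1.3]
        direct = one_sample_t_vs_one(ratios)
        composed = ab_ratio_vs_one([1.1, 2.4, 3.9], [1.0, 2.0, 3.0])
        assert composed.statistic == pytest.approx(direct.statistic, rel=1e-9)
        assert composed.p_value == pytest.approx(direct.p_value, rel=1e-9)

    def test_parameter_recovery(self, rng):
        n = 30
        b = rng.uniform(5, 10, n)
        a = 1.3 * b * (1 + rng.normal(0, 0.1, n))
        res = ab_ratio_vs_one(a, b)
        se = np.std(a / b, ddof=1) / math.sqrt(n)
        assert abs(res.estimate - 1.3) < 3 * se

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ab_ratio_vs_one([1.0, 2.0], [1.0])


class TestPolarityExperiment:
    def test_identical_measurement_sets_give_unit_ratio(self):
        ms = []
        for i in range(3):
            for ct in ("wt", "kd"):
                ms.append(PolarityMeasurement(f"p{i}_{ct}", 8.0, 4.0, 2.0, cell_type=ct,
                                              rna_id="r", condition="c"))
        res = PolarityExperiment(ms).fit()
        assert res.table["mean_kd_wt_doa"].iloc[0] == pytest.approx(1.0)
        assert res.table["p_value"].iloc[0] == 1.0

    def test_invalid_measurements_excluded_not_clamped(self):
        good = PolarityMeasurement("p1_wt", 8.0, 4.0, 2.0, cell_type="wt")
        bad = PolarityMeasurement("p1_kd", 8.0, 1.0, 2.0, cell_type="kd")
        exp = PolarityExperiment([good, bad])
        assert len(exp.measurements) == 1 and len(exp.excluded) == 1

    def test_noise_free_simulation_recovers_truth_exactly(self):
        ms, truth = simulate_polarity_measurements(
            SimPolarityConfig(true_doa_wt=2.0, kd_effect=1.5, noise_cv=0.0, seed=1)
        )
        exp = PolarityExperiment(ms)
        doas = exp.doas()
        assert np.allclose(doas[doas.cell_type == "wt"]["doa"], 2.0)
        assert np.allclose(doas[doas.cell_type == "kd"]["doa"], 3.0)
        assert np.allclose(exp.kd_wt_ratios()["kd_wt_doa"], 1.5)
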