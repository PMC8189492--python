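"""FDR procedures: worked values, pi0 estimation, q-value properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from mtcorrect import (
    BenjaminiYekutieli,
    bh_critical_values,
    bh_reject,
    by_adjust,
    estimate_pi0,
    expected_false_positives,
    fdr_curve,
    harmonic_number,
    hochberg_adjust,
    pfp_estimate,
    qvalues,
    storey_fdr,
)

pvec = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30
)


class TestBenjaminiHochberg:
    def test_critical_values_smallest_ranks(self):
        # n=100 at FDR 5%: rank 1 cut-off 0.0005, rank 2 cut-off 0.001
        p = np.full(100, 0.5)
        p[0] = 0.0001
        crit = bh_critical_values(p, fdr_level=0.05)
        assert crit[0] == pytest.approx(0.0005, rel=1e-12)
        assert crit[1] == pytest.approx(0.001, rel=1e-12)
        res = bh_reject(p, fdr_level=0.05)
        assert res.rejected[0]  # 0.0001 < 0.0005

    def test_single_test_critical_value_is_level(self):
        assert bh_critical_values([0.2], fdr_level=0.05)[0] == pytest.approx(0.05)

    def test_adjusted_min_over_tail(self):
        np.testing.assert_allclose(
            bh_reject([0.01, 0.02, 0.03]).adjusted, [0.03, 0.03, 0.03], rtol=1e-12
        )

    def test_all_ones_rejects_nothing(self):
        res = bh_reject([1.0] * 5)
        np.testing.assert_array_equal(res.adjusted, np.ones(5))
        assert res.n_rejected == 0

    def test_step_up_rejects_everything_below_highest_qualifier(self):
        # rank 3 qualifies (0.028 < 3/4*0.05) so ranks 1-3 are all rejected,
        # including 0.02 which alone fails its own cut-off (0.02 > 2/4*0.05)
        res = bh_reject([0.001, 0.028, 0.02, 0.9], fdr_level=0.05)
        assert list(res.rejected) == [True, True, True, False]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(pvec)
    def test_dominates_hochberg(self, p):
        bh = bh_reject(p, fdr_level=0.05)
        hoch = hochberg_adjust(p, alpha=0.05)
        assert set(np.flatnonzero(hoch.rejected)) <= set(np.flatnonzero(bh.rejected))

    def test_agreement_with_statsmodels(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            res = bh_reject(p)
            _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(res.adjusted, sm_adj, rtol=1e-10, atol=1e-12)


class TestBenjaminiYekutieli:
    def test_positive_dependence_reduces_to_bh(self, rng):
        p = rng.uniform(0, 1, size=25)
        bh = bh_reject(p)
        by = by_adjust(p, dependence="positive")
        np.testing.assert_array_equal(by.adjusted, bh.adjusted)
        np.testing.assert_array_equal(by.rejected, bh.rejected)
        assert by.params["c_n"] == 1.0

    def test_arbitrary_dependence_scales_by_harmonic_number(self):
        assert harmonic_number(3) == pytest.approx(11 / 6, rel=1e-12)
        p = [0.01, 0.02, 0.03]
        by = by_adjust(p, dependence="arbitrary")
        bh = bh_reject(p)
        np.testing.assert_allclose(
            by.adjusted, np.minimum(1.0, bh.adjusted * 11 / 6), rtol=1e-12
        )

    def test_single_test_identity_both_modes(self):
        for dep in ("positive", "arbitrary"):
            assert by_adjust([0.04], dependence=dep).adjusted[0] == pytest.approx(0.04)

    def test_never_rejects_more_than_bh(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 0.2, size=int(rng.integers(1, 30)))
            assert by_adjust(p).n_rejected <= bh_reject(p).n_rejected

    def test_agreement_with_statsmodels(self, rng):
        p = rng.uniform(0, 1, size=40)
        _, sm_adj, _, _ = multipletests(p, method="fdr_by")
        np.testing.assert_allclose(
            by_adjust(p).adjusted, sm_adj, rtol=1e-10, atol=1e-12
        )

    def test_invalid_dependence_mode(self):
        with pytest.raises(ValueError, match="dependence"):
            BenjaminiYekutieli(dependence="negative").fit([0.1])


class TestPi0:
    def test_count_above_half(self):
        p = [0.6, 0.7, 0.8, 0.9] + [0.1] * 6  # 4 of 10 above 0.5
        est = estimate_pi0(p, "count_above_half")
        assert est.value == pytest.approx(0.8, rel=1e-12)
        assert est.estimator == "count_above_half" and est.n_used == 10

    def test_twice_mean(self):
        p = [0.1, 0.2, 0.3, 0.4]  # mean 0.25
        assert estimate_pi0(p, "twice_mean_p").value == pytest.approx(0.5, rel=1e-12)

    def test_clamped_into_unit_interval(self):
        assert estimate_pi0([1.0] * 4, "twice_mean_p").value == 1.0
        assert estimate_pi0([0.0] * 4, "count_above_half").value == 0.25  # floor 1/n

    def test_unknown_estimator(self):
        with pytest.raises(ValueError, match="estimator"):
            estimate_pi0([0.5], "oracle")


class TestStoreyAndPfp:
    def test_worked_value(self):
        # 100 tests, 10 at or below t=0.05, pi0=1: FDR(t) = 100*0.05/10 = 0.5
        p = np.concatenate([np.full(10, 0.04), np.full(90, 0.9)])
        assert storey_fdr(p, t=0.05, pi0=1.0) == pytest.approx(0.5, rel=1e-12)
        # pi0=0.8 scales the numerator: PFP = 0.8*100*0.05/10 = 0.4
        assert pfp_estimate(p, t=0.05, pi0=0.8) == pytest.approx(0.4, rel=1e-12)

    def test_threshold_one_all_null(self, rng):
        p = rng.uniform(0, 1, size=50)
        assert storey_fdr(p, t=1.0, pi0=1.0) == 1.0

    def test_undefined_when_nothing_rejected(self):
        p = [0.9, 0.95]
        with pytest.raises(ValueError, match="no rejections"):
            storey_fdr(p, t=0.05, pi0=1.0)
        with pytest.raises(ValueError, match="no rejections"):
            pfp_estimate(p, t=0.05, pi0=1.0)

    def test_pfp_coincides_with_storey_at_equal_pi0(self, rng):
        p = rng.uniform(0, 1, size=30)
        for t in (0.1, 0.5, 1.0):
            assert pfp_estimate(p, t, 1.0) == storey_fdr(p, t, 1.0)

    def test_fdr_curve_monotone_rejections(self, rng):
        p = rng.uniform(0, 1, size=40)
        curve = fdr_curve(p, pi0=1.0)
        assert np.all(np.diff(curve.s_at) >= 0)
        assert np.all((0 <= curve.fdr_at) & (curve.fdr_at <= 1))
        assert curve.s_at[-1] == 40


class TestQValues:
    def test_reduces_to_bh_when_pi0_is_one(self, rng):
        p = rng.uniform(0, 1, size=30)
        res = qvalues(p, pi0=1.0)
        np.testing.assert_array_equal(res.qvalues, bh_reject(p).adjusted)

    def test_scaled_below_bh_when_pi0_below_one(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(0, 1, 80)])
        res = qvalues(p, estimator="count_above_half")
        assert res.pi0.value < 1.0
        assert np.all(res.qvalues <= bh_reject(p).adjusted + 1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(pvec)
    def test_monotone_in_p_and_bounded(self, p):
        res = qvalues(p, pi0=1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(res.qvalues[order]) >= -1e-15)
        assert np.all((0 <= res.qvalues) & (res.qvalues <= 1))

    def test_rejection_counts_by_level(self):
        p = [0.0001, 0.0002, 0.5, 0.9]
        res = qvalues(p, pi0=1.0)
        assert res.fdr_level_rejections[0.05] == 2
        assert res.fdr_level_rejections[0.01] == 2


class TestExpectedFalsePositives:
    @pytest.mark.parametrize(
        "threshold, m, expected",
        [
            (0.015, 5000, 75.0),   # p-value rule over the whole family
            (0.017, 500, 8.5),     # q-value rule over the called set
            (0.05, 20000, 1000.0),  # genome-wide screen at nominal 5%
            (0.0, 123, 0.0),
        ],
    )
    def test_worked_values(self, threshold, m, expected):
        assert expected_false_positives(threshold, m) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            expected_false_positives(1.5, 10)
        with pytest.raises(ValueError):
            expected_false_positives(0.05, 0)
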