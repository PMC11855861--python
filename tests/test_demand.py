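"""Exponential demand model: prediction, fitting, derived indices, F test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import demandtx as dx
from demandtx.errors import (
    NoUnitElasticPointError,
    UnfittableCurveError,
    ValidationError,
)

from conftest import make_noiseless_curve, make_noisy_curve

LN10 = math.log(10.0)

# k below ~1.6 puts the consumption floor Q0*10^-k so high that expenditure
# C*Q(C) rises again past the interior maximum; keep to the typical range
# where Pmax is the global maximum on (0, 10*Pmax].
positive_params = st.builds(
    dx.DemandParams,
    q0=st.floats(0.3, 30.0),
    alpha=st.floats(1e-4, 0.1),
    k=st.floats(1.8, 4.0),
)


class TestPrediction:
    def test_zero_price_is_intensity_limit(self):
        p = dx.DemandParams(19.0, 0.005, 2.38)
        assert dx.predict_log10_consumption(p, 0.0) == pytest.approx(math.log10(19.0))

    def test_vanishing_alpha_gives_flat_demand(self):
        p = dx.DemandParams(5.0, 1e-12, 2.5)
        assert dx.predict_log10_consumption(p, 292.0) == pytest.approx(math.log10(5.0), abs=1e-8)

    def test_known_subject_point_matches_direct_arithmetic(self):
        # a METH subject's printed row: EV 0.82, Q0 19.00, Pmax 3.69 at k=2.38
        k = 2.38
        alpha = 1.0 / (100.0 * 0.82 * k**1.5)
        expected = math.log10(19.0) + k * (math.exp(-alpha * 19.0 * 3.69) - 1.0)
        got = dx.predict_log10_consumption(dx.DemandParams(19.0, alpha, k), 3.69)
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params=positive_params)
    def test_decreasing_in_price_and_bounded_below(self, params):
        prices = np.array([0.0, 1.0, 5.0, 58.0, 292.0, 5000.0])
        vals = np.asarray(dx.predict_log10_consumption(params, prices))
        assert np.all(np.isfinite(vals))
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals >= math.log10(params.q0) - params.k - 1e-12)

    @pytest.mark.parametrize("bad", [(0, 0.01, 2.5), (1, -1, 2.5), (1, 0.01, 0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValidationError):
            dx.DemandParams(*bad)


class TestDerivedIndices:
    def test_essential_value_forced_to_one(self):
        k = 2.5
        alpha = 1.0 / (100.0 * k**1.5)
        assert dx.derive_essential_value(dx.DemandParams(1.0, alpha, k)) == pytest.approx(1.0)

    def test_doubling_alpha_halves_ev(self):
        a, b = dx.DemandParams(5, 0.004, 2.4), dx.DemandParams(5, 0.008, 2.4)
        assert dx.derive_essential_value(a) == pytest.approx(2 * dx.derive_essential_value(b))

    def test_ev_matches_published_subject(self):
        # back-solve alpha from the printed EV at k=2.38, then re-derive
        k, ev_printed = 2.38, 0.82
        alpha = 1.0 / (100.0 * ev_printed * k**1.5)
        assert alpha == pytest.approx(0.00332, rel=5e-3)
        assert dx.derive_essential_value(dx.DemandParams(19.0, alpha, k)) == pytest.approx(0.82)

    def test_pmax_inversely_proportional_to_alpha_q0(self):
        p1 = dx.DemandParams(10.0, 0.002, 2.4)
        p2 = dx.DemandParams(5.0, 0.008, 2.4)  # alpha*q0 2x larger
        assert dx.derive_pmax(p1) == pytest.approx(2.0 * dx.derive_pmax(p2))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(params=positive_params)
    def test_pmax_is_expenditure_argmax(self, params):
        from scipy import optimize

        pmax = dx.derive_pmax(params)
        neg_spend = lambda c: -c * float(dx.predict_consumption(params, c))
        res = optimize.minimize_scalar(neg_spend, bounds=(1e-9, 10 * pmax), method="bounded",
                                       options={"xatol": 1e-12})
        assert pmax == pytest.approx(res.x, rel=1e-6)

    def test_no_unit_elastic_point_for_small_k(self):
        with pytest.raises(NoUnitElasticPointError):
            dx.derive_pmax(dx.DemandParams(5.0, 0.01, 1.0))

    def test_omax_over_q0_pmax_depends_only_on_k(self):
        sets = [dx.DemandParams(q0, a, 2.38) for q0, a in [(19, 0.003), (2.8, 0.02), (0.5, 0.1)]]
        ratios = []
        for p in sets:
            omax, _ = dx.derive_omax(p)
            ratios.append(omax / (p.q0 * dx.derive_pmax(p)))
        assert np.ptp(ratios) < 1e-10

    def test_omax_observed_takes_first_maximizer(self):
        curve = dx.ConsumptionCurve("s", "SAL", np.array([1.0, 2.0, 4.0]), np.array([4.0, 2.0, 1.0]))
        _, observed = dx.derive_omax(dx.DemandParams(4.0, 0.05, 2.4), curve)
        assert observed == 4.0  # price 1 wins the tie with prices 2 and 4

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=positive_params, c=st.floats(1.5, 20.0))
    def test_price_rescaling_invariance(self, params, c):
        """Scaling prices by c and alpha by 1/c leaves log10 Q unchanged; Pmax scales by c."""
        scaled = dx.DemandParams(params.q0, params.alpha / c, params.k)
        prices = np.array([1.0, 12.0, 86.0])
        a = np.asarray(dx.predict_log10_consumption(params, prices))
        b = np.asarray(dx.predict_log10_consumption(scaled, prices * c))
        np.testing.assert_allclose(a, b, rtol=1e-12)
        assert dx.derive_pmax(scaled) == pytest.approx(c * dx.derive_pmax(params), rel=1e-10)

    def test_back_solved_k_consistent_across_published_subjects(self):
        """Each subject's printed Omax/(Q0*Pmax) back-solves to nearly the same k."""
        cohort = dx.load_demand_cohort()
        ks = [
            dx.infer_k_from_expenditure_ratio(r.omax / (r.q0 * r.pmax))
            for r in cohort.itertuples()
        ]
        ks = np.asarray(ks)
        assert ks.std() / ks.mean() < 0.01


class TestIndividualFit:
    def test_noiseless_recovery_free_k(self, ladder, noiseless_curve):
        fit = dx.fit_demand_individual(noiseless_curve, k="free")
        assert fit.params.q0 == pytest.approx(10.0, rel=1e-6)
        assert fit.params.alpha == pytest.approx(0.003, rel=1e-6)
        assert fit.params.k == pytest.approx(2.5, rel=1e-6)
        assert fit.rss < 1e-12 and fit.r_squared == pytest.approx(1.0)

    def test_estimator_api_roundtrip(self, ladder):
        true = dx.DemandParams(8.0, 0.004, 2.3)
        q = dx.predict_consumption(true, ladder)
        est = dx.ExponentialDemandModel(k=2.3).fit(ladder, q)
        assert est.get_params()["k"] == 2.3
        np.testing.assert_allclose(est.predict(ladder), q, rtol=1e-6)
        assert est.ev_ == pytest.approx(dx.derive_essential_value(true), rel=1e-6)

    def test_zero_consumption_points_are_excluded(self, ladder):
        q = dx.predict_consumption(dx.DemandParams(10.0, 0.003, 2.5), ladder)
        q[-3:] = 0.0
        fit = dx.fit_demand_individual(dx.ConsumptionCurve("s", "METH", ladder, q), k="free")
        assert fit.n_points_used == 10
        assert fit.params.q0 == pytest.approx(10.0, rel=1e-5)

    def test_all_zero_consumption_is_unfittable(self, ladder):
        curve = dx.ConsumptionCurve("s", "SAL", ladder, np.zeros_like(ladder))
        with pytest.raises(UnfittableCurveError):
            dx.fit_demand_individual(curve)

    def test_free_k_needs_four_positive_points(self):
        curve = dx.ConsumptionCurve("s", "SAL", np.array([1.0, 3.0, 5.0]), np.array([2.0, 1.5, 1.0]))
        with pytest.raises(UnfittableCurveError):
            dx.fit_demand_individual(curve, k="free")
        dx.fit_demand_individual(curve, k=2.4)  # fixed k is fine with 3 points


class TestSharedK:
    def test_two_noiseless_curves_recover_common_k(self, ladder):
        c1 = make_noiseless_curve(dx.DemandParams(8.0, 0.002, 2.38), ladder, "a", "METH")
        c2 = make_noiseless_curve(dx.DemandParams(1.5, 0.03, 2.38), ladder, "b", "SAL")
        k, fits = dx.fit_demand_shared_k([c1, c2])
        assert k == pytest.approx(2.38, rel=1e-5)
        assert fits[0].params.q0 == pytest.approx(8.0, rel=1e-5)
        assert fits[1].params.alpha == pytest.approx(0.03, rel=1e-5)

    def test_shared_k_estimator_long_format(self, ladder):
        q1 = dx.predict_consumption(dx.DemandParams(8.0, 0.002, 2.38), ladder)
        q2 = dx.predict_consumption(dx.DemandParams(1.5, 0.03, 2.38), ladder)
        X = np.concatenate([ladder, ladder])
        y = np.concatenate([q1, q2])
        groups = ["a"] * ladder.size + ["b"] * ladder.size
        est = dx.SharedKDemandModel().fit(X, y, groups)
        assert est.k_ == pytest.approx(2.38, rel=1e-5)
        assert set(est.fits_) == {"a", "b"}

    def test_pooled_shared_k_rss_at_least_sum_of_free_fits(self, ladder):
        rng = np.random.default_rng(11)
        curves = [
            make_noisy_curve(dx.DemandParams(q0, a, 2.4), ladder, 0.1, rng, s)
            for s, (q0, a) in zip("abcd", [(8, 0.002), (3, 0.01), (1.5, 0.03), (12, 0.001)])
        ]
        _, shared_fits = dx.fit_demand_shared_k(curves)
        rss_shared = sum(f.rss for f in shared_fits)
        rss_free = sum(dx.fit_demand_individual(c, k="free").rss for c in curves)
        assert rss_shared >= rss_free - 1e-10

    def test_single_curve_delegates_to_free_fit(self, ladder, noiseless_curve):
        k, fits = dx.fit_demand_shared_k([noiseless_curve])
        assert k == pytest.approx(2.5, rel=1e-6)
        assert len(fits) == 1


class TestExtraSumOfSquaresF:
    def test_identical_groups_give_f_near_zero(self, ladder):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.1, ladder.size)
        params = dx.DemandParams(5.0, 0.01, 2.4)
        log10_q = np.asarray(dx.predict_log10_consumption(params, ladder))
        q = 10.0 ** (log10_q + noise)
        curves = [
            dx.ConsumptionCurve("a", "METH", ladder, q),
            dx.ConsumptionCurve("b", "SAL", ladder, q),
        ]
        res = dx.compare_alpha_extra_ss_f(curves)
        assert res.f_stat == pytest.approx(0.0, abs=1e-4)
        assert res.p_value > 0.99

    def test_df_num_is_one_when_only_alpha_is_unshared(self, ladder):
        rng = np.random.default_rng(4)
        curves = [
            make_noisy_curve(dx.DemandParams(8.0, 0.002, 2.4), ladder, 0.1, rng, "a", "METH"),
            make_noisy_curve(dx.DemandParams(1.5, 0.03, 2.4), ladder, 0.1, rng, "b", "SAL"),
        ]
        res = dx.compare_alpha_extra_ss_f(curves)
        assert res.df_num == 1
        assert res.df_den == sum(c.n_positive for c in curves) - 5
        assert res.rss_reduced >= res.rss_full >= 0

    def test_requires_exactly_two_groups(self, ladder, noiseless_curve):
        with pytest.raises(ValidationError):
            dx.compare_alpha_extra_ss_f([noiseless_curve])


class TestDoseArithmetic:
    @pytest.mark.parametrize(
        "infusions,expected",
        [(258.83, 12.94), (45.66, 2.28), (172.19, 8.61), (0.0, 0.0)],
    )
    def test_unit_dose_products(self, infusions, expected):
        assert round(dx.dose_from_infusions(infusions), 2) == expected

    def test_rejects_negative_and_bad_unit_dose(self):
        with pytest.raises(ValidationError):
            dx.dose_from_infusions(-1.0)
        with pytest.raises(ValidationError):
            dx.dose_from_infusions(1.0, unit_dose=0.0)
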