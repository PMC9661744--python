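import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_km, naive_logrank
from conftest import make_profile
from ctdyn.concordance import cohens_kappa
from ctdyn.survival import (
    Endpoint,
    ResponseCall,
    SurvivalRecord,
    call_response,
    km_fit,
    logrank_test,
    response_vs_radiology,
    univariate_hr,
)
from ctdyn.variants import Compartment, Timepoint


def records(times, events, endpoint=Endpoint.INTRACRANIAL_PFS, group=""):
    return [
        SurvivalRecord(f"P{i}", endpoint, float(t), bool(e), group)
        for i, (t, e) in enumerate(zip(times, events))
    ]


def random_instance(rng, n_max=30):
    n = int(rng.integers(2, n_max + 1))
    times = np.round(rng.exponential(10.0, n), 2) + 0.01
    if rng.random() < 0.3:  # force ties sometimes
        times = np.round(times)+1.0
    events = rng.random(n) < 0.7
    return times, events


class TestCallResponse:
    def _pair(self, base_vafs, follow_vafs, cfdna=(33.0, 33.0)):
        base = make_profile(vafs=base_vafs, cfdna=cfdna[0])
        follow = make_profile(vafs=follow_vafs, cfdna=cfdna[1], timepoint=Timepoint.WEEK8)
        return base, follow

    def test_exact_50pct_drop_is_a_response(self):
        base, follow = self._pair((0.10,), (0.05,))
        call = call_response(base, follow)
        assert call.pct_change == pytest.approx(-50.0)
        assert call.responder and call.evaluable

    def test_40pct_drop_is_not_a_response(self):
        base, follow = self._pair((0.10,), (0.06,))
        assert not call_response(base, follow).responder

    def test_baseline_negative_is_not_evaluable(self):
        base, follow = self._pair((), (0.05,))
        call = call_response(base, follow)
        assert not call.evaluable and not call.responder and call.pct_change is None

    def test_followup_clearance_is_a_full_response(self):
        base, follow = self._pair((0.10,), ())
        call = call_response(base, follow)
        assert call.responder and call.pct_change == pytest.approx(-100.0)

    def test_pairing_contract(self):
        base = make_profile(vafs=(0.1,))
        with pytest.raises(ValueError):
            call_response(base, make_profile(vafs=(0.1,), patient_id="P2", timepoint=Timepoint.WEEK8))
        with pytest.raises(ValueError):
            call_response(
                base, make_profile(vafs=(0.1,), compartment=Compartment.PLASMA, timepoint=Timepoint.WEEK8)
            )
        with pytest.raises(ValueError):  # follow-up must come after baseline
            call_response(make_profile(vafs=(0.1,), timepoint=Timepoint.WEEK8), base)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=40, derandomize=True)
    def test_scale_invariance_in_cfdna(self, scale):
        base, follow = self._pair((0.10,), (0.04,), cfdna=(100.0 * scale, 100.0 * scale))
        assert call_response(base, follow).responder

    def test_independent_labels_give_near_zero_kappa(self):
        rng = np.random.default_rng(42)
        n = 10_000
        calls = [
            ResponseCall(f"P{i}", "CSF", 10.0, 1.0, -90.0, bool(rng.random() < 0.5), True)
            for i in range(n)
        ]
        labels = {f"P{i}": ("PR" if rng.random() < 0.5 else "SD") for i in range(n)}
        table = response_vs_radiology(calls, labels)
        assert abs(cohens_kappa(table)) < 0.05

    def test_all_agree_gives_kappa_one(self):
        calls = [
            ResponseCall("P1", "CSF", 10, 1, -90, True, True),
            ResponseCall("P2", "CSF", 10, 12, 20, False, True),
        ]
        table = response_vs_radiology(calls, {"P1": "PR", "P2": "PD"})
        assert cohens_kappa(table) == 1.0

    def test_unmapped_recist_label_is_a_config_error(self):
        calls = [ResponseCall("P1", "CSF", 10, 1, -90, True, True)]
        with pytest.raises(KeyError, match="MR"):
            response_vs_radiology(calls, {"P1": "MR"})


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        est = km_fit(records([1, 2, 3, 4], [1, 1, 1, 1]))
        assert est.times == (1.0, 2.0, 3.0, 4.0)
        assert est.survival == pytest.approx((0.75, 0.5, 0.25, 0.0))
        assert est.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        est = km_fit(records([5, 7], [0, 0]))
        assert est.times == ()
        assert est.median is None

    def test_hand_product_limit_with_censoring(self):
        # censored at 3, event at 5: risk set at 5 has a single subject
        est = km_fit(records([3, 5], [0, 1]))
        assert est.times == (5.0,)
        assert est.survival == pytest.approx((0.0,))
        assert est.n_at_risk == (1,)

    def test_nonpositive_time_is_a_domain_error(self):
        with pytest.raises(ValueError):
            SurvivalRecord("P1", Endpoint.OS, 0.0, True)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            times, events = random_instance(rng)
            est = km_fit(records(times, events))
            o_t, o_s, o_n = naive_km(times, events)
            assert list(est.times) == o_t
            assert np.allclose(est.survival, o_s, atol=1e-10)
            assert list(est.n_at_risk) == o_n


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        a = records([1, 2, 3], [1, 1, 0])
        stat, p = logrank_test(a, records([1, 2, 3], [1, 1, 0]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_zero_events_in_both_groups(self):
        stat, p = logrank_test(records([1, 2], [0, 0]), records([3], [0]))
        assert (stat, p) == (0.0, 1.0)

    def test_six_patient_hand_worked_example(self):
        a, b = records([1, 3, 5], [1, 1, 1]), records([2, 4, 6], [1, 1, 1])
        stat, p = logrank_test(a, b)
        o_stat, o_p = naive_logrank([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t1, e1 = random_instance(rng)
            t2, e2 = random_instance(rng)
            if e1.sum() + e2.sum() == 0:
                continue
            stat, p = logrank_test(records(t1, e1), records(t2, e2))
            o_stat, o_p = naive_logrank(t1, e1, t2, e2)
            assert stat == pytest.approx(o_stat, abs=1e-10)
            assert p == pytest.approx(o_p, abs=1e-10)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        t1, e1 = random_instance(rng)
        t2, e2 = random_instance(rng)
        a, b = records(t1, e1), records(t2, e2)
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_censoring_before_first_event_leaves_statistic_unchanged(self):
        a = records([4, 6, 8], [1, 1, 0])
        b = records([5, 7, 9], [1, 0, 1])
        early_censored = records([1.0], [0])
        stat_plain, _ = logrank_test(a, b)
        stat_padded, _ = logrank_test(a + early_censored, b)
        # a subject censored before the first event never enters any risk set
        # that contains an event, so the statistic is unchanged
        o_stat, _ = naive_logrank([4, 6, 8, 1.0], [1, 1, 0, 0], [5, 7, 9], [1, 0, 1])
        assert stat_padded == pytest.approx(o_stat, abs=1e-10)
        assert stat_padded == pytest.approx(stat_plain, abs=1e-10)


class TestHazardRatio:
    def test_identical_groups_give_unit_hr(self):
        times, events = [1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 0]
        hr, (lo, hi) = univariate_hr(records(times, events), records(times, events))
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo < 1.0 < hi

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(4)
        a = records(rng.exponential(5, 40) + 0.01, np.ones(40))
        b = records(rng.exponential(15, 40) + 0.01, np.ones(40))
        hr_ab, _ = univariate_hr(a, b)
        hr_ba, _ = univariate_hr(b, a)
        assert hr_ab == pytest.approx(1.0 / hr_ba, rel=1e-6)
        assert hr_ab > 1.0  # group a has the higher hazard

    def test_no_events_is_an_estimation_error(self):
        with pytest.raises(ValueError):
            univariate_hr(records([1, 2], [0, 0]), records([3], [0]))

    @pytest.mark.parametrize("n", [100, 500, 2000])
    def test_consistency_under_proportional_hazards(self, n):
        """Bias of the log-HR estimate shrinks as the sample grows."""
        rng = np.random.default_rng(5)
        true_hr = 0.5
        a = records(rng.exponential(1.0 / (0.1 * true_hr), n) + 1e-6, np.ones(n))
        b = records(rng.exponential(1.0 / 0.1, n) + 1e-6, np.ones(n))
        hr, _ = univariate_hr(a, b)
        tol = {100: 0.25, 500: 0.12, 2000: 0.08}[n]
        assert abs(np.log(hr) - np.log(true_hr)) < tol
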