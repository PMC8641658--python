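import numpy as np
import pytest
from scipy import stats

from graftval.cohort import OutcomeRecord
from graftval.survival import (
    KMCurve,
    derive_labels,
    km_estimate,
    logrank_test,
    time_and_event,
)


def outcome(pid="X", follow=400.0, death_day=None, retx_day=None):
    return OutcomeRecord(
        patient_id=pid,
        follow_up_days=follow,
        death=death_day is not None,
        death_day=death_day,
        retransplant=retx_day is not None,
        retransplant_day=retx_day,
    )


class TestDeriveLabels:
    def test_death_before_horizon_event_both_endpoints(self):
        o = outcome(follow=30.0, death_day=30.0)
        for endpoint in ("graft", "patient"):
            (lbl,) = derive_labels([o], 90, endpoint)
            assert lbl.label == "event"

    def test_censored_before_horizon_excluded(self):
        (lbl,) = derive_labels([outcome(follow=60.0)], 90, "graft")
        assert lbl.label == "excluded"

    def test_censored_before_horizon_optional_survivor(self):
        (lbl,) = derive_labels([outcome(follow=60.0)], 90, "graft", censored_as_survivor=True)
        assert lbl.label == "survivor"

    def test_retransplant_graft_event_patient_depends_on_follow_up(self):
        followed = outcome(follow=200.0, retx_day=50.0)
        (g,) = derive_labels([followed], 90, "graft")
        (p,) = derive_labels([followed], 90, "patient")
        assert g.label == "event" and p.label == "survivor"
        short = outcome(follow=60.0, retx_day=50.0)
        (p2,) = derive_labels([short], 90, "patient")
        assert p2.label == "excluded"

    def test_event_after_horizon_is_survivor(self):
        (lbl,) = derive_labels([outcome(follow=200.0, death_day=150.0)], 90, "graft")
        assert lbl.label == "survivor"

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        outcomes = []
        for i in range(300):
            follow = float(rng.uniform(10, 500))
            death = float(rng.uniform(5, follow)) if rng.random() < 0.3 else None
            outcomes.append(outcome(pid=f"P{i}", follow=follow, death_day=death))
        labels = derive_labels(outcomes, 180, "patient")
        counts = {"event": 0, "survivor": 0, "excluded": 0}
        for lbl in labels:
            counts[lbl.label] += 1
        assert sum(counts.values()) == 300

    def test_time_and_event_pairs(self):
        t, e = time_and_event(outcome(follow=200.0, retx_day=50.0), "graft")
        assert (t, e) == (50.0, True)
        t, e = time_and_event(outcome(follow=200.0, retx_day=50.0), "patient")
        assert (t, e) == (200.0, False)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # times (1, 2+, 3), events (1, 0, 1): S(1)=2/3, S(3)=2/3 * (1 - 1/1)=0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_no_events_survival_one(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100) == 1.0

    def test_reduces_to_ecdf_without_censoring(self):
        times = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        curve = km_estimate(times, np.ones(5, dtype=int))
        for t in times:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_tied_event_times_simultaneous_decrement(self):
        curve = km_estimate([2, 2, 5], [1, 1, 1])
        assert curve.survival_at(2) == pytest.approx(1 / 3)

    def test_survival_non_increasing_starts_at_one(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(50, 200)
        events = rng.integers(0, 2, 200)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert curve.survival_at(0.0) == 1.0

    def test_largest_event_time_equals_survivor_fraction(self):
        # no censoring: S at the largest event time = survivors / n
        times = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 9.5])
        events = np.array([1, 1, 1, 0, 0, 0])  # censored strictly after events
        events = np.ones(6, dtype=int)
        curve = km_estimate(times, events)
        assert curve.survival_at(times.max()) == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        times = rng.exponential(100, 150)
        events = (rng.random(150) < 0.6).astype(int)
        curve = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        g = ([1, 2, 3, 4], [1, 0, 1, 0])
        chi2, df, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == 1.0

    def test_hand_computed_toy(self):
        # group A: events at 1, 2; censored at 3.  group B: event at 4; censored 5, 6.
        ga = ([1.0, 2.0, 3.0], [1, 1, 0])
        gb = ([4.0, 5.0, 6.0], [0, 1, 0])
        # hand observed-vs-expected for group A:
        # t=1: n=6, nA=3, d=1 -> e=0.5, v=(1*5/5)*(3/6)(1-3/6)=0.25
        # t=2: n=5, nA=2, d=1 -> e=0.4, v=(2/5)(3/5)=0.24
        # t=4: n=3, nA=0, d=1 -> e=0.0, v=0
        # O_A=2, E_A=0.9, V=0.49 -> chi2 = (2-0.9)^2/0.49
        chi2, df, p = logrank_test([ga, gb])
        assert chi2 == pytest.approx((2 - 0.9) ** 2 / 0.49, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(float(stats.chi2.sf(chi2, 1)))

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_k_identical_groups_p_one(self, k):
        g = ([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        chi2, df, p = logrank_test([g] * k)
        assert p == pytest.approx(1.0)
        assert df == k - 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero subjects"):
            logrank_test([([1, 2], [1, 1]), ([], [])])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [1, 1])])

    def test_two_group_agreement_with_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(11)
        ta = rng.exponential(50, 80)
        tb = rng.exponential(80, 60)
        ea = (rng.random(80) < 0.7).astype(int)
        eb = (rng.random(60) < 0.7).astype(int)
        chi2, _, p = logrank_test([(ta, ea), (tb, eb)])
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_multigroup_agreement_with_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(13)
        times, events, groups = [], [], []
        for g, scale in enumerate([40, 60, 90]):
            t = rng.exponential(scale, 50)
            e = (rng.random(50) < 0.8).astype(int)
            times.append(t), events.append(e), groups.append(np.full(50, g))
        chi2, df, p = logrank_test(list(zip(times, events)))
        ref = lifelines_stats.multivariate_logrank_test(
            np.concatenate(times), np.concatenate(groups), np.concatenate(events)
        )
        assert df == 2
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
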