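"""Confirmed-event extraction, interval statistics and the attack forcing."""

import numpy as np
import pytest
from scipy import stats

from msdamage import (
    IntervalDistribution,
    IntervalSample,
    PulseTrain,
    build_lambda,
    extract_confirmed_events,
    fit_interval_distribution,
    interevent_intervals,
    sample_pulse_train,
)
from msdamage.inflammatory import DeltaEvent
from tests.conftest import make_patient


class TestEventExtraction:
    def test_single_confirmed_increase(self):
        p = make_patient("p", [0, 3, 6], [2.0, 3.0, 3.0])
        events = extract_confirmed_events(p)
        assert len(events) == 1
        e = events[0]
        assert (e.onset_time, e.delta_edss, e.confirmed_at) == (3.0, 1.0, 6.0)

    def test_constant_series_has_no_events(self):
        p = make_patient("p", [0, 6, 12, 18], [3.0, 3.0, 3.0, 3.0])
        assert extract_confirmed_events(p) == []

    def test_decreasing_series_has_no_events(self):
        p = make_patient("p", [0, 6, 12], [5.0, 4.0, 3.0])
        assert extract_confirmed_events(p) == []

    def test_unconfirmed_transient_is_ignored(self):
        # the increase at month 3 has vanished by month 6: no event
        p = make_patient("p", [0, 3, 6, 9], [2.0, 3.5, 2.0, 2.0])
        assert extract_confirmed_events(p) == []

    def test_baseline_resets_after_event(self):
        p = make_patient("p", [0, 3, 6, 12, 15, 18], [1.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        events = extract_confirmed_events(p)
        assert [e.onset_time for e in events] == [3.0, 12.0]
        assert all(e.delta_edss == 1.0 for e in events)

    def test_extraction_invariant_to_nonqualifying_padding(self):
        base = make_patient("p", [0, 3, 6], [2.0, 3.0, 3.0])
        padded = make_patient("p", [0, 1, 2, 3, 4.5, 6, 7], [2.0, 2.0, 2.0, 3.0, 3.0, 3.0, 3.0])
        e1 = extract_confirmed_events(base)
        e2 = extract_confirmed_events(padded)
        assert [e.onset_time for e in e1] == [e.onset_time for e in e2]


class TestIntervals:
    def test_interval_arithmetic(self):
        events = [
            DeltaEvent(onset_time=t, delta_edss=1.0, confirmed_at=t + 3)
            for t in (3.0, 15.0, 27.0)
        ]
        s = interevent_intervals(events)
        assert s.dt_values.tolist() == [12.0, 12.0]

    def test_single_event_yields_empty_sample(self):
        events = [DeltaEvent(onset_time=3.0, delta_edss=1.0, confirmed_at=6.0)]
        assert interevent_intervals(events).dt_values.size == 0


class TestDistributionFitting:
    def test_gev_recovery_from_500_draws(self):
        rng = np.random.default_rng(5)
        x = stats.genextreme(-0.3, loc=10.0, scale=3.0).rvs(500, random_state=rng)
        x = x[x > 0]
        fits = fit_interval_distribution(IntervalSample(x, "sim"))
        best = fits[0]
        assert best.family == "GEV"
        assert best.params["loc"] == pytest.approx(10.0, rel=0.15)
        assert best.params["scale"] == pytest.approx(3.0, rel=0.15)
        assert best.params["shape"] == pytest.approx(0.3, abs=0.15)

    def test_each_family_recovers_its_own_parameters(self):
        # location/scale of each candidate family recovered within 10%
        rng = np.random.default_rng(11)
        cases = {
            "GEV": stats.genextreme(-0.2, loc=20, scale=4),
            "logistic": stats.logistic(loc=20, scale=4),
            "t-location-scale": stats.t(5, loc=20, scale=4),
        }
        for fam, dist in cases.items():
            x = dist.rvs(1000, random_state=rng)
            fits = fit_interval_distribution(IntervalSample(x[x > 0], "sim"), families=[fam])
            p = fits[0].params
            assert p["loc"] == pytest.approx(20.0, rel=0.1), fam
            assert p["scale"] == pytest.approx(4.0, rel=0.1), fam

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_interval_distribution(IntervalSample(np.full(20, 6.0), "x"))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            fit_interval_distribution(IntervalSample(np.arange(1.0, 6.0), "x"))

    def test_ranking_uses_requested_criterion(self):
        rng = np.random.default_rng(3)
        x = stats.expon(scale=10).rvs(300, random_state=rng)
        bic = fit_interval_distribution(IntervalSample(x, "x"), criterion="bic")
        aic = fit_interval_distribution(IntervalSample(x, "x"), criterion="aic")
        assert {f.family for f in bic} == {f.family for f in aic}


class TestPulseTrains:
    DIST = IntervalDistribution(
        family="GEV", params={"shape": 0.3, "loc": 10.0, "scale": 3.0}, criterion_value=0.0
    )
    AMP = staticmethod(lambda n, rng: np.full(n, 1.5))

    def test_zero_horizon_gives_empty_train(self, rng):
        train = sample_pulse_train(self.DIST, self.AMP, horizon=0.0, rng=rng)
        assert train.n_events == 0

    def test_fixed_seed_reproducible(self):
        t1 = sample_pulse_train(self.DIST, self.AMP, 3650.0, np.random.default_rng(9))
        t2 = sample_pulse_train(self.DIST, self.AMP, 3650.0, np.random.default_rng(9))
        assert np.array_equal(t1.event_times, t2.event_times)
        assert np.array_equal(t1.amplitudes, t2.amplitudes)

    def test_mean_interevent_time_matches_distribution(self):
        # Monte-Carlo check against the analytic GEV mean
        rng = np.random.default_rng(17)
        gaps = []
        for _ in range(3000):
            tr = sample_pulse_train(self.DIST, self.AMP, horizon=36500.0, rng=rng)
            if tr.n_events >= 2:
                gaps.append(np.diff(tr.event_times))
        mean_gap_months = np.concatenate(gaps).mean() / 30.4375
        expected = stats.genextreme(-0.3, loc=10.0, scale=3.0).mean()
        assert mean_gap_months == pytest.approx(expected, rel=0.02)

    def test_amplitudes_scale_with_delta_edss(self, rng):
        train = sample_pulse_train(
            self.DIST, self.AMP, 3650.0, rng, amp_scale=0.2
        )
        assert np.allclose(train.amplitudes, 0.2 * 1.5 / 10.0)


class TestLambda:
    def test_empty_train_is_identically_zero(self):
        lam = build_lambda(PulseTrain(np.empty(0), np.empty(0)))
        t = np.linspace(0, 1000, 101)
        assert np.all(lam(t) == 0.0)

    def test_rectangular_pulse_evaluation(self):
        train = PulseTrain(np.array([100.0]), np.array([0.02]), width=30.0)
        lam = build_lambda(train)
        assert lam(np.array([99.0]))[0] == 0.0
        assert lam(np.array([100.0]))[0] == 0.02
        assert lam(np.array([129.9]))[0] == 0.02
        assert lam(np.array([130.0]))[0] == 0.0

    def test_lambda_nonnegative_everywhere(self, rng):
        train = sample_pulse_train(
            TestPulseTrains.DIST, TestPulseTrains.AMP, 7300.0, rng
        )
        for smooth in (False, True):
            lam = build_lambda(
                train, rng=np.random.default_rng(3), smooth=smooth, horizon=7300.0
            )
            t = np.linspace(0, 7300, 100_000)
            v = lam(t)
            assert np.all(np.isfinite(v)) and np.all(v >= 0.0)

    def test_smooth_mode_bitwise_reproducible(self, rng):
        train = sample_pulse_train(
            TestPulseTrains.DIST, TestPulseTrains.AMP, 3650.0, rng
        )
        t = np.linspace(0, 3650, 1000)
        v1 = build_lambda(train, rng=np.random.default_rng(5), smooth=True, horizon=3650.0)(t)
        v2 = build_lambda(train, rng=np.random.default_rng(5), smooth=True, horizon=3650.0)(t)
        assert np.array_equal(v1, v2)

    def test_smooth_mode_requires_rng(self):
        train = PulseTrain(np.array([10.0]), np.array([0.01]))
        with pytest.raises(ValueError, match="seeded rng"):
            build_lambda(train, smooth=True)
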