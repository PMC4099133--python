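import numpy as np
import pytest

import heroinmarket as hm
from heroinmarket.errors import DomainError, IntegrityError
from heroinmarket.trips import (TripRecord, empirical_summaries,
                                hourly_rate_table, hourly_rates,
                                steady_state_window)


def trip(**kw):
    base = dict(customer_id=0, day=0, entry_minute=0.0, obtained=1,
                duration=30.0, via_broker=0)
    base.update(kw)
    return TripRecord(**base).validate()


class TestValidation:
    def test_failed_trip_cannot_be_arrested(self):
        with pytest.raises(IntegrityError):
            TripRecord(customer_id=0, day=0, entry_minute=0, obtained=0,
                       duration=10.0, arrested=1).validate()

    def test_invited_requires_broker(self):
        with pytest.raises(IntegrityError):
            TripRecord(customer_id=0, day=0, entry_minute=0, obtained=1,
                       duration=10.0, via_broker=0, invited=1).validate()

    def test_broker_flag_undefined_on_failure(self):
        with pytest.raises(IntegrityError):
            TripRecord(customer_id=0, day=0, entry_minute=0, obtained=0,
                       duration=10.0, via_broker=1).validate()


class TestSteadyStateWindow:
    def test_reference_window_filters_transient(self):
        recs = [trip(day=100), trip(day=200)]
        out = steady_state_window(recs, 180, 365)
        assert [r.day for r in out] == [200]

    def test_empty_input(self):
        assert steady_state_window([], 180) == []

    def test_unbounded_window_is_identity(self):
        recs = [trip(day=d) for d in (0, 50, 400)]
        assert steady_state_window(recs, 0) == recs

    def test_inverted_window_rejected(self):
        with pytest.raises(DomainError):
            steady_state_window([], 10, 5)


class TestHourlyRates:
    def test_single_interval_proportion(self):
        recs = [trip(entry_minute=0.0, duration=10.0, obtained=1, via_broker=0)
                for _ in range(3)]
        recs.append(trip(entry_minute=0.0, duration=10.0, obtained=0,
                         via_broker=None))
        assert hourly_rates(recs, "obtained") == [(0, 0.75)]

    def test_conditioning_excludes_non_broker_trips(self):
        recs = [trip(via_broker=0) for _ in range(4)]
        with pytest.warns(UserWarning):
            assert hourly_rates(recs, "invited") == []

    def test_two_intervals_direct_counts(self):
        early = [trip(entry_minute=0.0, duration=10.0) for _ in range(2)]
        late = [trip(entry_minute=120.0, duration=10.0, obtained=0,
                     via_broker=None) for _ in range(3)]
        assert hourly_rates(early + late, "obtained") == [(0, 1.0), (2, 0.0)]

    def test_rate_table_counts_match(self):
        recs = [trip() for _ in range(5)]
        table = hourly_rate_table(recs, "obtained")
        assert table.n.sum() == 5
        assert (table.rate == 1.0).all()


class TestEmpiricalSummaries:
    def test_two_trip_means(self):
        recs = [trip(obtained=1, duration=60.0, via_broker=0),
                trip(obtained=0, duration=120.0, via_broker=None)]
        s = empirical_summaries(recs)
        assert s.p_obtain == 0.5
        assert s.t_mean_success == 60.0
        assert s.t_mean_failure == 120.0
        assert s.t_mean == 90.0

    def test_all_failures_flags_conditionals_undefined(self):
        recs = [trip(obtained=0, via_broker=None) for _ in range(3)]
        s = empirical_summaries(recs)
        assert s.p_obtain == 0.0
        assert s.p_arrest is None and s.p_broker is None and s.p_invite is None

    def test_conditional_proportions(self):
        recs = [trip(via_broker=1, invited=1), trip(via_broker=1, invited=0),
                trip(via_broker=0), trip(via_broker=0)]
        s = empirical_summaries(recs)
        assert s.p_broker == 0.5
        assert s.p_invite == 0.5

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            empirical_summaries([])


def test_hourly_rates_weighted_by_counts_match_overall_summary():
    """The count-weighted average of hourly rates is exactly the per-trip
    rate of the same outcome (consistency of the two estimators)."""
    rng = np.random.default_rng(3)
    recs = []
    for i in range(400):
        obtained = int(rng.random() < 0.6)
        vb = int(rng.random() < 0.5) if obtained else None
        inv = int(rng.random() < 0.1) if vb == 1 else None
        recs.append(trip(day=int(rng.integers(0, 5)),
                         entry_minute=float(rng.uniform(0, 1440)),
                         duration=float(rng.uniform(10, 200)),
                         obtained=obtained, via_broker=vb, invited=inv))
    for outcome, expected in [
        ("obtained", np.mean([r.obtained for r in recs])),
        ("via_broker", np.mean([r.via_broker for r in recs if r.obtained])),
        ("invited", np.mean([r.invited for r in recs if r.via_broker == 1])),
    ]:
        table = hourly_rate_table(recs, outcome)
        weighted = np.average(table.rate, weights=table.n)
        assert weighted == pytest.approx(expected, abs=1e-12)


class TestTripIO:
    def test_round_trip(self, tmp_path):
        recs = [trip(), trip(obtained=0, via_broker=None, duration=200.0),
                trip(via_broker=1, invited=0)]
        path = tmp_path / "trips.jsonl"
        hm.write_trips(path, recs)
        back = hm.read_trips(path)
        assert [r.to_dict() for r in back] == [r.to_dict() for r in recs]

    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "trips.jsonl"
        hm.write_trips(path, [])
        assert hm.read_trips(path) == []

    def test_corrupted_line_reports_line_number(self, tmp_path):
        path = tmp_path / "trips.jsonl"
        hm.write_trips(path, [trip()])
        with open(path, "a") as fh:
            fh.write("{not json\n")
        with pytest.raises(IntegrityError, match="line 2"):
            hm.read_trips(path)

    def test_invariant_violation_rejected_on_read(self, tmp_path):
        path = tmp_path / "trips.jsonl"
        bad = trip().to_dict()
        bad["obtained"], bad["arrested"], bad["via_broker"] = 0, 1, None
        import json
        path.write_text(json.dumps(bad) + "\n")
        with pytest.raises(IntegrityError, match="line 1"):
            hm.read_trips(path)
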