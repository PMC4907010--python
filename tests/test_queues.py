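"""Interval grid, event counting, queue recursion and its census oracle."""
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edcrowd import (
    BLACKBOX,
    BUILTIN_QUEUES,
    Q1,
    Q2,
    Q3,
    Q4,
    FlowCompleteness,
    QueueDefinition,
    aggregate_table,
    census_oracle,
    classify_flow,
    count_events,
    make_interval_grid,
    queue_recursion,
)
from conftest import make_record, random_records

T0 = datetime(2013, 1, 1, 0, 0)


class TestGrid:
    def test_one_year_at_30_min_gives_17520_intervals(self):
        grid = make_interval_grid(T0, T0 + timedelta(days=365))
        assert len(grid) == 17520

    def test_one_hour_gives_two_intervals(self):
        assert len(make_interval_grid(T0, T0 + timedelta(hours=1))) == 2

    def test_partial_trailing_interval_keeps_its_start(self):
        grid = make_interval_grid(T0, T0 + timedelta(minutes=70))
        assert len(grid) == 3  # ceil(70 / 30)

    @pytest.mark.parametrize("width", [timedelta(0), timedelta(minutes=-30),
                                       timedelta(minutes=7)])
    def test_bad_widths_rejected(self, width):
        with pytest.raises(ValueError):
            make_interval_grid(T0, T0 + timedelta(days=1), width)


class TestQueueDefinition:
    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            QueueDefinition("bad", "departure", "arrival")

    def test_builtins_cover_the_extended_flow(self):
        assert set(BUILTIN_QUEUES) == {"blackbox", "Q1", "Q2", "Q3", "Q4"}


class TestCountEvents:
    def test_event_on_interval_start_binned_there(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=3))
        rec = make_record("a", grid[3].to_pydatetime(), stay_min=10)
        ec = count_events([rec], grid)
        assert ec.A[3] == 1 and ec.D[3] == 1

    def test_arrival_and_departure_same_interval(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=2))
        rec = make_record("a", T0 + timedelta(minutes=35), stay_min=10)
        ec = count_events([rec], grid)
        assert ec.A[1] == 1 and ec.D[1] == 1

    def test_total_arrivals_match_direct_count(self, rng):
        grid = make_interval_grid(T0, T0 + timedelta(days=7))
        records = random_records(rng, 1000, T0, period_minutes=7 * 1440)
        ec = count_events(records, grid)
        n_in = sum(1 for r in records if T0 <= r.arrival < T0 + timedelta(days=7))
        assert ec.A.sum() == n_in == 1000

    def test_events_outside_grid_spill(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=1))
        rec = make_record("late", T0 + timedelta(hours=5), stay_min=30)
        ec = count_events([rec], grid)
        assert ec.A.sum() == 0 and ec.n_entry_spill == 1

    def test_missing_bound_contributes_nothing(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=2))
        rec = make_record("a", T0, stay_min=60)  # no triage time
        ec = count_events([rec], grid, Q1)
        assert ec.A.sum() == 0 and ec.D.sum() == 0


class TestRecursion:
    def test_hand_recursion(self):
        Q = queue_recursion([2, 1, 0], [0, 2, 1])
        assert Q.tolist() == [0, 2, 1, 0]

    def test_equal_flows_keep_queue_constant(self):
        A = [3, 1, 4, 1]
        Q = queue_recursion(A, A, q0=5)
        assert Q.tolist() == [5] * 5

    def test_telescoping_sum(self, rng):
        A = rng.integers(0, 10, 500)
        D = rng.integers(0, 10, 500)
        Q = queue_recursion(A, D, q0=2)
        assert Q[-1] == 2 + A.sum() - D.sum()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            queue_recursion([1, 2], [1])

    def test_negative_values_returned_unchanged(self, caplog):
        with caplog.at_level("WARNING"):
            Q = queue_recursion([0, 0], [1, 0])
        assert Q.tolist() == [0, -1, -1]
        assert any("negative" in r.message for r in caplog.records)


class TestCensusOracle:
    def test_empty_record_set_all_zero(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=2))
        assert census_oracle([], grid).tolist() == [0, 0, 0, 0]

    def test_single_visit_spanning_three_interval_starts(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=3))
        rec = make_record("a", T0 + timedelta(minutes=10), stay_min=90)  # 00:10-01:40
        assert census_oracle([rec], grid).tolist() == [0, 1, 1, 1, 0, 0]

    def test_equals_recursion_on_simulated_visits(self, rng):
        grid = make_interval_grid(T0, T0 + timedelta(days=10))
        records = random_records(rng, 2000, T0, period_minutes=10 * 1440 - 600)
        ec = count_events(records, grid)
        Q = queue_recursion(ec.A, ec.D)
        np.testing.assert_array_equal(census_oracle(records, grid), Q[: len(grid)])

    def test_departure_on_interval_start_still_present_there(self):
        # the departure event belongs to the interval starting at that minute,
        # so it first affects Q at the *next* interval start
        grid = make_interval_grid(T0, T0 + timedelta(hours=2))
        rec = make_record("a", T0 + timedelta(minutes=10), stay_min=50)  # leaves 01:00
        census = census_oracle([rec], grid)
        ec = count_events([rec], grid)
        np.testing.assert_array_equal(census, queue_recursion(ec.A, ec.D)[:4])
        assert census.tolist() == [0, 1, 1, 0]


@st.composite
def record_sets(draw):
    n = draw(st.integers(1, 40))
    horizon = 3 * 1440
    recs = []
    for i in range(n):
        a = draw(st.integers(0, horizon - 1))
        s = draw(st.integers(0, 2000))
        recs.append(make_record(f"h{i}", T0 + timedelta(minutes=a), s))
    return recs


class TestInvariants:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(record_sets())
    def test_recursion_equals_census_oracle(self, records):
        grid = make_interval_grid(T0, T0 + timedelta(days=3))
        ec = count_events(records, grid)
        Q = queue_recursion(ec.A, ec.D)
        np.testing.assert_array_equal(census_oracle(records, grid), Q[: len(grid)])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(record_sets())
    def test_conservation(self, records):
        grid = make_interval_grid(T0, T0 + timedelta(days=3))
        ec = count_events(records, grid)
        Q = queue_recursion(ec.A, ec.D, q0=0)
        assert Q[-1] == ec.A.sum() - ec.D.sum()

    def test_halving_width_preserves_totals(self, rng):
        records = random_records(rng, 500, T0, period_minutes=2 * 1440)
        coarse = make_interval_grid(T0, T0 + timedelta(days=4), timedelta(minutes=30))
        fine = make_interval_grid(T0, T0 + timedelta(days=4), timedelta(minutes=15))
        ec_c = count_events(records, coarse)
        ec_f = count_events(records, fine)
        assert ec_c.A.sum() == ec_f.A.sum()
        assert ec_c.D.sum() == ec_f.D.sum()

    def test_subqueues_nest_and_sum_to_blackbox(self, rng):
        # complete, ordered surrogate timestamps: Q1+Q2+Q3+Q4 == blackbox Q
        grid = make_interval_grid(T0, T0 + timedelta(days=2))
        records = []
        for i in range(300):
            a = int(rng.integers(0, 2 * 1440 - 700))
            stay = int(rng.integers(4, 600))
            cuts = sorted(rng.integers(0, stay + 1, 3))
            records.append(make_record(
                f"c{i}", T0 + timedelta(minutes=a), stay,
                triage=int(cuts[0]), first=int(cuts[1]), last=int(cuts[2]),
            ))
        tab = aggregate_table(records, grid, [BLACKBOX, Q1, Q2, Q3, Q4],
                              attributes=False)
        total = sum(tab[f"Q_{q}"] for q in ("Q1", "Q2", "Q3", "Q4"))
        np.testing.assert_array_equal(total.to_numpy(), tab["Q_blackbox"].to_numpy())
        for q in ("Q1", "Q2", "Q3", "Q4"):
            assert (tab["Q_blackbox"] >= tab[f"Q_{q}"]).all()


class TestAggregateTable:
    def test_empty_interval_has_missing_mean_age(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=2))
        rec = make_record("a", T0 + timedelta(minutes=10), stay_min=40,
                          age=50, triage_score=1, trauma=True)
        tab = aggregate_table([rec], grid)
        assert np.isnan(tab["mean_age"].iloc[0])      # nobody present at T0
        assert tab["n_red"].iloc[0] == 0

    def test_red_trauma_patient_counted_while_present(self):
        grid = make_interval_grid(T0, T0 + timedelta(hours=2))
        rec = make_record("a", T0 + timedelta(minutes=10), stay_min=40,
                          age=50, triage_score=1, trauma=True)
        tab = aggregate_table([rec], grid)
        assert tab["n_red"].iloc[1] == 1 and tab["n_trauma"].iloc[1] == 1
        assert tab["mean_age"].iloc[1] == 50

    def test_column_sums_match_counting_oracle(self, rng):
        grid = make_interval_grid(T0, T0 + timedelta(days=5))
        records = random_records(rng, 800, T0, period_minutes=4 * 1440)
        tab = aggregate_table(records, grid)
        ec = count_events(records, grid)
        assert tab["A_blackbox"].sum() == ec.A.sum()
        assert tab["D_blackbox"].sum() == ec.D.sum()


class TestClassifyFlow:
    def test_category_assignment(self):
        a = make_record("all", T0, 60, triage=5, first=20, last=40)
        tri = make_record("tri", T0, 60, triage=5)
        ews = make_record("ews", T0, 60, first=20)
        bb = make_record("bb", T0, 60)
        fc = classify_flow([a, tri, ews, bb])
        assert (fc.complete, fc.triage_only, fc.ews_no_triage, fc.blackbox_only) \
            == (1, 1, 1, 1)
        assert fc.total == 4

    def test_triage_with_partial_ews_counts_as_triage_only(self):
        r = make_record("p", T0, 60, triage=5, first=20)  # no last EWS
        fc = classify_flow([r])
        assert fc.triage_only == 1 and fc.complete == 0

    def test_reported_percentages_to_one_decimal(self):
        # counts with the shares 28.2 / 0.8 / 71.0 over 41,693 records
        fc = FlowCompleteness(complete=3926, triage_only=11742 - 3926,
                              ews_no_triage=338, blackbox_only=29613)
        assert fc.total == 41693
        pct = fc.percentages()
        assert pct["triaged"] == 28.2
        assert pct["ews_no_triage"] == 0.8
        assert pct["blackbox_only"] == 71.0
        assert pct["complete"] == 9.4
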