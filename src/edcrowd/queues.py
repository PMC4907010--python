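"""Interval grid, event counting, queue recursion and flow completeness.

The central object is the aggregated interval table: the study period is cut
into half-open intervals of fixed width (default 30 min), arrivals ``A(t)``
and departures ``D(t)`` are counted per interval for each queue definition,
and the queue length at the start of every interval follows the recursion

    Q(t + 1) = Q(t) + A(t) - D(t),    Q(0) = 0.

``Q(t)`` is a start-of-interval census: a patient whose entry event falls in
interval ``t`` first appears in ``Q(t + 1)``, and one who both enters and
leaves strictly inside one interval never appears in any ``Q``.  An
independent census oracle (direct counting of who is present at each interval
start) is provided to verify the recursion exactly.

Boundary convention: an event exactly on an interval boundary belongs to the
interval starting there.  Consequently the census at interval start ``s``
counts records with ``entry < s <= exit`` — a patient departing exactly at
``s`` still occupies the queue at ``s``, because that departure is counted
during the interval beginning at ``s``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import PatientRecord, TIMESTAMP_ORDER

log = logging.getLogger(__name__)

_NS_PER_MIN = 60_000_000_000


@dataclass(frozen=True)
class QueueDefinition:
    """A named queue bounded by an entry and an exit timestamp field.

    Built-ins: ``blackbox`` (arrival -> departure) plus the extended flow
    ``Q1`` (arrival -> triage), ``Q2`` (triage -> first EWS), ``Q3`` (first ->
    last EWS) and ``Q4`` (last EWS -> departure).
    """

    name: str
    entry_field: str
    exit_field: str

    def __post_init__(self):
        for f in (self.entry_field, self.exit_field):
            if f not in TIMESTAMP_ORDER:
                raise ValueError(f"unknown timestamp field {f!r}")
        if TIMESTAMP_ORDER.index(self.entry_field) >= TIMESTAMP_ORDER.index(self.exit_field):
            raise ValueError(
                f"entry field {self.entry_field!r} must precede exit field "
                f"{self.exit_field!r} in the idealised flow"
            )


BLACKBOX = QueueDefinition("blackbox", "arrival", "departure")
Q1 = QueueDefinition("Q1", "arrival", "triage_time")
Q2 = QueueDefinition("Q2", "triage_time", "first_ews_time")
Q3 = QueueDefinition("Q3", "first_ews_time", "last_ews_time")
Q4 = QueueDefinition("Q4", "last_ews_time", "departure")
BUILTIN_QUEUES = {q.name: q for q in (BLACKBOX, Q1, Q2, Q3, Q4)}


def make_interval_grid(period_start, period_end, width=timedelta(minutes=30)) -> pd.DatetimeIndex:
    """Starts of half-open intervals ``[s, s + width)`` tiling the period.

    ``width`` must be positive and divide 24 h evenly, so every day holds the
    same number of intervals.  The number of starts is
    ``ceil((period_end - period_start) / width)``; a trailing partial interval
    keeps its start.
    """
    width = pd.Timedelta(width)
    if width <= pd.Timedelta(0):
        raise ValueError("interval width must be positive")
    if pd.Timedelta(days=1) % width != pd.Timedelta(0):
        raise ValueError(f"interval width {width} must divide 24 h evenly")
    start, end = pd.Timestamp(period_start), pd.Timestamp(period_end)
    if start >= end:
        raise ValueError("period_start must precede period_end")
    return pd.date_range(start, end, freq=width, inclusive="left")


def _grid_width(grid: pd.DatetimeIndex) -> pd.Timedelta:
    if getattr(grid, "freq", None) is not None:
        return pd.Timedelta(grid.freq)
    if len(grid) >= 2:
        return grid[1] - grid[0]
    raise ValueError("cannot infer interval width from a single-point grid without freq")


def _queue_bounds(records: Iterable[PatientRecord], qdef: QueueDefinition):
    """Entry/exit times (ns since epoch) of records usable for this queue.

    A record contributes only when both bounds are present and ordered; an
    inverted pair (an order violation for this queue) is excluded and counted.
    """
    entries, exits, n_order_excluded = [], [], 0
    for r in records:
        e = getattr(r, qdef.entry_field)
        x = getattr(r, qdef.exit_field)
        if e is None or x is None:
            continue
        if x < e:
            n_order_excluded += 1
            continue
        entries.append(e)
        exits.append(x)
    if not entries:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), n_order_excluded
    return (
        pd.DatetimeIndex(entries).asi8,
        pd.DatetimeIndex(exits).asi8,
        n_order_excluded,
    )


@dataclass
class EventCounts:
    """Per-interval arrival/departure counts plus spill diagnostics."""

    A: np.ndarray
    D: np.ndarray
    n_entry_spill: int = 0
    n_exit_spill: int = 0
    n_order_excluded: int = 0


def count_events(records, grid: pd.DatetimeIndex, qdef: QueueDefinition = BLACKBOX) -> EventCounts:
    """Count queue entries (A) and exits (D) per half-open grid interval.

    An event at time ``x`` is counted in the unique interval with
    ``start <= x < start + width``; events outside the grid are ignored but
    tallied as spill.  Records missing either bound of ``qdef`` contribute
    nothing to this queue.
    """
    if len(grid) == 0:
        raise ValueError("empty interval grid")
    width_ns = _grid_width(grid).value
    g0 = grid.asi8[0]
    n = len(grid)
    entries, exits, n_order = _queue_bounds(records, qdef)

    def bin_events(ts: np.ndarray) -> tuple[np.ndarray, int]:
        idx = (ts - g0) // width_ns
        inside = (idx >= 0) & (idx < n)
        counts = np.bincount(idx[inside].astype(np.intp), minlength=n).astype(np.int64)
        return counts, int(ts.size - inside.sum())

    A, spill_a = bin_events(entries)
    D, spill_d = bin_events(exits)
    if spill_a or spill_d:
        log.warning(
            "queue %s: %d entry and %d exit events fall outside the grid and were ignored",
            qdef.name, spill_a, spill_d,
        )
    return EventCounts(A=A, D=D, n_entry_spill=spill_a, n_exit_spill=spill_d,
                       n_order_excluded=n_order)


def queue_recursion(A, D, q0: int = 0) -> np.ndarray:
    """Run ``Q(t + 1) = Q(t) + A(t) - D(t)`` from ``Q(0) = q0``.

    Returns the integer series ``Q(0) .. Q(n)`` of length ``len(A) + 1``.
    Negative values are returned unchanged (clamping would break the
    conservation identity ``q0 + sum(A) - sum(D) = Q(n)``) but logged, since
    they signal patients present before the period start that the recursion
    cannot see.
    """
    A = np.asarray(A, dtype=np.int64)
    D = np.asarray(D, dtype=np.int64)
    if A.shape != D.shape or A.ndim != 1:
        raise ValueError("A and D must be 1-d arrays of equal length")
    Q = np.empty(A.size + 1, dtype=np.int64)
    Q[0] = q0
    np.cumsum(A - D, out=Q[1:])
    Q[1:] += q0
    if Q.size and Q.min() < 0:
        log.warning("queue length went negative (min %d); the recursion started from "
                    "Q(0)=%d cannot see patients already present", int(Q.min()), q0)
    return Q


def census_oracle(records, grid: pd.DatetimeIndex, qdef: QueueDefinition = BLACKBOX) -> np.ndarray:
    """Direct census: patients with ``entry < s <= exit`` at each interval start.

    Independent of the recursion; for any record set whose entry events all
    fall inside the grid the result equals
    ``queue_recursion(count_events(...))`` at every interval start.
    """
    if len(grid) == 0:
        raise ValueError("empty interval grid")
    g = grid.asi8
    n = len(grid)
    entries, exits, _ = _queue_bounds(records, qdef)
    if entries.size == 0:
        return np.zeros(n, dtype=np.int64)
    first = np.searchsorted(g, entries, side="right")       # first start > entry
    last = np.searchsorted(g, exits, side="right") - 1      # last start <= exit
    last = np.minimum(last, n - 1)
    keep = (first <= last) & (first < n)
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, first[keep], 1)
    np.add.at(diff, last[keep] + 1, -1)
    return np.cumsum(diff[:n])


def _presence_index(records: Sequence[PatientRecord], grid: pd.DatetimeIndex):
    """First/last interval-start index at which each record is present (blackbox)."""
    g = grid.asi8
    n = len(grid)
    arr = pd.DatetimeIndex([r.arrival for r in records]).asi8
    dep = pd.DatetimeIndex([r.departure for r in records]).asi8
    first = np.searchsorted(g, arr, side="right")
    last = np.minimum(np.searchsorted(g, dep, side="right") - 1, n - 1)
    keep = (first <= last) & (first < n)
    return first, last, keep


def aggregate_table(
    records: Sequence[PatientRecord],
    grid: pd.DatetimeIndex,
    qdefs: Sequence[QueueDefinition] = (BLACKBOX,),
    attributes: bool = True,
) -> pd.DataFrame:
    """Build the aggregated interval table.

    One row per grid interval with, per queue ``q``: ``A_q``, ``D_q`` and the
    start-of-interval queue length ``Q_q`` from the recursion.  With
    ``attributes=True`` the table also carries, over patients present under
    the black-box queue at the interval start: ``mean_age`` (NaN when nobody
    with a known age is present), ``n_red`` (patients triaged red) and
    ``n_trauma``.
    """
    if not qdefs:
        raise ValueError("at least one queue definition is required")
    records = list(records)
    data: dict = {"interval_start": grid.to_numpy()}
    for q in qdefs:
        ec = count_events(records, grid, q)
        data[f"A_{q.name}"] = ec.A
        data[f"D_{q.name}"] = ec.D
        data[f"Q_{q.name}"] = queue_recursion(ec.A, ec.D)[: len(grid)]

    if attributes:
        n = len(grid)
        age_sum = np.zeros(n + 1)
        age_cnt = np.zeros(n + 1, dtype=np.int64)
        red = np.zeros(n + 1, dtype=np.int64)
        trauma = np.zeros(n + 1, dtype=np.int64)
        if records:
            first, last, keep = _presence_index(records, grid)
            ages = np.array([np.nan if r.age is None else float(r.age) for r in records])
            is_red = np.array([r.triage_score == 1 for r in records])
            is_trauma = np.array([bool(r.trauma) for r in records])

            def scatter(target, weights, mask):
                m = keep & mask
                np.add.at(target, first[m], weights[m] if weights is not None else 1)
                np.subtract.at(target, last[m] + 1, weights[m] if weights is not None else 1)

            has_age = ~np.isnan(ages)
            scatter(age_sum, ages, has_age)
            scatter(age_cnt, None, has_age)
            scatter(red, None, is_red)
            scatter(trauma, None, is_trauma)
        age_sum = np.cumsum(age_sum[:n])
        age_cnt = np.cumsum(age_cnt[:n])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_age = np.where(age_cnt > 0, age_sum / np.maximum(age_cnt, 1), np.nan)
        data["mean_age"] = mean_age
        data["n_red"] = np.cumsum(red[:n])
        data["n_trauma"] = np.cumsum(trauma[:n])

    return pd.DataFrame(data)


@dataclass(frozen=True)
class FlowCompleteness:
    """Mutually exclusive classification of surrogate-timestamp availability.

    ``complete``: triage, first and last EWS all present; ``triage_only``:
    triage present but the flow otherwise incomplete; ``ews_no_triage``:
    first EWS without triage; ``blackbox_only``: neither triage nor first EWS
    (only arrival/departure usable).
    """

    complete: int
    triage_only: int
    ews_no_triage: int
    blackbox_only: int

    @property
    def total(self) -> int:
        return self.complete + self.triage_only + self.ews_no_triage + self.blackbox_only

    @property
    def n_triaged(self) -> int:
        """Records with any triage timestamp (complete or not)."""
        return self.complete + self.triage_only

    def percentages(self) -> dict[str, float]:
        """Category shares of the total, in percent to one decimal."""
        if self.total == 0:
            return {}
        return {
            "complete": round(100 * self.complete / self.total, 1),
            "triage_only": round(100 * self.triage_only / self.total, 1),
            "ews_no_triage": round(100 * self.ews_no_triage / self.total, 1),
            "blackbox_only": round(100 * self.blackbox_only / self.total, 1),
            "triaged": round(100 * self.n_triaged / self.total, 1),
        }


def classify_flow(records: Iterable[PatientRecord]) -> FlowCompleteness:
    """Assign each record to exactly one flow-completeness category."""
    complete = triage_only = ews_no_triage = blackbox_only = 0
    for r in records:
        has_tri = r.triage_time is not None
        has_first = r.first_ews_time is not None
        has_last = r.last_ews_time is not None
        if has_tri and has_first and has_last:
            complete += 1
        elif has_first and not has_tri:
            ews_no_triage += 1
        elif has_tri:
            triage_only += 1
        else:
            blackbox_only += 1
    return FlowCompleteness(
        complete=complete,
        triage_only=triage_only,
        ews_no_triage=ews_no_triage,
        blackbox_only=blackbox_only,
    )
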