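"""Operational days, 8-hour shifts, per-shift maximum queues and nurse ratios.

The operational day starts with the day shift at 07:00; shifts are day
(07:00-14:59), evening (15:00-22:59) and night (23:00-06:59), the night being
attributed to the operational day on which it began.  Friday and Saturday
nights count as weekend nights; day and evening shifts are weekend shifts on
Saturday and Sunday calendar dates.

The headline statistic per (operational day, shift) cell is the *max queue*:
the largest start-of-interval census observed during the shift.  Because the
recursion starts from an empty queue, the first shifts of a period understate
the census; analyses therefore discard a burn-in of three shifts (24 h) by
default.
"""
from __future__ import annotations

import logging
from datetime import date, datetime, time, timedelta
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import RosterConfig
from .risk import season_of

log = logging.getLogger(__name__)

SHIFTS = ("day", "evening", "night")
#: Clock windows per shift; ends are inclusive minutes, night wraps midnight.
SHIFT_WINDOWS = {
    "day": (time(7, 0), time(14, 59)),
    "evening": (time(15, 0), time(22, 59)),
    "night": (time(23, 0), time(6, 59)),
}


def shift_of(ts: datetime) -> tuple[date, str, bool]:
    """Map a timestamp to (operational day, shift, weekend flag)."""
    h = ts.hour
    if 7 <= h < 15:
        shift = "day"
    elif 15 <= h < 23:
        shift = "evening"
    else:
        shift = "night"
    op_day = ts.date() - timedelta(days=1) if h < 7 else ts.date()
    if shift == "night":
        weekend = op_day.weekday() in (4, 5)      # Friday/Saturday night
    else:
        weekend = op_day.weekday() >= 5           # Saturday/Sunday
    return op_day, shift, weekend


def _shift_columns(interval_start: pd.Series) -> pd.DataFrame:
    """Vectorised :func:`shift_of` for a series of interval starts."""
    ts = pd.to_datetime(interval_start)
    hour = ts.dt.hour
    shift = pd.Series(
        np.select([(hour >= 7) & (hour < 15), (hour >= 15) & (hour < 23)],
                  ["day", "evening"], default="night"),
        index=ts.index,
    )
    op_day = (ts - pd.to_timedelta((hour < 7).astype(int), unit="D")).dt.date
    dow = pd.Series([d.weekday() for d in op_day], index=ts.index)
    weekend = np.where(shift == "night", dow.isin([4, 5]), dow >= 5)
    return pd.DataFrame(
        {"operational_day": op_day, "shift": shift, "weekend": weekend}, index=ts.index
    )


def round_half_up(x, ndigits: int = 1) -> float:
    """Round half away from zero (2.85 -> 2.9, 1.75 -> 1.8), decimal-exact."""
    if isinstance(x, Fraction):
        dec = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        dec = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def patient_nurse_ratio(queue_len: int, n_nurses: int) -> float:
    """Patients per nurse, rounded half-away-from-zero to one decimal."""
    if n_nurses < 1:
        raise ValueError("n_nurses must be a positive integer")
    if queue_len < 0:
        raise ValueError("queue_len must be non-negative")
    return round_half_up(Fraction(queue_len) / n_nurses, 1)


def shift_nurses(roster: RosterConfig, shift: str, weekend: bool) -> tuple[int, Optional[int]]:
    """Nurse count applying to a shift, with the alternative band's count.

    A shift overlapping several roster bands takes the band covering the
    majority of its minutes (ties broken toward the band covering the shift
    start); the runner-up band's count is returned as the alternative when it
    differs, mirroring dual staffing presentations such as "2.5 when 8
    nurses".
    """
    if shift not in SHIFT_WINDOWS:
        raise ValueError(f"unknown shift {shift!r}")
    day_class = "weekend" if weekend else "weekday"
    start, end = SHIFT_WINDOWS[shift]
    s = start.hour * 60 + start.minute
    e = end.hour * 60 + end.minute
    shift_minutes = (
        frozenset(range(s, e + 1)) if s <= e
        else frozenset(range(s, 1440)) | frozenset(range(0, e + 1))
    )
    overlaps = []
    for band in roster.bands_for(day_class):
        ov = len(shift_minutes & band.minutes())
        if ov:
            overlaps.append((ov, s in band.minutes(), band))
    if not overlaps:
        raise ValueError(f"roster has no {day_class} band overlapping the {shift} shift")
    overlaps.sort(key=lambda t: (t[0], t[1]), reverse=True)
    primary = overlaps[0][2].nurses
    alt = next((b.nurses for _, _, b in overlaps[1:] if b.nurses != primary), None)
    return primary, alt


def max_queue_per_shift(
    intervals: pd.DataFrame,
    queue: str = "blackbox",
    burn_in_shifts: int = 3,
    roster: Optional[RosterConfig] = None,
) -> pd.DataFrame:
    """Extract the maximum queue length of every (operational day, shift) cell.

    ``intervals`` is an aggregated table with ``interval_start`` and
    ``Q_<queue>`` columns, ordered and contiguous.  The first
    ``burn_in_shifts`` cells are discarded so the census has recovered from
    the empty start.  A full 8-h shift holds ``8 h / width`` intervals (16 at
    30 min); trailing partial shifts are kept and recognisable by a smaller
    ``n_intervals``.  When a roster is supplied, each row also carries the
    applicable nurse count (plus alternative) and the max-queue-to-nurse
    ratios.
    """
    qcol = f"Q_{queue}"
    if qcol not in intervals.columns:
        raise KeyError(f"column {qcol!r} not found in interval table")
    if burn_in_shifts < 0:
        raise ValueError("burn_in_shifts must be >= 0")
    columns = ["operational_day", "shift", "weekend", "max_queue", "n_intervals"]
    if roster is not None:
        columns += ["n_nurses", "n_nurses_alt", "ratio", "ratio_alt"]
    if len(intervals) == 0:
        return pd.DataFrame(columns=columns)

    ts = pd.to_datetime(intervals["interval_start"])
    if not ts.is_monotonic_increasing:
        raise ValueError("interval table must be ordered by interval_start")

    df = pd.concat([_shift_columns(ts), intervals[[qcol]].reset_index(drop=True)], axis=1)
    grouped = (
        df.groupby(["operational_day", "shift"], sort=False)
        .agg(
            weekend=("weekend", "first"),
            max_queue=(qcol, "max"),
            n_intervals=(qcol, "size"),
        )
        .reset_index()
    )
    out = grouped.iloc[burn_in_shifts:].reset_index(drop=True)

    if roster is not None:
        primary, alt, ratio, ratio_alt = [], [], [], []
        for row in out.itertuples(index=False):
            p, a = shift_nurses(roster, row.shift, bool(row.weekend))
            primary.append(p)
            alt.append(a)
            ratio.append(patient_nurse_ratio(int(row.max_queue), p))
            ratio_alt.append(patient_nurse_ratio(int(row.max_queue), a) if a else np.nan)
        out = out.assign(n_nurses=primary, n_nurses_alt=alt, ratio=ratio, ratio_alt=ratio_alt)
    return out


def daily_arrivals(intervals: pd.DataFrame, queue: str = "blackbox") -> pd.Series:
    """Total arrivals per operational day, as a Series indexed by date."""
    acol = f"A_{queue}"
    if acol not in intervals.columns:
        raise KeyError(f"column {acol!r} not found in interval table")
    sc = _shift_columns(pd.to_datetime(intervals["interval_start"]))
    return intervals[acol].groupby(sc["operational_day"]).sum()


def _quantiles(values: np.ndarray) -> tuple[float, float]:
    """Median and IQR with linear interpolation between order statistics."""
    q25, q50, q75 = np.percentile(values, [25, 50, 75], method="linear")
    return float(q50), float(q75 - q25)


def summarize_max_queues(
    shift_records: pd.DataFrame,
    capacity: int,
    by_season: bool = False,
    roster: Optional[RosterConfig] = None,
) -> pd.DataFrame:
    """Per-stratum summary of shift maxima.

    Strata are shift x weekend (x season of the operational day when
    ``by_season``).  Each row reports n_shifts, min, max, median, IQR
    (linear-interpolation quantiles) and the percentage of shifts whose max
    queue reached or exceeded ``capacity``.  With a roster, the median
    patient-to-nurse ratio (and the alternative-band ratio) is added.  Empty
    strata yield all-missing rows.
    """
    df = shift_records.copy()
    keys = ["shift", "weekend"]
    levels: list[Sequence] = [SHIFTS, (False, True)]
    if by_season:
        df["season"] = [season_of(d) for d in df["operational_day"]]
        keys.append("season")
        levels.append(("summer", "winter"))

    index = pd.MultiIndex.from_product(levels, names=keys)
    rows = []
    grouped = dict(tuple(df.groupby(keys))) if len(df) else {}
    for key in index:
        g = grouped.get(key if len(keys) > 1 else key[0])
        row = dict(zip(keys, key))
        if g is None or len(g) == 0:
            row.update(n_shifts=0, min=np.nan, max=np.nan, median=np.nan, iqr=np.nan,
                       pct_ge_capacity=np.nan)
            if roster is not None:
                row.update(n_nurses=np.nan, median_ratio=np.nan,
                           n_nurses_alt=np.nan, median_ratio_alt=np.nan)
        else:
            v = g["max_queue"].to_numpy()
            median, iqr = _quantiles(v)
            row.update(
                n_shifts=len(v),
                min=int(v.min()),
                max=int(v.max()),
                median=median,
                iqr=iqr,
                pct_ge_capacity=round(100 * float(np.mean(v >= capacity)), 1),
            )
            if roster is not None:
                shift, weekend = key[0], key[1]
                p, a = shift_nurses(roster, shift, bool(weekend))
                row.update(
                    n_nurses=p,
                    median_ratio=patient_nurse_ratio(median, p),
                    n_nurses_alt=a if a is not None else np.nan,
                    median_ratio_alt=patient_nurse_ratio(median, a) if a else np.nan,
                )
        rows.append(row)
    return pd.DataFrame(rows)
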