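"""Patient-level visit records and duty-roster configuration.

A visit record carries up to five ordered timestamps — arrival, triage,
first early-warning-score (EWS) assessment, last EWS assessment, departure —
of which only arrival and departure are mandatory.  The three in-visit
timestamps are surrogate markers for clinical milestones (start of nurse
assessment, evaluation by a doctor, completion of treatment) and are often
missing in routine data; readers therefore treat them as optional and never
drop a record for their absence.

The roster configuration holds the resources a crowding analysis is judged
against: the number of ED beds and the on-duty nurse count per clock band,
separately for weekdays and weekends.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Idealised order of the five visit timestamps.
TIMESTAMP_ORDER = ("arrival", "triage_time", "first_ews_time", "last_ews_time", "departure")
OPTIONAL_TIMESTAMPS = ("triage_time", "first_ews_time", "last_ews_time")
DEFAULT_TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M"
CANONICAL_COLUMNS = (
    "visit_id", "arrival", "departure", "triage_time", "first_ews_time",
    "last_ews_time", "age", "sex", "triage_score", "trauma", "diagnosis",
)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"", "0", "false", "f", "no", "n"}


class ConfigurationError(ValueError):
    """Invalid column map, roster or simulation specification."""


@dataclass
class PatientRecord:
    """One ED visit.

    ``arrival <= departure`` always holds for accepted records; every present
    optional timestamp lies within ``[arrival, departure]``.  Records whose
    in-visit timestamps violate the idealised order are kept but flagged (see
    :meth:`order_violations`); downstream queue counting excludes them only
    from the specific queues whose bounds are inverted.
    """

    visit_id: str
    arrival: datetime
    departure: datetime
    triage_time: Optional[datetime] = None
    first_ews_time: Optional[datetime] = None
    last_ews_time: Optional[datetime] = None
    age: Optional[float] = None
    sex: Optional[str] = None            # 'F', 'M' or 'other'
    triage_score: Optional[int] = None   # 1..5, 1 = red (most acute)
    trauma: bool = False
    diagnosis: Optional[str] = None

    @property
    def length_of_stay(self) -> timedelta:
        return self.departure - self.arrival

    def timestamp(self, name: str) -> Optional[datetime]:
        if name not in TIMESTAMP_ORDER:
            raise ValueError(f"unknown timestamp field {name!r}")
        return getattr(self, name)

    def order_violations(self) -> list[str]:
        """Adjacent pairs of *present* timestamps that break the idealised order."""
        present = [(f, getattr(self, f)) for f in TIMESTAMP_ORDER if getattr(self, f) is not None]
        return [
            f"{f0}>{f1}"
            for (f0, t0), (f1, t1) in zip(present, present[1:])
            if t1 < t0
        ]


@dataclass
class ValidationReport:
    """Outcome of reading a visit file: counts plus itemised violations.

    ``violations`` lists fatal problems (the record was dropped);
    ``warnings`` lists non-fatal ones (the record was kept, possibly with a
    field blanked).  ``n_read == n_accepted + n_dropped`` always.
    """

    n_read: int = 0
    n_accepted: int = 0
    n_dropped: int = 0
    violations: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_read": self.n_read,
                "n_accepted": self.n_accepted,
                "n_dropped": self.n_dropped,
                "violations": [list(v) for v in self.violations],
                "warnings": [list(w) for w in self.warnings],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def log_summary(self) -> None:
        log.info("read %d visit rows: %d accepted, %d dropped",
                 self.n_read, self.n_accepted, self.n_dropped)
        for visit_id, kind in self.violations:
            log.warning("dropped visit %s: %s", visit_id, kind)
        for visit_id, kind in self.warnings:
            log.info("visit %s: %s", visit_id, kind)


def _parse_ts(raw: Optional[str], fmt: str) -> Optional[datetime]:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        return datetime.strptime(raw, fmt)
    except ValueError:
        return None


def read_patients(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    timestamp_format: str = DEFAULT_TIMESTAMP_FORMAT,
) -> tuple[list[PatientRecord], ValidationReport]:
    """Read visit records from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row; lines starting with ``#`` are comments.
    column_map
        Maps canonical field names (``arrival``, ``departure``, ...) to the
        column names used in the file.  Unmapped fields default to their
        canonical name; ``arrival`` and ``departure`` columns are mandatory.
    timestamp_format
        :func:`~datetime.datetime.strptime` format for every timestamp column.

    Returns
    -------
    (records, report)
        Accepted records (arrival and departure parseable, arrival <=
        departure) and a :class:`ValidationReport` itemising drops.  Optional
        fields that are absent or unparseable become missing, never fatal; an
        optional timestamp outside ``[arrival, departure]`` is blanked with a
        warning.
    """
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        unknown = set(column_map) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown record fields in column_map: {sorted(unknown)}")
        colmap.update(column_map)

    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    for mandatory in ("arrival", "departure"):
        if colmap[mandatory] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[mandatory]!r} (field {mandatory!r}) missing from {path}"
            )

    def cell(row: Mapping[str, str], fld: str) -> str:
        col = colmap[fld]
        return (row.get(col) or "").strip() if col in df.columns else ""

    report = ValidationReport()
    records: list[PatientRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        report.n_read += 1
        visit_id = cell(row, "visit_id") or f"row{i + 1}"

        arrival = _parse_ts(cell(row, "arrival"), timestamp_format)
        departure = _parse_ts(cell(row, "departure"), timestamp_format)
        if arrival is None:
            report.n_dropped += 1
            report.violations.append((visit_id, "unparseable arrival"))
            continue
        if departure is None:
            report.n_dropped += 1
            report.violations.append((visit_id, "unparseable departure"))
            continue
        if departure < arrival:
            report.n_dropped += 1
            report.violations.append((visit_id, "negative stay"))
            continue

        rec = PatientRecord(visit_id=visit_id, arrival=arrival, departure=departure)
        for fld in OPTIONAL_TIMESTAMPS:
            raw = cell(row, fld)
            ts = _parse_ts(raw, timestamp_format)
            if raw and ts is None:
                report.warnings.append((visit_id, f"unparseable {fld}"))
            elif ts is not None and not (arrival <= ts <= departure):
                report.warnings.append((visit_id, f"{fld} outside stay"))
                ts = None
            setattr(rec, fld, ts)

        raw_age = cell(row, "age")
        if raw_age:
            try:
                age = float(raw_age)
                rec.age = age if age >= 0 else None
                if age < 0:
                    report.warnings.append((visit_id, "negative age"))
            except ValueError:
                report.warnings.append((visit_id, "unparseable age"))

        raw_sex = cell(row, "sex").lower()
        if raw_sex in {"f", "female"}:
            rec.sex = "F"
        elif raw_sex in {"m", "male"}:
            rec.sex = "M"
        elif raw_sex:
            rec.sex = "other"

        raw_score = cell(row, "triage_score")
        if raw_score:
            try:
                score = int(raw_score)
                if 1 <= score <= 5:
                    rec.triage_score = score
                else:
                    report.warnings.append((visit_id, "triage score out of range"))
            except ValueError:
                report.warnings.append((visit_id, "unparseable triage score"))

        raw_trauma = cell(row, "trauma").lower()
        if raw_trauma in _TRUTHY:
            rec.trauma = True
        elif raw_trauma not in _FALSY:
            report.warnings.append((visit_id, "unparseable trauma flag"))

        rec.diagnosis = cell(row, "diagnosis") or None

        bad_order = rec.order_violations()
        if bad_order:
            report.warnings.append((visit_id, "order violation: " + ", ".join(bad_order)))

        report.n_accepted += 1
        records.append(rec)

    report.log_summary()
    return records, report


def _format_age(age: Optional[float]) -> str:
    if age is None:
        return ""
    return str(int(age)) if float(age).is_integer() else repr(float(age))


def write_patients(
    records: Iterable[PatientRecord],
    path,
    timestamp_format: str = DEFAULT_TIMESTAMP_FORMAT,
    header_comment: Optional[str] = None,
) -> None:
    """Write records as CSV in the same dialect :func:`read_patients` accepts."""

    def fmt(ts: Optional[datetime]) -> str:
        return ts.strftime(timestamp_format) if ts is not None else ""

    rows = [
        {
            "visit_id": r.visit_id,
            "arrival": fmt(r.arrival),
            "departure": fmt(r.departure),
            "triage_time": fmt(r.triage_time),
            "first_ews_time": fmt(r.first_ews_time),
            "last_ews_time": fmt(r.last_ews_time),
            "age": _format_age(r.age),
            "sex": r.sex or "",
            "triage_score": "" if r.triage_score is None else str(r.triage_score),
            "trauma": "1" if r.trauma else "0",
            "diagnosis": r.diagnosis or "",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


# --------------------------------------------------------------------------
# Roster / capacity configuration
# --------------------------------------------------------------------------

DAY_CLASSES = ("weekday", "weekend")


@dataclass(frozen=True)
class NurseBand:
    """Nurses on duty during a clock band.  ``end`` is the last covered minute."""

    day_class: str
    start: time
    end: time
    nurses: int

    def minutes(self) -> frozenset[int]:
        s = self.start.hour * 60 + self.start.minute
        e = self.end.hour * 60 + self.end.minute
        if s <= e:
            return frozenset(range(s, e + 1))
        return frozenset(range(s, 1440)) | frozenset(range(0, e + 1))


@dataclass(frozen=True)
class RosterConfig:
    """Bed capacity plus the nurse roster, validated to cover each day class."""

    bed_capacity: int
    bands: tuple[NurseBand, ...]

    def __post_init__(self):
        if self.bed_capacity < 1:
            raise ConfigurationError("bed_capacity must be a positive integer")
        for band in self.bands:
            if band.day_class not in DAY_CLASSES:
                raise ConfigurationError(f"unknown day class {band.day_class!r}")
            if band.nurses < 1:
                raise ConfigurationError(f"band {band} must have a positive nurse count")
        for day_class in {b.day_class for b in self.bands}:
            covered: dict[int, NurseBand] = {}
            for band in self.bands_for(day_class):
                for m in band.minutes():
                    if m in covered:
                        raise ConfigurationError(
                            f"{day_class} bands overlap at "
                            f"{m // 60:02d}:{m % 60:02d} ({covered[m]} vs {band})"
                        )
                    covered[m] = band
            missing = sorted(set(range(1440)) - set(covered))
            if missing:
                m = missing[0]
                raise ConfigurationError(
                    f"{day_class} bands leave {m // 60:02d}:{m % 60:02d} uncovered"
                )

    def bands_for(self, day_class: str) -> tuple[NurseBand, ...]:
        return tuple(b for b in self.bands if b.day_class == day_class)

    def nurses_at(self, day_class: str, t: time) -> int:
        """Nurses on duty at clock time ``t`` on a day of the given class."""
        minute = t.hour * 60 + t.minute
        for band in self.bands_for(day_class):
            if minute in band.minutes():
                return band.nurses
        raise ConfigurationError(f"no {day_class} band defined at {t}")


def _parse_band(day_class: str, entry: Mapping) -> NurseBand:
    try:
        start = time.fromisoformat(str(entry["start"]))
        end = time.fromisoformat(str(entry["end"]))
        nurses = int(entry["nurses"])
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"bad {day_class} band {entry!r}: {exc}") from exc
    return NurseBand(day_class=day_class, start=start, end=end, nurses=nurses)


def read_roster(path) -> RosterConfig:
    """Read a roster configuration from a YAML (or JSON) file.

    Expected structure::

        bed_capacity: 19
        nurse_bands:
          weekday:
            - {start: "07:00", end: "11:59", nurses: 7}
            ...
          weekend:
            - ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "bed_capacity" not in raw or "nurse_bands" not in raw:
        raise ConfigurationError(f"roster {path} must declare bed_capacity and nurse_bands")
    bands: list[NurseBand] = []
    for day_class, entries in raw["nurse_bands"].items():
        if day_class not in DAY_CLASSES:
            raise ConfigurationError(f"unknown day class {day_class!r} in {path}")
        for entry in entries or []:
            bands.append(_parse_band(day_class, entry))
    return RosterConfig(bed_capacity=int(raw["bed_capacity"]), bands=tuple(bands))


def default_roster() -> RosterConfig:
    """Roster of the bundled demo site: 19 beds, 4-8 nurses by time band.

    Weekday bands 07:00-11:59 -> 7, 12:00-19:59 -> 8, 20:00-22:59 -> 7,
    23:00-06:59 -> 4; weekend bands 07:00-10:59 -> 7, 11:00-19:59 -> 8,
    20:00-22:59 -> 7, 23:00-06:59 -> 5.
    """
    ref = resources.files("edcrowd").joinpath("data/default_roster.yaml")
    with resources.as_file(ref) as p:
        return read_roster(p)
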