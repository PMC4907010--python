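"""Synthetic ED-visit generator.

Emulates the structure of routinely collected ED flow data so every analysis
stage can be exercised without hospital records:

* a non-homogeneous arrival process at interval resolution — per 30-min
  interval the arrival count is Poisson or negative-binomial with mean
  ``daily mean x diurnal profile weight``, with separate daily means and
  profiles for weekdays and weekends;
* a log-normal length of stay truncated to [1 min, 48 h];
* in-visit surrogate timestamps (triage, first/last EWS) placed at cumulative
  Dirichlet fractions of the stay, hence always ordered and inside the stay
  before any missingness is applied;
* independent per-field missingness of the three surrogate timestamps;
* patient attributes (age, sex, triage score, trauma flag, diagnosis code).

Randomness is fully determined by a single integer seed, split into named
substreams (counts, placement, LOS, gaps, missingness, attributes) so that
changing, say, a missingness probability leaves arrival times untouched.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .queues import make_interval_grid
from .records import ConfigurationError, PatientRecord

_STREAMS = ("counts", "placement", "los", "gaps", "missingness", "attributes")
_NS_PER_MIN = 60_000_000_000


def default_diurnal_profile(n_intervals: int = 48) -> np.ndarray:
    """Normalised within-day arrival weights: quiet nights, late-morning peak
    and a smaller early-evening bump, evaluated at interval midpoints."""
    step = 24.0 / n_intervals
    h = np.arange(n_intervals) * step + step / 2
    w = 0.25 + np.exp(-0.5 * ((h - 11.0) / 3.5) ** 2) \
        + 0.8 * np.exp(-0.5 * ((h - 18.5) / 3.0) ** 2)
    return w / w.sum()


@dataclass
class SimulationSpec:
    """Full parameterisation of the generator; identical specs give identical
    output.

    Defaults describe a mid-size ED over one year: ~114 arrivals per weekday
    and ~115 per weekend day, moderately over-dispersed interval counts
    (negative-binomial, variance = mean * (1 + mean / k) with k = 8), a
    log-normal stay with median about 106 min, and surrogate-timestamp
    missingness matching routine-data marginals (71.8 % of triage times and
    87.9 % of first-EWS times missing).
    """

    period_start: datetime = datetime(2013, 1, 1, 7, 0)
    period_end: datetime = datetime(2014, 1, 1, 7, 0)
    interval_width_min: int = 30
    daily_mean_weekday: float = 113.9
    daily_mean_weekend: float = 115.2
    weekday_profile: Optional[Sequence[float]] = None   # None -> default shape
    weekend_profile: Optional[Sequence[float]] = None
    count_model: str = "negative_binomial"              # or "poisson"
    dispersion_k: float = 8.0
    los_meanlog: float = 4.66                           # log-minutes
    los_sdlog: float = 0.65
    los_min_minutes: float = 1.0
    los_max_minutes: float = 2880.0
    gap_alpha: tuple = (1.5, 2.0, 8.0, 2.5)             # Q1..Q4 stay fractions
    p_missing_triage: float = 0.718
    p_missing_first_ews: float = 0.879
    p_missing_last_ews: float = 0.219
    age_shape: float = 2.0
    age_scale: float = 19.0
    age_max: float = 105.0
    p_female: float = 0.461
    p_red: float = 0.0117
    p_trauma: float = 0.0149
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def intervals_per_day(self) -> int:
        if self.interval_width_min <= 0 or 1440 % self.interval_width_min:
            raise ConfigurationError("interval_width_min must divide 24 h evenly")
        return 1440 // self.interval_width_min

    def profile(self, day_class: str) -> np.ndarray:
        raw = self.weekday_profile if day_class == "weekday" else self.weekend_profile
        n = self.intervals_per_day()
        if raw is None:
            return default_diurnal_profile(n)
        w = np.asarray(raw, dtype=float)
        if w.shape != (n,):
            raise ConfigurationError(
                f"{day_class} profile must have {n} weights, got {w.shape}")
        if (w < 0).any() or w.sum() <= 0:
            raise ConfigurationError(f"{day_class} profile weights must be "
                                     "non-negative with positive sum")
        return w / w.sum()

    def validate(self) -> None:
        if self.period_start >= self.period_end:
            raise ConfigurationError("period_start must precede period_end")
        self.intervals_per_day()
        for name in ("daily_mean_weekday", "daily_mean_weekend"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ConfigurationError(f"unknown count_model {self.count_model!r}")
        if self.count_model == "negative_binomial" and self.dispersion_k <= 0:
            raise ConfigurationError("dispersion_k must be > 0")
        if self.los_sdlog <= 0:
            raise ConfigurationError("los_sdlog must be > 0")
        if not (0 < self.los_min_minutes <= self.los_max_minutes):
            raise ConfigurationError("need 0 < los_min_minutes <= los_max_minutes")
        if len(self.gap_alpha) != 4 or any(a <= 0 for a in self.gap_alpha):
            raise ConfigurationError("gap_alpha must be 4 positive concentrations")
        for name in ("p_missing_triage", "p_missing_first_ews", "p_missing_last_ews",
                     "p_female", "p_red", "p_trauma"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.age_shape <= 0 or self.age_scale <= 0 or self.age_max <= 0:
            raise ConfigurationError("age distribution parameters must be positive")
        for w in (self.weekday_profile, self.weekend_profile):
            if w is not None:
                self.profile("weekday" if w is self.weekday_profile else "weekend")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_start"] = self.period_start.strftime("%Y-%m-%d %H:%M")
        d["period_end"] = self.period_end.strftime("%Y-%m-%d %H:%M")
        d["gap_alpha"] = list(self.gap_alpha)
        for key in ("weekday_profile", "weekend_profile"):
            if d[key] is not None:
                d[key] = [float(v) for v in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown simulation parameters: {sorted(unknown)}")
        for key in ("period_start", "period_end"):
            if key in d and isinstance(d[key], str):
                d[key] = datetime.strptime(d[key], "%Y-%m-%d %H:%M")
        if "gap_alpha" in d:
            d["gap_alpha"] = tuple(d["gap_alpha"])
        spec = cls(**d)
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"simulation spec {path} must be a mapping")
        return cls.from_dict(raw)


def _apply_missingness(records: Sequence[PatientRecord],
                       probabilities: Sequence[float],
                       rng: np.random.Generator) -> list[PatientRecord]:
    p = tuple(probabilities)
    if len(p) != 3 or any(not 0 <= q <= 1 for q in p):
        raise ValueError("probabilities must be three values in [0, 1] for "
                         "(triage, first EWS, last EWS)")
    n = len(records)
    u = rng.random((n, 3))
    out = []
    for i, r in enumerate(records):
        out.append(dataclasses.replace(
            r,
            triage_time=None if u[i, 0] < p[0] else r.triage_time,
            first_ews_time=None if u[i, 1] < p[1] else r.first_ews_time,
            last_ews_time=None if u[i, 2] < p[2] else r.last_ews_time,
        ))
    return out


def inject_missingness(records, probabilities, seed) -> list[PatientRecord]:
    """Blank each surrogate timestamp independently with its probability.

    Arrival and departure are never blanked.  Returns new records; the input
    is not modified.
    """
    return _apply_missingness(list(records), probabilities, np.random.default_rng(seed))


def simulate_ed(spec: SimulationSpec) -> list[PatientRecord]:
    """Generate synthetic visit records according to ``spec``.

    Per interval, a count is drawn from the arrival model; arrivals are
    placed uniformly within the interval at minute precision.  Departure is
    arrival plus a truncated log-normal stay; the surrogate timestamps sit at
    cumulative Dirichlet fractions of the stay (ordered by construction)
    before the configured missingness blanks them field-wise.  Records are
    returned in arrival order with sequential visit ids; the same spec always
    yields the same records.
    """
    spec.validate()
    grid = make_interval_grid(spec.period_start, spec.period_end,
                              timedelta(minutes=spec.interval_width_min))
    ss = np.random.SeedSequence(spec.seed)
    rng = {name: np.random.default_rng(child)
           for name, child in zip(_STREAMS, ss.spawn(len(_STREAMS)))}

    # expected arrivals per interval
    slot = ((grid.asi8 - grid.normalize().asi8) // _NS_PER_MIN) // spec.interval_width_min
    is_weekend = grid.weekday >= 5
    mu = np.where(
        is_weekend,
        spec.daily_mean_weekend * spec.profile("weekend")[slot],
        spec.daily_mean_weekday * spec.profile("weekday")[slot],
    )

    if spec.count_model == "poisson":
        counts = rng["counts"].poisson(mu)
    else:
        k = spec.dispersion_k
        with np.errstate(divide="ignore"):
            p = k / (k + mu)
        counts = rng["counts"].negative_binomial(k, p)
    total = int(counts.sum())
    if total == 0:
        return []

    interval_idx = np.repeat(np.arange(len(grid)), counts)
    offsets = rng["placement"].integers(0, spec.interval_width_min, total)
    arrival_ns = grid.asi8[interval_idx] + offsets * _NS_PER_MIN

    los = rng["los"].lognormal(spec.los_meanlog, spec.los_sdlog, total)
    los = np.clip(los, spec.los_min_minutes, spec.los_max_minutes)
    los_min = np.maximum(1, np.rint(los).astype(np.int64))

    cum = np.cumsum(rng["gaps"].dirichlet(spec.gap_alpha, total), axis=1)
    marks = np.floor(cum[:, :3] * los_min[:, None]).astype(np.int64)

    ages = np.minimum(np.round(rng["attributes"].gamma(spec.age_shape, spec.age_scale,
                                                       total)), spec.age_max)
    female = rng["attributes"].random(total) < spec.p_female
    red = rng["attributes"].random(total) < spec.p_red
    other_score = rng["attributes"].integers(2, 6, total)
    trauma = rng["attributes"].random(total) < spec.p_trauma
    diag = rng["attributes"].integers(10, 100, total)

    order = np.argsort(arrival_ns, kind="stable")
    to_dt = lambda ns: pd.Timestamp(ns).to_pydatetime()
    records: list[PatientRecord] = []
    for rank, i in enumerate(order):
        arr_ns = int(arrival_ns[i])
        records.append(PatientRecord(
            visit_id=f"V{rank + 1:06d}",
            arrival=to_dt(arr_ns),
            departure=to_dt(arr_ns + int(los_min[i]) * _NS_PER_MIN),
            triage_time=to_dt(arr_ns + int(marks[i, 0]) * _NS_PER_MIN),
            first_ews_time=to_dt(arr_ns + int(marks[i, 1]) * _NS_PER_MIN),
            last_ews_time=to_dt(arr_ns + int(marks[i, 2]) * _NS_PER_MIN),
            age=float(ages[i]),
            sex="F" if female[i] else "M",
            triage_score=1 if red[i] else int(other_score[i]),
            trauma=bool(trauma[i]),
            diagnosis=f"D{int(diag[i]):02d}",
        ))

    return _apply_missingness(
        records,
        (spec.p_missing_triage, spec.p_missing_first_ews, spec.p_missing_last_ews),
        rng["missingness"],
    )
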