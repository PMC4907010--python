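"""Nonparametric toolkit: dispersion, rank correlation, rank-sum comparison.

Queue lengths and per-interval arrival counts in an ED are typically skewed
and over-dispersed, so the analyses here are deliberately distribution-free:

* Fisher's index of dispersion (sample variance / sample mean) tests the
  Poisson assumption on count data; ``(n - 1) * index`` is compared to a
  chi-square distribution with ``n - 1`` degrees of freedom.  Index 1 under
  Poisson; > 1 indicates over-dispersion (negative-binomial-like counts).
* Spearman's rho measures carry-over: the rank correlation between the max
  queue of a shift and the max queue of the shift that follows it.
* The Kruskal-Wallis rank-sum test compares max-queue distributions across
  shifts or between weekdays and weekends.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from datetime import timedelta
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _sps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DispersionResult:
    """Fisher's index of dispersion with a two-one-sided chi-square verdict.

    ``p_value`` is the upper-tail (over-dispersion) probability, ``p_lower``
    the lower-tail (under-dispersion) one; ``verdict`` is ``over``/``under``
    when the corresponding tail falls below ``alpha``, else ``equi``.
    """

    index: float
    statistic: float
    df: int
    p_value: float
    p_lower: float
    verdict: str
    alpha: float
    n: int


def fisher_dispersion(counts, alpha: float = 0.05) -> DispersionResult:
    """Variance-to-mean ratio of count data, tested against Poisson."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("counts must be a 1-d sample of size >= 2")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    mean = x.mean()
    if mean == 0:
        raise ValueError("dispersion index is undefined for all-zero counts")
    index = x.var(ddof=1) / mean
    df = x.size - 1
    statistic = df * index
    p_upper = float(_sps.chi2.sf(statistic, df))
    p_lower = float(_sps.chi2.cdf(statistic, df))
    if p_upper < alpha:
        verdict = "over"
    elif p_lower < alpha:
        verdict = "under"
    else:
        verdict = "equi"
    return DispersionResult(index=float(index), statistic=float(statistic), df=df,
                            p_value=p_upper, p_lower=p_lower, verdict=verdict,
                            alpha=alpha, n=x.size)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float,
                      chunk: int = 40320) -> float:
    """Two-sided permutation p-value over all n! pairings of the rank vectors."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    it = itertools.permutations(ryc)
    n_ge = n_tot = 0
    thresh = abs(rho_obs) - 1e-12
    while batch := list(itertools.islice(it, chunk)):
        rhos = np.abs(np.asarray(batch) @ rxc / denom)
        n_ge += int((rhos >= thresh).sum())
        n_tot += len(batch)
    return n_ge / n_tot


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive mid-ranks; rho is the Pearson correlation of the rank
    vectors.  For ``n <= exact_max_n`` the p-value is an exact permutation
    probability; above that the usual t-distribution approximation with
    ``n - 2`` degrees of freedom is used.  A constant input vector leaves rho
    undefined: ``(nan, nan)`` is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("spearman: constant input vector, rho undefined")
        return float("nan"), float("nan")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        return rho, _exact_spearman_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return rho, float(2 * _sps.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis statistic with chi-square p-value."""

    H: float
    df: int
    p_value: float


def kruskal_wallis(groups) -> KWResult:
    """Compare the distributions of two or more groups by rank sums."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis: empty group")
    try:
        H, p = _sps.kruskal(*groups)
    except ValueError as exc:
        if "identical" in str(exc):
            # every observation equal: no rank separation at all
            H, p = 0.0, 1.0
        else:
            raise
    return KWResult(H=float(H), df=len(groups) - 1, p_value=float(p))


@dataclass(frozen=True)
class CarryOverResult:
    """Rank correlation between paired source and following-target values."""

    pairing: str
    rho: float
    p_value: float
    n_pairs: int


#: (source shift, target shift, operational-day lag of the target)
PAIRINGS = {
    "day->evening": ("day", "evening", 0),
    "evening->night": ("evening", "night", 0),
    "night->next_day": ("night", "day", 1),
    "day->next_day": ("day", "day", 1),
}
ARRIVALS_PAIRING = "day->next_day_arrivals"


def carry_over(
    shift_records: Optional[pd.DataFrame],
    pairing: str,
    daily_arrivals: Optional[pd.Series] = None,
) -> CarryOverResult:
    """Carry-over correlation between successive shifts or days.

    Pairs each source value with the immediately following target of the
    required type (same operational day for within-day pairings, the next
    operational day otherwise); a missing partner — across the burn-in
    boundary or a gap in the record — drops the pair.  The pairing
    ``day->next_day_arrivals`` correlates total arrivals of consecutive
    operational days and requires ``daily_arrivals`` (a Series indexed by
    date).  With exactly two pairs, rho is reported with an undefined
    p-value; fewer than two pairs is an error.
    """
    if pairing == ARRIVALS_PAIRING:
        if daily_arrivals is None:
            raise ValueError(f"pairing {pairing!r} requires a daily_arrivals series")
        s = daily_arrivals.sort_index()
        days = list(s.index)
        have = set(days)
        x = [s[d] for d in days if d + timedelta(days=1) in have]
        y = [s[d + timedelta(days=1)] for d in days if d + timedelta(days=1) in have]
    elif pairing in PAIRINGS:
        src, tgt, lag = PAIRINGS[pairing]
        table = {
            (row.operational_day, row.shift): row.max_queue
            for row in shift_records.itertuples(index=False)
        }
        x, y = [], []
        for (d, sh), v in table.items():
            if sh != src:
                continue
            partner = table.get((d + timedelta(days=lag), tgt))
            if partner is not None:
                x.append(v)
                y.append(partner)
    else:
        raise ValueError(
            f"unknown pairing {pairing!r}; choose from "
            f"{sorted(PAIRINGS) + [ARRIVALS_PAIRING]}"
        )

    n = len(x)
    if n < 2:
        raise ValueError(f"pairing {pairing!r}: only {n} pair(s) available")
    if n == 2:
        rx = _sps.rankdata(x)
        ry = _sps.rankdata(y)
        if np.ptp(rx) == 0 or np.ptp(ry) == 0:
            rho = float("nan")
        else:
            # two pairs are concordant or discordant, nothing in between
            rho = float(np.sign((rx[1] - rx[0]) * (ry[1] - ry[0])))
        log.warning("pairing %s: only 2 pairs, p-value undefined", pairing)
        return CarryOverResult(pairing=pairing, rho=rho, p_value=float("nan"), n_pairs=2)
    rho, p = spearman(np.asarray(x, float), np.asarray(y, float))
    return CarryOverResult(pairing=pairing, rho=rho, p_value=p, n_pairs=n)
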