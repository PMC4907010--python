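"""Empirical-CDF-based crowding risk.

Crowding risk is defined on shift maxima: the probability that, at least once
during a shift (i.e. in at least one 30-min interval), the queue reaches or
exceeds the bed capacity — "100 % bed occupancy or more", equality included.
The risk in a stratum is the share of its shifts with ``max_queue >=
threshold``, which equals ``1 - F(threshold - 1)`` of the stratum's empirical
CDF for integer maxima.
"""
from __future__ import annotations

import datetime as _dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


class Ecdf:
    """Right-continuous empirical CDF: ``F(x)`` = share of values ``<= x``."""

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot build an ECDF from an empty sample")
        if np.isnan(v).any():
            raise ValueError("ECDF sample contains NaN")
        self.n = int(v.size)
        self._cdf = _sps.ecdf(v).cdf

    def __call__(self, x):
        out = self._cdf.evaluate(np.asarray(x, dtype=float))
        return float(out) if np.isscalar(x) else out


def ecdf(values) -> Ecdf:
    """Empirical distribution function of ``values`` (non-empty)."""
    return Ecdf(values)


def season_of(d) -> str:
    """April through September is summer; October through March is winter."""
    return "summer" if 4 <= d.month <= 9 else "winter"


def exceedance_risk(
    shift_records: pd.DataFrame,
    threshold: int,
    by_season: bool = False,
) -> pd.DataFrame:
    """Share of shifts whose max queue reaches or exceeds ``threshold``.

    One row per stratum (shift x weekend, optionally x season) with
    ``n_shifts``, ``n_exceed``, ``risk`` (a fraction in [0, 1], NaN for empty
    strata) and the threshold used.  Stratum counts sum to the total number
    of shift records.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    df = shift_records.copy()
    keys = ["shift", "weekend"]
    levels: list[Sequence] = [("day", "evening", "night"), (False, True)]
    if by_season:
        df["season"] = [season_of(d) for d in df["operational_day"]]
        keys.append("season")
        levels.append(("summer", "winter"))

    index = pd.MultiIndex.from_product(levels, names=keys)
    grouped = dict(tuple(df.groupby(keys))) if len(df) else {}
    rows = []
    for key in index:
        g = grouped.get(key)
        row = dict(zip(keys, key))
        if g is None or len(g) == 0:
            row.update(n_shifts=0, n_exceed=0, risk=np.nan, threshold=threshold)
        else:
            v = g["max_queue"].to_numpy()
            n_exceed = int(np.sum(v >= threshold))
            row.update(n_shifts=len(v), n_exceed=n_exceed,
                       risk=n_exceed / len(v), threshold=threshold)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_ecdf(
    shift_records: pd.DataFrame,
    capacity: int,
    path=None,
    ax=None,
):
    """Step plot of per-stratum max-queue ECDFs with a capacity marker.

    Returns the matplotlib axes; saves to ``path`` when given.
    """
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for (shift, weekend), g in shift_records.groupby(["shift", "weekend"]):
        v = np.sort(g["max_queue"].to_numpy())
        if v.size == 0:
            continue
        label = f"{shift} ({'weekend' if weekend else 'weekday'})"
        ax.step(v, np.arange(1, v.size + 1) / v.size, where="post", label=label)
    ax.axvline(capacity, color="red", linestyle=":",
               label=f"100 % bed occupancy ({capacity})")
    ax.set_xlabel("max queue length per shift")
    ax.set_ylabel("ECDF")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
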