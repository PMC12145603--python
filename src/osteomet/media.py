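"""Cumulative blank-referenced correction of conditioned-media values.

For replicate j sampled at day i, the corrected value is

    S_corr[i, j] = mean(S_corr[i-1, :]) + (S[i, j] - B[i-1]) / TA[i, j]

with the day-0 mean set to zero.  B[i-1] is the mean fresh-medium (blank)
value of the batch applied at the previous media exchange, and TA[i, j] is
the replicate's total spectral area (a proxy for cell number / dilution).
Positive trajectories mean net secretion, negative net uptake: each step
adds the area-normalized change relative to fresh medium accumulated since
the last exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MediaSeries:
    """Replicate values for one variable over ordered sampling days.

    raw[day] and total_area[day] are aligned arrays of replicate values;
    blank_mean[day] is the fresh-medium mean applicable to the interval
    ending at that day.  Optional spans[day] gives the length (days) of the
    exchange interval each sampling covers, used only to impute days whose
    replicates are all missing.
    """

    days: list
    raw: dict
    blank_mean: dict
    total_area: dict
    spans: dict | None = None

    def __post_init__(self):
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        for d in self.days:
            r = np.asarray(self.raw[d], dtype=float)
            ta = np.asarray(self.total_area[d], dtype=float)
            if r.shape != ta.shape:
                raise ValueError(f"day {d}: raw/total_area length mismatch")
            if np.any(ta <= 0):
                raise ValueError(f"day {d}: total area must be > 0")


@dataclass
class CorrectedSeries:
    days: list
    corrected: dict = field(default_factory=dict)   # day -> replicate values
    day_means: dict = field(default_factory=dict)   # day -> mean of available


def correct_series(m: MediaSeries) -> CorrectedSeries:
    """Apply the exchange correction in day order.

    Per-day means use the available replicates only.  A day whose replicates
    are all missing would, if simply skipped, drop that exchange interval's
    footprint from the running sum and bias every later value of the series;
    its mean increment is instead imputed (with a warning) from the per-day
    footprint rates of the nearest measured neighbors, weighted by the
    interval spans when provided.
    """
    out = CorrectedSeries(days=list(m.days))
    increments: dict = {}
    for d in m.days:
        if d not in m.blank_mean or m.blank_mean[d] is None or (
                isinstance(m.blank_mean[d], float) and np.isnan(m.blank_mean[d])):
            raise ValueError(f"no blank mean available for day {d}")
        raw = np.asarray(m.raw[d], dtype=float)
        ta = np.asarray(m.total_area[d], dtype=float)
        increments[d] = (raw - float(m.blank_mean[d])) / ta

    spans = m.spans or {d: 1.0 for d in m.days}
    measured = [d for d in m.days if increments[d].size]
    if not measured:
        raise ValueError("series has no measured replicates at any day")

    def _imputed_mean(d):
        rates = []
        before = [x for x in measured if x < d]
        after = [x for x in measured if x > d]
        for nb in ([max(before)] if before else []) + \
                  ([min(after)] if after else []):
            rates.append(float(np.mean(increments[nb])) / spans[nb])
        return float(np.mean(rates)) * spans[d]

    prev_mean = 0.0  # day-0 anchor of the recursion
    for d in m.days:
        out.corrected[d] = prev_mean + increments[d]
        if increments[d].size:
            mean_inc = float(np.mean(increments[d]))
        else:
            warnings.warn(f"day {d}: no replicates; imputing increment from "
                          "neighboring days", stacklevel=2)
            mean_inc = _imputed_mean(d)
        prev_mean = prev_mean + mean_inc
        out.day_means[d] = prev_mean
    return out


def correct_table(media_long: pd.DataFrame, blanks: pd.DataFrame,
                  exchange_days=None) -> pd.DataFrame:
    """Vectorized correction of a long media table.

    media_long columns: sample_id, donor, arm, day, replicate, variable,
    raw, total_area.  blanks columns: day (sampling day the blank applies
    to), variable, value; replicate blank rows are averaged.  exchange_days,
    when given, provides interval spans for imputing fully-missing days.

    Returns the input plus a ``corrected`` column.
    """
    need = {"sample_id", "donor", "arm", "day", "replicate",
            "variable", "raw", "total_area"}
    missing = need - set(media_long.columns)
    if missing:
        raise ValueError(f"media table missing columns {sorted(missing)}")
    bmeans = blanks.groupby(["day", "variable"])["value"].mean()

    all_days = sorted(media_long["day"].unique())
    if exchange_days is not None:
        spans_all = {d: d - max(e for e in exchange_days if e < d)
                     for d in all_days}
    else:
        spans_all = None

    out = media_long.sort_values(
        ["donor", "arm", "variable", "day", "replicate"],
        kind="mergesort").reset_index(drop=True)
    corrected = np.full(len(out), np.nan)
    for (donor, arm, var), grp in out.groupby(
            ["donor", "arm", "variable"], sort=False):
        empty = np.empty(0)
        raw = {d: empty for d in all_days}
        ta = {d: empty for d in all_days}
        pos: dict = {}
        for d, g in grp.groupby("day", sort=True):
            raw[d] = g["raw"].to_numpy()
            ta[d] = g["total_area"].to_numpy()
            pos[d] = g.index.to_numpy()
        bl = {}
        for d in all_days:
            try:
                bl[d] = float(bmeans.loc[(d, var)])
            except KeyError:
                raise ValueError(
                    f"no blank mean for variable {var!r} at day {d}") from None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # missing-day imputation is routine here
            # keep fully-missing days in the series so they can be imputed
            series = correct_series(MediaSeries(all_days, raw, bl, ta,
                                                spans=spans_all))
        for d, idx in pos.items():
            corrected[idx] = series.corrected[d]
    out["corrected"] = corrected
    return out


def corrected_wide(corrected_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a corrected long table to samples x variables."""
    wide = corrected_long.pivot_table(
        index=["sample_id", "donor", "arm", "day", "replicate"],
        columns="variable", values="corrected")
    wide.columns.name = None
    return wide.reset_index()
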