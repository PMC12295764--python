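"""Descriptive trap-count summaries.

Three families of statistics:

* detection sensitivity — how many of the 15 traps register at least one
  insect per day, and the bin's total daily catch;
* capture percentage by layer, ``CP_L = 100 * C_L / T`` where ``C_L`` is the
  layer's catch over the trapping period and ``T`` the whole bin's;
* windowed trap frequency, ``TF_D`` = total catch over the most recent D
  days divided by D (adults/day), evaluated at D in {3, 5, 7, 10}.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LAYER_ORDER, LOCATIONS

__all__ = [
    "DEFAULT_WINDOWS",
    "detection_summary",
    "capture_percentage_by_layer",
    "trap_frequency",
    "tf_table",
    "per_trap_daily_mean",
    "layer_daily_counts",
]

DEFAULT_WINDOWS: tuple[int, ...] = (3, 5, 7, 10)

_GROUP = ["bin_id", "density", "mc"]


def detection_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per (bin, density phase): mean traps-detecting per day and mean daily total.

    A trap "detects" on a day when its count is >= 1.  Both metrics are
    averaged over the phase's days.  The mean daily total always dominates
    the mean number of detecting traps, since each detecting trap
    contributes at least one insect.
    """
    if records.empty:
        raise ValueError("no trap records supplied")
    daily = (
        records.assign(detected=records["count"] >= 1)
        .groupby(_GROUP + ["day"], sort=True)
        .agg(traps_detecting=("detected", "sum"), total_count=("count", "sum"))
        .reset_index()
    )
    out = (
        daily.groupby(_GROUP, sort=True)
        .agg(
            mean_traps_detecting=("traps_detecting", "mean"),
            mean_total_daily_count=("total_count", "mean"),
            n_days=("day", "nunique"),
        )
        .reset_index()
    )
    return out


def capture_percentage_by_layer(records: pd.DataFrame) -> pd.DataFrame:
    """Capture percentage per layer (CP_L) for each bin and density phase.

    Sums each layer's counts over the trapping period and expresses them as
    a percentage of the bin's period total.  When the bin caught nothing the
    percentages are undefined (0/0) and reported as NaN rather than 0.
    """
    if records.empty:
        raise ValueError("no trap records supplied")
    layer_totals = (
        records.groupby(_GROUP + ["layer"], sort=True)["count"].sum().reset_index()
    )
    rows = []
    for key, grp in layer_totals.groupby(_GROUP, sort=True):
        total = grp["count"].sum()
        by_layer = dict(zip(grp["layer"], grp["count"]))
        row = dict(zip(_GROUP, key))
        row["total_count"] = int(total)
        for layer in LAYER_ORDER:
            c = by_layer.get(layer.value, 0)
            row[f"cp_{layer.value}"] = (
                float("nan") if total == 0 else 100.0 * c / total
            )
        rows.append(row)
    return pd.DataFrame(rows)


def trap_frequency(series: Sequence[float] | np.ndarray, window: int) -> float:
    """Trap frequency TF_D: mean daily catch over the most recent D days.

    ``series`` is the location's daily counts in day order; only the final
    ``window`` entries contribute.
    """
    series = np.asarray(series, dtype=float)
    if window <= 0:
        raise ValueError("window must be a positive number of days")
    if window > series.size:
        raise ValueError(
            f"window of {window} days exceeds series length {series.size}"
        )
    return float(series[-window:].sum() / window)


def tf_table(
    records: pd.DataFrame, windows: Sequence[int] = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Per-location trap frequencies for each window length.

    One row per (bin, density phase, location, window) with the TF_D value
    in adults/day.  Days are sorted within each location series before the
    trailing window is taken.
    """
    if records.empty:
        raise ValueError("no trap records supplied")
    rows = []
    for (bin_id, density, mc, layer, position), grp in records.groupby(
        _GROUP + ["layer", "position"], sort=True
    ):
        series = grp.sort_values("day")["count"].to_numpy()
        for w in windows:
            rows.append(
                {
                    "bin_id": bin_id,
                    "density": density,
                    "mc": mc,
                    "layer": layer,
                    "position": position,
                    "window": int(w),
                    "tf": trap_frequency(series, int(w)),
                }
            )
    return pd.DataFrame(rows)


def per_trap_daily_mean(
    records: pd.DataFrame, density: float, mc: float
) -> tuple[float, float]:
    """Mean and SE of the daily per-trap count at one (density, MC) condition.

    Pools every trap-day across the condition's replicate bins, the phase's
    days, and the 15 locations.  Returns (mean, standard error) over the
    pooled trap-days.
    """
    sel = records[
        np.isclose(records["density"], density) & np.isclose(records["mc"], mc)
    ]
    if sel.empty:
        raise ValueError(f"no records at density {density}, MC {mc}")
    counts = sel["count"].to_numpy(dtype=float)
    se = counts.std(ddof=1) / math.sqrt(counts.size) if counts.size > 1 else float("nan")
    return float(counts.mean()), float(se)


def layer_daily_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-layer daily count distribution (long form, for plotting)."""
    cols = ["density", "mc", "bin_id", "day", "layer", "count"]
    return records[cols].copy()
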