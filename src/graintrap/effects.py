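"""Storage-condition effects on trap counts.

* Four-way main-effects ANOVA of daily per-trap counts on insect density,
  grain moisture content, binned grain temperature (0-20, 20-25, 25-30,
  30-40 degC) and binned relative humidity (0-50, 50-60, 60-70, 70-80 %RH).
  Type II sums of squares; a factor with a single observed level is dropped
  with a warning instead of silently producing a zero-DF row.
* Paired t-tests (two-sided), with an explicit pairing axis chosen by the
  caller.
* Pearson correlations between counts and the in-situ covariates, per
  density group.
* Density-trap-frequency correlation: TF_D per location per density phase,
  correlated with the introduced density across phases, for candidate
  windows D in {3, 5, 7, 10}; the window with the highest average
  correlation is identified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .descriptive import DEFAULT_WINDOWS, tf_table

__all__ = [
    "FactorBins",
    "bin_covariates",
    "fourway_anova",
    "paired_ttest",
    "covariate_correlations",
    "density_tf_correlation",
    "DensityTFResult",
]


@dataclass(frozen=True)
class FactorBins:
    """Left-closed right-open covariate bins for the factorial test.

    Values outside the outer edges are assigned to the nearest outer bin
    and counted in ``n_out_of_range`` by :func:`bin_covariates` rather than
    dropped.
    """

    temperature_edges: tuple[float, ...] = (0.0, 20.0, 25.0, 30.0, 40.0)
    humidity_edges: tuple[float, ...] = (0.0, 50.0, 60.0, 70.0, 80.0)

    def __post_init__(self) -> None:
        for edges in (self.temperature_edges, self.humidity_edges):
            if len(edges) < 2 or any(
                b <= a for a, b in zip(edges, edges[1:])
            ):
                raise ValueError("bin edges must be strictly increasing")

    @staticmethod
    def _assign(values: np.ndarray, edges: Sequence[float]) -> tuple[np.ndarray, int]:
        edges = np.asarray(edges, dtype=float)
        clipped = np.clip(values, edges[0], np.nextafter(edges[-1], -np.inf))
        out_of_range = int(((values < edges[0]) | (values >= edges[-1])).sum())
        idx = np.digitize(clipped, edges, right=False) - 1
        labels = np.asarray(
            [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
        )
        return labels[idx], out_of_range

    def temperature_bins(self, values: np.ndarray) -> tuple[np.ndarray, int]:
        return self._assign(np.asarray(values, dtype=float), self.temperature_edges)

    def humidity_bins(self, values: np.ndarray) -> tuple[np.ndarray, int]:
        return self._assign(np.asarray(values, dtype=float), self.humidity_edges)


def bin_covariates(records: pd.DataFrame, bins: FactorBins | None = None) -> pd.DataFrame:
    """Add temp_bin / rh_bin factor columns; warn about out-of-range values."""
    bins = bins or FactorBins()
    df = records.copy()
    df["temp_bin"], t_out = bins.temperature_bins(df["temperature"].to_numpy())
    df["rh_bin"], h_out = bins.humidity_bins(df["humidity"].to_numpy())
    if t_out or h_out:
        warnings.warn(
            f"{t_out} temperature and {h_out} humidity values fell outside the "
            "outer bin edges and were assigned to the nearest outer bin",
            stacklevel=2,
        )
    return df


_FACTORS = ("density", "mc", "temp_bin", "rh_bin")
_FACTOR_LABELS = {
    "density": "Insect density",
    "mc": "Moisture content",
    "temp_bin": "Temperature",
    "rh_bin": "Humidity",
}


def fourway_anova(
    records: pd.DataFrame,
    bins: FactorBins | None = None,
    response: str = "count",
) -> pd.DataFrame:
    """Main-effects ANOVA of daily trap counts on the four condition factors.

    Returns a table with one row per retained factor (DF, sum_sq, F, p)
    plus a residual row; Type II sums of squares, no interactions.  Factors
    observed at a single level are dropped with a warning.
    """
    df = bin_covariates(records, bins)
    kept = []
    for f in _FACTORS:
        n_levels = df[f].nunique()
        if n_levels >= 2:
            kept.append(f)
        else:
            warnings.warn(
                f"factor {_FACTOR_LABELS[f]!r} has a single level and was dropped",
                stacklevel=2,
            )
    if not kept:
        raise ValueError("no factor has at least two levels")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in kept)
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on unbalanced designs
        table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(
        index={f"C({f})": _FACTOR_LABELS[f] for f in kept} | {"Residual": "Error"}
    )
    table = table.rename(columns={"df": "DF", "PR(>F)": "p"})
    table["DF"] = table["DF"].astype(int)
    return table[["DF", "sum_sq", "F", "p"]]


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on x - y.

    Returns (t, p); both are NaN when the paired differences have zero
    variance (the statistic is undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        return float("nan"), float("nan")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def covariate_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among count, temperature and humidity, per density.

    One row per density group with the three pairwise coefficients (and
    p-values); an entry is NaN when either variable has zero variance.
    """
    pairs = (
        ("count", "temperature"),
        ("count", "humidity"),
        ("temperature", "humidity"),
    )
    rows = []
    for density, grp in records.groupby("density", sort=True):
        if len(grp) < 3:
            raise ValueError(f"density group {density} has fewer than 3 trap-days")
        row: dict = {"density": density, "n": len(grp)}
        for a, b in pairs:
            xa = grp[a].to_numpy(dtype=float)
            xb = grp[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                r = p = float("nan")
            else:
                r, p = stats.pearsonr(xa, xb)
            row[f"r_{a}_{b}"] = float(r)
            row[f"p_{a}_{b}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DensityTFResult:
    """Density-trap-frequency correlation over candidate windows.

    ``per_location``: one row per (mc group, location, window) with the
    Pearson r of TF_D against introduced density across density phases
    (pooling replicate bins as independent points).  ``window_means``: the
    location-averaged r per (mc group, window).  ``best_window``: window
    with the highest location-averaged r per group, and overall.
    """

    per_location: pd.DataFrame
    window_means: pd.DataFrame
    best_window: dict[str, int] = field(default_factory=dict)

    @property
    def overall_best_window(self) -> int:
        return self.best_window["overall"]


def density_tf_correlation(
    records: pd.DataFrame,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    by_mc: bool = True,
    log_density: bool = False,
) -> DensityTFResult:
    """Correlate windowed trap frequencies with introduced insect density.

    For every location and window length, TF_D is computed per density
    phase (and replicate bin) and correlated with the phase's introduced
    density across phases.  Raw densities are used by default; set
    ``log_density`` for log10 densities.  With fewer than 4 points per
    correlation the p-values are reported but low-powered.
    """
    tf = tf_table(records, windows=windows)
    if tf["density"].nunique() < 2:
        raise ValueError("density-TF correlation needs at least 2 density phases")

    def _corr(grp: pd.DataFrame) -> tuple[float, float, int]:
        x = grp["density"].to_numpy(dtype=float)
        if log_density:
            x = np.log10(x)
        y = grp["tf"].to_numpy(dtype=float)
        n = len(grp)
        if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan"), float("nan"), n
        r, p = stats.pearsonr(x, y)
        return float(r), float(p), n

    groups = []
    for mc, sub in records.groupby("mc", sort=True) if by_mc else [("pooled", records)]:
        groups.append((str(mc), sub))
    if by_mc and records["mc"].nunique() > 1:
        groups.append(("pooled", records))

    rows = []
    group_keys = {str(g) for g, _ in groups}
    tf["_mc_str"] = tf["mc"].astype(str)
    for gname, _ in groups:
        sel = tf if gname == "pooled" else tf[tf["_mc_str"] == gname]
        for (layer, position, window), grp in sel.groupby(
            ["layer", "position", "window"], sort=True
        ):
            r, p, n = _corr(grp)
            rows.append(
                {
                    "group": gname,
                    "layer": layer,
                    "position": position,
                    "window": int(window),
                    "r": r,
                    "p": p,
                    "n": n,
                }
            )
    per_location = pd.DataFrame(rows)
    window_means = (
        per_location.groupby(["group", "window"], sort=True)["r"]
        .mean()
        .reset_index()
        .rename(columns={"r": "mean_r"})
    )
    best: dict[str, int] = {}
    for gname, grp in window_means.groupby("group"):
        best[gname] = int(grp.loc[grp["mean_r"].idxmax(), "window"])
    overall = (
        window_means.groupby("window")["mean_r"].mean()
    )
    best["overall"] = int(overall.idxmax())
    return DensityTFResult(per_location=per_location, window_means=window_means, best_window=best)
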