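"""Dispersion statistics and aggregation-pattern classification.

The spatial pattern of insects in the bulk is characterized from the 15-trap
sample sets via three classical index families:

* **Lloyd's mean crowding** ``I_L = xbar + s^2/xbar - 1`` — the mean number
  of "neighbors" an individual shares its sampling unit with;
* the **Iwao patchiness regression** ``I_L = b0 + b1 * xbar`` over sample
  sets — the intercept ``b0`` describes the basic component of the pattern
  (``b0 = 0``: the individual; ``b0 > 0``: a colony; ``b0 < 0``: mutual
  repulsion) and the slope ``b1`` the spacing of those components
  (``b1 > 1`` aggregated, ``= 1`` random, ``< 1`` uniform);
* **Taylor's power law** ``ln s^2 = ln a + b ln xbar`` — the slope ``b``
  classifies dispersion the same way (``b > 1`` aggregated, ``= 1`` random,
  ``< 1`` uniform).

Because exact equality is measure-zero for fitted coefficients, the
classification rules carry a tolerance (default 0.05) and raw coefficients
are always reported next to the labels.

`AggregationAnalysis` is the model object built from a record table; its
:meth:`~AggregationAnalysis.fit` returns an :class:`AggregationResults`
carrying per-condition coefficients, standard errors, diagnostics, labels
and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import SampleSet, to_sample_sets

__all__ = [
    "lloyd_index",
    "iwao_points",
    "iwao_fit",
    "classify_iwao",
    "taylor_fit",
    "classify_taylor",
    "AggregationReport",
    "AggregationAnalysis",
    "AggregationResults",
    "DEFAULT_TOL",
]

DEFAULT_TOL = 0.05

BasicComponent = Literal["individual", "colony", "repulsion"]
Dispersion = Literal["aggregated", "random", "uniform"]


def lloyd_index(sample: SampleSet | Sequence[int]) -> float:
    """Lloyd's index of mean crowding for one sample set.

    Uses the sample variance with the n-1 denominator.  Undefined (NaN) when
    the mean is zero; such sets are excluded from the regressions.
    """
    if not isinstance(sample, SampleSet):
        counts = np.asarray(sample, dtype=float)
        mean = counts.mean()
        var = counts.var(ddof=1)
    else:
        mean, var = sample.mean, sample.variance
    if mean == 0:
        return float("nan")
    return float(mean + var / mean - 1.0)


def _ols(x: np.ndarray, y: np.ndarray):
    model = sm.OLS(y, sm.add_constant(x))
    return model.fit()


def iwao_points(sample_sets: Iterable[SampleSet]) -> pd.DataFrame:
    """Per sample-set (mean, variance, mean crowding) table.

    Sets with zero mean have undefined crowding and are marked excluded.
    """
    rows = []
    for s in sample_sets:
        il = lloyd_index(s)
        rows.append(
            {
                "bin_id": s.bin_id,
                "day": s.day,
                "density": s.density,
                "mc": s.mc,
                "mean": s.mean,
                "variance": s.variance,
                "mean_crowding": il,
                "excluded": not math.isfinite(il),
            }
        )
    return pd.DataFrame(rows)


def iwao_fit(points: Sequence[tuple[float, float]] | pd.DataFrame):
    """OLS fit of mean crowding on mean density: I_L = b0 + b1 * xbar.

    ``points`` is either an iterable of (mean, crowding) pairs or the frame
    from :func:`iwao_points` (excluded rows dropped).  Returns the fitted
    statsmodels results; params are (b0, b1).
    """
    if isinstance(points, pd.DataFrame):
        pts = points.loc[~points["excluded"], ["mean", "mean_crowding"]].to_numpy()
    else:
        pts = np.asarray(list(points), dtype=float)
    if len(pts) < 2:
        raise ValueError("Iwao regression needs at least 2 usable sample sets")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("Iwao regression slope undefined: all means identical")
    return _ols(x, y)


def taylor_fit(sample_sets: Iterable[SampleSet]):
    """OLS fit of Taylor's power law in log form: ln s^2 = ln a + b ln xbar.

    A sample set is usable iff both its mean and its variance are strictly
    positive (both logarithms defined).  Returns (statsmodels results,
    number of excluded sets); params are (ln a, b).
    """
    means, varis, excluded = [], [], 0
    for s in sample_sets:
        if s.mean > 0 and s.variance > 0:
            means.append(s.mean)
            varis.append(s.variance)
        else:
            excluded += 1
    if len(means) < 2:
        raise ValueError("Taylor fit needs at least 2 sample sets with positive mean and variance")
    x = np.log(np.asarray(means))
    y = np.log(np.asarray(varis))
    if np.ptp(x) == 0:
        raise ValueError("Taylor fit slope undefined: all log-means identical")
    return _ols(x, y), excluded


def classify_iwao(
    b0: float, b1: float, tol: float = DEFAULT_TOL
) -> tuple[BasicComponent, Dispersion]:
    """Label the Iwao coefficients: basic component from b0, dispersion from b1."""
    if not (math.isfinite(b0) and math.isfinite(b1)):
        raise ValueError("Iwao coefficients must be finite")
    if abs(b0) <= tol:
        basic: BasicComponent = "individual"
    elif b0 > tol:
        basic = "colony"
    else:
        basic = "repulsion"
    return basic, _dispersion_label(b1, tol)


def classify_taylor(b: float, tol: float = DEFAULT_TOL) -> Dispersion:
    """Label Taylor's slope b as aggregated (>1), random (=1) or uniform (<1)."""
    if not math.isfinite(b):
        raise ValueError("Taylor slope must be finite")
    return _dispersion_label(b, tol)


def _dispersion_label(slope: float, tol: float) -> Dispersion:
    if abs(slope - 1.0) <= tol:
        return "random"
    return "aggregated" if slope > 1.0 else "uniform"


@dataclass
class AggregationReport:
    """Fitted dispersion coefficients and pattern labels for one condition."""

    density: float
    mc: float
    b0: float
    b1: float
    b0_se: float
    b1_se: float
    iwao_r2: float
    lna: float
    b: float
    lna_se: float
    b_se: float
    taylor_r2: float
    basic_component: BasicComponent
    iwao_dispersion: Dispersion
    taylor_dispersion: Dispersion
    n_points: int
    n_excluded: int
    n_replicates: int = 1

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class AggregationAnalysis:
    """Dispersion analysis of a trap-record table.

    Forms the per-day 15-count sample sets for every (density, MC)
    condition and fits the Iwao and Taylor regressions.

    Parameters
    ----------
    records
        Validated long-format record table.
    days
        Restrict sample-set formation to these day indices (default: every
        day of each phase; pass ``[10]`` to use only the final sampling day,
        pooling across days of nothing but day 10).
    """

    def __init__(self, records: pd.DataFrame, days: Sequence[int] | None = None):
        self.records = records
        self.sample_sets = to_sample_sets(records, days=days)
        if not self.sample_sets:
            raise ValueError("no sample sets could be formed from the records")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AggregationAnalysis":
        from .core import read_trap_records

        return cls(read_trap_records(path), **kwargs)

    def fit(
        self,
        mode: Literal["per-replicate", "pooled"] = "per-replicate",
        tol: float = DEFAULT_TOL,
    ) -> "AggregationResults":
        """Fit both regressions per (density, MC) condition.

        ``per-replicate`` fits each replicate bin across its sampling days
        and averages coefficients across replicates (the convention used
        when replicate-mean coefficients are reported); ``pooled`` fits one
        regression over all replicates' sample sets jointly.
        """
        if mode not in ("per-replicate", "pooled"):
            raise ValueError(f"unknown mode {mode!r}")
        by_cond: dict[tuple[float, float], list[SampleSet]] = {}
        for s in self.sample_sets:
            by_cond.setdefault((s.density, s.mc), []).append(s)

        reports = []
        failures: list[tuple[float, float, str]] = []
        for (density, mc), sets in sorted(by_cond.items()):
            if mode == "pooled":
                groups = [sets]
            else:
                by_bin: dict[str, list[SampleSet]] = {}
                for s in sets:
                    by_bin.setdefault(s.bin_id, []).append(s)
                groups = [by_bin[k] for k in sorted(by_bin)]
            coefs = []
            n_points = n_excluded = 0
            try:
                group_fits = []
                for grp in groups:
                    pts = iwao_points(grp)
                    group_fits.append((grp, pts, iwao_fit(pts), taylor_fit(grp)[0]))
            except ValueError as exc:
                failures.append((density, mc, str(exc)))
                continue
            for grp, pts, iwao, taylor in group_fits:
                usable = int((~pts["excluded"]).sum())
                n_points += usable
                n_excluded += len(grp) - usable
                coefs.append(
                    (
                        iwao.params[0], iwao.params[1],
                        iwao.bse[0], iwao.bse[1], iwao.rsquared,
                        taylor.params[0], taylor.params[1],
                        taylor.bse[0], taylor.bse[1], taylor.rsquared,
                    )
                )
            mean_c = np.mean(np.asarray(coefs, dtype=float), axis=0)
            b0, b1, b0_se, b1_se, iwao_r2, lna, b, lna_se, b_se, taylor_r2 = mean_c
            basic, iwao_disp = classify_iwao(b0, b1, tol)
            reports.append(
                AggregationReport(
                    density=density, mc=mc,
                    b0=float(b0), b1=float(b1),
                    b0_se=float(b0_se), b1_se=float(b1_se),
                    iwao_r2=float(iwao_r2),
                    lna=float(lna), b=float(b),
                    lna_se=float(lna_se), b_se=float(b_se),
                    taylor_r2=float(taylor_r2),
                    basic_component=basic,
                    iwao_dispersion=iwao_disp,
                    taylor_dispersion=classify_taylor(b, tol),
                    n_points=n_points, n_excluded=n_excluded,
                    n_replicates=len(groups),
                )
            )
        if not reports:
            raise ValueError(
                "no condition could be fitted: "
                + "; ".join(m for *_ , m in failures)
            )
        return AggregationResults(self, reports, mode=mode, tol=tol, failures=failures)


class AggregationResults:
    """Per-condition dispersion coefficients, labels and diagnostics."""

    def __init__(
        self,
        model: AggregationAnalysis,
        reports: list[AggregationReport],
        mode: str,
        tol: float,
        failures: list[tuple[float, float, str]] | None = None,
    ):
        self.model = model
        self.reports = reports
        self.mode = mode
        self.tol = tol
        #: conditions that could not be fitted, as (density, mc, reason)
        self.failures = failures or []

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.reports])

    def summary(self) -> str:
        df = self.as_frame()
        lines = [
            "Aggregation-pattern analysis "
            f"(mode={self.mode}, label tolerance={self.tol})",
            "",
            f"{'dens':>6} {'MC':>5} | {'b0':>8} {'b1':>8} {'basic':>10} "
            f"{'Iwao':>10} | {'ln a':>8} {'b':>8} {'Taylor':>10} | "
            f"{'pts':>4} {'excl':>4}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['density']:>6.2f} {r['mc']:>5.1f} | "
                f"{r['b0']:>8.3f} {r['b1']:>8.3f} {r['basic_component']:>10} "
                f"{r['iwao_dispersion']:>10} | "
                f"{r['lna']:>8.3f} {r['b']:>8.3f} {r['taylor_dispersion']:>10} | "
                f"{int(r['n_points']):>4d} {int(r['n_excluded']):>4d}"
            )
        for density, mc, msg in self.failures:
            lines.append(f"  not fitted (density {density}, MC {mc}): {msg}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AggregationResults: {len(self.reports)} conditions, mode={self.mode}>"
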