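"""Spatial pair correlation of daily trap counts (h-scatterplot analysis).

Daily counts from pairs of traps separated by a fixed lag are pooled and
their Pearson correlation computed, for five named lag classes:

=============  =================================================  =====
name           pairs                                              count
=============  =================================================  =====
[H(0),H(30)]   center vs each half-radius trap, within a layer      12
[H(0),H(42)]   ring-adjacent half-radius traps, within a layer      12
[V(T),V(M)]    same planar position, top vs middle layer             5
[V(M),V(B)]    same planar position, middle vs bottom layer          5
[V(T),V(B)]    same planar position, top vs bottom layer             5
=============  =================================================  =====

The 30/42/60/120 cm distances follow from the deployment geometry; vertical
pairs match identical planar positions across layers, the only pairing
compatible with fixed 60/120 cm separations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import LOCATIONS, RING, Geometry, Layer, Position, TrapLocation

__all__ = ["PairSpec", "PairCorrelation", "build_pair_specs", "pair_correlation",
           "pair_correlation_table", "significance_stars"]

PAIR_NAMES = (
    "[H(0),H(30)]",
    "[H(0),H(42)]",
    "[V(T),V(M)]",
    "[V(M),V(B)]",
    "[V(T),V(B)]",
)


@dataclass(frozen=True)
class PairSpec:
    """A named set of equal-lag trap-location pairs."""

    name: str
    pairs: tuple[tuple[TrapLocation, TrapLocation], ...]
    distance_cm: float


@dataclass(frozen=True)
class PairCorrelation:
    """Pooled Pearson correlation for one pair spec.

    ``r`` is NaN (with ``undefined`` True) when either pooled coordinate has
    zero variance.
    """

    name: str
    r: float
    p: float
    n: int
    undefined: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p) if not self.undefined else ""


def significance_stars(p: float) -> str:
    """'**' at alpha <= 0.01, '*' at alpha <= 0.05, '' otherwise."""
    if not np.isfinite(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def build_pair_specs(
    locations: tuple[TrapLocation, ...] = LOCATIONS,
    geometry: Geometry | None = None,
) -> tuple[PairSpec, ...]:
    """Construct the five pair specs from the standard 15-trap layout.

    Raises if the layout is not the standard 3-layer x 5-position grid.
    Every constructed pair's geometric distance matches its spec's nominal
    lag (42 cm being 30*sqrt(2) rounded to whole cm).
    """
    geometry = geometry or Geometry()
    if set(locations) != set(LOCATIONS):
        raise ValueError("pair specs require the standard 15-location layout")

    def loc(layer: Layer, pos: Position) -> TrapLocation:
        return TrapLocation(layer, pos)

    h30 = tuple(
        (loc(layer, Position.CENTER), loc(layer, pos))
        for layer in Layer
        for pos in RING
    )
    h42 = tuple(
        (loc(layer, RING[i]), loc(layer, RING[(i + 1) % len(RING)]))
        for layer in Layer
        for i in range(len(RING))
    )

    def vertical(a: Layer, b: Layer):
        return tuple(
            (loc(a, pos), loc(b, pos))
            for pos in (Position.CENTER, *RING)
        )

    specs = (
        PairSpec(PAIR_NAMES[0], h30, geometry.center_to_half_radius),
        PairSpec(PAIR_NAMES[1], h42, geometry.adjacent_half_radius),
        PairSpec(PAIR_NAMES[2], vertical(Layer.TOP, Layer.MIDDLE), geometry.adjacent_layers),
        PairSpec(PAIR_NAMES[3], vertical(Layer.MIDDLE, Layer.BOTTOM), geometry.adjacent_layers),
        PairSpec(PAIR_NAMES[4], vertical(Layer.TOP, Layer.BOTTOM), geometry.top_to_bottom),
    )
    for spec in specs:
        for a, b in spec.pairs:
            d = geometry.distance(a, b)
            if abs(d - spec.distance_cm) > 1.0:
                raise AssertionError(
                    f"{spec.name}: pair {a}-{b} at {d:.1f} cm, expected {spec.distance_cm}"
                )
    return specs


def _pivot_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Wide table: one row per (bin, density, mc, day), one column per location."""
    wide = records.pivot_table(
        index=["bin_id", "density", "mc", "day"],
        columns=["layer", "position"],
        values="count",
        aggfunc="sum",
    )
    return wide


def pair_correlation(
    records: pd.DataFrame,
    spec: PairSpec,
    pooling: Literal["within-replicate", "all"] = "all",
) -> PairCorrelation:
    """Pooled Pearson correlation of daily counts for one pair spec.

    Each location pair contributes one (first, second) point per bin-day;
    points are pooled over days and, with ``pooling='all'``, over replicate
    bins.  Requires at least 3 pooled points; zero variance in either pooled
    coordinate yields an undefined flag instead of a number.
    """
    wide = _pivot_counts(records)
    xs, ys = [], []
    for a, b in spec.pairs:
        if a.key not in wide.columns or b.key not in wide.columns:
            raise ValueError(f"records lack counts for {a} or {b}")
        xs.append(wide[a.key].to_numpy(dtype=float))
        ys.append(wide[b.key].to_numpy(dtype=float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 pooled pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PairCorrelation(spec.name, float("nan"), float("nan"), n, undefined=True)
    r, p = stats.pearsonr(x, y)
    return PairCorrelation(spec.name, float(r), float(p), n)


def pair_correlation_table(
    records: pd.DataFrame,
    pooling: Literal["within-replicate", "all"] = "all",
) -> pd.DataFrame:
    """Pair correlations for every spec, per (density, MC) condition.

    ``pooling='all'`` pools replicate bins into one coefficient per
    condition (one row per MC x density, as in a condition-level summary);
    ``'within-replicate'`` computes one coefficient per replicate bin.
    """
    specs = build_pair_specs()
    group_cols = ["density", "mc"]
    if pooling == "within-replicate":
        group_cols = ["density", "mc", "bin_id"]
    elif pooling != "all":
        raise ValueError(f"unknown pooling {pooling!r}")
    rows = []
    for key, grp in records.groupby(group_cols, sort=True):
        for spec in specs:
            pc = pair_correlation(grp, spec, pooling=pooling)
            row = dict(zip(group_cols, key))
            row.update(
                pair=spec.name,
                distance_cm=spec.distance_cm,
                r=pc.r,
                p=pc.p,
                n=pc.n,
                significance=pc.stars,
                undefined=pc.undefined,
            )
            rows.append(row)
    return pd.DataFrame(rows)
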