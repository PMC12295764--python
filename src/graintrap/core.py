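"""Domain types and long-format trap-record I/O.

The experimental unit is a cylindrical grain bin instrumented with 15
electronic probe traps: three layers (top, middle, bottom), each holding one
trap at the bin center and four traps at the half-radius in the four radial
directions.  A *trap record* is one trap-day observation — the daily count of
insects registered by the trap plus the grain temperature and intergranular
relative humidity measured at the trap location, tagged with the experimental
condition (introduced insect density in adults/kg and grain moisture content
in % wet basis).

All vectorized statistics use a fixed location order:
``(top, middle, bottom) x (center, r1, r2, r3, r4)``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "Position",
    "TrapLocation",
    "Geometry",
    "LOCATIONS",
    "SampleSet",
    "TrapRecordError",
    "SchemaError",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "read_trap_records",
    "write_trap_records",
    "validate_records",
    "to_sample_sets",
]


class Layer(str, enum.Enum):
    """Vertical layer of the grain bulk holding a trap."""

    TOP = "top"
    MIDDLE = "middle"
    BOTTOM = "bottom"


class Position(str, enum.Enum):
    """Planar trap position: bin center or one of four half-radius spots.

    ``r1``–``r4`` are ring-ordered, so (r1, r2), (r2, r3), (r3, r4) and
    (r4, r1) are the adjacent half-radius pairs.
    """

    CENTER = "center"
    R1 = "r1"
    R2 = "r2"
    R3 = "r3"
    R4 = "r4"


LAYER_ORDER: tuple[Layer, ...] = (Layer.TOP, Layer.MIDDLE, Layer.BOTTOM)
POSITION_ORDER: tuple[Position, ...] = (
    Position.CENTER,
    Position.R1,
    Position.R2,
    Position.R3,
    Position.R4,
)

#: Half-radius ring, cyclic of length 4.
RING: tuple[Position, ...] = (Position.R1, Position.R2, Position.R3, Position.R4)


@dataclass(frozen=True, order=True)
class TrapLocation:
    """One of the 15 trap locations (layer x planar position)."""

    layer: Layer
    position: Position

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer", Layer(self.layer))
        object.__setattr__(self, "position", Position(self.position))

    @property
    def key(self) -> tuple[str, str]:
        return (self.layer.value, self.position.value)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.layer.value}/{self.position.value}"


#: Fixed location order used by every vectorized statistic.
LOCATIONS: tuple[TrapLocation, ...] = tuple(
    TrapLocation(layer, pos)
    for layer, pos in itertools.product(LAYER_ORDER, POSITION_ORDER)
)

_LOCATION_INDEX = {loc.key: i for i, loc in enumerate(LOCATIONS)}


@dataclass(frozen=True)
class Geometry:
    """Pairwise trap distances (cm) implied by the deployment scheme.

    The half-radius traps sit 30 cm from the center; two ring-adjacent
    half-radius traps are 30*sqrt(2) ~ 42 cm apart.  Layers are separated by
    60 cm vertically, so top and bottom traps at the same planar position are
    120 cm apart.
    """

    center_to_half_radius: float = 30.0
    adjacent_half_radius: float = 42.0
    adjacent_layers: float = 60.0
    top_to_bottom: float = 120.0

    def __post_init__(self) -> None:
        expected = round(self.center_to_half_radius * np.sqrt(2.0))
        if round(self.adjacent_half_radius) != expected:
            raise ValueError(
                "adjacent half-radius distance must equal "
                "center-to-half-radius x sqrt(2) rounded to whole cm "
                f"({expected}), got {self.adjacent_half_radius}"
            )
        if self.top_to_bottom != 2 * self.adjacent_layers:
            raise ValueError("top-to-bottom distance must be twice the layer spacing")

    def distance(self, a: TrapLocation, b: TrapLocation) -> float:
        """Euclidean distance between two trap locations in cm."""
        coords = {
            Position.CENTER: (0.0, 0.0),
            Position.R1: (self.center_to_half_radius, 0.0),
            Position.R2: (0.0, self.center_to_half_radius),
            Position.R3: (-self.center_to_half_radius, 0.0),
            Position.R4: (0.0, -self.center_to_half_radius),
        }
        z = {
            Layer.TOP: 2 * self.adjacent_layers,
            Layer.MIDDLE: self.adjacent_layers,
            Layer.BOTTOM: 0.0,
        }
        ax, ay = coords[a.position]
        bx, by = coords[b.position]
        return float(
            np.hypot(np.hypot(ax - bx, ay - by), z[a.layer] - z[b.layer])
        )


@dataclass(frozen=True)
class SampleSet:
    """The 15 same-day trap counts from one bin, in fixed location order.

    This is the sampling unit for the dispersion statistics: the sample mean
    and (n-1)-denominator variance of ``counts`` feed Lloyd's mean crowding,
    the Iwao regression and Taylor's power law.
    """

    counts: tuple[int, ...]
    bin_id: str = ""
    day: int = 0
    density: float = float("nan")
    mc: float = float("nan")

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != len(LOCATIONS):
            raise ValueError(
                f"a sample set holds exactly {len(LOCATIONS)} counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise ValueError("trap counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def variance(self) -> float:
        """Sample variance with the n-1 denominator."""
        return float(np.var(self.counts, ddof=1))


class TrapRecordError(Exception):
    """Base error for trap-record ingestion problems."""


class SchemaError(TrapRecordError):
    """The input table is missing required columns."""


class ValidationError(TrapRecordError):
    """A row violates the trap-record contract."""


REQUIRED_COLUMNS: tuple[str, ...] = (
    "bin_id",
    "replicate_id",
    "density",
    "mc",
    "day",
    "layer",
    "position",
    "count",
    "temperature",
    "humidity",
)

_LAYER_VALUES = frozenset(l.value for l in Layer)
_POSITION_VALUES = frozenset(p.value for p in Position)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format trap-record table in place.

    Checks the schema, coerces dtypes, and enforces the row contract:
    integral non-negative counts, day >= 1, humidity in (0, 100], known
    layer/position labels, and uniqueness of (bin_id, day, layer, position).

    Returns the validated frame (dtypes coerced, row order preserved).
    Raises :class:`SchemaError` or :class:`ValidationError` naming the
    offending column or 1-based data row.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    df["layer"] = df["layer"].astype(str).str.strip().str.lower()
    df["position"] = df["position"].astype(str).str.strip().str.lower()

    def _bad_rows(mask: pd.Series) -> str:
        rows = (np.flatnonzero(mask.to_numpy()) + 1)[:5]
        return ", ".join(str(r) for r in rows)

    bad = ~df["layer"].isin(_LAYER_VALUES)
    if bad.any():
        raise ValidationError(f"unknown layer label on row(s) {_bad_rows(bad)}")
    bad = ~df["position"].isin(_POSITION_VALUES)
    if bad.any():
        raise ValidationError(f"unknown position label on row(s) {_bad_rows(bad)}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        raise ValidationError(
            f"count must be a non-negative integer; bad row(s) {_bad_rows(bad)}"
        )
    df["count"] = counts.astype(int)

    for col in ("density", "mc", "temperature", "humidity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(
                f"non-numeric {col} on row(s) {_bad_rows(vals.isna())}"
            )
        df[col] = vals.astype(float)

    days = pd.to_numeric(df["day"], errors="coerce")
    bad = days.isna() | (days < 1) | (days != days.round())
    if bad.any():
        raise ValidationError(f"day must be an integer >= 1; bad row(s) {_bad_rows(bad)}")
    df["day"] = days.astype(int)

    bad = (df["humidity"] <= 0) | (df["humidity"] > 100)
    if bad.any():
        raise ValidationError(
            f"humidity must lie in (0, 100]; bad row(s) {_bad_rows(bad)}"
        )
    bad = df["density"] <= 0
    if bad.any():
        raise ValidationError(f"density must be positive; bad row(s) {_bad_rows(bad)}")

    key = ["bin_id", "density", "day", "layer", "position"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0]
        raise ValidationError(
            "duplicate trap-day record for "
            f"(bin {first['bin_id']}, density {first['density']}, day {first['day']}, "
            f"{first['layer']}/{first['position']})"
        )

    df["bin_id"] = df["bin_id"].astype(str)
    df["replicate_id"] = df["replicate_id"].astype(str)
    return df


def read_trap_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trap-record CSV.

    The file must carry a header naming all of :data:`REQUIRED_COLUMNS`
    (comma-separated, UTF-8, '.' decimal), one row per trap per day.
    """
    df = pd.read_csv(path)
    return validate_records(df)


def write_trap_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trap-record table as CSV (round-trips with read_trap_records)."""
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def _bin_key(df: pd.DataFrame) -> pd.Series:
    # A physical bin run is identified by bin_id within a density phase.
    return df["bin_id"].astype(str)


def to_sample_sets(
    records: pd.DataFrame,
    day: int | None = None,
    days: Sequence[int] | None = None,
) -> list[SampleSet]:
    """Form 15-count sample sets, one per (bin, density phase, day).

    Parameters
    ----------
    records
        Validated trap-record table.
    day
        Restrict to a single day index (e.g. 10 for the final sampling day).
    days
        Restrict to a set of day indices.  ``day`` and ``days`` are mutually
        exclusive; by default every day present is used.

    Raises
    ------
    ValidationError
        If a (bin, phase, day) group does not cover all 15 locations.
    """
    if day is not None and days is not None:
        raise ValueError("pass either day or days, not both")
    if day is not None:
        days = [day]
    df = records
    if days is not None:
        df = df[df["day"].isin(list(days))]
    if df.empty:
        return []

    out: list[SampleSet] = []
    for (bin_id, density, mc, d), grp in df.groupby(
        ["bin_id", "density", "mc", "day"], sort=True
    ):
        counts = np.zeros(len(LOCATIONS), dtype=int)
        seen = set()
        for _, row in grp.iterrows():
            key = (row["layer"], row["position"])
            seen.add(key)
            counts[_LOCATION_INDEX[key]] = int(row["count"])
        if len(seen) != len(LOCATIONS):
            missing = [str(loc) for loc in LOCATIONS if loc.key not in seen]
            raise ValidationError(
                f"bin {bin_id} day {d}: missing location(s) {', '.join(missing)}"
            )
        out.append(
            SampleSet(
                counts=tuple(int(c) for c in counts),
                bin_id=str(bin_id),
                day=int(d),
                density=float(density),
                mc=float(mc),
            )
        )
    return out
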