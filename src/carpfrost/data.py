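"""Domain types and CSV I/O for frozen-storage quality measurements.

The exchange object throughout the package is :class:`FrozenStorageDataset`, a
validated table of replicate measurements of five biochemical quality
indicators of fish muscle over a (storage temperature, storage time) grid:

* TBARS  - thiobarbituric acid reactive substances (mg MDA/kg); rises as
  lipids oxidise.
* FFA    - free fatty acids (g FFA/100 g lipid); rises as lipids hydrolyse.
* SSP    - salt-soluble protein (mg/g); falls as myofibrillar protein
  denatures and aggregates.
* CA_ATPASE - Ca2+-ATPase activity of the myosin head (umol Pi/mg/min);
  falls with protein denaturation.
* SH     - total sulfhydryl content of myofibrillar protein (mol/10^5 g);
  falls as thiols oxidise to disulfides.

Temperatures are stored in kelvin exactly as measured (261/253/245 K for the
reference study design); times in weeks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SchemaError, UniquenessError, ValidationError

#: Canonical CSV column order.
COLUMNS = ("temperature_K", "time_weeks", "indicator", "replicate", "value")

KEY_COLUMNS = ("temperature_K", "time_weeks", "indicator", "replicate")


class Direction(enum.Enum):
    """Whether an indicator rises or falls during frozen storage."""

    INCREASING = "increasing"
    DECREASING = "decreasing"


class Indicator(enum.Enum):
    """The five quality indicators, with printed unit labels.

    Unit labels are opaque text carried for reporting; no unit conversion is
    ever performed (including the SH label, which is kept as printed).
    """

    TBARS = ("TBARS", "mg MDA/kg", Direction.INCREASING)
    FFA = ("FFA", "g FFA/100 g lipid", Direction.INCREASING)
    SSP = ("SSP", "mg/g", Direction.DECREASING)
    CA_ATPASE = ("CA_ATPASE", "umol Pi/mg/min", Direction.DECREASING)
    SH = ("SH", "mol/10^5 g", Direction.DECREASING)

    def __init__(self, label: str, unit_label: str, direction: Direction):
        self.label = label
        self.unit_label = unit_label
        self.direction = direction

    @classmethod
    def from_name(cls, name: str) -> "Indicator":
        try:
            return cls[name]
        except KeyError:
            raise ValidationError(
                f"unknown indicator name {name!r}; expected one of "
                f"{[i.name for i in cls]}"
            ) from None


#: Canonical indicator order used for design matrices and reports.
INDICATOR_ORDER = (
    Indicator.TBARS,
    Indicator.FFA,
    Indicator.SSP,
    Indicator.CA_ATPASE,
    Indicator.SH,
)


@dataclass(frozen=True)
class Measurement:
    """A single replicate measurement of one indicator."""

    temperature_K: float
    time_weeks: float
    indicator: Indicator
    replicate: int
    value: float

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValidationError(f"temperature must be positive kelvin, got {self.temperature_K}")
        if self.time_weeks < 0:
            raise ValidationError(f"time must be non-negative, got {self.time_weeks}")
        if self.value < 0:
            raise ValidationError(f"value must be non-negative, got {self.value}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    for col in COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    frame = frame.loc[:, list(COLUMNS)].copy()
    frame["temperature_K"] = frame["temperature_K"].astype(float)
    frame["time_weeks"] = frame["time_weeks"].astype(float)
    frame["replicate"] = frame["replicate"].astype(int)
    frame["value"] = frame["value"].astype(float)
    frame["indicator"] = [Indicator.from_name(str(n)).name for n in frame["indicator"]]

    for row_no, (temp, t, val, rep) in enumerate(
        zip(frame["temperature_K"], frame["time_weeks"], frame["value"], frame["replicate"]),
        start=1,
    ):
        if temp <= 0:
            raise ValidationError(f"row {row_no}: temperature must be positive kelvin, got {temp}")
        if t < 0:
            raise ValidationError(f"row {row_no}: negative time {t}")
        if val < 0:
            raise ValidationError(f"row {row_no}: negative value {val}")
        if rep < 1:
            raise ValidationError(f"row {row_no}: replicate must be >= 1, got {rep}")

    dup = frame.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        first = frame.loc[dup].iloc[0]
        raise UniquenessError(
            "duplicate key (temperature_K={}, time_weeks={}, indicator={}, replicate={})".format(
                first["temperature_K"], first["time_weeks"], first["indicator"], first["replicate"]
            )
        )
    return frame


@dataclass
class FrozenStorageDataset:
    """Replicate measurements over (temperature, time) plus free-form metadata.

    The frame has columns ``temperature_K, time_weeks, indicator, replicate,
    value`` with a unique key on the first four. Metadata is a flat map of
    strings recording provenance (generator parameters, seed, ...).
    """

    frame: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrozenStorageDataset):
            return NotImplemented
        a = self.frame.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        return a.equals(b) and self.metadata == other.metadata

    def temperatures(self) -> list[float]:
        return sorted(self.frame["temperature_K"].unique())

    def value(self, temperature_K: float, time_weeks: float, indicator: Indicator,
              replicate: int = 1) -> float:
        """Look up a single replicate value; KeyError if absent."""
        m = self.frame[
            (self.frame["temperature_K"] == temperature_K)
            & (self.frame["time_weeks"] == time_weeks)
            & (self.frame["indicator"] == indicator.name)
            & (self.frame["replicate"] == replicate)
        ]
        if m.empty:
            raise KeyError((temperature_K, time_weeks, indicator.name, replicate))
        return float(m["value"].iloc[0])

    def has(self, temperature_K: float, time_weeks: float, indicator: Indicator) -> bool:
        m = self.frame[
            (self.frame["temperature_K"] == temperature_K)
            & (self.frame["time_weeks"] == time_weeks)
            & (self.frame["indicator"] == indicator.name)
        ]
        return not m.empty

    def replicate_means(self) -> pd.DataFrame:
        """Mean over replicates per (temperature, time, indicator)."""
        return (
            self.frame.groupby(["temperature_K", "time_weeks", "indicator"], as_index=False)
            ["value"].mean()
        )

    def merge(self, other: "FrozenStorageDataset") -> "FrozenStorageDataset":
        """Union of two datasets; keys must not collide."""
        frame = pd.concat([self.frame, other.frame], ignore_index=True)
        meta = {**self.metadata, **other.metadata}
        return FrozenStorageDataset(frame, meta)


def read_quality_csv(path: str | Path) -> FrozenStorageDataset:
    """Read a measurement table from the canonical CSV schema.

    The header must define ``temperature_K,time_weeks,indicator,replicate,value``
    (comma-separated, UTF-8, dot decimal). Unknown indicator names, duplicate
    keys, and negative times/values are rejected with the row identified.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    return FrozenStorageDataset(frame)


def write_quality_csv(dataset: FrozenStorageDataset, path: str | Path) -> None:
    """Write a dataset to CSV so that reading it back reproduces it exactly.

    Float values round-trip at full precision (shortest-repr formatting).
    """
    path = Path(path)
    # shortest-repr formatting so float64 values survive the text round-trip
    dataset.frame.loc[:, list(COLUMNS)].to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))
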