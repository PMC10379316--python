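"""Delta transform, design-matrix assembly, and min-max scaling to [-1, 1].

The prediction target is the change of each indicator from its own
temperature's baseline, dC = C_t - C_0, computed on replicate means (the model
describes one curve per temperature, not per fillet). Inputs (temperature,
time) and the five outputs are then scaled to [-1, 1] by min-max with exact
linear inversion; the fitted scaling parameters are stored with the model so
predictions are reproducible from the model file alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FrozenStorageDataset, INDICATOR_ORDER
from .errors import (
    BaselineMissingError,
    ConfigError,
    DegenerateVariableError,
    NoCompleteRowsError,
)

logger = logging.getLogger(__name__)

REQUIRE_T0 = "require_t0"
FIRST_OBSERVED = "first_observed"

INPUT_NAMES = ("temperature_K", "time_weeks")
OUTPUT_NAMES = tuple(f"delta_{ind.name}" for ind in INDICATOR_ORDER)


@dataclass
class DeltaDataset:
    """Per-(temperature, time, indicator) change from baseline.

    ``baselines`` maps (temperature, indicator name) to (baseline_time,
    baseline_value); under ``require_t0`` every baseline_time is 0, under
    ``first_observed`` it is the earliest observed time for that pair.
    """

    frame: pd.DataFrame  # columns: temperature_K, time_weeks, indicator, delta
    baselines: dict[tuple[float, str], tuple[float, float]]
    policy: str


def delta_transform(dataset: FrozenStorageDataset,
                    baseline_policy: str = REQUIRE_T0) -> DeltaDataset:
    """Compute dC = mean(C_t) - mean(C_baseline) per (temperature, indicator).

    Under ``require_t0`` a missing week-0 record is an error naming the pair;
    under ``first_observed`` the earliest available time serves as baseline
    (its own delta is exactly 0).
    """
    if baseline_policy not in (REQUIRE_T0, FIRST_OBSERVED):
        raise ConfigError(f"unknown baseline policy {baseline_policy!r}")
    means = dataset.replicate_means()
    baselines: dict[tuple[float, str], tuple[float, float]] = {}
    pieces = []
    for (temp, ind), grp in means.groupby(["temperature_K", "indicator"]):
        grp = grp.sort_values("time_weeks")
        times = grp["time_weeks"].to_numpy()
        if baseline_policy == REQUIRE_T0:
            if 0.0 not in times:
                raise BaselineMissingError(
                    f"no time-0 record for {ind} at {temp} K under require_t0"
                )
            base_t = 0.0
        else:
            base_t = float(times[0])
        base_v = float(grp.loc[grp["time_weeks"] == base_t, "value"].iloc[0])
        baselines[(float(temp), str(ind))] = (base_t, base_v)
        out = grp[["temperature_K", "time_weeks", "indicator"]].copy()
        out["delta"] = grp["value"].to_numpy() - base_v
        pieces.append(out)
    frame = pd.concat(pieces, ignore_index=True)
    return DeltaDataset(frame, baselines, baseline_policy)


@dataclass
class DesignMatrices:
    """Row-aligned input/output matrices for the network.

    X columns: (temperature_K, time_weeks); Y columns: the five indicator
    deltas in canonical order. Rows are sorted by (temperature, time); points
    missing any indicator are dropped and recorded in ``dropped``.
    """

    X: np.ndarray
    Y: np.ndarray
    index: pd.DataFrame  # temperature_K, time_weeks per row
    x_names: tuple[str, ...] = INPUT_NAMES
    y_names: tuple[str, ...] = OUTPUT_NAMES
    dropped: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.X)


def assemble_design(delta: DeltaDataset) -> DesignMatrices:
    """Pivot deltas to one row per (temperature, time) with all five outputs."""
    wide = delta.frame.pivot_table(
        index=["temperature_K", "time_weeks"], columns="indicator",
        values="delta", aggfunc="first",
    )
    names = [ind.name for ind in INDICATOR_ORDER]
    for n in names:
        if n not in wide.columns:
            wide[n] = np.nan
    wide = wide[names].sort_index()
    complete = wide.dropna()
    dropped = [tuple(map(float, ix)) for ix in wide.index.difference(complete.index)]
    if dropped:
        logger.info("dropping %d incomplete (temperature, time) rows: %s",
                    len(dropped), dropped)
    if complete.empty:
        raise NoCompleteRowsError("no (temperature, time) point has all five indicators")
    index = complete.index.to_frame(index=False)
    X = index.to_numpy(dtype=float)
    Y = complete.to_numpy(dtype=float)
    return DesignMatrices(X=X, Y=Y, index=index, dropped=dropped)


@dataclass
class NormalizationParams:
    """Per-variable (min, max) for the affine map onto [-1, 1]."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        bad = np.flatnonzero(self.maxs <= self.mins)
        if bad.size:
            raise DegenerateVariableError(
                f"variable {self.names[bad[0]]!r} has max <= min"
            )

    def transform(self, values: np.ndarray) -> np.ndarray:
        """v -> 2 (v - min)/(max - min) - 1; linear extrapolation out of range."""
        v = np.asarray(values, dtype=float)
        return 2.0 * (v - self.mins) / (self.maxs - self.mins) - 1.0

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        s = np.asarray(scaled, dtype=float)
        return (s + 1.0) / 2.0 * (self.maxs - self.mins) + self.mins

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(tuple(d["names"]), np.asarray(d["mins"]), np.asarray(d["maxs"]))


def fit_minmax(values: np.ndarray, names: tuple[str, ...],
               pad_degenerate: bool = False) -> NormalizationParams:
    """Column-wise min/max of the fitting rows; constant columns are rejected.

    With ``pad_degenerate`` a constant column is given the range value +/- 0.5
    (mapping the constant to 0) instead of raising; the pipeline uses this for
    the temperature input on single-temperature runs.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[1] != len(names):
        raise ConfigError(f"{v.shape[1]} columns but {len(names)} names")
    mins, maxs = v.min(axis=0), v.max(axis=0)
    if pad_degenerate:
        flat = maxs <= mins
        mins = np.where(flat, mins - 0.5, mins)
        maxs = np.where(flat, maxs + 0.5, maxs)
    return NormalizationParams(tuple(names), mins, maxs)


def normalize(params: NormalizationParams, values: np.ndarray) -> np.ndarray:
    return params.transform(values)


def denormalize(params: NormalizationParams, scaled: np.ndarray) -> np.ndarray:
    return params.inverse(scaled)
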