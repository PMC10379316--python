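"""Reference measurement series for common carp fillets under frozen storage.

The reference study stored carp fillets at 261, 253 and 245 K for 17 weeks and
assayed the five quality indicators in triplicate, but published only the
253 K series week by week (as mean +/- sd), plus initial and final summary
values at the other temperatures. This module transcribes those printed
numbers:

* :func:`carp_253K_fixture` - the full 253 K experimental series on the
  sampling grid weeks 1,2,3,5,7,9,11,13,15,17 plus the printed time-0 values
  (FFA, SSP, Ca2+-ATPase, SH; no initial TBARS value was published and none
  is fabricated). Only means were printed, so each point is stored as a
  single replicate; the printed +/- sd values are carried in metadata for the
  synthetic generator to target.
* :func:`anchor_table` - every initial (week 0) and final (week 17) value
  printed for any (indicator, temperature), used to calibrate the synthetic
  trajectories for the unpublished 261 K and 245 K series.

All values are transcribed constants; nothing here is fitted or simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .data import FrozenStorageDataset, Indicator

#: Sampling grid of the published 253 K series (weeks).
FIXTURE_WEEKS = (1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0)

#: Full simulation grid: the fixture weeks plus the week-0 baseline.
CANONICAL_GRID = (0.0,) + FIXTURE_WEEKS

# 253 K experimental series: {indicator: (means over FIXTURE_WEEKS, sds)}.
_TABLE_253K = {
    Indicator.TBARS: (
        (0.34, 0.60, 0.70, 0.74, 0.88, 0.89, 0.69, 0.75, 0.96, 1.06),
        (0.09, 0.11, 0.01, 0.02, 0.08, 0.04, 0.05, 0.08, 0.09, 0.11),
    ),
    Indicator.FFA: (
        (5.34, 7.06, 9.88, 10.90, 12.27, 13.61, 14.30, 14.69, 15.59, 16.81),
        (0.96, 0.60, 0.33, 1.27, 1.43, 0.68, 4.35, 0.25, 1.29, 0.99),
    ),
    Indicator.SSP: (
        (59.02, 58.10, 58.69, 58.22, 59.45, 57.08, 56.16, 46.05, 41.60, 43.14),
        (5.57, 3.97, 4.48, 0.23, 1.92, 0.52, 1.03, 7.10, 10.39, 2.07),
    ),
    Indicator.CA_ATPASE: (
        (0.24, 0.20, 0.19, 0.17, 0.13, 0.09, 0.05, 0.04, 0.03, 0.05),
        (0.01, 0.02, 0.02, 0.01, 0.00, 0.01, 0.01, 0.07, 0.01, 0.01),
    ),
    Indicator.SH: (
        (6.71, 5.29, 5.15, 4.97, 3.49, 3.53, 3.52, 2.93, 2.85, 2.45),
        (0.27, 0.18, 0.02, 0.78, 0.16, 0.34, 0.33, 0.76, 0.59, 0.09),
    ),
}

# Published time-0 values at 253 K (mean, sd). TBARS initial was never printed.
_T0_253K = {
    Indicator.FFA: (3.08, 0.09),
    Indicator.SSP: (69.74, 7.57),
    Indicator.CA_ATPASE: (0.27, 0.05),
    Indicator.SH: (6.98, 0.42),
}

# Published initial values (week 0) per temperature: {indicator: {K: (mean, sd)}}.
_INITIALS = {
    Indicator.FFA: {261.0: (4.33, 0.93), 253.0: (3.08, 0.09), 245.0: (2.99, 0.59)},
    Indicator.SSP: {261.0: (63.84, 5.12), 253.0: (69.74, 7.57), 245.0: (66.74, 2.72)},
    Indicator.CA_ATPASE: {261.0: (0.24, 0.05), 253.0: (0.27, 0.05), 245.0: (0.28, 0.09)},
    Indicator.SH: {261.0: (6.59, 0.20), 253.0: (6.98, 0.42), 245.0: (7.31, 0.43)},
}

# Published final values (week 17) per temperature.
_FINALS = {
    Indicator.TBARS: {253.0: (1.06, 0.11), 245.0: (1.14, 0.32)},
    Indicator.FFA: {261.0: (39.46, 9.89), 253.0: (16.81, 0.99)},
    Indicator.SSP: {261.0: (22.46, 0.47), 253.0: (43.14, 2.07), 245.0: (59.24, 1.26)},
    Indicator.CA_ATPASE: {253.0: (0.05, 0.01)},
    Indicator.SH: {253.0: (2.45, 0.09)},
}

# Published percentage summaries used where week-17 values were not printed
# directly: Ca2+-ATPase residual activity and SH decrease, per temperature,
# and the FFA 261 K final expressed as a multiple of the colder temperatures.
CA_ATPASE_RESIDUAL_PCT = {261.0: 12.50, 253.0: 18.52, 245.0: 28.57}
SH_DECREASE_PCT = {261.0: 70.71, 253.0: 64.92, 245.0: 56.51}
SSP_DECREASE_PCT = {261.0: 64.82, 253.0: 38.14, 245.0: 11.24}
FFA_261_RATIO = {253.0: 2.35, 245.0: 4.42}


def carp_253K_fixture() -> FrozenStorageDataset:
    """The published 253 K experimental series as a dataset of printed means.

    Each (week, indicator) mean is stored as replicate 1 (only mean +/- sd was
    printed, so no per-replicate values are fabricated); the sd values are
    serialized into ``metadata['replicate_sd_json']``.
    """
    rows = []
    sds: dict[str, dict[str, float]] = {}
    for ind, (means, sd) in _TABLE_253K.items():
        sds[ind.name] = {str(w): s for w, s in zip(FIXTURE_WEEKS, sd)}
        for week, mean in zip(FIXTURE_WEEKS, means):
            rows.append((253.0, week, ind.name, 1, mean))
    for ind, (mean, sd) in _T0_253K.items():
        rows.append((253.0, 0.0, ind.name, 1, mean))
        sds[ind.name]["0.0"] = sd
    frame = pd.DataFrame(rows, columns=["temperature_K", "time_weeks", "indicator",
                                        "replicate", "value"])
    metadata = {
        "source": "published 253 K experimental series (printed means)",
        "replicate_sd_json": json.dumps(sds, sort_keys=True),
    }
    return FrozenStorageDataset(frame, metadata)


@dataclass(frozen=True)
class AnchorEntry:
    """Printed initial/final values for one (indicator, temperature)."""

    initial: float | None = None
    initial_sd: float | None = None
    final: float | None = None
    final_sd: float | None = None


@dataclass
class AnchorTable:
    """Every printed week-0 / week-17 value, keyed by (indicator, kelvin)."""

    entries: dict[tuple[Indicator, float], AnchorEntry]

    def get(self, indicator: Indicator, temperature_K: float) -> AnchorEntry:
        return self.entries.get((indicator, temperature_K), AnchorEntry())

    def check_directions(self) -> None:
        """Assert the monotone-direction invariant on every complete pair."""
        from .data import Direction
        for (ind, temp), e in self.entries.items():
            if e.initial is None or e.final is None:
                continue
            if ind.direction is Direction.INCREASING and e.final < e.initial:
                raise AssertionError(f"{ind.name} at {temp} K: final < initial")
            if ind.direction is Direction.DECREASING and e.final > e.initial:
                raise AssertionError(f"{ind.name} at {temp} K: final > initial")


def anchor_table() -> AnchorTable:
    """Assemble the printed anchors; unprinted cells are simply absent."""
    entries: dict[tuple[Indicator, float], AnchorEntry] = {}
    keys = {(ind, temp) for ind, by_t in _INITIALS.items() for temp in by_t}
    keys |= {(ind, temp) for ind, by_t in _FINALS.items() for temp in by_t}
    for ind, temp in sorted(keys, key=lambda k: (k[0].name, -k[1])):
        ini = _INITIALS.get(ind, {}).get(temp)
        fin = _FINALS.get(ind, {}).get(temp)
        entries[(ind, temp)] = AnchorEntry(
            initial=None if ini is None else ini[0],
            initial_sd=None if ini is None else ini[1],
            final=None if fin is None else fin[0],
            final_sd=None if fin is None else fin[1],
        )
    table = AnchorTable(entries)
    table.check_directions()
    return table


def table3_sds(indicator: Indicator) -> tuple[float, ...]:
    """The printed +/- sd values of the 253 K weekly series for one indicator."""
    return _TABLE_253K[indicator][1]
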