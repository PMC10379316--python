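"""Synthetic frozen-storage trajectories with the structure the analysis assumes.

The reference study published the full weekly series only for 253 K; the 261 K
and 245 K series exist only as figures plus printed initial/final anchors. To
make the whole pipeline testable, this module generates replicate trajectories
from a first-order kinetic stand-in,

    C(t) = C_inf + (C0 - C_inf) * exp(-k t),

which covers both saturating increase (TBARS, FFA) and exponential decay
(SSP, Ca2+-ATPase, SH) by the sign of ``C0 - C_inf``. Rates are solved so the
curve interpolates the printed week-0/week-17 anchors; replicate noise is
Gaussian, homoscedastic per (indicator, temperature), truncated at zero, with
sd set to the median of the printed +/- values.

The generator emulates the degradation *trends* of the study; it makes no
mechanistic claim about oxidation chemistry, fits no Arrhenius law (each
temperature gets its own empirically anchored rate) and imposes no
cross-indicator noise correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import Direction, FrozenStorageDataset, Indicator, INDICATOR_ORDER
from .errors import ConfigError, InfeasibleAnchorError
from .fixtures import (
    CANONICAL_GRID,
    CA_ATPASE_RESIDUAL_PCT,
    FFA_261_RATIO,
    SH_DECREASE_PCT,
    anchor_table,
    table3_sds,
)

FORM_SATURATING = "saturating_increase"
FORM_DECAY = "exponential_decay"

#: Asymptote placement relative to the week-17 anchor: increasing indicators
#: plateau 30% above their final value, decreasing ones at half of it, keeping
#: week 17 on the curve's active range rather than at the plateau.
ASYMPTOTE_FACTOR = {Direction.INCREASING: 1.3, Direction.DECREASING: 0.5}

STUDY_TEMPERATURES = (261.0, 253.0, 245.0)

# Plug values for anchors the study never printed, flagged in the config.
# TBARS: no initial values were published at any temperature, and the 261 K
# final is only described as still rising past the ~1.06 mg/kg level it had
# already reached by week 11. The generator assumes (a) a 261 K final of
# 1.25 mg/kg, above both colder finals; (b) an initial level equal to one
# quarter of the final at each temperature (~0.26-0.31 mg/kg, below the
# 0.58 mg/kg freshness threshold). The proportional initial makes the solved
# TBARS rate identical across temperatures -- the least-committal choice the
# anchors allow, and the only one that keeps the rate ordering non-violated
# given that the printed colder finals (1.06 at 253 K, 1.14 at 245 K) invert
# within their +/- sd overlap.
_TBARS_FINAL_PLUGS = {261.0: 1.25}
_TBARS_INITIAL_FRACTION = 0.25


@dataclass
class KineticParams:
    """Per-indicator kinetic parameters, each field keyed by temperature (K)."""

    indicator: Indicator
    form: str
    C0: dict[float, float]
    C_inf: dict[float, float]
    rate: dict[float, float]
    noise_sd: dict[float, float]

    def validate(self) -> None:
        for temp, k in self.rate.items():
            if k < 0:
                raise ConfigError(f"{self.indicator.name} at {temp} K: negative rate {k}")
            c0, cinf = self.C0[temp], self.C_inf[temp]
            if self.form == FORM_SATURATING and cinf < c0:
                raise ConfigError(f"{self.indicator.name} at {temp} K: C_inf < C0 for saturating form")
            if self.form == FORM_DECAY and cinf > c0:
                raise ConfigError(f"{self.indicator.name} at {temp} K: C_inf > C0 for decay form")
        temps = sorted(self.rate, reverse=True)  # warm -> cold
        for warm, cold in zip(temps, temps[1:]):
            if self.rate[cold] > self.rate[warm] + 1e-12:
                raise ConfigError(
                    f"{self.indicator.name}: rate at {cold} K exceeds rate at {warm} K "
                    "(colder storage must change no faster)"
                )


@dataclass
class SyntheticConfig:
    """Full generator configuration: kinetics, grid, replicates, seed."""

    kinetics: dict[Indicator, KineticParams]
    temperatures: tuple[float, ...] = STUDY_TEMPERATURES
    time_grid: tuple[float, ...] = CANONICAL_GRID
    replicates: int = 3
    seed: int = 0
    plug_flags: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        grid = list(self.time_grid)
        if grid != sorted(grid) or grid[0] != 0:
            raise ConfigError("time_grid must be sorted ascending starting at 0")
        for params in self.kinetics.values():
            params.validate()

    def to_dict(self) -> dict:
        return {
            "temperatures": list(self.temperatures),
            "time_grid": list(self.time_grid),
            "replicates": self.replicates,
            "seed": self.seed,
            "plug_flags": list(self.plug_flags),
            "kinetics": {
                ind.name: {
                    "form": p.form,
                    "C0": dict(p.C0),
                    "C_inf": dict(p.C_inf),
                    "rate": dict(p.rate),
                    "noise_sd": dict(p.noise_sd),
                }
                for ind, p in self.kinetics.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        kinetics = {}
        for name, p in d["kinetics"].items():
            ind = Indicator.from_name(name)
            kinetics[ind] = KineticParams(
                indicator=ind,
                form=p["form"],
                C0={float(k): float(v) for k, v in p["C0"].items()},
                C_inf={float(k): float(v) for k, v in p["C_inf"].items()},
                rate={float(k): float(v) for k, v in p["rate"].items()},
                noise_sd={float(k): float(v) for k, v in p["noise_sd"].items()},
            )
        cfg = cls(
            kinetics=kinetics,
            temperatures=tuple(float(t) for t in d["temperatures"]),
            time_grid=tuple(float(t) for t in d["time_grid"]),
            replicates=int(d["replicates"]),
            seed=int(d["seed"]),
            plug_flags=list(d.get("plug_flags", [])),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def restricted_to(self, temperatures: tuple[float, ...]) -> "SyntheticConfig":
        """A copy generating only the given temperatures."""
        for t in temperatures:
            if t not in self.temperatures:
                raise ConfigError(f"temperature {t} K not in config")
        return SyntheticConfig(
            kinetics=self.kinetics,
            temperatures=tuple(temperatures),
            time_grid=self.time_grid,
            replicates=self.replicates,
            seed=self.seed,
            plug_flags=list(self.plug_flags),
        )


def mean_trajectory(params: KineticParams, temperature_K: float, t: float) -> float:
    """Noise-free indicator level at time ``t`` (weeks).

    Equals C0 at t=0, approaches C_inf as t grows, and is monotone in t.
    """
    if temperature_K not in params.C0:
        raise ConfigError(
            f"{params.indicator.name}: no kinetic parameters for {temperature_K} K"
        )
    if t < 0:
        raise ConfigError(f"time must be non-negative, got {t}")
    c0 = params.C0[temperature_K]
    cinf = params.C_inf[temperature_K]
    k = params.rate[temperature_K]
    return cinf + (c0 - cinf) * math.exp(-k * t)


def solve_rate_from_anchors(C0: float, C_t: float, C_inf: float, t: float) -> float:
    """Rate k such that the exponential through (0, C0) -> C_inf hits (t, C_t).

    k = -ln((C_t - C_inf)/(C0 - C_inf)) / t. The anchor is infeasible when
    C_t lies beyond the asymptote or on its far side, or exactly at it
    (infinite rate).
    """
    if t <= 0:
        raise ConfigError(f"anchor time must be positive, got {t}")
    num = C_t - C_inf
    den = C0 - C_inf
    if den == 0:
        raise InfeasibleAnchorError("C0 equals the asymptote; trajectory is constant")
    if num == 0:
        raise InfeasibleAnchorError("C_t equals the asymptote; rate would be infinite")
    ratio = num / den
    if ratio < 0:
        raise InfeasibleAnchorError(
            f"C_t={C_t} lies on the far side of the asymptote {C_inf} from C0={C0}"
        )
    if ratio > 1:
        raise InfeasibleAnchorError(
            f"C_t={C_t} lies beyond C0={C0} relative to the asymptote {C_inf}"
        )
    return -math.log(ratio) / t


def default_carp_config(seed: int) -> SyntheticConfig:
    """Generator configuration calibrated to the printed study anchors.

    For every (indicator, temperature) the week-0 and week-17 anchors come
    from :func:`anchor_table` where printed; unprinted cells use documented
    plug values (TBARS initials and off-253 K finals; Ca2+-ATPase and SH
    finals reconstructed from the printed residual/decrease percentages; the
    FFA 245 K final from the printed 261 K/245 K ratio), each flagged in
    ``plug_flags``. Noise sd per indicator is the median of the printed
    weekly +/- values at 253 K, applied to all temperatures. Rates are solved
    so each curve interpolates its anchors at week 17.
    """
    anchors = anchor_table()
    horizon = 17.0
    kinetics: dict[Indicator, KineticParams] = {}
    plug_flags: list[str] = []

    for ind in INDICATOR_ORDER:
        form = FORM_SATURATING if ind.direction is Direction.INCREASING else FORM_DECAY
        factor = ASYMPTOTE_FACTOR[ind.direction]
        noise = float(np.median(table3_sds(ind)))
        C0, C_inf, rate, noise_sd = {}, {}, {}, {}
        for temp in STUDY_TEMPERATURES:
            entry = anchors.get(ind, temp)
            final = entry.final
            if final is None:
                if ind is Indicator.TBARS:
                    final = _TBARS_FINAL_PLUGS[temp]
                elif ind is Indicator.FFA:
                    final = anchors.get(ind, 261.0).final / FFA_261_RATIO[temp]
                elif ind is Indicator.CA_ATPASE:
                    final = entry.initial * CA_ATPASE_RESIDUAL_PCT[temp] / 100.0
                elif ind is Indicator.SH:
                    final = entry.initial * (1.0 - SH_DECREASE_PCT[temp] / 100.0)
                plug_flags.append(f"{ind.name}@{temp:g}K:final={final:.6g}")
            initial = entry.initial
            if initial is None:
                # Only TBARS lacks printed initials.
                initial = _TBARS_INITIAL_FRACTION * final
                plug_flags.append(f"{ind.name}@{temp:g}K:initial={initial:.6g}")
            cinf = factor * final
            C0[temp] = initial
            C_inf[temp] = cinf
            rate[temp] = solve_rate_from_anchors(initial, final, cinf, horizon)
            noise_sd[temp] = noise
        params = KineticParams(ind, form, C0, C_inf, rate, noise_sd)
        kinetics[ind] = params

    cfg = SyntheticConfig(kinetics=kinetics, seed=seed, plug_flags=plug_flags)
    cfg.validate()
    return cfg


def simulate_dataset(config: SyntheticConfig) -> FrozenStorageDataset:
    """Draw a replicate dataset from the kinetic model.

    Each replicate is ``mean_trajectory + N(0, noise_sd)`` truncated at zero,
    drawn independently per (temperature, time, indicator, replicate) in a
    fixed iteration order, so output is deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for temp in config.temperatures:
        for t in config.time_grid:
            for ind in INDICATOR_ORDER:
                if ind not in config.kinetics:
                    continue
                params = config.kinetics[ind]
                mean = mean_trajectory(params, temp, t)
                sd = params.noise_sd[temp]
                draws = mean + sd * rng.standard_normal(config.replicates)
                for rep, v in enumerate(draws, start=1):
                    rows.append((temp, t, ind.name, rep, max(float(v), 0.0)))
    frame = pd.DataFrame(rows, columns=["temperature_K", "time_weeks", "indicator",
                                        "replicate", "value"])
    metadata = {
        "generator": "first-order-kinetic",
        "seed": str(config.seed),
        "config_yaml": yaml.safe_dump(config.to_dict(), sort_keys=True),
    }
    return FrozenStorageDataset(frame, metadata)
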