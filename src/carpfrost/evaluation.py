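"""Validation metrics, correlations and summary statistics.

The model's acceptance criterion is the per-point relative error between
experimental and predicted indicator values on the validation temperature's
time grid,

    relative error (%) = (C_exp - C_pre) / C_exp * 100,

positive when the prediction undershoots; the model passes when every
|relative error| <= 10%. Per-indicator MSE and R^2 (coefficient of
determination) are computed on the original measurement scale, and the
Pearson correlation matrix between the five indicators mirrors the study's
pooled correlation analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import FrozenStorageDataset, Indicator, INDICATOR_ORDER
from .errors import (
    ConfigError,
    DimensionError,
    InsufficientDataError,
    UndefinedValueError,
)
from .preprocess import FIRST_OBSERVED, delta_transform
from .rbf import RBFNetwork, predict

#: Acceptance band on |relative error| (percent).
ACCEPTANCE_BAND_PCT = 10.0

SIGNED = "signed"
ABSOLUTE = "absolute"


def relative_error(experimental: float, predicted: float, mode: str = SIGNED) -> float:
    """Percent deviation of prediction from experiment.

    Signed mode returns ((C_exp - C_pre)/C_exp)*100 (positive = undershoot);
    absolute mode its magnitude. Undefined for experimental = 0.
    """
    if experimental == 0:
        raise UndefinedValueError("relative error undefined for experimental value 0")
    err = (experimental - predicted) / experimental * 100.0
    if mode == SIGNED:
        return err
    if mode == ABSOLUTE:
        return abs(err)
    raise ConfigError(f"unknown relative-error mode {mode!r}")


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared difference."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise DimensionError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise InsufficientDataError("mse of empty arrays")
    return float(np.mean((y - yhat) ** 2))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (1 iff perfect fit)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise DimensionError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise InsufficientDataError("r_squared of empty arrays")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedValueError("r_squared undefined: zero variance in y")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def percent_decrease(C0: float, Ct: float) -> float:
    """(C0 - Ct)/C0 * 100; how much of the initial level was lost."""
    if C0 <= 0:
        raise UndefinedValueError(f"percent_decrease requires C0 > 0, got {C0}")
    return (C0 - Ct) / C0 * 100.0


def residual_fraction(C0: float, Ct: float) -> float:
    """Ct/C0 * 100; remaining level, complementing percent_decrease to 100."""
    if C0 <= 0:
        raise UndefinedValueError(f"residual_fraction requires C0 > 0, got {C0}")
    return Ct / C0 * 100.0


@dataclass
class CorrelationTable:
    """5x5 Pearson correlation matrix over indicators, with pooling recorded."""

    r: pd.DataFrame
    significant_01: pd.DataFrame  # two-tailed test at the 0.01 level
    pooling: str
    n_rows: int

    def __post_init__(self):
        vals = self.r.to_numpy()
        assert np.allclose(np.diag(vals), 1.0)
        assert np.allclose(vals, vals.T)
        assert (vals >= -1 - 1e-12).all() and (vals <= 1 + 1e-12).all()


def pearson_matrix(dataset: FrozenStorageDataset, pooling: str = "all"):
    """Pearson r between indicators over replicate means of complete rows.

    ``pooling="all"`` pools every (temperature, time) point with all five
    indicators into one matrix; ``pooling="per_temperature"`` returns a dict
    of per-temperature tables. Significance flags come from the two-tailed
    test at 0.01 (no multiplicity correction).
    """
    if pooling == "per_temperature":
        out = {}
        for temp in dataset.temperatures():
            sub = FrozenStorageDataset(
                dataset.frame[dataset.frame["temperature_K"] == temp].copy(),
                dict(dataset.metadata))
            out[temp] = pearson_matrix(sub, pooling="all")
            out[temp].pooling = f"temperature {temp:g} K only"
        return out
    if pooling != "all":
        raise ConfigError(f"unknown pooling {pooling!r}")
    wide = dataset.replicate_means().pivot_table(
        index=["temperature_K", "time_weeks"], columns="indicator",
        values="value", aggfunc="first")
    names = [ind.name for ind in INDICATOR_ORDER]
    wide = wide.reindex(columns=names).dropna()
    if len(wide) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete (temperature, time) rows, got {len(wide)}")
    r = pd.DataFrame(np.eye(5), index=names, columns=names)
    sig = pd.DataFrame(False, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.pearsonr(wide[a], wide[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            sig.loc[a, b] = sig.loc[b, a] = bool(res.pvalue < 0.01)
    return CorrelationTable(r=r, significant_01=sig,
                            pooling="all temperatures and times pooled",
                            n_rows=len(wide))


@dataclass
class ValidationReport:
    """Predicted vs experimental values at one temperature, week by week.

    ``rows`` has one record per (indicator, week) with the experimental
    replicate mean, the prediction (delta + baseline, original scale), the
    signed relative error in percent, and a ``defined`` flag (False where the
    experimental value is 0, in which case the cell is excluded from the
    maximum with a warning). ``per_indicator`` carries MSE and R^2 on the
    original scale. ``passed`` is True iff every defined |relative error| is
    within the +/-10% band.
    """

    temperature_K: float
    baseline_policy: str
    rows: pd.DataFrame
    per_indicator: pd.DataFrame
    max_abs_rel_error: float
    passed: bool
    baselines: dict[str, tuple[float, float]]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature_K,
            "baseline_policy": self.baseline_policy,
            "rows": self.rows.to_dict(orient="records"),
            "per_indicator": self.per_indicator.to_dict(orient="records"),
            "max_abs_rel_error": self.max_abs_rel_error,
            "passed": self.passed,
            "acceptance_band_pct": ACCEPTANCE_BAND_PCT,
            "baselines": {k: list(v) for k, v in self.baselines.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        """Aligned-column layout: predicted / experimental / error per indicator."""
        lines = [
            f"Validation at {self.temperature_K:g} K "
            f"(baseline policy: {self.baseline_policy})",
        ]
        weeks = sorted(self.rows["time_weeks"].unique())
        header = "{:<12}{:<22}".format("Indicator", "") + "".join(
            f"{w:>9.0f}" for w in weeks)
        lines.append(header)
        for ind in INDICATOR_ORDER:
            sub = self.rows[self.rows["indicator"] == ind.name].set_index("time_weeks")
            if sub.empty:
                continue
            for label, col, fmt in (("Predicted value", "predicted", "{:>9.2f}"),
                                    ("Experimental value", "experimental", "{:>9.2f}"),
                                    ("Relative errors (%)", "rel_error_pct", "{:>9.2f}")):
                cells = []
                for w in weeks:
                    if w in sub.index and not np.isnan(sub.loc[w, col]):
                        cells.append(fmt.format(sub.loc[w, col]))
                    else:
                        cells.append(f"{'-':>9}")
                name = ind.name if label == "Predicted value" else ""
                lines.append("{:<12}{:<22}".format(name, label) + "".join(cells))
        lines.append(
            f"max |relative error| = {self.max_abs_rel_error:.2f}% "
            f"({'PASS' if self.passed else 'FAIL'} at +/-{ACCEPTANCE_BAND_PCT:.0f}%)")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def validation_report(net: RBFNetwork, dataset: FrozenStorageDataset,
                      temperature_K: float,
                      baseline_policy: str = FIRST_OBSERVED) -> ValidationReport:
    """Predict the validation temperature's grid and score it against data.

    Deltas are predicted on the original scale, converted to absolute values
    by adding the baseline of each (temperature, indicator), and compared to
    the experimental replicate means at every observed week t > 0.
    """
    if temperature_K not in dataset.temperatures():
        raise ConfigError(f"dataset has no temperature {temperature_K} K")
    delta = delta_transform(dataset, baseline_policy)
    means = dataset.replicate_means()
    means = means[means["temperature_K"] == temperature_K]
    warnings: list[str] = []
    records = []
    for ind in INDICATOR_ORDER:
        sub = means[means["indicator"] == ind.name].sort_values("time_weeks")
        key = (temperature_K, ind.name)
        if sub.empty or key not in delta.baselines:
            continue
        _, base_v = delta.baselines[key]
        weeks = sub["time_weeks"].to_numpy()
        keep = weeks > 0
        weeks = weeks[keep]
        exp_vals = sub["value"].to_numpy()[keep]
        X = np.column_stack([np.full_like(weeks, temperature_K), weeks])
        deltas = predict(net, X, scale="original")
        col = net.output_names.index(f"delta_{ind.name}")
        pred_vals = base_v + deltas[:, col]
        for w, e, p in zip(weeks, exp_vals, pred_vals):
            if e == 0:
                warnings.append(
                    f"{ind.name} week {w:g}: experimental value 0, relative "
                    "error undefined; excluded from the maximum")
                records.append((ind.name, w, e, p, np.nan, False))
            else:
                records.append((ind.name, w, e, p, relative_error(e, p), True))
    rows = pd.DataFrame(records, columns=["indicator", "time_weeks", "experimental",
                                          "predicted", "rel_error_pct", "defined"])
    per_ind = []
    for ind in INDICATOR_ORDER:
        sub = rows[rows["indicator"] == ind.name]
        if sub.empty:
            continue
        try:
            r2 = r_squared(sub["experimental"], sub["predicted"])
        except UndefinedValueError:
            r2 = np.nan
        per_ind.append((ind.name, temperature_K,
                        mse(sub["experimental"], sub["predicted"]), r2))
    per_indicator = pd.DataFrame(per_ind, columns=["indicator", "temperature_K",
                                                   "mse", "r_squared"])
    defined = rows[rows["defined"]]
    max_abs = float(np.max(np.abs(defined["rel_error_pct"]))) if len(defined) else np.nan
    passed = bool(len(defined)) and bool(max_abs <= ACCEPTANCE_BAND_PCT)
    baselines = {ind: delta.baselines[(temperature_K, ind)]
                 for _, ind in [(temperature_K, i.name) for i in INDICATOR_ORDER]
                 if (temperature_K, ind) in delta.baselines}
    return ValidationReport(
        temperature_K=temperature_K, baseline_policy=baseline_policy,
        rows=rows, per_indicator=per_indicator, max_abs_rel_error=max_abs,
        passed=passed, baselines=baselines, warnings=warnings)
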