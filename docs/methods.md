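# Methods

## Data model

All measurements live in a single tidy table (`FrozenStorageDataset`):
storage temperature in kelvin exactly as designed (261/253/245; never
converted to Celsius), storage time in weeks, indicator name, replicate
index, and value in the indicator's printed unit. Units are opaque labels —
including the SH label (mol/10⁵ g), which is reported inconsistently in the
source material and is therefore carried verbatim, never converted. The key
(temperature, time, indicator, replicate) is unique; times and values are
non-negative.

The canonical sampling grid is weeks {0, 1, 2, 3, 5, 7, 9, 11, 13, 15, 17}
with triplicate sampling, matching the reference experiment's published
validation grid (the study's prose describes a denser late schedule, but the
published per-week series uses this grid, and it is the grid the model must
reproduce).

### Reference values

`fixtures.carp_253K_fixture()` transcribes the published 253 K series. Only
mean ± sd were published, so each point is stored as a single replicate mean
and the sd values ride along in metadata; no per-replicate values are
fabricated. TBARS has no published week-0 value at any temperature and the
fixture deliberately leaves it absent. `fixtures.anchor_table()` collects
every published week-0/week-17 value per (indicator, temperature), including
the week-17 253 K values from the published validation table; cells never
published are absent rather than guessed.

## Synthetic trajectory generator

The generator exists so the full three-temperature pipeline is testable:
the 261 K and 245 K weekly series were never published. Each indicator
follows a single-exponential approach to an asymptote,

    C(t) = C_inf + (C0 − C_inf) · e^(−k t),

which covers saturating increase (TBARS, FFA) and exponential decay (SSP,
Ca²⁺-ATPase, SH) by the sign of C0 − C_inf. This is the simplest monotone
family consistent with the published curves; the network, not the generator,
is the object under test.

Parameters, all recorded in the config and derived once from published
values:

- **Anchors.** C0 and the week-17 value come from the anchor table where
  published. Unpublished cells use documented plugs, each flagged in
  `plug_flags`: Ca²⁺-ATPase finals at 261/245 K from the published residual
  percentages (12.50%/28.57% of the initial), SH finals from the published
  decrease percentages (70.71%/56.51%), the FFA 245 K final from the
  published 261 K/245 K ratio (4.42), a TBARS 261 K final of 1.25 mg/kg
  (described only as still rising past the ~1.06 level reached by week 11),
  and TBARS initials of 0.25 × the final at each temperature (~0.26–0.31
  mg/kg, below the 0.58 mg/kg freshness threshold). The proportional TBARS
  initial makes the solved TBARS rate identical across temperatures — the
  least-committal choice, and the only one consistent with the rate-ordering
  constraint below, given that the published colder finals (1.06 at 253 K vs
  1.14 ± 0.32 at 245 K) invert within their uncertainty.
- **Asymptotes.** C_inf = 1.3 × final for increasing indicators, 0.5 × final
  for decreasing ones, keeping week 17 on the curve's active range rather
  than at the plateau.
- **Rates.** k = −ln((C_17 − C_inf)/(C0 − C_inf))/17, so every curve
  interpolates its anchors exactly. Rates are anchored per temperature, not
  Arrhenius-fitted: the reference analysis fits no Arrhenius law, and
  imposing one would overreach. The config validator enforces
  k(261) ≥ k(253) ≥ k(245) — colder storage never changes faster. The
  ordering is stated (and tested) on rates and fractional progress, not on
  absolute change: the published anchors themselves give 253 K a larger
  absolute Ca²⁺-ATPase/SH change than 261 K because its initial values were
  higher.
- **Noise.** Replicates are mean + Gaussian(0, sd) truncated at zero,
  homoscedastic per indicator (sd = median of the published weekly ± values
  at 253 K, applied to all temperatures; the published ± values show no
  clear variance trend). Noise is independent across (point, replicate);
  cross-indicator correlation emerges from the shared time/temperature
  dependence only.

What the generator does *not* emulate: mechanistic oxidation chemistry, the
non-monotone wobbles visible in the real series (e.g. the TBARS dip after
week 9), correlated replicate noise, and any measurement floor/ceiling
effects. Tests passing on synthetic data therefore demonstrate that the
pipeline recovers trajectories *of the assumed kinetic family* under
realistic noise — not that the kinetic family itself is the true chemistry.

## Preprocessing

Targets are changes from baseline, ΔC = C_t − C₀, computed on replicate
means per (temperature, indicator) — the model describes one curve per
temperature, not per fillet. The baseline is each temperature's own week-0
mean (`require_t0`); for fixture-based runs, where TBARS has no week-0
value, the `first_observed` policy uses the earliest available week as that
pair's baseline (flagged in the report). Design rows are (temperature, time)
points carrying all five deltas; incomplete rows are dropped and logged —
in the hybrid dataset only (253 K, week 0) drops, leaving 32 rows.

Inputs and outputs are min–max scaled to [−1, 1] (v ↦ 2(v−min)/(max−min)−1)
with exact linear inversion and no clipping out of range. Scaling is fitted
on the full development data, consistent with training on it (below); on
single-temperature runs the constant temperature column is padded to a unit
range so it maps to 0.

## Network and training

Gaussian RBF with two inputs, one hidden layer, five linear outputs.
Activation φ_j(x) = exp(−(0.8326/s)²‖x−w_j‖²): the 0.8326 constant makes the
activation exactly exp(−0.8326²) ≈ 0.5 at Euclidean distance s, so the
spread is the kernel's half-response radius on the normalized scale.

Training is classical greedy forward construction: start from the bias-only
least-squares fit; at each step add as a centre the training input (among
distinct rows not yet centres) that minimizes training MSE after re-solving
the output layer by rank-tolerant least squares (minimum-norm on
degeneracy); stop at the neuron budget or an MSE goal. Ties break on the
lowest row index and all randomness is confined to the seeded data split, so
training is bit-reproducible; the MSE trace is non-increasing by
construction. MSE here is the mean of squared residuals over all five
outputs jointly on the normalized scale; per-indicator MSE and R²
(coefficient of determination, the stricter reading of "regression
coefficient") are reported on the original measurement scale.

### Hyperparameter selection

The scan trains one greedy run per spread on the full development data and
reads off every hidden-layer size by prefix consistency. Selection is the
joint argmin of **training** MSE (ties: fewer neurons, then smaller spread).
Two facts make this sensible and reproduce the reference scan's structure:
the neuron trace is non-increasing, so the minimum sits at the largest
scanned size (28); and because 28 is below the number of development rows
(32), the training MSE at that size is U-shaped in the spread — tiny spreads
degenerate into point spikes that leave off-centre rows to the bias, huge
spreads flatten the basis into near-collinearity — which identifies a
moderate bandwidth (0.50–1.00 on the normalized scale) without touching
held-out data. The 70/15/15 random split is still drawn, and the
assessment-subset MSE is recorded in the scan table (`select_by="assess"`
switches selection to it, for sensitivity analysis); with a 5-row assessment
subset its argmin is noisy and selects substantially worse architectures,
which is why it is not the default. Scanned sizes exceeding the number of
distinct development rows are recorded as infeasible (NaN) and excluded from
selection rather than raised, so the standard 0–28 grid runs on small
datasets too.

### Validation

The validation report predicts the deltas on the validation temperature's
grid (original scale), adds the baselines back, and tabulates predicted vs
experimental values with signed relative errors, (C_exp − C_pre)/C_exp × 100
(positive = undershoot; the magnitude feeds the ±10% acceptance band). Cells
with experimental value 0 are flagged undefined and excluded from the
maximum with a warning. Correlations are Pearson r on replicate means of
complete rows, pooled across temperatures by default (the pooling scheme is
recorded in the table), with two-tailed significance flags at 0.01 and no
multiplicity correction.

## Problem sizes and numerical choices

The standard run uses 32 design rows (three temperatures × 11 grid points,
minus the incomplete 253 K week-0 row), a 15 × 8 hyperparameter grid, and a
28-neuron final network; a full scan-train-validate run takes well under a
second, and the ten-seed repetition a few seconds. Least squares uses
`numpy.linalg.lstsq` with default rcond; duplicate centres and
ill-conditioned wide-spread kernels resolve to the minimum-norm solution.
Normalization round-trips are exact to ~1e−12 relative; model files
round-trip predictions to 1e−15. Seeds: the generator, the split and the
pipeline all take explicit integer seeds; identical configs produce
bit-identical artifacts (no timestamps are written).

## Known limitations

- The 261/245 K series are synthetic stand-ins; no per-week published values
  exist to validate them, so three-temperature results are conditional on
  the kinetic family and the documented plug anchors.
- The reference model's exact random split, fitted weights and per-cell
  predictions are not reproducible from published information; the pipeline
  reproduces the procedure and its acceptance band, not the identical
  network.
- The relative-error metric is undefined at zero experimental values and
  unstable near them (the smallest Ca²⁺-ATPase values dominate the error
  maximum).
- R² between experimental and predicted values is reported per indicator
  over ten validation weeks; with so few points it is a descriptive, not
  inferential, quantity.
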