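"""Gaussian radial-basis-function network with greedy incremental training.

Architecture: two inputs (storage temperature, time), one hidden layer of
Gaussian units, five linear outputs (the indicator deltas). A hidden unit
centred at w_j with spread s responds to input x as

    phi_j(x) = exp( -(0.8326 / s)^2 * ||x - w_j||^2 ),

the 0.8326 convention making the activation exactly one half at Euclidean
distance s from the centre. Output k is the linear combination

    y_k(x) = sum_j W_kj phi_j(x) + b_k.

Training is classical incremental (greedy forward) construction: starting
from a bias-only model, the training input whose addition as a centre most
reduces training MSE is added, output weights being re-solved by exact linear
least squares after each addition, until a neuron budget or an MSE goal is
reached. All randomness is confined to the seeded train/assess/test split;
ties break on the lowest row index, so training is bit-reproducible.

Hyperparameters (hidden-layer size and spread) are selected by a grid scan
over the development data; see :func:`scan_hyperparameters` for the selection
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .errors import (
    ConfigError,
    DimensionError,
    InsufficientDataError,
    ModelParseError,
    ModelStateError,
)
from .preprocess import NormalizationParams

#: Bandwidth convention: activation = 0.5 at distance = spread, since
#: exp(-(0.8326)^2) = 0.49998.
BANDWIDTH_CONSTANT = 0.8326

MODEL_FORMAT_VERSION = "1"

#: Hidden-layer sizes and spreads scanned by default.
DEFAULT_NEURON_GRID = tuple(range(0, 29, 2))
DEFAULT_SPREAD_GRID = (0.05, 0.10, 0.50, 1.00, 1.50, 2.00, 2.50, 3.00)


@dataclass
class RBFNetwork:
    """A trained (or explicitly constructed) Gaussian RBF network.

    ``centers`` is (n, d); ``output_weights`` is (K, n); ``output_biases`` is
    (K,). ``x_norm``/``y_norm`` hold the min-max parameters used to move
    between original and normalized scales; they may be None for a network
    used purely on the normalized scale.
    """

    centers: np.ndarray
    spread: float
    output_weights: np.ndarray
    output_biases: np.ndarray
    bandwidth_constant: float = BANDWIDTH_CONSTANT
    x_norm: NormalizationParams | None = None
    y_norm: NormalizationParams | None = None
    input_names: tuple[str, ...] = ()
    output_names: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, max(self.centers.shape[-1], 1) if self.centers.ndim else 1)
        self.output_weights = np.atleast_2d(np.asarray(self.output_weights, dtype=float))
        self.output_biases = np.asarray(self.output_biases, dtype=float).ravel()
        if self.spread <= 0:
            raise ConfigError(f"spread must be positive, got {self.spread}")
        if self.n_hidden and self.output_weights.shape[1] != self.n_hidden:
            raise ConfigError(
                f"output_weights has {self.output_weights.shape[1]} columns "
                f"but there are {self.n_hidden} centers"
            )

    @property
    def n_hidden(self) -> int:
        return self.centers.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.output_biases.shape[0]


def _activation_matrix(centers: np.ndarray, spread: float, X: np.ndarray,
                       bandwidth_constant: float = BANDWIDTH_CONSTANT) -> np.ndarray:
    """Phi[i, j] = exp(-(b/spread)^2 * ||X_i - c_j||^2); shape (m, n)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if centers.shape[0] == 0:
        return np.zeros((X.shape[0], 0))
    if X.shape[1] != centers.shape[1]:
        raise DimensionError(
            f"input arity {X.shape[1]} does not match centers arity {centers.shape[1]}"
        )
    b = bandwidth_constant / spread
    d2 = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-(b * b) * d2)


def hidden_activations(net: RBFNetwork, x: np.ndarray) -> np.ndarray:
    """Hidden-layer response to a single (normalized) input point.

    Values lie in (0, 1]; a unit responds with exactly 1 iff x equals its
    centre and with ~0.5 at distance = spread.
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    return _activation_matrix(net.centers, net.spread, x, net.bandwidth_constant)[0]


def predict(net: RBFNetwork, X: np.ndarray, scale: str = "normalized") -> np.ndarray:
    """Network outputs for a batch of input points.

    ``scale="normalized"`` evaluates the linear read-out on inputs already on
    the [-1, 1] scale. ``scale="original"`` normalizes the inputs and
    denormalizes the outputs with the stored parameters (the outputs are
    still *deltas*; adding baselines back is the evaluation layer's job).
    """
    if net.output_weights.size == 0 and net.n_hidden > 0:
        raise ModelStateError("network has centers but no trained output weights")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if scale == "original":
        if net.x_norm is None or net.y_norm is None:
            raise ModelStateError("no normalization parameters stored on the network")
        Xn = net.x_norm.transform(X)
        Yn = predict(net, Xn, scale="normalized")
        return net.y_norm.inverse(Yn)
    if scale != "normalized":
        raise ConfigError(f"unknown scale {scale!r}")
    phi = _activation_matrix(net.centers, net.spread, X, net.bandwidth_constant)
    return phi @ net.output_weights.T + net.output_biases


def solve_output_weights(centers: np.ndarray, spread: float, X: np.ndarray,
                         Y: np.ndarray,
                         bandwidth_constant: float = BANDWIDTH_CONSTANT,
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares output layer for fixed centers and spread.

    Minimizes ||Y - (Phi W^T + b)||_F^2 with a rank-tolerant (minimum-norm)
    solver; returns (W, b, training MSE). The training MSE is the mean of
    squared residuals over all rows and outputs jointly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise DimensionError(f"{X.shape[0]} input rows vs {Y.shape[0]} target rows")
    if X.shape[0] == 0:
        raise InsufficientDataError("need at least one training row")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    phi = _activation_matrix(centers, spread, X, bandwidth_constant)
    A = np.hstack([phi, np.ones((X.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    W = coef[:-1].T
    b = coef[-1]
    resid = Y - (A @ coef)
    return W, b, float(np.mean(resid ** 2))


@dataclass
class TrainingConfig:
    """Spread, neuron budget, MSE goal, split fractions and seed."""

    spread: float = 1.0
    max_neurons: int = 1
    mse_goal: float = 0.0
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.spread <= 0:
            raise ConfigError("spread must be positive")
        if self.max_neurons < 0:
            raise ConfigError("max_neurons must be >= 0")
        if self.mse_goal < 0:
            raise ConfigError("mse_goal must be >= 0")
        f = self.split_fractions
        if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ConfigError("split fractions must be positive and sum to 1")


def split_dataset(n_rows: int, fractions: tuple[float, float, float],
                  seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/assess/test index split.

    Sizes are round(f1 n) / round(f2 n) / remainder; the permutation is drawn
    from a seeded generator, so the split is deterministic given the seed.
    """
    if n_rows < 3:
        raise InsufficientDataError(f"need at least 3 rows to split, got {n_rows}")
    n_train = int(round(fractions[0] * n_rows))
    n_assess = int(round(fractions[1] * n_rows))
    n_train = min(n_train, n_rows)
    n_assess = min(n_assess, n_rows - n_train)
    perm = np.random.default_rng(seed).permutation(n_rows)
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_assess]),
            np.sort(perm[n_train + n_assess:]))


def _distinct_row_indices(X: np.ndarray) -> np.ndarray:
    """Indices of the first occurrence of each distinct row, ascending."""
    _, first = np.unique(X, axis=0, return_index=True)
    return np.sort(first)


def greedy_center_order(X: np.ndarray, Y: np.ndarray, spread: float,
                        max_neurons: int, mse_goal: float = 0.0,
                        bandwidth_constant: float = BANDWIDTH_CONSTANT,
                        ) -> tuple[list[int], list[tuple[int, float]]]:
    """Greedy forward selection of centers from the training inputs.

    Returns the ordered list of selected row indices and the trace of
    (neuron count, training MSE) starting at the bias-only fit. Greedy
    selection is prefix-consistent: the first k entries are exactly the
    result of running with ``max_neurons=k``. Ties break on the lowest row
    index; the trace is non-increasing because each addition keeps the
    previous solution feasible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    candidates = list(_distinct_row_indices(X))
    if max_neurons > len(candidates):
        raise ConfigError(
            f"max_neurons={max_neurons} exceeds the {len(candidates)} distinct "
            "training inputs"
        )
    empty = np.zeros((0, X.shape[1]))
    _, _, mse0 = solve_output_weights(empty, spread, X, Y, bandwidth_constant)
    trace = [(0, mse0)]
    selected: list[int] = []
    current_mse = mse0
    while len(selected) < max_neurons and current_mse > mse_goal:
        best = None
        for idx in candidates:
            if idx in selected:
                continue
            trial = selected + [idx]
            _, _, mse = solve_output_weights(X[trial], spread, X, Y, bandwidth_constant)
            if best is None or mse < best[1] - 0.0:
                best = (idx, mse)
        if best is None:
            break
        selected.append(best[0])
        current_mse = best[1]
        trace.append((len(selected), current_mse))
    return selected, trace


def train_incremental(X: np.ndarray, Y: np.ndarray, config: TrainingConfig,
                      input_names: tuple[str, ...] = (),
                      output_names: tuple[str, ...] = (),
                      ) -> tuple[RBFNetwork, list[tuple[int, float]]]:
    """Train a network on (normalized) X, Y by greedy incremental construction.

    Stops at ``config.max_neurons`` hidden units or once training MSE drops
    to ``config.mse_goal``. Deterministic given its inputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    selected, trace = greedy_center_order(
        X, Y, config.spread, config.max_neurons, config.mse_goal)
    centers = X[selected] if selected else np.zeros((0, X.shape[1]))
    W, b, mse = solve_output_weights(centers, config.spread, X, Y)
    net = RBFNetwork(
        centers=centers, spread=config.spread, output_weights=W, output_biases=b,
        input_names=tuple(input_names), output_names=tuple(output_names),
        metadata={"n_hidden": len(selected), "training_mse": mse,
                  "center_rows": list(map(int, selected))},
    )
    return net, trace


@dataclass
class ScanResult:
    """MSE surface over (hidden-layer size, spread) and the selected optimum.

    ``table`` has one row per grid point with development-set training MSE
    and assessment-subset MSE (both on the normalized scale, jointly over the
    five outputs). Neuron counts exceeding the number of distinct development
    inputs are recorded as infeasible (NaN) and excluded from selection.
    """

    table: pd.DataFrame
    selected_neurons: int
    selected_spread: float
    select_by: str
    n_rows: int
    n_assess: int


def scan_hyperparameters(X: np.ndarray, Y: np.ndarray,
                         neuron_counts=DEFAULT_NEURON_GRID,
                         spreads=DEFAULT_SPREAD_GRID,
                         config: TrainingConfig | None = None,
                         assess_idx: np.ndarray | None = None,
                         select_by: str = "train",
                         ) -> ScanResult:
    """Grid scan of hidden-layer size x spread on the development data.

    For each spread a single greedy run to the largest feasible budget gives
    (by prefix consistency) the network at every scanned size; each grid
    point records the training MSE over all development rows and the MSE on
    the assessment subset (``assess_idx``, drawn from ``config.seed`` when
    not supplied).

    Selection (``select_by="train"``, the default) is the joint argmin of
    training MSE, ties preferring fewer neurons then smaller spread. Because
    the neuron trace is non-increasing, the minimum sits at the largest
    scanned size, where -- provided that size is below the number of
    development rows -- the training MSE is U-shaped in the spread: tiny
    spreads degenerate into point spikes that leave the off-centre rows to
    the bias, huge spreads flatten the basis into near-collinearity. That
    U-shape identifies the bandwidth without touching held-out data.
    ``select_by="assess"`` instead takes the argmin of the assessment-subset
    MSE (exposed for sensitivity analysis).
    """
    if not len(neuron_counts) or not len(spreads):
        raise ConfigError("neuron_counts and spreads must be non-empty")
    if select_by not in ("train", "assess"):
        raise ConfigError(f"unknown selection criterion {select_by!r}")
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if assess_idx is None:
        _, assess_idx, _ = split_dataset(len(X), config.split_fractions, config.seed)
    assess_idx = np.asarray(assess_idx, dtype=int)
    Xas, Yas = X[assess_idx], Y[assess_idx]
    n_cand = len(_distinct_row_indices(X))
    rows = []
    for spread in spreads:
        max_feasible = min(max(neuron_counts), n_cand)
        order, _ = greedy_center_order(X, Y, spread, max_feasible, config.mse_goal)
        for n in neuron_counts:
            if n > n_cand:
                rows.append((n, spread, np.nan, np.nan, False))
                continue
            k = min(n, len(order))  # mse_goal may have stopped growth early
            centers = X[order[:k]] if k else np.zeros((0, X.shape[1]))
            W, b, mse_train = solve_output_weights(centers, spread, X, Y)
            if len(Xas):
                net = RBFNetwork(centers, spread, W, b)
                resid = Yas - predict(net, Xas)
                mse_assess = float(np.mean(resid ** 2))
            else:
                mse_assess = np.nan
            rows.append((n, spread, mse_train, mse_assess, True))
    table = pd.DataFrame(rows, columns=["neurons", "spread", "mse_train",
                                        "mse_assess", "feasible"])
    feasible = table[table["feasible"]]
    if feasible.empty:
        raise ConfigError("no feasible (neurons, spread) grid point")
    key = "mse_train" if select_by == "train" else "mse_assess"
    best = min(feasible.itertuples(index=False),
               key=lambda r: (getattr(r, key), r.neurons, r.spread))
    return ScanResult(table=table, selected_neurons=int(best.neurons),
                      selected_spread=float(best.spread), select_by=select_by,
                      n_rows=len(X), n_assess=len(assess_idx))


# ---------------------------------------------------------------------------
# Model persistence (human-readable YAML)

def save_model(net: RBFNetwork, path: str | Path) -> None:
    """Serialize a network losslessly to YAML."""
    doc = {
        "version": MODEL_FORMAT_VERSION,
        "spread": float(net.spread),
        "bandwidth_constant": float(net.bandwidth_constant),
        "centers": [[float(v) for v in row] for row in net.centers],
        "output_weights": [[float(v) for v in row] for row in net.output_weights],
        "output_biases": [float(v) for v in net.output_biases],
        "input_names": list(net.input_names),
        "output_names": list(net.output_names),
        "normalization": {
            "x": net.x_norm.to_dict() if net.x_norm else None,
            "y": net.y_norm.to_dict() if net.y_norm else None,
        },
        "metadata": {str(k): v for k, v in net.metadata.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_model(path: str | Path) -> RBFNetwork:
    """Load a network saved by :func:`save_model`; names the missing field."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelParseError("model file does not contain a mapping")
    for key in ("version", "spread", "bandwidth_constant", "centers",
                "output_weights", "output_biases", "normalization"):
        if key not in doc:
            raise ModelParseError(f"model file missing field {key!r}")
    norm = doc["normalization"] or {}
    x_norm = NormalizationParams.from_dict(norm["x"]) if norm.get("x") else None
    y_norm = NormalizationParams.from_dict(norm["y"]) if norm.get("y") else None
    n_out = len(doc["output_biases"])
    weights = np.asarray(doc["output_weights"], dtype=float)
    if weights.size == 0:
        weights = weights.reshape(n_out, 0)
    centers = np.asarray(doc["centers"], dtype=float)
    if centers.size == 0:
        centers = centers.reshape(0, len(doc.get("input_names", (1,))) or 1)
    net = RBFNetwork(
        centers=centers,
        spread=float(doc["spread"]),
        output_weights=weights,
        output_biases=np.asarray(doc["output_biases"], dtype=float),
        bandwidth_constant=float(doc["bandwidth_constant"]),
        x_norm=x_norm, y_norm=y_norm,
        input_names=tuple(doc.get("input_names", ())),
        output_names=tuple(doc.get("output_names", ())),
        metadata=dict(doc.get("metadata", {})),
    )
    net.metadata.setdefault("format_version", doc["version"])
    return net
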