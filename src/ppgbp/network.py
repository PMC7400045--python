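"""Two-layer feed-forward regression with Bayesian-regularization training.

The regressor is a classic single-hidden-layer perceptron: tanh hidden
units, linear output units, inputs and targets affinely normalized to
[-1, 1] from the training split's min/max. Training minimizes the
regularized objective

    F = beta * E_D + alpha * E_W,

where E_D is the sum of squared (normalized) errors and E_W the sum of
squared weights, by Levenberg-Marquardt steps. After each accepted step the
hyperparameters are re-estimated from the evidence framework:

    gamma = P - 2*alpha*tr(H^-1),   alpha = gamma / (2*E_W),
    beta  = (N - gamma) / (2*E_D),

with H = 2*beta*J'J + 2*alpha*I the Gauss-Newton Hessian of F, P the number
of weights and N the number of error terms; gamma is the effective number
of parameters. Training halts at a maximum epoch count, when the validation
error fails to improve for a fixed number of consecutive epochs (the
weights at the best validation epoch are restored), or when the gradient or
damping hits its floor/ceiling.

The combinatorial estimator cascades two such networks: stage 1 maps the
averaged PPG level to MAP (1 -> 10 -> 1), stage 2 maps MAP to (SBP, DBP)
(1 -> 30 -> 2). Stage 2 is trained on true (Eq 2) MAP but fed stage 1's
estimate at prediction time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "MLPRegressor",
    "TrainConfig",
    "TrainRecord",
    "CombinatorialModel",
    "split_data",
    "train_bayesian_regularization",
    "fit_stage1_ppg_to_map",
    "fit_stage2_map_to_bp",
]


def split_data(
    n: int, fractions: Sequence[float] = (0.70, 0.15, 0.15), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index sets.

    Sizes follow the floor rule: floor(f_train*n) rows train; the remainder
    is divided between validation and test in proportion to their fractions
    (validation takes the floor, test the rest), so equal fractions split
    the remainder as evenly as possible. The permutation is seeded. Any
    empty set is rejected.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split three ways")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("three positive fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor((n - n_train) * fractions[1] / (fractions[1] + fractions[2])))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of n={n} leaves an empty set")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


@dataclass
class MLPRegressor:
    """Two-layer perceptron: tanh hidden layer, linear output layer.

    ``in_min``/``in_max`` and ``out_min``/``out_max`` hold the per-feature
    affine normalization to [-1, 1] fixed from the training split.
    """

    n_input: int
    n_hidden: int
    n_output: int
    hidden_weights: np.ndarray = None  # (H, I)
    hidden_biases: np.ndarray = None  # (H,)
    output_weights: np.ndarray = None  # (O, H)
    output_biases: np.ndarray = None  # (O,)
    in_min: np.ndarray = None
    in_max: np.ndarray = None
    out_min: np.ndarray = None
    out_max: np.ndarray = None
    trained: bool = False

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be positive")
        if self.hidden_weights is None:
            self.hidden_weights = np.zeros((self.n_hidden, self.n_input))
            self.hidden_biases = np.zeros(self.n_hidden)
            self.output_weights = np.zeros((self.n_output, self.n_hidden))
            self.output_biases = np.zeros(self.n_output)
        if self.in_min is None:  # identity normalization until fitted
            self.in_min = np.full(self.n_input, -1.0)
            self.in_max = np.full(self.n_input, 1.0)
            self.out_min = np.full(self.n_output, -1.0)
            self.out_max = np.full(self.n_output, 1.0)
        self._check_shapes()

    def _check_shapes(self) -> None:
        expect = {
            "hidden_weights": (self.n_hidden, self.n_input),
            "hidden_biases": (self.n_hidden,),
            "output_weights": (self.n_output, self.n_hidden),
            "output_biases": (self.n_output,),
            "in_min": (self.n_input,),
            "in_max": (self.n_input,),
            "out_min": (self.n_output,),
            "out_max": (self.n_output,),
        }
        for name, shape in expect.items():
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if np.any(self.in_max - self.in_min <= 0) or np.any(self.out_max - self.out_min <= 0):
            raise ValueError("normalization ranges must have positive width")

    # -- normalization -----------------------------------------------------

    def set_normalization(self, X: np.ndarray, Y: np.ndarray) -> None:
        """Fix [-1, 1] normalization from training-split min/max."""
        in_min, in_max = X.min(axis=0), X.max(axis=0)
        out_min, out_max = Y.min(axis=0), Y.max(axis=0)
        if np.any(in_max - in_min <= 0):
            raise ValueError("degenerate input: a feature is constant on the training split")
        if np.any(out_max - out_min <= 0):
            raise ValueError("degenerate target: an output is constant on the training split")
        self.in_min, self.in_max = in_min, in_max
        self.out_min, self.out_max = out_min, out_max

    def normalize_x(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.in_min) / (self.in_max - self.in_min) - 1.0

    def normalize_y(self, Y: np.ndarray) -> np.ndarray:
        return 2.0 * (Y - self.out_min) / (self.out_max - self.out_min) - 1.0

    def denormalize_y(self, Yn: np.ndarray) -> np.ndarray:
        return (Yn + 1.0) / 2.0 * (self.out_max - self.out_min) + self.out_min

    # -- parameter vector --------------------------------------------------

    @property
    def n_params(self) -> int:
        return (self.n_input + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_output

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [
                self.hidden_weights.ravel(),
                self.hidden_biases,
                self.output_weights.ravel(),
                self.output_biases,
            ]
        )

    def set_params(self, w: np.ndarray) -> None:
        h, i, o = self.n_hidden, self.n_input, self.n_output
        w = np.asarray(w, float)
        if w.shape != (self.n_params,):
            raise ValueError("parameter vector has wrong length")
        pos = 0
        self.hidden_weights = w[pos : pos + h * i].reshape(h, i).copy()
        pos += h * i
        self.hidden_biases = w[pos : pos + h].copy()
        pos += h
        self.output_weights = w[pos : pos + o * h].reshape(o, h).copy()
        pos += o * h
        self.output_biases = w[pos:].copy()

    def init_weights(self, rng: np.random.Generator) -> None:
        """Nguyen-Widrow-style seeded initialization, scaled to layer sizes."""
        h, i, o = self.n_hidden, self.n_input, self.n_output
        w = rng.uniform(-1.0, 1.0, (h, i))
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        magnitude = 0.7 * h ** (1.0 / i)
        self.hidden_weights = magnitude * w / norms
        spread = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
        self.hidden_biases = magnitude * spread * np.sign(self.hidden_weights[:, 0])
        self.output_weights = rng.uniform(-0.5, 0.5, (o, h))
        self.output_biases = rng.uniform(-0.5, 0.5, o)

    # -- forward pass ------------------------------------------------------

    def _forward_normalized(self, Xn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = np.tanh(Xn @ self.hidden_weights.T + self.hidden_biases)
        return Z @ self.output_weights.T + self.output_biases, Z

    def forward(self, X) -> np.ndarray:
        """Denormalized network output for raw input X of shape (n, n_input)."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_input:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects {self.n_input}"
            )
        Yn, _ = self._forward_normalized(self.normalize_x(X))
        return self.denormalize_y(Yn)

    predict = forward

    def jacobian(self, Xn: np.ndarray) -> np.ndarray:
        """Jacobian d(output)/d(params) in normalized space.

        Rows are error terms in C order over (sample, output); columns follow
        the get_params packing.
        """
        n = Xn.shape[0]
        h, i, o = self.n_hidden, self.n_input, self.n_output
        _, Z = self._forward_normalized(Xn)
        dZ = 1.0 - Z**2  # (n, h)
        J = np.empty((n * o, self.n_params))
        rows = np.arange(n * o).reshape(n, o)
        # hidden weights: dy_o/dW1[h,i] = W2[o,h] * dZ[n,h] * x[n,i]
        g_hidden = self.output_weights[None, :, :] * dZ[:, None, :]  # (n, o, h)
        J[:, : h * i] = (g_hidden[:, :, :, None] * Xn[:, None, None, :]).reshape(
            n * o, h * i
        )
        J[:, h * i : h * i + h] = g_hidden.reshape(n * o, h)
        pos = h * i + h
        block = np.zeros((n, o, o, h))
        idx = np.arange(o)
        block[:, idx, idx, :] = Z[:, None, :]
        J[:, pos : pos + o * h] = block.reshape(n * o, o * h)
        pos += o * h
        eye = np.zeros((n, o, o))
        eye[:, idx, idx] = 1.0
        J[:, pos:] = eye.reshape(n * o, o)
        return J

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_hidden": self.n_hidden,
            "n_output": self.n_output,
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
            "in_min": self.in_min.tolist(),
            "in_max": self.in_max.tolist(),
            "out_min": self.out_min.tolist(),
            "out_max": self.out_max.tolist(),
            "trained": self.trained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPRegressor":
        return cls(
            n_input=d["n_input"],
            n_hidden=d["n_hidden"],
            n_output=d["n_output"],
            hidden_weights=np.asarray(d["hidden_weights"], float),
            hidden_biases=np.asarray(d["hidden_biases"], float),
            output_weights=np.asarray(d["output_weights"], float),
            output_biases=np.asarray(d["output_biases"], float),
            in_min=np.asarray(d["in_min"], float),
            in_max=np.asarray(d["in_max"], float),
            out_min=np.asarray(d["out_min"], float),
            out_max=np.asarray(d["out_max"], float),
            trained=d.get("trained", False),
        )

    def to_json(self, path=None, **extra) -> str:
        doc = {**self.to_dict(), **extra}
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "MLPRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters and stopping rules.

    Defaults: 1000-epoch cap, stop after 6 consecutive epochs without a
    validation-error improvement, random 70/15/15 train/validation/test
    split. The Levenberg-Marquardt damping mu starts at 0.005, is multiplied
    by 10 on a rejected step and by 0.1 on acceptance, and overflowing
    ``mu_max`` halts training.
    """

    max_epochs: int = 1000
    max_validation_failures: int = 6
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    mu_init: float = 0.005
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    alpha_init: float = 0.0
    beta_init: float = 1.0
    gradient_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.max_validation_failures < 1:
            raise ValueError("max_validation_failures must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.mu_init, self.mu_increase, self.mu_decrease) <= 0:
            raise ValueError("damping controls must be positive")


@dataclass
class TrainRecord:
    """Per-epoch training trace and the reason training stopped."""

    epochs: list[dict] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1
    train_idx: np.ndarray = None
    val_idx: np.ndarray = None
    test_idx: np.ndarray = None

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def series(self, key: str) -> np.ndarray:
        return np.array([e[key] for e in self.epochs])


_EPS = 1e-12


def _objective(model: MLPRegressor, Xn, Yn, w, alpha, beta):
    model.set_params(w)
    out, _ = model._forward_normalized(Xn)
    e = (Yn - out).ravel()
    e_d = float(e @ e)
    e_w = float(w @ w)
    return beta * e_d + alpha * e_w, e_d, e_w, e


def _solve_step(JtJ, Jte, w, alpha, beta, mu):
    A = beta * JtJ + (alpha + mu) * np.eye(len(w))
    b = beta * Jte - alpha * w
    try:
        c, low = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve((c, low), b)
    except scipy.linalg.LinAlgError:
        return None


def train_bayesian_regularization(
    model: MLPRegressor,
    X,
    Y,
    config: TrainConfig = TrainConfig(),
    indices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[MLPRegressor, TrainRecord]:
    """Train the network in place; returns (model, TrainRecord).

    The data are split 70/15/15 (configurable) with the config seed, which
    also seeds the weight initialization; pass ``indices`` as explicit
    (train, validation, test) index arrays to override the random split.
    The trainer works entirely in normalized space; accepted
    Levenberg-Marquardt steps never increase the regularized objective F at
    the epoch's current (alpha, beta). On halting, the weights from the best
    validation epoch are restored.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must have equal row counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data must be finite")

    if indices is None:
        train_idx, val_idx, test_idx = split_data(
            X.shape[0], config.split_fractions, config.seed
        )
    else:
        train_idx, val_idx, test_idx = (np.asarray(i, int) for i in indices)
        if min(train_idx.size, val_idx.size) < 1:
            raise ValueError("explicit split needs nonempty training and validation sets")
    record = TrainRecord(train_idx=train_idx, val_idx=val_idx, test_idx=test_idx)

    model.set_normalization(X[train_idx], Y[train_idx])
    Xn, Yn = model.normalize_x(X[train_idx]), model.normalize_y(Y[train_idx])
    Xv, Yv = model.normalize_x(X[val_idx]), model.normalize_y(Y[val_idx])

    rng = np.random.default_rng(config.seed)
    model.init_weights(rng)
    w = model.get_params()
    n_params = w.size
    n_terms = Yn.size
    alpha, beta = float(config.alpha_init), float(config.beta_init)
    mu = config.mu_init
    f, e_d, e_w, e = _objective(model, Xn, Yn, w, alpha, beta)
    gamma = float(n_params)

    best_val = np.inf
    best_w = w.copy()
    fails = 0
    stop = ""

    for epoch in range(config.max_epochs):
        J = model.jacobian(Xn)
        JtJ = J.T @ J
        Jte = J.T @ e

        # evidence-framework hyperparameter update (skipped before the first
        # step when alpha_init keeps the objective data-only)
        if epoch > 0:
            H = 2.0 * beta * JtJ + 2.0 * alpha * np.eye(n_params)
            try:
                tr_hinv = float(np.trace(np.linalg.inv(H)))
            except np.linalg.LinAlgError:
                tr_hinv = float(np.trace(np.linalg.pinv(H)))
            gamma = min(max(n_params - 2.0 * alpha * tr_hinv, 0.0), float(n_params))
            alpha = gamma / max(2.0 * e_w, _EPS)
            beta = max(n_terms - gamma, _EPS) / max(2.0 * e_d, _EPS)
            f = beta * e_d + alpha * e_w

        grad = -2.0 * beta * Jte + 2.0 * alpha * w
        if float(np.max(np.abs(grad))) < config.gradient_floor:
            stop = "gradient_floor"
            break

        f_before = f
        accepted = False
        while mu <= config.mu_max:
            step = _solve_step(JtJ, Jte, w, alpha, beta, mu)
            if step is not None:
                f_try, e_d_try, e_w_try, e_try = _objective(
                    model, Xn, Yn, w + step, alpha, beta
                )
                if f_try < f:
                    w = w + step
                    f, e_d, e_w, e = f_try, e_d_try, e_w_try, e_try
                    mu = max(mu * config.mu_decrease, 1e-20)
                    accepted = True
                    break
            mu *= config.mu_increase
        model.set_params(w)
        if not accepted:
            stop = "gradient_floor"  # damping overflow: no descent direction left
            break

        out_v, _ = model._forward_normalized(Xv)
        val_error = float(np.mean((Yv - out_v) ** 2))
        if val_error < best_val:
            best_val = val_error
            best_w = w.copy()
            record.best_epoch = epoch
            fails = 0
        else:
            fails += 1

        record.epochs.append(
            {
                "epoch": epoch,
                "F_before": f_before,
                "F": f,
                "E_D": e_d,
                "E_W": e_w,
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "mu": mu,
                "val_error": val_error,
            }
        )

        if fails >= config.max_validation_failures:
            stop = "validation_failures"
            break

    record.stop_reason = stop or "max_epochs"
    model.set_params(best_w if np.isfinite(best_val) else w)
    model.trained = True
    return model, record


# ---------------------------------------------------------------------------
# the two stages and their cascade


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    cols = {c.lower(): c for c in table.columns}
    if name not in cols:
        raise ValueError(f"table lacks required column '{name}'")
    return table[cols[name]].to_numpy(float)


def fit_stage1_ppg_to_map(
    paired_table: pd.DataFrame,
    config: TrainConfig = TrainConfig(),
    n_hidden: int = 10,
) -> tuple[MLPRegressor, TrainRecord]:
    """Train the 1 -> n_hidden -> 1 network mapping averaged PPG to MAP."""
    ppg = _column(paired_table, "ppg")
    map_ = _column(paired_table, "map")
    if ppg.size < 30:
        raise ValueError("stage 1 requires at least 30 paired records")
    if np.ptp(ppg) == 0:
        raise ValueError("degenerate PPG input: no variance")
    model = MLPRegressor(1, n_hidden, 1)
    return train_bayesian_regularization(model, ppg[:, None], map_[:, None], config)


def fit_stage2_map_to_bp(
    cohort_table: pd.DataFrame,
    config: TrainConfig = TrainConfig(),
    n_hidden: int = 30,
) -> tuple[MLPRegressor, TrainRecord]:
    """Train the 1 -> n_hidden -> 2 network mapping MAP to (SBP, DBP)."""
    map_ = _column(cohort_table, "map")
    sbp = _column(cohort_table, "sbp")
    dbp = _column(cohort_table, "dbp")
    if np.ptp(map_) == 0:
        raise ValueError("degenerate MAP input: no variance")
    model = MLPRegressor(1, n_hidden, 2)
    return train_bayesian_regularization(
        model, map_[:, None], np.column_stack([sbp, dbp]), config
    )


@dataclass
class CombinatorialModel:
    """Cascade of the two stages: PPG -> MAP -> (SBP, DBP)."""

    stage1: MLPRegressor
    stage2: MLPRegressor

    def __post_init__(self) -> None:
        if self.stage1.n_output != self.stage2.n_input:
            raise ValueError("stage-1 output dimension must match stage-2 input")

    def predict_bp(self, ppg) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted (sbp, dbp, map_hat) for averaged PPG levels."""
        if not (self.stage1.trained and self.stage2.trained):
            raise ValueError("both stages must be trained before prediction")
        ppg = np.asarray(ppg, float).reshape(-1, 1)
        map_hat = self.stage1.forward(ppg)
        bp = self.stage2.forward(map_hat)
        return bp[:, 0], bp[:, 1], map_hat[:, 0]

    def to_json(self, path=None) -> str:
        doc = {"stage1": self.stage1.to_dict(), "stage2": self.stage2.to_dict()}
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CombinatorialModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            MLPRegressor.from_dict(doc["stage1"]),
            MLPRegressor.from_dict(doc["stage2"]),
        )
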