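"""Feed-forward AUC regressor with gene-addressable first-layer transfer.

Architecture: dense(n_genes -> H1, sigmoid) -> dropout -> dense(H1 -> H2,
softplus) -> dropout -> dense(H2 -> 1, softplus). The softplus output keeps
predictions non-negative, matching the normalized AUC target range [0, 10].
Training minimizes mean squared error plus an L2 penalty on every weight
matrix and bias, with minibatch Adam. All randomness (initialization, batch
shuffling, dropout masks) derives from the config seed, so (build, train,
predict) is a pure function of (config, data).

Transfer between cohorts moves only the first dense layer: rows of ``W1`` are
addressed by gene id, never by position, so a source model trained on one
gene space can initialize a target model built on an intersecting, reordered
or smaller gene space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .containers import (AlignmentError, DataError, DrugScreenDataset,
                         ExpressionMatrix, InputLayerWeights)


class ConfigError(ValueError):
    """Invalid network configuration."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _dsigmoid(x: np.ndarray) -> np.ndarray:
    s = expit(x)
    return s * (1.0 - s)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _dsoftplus(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _linear(x: np.ndarray) -> np.ndarray:
    return x


def _dlinear(x: np.ndarray) -> np.ndarray:
    return np.ones_like(x)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _drelu(x: np.ndarray) -> np.ndarray:
    return (x > 0).astype(x.dtype)


ACTIVATIONS = {
    "sigmoid": (_sigmoid, _dsigmoid),
    "softplus": (_softplus, _dsoftplus),
    "linear": (_linear, _dlinear),
    "relu": (_relu, _drelu),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyper-parameters of the regressor.

    Defaults follow the modelled design: hidden widths 1000 and 100,
    activations sigmoid/softplus/softplus, dropout 0.3 and 0.1 after the two
    hidden layers, L2 strength 1e-4 on all weights and biases, uniform
    initialization in +-0.05, MSE loss. Optimizer settings (Adam, learning
    rate, epochs, batch size) are exposed because no single published value
    fits every cohort size; ``grid_search`` in the pipeline module tunes them
    by cross-validation on the source cohort.
    """

    n_genes: int
    hidden_sizes: tuple[int, int] = (1000, 100)
    activations: tuple[str, str, str] = ("sigmoid", "softplus", "softplus")
    dropout: tuple[float, float] = (0.3, 0.1)
    reg_strength: float = 1e-4
    init_bounds: tuple[float, float] = (-0.05, 0.05)
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if any(h < 1 for h in self.hidden_sizes) or len(self.hidden_sizes) != 2:
            raise ConfigError("hidden_sizes must be two positive integers")
        if any(not 0.0 <= d < 1.0 for d in self.dropout):
            raise ConfigError("dropout fractions must lie in [0, 1)")
        if self.reg_strength < 0:
            raise ConfigError("reg_strength must be non-negative")
        if not self.init_bounds[0] < self.init_bounds[1]:
            raise ConfigError("init_bounds must satisfy lo < hi")
        for a in self.activations:
            if a not in ACTIVATIONS:
                raise ConfigError(f"unknown activation '{a}'")
        if self.loss != "mse":
            raise ConfigError("only the 'mse' loss is supported")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError("optimizer must be 'adam' or 'sgd'")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch_size >= 1")

    def param_count(self) -> int:
        """Total trainable parameters: n*H1+H1 + H1*H2+H2 + H2+1."""
        h1, h2 = self.hidden_sizes
        return self.n_genes * h1 + h1 + h1 * h2 + h2 + h2 + 1

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "hidden_sizes": list(self.hidden_sizes),
            "activations": list(self.activations),
            "dropout": list(self.dropout),
            "reg_strength": self.reg_strength,
            "init_bounds": list(self.init_bounds),
            "loss": self.loss,
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("hidden_sizes", "activations", "dropout", "init_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ModelState:
    """A configured network plus its parameter tensors and training log."""

    config: NetworkConfig
    parameters: dict[str, np.ndarray]
    training_log: list[float] = field(default_factory=list)
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        h1, h2 = self.config.hidden_sizes
        expected = {"W1": (self.config.n_genes, h1), "b1": (h1,),
                    "W2": (h1, h2), "b2": (h2,),
                    "W3": (h2, 1), "b3": (1,)}
        for name, shape in expected.items():
            if name not in self.parameters:
                raise ConfigError(f"missing parameter tensor '{name}'")
            arr = np.asarray(self.parameters[name], dtype=np.float64)
            if arr.shape != shape:
                raise ConfigError(
                    f"parameter '{name}' has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"parameter '{name}' contains non-finite values")
            self.parameters[name] = arr
        if self.gene_ids is not None and len(self.gene_ids) != self.config.n_genes:
            raise ConfigError("gene_ids length does not match n_genes")

    def copy(self) -> "ModelState":
        return ModelState(self.config,
                          {k: v.copy() for k, v in self.parameters.items()},
                          list(self.training_log),
                          None if self.gene_ids is None else list(self.gene_ids))


def build_model(config: NetworkConfig,
                gene_ids: list[str] | None = None) -> ModelState:
    """Initialize all parameters from the seeded uniform distribution."""
    if gene_ids is not None and len(gene_ids) != config.n_genes:
        raise ConfigError(
            f"{len(gene_ids)} gene ids given but config.n_genes={config.n_genes}")
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.init_bounds
    h1, h2 = config.hidden_sizes
    shapes = {"W1": (config.n_genes, h1), "b1": (h1,),
              "W2": (h1, h2), "b2": (h2,),
              "W3": (h2, 1), "b3": (1,)}
    params = {name: rng.uniform(lo, hi, size=shape)
              for name, shape in shapes.items()}
    return ModelState(config, params, [], list(gene_ids) if gene_ids else None)


def _forward(params: dict, config: NetworkConfig, X: np.ndarray,
             rng: np.random.Generator | None = None):
    """Forward pass; dropout is active only when a training rng is supplied."""
    a1, _ = ACTIVATIONS[config.activations[0]]
    a2, _ = ACTIVATIONS[config.activations[1]]
    a3, _ = ACTIVATIONS[config.activations[2]]
    d1, d2 = config.dropout
    z1 = X @ params["W1"] + params["b1"]
    h1 = a1(z1)
    if rng is not None and d1 > 0:
        m1 = (rng.random(h1.shape) >= d1) / (1.0 - d1)
        h1 = h1 * m1
    z2 = h1 @ params["W2"] + params["b2"]
    h2 = a2(z2)
    if rng is not None and d2 > 0:
        m2 = (rng.random(h2.shape) >= d2) / (1.0 - d2)
        h2 = h2 * m2
    z3 = h2 @ params["W3"] + params["b3"]
    out = a3(z3)
    return z1, h1, z2, h2, z3, out


def predict(model: ModelState, expr: ExpressionMatrix) -> np.ndarray:
    """Point predictions (one per sample); dropout disabled, output >= 0."""
    if model.gene_ids is not None and expr.gene_ids != model.gene_ids:
        raise AlignmentError(
            "expression gene ids/order do not match the model's gene space; "
            "reorder explicitly before predicting")
    if expr.n_genes != model.config.n_genes:
        raise AlignmentError(
            f"matrix has {expr.n_genes} genes, model expects {model.config.n_genes}")
    X = expr.values.T
    *_, out = _forward(model.parameters, model.config, X)
    return out[:, 0]


def train(model: ModelState, ds: DrugScreenDataset,
          require_normalized: bool = True) -> ModelState:
    """Train a copy of ``model`` on ``ds`` by minibatch gradient descent.

    The dataset's gene order must match the model's gene space exactly
    (never silently reordered). Returns a new ModelState whose
    ``training_log`` holds one data-term MSE per epoch; with
    ``config.epochs == 0`` the returned model predicts identically to the
    input model.
    """
    config = model.config
    if model.gene_ids is not None and ds.gene_ids != model.gene_ids:
        raise AlignmentError(
            "dataset gene ids/order do not match the model's gene space")
    if ds.expression.n_genes != config.n_genes:
        raise AlignmentError(
            f"dataset has {ds.expression.n_genes} genes, model expects "
            f"{config.n_genes}")
    if require_normalized and not ds.response.normalized:
        raise DataError("response must be min-max normalized before training")

    out = model.copy()
    if out.gene_ids is None:
        out.gene_ids = list(ds.gene_ids)
    params = out.parameters
    X = ds.expression.values.T
    y = ds.response.auc
    n = X.shape[0]
    rng = np.random.default_rng([config.seed, 1])

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lam = config.reg_strength

    _, da1 = ACTIVATIONS[config.activations[0]]
    _, da2 = ACTIVATIONS[config.activations[1]]
    _, da3 = ACTIVATIONS[config.activations[2]]

    log: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_sse = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            nb = len(idx)
            z1, h1, z2, h2, z3, pred = _forward(params, config, Xb, rng)
            resid = pred[:, 0] - yb
            epoch_sse += float(np.sum(resid ** 2))
            # backprop of mean squared error
            dz3 = (2.0 / nb) * resid[:, None] * da3(z3)
            gW3 = h2.T @ dz3 + 2.0 * lam * params["W3"]
            gb3 = dz3.sum(axis=0) + 2.0 * lam * params["b3"]
            dh2 = dz3 @ params["W3"].T
            dz2 = dh2 * da2(z2)
            gW2 = h1.T @ dz2 + 2.0 * lam * params["W2"]
            gb2 = dz2.sum(axis=0) + 2.0 * lam * params["b2"]
            dh1 = dz2 @ params["W2"].T
            dz1 = dh1 * da1(z1)
            gW1 = Xb.T @ dz1 + 2.0 * lam * params["W1"]
            gb1 = dz1.sum(axis=0) + 2.0 * lam * params["b1"]
            grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
                     "W3": gW3, "b3": gb3}
            if config.optimizer == "adam":
                t += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mh = m[k] / (1 - beta1 ** t)
                    vh = v[k] / (1 - beta2 ** t)
                    params[k] -= config.learning_rate * mh / (np.sqrt(vh) + eps)
            else:  # plain sgd
                for k in params:
                    params[k] -= config.learning_rate * grads[k]
        log.append(epoch_sse / n)
    out.training_log = log if config.epochs > 0 else list(model.training_log)
    return out


def training_mse(model: ModelState, ds: DrugScreenDataset) -> float:
    """Data-term MSE of the model on a dataset (no dropout, no penalty)."""
    pred = predict(model, ds.expression)
    return float(np.mean((pred - ds.response.auc) ** 2))


def extract_input_layer(model: ModelState,
                        gene_ids: list[str] | None = None) -> InputLayerWeights:
    """Copy out (gene_ids, W1, b1); mutating the copy never affects the model."""
    if gene_ids is None:
        gene_ids = model.gene_ids
    if gene_ids is None:
        raise ConfigError("model carries no gene ids; pass gene_ids explicitly")
    if len(gene_ids) != model.config.n_genes:
        raise ConfigError(
            f"{len(gene_ids)} gene ids given for a model with "
            f"{model.config.n_genes} input genes")
    return InputLayerWeights(list(gene_ids), model.parameters["W1"].copy(),
                             model.parameters["b1"].copy())


def inject_input_layer(model: ModelState, w: InputLayerWeights) -> ModelState:
    """Initialize the first dense layer of a copy of ``model`` from ``w``.

    Rows are matched by gene id: every model gene must be present in ``w``
    (strict mode; missing genes raise, listing them), source genes absent
    from the model are ignored, and upper layers are untouched. All
    parameters remain trainable afterwards.
    """
    if model.gene_ids is None:
        raise ConfigError("model carries no gene ids; cannot align by gene")
    if w.hidden_size != model.config.hidden_sizes[0]:
        raise ConfigError(
            f"hidden width mismatch: source H1={w.hidden_size}, "
            f"model H1={model.config.hidden_sizes[0]}")
    src_index = {g: i for i, g in enumerate(w.gene_ids)}
    missing = [g for g in model.gene_ids if g not in src_index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} model gene(s) absent from source weights: "
            f"{missing[:10]}")
    out = model.copy()
    rows = [src_index[g] for g in model.gene_ids]
    out.parameters["W1"] = w.W[rows, :].copy()
    out.parameters["b1"] = w.b.copy()
    return out


def with_seed(config: NetworkConfig, seed: int) -> NetworkConfig:
    """Convenience: same architecture/hyper-parameters, different seed."""
    return replace(config, seed=int(seed))
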