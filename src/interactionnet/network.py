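"""Forward computation of the two-graph interaction network.

The model stacks five functional stages::

    X -> node embedding -> covalent convolutions -> noncovalent convolutions
      -> sum pooling -> fully-connected head -> pKd

Node embedding is two row-local dense+ReLU layers.  Each graph convolution
is residual: ``X_out = X_in + ReLU(A @ X_in @ W)`` with A either the fixed
covalent adjacency (CV_C) or the fixed noncovalent adjacency (CV_NC); the
adjacencies carry no self-loops and are not normalized, self-information
flows through the residual branch.  Sum pooling collapses atoms to one
molecular vector; a two-layer dense+ReLU head emits the scalar prediction
(nonnegative, consistent with pKd targets).

Three variants differ only in which convolution types are present:
``C`` (covalent only), ``NC`` (noncovalent only), ``C-NC`` (covalent layers
first, then noncovalent).  Every intermediate activation is cached in an
:class:`ActivationTrace` so relevance propagation can replay the pass.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graphs import ComplexGraph

VARIANTS = ("C", "NC", "C-NC")


@dataclass(frozen=True)
class VariantSpec:
    """Architecture of one model variant."""

    name: str = "C-NC"
    n_cov_layers: int = 1
    n_nc_layers: int = 1
    hidden_dim: int = 128

    def __post_init__(self) -> None:
        if self.name not in VARIANTS:
            raise ValueError(f"unknown variant {self.name!r}")
        if self.name == "C" and self.n_nc_layers != 0:
            object.__setattr__(self, "n_nc_layers", 0)
        if self.name == "NC" and self.n_cov_layers != 0:
            object.__setattr__(self, "n_cov_layers", 0)
        if self.name == "C" and self.n_cov_layers < 1:
            raise ValueError("variant C needs >= 1 covalent layer")
        if self.name == "NC" and self.n_nc_layers < 1:
            raise ValueError("variant NC needs >= 1 noncovalent layer")
        if self.name == "C-NC" and (self.n_cov_layers < 1 or self.n_nc_layers < 1):
            raise ValueError("variant C-NC needs >= 1 layer of each type")

    @classmethod
    def for_variant(cls, name: str, n_layers: int = 1, hidden_dim: int = 128):
        if name == "C":
            return cls(name, n_layers, 0, hidden_dim)
        if name == "NC":
            return cls(name, 0, n_layers, hidden_dim)
        return cls(name, n_layers, n_layers, hidden_dim)


@dataclass
class ModelParams:
    """All trainable weights and biases of one variant."""

    W_ne1: np.ndarray
    b_ne1: np.ndarray
    W_ne2: np.ndarray
    b_ne2: np.ndarray
    W_c: list[np.ndarray]
    W_nc: list[np.ndarray]
    W_fc1: np.ndarray
    b_fc1: np.ndarray
    W_fc2: np.ndarray
    b_fc2: np.ndarray

    def named(self) -> dict[str, np.ndarray]:
        out = {
            "W_ne1": self.W_ne1, "b_ne1": self.b_ne1,
            "W_ne2": self.W_ne2, "b_ne2": self.b_ne2,
            "W_fc1": self.W_fc1, "b_fc1": self.b_fc1,
            "W_fc2": self.W_fc2, "b_fc2": self.b_fc2,
        }
        for k, w in enumerate(self.W_c):
            out[f"W_c{k}"] = w
        for k, w in enumerate(self.W_nc):
            out[f"W_nc{k}"] = w
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.W_ne1.copy(), self.b_ne1.copy(),
            self.W_ne2.copy(), self.b_ne2.copy(),
            [w.copy() for w in self.W_c],
            [w.copy() for w in self.W_nc],
            self.W_fc1.copy(), self.b_fc1.copy(),
            self.W_fc2.copy(), self.b_fc2.copy(),
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(
    n_features: int, v: VariantSpec, seed: int = 0, output_bias: float = 1.0
) -> ModelParams:
    """Glorot-uniform initialization, deterministic per seed.

    The output layer starts with zero weights and a small positive bias:
    the prediction is clamped nonnegative by its outer ReLU, and a random
    first layer easily starts (and then stays) in the dead regime where no
    gradient flows.  Starting at a small positive constant keeps the output
    unit active; its weights receive gradient from the first step.
    """
    rng = np.random.default_rng(seed)
    h = v.hidden_dim
    return ModelParams(
        W_ne1=_glorot(rng, n_features, h), b_ne1=np.zeros(h),
        W_ne2=_glorot(rng, h, h), b_ne2=np.zeros(h),
        W_c=[_glorot(rng, h, h) for _ in range(v.n_cov_layers)],
        W_nc=[_glorot(rng, h, h) for _ in range(v.n_nc_layers)],
        W_fc1=_glorot(rng, h, h), b_fc1=np.zeros(h),
        W_fc2=np.zeros((h, 1)), b_fc2=np.full(1, float(output_bias)),
    )


@dataclass
class ConvRecord:
    """One residual convolution step, as executed."""

    kind: str                 # "C" or "NC"
    A: np.ndarray             # adjacency actually used (not copied)
    W: np.ndarray
    X_in: np.ndarray
    Z: np.ndarray             # pre-activation A @ X_in @ W
    X_out: np.ndarray         # X_in + relu(Z)


@dataclass
class ActivationTrace:
    """Every intermediate of one forward pass (inputs to the next stage)."""

    X: np.ndarray
    Z_ne1: np.ndarray
    H_ne1: np.ndarray
    Z_ne2: np.ndarray
    X_ne: np.ndarray
    convs: list[ConvRecord] = field(default_factory=list)
    X_last: np.ndarray | None = None
    X_gp: np.ndarray | None = None
    z_fc1: np.ndarray | None = None
    h_fc1: np.ndarray | None = None
    z_fc2: np.ndarray | None = None
    y_hat: float = 0.0


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def node_embed(X: np.ndarray, p: ModelParams) -> np.ndarray:
    """Two dense+ReLU layers applied row-locally (no cross-atom mixing)."""
    return relu(relu(X @ p.W_ne1 + p.b_ne1) @ p.W_ne2 + p.b_ne2)


def graph_conv(X_in: np.ndarray, A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Residual graph convolution ``X_in + ReLU(A @ X_in @ W)``."""
    return X_in + relu(A @ X_in @ W)


def global_pool(X_last: np.ndarray) -> np.ndarray:
    """Sum pooling: permutation-invariant column sums."""
    if X_last.shape[0] < 1:
        raise ValueError("cannot pool an empty graph")
    return X_last.sum(axis=0)


def fc_head(X_gp: np.ndarray, p: ModelParams) -> float:
    """Two dense+ReLU layers mapping the pooled vector to the prediction."""
    return float(relu(relu(X_gp @ p.W_fc1 + p.b_fc1) @ p.W_fc2 + p.b_fc2)[0])


def forward(
    g: ComplexGraph, p: ModelParams, v: VariantSpec
) -> tuple[float, ActivationTrace]:
    """Full forward pass, caching every intermediate activation."""
    if len(p.W_c) != v.n_cov_layers or len(p.W_nc) != v.n_nc_layers:
        raise ValueError("parameter layer counts do not match the variant")
    X = np.asarray(g.X, dtype=float)
    z1 = X @ p.W_ne1 + p.b_ne1
    h1 = relu(z1)
    z2 = h1 @ p.W_ne2 + p.b_ne2
    x_ne = relu(z2)
    trace = ActivationTrace(X=X, Z_ne1=z1, H_ne1=h1, Z_ne2=z2, X_ne=x_ne)

    x = x_ne
    for kind, A, weights in (("C", g.A_C, p.W_c), ("NC", g.A_NC, p.W_nc)):
        for W in weights:
            z = A @ x @ W
            x_out = x + relu(z)
            trace.convs.append(ConvRecord(kind, A, W, x, z, x_out))
            x = x_out

    trace.X_last = x
    trace.X_gp = global_pool(x)
    trace.z_fc1 = trace.X_gp @ p.W_fc1 + p.b_fc1
    trace.h_fc1 = relu(trace.z_fc1)
    trace.z_fc2 = trace.h_fc1 @ p.W_fc2 + p.b_fc2
    trace.y_hat = float(relu(trace.z_fc2)[0])
    return trace.y_hat, trace


def predict(g: ComplexGraph, p: ModelParams, v: VariantSpec) -> float:
    return forward(g, p, v)[0]


# ---- checkpoint I/O -----------------------------------------------------


def save_checkpoint(
    path: str | Path,
    p: ModelParams,
    v: VariantSpec,
    feature_config=None,
) -> None:
    """Single-archive checkpoint with a JSON header (variant, shapes)."""
    header = {
        "variant": v.name,
        "n_cov_layers": v.n_cov_layers,
        "n_nc_layers": v.n_nc_layers,
        "hidden_dim": v.hidden_dim,
        "feature_config": (
            feature_config.to_dict() if feature_config is not None else None
        ),
        "feature_config_hash": (
            feature_config.config_hash() if feature_config is not None else ""
        ),
        "shapes": {k: list(w.shape) for k, w in p.named().items()},
    }
    arrays = {k: w for k, w in p.named().items()}
    np.savez(path, __header__=np.array(json.dumps(header)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, VariantSpec, dict]:
    with np.load(path) as z:
        header = json.loads(str(z["__header__"]))
        v = VariantSpec(
            header["variant"],
            header["n_cov_layers"],
            header["n_nc_layers"],
            header["hidden_dim"],
        )
        p = ModelParams(
            W_ne1=z["W_ne1"], b_ne1=z["b_ne1"],
            W_ne2=z["W_ne2"], b_ne2=z["b_ne2"],
            W_c=[z[f"W_c{k}"] for k in range(v.n_cov_layers)],
            W_nc=[z[f"W_nc{k}"] for k in range(v.n_nc_layers)],
            W_fc1=z["W_fc1"], b_fc1=z["b_fc1"],
            W_fc2=z["W_fc2"], b_fc2=z["b_fc2"],
        )
    return p, v, header
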