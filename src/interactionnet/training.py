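"""Dataset splitting, gradient-based fitting and RMSE evaluation.

Training minimizes mean-squared error on pKd with Adam, under the schedule:
learning rate starts at 1.5e-4 and is multiplied by 0.75 whenever the
validation loss has not improved for 200 consecutive epochs; training stops
when it has not improved for 400 epochs.  Gradients are clipped by global
L2 norm at 0.5.  The parameters with the lowest validation loss are
returned.

Cross-validation uses repeated random sub-sampling: each of the 20 folds is
an independent random 8:1:1 train/validation/test partition of the ids (not
disjoint-fold CV).

Gradients are computed by reverse-mode differentiation of the exact forward
pass, written out by hand; minibatches accumulate per-graph gradients, which
is value-identical to block-diagonal batching because sum pooling acts per
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import ComplexGraph
from .network import ActivationTrace, ModelParams, VariantSpec, forward, init_params


@dataclass(frozen=True)
class SplitPlan:
    """One random 8:1:1 partition of complex ids."""

    fold_id: int
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (defaults follow the training protocol)."""

    initial_lr: float = 0.00015
    lr_factor: float = 0.75
    lr_patience: int = 200
    stop_patience: int = 400
    grad_clip_norm: float = 0.5
    batch_size: int = 32
    max_epochs: int = 10000
    train_loss_target: float | None = None  # optional early exit on train MSE

    def __post_init__(self) -> None:
        if not (0.0 < self.lr_factor < 1.0):
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patience values must be positive")


def make_splits(
    ids: list[str],
    n_folds: int = 20,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> list[SplitPlan]:
    """Repeated random sub-sampling partitions, deterministic per seed."""
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 ids for an 8:1:1 split")
    total = sum(ratio)
    n_val = max(1, round(n * ratio[1] / total))
    n_test = max(1, round(n * ratio[2] / total))
    plans = []
    for fold, ss in enumerate(np.random.SeedSequence(seed).spawn(n_folds)):
        rng = np.random.default_rng(ss)
        perm = [ids[i] for i in rng.permutation(n)]
        plans.append(
            SplitPlan(
                fold_id=fold,
                test=tuple(perm[:n_test]),
                validation=tuple(perm[n_test : n_test + n_val]),
                train=tuple(perm[n_test + n_val :]),
                seed=seed,
            )
        )
    return plans


# ---- reverse-mode gradients --------------------------------------------


def _zero_grads(p: ModelParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(w) for k, w in p.named().items()}


def _backward(
    g: ComplexGraph,
    p: ModelParams,
    trace: ActivationTrace,
    dy: float,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate d(loss)/d(params) for one graph given d(loss)/d(y_hat)."""
    # output layer: y = relu(z2), z2 = h1 @ W_fc2 + b_fc2
    dz2 = np.array([dy]) * (trace.z_fc2 > 0)
    grads["W_fc2"] += np.outer(trace.h_fc1, dz2)
    grads["b_fc2"] += dz2
    dh1 = p.W_fc2 @ dz2
    dz1 = dh1 * (trace.z_fc1 > 0)
    grads["W_fc1"] += np.outer(trace.X_gp, dz1)
    grads["b_fc1"] += dz1
    dgp = p.W_fc1 @ dz1
    # sum pooling broadcasts the pooled gradient to every atom row
    dx = np.tile(dgp, (trace.X_last.shape[0], 1))

    n_c = len(p.W_c)
    for k in range(len(trace.convs) - 1, -1, -1):
        rec = trace.convs[k]
        dz = dx * (rec.Z > 0)
        key = f"W_c{k}" if rec.kind == "C" else f"W_nc{k - n_c}"
        grads[key] += (rec.A @ rec.X_in).T @ dz
        dx = dx + rec.A.T @ dz @ rec.W.T

    dz_ne2 = dx * (trace.Z_ne2 > 0)
    grads["W_ne2"] += trace.H_ne1.T @ dz_ne2
    grads["b_ne2"] += dz_ne2.sum(axis=0)
    dh_ne1 = dz_ne2 @ p.W_ne2.T
    dz_ne1 = dh_ne1 * (trace.Z_ne1 > 0)
    grads["W_ne1"] += trace.X.T @ dz_ne1
    grads["b_ne1"] += dz_ne1.sum(axis=0)


def _clip_by_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(v * v)) for v in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for v in grads.values():
            v *= scale


class _Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, p: ModelParams, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = _zero_grads(p)
        self.v = _zero_grads(p)
        self.t = 0

    def step(self, p: ModelParams, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        named = p.named()
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, grad in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grad * grad
            named[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


@dataclass
class FitHistory:
    """Per-epoch optimization record."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _dataset_mse(graphs, p: ModelParams, v: VariantSpec) -> float:
    errs = [(forward(g, p, v)[0] - g.label) ** 2 for g in graphs]
    return float(np.mean(errs))


def fit(
    train_graphs: list[ComplexGraph],
    val_graphs: list[ComplexGraph],
    v: VariantSpec,
    tc: TrainingConfig | None = None,
    seed: int = 0,
) -> tuple[ModelParams, FitHistory]:
    """Fit one model; returns the best-validation parameters and history.

    Deterministic given the seed (initialization and shuffling both derive
    from it).  Raises on divergence (non-finite loss).
    """
    tc = tc or TrainingConfig()
    if not train_graphs:
        raise ValueError("empty training set")
    n_feat = train_graphs[0].X.shape[1]
    if any(g.X.shape[1] != n_feat for g in train_graphs + val_graphs):
        raise ValueError("graphs disagree on feature dimensionality")
    if any(g.label is None for g in train_graphs + val_graphs):
        raise ValueError("all graphs must be labeled")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    params = init_params(n_feat, v, seed=seed)
    opt = _Adam(params)
    history = FitHistory()

    lr = tc.initial_lr
    best_val = np.inf
    best_params = params.copy()
    since_improve = 0
    since_lr_drop = 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(train_graphs))
        epoch_sq = 0.0
        for start in range(0, len(order), tc.batch_size):
            batch = [train_graphs[i] for i in order[start : start + tc.batch_size]]
            grads = _zero_grads(params)
            for g in batch:
                y_hat, trace = forward(g, params, v)
                err = y_hat - g.label
                epoch_sq += err * err
                _backward(g, params, trace, 2.0 * err / len(batch), grads)
            _clip_by_global_norm(grads, tc.grad_clip_norm)
            opt.step(params, grads, lr)
        train_loss = epoch_sq / len(order)
        val_loss = (
            _dataset_mse(val_graphs, params, v) if val_graphs else train_loss
        )
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} "
                f"(train={train_loss}, val={val_loss})"
            )
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(lr)

        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
            history.best_epoch = epoch
            since_improve = 0
            since_lr_drop = 0
        else:
            since_improve += 1
            since_lr_drop += 1

        if tc.train_loss_target is not None and train_loss < tc.train_loss_target:
            # the running epoch loss is averaged over pre-update minibatch
            # losses; confirm with the final parameters before stopping
            if _dataset_mse(train_graphs, params, v) < tc.train_loss_target:
                best_params = params.copy()
                history.best_epoch = epoch
                break
        if since_improve >= tc.stop_patience:
            break
        if since_lr_drop >= tc.lr_patience:
            lr *= tc.lr_factor
            since_lr_drop = 0

    history.stopped_epoch = len(history.train_loss) - 1
    return best_params, history


def evaluate_rmse(
    p: ModelParams, v: VariantSpec, graphs: list[ComplexGraph]
) -> float:
    """Root-mean-square prediction error in pKd units."""
    if not graphs:
        raise ValueError("need at least one graph")
    sq = [(forward(g, p, v)[0] - g.label) ** 2 for g in graphs]
    return float(np.sqrt(np.mean(sq)))


def run_fold(
    graphs_by_id: dict[str, ComplexGraph],
    plan: SplitPlan,
    v: VariantSpec,
    tc: TrainingConfig | None = None,
    seed: int = 0,
) -> dict:
    """Train on one split plan and report train/val/test RMSE."""
    train = [graphs_by_id[i] for i in plan.train]
    val = [graphs_by_id[i] for i in plan.validation]
    test = [graphs_by_id[i] for i in plan.test]
    params, history = fit(train, val, v, tc, seed=seed + plan.fold_id)
    return {
        "fold": plan.fold_id,
        "train_rmse": evaluate_rmse(params, v, train),
        "val_rmse": evaluate_rmse(params, v, val),
        "test_rmse": evaluate_rmse(params, v, test),
        "params": params,
        "history": history,
    }
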