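"""Layer-wise relevance propagation down to signed per-atom contributions.

The prediction is decomposed by propagating relevance backward through the
network, one layer at a time.  For a linear layer with inputs ``a_j``,
weights ``w_jk`` and pre-activations ``z_k = sum_j a_j w_jk + b_k``:

* LRP-0:   ``R_j = sum_k a_j w_jk / z_k * R_k``
* LRP-eps: adds a signed stabilizer, ``z_k + eps * sign(z_k)``, to the
  denominator (eps = 0 recovers LRP-0);
* LRP-gamma: replaces ``w_jk`` by ``w_jk + gamma * max(w_jk, 0)`` in both
  numerator and denominator (gamma = 0 recovers LRP-0).

The bias participates in the denominator as a virtual input (a_0 = 1,
w_0k = b_k) and its relevance share is absorbed.  Rule assignment: LRP-0 on
the output layer, LRP-eps (eps = 0.25) on the remaining dense head layers,
LRP-gamma (gamma = 100) on the graph convolutions.  Sum pooling
redistributes each pooled feature's relevance proportionally to the atoms'
activations.  The node-embedding layers are skipped: they are row-local, so
they only shuffle relevance between the features of one atom and cannot
change the per-atom totals.  Relevance at the embedded representation is
summed over features to give one signed contribution per atom (positive =
pushes the predicted affinity up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import ComplexGraph
from .network import ActivationTrace, ModelParams, VariantSpec, forward

#: denominators within this of zero short-circuit to zero relevance flow
DENOM_GUARD = 1e-12

LRP0 = "LRP0"
LRPEPS = "LRPeps"
LRPGAMMA = "LRPgamma"


@dataclass(frozen=True)
class LRPConfig:
    """Stabilizer and positive-weight boost for the propagation rules."""

    epsilon: float = 0.25
    gamma: float = 100.0

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.gamma < 0:
            raise ValueError("epsilon and gamma must be nonnegative")


@dataclass
class AtomContribution:
    """Signed per-atom relevance for one prediction."""

    complex_id: str
    variant: str
    values: np.ndarray          # length n_ligand + n_protein
    n_ligand: int
    y_hat: float
    config: LRPConfig = field(default_factory=LRPConfig)


def _safe_ratio(numer: np.ndarray, denom: np.ndarray) -> np.ndarray:
    out = np.zeros_like(numer)
    ok = np.abs(denom) > DENOM_GUARD
    out[ok] = numer[ok] / denom[ok]
    return out


def lrp_linear(
    R_k: np.ndarray,
    a: np.ndarray,
    W: np.ndarray,
    b: np.ndarray | None,
    rule: str = LRP0,
    cfg: LRPConfig | None = None,
) -> np.ndarray:
    """Propagate relevance backward through one dense layer.

    ``a`` is the layer input (length J), ``W`` is J x K, ``b`` length K (or
    None for no bias), ``R_k`` length K.  Returns relevance length J.
    """
    cfg = cfg or LRPConfig()
    if rule == LRPGAMMA:
        W_eff = W + cfg.gamma * np.maximum(W, 0.0)
    else:
        W_eff = W
    contrib = a[:, None] * W_eff            # J x K
    z = contrib.sum(axis=0)
    if b is not None:
        if rule == LRPGAMMA:
            z = z + b + cfg.gamma * np.maximum(b, 0.0)
        else:
            z = z + b
    if rule == LRPEPS:
        z = z + cfg.epsilon * np.sign(z)
    return contrib @ _safe_ratio(R_k, z)


def lrp_pool(R_gp: np.ndarray, X_last: np.ndarray) -> np.ndarray:
    """Backward step for sum pooling: proportional redistribution.

    Feature f's pooled relevance is split over atoms in proportion to
    ``X_last[i, f]``; features whose column sums to (near) zero contributed
    nothing and receive nothing.
    """
    col = X_last.sum(axis=0)
    share = _safe_ratio(R_gp, col)
    return X_last * share[None, :]


def lrp_conv(
    R_out: np.ndarray,
    X_in: np.ndarray,
    A: np.ndarray,
    W: np.ndarray,
    cfg: LRPConfig | None = None,
    Z: np.ndarray | None = None,
) -> np.ndarray:
    """Backward step for a residual convolution ``X_out = X_in + ReLU(AXW)``.

    Each output entry's relevance splits between the identity branch
    (contribution ``X_in``) and the convolution branch (contribution
    ``ReLU(AXW)``) in proportion to those two nonnegative contributions.
    Identity relevance passes through unchanged.  Branch relevance is
    propagated by LRP-gamma over the composite linear map with effective
    weight ``A[k,i] * W[f,f']`` (A is binary, so the positive part is
    ``A[k,i] * max(W,0)[f,f']``), then the two flows are summed at X_in.
    """
    cfg = cfg or LRPConfig()
    if Z is None:
        Z = A @ X_in @ W
    B = np.maximum(Z, 0.0)
    X_out = X_in + B
    frac_branch = _safe_ratio(B, X_out)
    R_id = R_out * _safe_ratio(X_in, X_out)
    R_branch = R_out * frac_branch

    W_g = W + cfg.gamma * np.maximum(W, 0.0)
    z_g = A @ X_in @ W_g                      # gamma-modified pre-activations
    S = _safe_ratio(R_branch, z_g)
    # numerator X_in[i,f] * A[k,i] * W_g[f,f'] summed over (k,f') against S
    R_in_branch = X_in * (A.T @ S @ W_g.T)
    return R_id + R_in_branch


def explain(
    g: ComplexGraph,
    p: ModelParams,
    v: VariantSpec,
    cfg: LRPConfig | None = None,
    trace: ActivationTrace | None = None,
) -> AtomContribution:
    """Decompose one prediction into signed per-atom contributions.

    Seeds the output relevance at the predicted value, applies LRP-0 to the
    output layer, LRP-eps to the remaining head layer, proportional
    redistribution through sum pooling, then LRP-gamma through each
    convolution in reverse order, and finally sums relevance across features
    per atom at the embedded representation.
    """
    cfg = cfg or LRPConfig()
    if trace is None:
        _, trace = forward(g, p, v)

    # output layer (LRP-0), seeded with y_hat itself
    R = np.array([trace.y_hat])
    R = lrp_linear(R, trace.h_fc1, p.W_fc2, p.b_fc2, rule=LRP0, cfg=cfg)
    # remaining head layer (LRP-eps)
    R = lrp_linear(R, trace.X_gp, p.W_fc1, p.b_fc1, rule=LRPEPS, cfg=cfg)
    # sum pooling
    R = lrp_pool(R, trace.X_last)
    # convolutions, newest first (LRP-gamma)
    for rec in reversed(trace.convs):
        R = lrp_conv(R, rec.X_in, rec.A, rec.W, cfg=cfg, Z=rec.Z)
    # node embedding skipped: row-local, per-atom totals unchanged
    values = R.sum(axis=1)
    return AtomContribution(
        complex_id=g.complex_id,
        variant=v.name,
        values=values,
        n_ligand=g.n_ligand,
        y_hat=trace.y_hat,
        config=cfg,
    )


def contributions_frame(contrib: AtomContribution, structure=None):
    """Tabulate contributions as a DataFrame (atom, element, role, value)."""
    import pandas as pd

    n = len(contrib.values)
    roles = ["ligand"] * contrib.n_ligand + ["protein"] * (n - contrib.n_ligand)
    data = {
        "atom_index": np.arange(n),
        "role": roles,
        "contribution": contrib.values,
    }
    if structure is not None:
        data["element"] = [a.element for a in structure.atoms]
        data["residue"] = [
            f"{a.residue_name}{a.residue_number}" if a.role == "protein" else ""
            for a in structure.atoms
        ]
    return pd.DataFrame(data)
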