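"""Graph attention (GATv2-style) layer, single head, NumPy forward pass.

For node features f_i the layer scores every directed neighbor pair

    e(f_i, f_j) = a^T LeakyReLU(W_l f_i + W_r f_j),

normalizes the scores across each node's neighborhood N_i with a softmax,

    alpha_ij = exp(e_ij) / sum_{k in N_i} exp(e_ik),

and updates features as f'_i = sigma(sum_j alpha_ij W_r f_j).  Applying the
shared linear map before the nonlinearity (rather than after, as in the
original GAT) gives the layer dynamic attention.  An isolated node receives
a self-loop so its softmax is defined.  When the graph is weighted (e.g. a
residue interaction network with dissociation energies), edge weights scale
the attention scores multiplicatively before the softmax; rescale or
disable via ``edge_weight_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import ELU

__all__ = ["GATv2Params", "gatv2_layer", "init_gatv2_params"]


@dataclass
class GATv2Params:
    W_left: np.ndarray  # (d_in, d_out), applied to the center node i
    W_right: np.ndarray  # (d_in, d_out), applied to the neighbor j
    a: np.ndarray  # (d_out,)
    leaky_slope: float = 0.2

    @property
    def d_out(self) -> int:
        return self.W_left.shape[1]


def init_gatv2_params(
    d_in: int, d_out: int, rng: np.random.Generator | None = None, leaky_slope: float = 0.2
) -> GATv2Params:
    rng = rng or np.random.default_rng(0)
    scale = np.sqrt(2.0 / d_in)
    return GATv2Params(
        W_left=rng.normal(0.0, scale, (d_in, d_out)),
        W_right=rng.normal(0.0, scale, (d_in, d_out)),
        a=rng.normal(0.0, 1.0 / np.sqrt(d_out), d_out),
        leaky_slope=leaky_slope,
    )


def gatv2_layer(
    features: np.ndarray,
    adjacency: np.ndarray,
    params: GATv2Params,
    activation: str = "elu",
    edge_weights: np.ndarray | None = None,
    edge_weight_mode: str = "scale_scores",
) -> np.ndarray:
    """One graph-attention update; returns (n, d_out) features.

    ``adjacency`` is a symmetric 0/1 matrix; a node's neighborhood is the
    set of adjacent nodes, plus itself when it is isolated.  ``edge_weights``
    (same shape) optionally scales attention scores before the softmax when
    ``edge_weight_mode`` is "scale_scores"; "none" ignores them.
    """
    F = np.asarray(features, dtype=np.float64)
    A = np.asarray(adjacency) != 0
    n = F.shape[0]
    if A.shape != (n, n):
        raise ValueError(f"adjacency shape {A.shape} does not match {n} nodes")
    if F.shape[1] != params.W_left.shape[0]:
        raise ValueError(
            f"feature dim {F.shape[1]} does not match W input dim {params.W_left.shape[0]}"
        )
    mask = A.copy()
    isolated = ~mask.any(axis=1)
    if isolated.any():  # self-loop so the softmax is defined
        mask[isolated, isolated] = True

    Hl = F @ params.W_left  # (n, d_out)
    Hr = F @ params.W_right
    pre = Hl[:, None, :] + Hr[None, :, :]  # (n, n, d_out)
    act = np.where(pre > 0, pre, params.leaky_slope * pre)
    e = act @ params.a  # (n, n)
    if edge_weights is not None and edge_weight_mode == "scale_scores":
        w = np.asarray(edge_weights, dtype=np.float64).copy()
        w[~A] = 1.0  # self-loops and non-edges unscaled
        e = e * w
    e = np.where(mask, e, -np.inf)
    e -= e.max(axis=1, keepdims=True)
    ex = np.exp(e)
    alpha = ex / ex.sum(axis=1, keepdims=True)
    out = alpha @ Hr
    if activation == "elu":
        return ELU().forward(out)
    if activation == "none":
        return out
    raise ValueError(f"unknown activation {activation!r}")
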