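"""Feature-extraction towers: conv/pool stacks, fingerprint MLPs, global-window
sequence convolution, and graph-attention target encoding.

Every tower maps one input representation to a fixed-width vector; in the
full pair classifier the compound and target representative vectors (128-d
each) are concatenated and passed through fully connected layers to a
2-neuron output.

Reference stage geometries (single channel, shape formula
floor((H - K + 2P)/S) + 1 per axis):

* Physicochemical target tower: (1400, 20) -> conv (603, 8), padding 1 ->
  (800, 15) -> max-pool (201, 4), stride 1 -> (600, 12) -> conv (303, 7),
  padding 1 -> (300, 8) -> max-pool (101, 4), stride 1 -> (200, 5) ->
  flatten -> 1000.
* Conformer-fingerprint compound tower: (3, 2048) -> conv (3, 501),
  padding 1 -> (3, 1550) -> max-pool (3, 5) with kernel-sized
  (non-overlapping) stride -> (1, 310) -> flatten -> 310.
* Graph-attention target encoding: two attention layers with output widths
  8 then 4 over the 1400-row padded residue graph; flattening the final
  (1400, 4) features gives a 5600-d vector.
* Fingerprint MLP: 3239 -> 2048 -> 512 -> 128 with ReLU on the two hidden
  layers and a plain affine output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import correlate2d

from .gat import GATv2Params, gatv2_layer, init_gatv2_params
from .layers import Dense, ReLU, Sequential

__all__ = [
    "ConvPoolSpec",
    "PHYGRATT_TARGET_SPECS",
    "E3FP_TOWER_SPECS",
    "conv_pool_output_shape",
    "conv_pool_tower",
    "build_fp_mlp_tower",
    "fp_mlp_tower",
    "build_embedding_mlp_tower",
    "deepconv_target_tower",
    "phys_init_embeddings",
    "random_embeddings",
    "gatts_target_vector",
]


@dataclass
class ConvPoolSpec:
    """One conv + max-pool stage of a 2D tower."""

    conv_kernel: tuple[int, int]
    pool_kernel: tuple[int, int]
    conv_padding: int = 1
    conv_stride: int = 1
    pool_stride: tuple[int, int] | str = (1, 1)  # "kernel" = non-overlapping

    def resolved_pool_stride(self) -> tuple[int, int]:
        if self.pool_stride == "kernel":
            return self.pool_kernel
        return tuple(self.pool_stride)  # type: ignore[arg-type]


PHYGRATT_TARGET_SPECS: list[ConvPoolSpec] = [
    ConvPoolSpec(conv_kernel=(603, 8), pool_kernel=(201, 4)),
    ConvPoolSpec(conv_kernel=(303, 7), pool_kernel=(101, 4)),
]

E3FP_TOWER_SPECS: list[ConvPoolSpec] = [
    ConvPoolSpec(conv_kernel=(3, 501), pool_kernel=(3, 5), pool_stride="kernel"),
]


def _stage_out(size: int, kernel: int, padding: int, stride: int) -> int:
    out = (size - kernel + 2 * padding) // stride + 1
    if out < 1:
        raise ValueError(
            f"kernel {kernel} larger than padded input {size + 2 * padding}"
        )
    return out


def conv_pool_output_shape(
    input_shape: tuple[int, int], specs: list[ConvPoolSpec]
) -> tuple[int, int]:
    h, w = input_shape
    for spec in specs:
        h = _stage_out(h, spec.conv_kernel[0], spec.conv_padding, spec.conv_stride)
        w = _stage_out(w, spec.conv_kernel[1], spec.conv_padding, spec.conv_stride)
        sh, sw = spec.resolved_pool_stride()
        h = _stage_out(h, spec.pool_kernel[0], 0, sh)
        w = _stage_out(w, spec.pool_kernel[1], 0, sw)
    return h, w


def _max_pool(x: np.ndarray, kernel: tuple[int, int], stride: tuple[int, int]) -> np.ndarray:
    windows = sliding_window_view(x, kernel)[:: stride[0], :: stride[1]]
    return windows.max(axis=(-2, -1))


def conv_pool_tower(
    matrix: np.ndarray, specs: list[ConvPoolSpec], seed: int = 0
) -> np.ndarray:
    """Run a conv/max-pool stack on a 2D matrix and return the flattened vector.

    Convolution kernels are randomly initialized from ``seed`` (this is the
    untrained forward pass; stage geometry is the architectural content).
    Raises with the computed shapes when a kernel exceeds its padded input.
    """
    x = np.asarray(matrix, dtype=np.float32)
    rng = np.random.default_rng(seed)
    for spec in specs:
        kh, kw = spec.conv_kernel
        p = spec.conv_padding
        if kh > x.shape[0] + 2 * p or kw > x.shape[1] + 2 * p:
            raise ValueError(
                f"conv kernel {spec.conv_kernel} larger than padded input "
                f"{(x.shape[0] + 2 * p, x.shape[1] + 2 * p)}"
            )
        kernel = rng.normal(0.0, np.sqrt(2.0 / (kh * kw)), (kh, kw)).astype(np.float32)
        padded = np.pad(x, p)
        x = correlate2d(padded, kernel, mode="valid")
        if spec.conv_stride != 1:
            x = x[:: spec.conv_stride, :: spec.conv_stride]
        x = _max_pool(x, spec.pool_kernel, spec.resolved_pool_stride())
    return x.ravel()


FP2D_DIMS = (3239, 2048, 512, 128)


def build_fp_mlp_tower(seed: int = 0) -> Sequential:
    """3239 -> 2048 -> 512 -> 128 MLP: ReLU, ReLU, then plain affine output."""
    rng = np.random.default_rng(seed)
    return Sequential(
        Dense(FP2D_DIMS[0], FP2D_DIMS[1], rng),
        ReLU(),
        Dense(FP2D_DIMS[1], FP2D_DIMS[2], rng),
        ReLU(),
        Dense(FP2D_DIMS[2], FP2D_DIMS[3], rng),
    )


def fp_mlp_tower(fingerprint: np.ndarray, tower: Sequential | None = None) -> np.ndarray:
    """Apply the fingerprint MLP tower to one 3239-d vector (or a batch)."""
    x = np.asarray(fingerprint, dtype=np.float32)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != FP2D_DIMS[0]:
        raise ValueError(f"expected {FP2D_DIMS[0]}-d fingerprint, got {x.shape[1]}")
    tower = tower or build_fp_mlp_tower()
    out = tower.forward(x)
    return out[0] if single else out


def build_embedding_mlp_tower(d_in: int, seed: int = 0, hidden: int = 512) -> Sequential:
    """MLP tower for precomputed protein embeddings -> 128-d vector."""
    rng = np.random.default_rng(seed)
    return Sequential(Dense(d_in, hidden, rng), ReLU(), Dense(hidden, 128, rng))


def random_embeddings(
    dim: int, seed: int = 0, n_residues: int = 20, low: float = -0.05, high: float = 0.05
) -> np.ndarray:
    """Uniform-random trainable embedding table (n_residues + pad row, dim)."""
    rng = np.random.default_rng(seed)
    table = rng.uniform(low, high, size=(n_residues + 1, dim))
    table[0] = 0.0  # pad row
    return table


def phys_init_embeddings(projection, dim: int | None = None) -> np.ndarray:
    """Embedding table initialized from normalized physicochemical projections.

    Row 0 is the zero pad row; row 1+i is the L2-normalized projected
    property vector of the i-th residue letter (alphabetical one-letter
    order).  The table is a plain array and remains trainable downstream.
    """
    from ..io_data import AMINO_ACIDS

    vecs = np.stack([projection.aa_vectors[aa] for aa in AMINO_ACIDS])
    if dim is not None and dim != vecs.shape[1]:
        raise ValueError(
            f"model embedding width {dim} != projection dim {vecs.shape[1]}"
        )
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    table = np.zeros((vecs.shape[0] + 1, vecs.shape[1]))
    table[1:] = vecs / norms
    return table


def deepconv_target_tower(
    seq: str,
    embedding_table: np.ndarray,
    window_sizes: tuple[int, ...] = (4, 8, 12),
    filters_per_window: int = 16,
    seed: int = 0,
    max_len: int = 1400,
) -> np.ndarray:
    """Global-window convolutional target tower over trainable embeddings.

    Each residue is looked up in ``embedding_table`` (row 0 = pad); for every
    window size a bank of 1-D filters slides over the full sequence and a
    global max-pool keeps each filter's best response.  Padded positions are
    masked out and can never win the max.  Output width is
    ``len(window_sizes) * filters_per_window``.
    """
    from ..io_data import AMINO_ACIDS

    if max(window_sizes) > max_len:
        raise ValueError(f"window {max(window_sizes)} longer than max length {max_len}")
    if len(seq) < max(window_sizes):
        raise ValueError(f"sequence length {len(seq)} shorter than largest window")
    aa_index = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
    idx = np.zeros(max_len, dtype=np.int64)
    for i, aa in enumerate(seq[:max_len]):
        idx[i] = aa_index[aa]
    emb = embedding_table[idx]  # (max_len, d)
    d = emb.shape[1]
    rng = np.random.default_rng(seed)
    outputs = []
    for w in window_sizes:
        filters = rng.normal(0.0, np.sqrt(2.0 / (w * d)), size=(filters_per_window, w * d))
        windows = sliding_window_view(emb, (w, d)).reshape(-1, w * d)
        responses = windows @ filters.T  # (positions, filters)
        valid = len(seq) - w + 1  # windows fully inside the true sequence
        outputs.append(responses[:valid].max(axis=0))
    return np.concatenate(outputs)


def gatts_target_vector(
    features: np.ndarray,
    adjacency: np.ndarray,
    dims: tuple[int, int] = (8, 4),
    seed: int = 0,
    edge_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Two stacked graph-attention layers, flattened to one target vector.

    With 1400 padded residue rows and output widths (8, 4) the result is
    5600-d, ready for the fully connected stack of the graph-attention
    target model.
    """
    rng = np.random.default_rng(seed)
    d_in = features.shape[1]
    p1 = init_gatv2_params(d_in, dims[0], rng)
    p2 = init_gatv2_params(dims[0], dims[1], rng)
    h = gatv2_layer(features, adjacency, p1, edge_weights=edge_weights)
    h = gatv2_layer(h, adjacency, p2, edge_weights=edge_weights)
    return h.ravel()
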