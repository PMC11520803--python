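"""Target (protein) featurization.

* Sequence one-hot: (1400, 20) binary matrix over the canonical amino-acid
  alphabet, zero-padded past the true length.
* Physicochemical projection: an amino-acid property table (20 residues x P
  properties, AAindex-style) is z-scored and reduced by PCA to 20 principal
  components; each residue letter then maps to a fixed 20-d vector, and a
  sequence becomes a (1400, 20) matrix of projected rows.
* Residue interaction graph: residues as nodes (20-d physicochemical
  features), typed contacts as undirected edges weighted by the dissociation
  energy of the interaction type (disulfide 167, ionic 20, hydrogen 17,
  pi-cation 9.6, pi-pi 9.4, van der Waals 6).
* External embeddings: per-target vectors from pretrained protein language
  models (768-d BERT-style, 1900-d UniRep-style, or a declared width) are
  loaded and validated, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_data import AMINO_ACIDS, _AA_SET

MAX_SEQ_LEN = 1400
N_COMPONENTS = 20

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class TargetMatrix:
    matrix: np.ndarray  # (1400, 20)
    true_length: int


def _check_sequence(seq: str, max_len: int) -> None:
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds {max_len}")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"non-canonical residues: {sorted(bad)}")


def encode_sequence_onehot(seq: str, max_len: int = MAX_SEQ_LEN) -> TargetMatrix:
    """One-hot encode an amino-acid sequence into a (1400, 20) matrix."""
    _check_sequence(seq, max_len)
    matrix = np.zeros((max_len, len(AMINO_ACIDS)), dtype=np.uint8)
    for i, aa in enumerate(seq):
        matrix[i, _AA_INDEX[aa]] = 1
    return TargetMatrix(matrix=matrix, true_length=len(seq))


@dataclass
class PhyschemProjection:
    """Fitted PCA projection of an amino-acid property table.

    ``aa_vectors`` maps each residue letter to its projected 20-d vector;
    the projection is fitted once on the 20-row property table (one row per
    residue type) so the representation is sequence-independent.
    """

    components: np.ndarray  # (20, P) orthonormal rows
    mean: np.ndarray  # (P,) column means of the standardized table
    scale_mean: np.ndarray  # (P,) raw column means
    scale_std: np.ndarray  # (P,) raw column stds
    explained_variance_ratio: np.ndarray
    aa_vectors: dict[str, np.ndarray]

    def project(self, raw: np.ndarray) -> np.ndarray:
        z = (np.asarray(raw, dtype=float) - self.scale_mean) / self.scale_std
        return (z - self.mean) @ self.components.T


def fit_physchem_pca(
    property_table: pd.DataFrame | np.ndarray, n_components: int = N_COMPONENTS
) -> PhyschemProjection:
    """Standardize a 20 x P property table and fit PCA to 20 components.

    Rows must be the 20 canonical residues (index order is taken from the
    DataFrame index when present, otherwise alphabetical one-letter order).
    Component signs follow the convention that each component's
    largest-magnitude loading is positive.  Note a centered 20-row table has
    rank at most 19, so the 20th component carries (numerically) zero
    variance; it is kept to preserve the stated 20-dim output width.
    """
    if isinstance(property_table, pd.DataFrame):
        index = list(property_table.index)
        values = property_table.to_numpy(dtype=float)
    else:
        index = list(AMINO_ACIDS)
        values = np.asarray(property_table, dtype=float)
    if values.shape[0] != 20:
        raise ValueError(f"property table must have 20 rows, got {values.shape[0]}")
    if sorted(index) != sorted(AMINO_ACIDS):
        raise ValueError("property table rows must be the 20 canonical residues")
    P = values.shape[1]
    if P < n_components:
        raise ValueError(f"need at least {n_components} properties, got {P}")
    if np.isnan(values).any():
        raise ValueError("property table contains missing values")

    scale_mean = values.mean(axis=0)
    scale_std = values.std(axis=0)
    if (scale_std == 0).any():
        raise ValueError("constant property columns; drop them before fitting")
    z = (values - scale_mean) / scale_std
    # z-scoring centers the 20 rows' columns, so rank(z) <= 19 by construction;
    # require the maximum attainable rank and keep a 20th (zero-variance)
    # component to preserve the stated output width.
    if np.linalg.matrix_rank(z) < n_components - 1:
        raise ValueError(
            f"standardized table rank < {n_components - 1}; use fewer components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(z)
    components = pca.components_.copy()
    for i in range(components.shape[0]):  # sign convention
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
    projected = (z - pca.mean_) @ components.T
    aa_vectors = {aa: projected[index.index(aa)].copy() for aa in AMINO_ACIDS}
    return PhyschemProjection(
        components=components,
        mean=pca.mean_,
        scale_mean=scale_mean,
        scale_std=scale_std,
        explained_variance_ratio=pca.explained_variance_ratio_,
        aa_vectors=aa_vectors,
    )


def encode_physchem(
    seq: str, projection: PhyschemProjection, max_len: int = MAX_SEQ_LEN
) -> TargetMatrix:
    """Per-residue projected physicochemical features, zero-padded to (1400, 20)."""
    _check_sequence(seq, max_len)
    matrix = np.zeros((max_len, N_COMPONENTS), dtype=np.float64)
    for i, aa in enumerate(seq):
        matrix[i] = projection.aa_vectors[aa]
    return TargetMatrix(matrix=matrix, true_length=len(seq))


INTERACTION_TYPES = ("disulfide", "ionic", "hydrogen", "pi_cation", "pi_pi", "vdw")
DISSOCIATION_ENERGY: dict[str, float] = {
    "disulfide": 167.0,
    "ionic": 20.0,
    "hydrogen": 17.0,
    "pi_cation": 9.6,
    "pi_pi": 9.4,
    "vdw": 6.0,
}


@dataclass
class ResidueEdge:
    i: int
    j: int
    interaction_type: str
    weight: float


@dataclass
class ResidueGraph:
    node_features: np.ndarray  # (n_residues, 20)
    edges: list[ResidueEdge]
    sequence: str

    @property
    def n_nodes(self) -> int:
        return len(self.sequence)

    def adjacency(self, weighted: bool = True) -> np.ndarray:
        n = self.n_nodes
        adj = np.zeros((n, n))
        for e in self.edges:
            w = e.weight if weighted else 1.0
            adj[e.i, e.j] = adj[e.j, e.i] = w
        return adj


def build_residue_graph(
    seq: str,
    contacts: Sequence[tuple[int, int, str]],
    projection: PhyschemProjection,
) -> ResidueGraph:
    """Residue interaction network from a typed contact list.

    ``contacts`` are (res_i, res_j, type) with 0-based residue indices; edge
    weights come solely from the fixed dissociation-energy table.  Self-loops
    and unknown types are errors; duplicate undirected contacts collapse.
    """
    _check_sequence(seq, MAX_SEQ_LEN)
    n = len(seq)
    seen: set[tuple[int, int, str]] = set()
    edges: list[ResidueEdge] = []
    for i, j, typ in contacts:
        if typ not in DISSOCIATION_ENERGY:
            raise ValueError(f"unknown interaction type {typ!r}")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"contact ({i},{j}) out of range for length {n}")
        if i == j:
            raise ValueError(f"self-loop contact at residue {i}")
        key = (min(i, j), max(i, j), typ)
        if key in seen:
            continue
        seen.add(key)
        edges.append(ResidueEdge(key[0], key[1], typ, DISSOCIATION_ENERGY[typ]))
    node_features = encode_physchem(seq, projection).matrix[:n]
    return ResidueGraph(node_features=node_features, edges=edges, sequence=seq)


EMBEDDING_SCHEMES = {"unirep": 1900, "bert": 768}


@dataclass
class ProteinEmbedding:
    vector: np.ndarray
    scheme: str


def load_embedding(
    path: str | Path, scheme: str, dim: int | None = None
) -> dict[str, ProteinEmbedding]:
    """Load per-target embedding vectors from a TSV (target_id, v1..vD).

    ``scheme`` is "unirep" (1900-d), "bert" (768-d) or "custom" with an
    explicit ``dim``.  Any row whose width disagrees with the declared
    dimension is an error naming expected and found widths.
    """
    scheme = scheme.lower()
    if scheme in EMBEDDING_SCHEMES:
        expected = EMBEDDING_SCHEMES[scheme]
    elif dim is not None:
        expected = int(dim)
    else:
        raise ValueError(f"unknown scheme {scheme!r} and no explicit dim given")
    out: dict[str, ProteinEmbedding] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            target_id, values = parts[0], parts[1:]
            if len(values) != expected:
                raise ValueError(
                    f"{path} line {lineno}: expected {expected}-d vector for "
                    f"scheme {scheme!r}, found {len(values)}-d"
                )
            out[target_id] = ProteinEmbedding(
                vector=np.array(values, dtype=float), scheme=scheme
            )
    return out


def write_embedding(
    embeddings: dict[str, np.ndarray], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for target_id, vec in embeddings.items():
            fh.write(target_id + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")
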