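"""Compound featurization.

Four compound representations feed the model towers:

* SMILES one-hot: a (348, 98) binary matrix over a frozen 98-symbol
  character table, zero-padded beyond the true SMILES length.
* 2D fingerprints (2DFP): Morgan(1024) + MACCS(167) + RDKit topological
  (1024) + AtomPair(1024) concatenated into one 3239-bit vector.
* Conformer (3D) fingerprints: up to 3 low-energy conformers, each hashed
  into a 2048-bit shell fingerprint built from growing spatial
  neighborhoods, stacked into a (3, 2048) matrix with zero rows for
  missing conformers.
* Atom interaction graph: heavy atoms as nodes with 34-dimensional feature
  vectors (atom type, degree, formal charge, hybridization, chirality,
  radical, aromaticity, R/S configuration, attached hydrogens), bonds as
  undirected edges.
"""

from __future__ import annotations

import hashlib
import logging
import string
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

log = logging.getLogger(__name__)

MAX_SMILES_LEN = 348

# Frozen 98-symbol character table: the 94 printable (non-space) ASCII
# characters plus 4 reserved columns kept for forward compatibility of the
# fixed encoder width.  Two-letter element symbols (Cl, Br) are encoded
# character by character.  Unknown characters are an error, never remapped.
SMILES_VOCAB: tuple[str, ...] = tuple(
    string.digits + string.ascii_uppercase + string.ascii_lowercase + string.punctuation
) + ("<r0>", "<r1>", "<r2>", "<r3>")
assert len(SMILES_VOCAB) == 98
_VOCAB_INDEX = {ch: i for i, ch in enumerate(SMILES_VOCAB)}


def vocabulary_hash() -> str:
    return hashlib.sha256("".join(SMILES_VOCAB).encode()).hexdigest()[:16]


class FeaturizationError(ValueError):
    pass


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass
class SmilesOneHot:
    matrix: np.ndarray  # (348, 98) uint8
    true_length: int
    smiles: str


def encode_smiles_onehot(
    smiles: str, max_len: int = MAX_SMILES_LEN, canonicalize: bool = True
) -> SmilesOneHot:
    """One-hot encode a SMILES string into a (348, 98) binary matrix.

    The string is canonicalized first (so two spellings of one molecule
    encode identically); rows past the string length are zero padding.
    """
    if canonicalize:
        smiles = Chem.MolToSmiles(_mol(smiles))
    if len(smiles) > max_len:
        raise FeaturizationError(
            f"SMILES length {len(smiles)} exceeds encoder width {max_len}"
        )
    matrix = np.zeros((max_len, len(SMILES_VOCAB)), dtype=np.uint8)
    for i, ch in enumerate(smiles):
        col = _VOCAB_INDEX.get(ch)
        if col is None:
            raise FeaturizationError(f"character {ch!r} not in the SMILES vocabulary")
        matrix[i, col] = 1
    return SmilesOneHot(matrix=matrix, true_length=len(smiles), smiles=smiles)


FP2D_SEGMENTS: dict[str, tuple[int, int]] = {
    "morgan": (0, 1024),
    "maccs": (1024, 1191),
    "rdkit": (1191, 2215),
    "atompair": (2215, 3239),
}
FP2D_LENGTH = 3239


@dataclass
class Fingerprint2D:
    vector: np.ndarray  # (3239,) uint8
    segments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(FP2D_SEGMENTS)
    )

    def segment(self, name: str) -> np.ndarray:
        lo, hi = self.segments[name]
        return self.vector[lo:hi]


def encode_2dfp(smiles: str) -> Fingerprint2D:
    """Concatenated Morgan/MACCS/RDKit-topological/AtomPair fingerprint (3239 bits)."""
    mol = _mol(smiles)
    morgan = rdFingerprintGenerator.GetMorganGenerator(
        radius=2, fpSize=1024
    ).GetFingerprintAsNumPy(mol)
    maccs = np.zeros(167, dtype=np.uint8)
    for bit in MACCSkeys.GenMACCSKeys(mol).GetOnBits():
        maccs[bit] = 1
    rdk = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=1024).GetFingerprintAsNumPy(
        mol
    )
    atompair = rdFingerprintGenerator.GetAtomPairGenerator(
        fpSize=1024
    ).GetFingerprintAsNumPy(mol)
    vector = np.concatenate(
        [
            np.asarray(morgan, dtype=np.uint8),
            maccs,
            np.asarray(rdk, dtype=np.uint8),
            np.asarray(atompair, dtype=np.uint8),
        ]
    )
    assert vector.shape == (FP2D_LENGTH,)
    return Fingerprint2D(vector=vector)


@dataclass
class ConformerFingerprints:
    matrix: np.ndarray  # (3, 2048) uint8
    n_conformers_generated: int


def _hash32(*values: int) -> int:
    data = struct.pack(f"<{len(values)}q", *values)
    return zlib.crc32(data) & 0xFFFFFFFF


def _shell_fingerprint(
    mol: Chem.Mol,
    conf_id: int,
    n_bits: int,
    n_levels: int = 5,
    radius_multiplier: float = 1.718,
) -> np.ndarray:
    """Iterative 3D shell fingerprint for one conformer.

    Level-0 identifiers hash per-atom invariants; at level L each atom's
    identifier is rehashed with the sorted identifiers (and bonded flags) of
    all atoms inside a sphere of radius L * radius_multiplier angstroms.
    Every identifier from every level sets one bit of the folded vector.
    """
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    bonded = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds()
    }
    ids = {
        i: _hash32(
            0,
            mol.GetAtomWithIdx(i).GetAtomicNum(),
            mol.GetAtomWithIdx(i).GetDegree(),
            mol.GetAtomWithIdx(i).GetFormalCharge(),
            mol.GetAtomWithIdx(i).GetTotalNumHs(),
            int(mol.GetAtomWithIdx(i).GetIsAromatic()),
        )
        for i in heavy
    }
    bits = set(ids.values())
    dists = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
    for level in range(1, n_levels + 1):
        radius = radius_multiplier * level
        new_ids = {}
        for i in heavy:
            inside = [
                (ids[j], int(frozenset((i, j)) in bonded))
                for j in heavy
                if j != i and dists[i, j] <= radius
            ]
            inside.sort()
            flat = [level, ids[i]]
            for ident, flag in inside:
                flat.extend((ident, flag))
            new_ids[i] = _hash32(*flat)
        ids = new_ids
        bits.update(ids.values())
    vec = np.zeros(n_bits, dtype=np.uint8)
    for b in bits:
        vec[b % n_bits] = 1
    return vec


def encode_e3fp(
    smiles: str,
    max_conformers: int = 3,
    n_bits: int = 2048,
    seed: int = 7,
) -> ConformerFingerprints:
    """Conformer fingerprints: up to 3 low-energy conformers, 2048 bits each.

    Conformers come from distance-geometry embedding (fixed seed) followed by
    force-field optimization; the ``max_conformers`` lowest-energy ones are
    fingerprinted, the rest of the (3, 2048) matrix stays zero.
    """
    mol = Chem.AddHs(_mol(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    conf_ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=max_conformers * 2, params=params))
    if not conf_ids:
        raise FeaturizationError(f"3D embedding failed for {smiles!r}")
    energies = []
    for cid in conf_ids:
        try:
            ff = AllChem.MMFFGetMoleculeForceField(
                mol, AllChem.MMFFGetMoleculeProperties(mol), confId=cid
            )
        except Exception:
            ff = None
        if ff is None:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
        if ff is not None:
            ff.Minimize(maxIts=200)
            energies.append((ff.CalcEnergy(), cid))
        else:
            energies.append((0.0, cid))
    energies.sort()
    keep = [cid for _, cid in energies[:max_conformers]]
    matrix = np.zeros((max_conformers, n_bits), dtype=np.uint8)
    for row, cid in enumerate(keep):
        matrix[row] = _shell_fingerprint(mol, cid, n_bits)
    return ConformerFingerprints(matrix=matrix, n_conformers_generated=len(keep))


ATOM_TYPES = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")  # + "other"
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)  # + other
ATOM_FEATURE_DIM = 34


@dataclass
class AtomGraph:
    node_features: np.ndarray  # (n_atoms, 34) float32
    adjacency: np.ndarray  # (n_atoms, n_atoms) uint8, symmetric
    edges: list[tuple[int, int]]
    smiles: str


def _atom_features(atom: Chem.Atom, chiral_centers: set[int], degree_mode: str) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM, dtype=np.float32)
    # atom type (10)
    sym = atom.GetSymbol()
    v[ATOM_TYPES.index(sym) if sym in ATOM_TYPES else 9] = 1
    # degree (7 bins, 0-6, clamped)
    if degree_mode == "carbon":
        degree = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "C")
    else:
        degree = atom.GetDegree()
    if degree > 6:
        log.warning("atom degree %d clamped to 6", degree)
        degree = 6
    v[10 + degree] = 1
    # formal charge present (1)
    v[17] = float(atom.GetFormalCharge() != 0)
    # hybridization (6)
    hyb = atom.GetHybridization()
    v[18 + (HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS else 5)] = 1
    # possible chiral center (1)
    v[24] = float(atom.GetIdx() in chiral_centers)
    # radical (1)
    v[25] = float(atom.GetNumRadicalElectrons() > 0)
    # aromatic (1)
    v[26] = float(atom.GetIsAromatic())
    # CIP configuration R/S (2)
    if atom.HasProp("_CIPCode"):
        v[27 + (0 if atom.GetProp("_CIPCode") == "R" else 1)] = 1
    # attached hydrogens (5 bins, 0-4, clamped)
    v[29 + min(atom.GetTotalNumHs(), 4)] = 1
    return v


def build_atom_graph(smiles: str, degree_mode: str = "heavy") -> AtomGraph:
    """Molecular graph with 34-d node features in canonical atom order.

    ``degree_mode`` selects between counting all heavy neighbors ("heavy",
    default) or carbon neighbors only ("carbon") for the degree bins.
    """
    mol = _mol(smiles)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    # canonical atom order
    order = list(
        Chem.CanonicalRankAtoms(mol, breakTies=True)
    )  # atom idx -> canonical rank
    n = mol.GetNumAtoms()
    chiral_centers = {
        idx for idx, _ in Chem.FindMolChiralCenters(mol, includeUnassigned=True)
    }
    features = np.zeros((n, ATOM_FEATURE_DIM), dtype=np.float32)
    for atom in mol.GetAtoms():
        features[order[atom.GetIdx()]] = _atom_features(atom, chiral_centers, degree_mode)
    adjacency = np.zeros((n, n), dtype=np.uint8)
    edges = []
    for bond in mol.GetBonds():
        i = order[bond.GetBeginAtomIdx()]
        j = order[bond.GetEndAtomIdx()]
        adjacency[i, j] = adjacency[j, i] = 1
        edges.append((min(i, j), max(i, j)))
    return AtomGraph(
        node_features=features,
        adjacency=adjacency,
        edges=sorted(edges),
        smiles=Chem.MolToSmiles(mol),
    )
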