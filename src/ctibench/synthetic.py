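"""Synthetic fixture generator.

Emulates the structure of real compound-target interaction corpora so that
every pipeline stage (dataset construction, splitting, featurization,
training, evaluation) runs end-to-end without downloads:

* Compounds are assembled from a fragment grammar, guaranteeing parseable
  SMILES with meaningful fingerprints and rotatable-bond counts spanning
  rigid to highly flexible.
* Targets are random sequences over the canonical alphabet; mutants are
  single-point substitutions of a generated wild-type.
* Interactions carry a planted signal: a compound substructure (a CF3
  group) co-occurring with a target sequence motif raises the interaction
  probability, so both compound-side and target-side feature extractors
  can in principle learn the rule.  Affinities are drawn consistently with
  the label under the requested measure's threshold.
* Residue contacts are random index pairs typed over the six interaction
  categories (disulfide only between cysteines).

It does not emulate binding physics, realistic affinity distributions, or
conformational thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .io_data import AMINO_ACIDS, InteractionRecord, Measure, Source, Variant

__all__ = [
    "SyntheticSpec",
    "PLANTED_SUBSTRUCTURE",
    "PLANTED_MOTIF",
    "gen_compounds",
    "gen_targets",
    "gen_interactions",
    "gen_contacts",
    "synthetic_property_table",
]

PLANTED_SUBSTRUCTURE = "C(F)(F)F"  # trifluoromethyl, Morgan-visible
PLANTED_SUBSTRUCTURE_SMARTS = "C(F)(F)F"
PLANTED_MOTIF = "WYKHW"  # rare 5-mer motif

# Fragment grammar: every fragment concatenates into valid SMILES.
_CORES = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "c1ccsc1", "C1CCOC1"]
_CHAINS = ["CC", "CCO", "CCN", "C(=O)C", "CCCC", "C(C)C", "C=CC", "CCOCC", "CCCCCC"]
_POLAR = ["O", "N", "C(=O)N", "S(=O)(=O)C"]


@dataclass
class SyntheticSpec:
    n_compounds: int = 40
    n_targets: int = 12
    n_pairs: int = 200
    label_noise: float = 0.0
    mutant_fraction: float = 0.0
    prevalence: float | None = None  # None: prevalence follows the planted rule
    measure: Measure = Measure.KD_MICROMOLAR
    length_range: tuple[int, int] = (80, 200)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def gen_compounds(n: int, seed: int = 0, planted_fraction: float = 0.5) -> list[str]:
    """Canonical, parseable SMILES from a fragment grammar.

    Roughly ``planted_fraction`` of compounds carry the planted CF3
    substructure; chain counts vary so rotatable-bond counts span from
    rigid rings to >10 rotatable bonds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        parts = [str(rng.choice(_CHAINS))] if rng.random() < 0.7 else []
        parts.append(str(rng.choice(_CORES)))
        for _ in range(int(rng.integers(0, 4))):
            parts.append(str(rng.choice(_CHAINS + _POLAR)))
        if rng.random() < planted_fraction:
            parts.append(PLANTED_SUBSTRUCTURE)
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, f"grammar produced unparseable SMILES {smiles!r}"
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


@dataclass
class TargetSpecimen:
    target_id: str
    sequence: str
    variant: Variant
    wild_ref: str | None = None  # id of the wild-type a mutant derives from


def gen_targets(
    n: int,
    length_range: tuple[int, int] = (80, 200),
    mutant_fraction: float = 0.0,
    seed: int = 0,
    motif_fraction: float = 0.5,
) -> list[TargetSpecimen]:
    """Random protein sequences; mutants are single-point substitutions.

    About ``motif_fraction`` of wild-type sequences carry the planted motif.
    The WILD/MUTANT flags partition the list at the requested fraction
    (within one target).
    """
    if length_range[1] > 1400:
        raise ValueError("target lengths must be <= 1400")
    rng = np.random.default_rng(seed)
    n_mut = int(round(n * mutant_fraction))
    n_wild = n - n_mut
    aa = np.array(list(AMINO_ACIDS))
    wilds: list[TargetSpecimen] = []
    for i in range(n_wild):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(aa, size=length))
        if rng.random() < motif_fraction:
            pos = int(rng.integers(0, length - len(PLANTED_MOTIF)))
            seq = seq[:pos] + PLANTED_MOTIF + seq[pos + len(PLANTED_MOTIF) :]
        wilds.append(TargetSpecimen(f"T{i:04d}", seq, Variant.WILD))
    specimens = list(wilds)
    for j in range(n_mut):
        wild = wilds[int(rng.integers(len(wilds)))]
        pos = int(rng.integers(len(wild.sequence)))
        old = wild.sequence[pos]
        new = str(rng.choice([a for a in AMINO_ACIDS if a != old]))
        seq = wild.sequence[:pos] + new + wild.sequence[pos + 1 :]
        specimens.append(
            TargetSpecimen(f"M{j:04d}", seq, Variant.MUTANT, wild_ref=wild.target_id)
        )
    return specimens


def _affinity_for(label: int, measure: Measure, rng: np.random.Generator) -> float:
    if measure is Measure.KD_MICROMOLAR:
        return float(rng.uniform(0.01, 9.5)) if label else float(rng.uniform(10.5, 100.0))
    if measure is Measure.KIBA_SCORE:
        return float(rng.uniform(0.5, 3.0)) if label else float(rng.uniform(3.5, 8.0))
    return float(label)


def gen_interactions(
    compounds: list[str],
    targets: list[TargetSpecimen],
    spec: SyntheticSpec,
) -> list[InteractionRecord]:
    """Interaction records with a planted co-occurrence rule.

    With zero label noise the label is exactly the indicator of "compound
    has the planted substructure AND target has the planted motif".  When
    ``spec.prevalence`` is set, pairs are sampled so the positive fraction
    matches it in expectation.  Records pass preprocessing unchanged.
    """
    rng = np.random.default_rng(spec.seed + 1)
    patt = Chem.MolFromSmarts(PLANTED_SUBSTRUCTURE_SMARTS)
    has_sub = np.array(
        [Chem.MolFromSmiles(s).HasSubstructMatch(patt) for s in compounds]
    )
    has_motif = np.array([PLANTED_MOTIF in t.sequence for t in targets])

    pos_pairs = [
        (ci, ti)
        for ci in range(len(compounds))
        for ti in range(len(targets))
        if has_sub[ci] and has_motif[ti]
    ]
    neg_pairs = [
        (ci, ti)
        for ci in range(len(compounds))
        for ti in range(len(targets))
        if not (has_sub[ci] and has_motif[ti])
    ]
    records: list[InteractionRecord] = []
    seen: set[tuple[int, int]] = set()
    for _ in range(spec.n_pairs):
        if spec.prevalence is not None:
            pool = pos_pairs if rng.random() < spec.prevalence else neg_pairs
            if not pool:
                pool = pos_pairs or neg_pairs
        else:
            pool = pos_pairs + neg_pairs
        unseen = [p for p in pool if p not in seen]
        pick = unseen if unseen else pool  # duplicates only when pool exhausted
        ci, ti = pick[int(rng.integers(len(pick)))]
        seen.add((ci, ti))
        label = int(has_sub[ci] and has_motif[ti])
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = 1 - label
        tgt = targets[ti]
        records.append(
            InteractionRecord(
                compound_id=f"C{ci:04d}",
                smiles=compounds[ci],
                target_id=tgt.target_id,
                sequence=tgt.sequence,
                affinity_value=_affinity_for(label, spec.measure, rng),
                measure=spec.measure,
                label=label,
                source=Source.SYNTHETIC,
                variant=tgt.variant,
            )
        )
    return records


def gen_contacts(
    sequence: str, seed: int = 0, density: float = 0.02
) -> list[tuple[int, int, str]]:
    """Random typed residue contacts (no self-loops, indices in range).

    Types are drawn over the six interaction categories; disulfide is only
    emitted between two cysteines.
    """
    rng = np.random.default_rng(seed)
    n = len(sequence)
    types = ["ionic", "hydrogen", "pi_cation", "pi_pi", "vdw"]
    n_edges = max(1, int(density * n * 4))
    seen: set[tuple[int, int]] = set()
    contacts: list[tuple[int, int, str]] = []
    for _ in range(n_edges * 3):
        if len(contacts) >= n_edges:
            break
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        if sequence[i] == "C" and sequence[j] == "C" and rng.random() < 0.5:
            typ = "disulfide"
        else:
            typ = str(rng.choice(types))
        contacts.append((key[0], key[1], typ))
    return contacts


def synthetic_property_table(
    n_props: int = 512, seed: int = 0, n_factors: int = 6
) -> pd.DataFrame:
    """Synthetic amino-acid property table (20 x n_props), AAindex-style.

    Columns are noisy linear combinations of a few latent per-residue
    factors, giving the correlated-column structure that makes a PCA to 20
    components meaningful.  Deterministic in ``seed``.  Synthetic stand-in:
    the values are not measured physicochemical properties.
    """
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(20, n_factors))
    loadings = rng.normal(size=(n_factors, n_props))
    noise = 0.3 * rng.normal(size=(20, n_props))
    values = factors @ loadings + noise
    return pd.DataFrame(
        values, index=list(AMINO_ACIDS), columns=[f"prop{i:03d}" for i in range(n_props)]
    )
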