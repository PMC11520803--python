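"""Interaction tables: reading, writing, label binarization and preprocessing.

A compound-target interaction (CTI) record pairs a small molecule (SMILES) with
a protein (amino-acid sequence) and an experimental affinity.  Affinities are
binarized into bind / non-bind labels with measure-specific thresholds:

* KiBA score: a pair is a hit iff the score is <= 3 (lower score = stronger).
* Kd in micromolar: a hit iff Kd < 10 uM; Kd >= 10 uM is a non-bind.
* BINARY: the affinity value already is the 0/1 label.

Preprocessing removes over-long targets (> 1400 residues), over-long SMILES
(> 348 characters, the width of the one-hot encoder), unparseable SMILES, and
exact duplicate (canonical SMILES, sequence, label) triples.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

MAX_SEQ_LEN = 1400
MAX_SMILES_LEN = 348


class Measure(str, Enum):
    KIBA_SCORE = "KIBA_SCORE"
    KD_MICROMOLAR = "KD_MICROMOLAR"
    BINARY = "BINARY"


class Source(str, Enum):
    KIBA = "KiBA"
    DRUGBANK = "DrugBank"
    DAVIS = "Davis"
    D3R = "D3R"
    SYNTHETIC = "SYNTHETIC"


class Variant(str, Enum):
    WILD = "WILD"
    MUTANT = "MUTANT"
    UNKNOWN = "UNKNOWN"


@dataclass
class Thresholds:
    """Affinity binarization thresholds (benchmark defaults)."""

    kiba_max_hit: float = 3.0       # hit iff score <= this
    kd_micromolar_hit: float = 10.0  # hit iff Kd < this


@dataclass
class InteractionRecord:
    compound_id: str
    smiles: str
    target_id: str
    sequence: str
    affinity_value: float
    measure: Measure
    label: int | None = None
    source: Source = Source.SYNTHETIC
    variant: Variant = Variant.UNKNOWN

    def validate(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"sequence of {self.target_id} contains non-canonical residues: {sorted(bad)}"
            )


COLUMNS = [
    "compound_id",
    "smiles",
    "target_id",
    "sequence",
    "affinity",
    "measure",
    "label",
    "source",
    "variant",
]
REQUIRED_COLUMNS = COLUMNS[:6]


@dataclass
class ParseFailure:
    line_number: int
    reason: str


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect:
        return dialect
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_interaction_table(
    path: str | Path, dialect: str | None = None
) -> tuple[list[InteractionRecord], list[ParseFailure]]:
    """Read a CSV/TSV interaction table.

    Returns the parsed records together with a list of row-level parse
    failures (unparseable affinity, bad label, ...), reported with their
    1-based line numbers.  A missing required column is a hard error.
    """
    path = Path(path)
    delim = _dialect_for(path, dialect)
    records: list[InteractionRecord] = []
    failures: list[ParseFailure] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                affinity = float(row["affinity"])
                if not math.isfinite(affinity):
                    raise ValueError("non-finite affinity")
                label_raw = (row.get("label") or "").strip()
                label = int(label_raw) if label_raw else None
                rec = InteractionRecord(
                    compound_id=row["compound_id"],
                    smiles=row["smiles"],
                    target_id=row["target_id"],
                    sequence=row["sequence"],
                    affinity_value=affinity,
                    measure=Measure(row["measure"]),
                    label=label,
                    source=Source(row["source"]) if (row.get("source") or "").strip() else Source.SYNTHETIC,
                    variant=Variant(row["variant"]) if (row.get("variant") or "").strip() else Variant.UNKNOWN,
                )
                rec.validate()
            except (ValueError, KeyError) as exc:
                failures.append(ParseFailure(lineno, str(exc)))
                continue
            records.append(rec)
    return records, failures


def write_interaction_table(
    records: Iterable[InteractionRecord], path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    delim = _dialect_for(path, dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.compound_id,
                    r.smiles,
                    r.target_id,
                    r.sequence,
                    repr(r.affinity_value),
                    r.measure.value,
                    "" if r.label is None else r.label,
                    r.source.value,
                    r.variant.value,
                ]
            )


def binarize_affinity(
    value: float, measure: Measure, thresholds: Thresholds | None = None
) -> int:
    """Binarize an affinity into a bind(1)/non-bind(0) label."""
    if not math.isfinite(value):
        raise ValueError(f"affinity must be finite, got {value!r}")
    t = thresholds or Thresholds()
    measure = Measure(measure)
    if measure is Measure.KIBA_SCORE:
        return int(value <= t.kiba_max_hit)
    if measure is Measure.KD_MICROMOLAR:
        return int(value < t.kd_micromolar_hit)
    if measure is Measure.BINARY:
        if value not in (0.0, 1.0):
            raise ValueError(f"BINARY affinity must be 0 or 1, got {value!r}")
        return int(value)
    raise ValueError(f"unknown measure {measure!r}")


def binarize_records(
    records: Sequence[InteractionRecord], thresholds: Thresholds | None = None
) -> list[InteractionRecord]:
    """Fill in labels for every record from its affinity and measure."""
    return [
        replace(r, label=binarize_affinity(r.affinity_value, r.measure, thresholds))
        for r in records
    ]


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None if the chemistry backend cannot parse it."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@dataclass
class ExclusionReport:
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "sequence_too_long": 0,
            "smiles_too_long": 0,
            "smiles_unparseable": 0,
            "invalid_sequence": 0,
            "duplicate": 0,
        }
    )
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)

    def add(self, reason: str, record: InteractionRecord) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.excluded_ids.setdefault(reason, []).append(
            f"{record.compound_id}:{record.target_id}"
        )

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "excluded_ids": self.excluded_ids}, indent=2
        )


def preprocess(
    records: Sequence[InteractionRecord],
    max_seq_len: int = MAX_SEQ_LEN,
    max_smiles_len: int = MAX_SMILES_LEN,
    require_parseable: bool = True,
) -> tuple[list[InteractionRecord], ExclusionReport]:
    """Length/validity filtering and exact-duplicate removal.

    A duplicate is an exact (canonical SMILES, sequence, label) triple;
    canonicalization happens before deduplication, so two spellings of the
    same molecule count as the same compound.  Idempotent.
    """
    report = ExclusionReport()
    kept: list[InteractionRecord] = []
    seen: set[tuple[str, str, int | None]] = set()
    for rec in records:
        if len(rec.sequence) > max_seq_len:
            report.add("sequence_too_long", rec)
            continue
        if set(rec.sequence) - _AA_SET:
            report.add("invalid_sequence", rec)
            continue
        if len(rec.smiles) > max_smiles_len:
            report.add("smiles_too_long", rec)
            continue
        canon = canonical_smiles(rec.smiles) if require_parseable else rec.smiles
        if canon is None:
            report.add("smiles_unparseable", rec)
            continue
        key = (canon, rec.sequence, rec.label)
        if key in seen:
            report.add("duplicate", rec)
            continue
        seen.add(key)
        kept.append(rec)
    return kept, report


def read_fasta(path: str | Path) -> dict[str, str]:
    """Target sequences keyed by FASTA id (first word of the header)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file: one `SMILES id` per line -> [(id, smiles), ...]."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"cmpd{i}"
            out.append((cid, smiles))
    return out


def write_smi(compounds: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, smiles in compounds:
            fh.write(f"{smiles}\t{cid}\n")
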