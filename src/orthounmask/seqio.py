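"""Core sequence, alignment and structure containers with file I/O.

Every stage of the ortholog-unmasking workflow moves data through the three
types defined here: :class:`SequenceRecord` (a validated protein or
nucleotide sequence), :class:`Alignment` (equal-length gapped rows), and
:class:`StructureModel` (a backbone trace with per-residue confidence as
written by structure-prediction tools in the B-factor field).

File formats are handled by established parsers — FASTA via Biopython,
PDB ATOM records via gemmi — and wrapped into the package's containers.
Coordinates and column indices are 0-based half-open internally; report
writers convert to 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")
GAP = "-"

#: canonical residue order used by every scoring matrix in the package
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SequenceFormatError(ValueError):
    """Raised for malformed sequence/alignment/structure input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single validated sequence.

    Residues are upper-cased on construction and checked against the
    declared alphabet (20 amino acids plus ``X``, or ``ACGTN``).
    """

    id: str
    residues: str
    molecule: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(f"invalid sequence id {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceFormatError(f"empty sequence for id {self.id!r}")
        if self.molecule not in ("protein", "nucleotide"):
            raise SequenceFormatError(f"unknown molecule type {self.molecule!r}")
        alphabet = PROTEIN_ALPHABET if self.molecule == "protein" else NUCLEOTIDE_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise SequenceFormatError(
                    f"illegal character {ch!r} at position {pos + 1} in {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Gapped, equal-length rows; all-gap columns are dropped on construction.

    Rows keep the :class:`SequenceRecord` id/description but permit the gap
    character. ``removed_columns`` records the (original, 0-based) indices of
    all-gap columns dropped to satisfy the class invariant.
    """

    rows: list  # list of (id, gapped string) pairs after validation
    molecule: str = "protein"
    removed_columns: list = field(default_factory=list)

    def __init__(self, records: Sequence[tuple[str, str]] | Sequence[SequenceRecord],
                 molecule: str = "protein"):
        pairs = []
        for rec in records:
            if isinstance(rec, SequenceRecord):
                pairs.append((rec.id, rec.residues))
            else:
                rid, res = rec
                pairs.append((rid, res.upper()))
        if len(pairs) < 2:
            raise SequenceFormatError("alignment needs at least 2 rows")
        lengths = {len(r) for _, r in pairs}
        if len(lengths) != 1:
            detail = ", ".join(f"{rid}:{len(r)}" for rid, r in pairs)
            raise SequenceFormatError(f"ragged alignment rows ({detail})")
        ids = [rid for rid, _ in pairs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceFormatError(f"duplicate row id {dup!r}")
        alphabet = (PROTEIN_ALPHABET if molecule == "protein" else NUCLEOTIDE_ALPHABET) | {GAP}
        for rid, res in pairs:
            for pos, ch in enumerate(res):
                if ch not in alphabet:
                    raise SequenceFormatError(
                        f"illegal character {ch!r} at column {pos + 1} in row {rid!r}"
                    )
        ncol = len(pairs[0][1])
        keep, removed = [], []
        for j in range(ncol):
            if all(res[j] == GAP for _, res in pairs):
                removed.append(j)
            else:
                keep.append(j)
        if not keep:
            raise SequenceFormatError("alignment has no non-gap columns")
        if removed:
            logger.info("dropped %d all-gap columns: %s", len(removed), removed)
            pairs = [(rid, "".join(res[j] for j in keep)) for rid, res in pairs]
        self.rows = pairs
        self.molecule = molecule
        self.removed_columns = removed

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, res in self.rows:
            if r == rid:
                return res
        raise KeyError(rid)

    def column(self, j: int) -> str:
        return "".join(res[j] for _, res in self.rows)

    def ungapped_record(self, rid: str) -> SequenceRecord:
        return SequenceRecord(rid, self.row(rid).replace(GAP, ""), self.molecule)

    def to_records(self) -> list[SequenceRecord]:
        return [self.ungapped_record(rid) for rid in self.ids]


@dataclass(frozen=True)
class Residue:
    """One residue of a backbone trace; missing atoms are None, never made up."""

    number: int
    name: str
    atoms: dict  # atom name -> np.ndarray(3,)
    confidence: float

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class StructureModel:
    """Backbone (N/CA/C/O) coordinates for one chain, with per-residue
    confidence read from the B-factor column (pLDDT convention)."""

    chain_id: str
    residues: list

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise SequenceFormatError(
                f"residue numbers not strictly increasing in chain {self.chain_id!r}"
            )
        for r in self.residues:
            if "CA" not in r.atoms:
                raise SequenceFormatError(
                    f"residue {r.number} in chain {self.chain_id!r} lacks a CA atom"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def confidences(self) -> np.ndarray:
        return np.array([r.confidence for r in self.residues])

    def by_number(self) -> dict:
        return {r.number: r for r in self.residues}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, molecule: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Terminal ``*`` stop characters on protein sequences are stripped (and
    logged); duplicate ids and illegal characters raise
    :class:`SequenceFormatError`.
    """
    path = Path(path)
    raw = list(_BioSeqIO.parse(str(path), "fasta"))
    if not raw:
        raise SequenceFormatError(f"no FASTA records in {path}")
    records, seen = [], set()
    for r in raw:
        if r.id in seen:
            raise SequenceFormatError(f"duplicate sequence id {r.id!r} in {path}")
        seen.add(r.id)
        seq = str(r.seq).upper()
        if molecule == "protein" and seq.endswith("*"):
            logger.info("stripped terminal stop from %s", r.id)
            seq = seq[:-1]
        records.append(SequenceRecord(r.id, seq, molecule, r.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    recs = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_alignment(path, molecule: str = "protein") -> Alignment:
    """Read an aligned FASTA file; all-gap columns are dropped (reported on
    the returned object's ``removed_columns``)."""
    path = Path(path)
    raw = list(_BioSeqIO.parse(str(path), "fasta"))
    if not raw:
        raise SequenceFormatError(f"no FASTA records in {path}")
    return Alignment([(r.id, str(r.seq)) for r in raw], molecule=molecule)


def write_alignment(alignment: Alignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, res in alignment.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(res), width):
                fh.write(res[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")


def read_structure(path, chain: str) -> StructureModel:
    """Extract one chain's backbone and confidence from PDB ATOM records.

    Alternate locations are resolved by keeping the highest-occupancy copy
    (ties keep the first encountered, logged). Absent chains raise with the
    list of available chains; a chain without CA atoms is an error.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model = st[0]
    names = [ch.name for ch in model]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise SequenceFormatError(
            f"chain {chain!r} not found; available chains: {sorted(set(names))}"
        )
    residues = []
    for res in target:
        atoms: dict = {}
        conf = None
        for atom in res:
            if atom.name not in _BACKBONE:
                continue
            if atom.name in atoms:
                prev_occ, _ = atoms[atom.name]
                if atom.occ > prev_occ:
                    atoms[atom.name] = (atom.occ, atom)
                else:
                    logger.info(
                        "altloc tie at residue %d atom %s: keeping first",
                        res.seqid.num, atom.name)
            else:
                atoms[atom.name] = (atom.occ, atom)
        if not atoms:
            continue
        coords = {n: np.array([a.pos.x, a.pos.y, a.pos.z]) for n, (_, a) in atoms.items()}
        conf = next(iter(atoms.values()))[1].b_iso
        if "CA" in atoms:
            conf = atoms["CA"][1].b_iso
        missing = [n for n in _BACKBONE if n not in coords]
        if missing:
            logger.info("residue %d missing backbone atoms %s", res.seqid.num, missing)
        residues.append(Residue(res.seqid.num, res.name, coords, float(conf)))
    if not any("CA" in r.atoms for r in residues):
        raise SequenceFormatError(f"chain {chain!r} has no CA atoms")
    residues = [r for r in residues if "CA" in r.atoms]
    return StructureModel(chain, residues)


def write_structure(model: StructureModel, path) -> None:
    """Write backbone ATOM records (PDB fixed-width, 3-decimal coordinates)."""
    serial = 1
    with open(path, "w") as fh:
        for res in model.residues:
            for name in _BACKBONE:
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{res.name:>3s} {model.chain_id:1s}"
                    f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
                    f"{res.confidence:6.2f}           {name[0]:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Identity statistics
# ---------------------------------------------------------------------------

def mean_pairwise_identity(alignment: Alignment, columns: range | None = None) -> float:
    """Mean percent identity over all unordered row pairs.

    The denominator for a pair is the number of columns where at least one
    row is non-gap (union convention — indels count against identity). ``X``
    never counts as identical. Pairs with no countable positions are
    excluded from the mean (logged).
    """
    if columns is None:
        columns = range(alignment.n_columns)
    else:
        if columns.start < 0 or columns.stop > alignment.n_columns:
            raise ValueError(
                f"column range [{columns.start}, {columns.stop}) outside "
                f"[0, {alignment.n_columns})"
            )
    seqs = [res for _, res in alignment.rows]
    values = []
    for a, b in combinations(seqs, 2):
        ident = countable = 0
        for j in columns:
            ca, cb = a[j], b[j]
            if ca == GAP and cb == GAP:
                continue
            countable += 1
            if ca == cb and ca != GAP and ca != "X":
                ident += 1
        if countable == 0:
            logger.info("pair with zero countable positions excluded")
            continue
        values.append(100.0 * ident / countable)
    if not values:
        raise ValueError("no pairs with countable positions")
    return float(np.mean(values))
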