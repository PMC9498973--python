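"""Sequence and metadata I/O plus the shared data model.

Sequences are nuclear ribosomal ITS barcodes (or any short marker): strings
over the DNA alphabet A/C/G/T, IUPAC ambiguity codes, and ``-`` for
alignment gaps.  Every sample carries a species label, an optional locality
and an optional GenBank-style accession; exactly one species per dataset may
be flagged as the outgroup used for tree rooting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
BASES = "ACGT"

#: IUPAC nucleotide ambiguity codes -> the set of bases they stand for.
IUPAC_AMBIGUITY: Mapping[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ALPHABET = frozenset(BASES) | frozenset(IUPAC_AMBIGUITY) | {GAP}

METADATA_COLUMNS = ("sample_id", "species", "locality", "accession", "is_outgroup")


class SequenceError(ValueError):
    """Malformed sequence data (bad alphabet, ragged alignment, ...)."""


class MetadataError(ValueError):
    """Malformed or inconsistent sample metadata."""


def ambiguity_set(char: str) -> frozenset[str]:
    """Bases an alignment character may stand for (gap -> empty set)."""
    if char in IUPAC_AMBIGUITY:
        return IUPAC_AMBIGUITY[char]
    if char in BASES:
        return frozenset(char)
    if char == GAP:
        return frozenset()
    raise SequenceError(f"not a nucleotide character: {char!r}")


@dataclass
class SequenceRecord:
    """One sample's barcode sequence with its metadata."""

    id: str
    seq: str
    species: str = ""
    locality: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq, record_id=self.id)

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    species: str
    locality: str = ""
    accession: str = ""
    is_outgroup: bool = False


@dataclass
class Alignment:
    """A rectangular character matrix with labelled rows.

    All reported column coordinates are 1-based inclusive.
    """

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment needs at least one record")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise SequenceError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate record ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def to_matrix(self) -> np.ndarray:
        """Rows as a (n_records, length) array of single characters."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")

    def column(self, pos: int) -> str:
        """Column ``pos`` (1-based) as a string, one character per row."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"column {pos} outside 1..{self.length}")
        return "".join(r.seq[pos - 1] for r in self.records)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of columns ``start..end`` (1-based inclusive)."""
        if not (1 <= start <= end <= self.length):
            raise IndexError(f"span {start}..{end} outside 1..{self.length}")
        return Alignment(
            [replace(r, seq=r.seq[start - 1 : end]) for r in self.records]
        )

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {r.id: r for r in self.records}
        return Alignment([index[i] for i in ids])


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase, map U->T and '.'->'-', and validate the alphabet."""
    if not seq:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    out = seq.upper().replace("U", "T").replace(".", GAP)
    for pos, ch in enumerate(out, start=1):
        if ch not in ALPHABET:
            raise SequenceError(
                f"record {record_id!r}: illegal character {ch!r} at position {pos}"
            )
    return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects."""
    path = Path(path)
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"{path}: duplicate sequence ids {dup}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA; round-trips ids and sequences exactly."""
    records = list(records)
    if not records:
        raise SequenceError("refusing to write an empty FASTA file")
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the 5-column sample metadata TSV.

    Columns: sample_id, species, locality, accession, is_outgroup (0/1).
    """
    path = Path(path)
    rows: list[SampleMetadata] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(METADATA_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise MetadataError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            rows.append(
                SampleMetadata(
                    sample_id=row["sample_id"].strip(),
                    species=row["species"].strip(),
                    locality=(row["locality"] or "").strip(),
                    accession=(row["accession"] or "").strip(),
                    is_outgroup=_parse_flag(row["is_outgroup"], path),
                )
            )
    seen: set[str] = set()
    for r in rows:
        if r.sample_id in seen:
            raise MetadataError(f"{path}: duplicate sample_id {r.sample_id!r}")
        seen.add(r.sample_id)
    outgroups = {r.species for r in rows if r.is_outgroup}
    if len(outgroups) > 1:
        raise MetadataError(
            f"{path}: more than one outgroup species: {sorted(outgroups)}"
        )
    return rows


def write_metadata(rows: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.sample_id, r.species, r.locality, r.accession, int(r.is_outgroup)]
            )


def _parse_flag(value: str | None, path: Path) -> bool:
    v = (value or "").strip().lower()
    if v in {"0", "false", "no", ""}:
        return False
    if v in {"1", "true", "yes"}:
        return True
    raise MetadataError(f"{path}: is_outgroup value {value!r} not parseable")


def attach_metadata(
    records: Sequence[SequenceRecord], metadata: Sequence[SampleMetadata]
) -> list[SequenceRecord]:
    """Join sequences to metadata by sample id; the join must be total."""
    table = {m.sample_id: m for m in metadata}
    out = []
    for r in records:
        if r.id not in table:
            raise MetadataError(f"sample {r.id!r} in FASTA but not in metadata")
        m = table[r.id]
        out.append(
            replace(r, species=m.species, locality=m.locality, accession=m.accession)
        )
    return out


def species_map(metadata: Sequence[SampleMetadata]) -> dict[str, str]:
    """sample_id -> species lookup."""
    return {m.sample_id: m.species for m in metadata}


def outgroup_species(metadata: Sequence[SampleMetadata]) -> str | None:
    for m in metadata:
        if m.is_outgroup:
            return m.species
    return None
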