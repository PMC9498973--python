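"""Collapse identical aligned sequences into haplotypes.

Haplotype identity is exact string equality on the aligned sequence after
trimming columns that are gaps in every row: indels distinguish haplotypes
(two sequences differing by a single 1-bp deletion are distinct) and IUPAC
ambiguity codes are distinct states.  By default collapsing is per species,
so two species sharing a sequence still get distinct haplotype ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import pandas as pd

from .seqio import (
    GAP,
    Alignment,
    SampleMetadata,
    SequenceError,
    SequenceRecord,
)

Scope = Literal["per-species", "global"]


@dataclass
class Haplotype:
    hap_id: str
    representative: str  # aligned sequence (all-gap edge columns trimmed)
    species: str  # "" under global scope with mixed membership
    members: list[str] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]
    scope: Scope = "per-species"

    def __post_init__(self) -> None:
        reps = set()
        for h in self.haplotypes:
            if not h.members:
                raise ValueError(f"haplotype {h.hap_id} has no members")
            key = (h.species if self.scope == "per-species" else "", h.representative)
            if key in reps:
                raise ValueError(f"duplicate representative for {h.hap_id}")
            reps.add(key)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_samples(self) -> int:
        return sum(h.frequency for h in self.haplotypes)

    def richness_by_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.haplotypes:
            out[h.species] = out.get(h.species, 0) + 1
        return out

    def membership(self) -> dict[str, str]:
        """sample_id -> hap_id."""
        return {m: h.hap_id for h in self.haplotypes for m in h.members}

    def partition(self) -> set[frozenset[str]]:
        """The sample partition, ignoring haplotype labels."""
        return {frozenset(h.members) for h in self.haplotypes}


def _species_prefix(species: str, taken: set[str]) -> str:
    initials = "".join(w[0] for w in species.replace(".", " ").split() if w).upper()
    prefix = initials or "H"
    candidate = prefix
    k = 2
    while candidate in taken:
        candidate = f"{prefix}{k}_"
        k += 1
    taken.add(candidate)
    return candidate


def trim_flanking_gap_columns(alignment: Alignment) -> Alignment:
    """Drop leading/trailing columns that are gaps in every row."""
    L = alignment.length
    seqs = [r.seq for r in alignment.records]
    lo = 0
    while lo < L and all(s[lo] == GAP for s in seqs):
        lo += 1
    hi = L
    while hi > lo and all(s[hi - 1] == GAP for s in seqs):
        hi -= 1
    if lo == 0 and hi == L:
        return alignment
    if lo >= hi:
        raise SequenceError("alignment is entirely gaps")
    return alignment.slice_columns(lo + 1, hi)


def collapse_haplotypes(
    alignment: Alignment,
    metadata: Sequence[SampleMetadata],
    scope: Scope = "per-species",
) -> HaplotypeTable:
    """Group identical aligned sequences into haplotypes.

    Ids are deterministic: a species-derived prefix (or ``H`` under global
    scope) plus the rank of first occurrence in the input row order.
    """
    if scope not in ("per-species", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    species_of = {m.sample_id: m.species for m in metadata}
    for rec in alignment.records:
        if rec.id not in species_of:
            raise SequenceError(f"sample {rec.id!r} missing from metadata")
    trimmed = trim_flanking_gap_columns(alignment)

    groups: dict[tuple[str, str], Haplotype] = {}
    order: list[tuple[str, str]] = []
    for rec in trimmed.records:
        sp = species_of[rec.id]
        key = (sp if scope == "per-species" else "", rec.seq)
        if key not in groups:
            groups[key] = Haplotype(
                hap_id="", representative=rec.seq, species=key[0], members=[]
            )
            order.append(key)
        groups[key].members.append(rec.id)

    prefixes: dict[str, str] = {}
    counters: dict[str, int] = {}
    taken: set[str] = set()
    haplotypes = []
    for key in order:
        hap = groups[key]
        group_label = hap.species if scope == "per-species" else ""
        if group_label not in prefixes:
            prefixes[group_label] = (
                _species_prefix(group_label, taken) if group_label else "H"
            )
            counters[group_label] = 0
        counters[group_label] += 1
        hap.hap_id = f"{prefixes[group_label]}{counters[group_label]}"
        if scope == "global":
            members_sp = {species_of[m] for m in hap.members}
            hap.species = members_sp.pop() if len(members_sp) == 1 else ""
        haplotypes.append(hap)
    return HaplotypeTable(haplotypes, scope=scope)


def counts_by_group(
    table: HaplotypeTable,
    metadata: Sequence[SampleMetadata],
    group: Literal["species", "locality"] = "species",
) -> pd.DataFrame:
    """Per-group haplotype richness and per-haplotype sample frequencies.

    One row per (group value, haplotype) pair with the number of member
    samples from that group; total counts are preserved.
    """
    if group not in ("species", "locality"):
        raise ValueError(f"unknown group key {group!r}")
    lookup = {m.sample_id: getattr(m, group) for m in metadata}
    rows = []
    for hap in table.haplotypes:
        per_group: dict[str, int] = {}
        for m in hap.members:
            g = lookup[m]
            per_group[g] = per_group.get(g, 0) + 1
        for g, n in sorted(per_group.items()):
            rows.append({group: g, "hap_id": hap.hap_id, "count": n})
    df = pd.DataFrame(rows, columns=[group, "hap_id", "count"])
    return df.sort_values([group, "hap_id"], kind="stable").reset_index(drop=True)


def group_richness(counts: pd.DataFrame) -> pd.Series:
    """Haplotype richness per group from a counts_by_group table."""
    group_col = counts.columns[0]
    return counts.groupby(group_col)["hap_id"].nunique()


def representative_alignment(table: HaplotypeTable) -> Alignment:
    """One row per haplotype (labelled by hap_id) for downstream analyses."""
    return Alignment(
        [
            SequenceRecord(
                id=h.hap_id, seq=h.representative, species=h.species
            )
            for h in table.haplotypes
        ]
    )


def haplotype_table_frame(table: HaplotypeTable) -> pd.DataFrame:
    """Flat report: hap_id, species, frequency, member sample ids."""
    return pd.DataFrame(
        [
            {
                "hap_id": h.hap_id,
                "species": h.species,
                "frequency": h.frequency,
                "members": ",".join(h.members),
            }
            for h in table.haplotypes
        ]
    )
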