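"""Alignment-column classification and species-diagnostic site calling.

A column is *variable* when at least two distinct unambiguous bases occur
among the included rows; variable columns where at least two states each
occur in at least two rows are *parsimony-informative*.  A (position,
state) pair is *diagnostic* for a species when every conspecific row
carries exactly that state and no row of any other ingroup species can
carry it.  Diagnostic sites operationalize barcode-based identification:
a query matching a species' complete diagnostic set is assigned to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    BASES,
    GAP,
    IUPAC_AMBIGUITY,
    Alignment,
    SampleMetadata,
    SequenceError,
    ambiguity_set,
)


@dataclass(frozen=True)
class SitePolicy:
    """How gaps and ambiguity codes enter diagnostic-site calling.

    Ambiguity within the candidate species always disqualifies a column.
    An ambiguity code in another species disqualifies the candidate state
    when its base set contains that state (conservative: it *might* match).
    Gaps in other species count as a different state; a gap is itself a
    legal diagnostic state only when ``allow_indel_diagnostics`` is set.
    """

    allow_indel_diagnostics: bool = False


@dataclass
class DiagnosticKey:
    sites: dict[str, list[tuple[int, str]]]
    low_confidence: set[str] = field(default_factory=set)  # single-row species

    @property
    def species_with_sites(self) -> list[str]:
        return [s for s, v in self.sites.items() if v]

    @property
    def species_without_sites(self) -> list[str]:
        return [s for s, v in self.sites.items() if not v]


def _included_rows(
    alignment: Alignment,
    metadata: Sequence[SampleMetadata] | None,
    include_outgroup: bool,
) -> list[int]:
    if metadata is None:
        return list(range(len(alignment)))
    meta = {m.sample_id: m for m in metadata}
    rows = []
    for i, rec in enumerate(alignment.records):
        if rec.id not in meta:
            raise SequenceError(f"sample {rec.id!r} missing from metadata")
        if include_outgroup or not meta[rec.id].is_outgroup:
            rows.append(i)
    return rows


def classify_sites(
    alignment: Alignment,
    metadata: Sequence[SampleMetadata] | None = None,
    include_outgroup: bool = False,
) -> pd.DataFrame:
    """Classify every column; positions are 1-based alignment coordinates.

    Returns a frame with position, per-base counts, gap/ambiguity flags and
    a mutually exclusive class in {invariant, variable,
    parsimony-informative}.  Outgroup rows are excluded by default when
    metadata is supplied.
    """
    rows = _included_rows(alignment, metadata, include_outgroup)
    mat = alignment.to_matrix()[rows]
    records = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        counts = {b: int((col == b).sum()) for b in BASES}
        n_gap = int((col == GAP).sum())
        n_amb = len(col) - n_gap - sum(counts.values())
        states = [b for b in BASES if counts[b] > 0]
        if len(states) < 2:
            klass = "invariant"
        elif sum(1 for b in states if counts[b] >= 2) >= 2:
            klass = "parsimony-informative"
        else:
            klass = "variable"
        records.append(
            {
                "position": j + 1,
                **{f"n_{b}": counts[b] for b in BASES},
                "n_gap": n_gap,
                "n_ambiguous": n_amb,
                "gap_present": n_gap > 0,
                "ambiguity_present": n_amb > 0,
                "class": klass,
            }
        )
    return pd.DataFrame(records)


def variable_site_count(report: pd.DataFrame) -> int:
    """Number of variable columns (singleton variants plus informative)."""
    return int((report["class"] != "invariant").sum())


def diagnostic_sites(
    alignment: Alignment,
    metadata: Sequence[SampleMetadata],
    policy: SitePolicy = SitePolicy(),
) -> DiagnosticKey:
    """Call species-diagnostic (position, state) pairs; outgroup excluded."""
    meta = {m.sample_id: m for m in metadata}
    ingroup_rows: dict[str, list[int]] = {}
    for i, rec in enumerate(alignment.records):
        if rec.id not in meta:
            raise SequenceError(f"sample {rec.id!r} missing from metadata")
        m = meta[rec.id]
        if not m.is_outgroup:
            ingroup_rows.setdefault(m.species, []).append(i)
    if len(ingroup_rows) < 2:
        raise ValueError("diagnostic sites need at least two ingroup species")

    mat = alignment.to_matrix()
    key = DiagnosticKey(sites={sp: [] for sp in ingroup_rows})
    key.low_confidence = {sp for sp, r in ingroup_rows.items() if len(r) == 1}

    for j in range(alignment.length):
        col = mat[:, j]
        for sp, rows in ingroup_rows.items():
            own = set(col[rows])
            if len(own) != 1:
                continue
            state = own.pop()
            if state in IUPAC_AMBIGUITY:
                continue  # ambiguity within the species disqualifies
            if state == GAP and not policy.allow_indel_diagnostics:
                continue
            others = [
                c
                for osp, orows in ingroup_rows.items()
                if osp != sp
                for c in col[orows]
            ]
            if _state_possible_elsewhere(state, others):
                continue
            key.sites[sp].append((j + 1, str(state)))
    return key


def _state_possible_elsewhere(state: str, others: Sequence[str]) -> bool:
    for c in others:
        if c == state:
            return True
        if c in IUPAC_AMBIGUITY and state in IUPAC_AMBIGUITY[c]:
            return True  # conservative: the ambiguous base might match
    return False


def identify_sample(
    query: str, key: DiagnosticKey, alignment_length: int | None = None
) -> tuple[str, dict[str, list[tuple[int, str]]]]:
    """Assign a query row (aligned to the master alignment) to a species.

    Returns (call, matches) where call is the species matching its full
    diagnostic set, ``"ambiguous"`` when several species match, or
    ``"no-call"`` when none does.  Species without diagnostic sites can
    never be called.
    """
    if alignment_length is not None and len(query) != alignment_length:
        raise SequenceError(
            f"query length {len(query)} != alignment length {alignment_length}"
        )
    query = query.upper()
    matches: dict[str, list[tuple[int, str]]] = {}
    for sp, sites in key.sites.items():
        if not sites:
            continue
        if any(pos > len(query) for pos, _ in sites):
            raise SequenceError("query shorter than diagnostic positions")
        if all(query[pos - 1] == state for pos, state in sites):
            matches[sp] = list(sites)
    if not matches:
        return "no-call", matches
    if len(matches) > 1:
        return "ambiguous", matches
    return next(iter(matches)), matches


def key_to_dict(key: DiagnosticKey) -> dict:
    """JSON-ready form: {species: [{"pos": p, "state": s}, ...]}."""
    return {
        sp: [{"pos": p, "state": s} for p, s in sites]
        for sp, sites in key.sites.items()
    }


def key_from_dict(data: Mapping[str, Sequence[Mapping]]) -> DiagnosticKey:
    return DiagnosticKey(
        sites={
            sp: [(int(e["pos"]), str(e["state"])) for e in entries]
            for sp, entries in data.items()
        }
    )
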