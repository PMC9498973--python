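"""Partition an ITS alignment into ITS1 / 5.8S / ITS2 and per-region stats.

The 5.8S rRNA gene is highly conserved across the genus (canonically 164 bp
here) while the flanking spacers vary, so when explicit boundaries are not
supplied the gene is located as the minimum-diversity window of the
configured length; ITS1 is everything to its left, ITS2 everything to its
right.  Lengths and GC are reported per record over ungapped characters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import BASES, GAP, Alignment

DEFAULT_58S_LENGTH = 164


@dataclass(frozen=True)
class RegionBoundaries:
    """1-based inclusive column spans on the master alignment."""

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self) -> None:
        (a1, b1), (a2, b2), (a3, b3) = self.its1, self.r58s, self.its2
        spans = [s for s in (self.its1, self.r58s, self.its2) if s[1] >= s[0]]
        for lo, hi in spans:
            if lo < 1:
                raise ValueError(f"span {lo}..{hi} not 1-based")
        if not (b1 + 1 == a2 and b2 + 1 == a3):
            # ITS1 may be empty (b1 = a1 - 1) but spans must stay contiguous
            raise ValueError(
                f"regions not contiguous: ITS1 {self.its1}, 5.8S {self.r58s}, "
                f"ITS2 {self.its2}"
            )

    @classmethod
    def from_58s_span(cls, start: int, end: int, aln_length: int) -> "RegionBoundaries":
        return cls(
            its1=(1, start - 1), r58s=(start, end), its2=(end + 1, aln_length)
        )


def parse_boundaries(text: str) -> "RegionBoundaries":
    """Parse ``its1:1-246,58s:247-410,its2:411-633`` style strings."""
    spans: dict[str, tuple[int, int]] = {}
    for part in text.split(","):
        name, _, rng = part.strip().partition(":")
        lo, _, hi = rng.partition("-")
        spans[name.strip().lower()] = (int(lo), int(hi))
    try:
        return RegionBoundaries(
            its1=spans["its1"], r58s=spans["58s"], its2=spans["its2"]
        )
    except KeyError as exc:
        raise ValueError(f"boundary spec missing region {exc}") from exc


def _column_diversity(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per column: (#rows not carrying the modal base, modal-state-is-gap)."""
    mat = alignment.to_matrix()
    n = mat.shape[0]
    base_counts = np.stack([(mat == b).sum(axis=0) for b in BASES])
    gap_counts = (mat == GAP).sum(axis=0)
    modal = base_counts.max(axis=0)
    diversity = n - modal
    gap_modal = gap_counts > modal
    return diversity, gap_modal


def infer_58s_window(
    alignment: Alignment, window_len: int = DEFAULT_58S_LENGTH
) -> RegionBoundaries:
    """Locate the conserved 5.8S gene as the minimum-diversity window.

    The window of ``window_len`` consecutive columns (none of which may have
    a gap as its modal state) minimizing total column diversity is returned;
    ties break to the leftmost window.
    """
    L = alignment.length
    if L <= window_len:
        raise ValueError(
            f"alignment length {L} must exceed the 5.8S window ({window_len})"
        )
    diversity, gap_modal = _column_diversity(alignment)
    div_cum = np.concatenate([[0], np.cumsum(diversity)])
    gap_cum = np.concatenate([[0], np.cumsum(gap_modal)])

    best_start = -1
    best_score = None
    for start in range(0, L - window_len + 1):
        end = start + window_len
        if gap_cum[end] - gap_cum[start] > 0:
            continue
        score = div_cum[end] - div_cum[start]
        if best_score is None or score < best_score:
            best_score = score
            best_start = start
    if best_start < 0:
        raise ValueError(
            "no gap-consensus-free window of the requested length; "
            "supply boundaries manually"
        )
    return RegionBoundaries.from_58s_span(best_start + 1, best_start + window_len, L)


def _region_values(seq: str) -> tuple[int, float]:
    """(ungapped length, GC% over unambiguous bases; NaN if none)."""
    counts = {b: seq.count(b) for b in BASES}
    unambiguous = sum(counts.values())
    length = sum(1 for c in seq if c != GAP)
    if unambiguous == 0:
        return length, float("nan")
    gc = 100.0 * (counts["G"] + counts["C"]) / unambiguous
    return length, gc


def region_stats(
    alignment: Alignment, boundaries: RegionBoundaries
) -> pd.DataFrame:
    """Per-record region lengths (bp, ungapped) and GC content (%).

    GC excludes gaps and ambiguity codes from both numerator and
    denominator.  Values are full precision; round at the reporting layer.
    """
    for lo, hi in (boundaries.its1, boundaries.r58s, boundaries.its2):
        if hi >= lo and not (1 <= lo and hi <= alignment.length):
            raise ValueError(f"span {lo}..{hi} outside alignment 1..{alignment.length}")
    rows = []
    for rec in alignment.records:
        row: dict[str, object] = {"id": rec.id, "species": rec.species}
        total_len = 0
        for name, (lo, hi) in (
            ("its1", boundaries.its1),
            ("58s", boundaries.r58s),
            ("its2", boundaries.its2),
        ):
            segment = rec.seq[lo - 1 : hi] if hi >= lo else ""
            length, gc = _region_values(segment)
            row[f"{name}_len"] = length
            row[f"gc_{name}"] = gc
            total_len += length
        row["total_len"], row["gc_total"] = _region_values(
            rec.seq[boundaries.its1[0] - 1 : boundaries.its2[1]]
        )
        assert row["total_len"] == total_len
        rows.append(row)
    return pd.DataFrame(rows)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero (report convention; numpy rounds half-even)."""
    if not np.isfinite(value):
        return value
    factor = 10.0 ** decimals
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)


def format_region_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: GC rounded half away from zero to 2 decimals."""
    out = stats.copy()
    for col in out.columns:
        if col.startswith("gc_"):
            out[col] = out[col].map(round_half_up)
    return out
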