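"""Published reference data for an eight-species *Actinidia* ITS survey.

The survey genotyped 185 samples of *A. eriantha* and seven relatives
(plus a *Saurauia tristyla* outgroup) and printed, for its 46 ITS
haplotypes, the haplotype-by-variable-site matrix over 38 reported
positions (1-based coordinates on the study's master alignment).  That
printed matrix is reproduced here verbatim — ``*`` meaning "same state as
the first haplotype" and ``/`` a deletion — so diagnostic-site detection
and sample identification can be exercised against real published
genotypes without any sequence download.  The matrix covers only the
printed variable positions, not the full ~630 bp sequences.
"""

from __future__ import annotations

from .seqio import Alignment, SampleMetadata, SequenceRecord

#: 1-based positions of the printed variable sites on the study alignment.
VARIATION_POSITIONS: tuple[int, ...] = (
    28, 48, 73, 79, 83, 85, 92, 93, 95,
    109, 115, 122, 128, 147, 184, 205, 232,
    416, 422, 435, 436, 446, 448, 487, 493, 501,
    530, 542, 574, 582, 602, 603, 604, 605, 606, 610, 620, 640,
)

#: Haplotype prefix -> species, as printed.
PREFIX_SPECIES: dict[str, str] = {
    "MH": "Actinidia eriantha",
    "CY": "Actinidia hemsleyana",
    "DE": "Actinidia valvata",
    "GZ": "Actinidia polygama",
    "HL": "Actinidia melanandra",
    "WD": "Actinidia arguta",
    "YS": "Actinidia callosa",
    "ZH": "Actinidia chinensis",
}

#: Sample count behind each haplotype (from the survey's sample table).
HAPLOTYPE_COUNTS: dict[str, int] = {
    "MH1": 43, "MH2": 1, "MH3": 5, "MH4": 2, "MH5": 1, "MH6": 1, "MH7": 1,
    "MH8": 1, "MH9": 1,
    "GZ1": 12, "GZ2": 3, "GZ3": 1, "GZ4": 2, "GZ5": 1,
    "HL1": 11, "HL2": 1, "HL3": 1, "HL4": 1,
    "WD1": 10, "WD2": 1, "WD3": 1, "WD4": 4, "WD5": 1, "WD6": 1,
    "ZH1": 21, "ZH2": 1, "ZH3": 1, "ZH4": 1, "ZH5": 1, "ZH6": 2,
    "DE1": 10, "DE2": 1, "DE3": 1, "DE4": 3, "DE5": 1,
    "CY1": 11, "CY2": 3, "CY3": 1,
    "YS1": 10, "YS2": 1, "YS3": 1, "YS4": 1, "YS5": 1, "YS6": 1, "YS7": 1,
    "YS8": 1,
}

# The printed matrix, one 38-character string per haplotype.
# '*' = state of MH1 (the reference row); '/' = deletion.
_MH1 = "CCCCTCCCT" "CGG/GTTCG" "TACACTCCA" "GCCTTACTG" "G/"
_STAR = "*********" "***/*****" "*********" "*********" "*/"
VARIATION_ROWS: dict[str, str] = {
    "MH1": _MH1,
    "MH2": _STAR, "MH3": _STAR, "MH4": _STAR, "MH5": _STAR, "MH6": _STAR,
    "MH7": _STAR, "MH8": _STAR, "MH9": _STAR,
    "CY1": "T*TAAT***" "T**A**A**" "****T*TT*" "ATG*****T" "*/",
    "CY2": "T*TAAT***" "T**A**A**" "****T*TT*" "ATG*****T" "*/",
    "CY3": "T*TAAT***" "T**A**A**" "****T*TT*" "ATG*****T" "*/",
    "DE1": "*GA**TT*C" "**C/*CAA*" "*C***CT*G" "ATGC*G**C" "TT",
    "DE2": "*GA**TT*C" "**C/*CAA*" "*C***CT*G" "ATGC*G**C" "TT",
    "DE3": "*GA**TT*C" "**C/*CAA*" "*C***CT*G" "ATGC*G**C" "TT",
    "DE4": "*GA**TT*C" "**C/*CAA*" "*C***CT*G" "ATGC*G**C" "TT",
    "DE5": "*GA**TT*C" "**C/*CAA*" "*C***CT*G" "ATGC*G**C" "TT",
    "GZ1": "*TT**T*T*" "*A*/T*A*A" "**T***T**" "ATG*GCTCT" "*/",
    "GZ2": "*TT**T*T*" "*A*/T*A*A" "**T*G*T**" "ATG*GCTCT" "*/",
    "GZ3": "*TT**T*T*" "*A*/T*A*A" "**T*G*T**" "ATG*GCTCT" "*/",
    "GZ4": "*TT**T*T*" "*A*/T*A*A" "**T***T**" "ATG*GCTCT" "*/",
    "GZ5": "*TT**T*T*" "*A*/T*A*A" "**T*G*T**" "ATG*GCTCT" "*/",
    "HL1": "**/G*T***" "***/**A**" "*G****T**" "ATG**G**C" "*/",
    "HL2": "**T**T***" "***/**A**" "******T**" "ATG**T**C" "*/",
    "HL3": "*****T***" "***/**A**" "*G****T**" "ATG**G**C" "*/",
    "HL4": "**/G*T***" "***/**A**" "******T**" "ATG**T**C" "*/",
    "WD1": "**T**T***" "***/**A**" "******T**" "ATG**G**C" "*/",
    "WD2": "**/G*T***" "***/**A**" "******T**" "ATG**G**C" "*/",
    "WD3": "**T**T***" "***/**A**" "******T**" "ATG**G**C" "*/",
    "WD4": "**/G*T***" "***/**A**" "******T**" "ATG**G**C" "*/",
    "WD5": "**/G*T***" "***/**A**" "******T**" "ATG**G**C" "*/",
    "WD6": "**T**T***" "***/**A**" "******T**" "ATG**G**C" "*/",
    "YS1": "*****T***" "***/**A**" "C**G**T**" "ATG*****T" "*/",
    "YS2": "*****T***" "***/**A**" "C**G**T**" "ATG*****T" "*/",
    "YS3": "*****T***" "***/**A**" "C**G**T**" "ATG*****T" "*/",
    "YS4": "*****T***" "***/**A**" "C**G**T**" "ATT*****C" "*/",
    "YS5": "*****T***" "***/**A**" "C**G**T**" "ATT*****C" "*/",
    "YS6": "*****T***" "***/**A**" "C**G**T**" "ATG*****T" "*/",
    "YS7": "*****T***" "***/**A**" "C**G**T**" "ATG*****T" "*/",
    "YS8": "*TTTCT***" "***/**A**" "C**G**T**" "ATT*****C" "*/",
    "ZH1": "*TTTCT***" "***/A*A**" "******T**" "ATG*****T" "*/",
    "ZH2": "*TTTCT***" "***/**A**" "******T**" "ATG*****T" "*/",
    "ZH3": "**TT*T***" "***/A*A**" "******T**" "ATG*****T" "*/",
    "ZH4": "**TTCT***" "***/**A**" "******T**" "ATG*****T" "*/",
    "ZH5": "**TT*T***" "***/**A**" "******T**" "ATG*****T" "*/",
    "ZH6": "**TT*T***" "***/A*A**" "******T**" "ATG*****T" "*/",
}


def expand_row(hap_id: str) -> str:
    """Resolve '*' against the MH1 reference and '/' to a gap character."""
    row = VARIATION_ROWS[hap_id]
    if len(row) != len(VARIATION_POSITIONS):
        raise AssertionError(f"row {hap_id} has {len(row)} states")
    out = []
    for state, ref in zip(row, _MH1):
        state = ref if state == "*" else state
        out.append("-" if state == "/" else state)
    return "".join(out)


def published_variation_alignment() -> tuple[Alignment, list[SampleMetadata]]:
    """The printed variable-site matrix as a 46 x 38 alignment.

    Columns are the printed positions in order (use
    :data:`VARIATION_POSITIONS` to translate back to study coordinates);
    the outgroup is not part of the printed matrix, so the metadata carry
    no outgroup flag.
    """
    records = []
    metadata = []
    for hap_id in VARIATION_ROWS:
        species = PREFIX_SPECIES[hap_id[:2]]
        records.append(
            SequenceRecord(id=hap_id, seq=expand_row(hap_id), species=species)
        )
        metadata.append(SampleMetadata(sample_id=hap_id, species=species))
    return Alignment(records), metadata


def study_position(column: int) -> int:
    """Translate a matrix column (1-based) to the study's printed position."""
    return VARIATION_POSITIONS[column - 1]


def matrix_column(position: int) -> int:
    """Translate a printed study position to the matrix column (1-based)."""
    return VARIATION_POSITIONS.index(position) + 1
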