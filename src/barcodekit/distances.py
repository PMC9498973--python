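"""Kimura two-parameter (K80) distances and their intra/inter-species structure.

For an aligned pair, columns where either row carries a gap or an IUPAC
ambiguity code are deleted pairwise; over the remaining L sites P is the
proportion of transitions (A<->G, C<->T) and Q the proportion of
transversions, and

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

in expected substitutions per site.  The distance is undefined (flagged,
never fabricated) when the logarithm's argument leaves its domain or no
sites survive pairwise deletion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import Alignment, SequenceError

# base encoding used throughout the numeric layer: A=0 C=1 G=2 T=3;
# gaps/ambiguity -> -1 (missing for pairwise comparison purposes)
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}
PURINES = {0, 2}
PYRIMIDINES = {1, 3}


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """(n_rows, L) int8 matrix; -1 marks gap or ambiguity."""
    mat = alignment.to_matrix()
    out = np.full(mat.shape, -1, dtype=np.int8)
    for base, code in _ENCODE.items():
        out[mat == base] = code
    return out


def _is_transition(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    both_purine = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    both_pyrimidine = np.isin(a, (1, 3)) & np.isin(b, (1, 3))
    return (a != b) & (both_purine | both_pyrimidine)


@dataclass(frozen=True)
class DistancePair:
    P: float
    Q: float
    L_valid: int
    d: float  # NaN when undefined
    defined: bool


def k2p_from_proportions(P: float, Q: float) -> tuple[float, bool]:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan"), False
    return -0.5 * math.log(w1 * math.sqrt(w2)), True


def k2p_distance(a: str | np.ndarray, b: str | np.ndarray) -> DistancePair:
    """K2P distance between two aligned rows (strings or encoded vectors)."""
    va = _as_codes(a)
    vb = _as_codes(b)
    if va.shape != vb.shape:
        raise SequenceError("rows have different lengths")
    valid = (va >= 0) & (vb >= 0)
    L = int(valid.sum())
    if L == 0:
        return DistancePair(0.0, 0.0, 0, float("nan"), False)
    xa, xb = va[valid], vb[valid]
    ts = int(_is_transition(xa, xb).sum())
    diff = int((xa != xb).sum())
    tv = diff - ts
    P, Q = ts / L, tv / L
    d, ok = k2p_from_proportions(P, Q)
    return DistancePair(P, Q, L, d if ok else float("nan"), ok)


def _as_codes(x: str | np.ndarray) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.int8)
    chars = np.array(list(x.upper()), dtype="U1")
    out = np.full(chars.shape, -1, dtype=np.int8)
    for base, code in _ENCODE.items():
        out[chars == base] = code
    return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # (n, n) float, NaN where undefined
    defined: np.ndarray  # (n, n) bool mask

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix size does not match label count")
        if not np.allclose(np.nan_to_num(np.diagonal(self.values)), 0.0):
            raise ValueError("diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int((~self.defined[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs K2P matrix over the alignment rows."""
    if len(alignment) < 2:
        raise SequenceError("need at least two rows for a distance matrix")
    codes = encode_alignment(alignment)
    n = codes.shape[0]
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            pair = k2p_distance(codes[i], codes[j])
            values[i, j] = values[j, i] = pair.d
            defined[i, j] = defined[j, i] = pair.defined
    if not defined.all():
        warnings.warn(
            "distance matrix contains undefined pairs; they are masked and "
            "excluded from group means",
            stacklevel=2,
        )
    return DistanceMatrix(list(alignment.ids), values, defined)


@dataclass
class GroupDistanceSummary:
    within: dict[str, float]  # species -> mean intra-specific d (subs/site)
    between: dict[tuple[str, str], float]  # sorted species pair -> mean d
    n_within_pairs: dict[str, int] = field(default_factory=dict)
    n_between_pairs: dict[tuple[str, str], int] = field(default_factory=dict)


def group_means(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str],
    weights: Mapping[str, int] | None = None,
    exclude: Sequence[str] = (),
) -> GroupDistanceSummary:
    """Mean within- and between-species distances.

    Unweighted over unordered pairs of rows by default (row = haplotype);
    pass per-label sample counts as ``weights`` for frequency-weighted
    means.  Undefined pairs are skipped.  Species named in ``exclude``
    (typically the outgroup) are dropped entirely.
    """
    species = {}
    for label in matrix.labels:
        if label not in species_of:
            raise KeyError(f"no species for label {label!r}")
        if species_of[label] not in exclude:
            species[label] = species_of[label]

    by_species: dict[str, list[int]] = {}
    for idx, label in enumerate(matrix.labels):
        if label in species:
            by_species.setdefault(species[label], []).append(idx)

    def _mean(pairs: list[tuple[int, int]]) -> tuple[float, int]:
        num = den = 0.0
        n_used = 0
        for i, j in pairs:
            if not matrix.defined[i, j]:
                continue
            w = 1.0
            if weights is not None:
                w = weights[matrix.labels[i]] * weights[matrix.labels[j]]
            num += w * matrix.values[i, j]
            den += w
            n_used += 1
        return (num / den if den else float("nan")), n_used

    summary = GroupDistanceSummary(within={}, between={})
    names = sorted(by_species)
    for sp in names:
        rows = by_species[sp]
        if len(rows) < 2:
            continue  # within-distance undefined for singletons
        pairs = [(rows[i], rows[j]) for i in range(len(rows)) for j in range(i + 1, len(rows))]
        summary.within[sp], summary.n_within_pairs[sp] = _mean(pairs)
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            a, b = names[a_idx], names[b_idx]
            pairs = [(i, j) for i in by_species[a] for j in by_species[b]]
            summary.between[(a, b)], summary.n_between_pairs[(a, b)] = _mean(pairs)
    return summary


@dataclass(frozen=True)
class BarcodeGapReport:
    max_within: float
    min_between: float
    max_between: float
    gap: float  # min_between - max_within; negative means overlap
    nearest_neighbor: Mapping[str, tuple[str, float]]


def barcode_gap(summary: GroupDistanceSummary) -> BarcodeGapReport:
    """Barcoding-gap summary: a positive gap separates intra- from
    inter-specific divergence; a negative gap (overlap) is reported as-is."""
    withins = [v for v in summary.within.values() if np.isfinite(v)]
    betweens = {k: v for k, v in summary.between.items() if np.isfinite(v)}
    if not betweens:
        raise ValueError("no defined between-species distances")
    max_within = max(withins) if withins else float("nan")
    min_between = min(betweens.values())
    max_between = max(betweens.values())
    species = sorted({s for pair in betweens for s in pair})
    nn: dict[str, tuple[str, float]] = {}
    for sp in species:
        candidates = [
            (other, v)
            for (a, b), v in betweens.items()
            for other in ((b,) if a == sp else (a,) if b == sp else ())
        ]
        if candidates:
            nn[sp] = min(candidates, key=lambda t: (t[1], t[0]))
    gap = min_between - max_within if withins else float("nan")
    return BarcodeGapReport(max_within, min_between, max_between, gap, nn)


def summary_tables(summary: GroupDistanceSummary) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reporting views in percent, rounded to 2 decimals.

    Returns (within, between) frames; the between frame is a lower-triangle
    species-by-species matrix.
    """
    from .regions import round_half_up

    within = pd.DataFrame(
        [
            {"species": sp, "within_pct": round_half_up(100.0 * v)}
            for sp, v in sorted(summary.within.items())
        ]
    )
    species = sorted(
        {s for pair in summary.between for s in pair} | set(summary.within)
    )
    between = pd.DataFrame(index=species, columns=species, dtype=float)
    for (a, b), v in summary.between.items():
        lo, hi = sorted((a, b), key=species.index)
        between.loc[hi, lo] = round_half_up(100.0 * v)
    return within, between
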