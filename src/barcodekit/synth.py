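"""Simulate barcode datasets with known ground truth.

The generator emulates the statistical structure of a multi-species ITS
barcoding study: a small ingroup of species whose consensus sequences
diverged on an ultrametric species tree under the K80 model, a distant
outgroup, species-private fixed (diagnostic) sites, shallow within-species
haplotype variation with skewed haplotype frequencies, occasional short
deletions and occasional IUPAC ambiguity codes.  Every emitted dataset
ships a machine-readable ground truth (tree, consensus distances,
haplotype partition, diagnostic sites) so each analysis stage can be
tested end to end without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import (
    GAP,
    Alignment,
    SampleMetadata,
    SequenceRecord,
    write_fasta,
    write_metadata,
)
from .phylo import Node, Tree, k80_transition_matrix, write_newick
from .distances import k2p_distance

_BASES = "ACGT"
# two-base IUPAC codes containing each base, used for ambiguity sprinkling
_AMBIG_FOR = {
    "A": ("M", "R", "W"),
    "C": ("M", "Y", "S"),
    "G": ("R", "S", "K"),
    "T": ("W", "Y", "K"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 8 ingroup species plus one outgroup.

    Sample sizes, haplotype richness, divergence ranges and per-species
    diagnostic-site counts default to the structure of a published
    *Actinidia* ITS survey (185 samples, within-species divergence
    0.35-2.26%, between-species divergence 2.28-11%, five species with
    private fixed sites).  All rates are per site; divergences are in
    expected substitutions per site.
    """

    n_species: int = 8
    samples_per_species: tuple[int, ...] = (59, 19, 14, 18, 27, 16, 15, 17)
    haplotypes_per_species: tuple[int, ...] = (9, 5, 4, 6, 6, 5, 3, 8)
    seq_len: int = 630
    kappa: float = 4.0
    between_divergence: tuple[float, float] = (0.0228, 0.11)
    within_divergence: tuple[float, float] = (0.0035, 0.0226)
    n_diagnostic_per_species: tuple[int, ...] = (7, 8, 0, 0, 0, 13, 8, 2)
    indel_rate: float = 0.25  # P(one 1-12 bp deletion) per ingroup species
    within_indel_rate: float = 0.0  # optional 1 bp within-species deletions
    ambiguity_rate: float = 2.5e-5  # per sample base
    outgroup_divergence: float = 0.25
    hap_freq_ratio: float = 0.25  # geometric skew of haplotype frequencies
    outgroup_name: str = "outgroup"
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_species
        for name in ("samples_per_species", "haplotypes_per_species",
                     "n_diagnostic_per_species"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have {k} entries")
        if any(h < 1 for h in self.haplotypes_per_species):
            raise ValueError("each species needs at least one haplotype")
        if any(s < h for s, h in zip(self.samples_per_species,
                                     self.haplotypes_per_species)):
            raise ValueError("sample count must cover haplotype count")
        lo, hi = self.between_divergence
        if not (0 <= lo <= hi):
            raise ValueError("invalid between-species divergence range")
        wlo, whi = self.within_divergence
        if not (0 <= wlo <= whi):
            raise ValueError("invalid within-species divergence range")
        for rate in (self.indel_rate, self.within_indel_rate,
                     self.ambiguity_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class GroundTruth:
    tree_newick: str  # species tree incl. outgroup
    species_distances: dict[tuple[str, str], float]  # consensus K2P
    haplotype_partition: dict[str, list[str]]  # truth label -> sample ids
    diagnostics: dict[str, list[tuple[int, str]]]  # planted, master columns
    sample_species: dict[str, str]
    within_targets: dict[str, float]

    def partition_sets(self) -> set[frozenset[str]]:
        return {frozenset(v) for v in self.haplotype_partition.values()}


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    records: list[SequenceRecord]  # ungapped, as sequenced
    metadata: list[SampleMetadata]
    alignment: Alignment  # truth alignment in the master frame
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "seqs.fasta")
        write_fasta(self.alignment.records, out / "aligned.fasta")
        write_metadata(self.metadata, out / "meta.tsv")
        (out / "tree.nwk").write_text(self.truth.tree_newick + "\n")
        truth = {
            "species_distances": {
                f"{a}|{b}": v for (a, b), v in self.truth.species_distances.items()
            },
            "haplotype_partition": self.truth.haplotype_partition,
            "diagnostics": {
                sp: [{"pos": p, "state": s} for p, s in sites]
                for sp, sites in self.truth.diagnostics.items()
            },
            "sample_species": self.truth.sample_species,
            "within_targets": self.truth.within_targets,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# K80 sequence evolution


def _encode(seq: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(_BASES)}
    return np.array([lut[c] for c in seq], dtype=np.int8)


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def evolve_k80(
    seq: str | np.ndarray, branch_length: float, kappa: float,
    rng: np.random.Generator,
) -> str | np.ndarray:
    """Evolve a sequence for ``branch_length`` expected substitutions/site
    under K80 by sampling each site from the exact transition probabilities."""
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    as_string = isinstance(seq, str)
    codes = _encode(seq) if as_string else np.asarray(seq, dtype=np.int8)
    if branch_length == 0.0:
        out = codes.copy()
        return _decode(out) if as_string else out
    P = k80_transition_matrix(branch_length, kappa)
    cum = P.cumsum(axis=1)
    u = rng.random(codes.shape[0])
    out = (u[:, None] > cum[codes]).sum(axis=1).astype(np.int8)
    return _decode(out) if as_string else out


def simulate_k80_pair(
    distance: float, kappa: float, length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """An ancestor/descendant pair separated by ``distance`` subs/site —
    the workbench for distance-estimator calibration."""
    a = rng.integers(0, 4, size=length).astype(np.int8)
    b = evolve_k80(a, distance, kappa, rng)
    return a, b


# ---------------------------------------------------------------------------
# species tree


def _random_ultrametric_tree(
    names: Sequence[str], depth_range: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[Node, dict[str, float]]:
    """Random join order with join depths affinely rescaled so pairwise
    path lengths (2x the MRCA depth) span ``depth_range``... returns the
    ingroup root and nothing else; branch lengths are depth differences."""
    n = len(names)
    lo, hi = depth_range
    if n == 1:
        leaf = Node(name=names[0], length=0.0)
        return leaf, {}
    raw = np.sort(rng.random(n - 1))
    if n == 2:
        depths = np.array([(lo + hi) / 4.0])  # single join: midpoint distance
    else:
        dmin, dmax = raw[0], raw[-1]
        a = (hi - lo) / (2.0 * (dmax - dmin))
        c = lo / 2.0 - a * dmin
        depths = a * raw + c
    nodes: list[tuple[Node, float]] = [
        (Node(name=nm), 0.0) for nm in names
    ]
    for depth in depths:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, da) = nodes[i]
        (nb, db) = nodes[j]
        parent = Node()
        na.length = depth - da
        nb.length = depth - db
        parent.add(na)
        parent.add(nb)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, depth))
    root, _ = nodes[0]
    return root, {}


def _consensus_sequences(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], Tree]:
    """Species consensus sequences evolved along a random species tree,
    plus the full truth tree including the outgroup."""
    names = config.species_names
    ingroup_root, _ = _random_ultrametric_tree(
        names, config.between_divergence, rng
    )
    root_seq = rng.integers(0, 4, size=config.seq_len).astype(np.int8)
    consensi: dict[str, np.ndarray] = {}

    def down(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = evolve_k80(seq, child.length or 0.0, config.kappa, rng)
            if child.is_leaf:
                consensi[child.name] = child_seq
            else:
                down(child, child_seq)

    if ingroup_root.is_leaf:
        consensi[ingroup_root.name] = root_seq.copy()
    else:
        down(ingroup_root, root_seq)
    consensi[config.outgroup_name] = evolve_k80(
        root_seq, config.outgroup_divergence, config.kappa, rng
    )
    top = Node()
    ingroup_root.length = 0.0
    top.add(ingroup_root)
    top.add(Node(name=config.outgroup_name, length=config.outgroup_divergence))
    return consensi, Tree(top)


# ---------------------------------------------------------------------------
# dataset assembly


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset plus ground truth; byte-identical per seed."""
    rng = np.random.default_rng(config.seed)
    names = config.species_names
    L = config.seq_len

    consensi, truth_tree = _consensus_sequences(config, rng)

    # implant species-private fixed sites at columns invariant across all
    # species (guarantees a known-truth diagnostic key exists)
    all_seqs = np.stack([consensi[nm] for nm in names + [config.outgroup_name]])
    invariant_cols = np.flatnonzero((all_seqs == all_seqs[0]).all(axis=0))
    need = int(sum(config.n_diagnostic_per_species))
    if need > invariant_cols.size:
        raise ValueError(
            f"requested {need} diagnostic sites but only "
            f"{invariant_cols.size} invariant columns are available"
        )
    chosen = rng.choice(invariant_cols, size=need, replace=False)
    diagnostics: dict[str, list[tuple[int, str]]] = {nm: [] for nm in names}
    cursor = 0
    for nm, n_diag in zip(names, config.n_diagnostic_per_species):
        for _ in range(n_diag):
            col = int(chosen[cursor])
            cursor += 1
            old = int(consensi[nm][col])
            new = int(rng.choice([b for b in range(4) if b != old]))
            consensi[nm][col] = new
            diagnostics[nm].append((col + 1, _BASES[new]))
        diagnostics[nm].sort()
    protected = set(int(c) for c in chosen)

    # within-species haplotypes: few-mutation derivatives of the consensus
    wlo, whi = config.within_divergence
    within_targets = {
        nm: float(rng.uniform(wlo, whi)) for nm in names
    }
    hap_seqs: dict[str, list[np.ndarray]] = {}
    free_cols = np.array(
        [c for c in range(L) if c not in protected], dtype=int
    )
    for nm, n_hap in zip(names, config.haplotypes_per_species):
        max_m = max(1, int(within_targets[nm] * L / 2.0))
        haps = [consensi[nm].copy()]
        seen = {haps[0].tobytes()}
        for _ in range(n_hap - 1):
            for _attempt in range(100):
                m = int(rng.integers(1, max_m + 1))
                cols = rng.choice(free_cols, size=m, replace=False)
                hap = consensi[nm].copy()
                for col in cols:
                    old = int(hap[col])
                    hap[col] = int(rng.choice([b for b in range(4) if b != old]))
                if hap.tobytes() not in seen:
                    seen.add(hap.tobytes())
                    haps.append(hap)
                    break
            else:
                raise RuntimeError(f"could not generate distinct haplotypes for {nm}")
        hap_seqs[nm] = haps
    hap_seqs[config.outgroup_name] = [consensi[config.outgroup_name]]

    # aligned haplotype strings in the master frame (deletions -> gaps)
    hap_strings: dict[str, list[str]] = {
        nm: [_decode(h) for h in haps] for nm, haps in hap_seqs.items()
    }
    for nm in names:
        if rng.random() < config.indel_rate:
            window = _pick_deletion_window(rng, L, protected)
            if window is not None:
                lo_c, hi_c = window
                hap_strings[nm] = [
                    s[:lo_c] + GAP * (hi_c - lo_c) + s[hi_c:]
                    for s in hap_strings[nm]
                ]
        if config.within_indel_rate > 0:
            updated = []
            for k, s in enumerate(hap_strings[nm]):
                if k > 0 and rng.random() < config.within_indel_rate:
                    window = _pick_deletion_window(rng, L, protected, max_len=1)
                    if window is not None:
                        lo_c, hi_c = window
                        s = s[:lo_c] + GAP + s[hi_c:]
                updated.append(s)
            hap_strings[nm] = updated

    # samples: skewed haplotype frequencies, every haplotype observed
    records: list[SequenceRecord] = []
    metadata: list[SampleMetadata] = []
    aligned_rows: list[SequenceRecord] = []
    partition: dict[str, list[str]] = {}
    sample_species: dict[str, str] = {}
    localities = ("siteA", "siteB", "siteC")
    for si, (nm, n_samples) in enumerate(zip(names, config.samples_per_species)):
        haps = hap_strings[nm]
        n_hap = len(haps)
        assignment = list(range(n_hap))
        weights = config.hap_freq_ratio ** np.arange(n_hap)
        weights = weights / weights.sum()
        extra = rng.choice(n_hap, size=n_samples - n_hap, p=weights)
        assignment.extend(int(x) for x in extra)
        for k, hap_idx in enumerate(assignment):
            sid = f"{nm}_{k + 1:03d}"
            aligned = _sprinkle_ambiguity(
                haps[hap_idx], config.ambiguity_rate, protected, rng
            )
            locality = localities[(si + k) % len(localities)]
            records.append(
                SequenceRecord(id=sid, seq=aligned.replace(GAP, ""),
                               species=nm, locality=locality)
            )
            aligned_rows.append(
                SequenceRecord(id=sid, seq=aligned, species=nm,
                               locality=locality)
            )
            sample_species[sid] = nm
            metadata.append(
                SampleMetadata(sample_id=sid, species=nm, locality=locality)
            )
    og = config.outgroup_name
    og_id = f"{og}_001"
    og_seq = hap_strings[og][0]
    records.append(SequenceRecord(id=og_id, seq=og_seq.replace(GAP, ""),
                                  species=og))
    aligned_rows.append(SequenceRecord(id=og_id, seq=og_seq, species=og))
    sample_species[og_id] = og
    metadata.append(SampleMetadata(sample_id=og_id, species=og, is_outgroup=True))

    # truth haplotype partition: identical emitted aligned strings, per species
    keys: dict[tuple[str, str], str] = {}
    for row in aligned_rows:
        key = (sample_species[row.id], row.seq)
        if key not in keys:
            keys[key] = f"{key[0]}_h{sum(1 for k in keys if k[0] == key[0]) + 1}"
        partition.setdefault(keys[key], []).append(row.id)

    species_distances: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pair = k2p_distance(_decode(consensi[a]), _decode(consensi[b]))
            species_distances[(a, b)] = pair.d

    truth = GroundTruth(
        tree_newick=write_newick(truth_tree),
        species_distances=species_distances,
        haplotype_partition=partition,
        diagnostics=diagnostics,
        sample_species=sample_species,
        within_targets=within_targets,
    )
    return SimulatedDataset(
        config=config,
        records=records,
        metadata=metadata,
        alignment=Alignment(aligned_rows),
        truth=truth,
    )


def _pick_deletion_window(
    rng: np.random.Generator, L: int, protected: set[int], max_len: int = 12
) -> tuple[int, int] | None:
    """A deletion window [lo, hi) of 1..max_len columns avoiding the
    planted diagnostic columns; None if none found quickly."""
    for _ in range(50):
        length = int(rng.integers(1, max_len + 1))
        lo = int(rng.integers(0, L - length + 1))
        if not any(c in protected for c in range(lo, lo + length)):
            return lo, lo + length
    return None


def _sprinkle_ambiguity(
    seq: str, rate: float, protected: set[int], rng: np.random.Generator
) -> str:
    """Replace occasional bases with IUPAC codes containing the true base.

    Diagnostic columns are never touched: planted fixed differences are,
    by construction, cleanly resolved in every sample.
    """
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for idx in hits:
        if idx in protected or chars[idx] not in _AMBIG_FOR:
            continue
        options = _AMBIG_FOR[chars[idx]]
        chars[idx] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


def map_master_to_alignment(truth_row: str, new_row: str, master_col: int) -> int:
    """Translate a 1-based master-frame column to the column of a re-built
    alignment, via a sample carrying a base (not a gap) at that column."""
    if truth_row[master_col - 1] == GAP:
        raise ValueError("reference row has a gap at the master column")
    k = sum(1 for c in truth_row[: master_col - 1] if c != GAP)
    seen = 0
    for j, c in enumerate(new_row, start=1):
        if c != GAP:
            if seen == k:
                return j
            seen += 1
    raise ValueError("new row has fewer bases than the master row")
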