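# Methods

## Scope and data model

The package analyses single-marker barcode data (nuclear ribosomal ITS in
the motivating application): a set of samples, each with a species label,
optional locality/accession, and one designated outgroup species used for
rooting. Sequences are strings over A/C/G/T, the IUPAC ambiguity codes and
`-`; `U` is silently normalized to `T` and `.` to `-`. All reported
coordinates are **1-based inclusive columns on the master alignment** —
the only frame in which positions are comparable across samples. Species
labels are exact-match keys; no fuzzy normalization is attempted.

## Alignment

Barcode datasets are near-identical within the marker (>90% identity), so
a center-star progressive alignment over optimal pairwise global
alignments is sufficient and easy to verify. Pairwise alignment is
affine-gap Needleman–Wunsch (Gotoh): a gap of length k costs
`gap_open + k*gap_extend`; defaults match=5, mismatch=−4, gap_open=−10,
gap_extend=−0.5 (EDNAFULL-like — at barcode-level identity the layout is
insensitive to the exact values, but a fixed default is needed for
determinism). Traceback ties prefer diagonal, then up (gap in the second
sequence), then left, so scores and layouts are bit-reproducible. The
center sequence minimizes a cheap proxy distance (Hamming over the shared
prefix plus length difference) summed over all unique sequences; identical
input sequences are aligned once and share a row layout. Equal-length
input containing gaps can bypass alignment entirely (`--prealigned`),
which is how an externally produced alignment is consumed.

Limitations: no iterative refinement and no guide tree; center-star can
misplace gaps when indels are long or clustered. For the shallow
divergences this package targets that regime does not arise.

## Region partition (ITS1 / 5.8S / ITS2)

The 5.8S gene is highly conserved (canonically 164 bp in the motivating
genus) while the spacers vary, so when boundaries are not supplied the
gene is located as the length-164 window of consecutive columns minimizing
total column diversity (rows not carrying the column's modal base),
skipping windows containing any column whose modal state is a gap; ties
break to the leftmost window. Boundaries can instead be given explicitly
(`its1:1-246,58s:247-410,its2:411-633`). Per-record region lengths count
non-gap characters only, so individual records may deviate from the
canonical gene length (insertions in one sample appear as gap-consensus
columns and lengthen only that record); lengths are reported per record,
never asserted equal. GC% excludes gaps and ambiguity codes from both
numerator and denominator (conservative; affects well under 1%).
Reporting rounds half away from zero to 2 decimals; internal values keep
full precision.

## Haplotypes

Haplotype identity is exact string equality of the aligned sequence after
trimming columns that are gaps in every row. Consequences, all
deliberate: indels distinguish haplotypes (two sequences differing by one
1-bp deletion are distinct); IUPAC ambiguity codes are distinct states
(collapsing an ambiguous sequence into a clean one would overstate
richness confidence); and collapsing is per species by default, so two
species sharing a sequence still get distinct haplotype ids — ids are a
species-derived prefix plus rank of first occurrence, making labels
deterministic under row order while the partition itself is
order-invariant.

## Site classification and diagnostic sites

A column is *variable* when at least two distinct unambiguous bases occur
among the included rows (outgroup excluded by default); variable columns
with at least two states each in ≥2 rows are *parsimony-informative*.
Deletion-only polymorphisms (gap vs a single base) are therefore not
counted as variable — they surface through the `gap_present` flag.

A (position, state) pair is *diagnostic* for species X iff every row of X
carries exactly that state there and no row of any other ingroup species
can carry it. Policy details: ambiguity within X disqualifies the column
for X; ambiguity in another species disqualifies the state when its base
set contains it (the ambiguous read *might* match); a gap in another
species counts as a different state; a gap is itself a legal diagnostic
state only when `allow_indel_diagnostics` is enabled (off by default —
published diagnostic sets in this domain are base states). Diagnostic
sets are disjoint across species at the (position, state) level by
construction, and removing a species can only grow the others' sets
(property-tested). Identification calls the species whose complete
diagnostic set a query matches; several matches give `ambiguous`, none
gives `no-call`; species without diagnostic sites are never callable.

## K2P distances

For each pair, columns where either row has a gap or ambiguity code are
deleted pairwise (pairwise rather than complete deletion: it preserves
more signal and is the default in the desktop packages practitioners
use). Over the remaining L sites, P = transition proportion (A↔G, C↔T),
Q = transversion proportion, and d = −½·ln[(1−2P−Q)√(1−2Q)]. When the
logarithm's argument leaves its domain (saturation) or L = 0 the pair is
flagged undefined, masked out of group means with a warning, and never
imputed. Group summaries (mean within-species, mean between-species,
barcoding gap, nearest neighbor) are computed over **unique haplotypes,
unweighted** by default — the matrix a practitioner builds contains
haplotype sequences — with frequency-weighted means available via the
`weights` argument. Percentages are formatted at 2 decimals only in the
reporting layer. Note that K2P with transitions:transversions in 1:2
proportion collapses to the Jukes–Cantor form; this nesting is verified
numerically in the tests.

## Trees

*Neighbor joining* is the standard Saitou–Nei agglomeration, exact on
additive matrices (property-tested on random additive matrices, 4–8
taxa). Q-matrix ties break to the lexicographically smallest pair of
subtree keys (the smallest leaf label below each node), making the result
deterministic; negative branch lengths are clamped to zero. Undefined
distance pairs are a hard error — impute or drop rows first.

*Maximum likelihood* uses the K80 model, the likelihood counterpart of
the K2P distance: equal base frequencies, one transition/transversion
rate ratio κ. Using the matching model keeps the implementation
self-contained and checkable against closed forms (two-taxon likelihoods,
κ=1 ≡ Jukes–Cantor) rather than importing a black-box GTR+Γ machine.
Likelihoods come from Felsenstein pruning with per-node rescaling; gaps
and ambiguity codes are missing data (uniform over their base sets). The
search alternates bounded univariate branch-length optimization
(bounds [0, 10], tolerance 1e-6), κ optimization (initialized at 2.0),
and an NNI sweep accepting strict improvements, restarting from each
accepted move; it terminates at an NNI-local optimum and is deterministic
given the start tree (default: NJ). SPR and rate heterogeneity are out of
scope; at a few dozen leaves with strong signal NNI from an NJ start is
sufficient, which the exhaustive 15-topology five-taxon oracle in the
test suite confirms.

*Bootstrap* resamples alignment columns with replacement; supports are
the percentage of replicates containing each internal bipartition of the
point-estimate tree (mapped onto the point estimate, not a consensus
tree, so the reported topology is seed-independent). Replicate r draws
from `default_rng([seed, r])`, so the replicate set is reproducible and
order-independent; replicates with undefined distances are dropped and
counted. NJ replicates reuse precomputed per-pair per-column
transition/transversion indicators, making a 1000-replicate bootstrap on
~50 haplotypes a matter of seconds.

*Rooting and monophyly*: the root bisects the edge separating the
outgroup from the ingroup; a species is monophyletic iff its leaves form
a complete clade of the rooted tree (single-leaf species trivially so).
Region-restricted trees (ITS1-only, ITS2-only) run the same machinery on
column slices, yielding a per-region monophyly table that operationalizes
"which region discriminates which species".

## Synthetic data generator

The generator emulates the statistical structure of a multi-species
barcoding survey; defaults are the study conditions of the motivating
eight-species dataset:

| parameter | default | rationale |
|---|---|---|
| species / samples | 8 ingroup, (59,19,14,18,27,16,15,17) + 1 outgroup | survey sample table (185 samples) |
| haplotypes per species | (9,5,4,6,6,5,3,8) | survey haplotype table (46 total) |
| sequence length | 630 bp | ITS length range 624–636 |
| κ | 4.0 | typical plant ITS transition bias |
| between-species divergence | 0.0228–0.11 | survey inter-specific K2P range |
| within-species divergence cap | 0.0035–0.0226 | survey intra-specific K2P range |
| diagnostic sites per species | (7,8,0,0,0,13,8,2) | survey species-private site counts |
| deletion probability per species | 0.25, length 1–12 bp | occasional indels seen between species |
| ambiguity rate | 2.5e-5 per base | a few ambiguous reads per ~185 samples |
| outgroup branch | 0.25 subs/site | distant outgroup to exercise rooting |

Mechanics: a random ultrametric species tree is drawn by random joins and
its node depths affinely rescaled so leaf-to-leaf path lengths span the
configured between-species range; the root sequence is uniform and
evolves along branches via exact K80 transition probabilities. Diagnostic
sites are implanted post hoc at columns invariant across all species —
hoping drift fixes them would not guarantee a known-truth key — and those
columns are protected from within-species mutation, deletions and
ambiguity sprinkling, so the planted key is guaranteed recoverable.
Within-species haplotypes are few-mutation derivatives of the species
consensus, capped so the maximum within-species pairwise divergence stays
below the species' drawn target (realized *mean* within-species distances
therefore sit below the cap, consistent with strong intraspecific
conservation). Samples are assigned to haplotypes with a geometric skew
(ratio 0.25, every haplotype observed at least once), mirroring the
dominant-haplotype pattern of real surveys. Deletions apply per species
to all its haplotypes; 1-bp within-species deletions are available behind
`within_indel_rate`. Ambiguity codes replace occasional bases with a
2-base code containing the true base; because such a sample's string is
unique, each hit adds a singleton haplotype — the emitted ground-truth
partition is always computed from the final strings, so truth and data
cannot drift apart.

What the generator does **not** emulate: coalescent within-species
genealogies, recombination, rate variation across sites, alignment error
from heterogeneous sequence quality, and insertions relative to the
master frame (indels are deletions only). Passing the recovery tests
therefore demonstrates correctness of the analysis machinery under the
model's assumptions, not robustness to every artefact of real Sanger
data. Two bookkeeping consequences are deliberate: planted diagnostic
substitutions add up to n_diag/L to that species' pairwise distances, so
realized between-species distances can exceed the configured ceiling by a
few percent; and the analysis may legitimately report *more* diagnostic
sites than were planted (substitutions fixed on a terminal species branch
are genuine diagnostics), so recovery checks assert the planted key is a
subset of the recovered one.

## Pipeline and reproducibility

`run_full_analysis` chains the stages in order (read → align → haplotypes
→ regions → sites → distances → trees → monophyly → log) with fixed
output filenames and column schemas; any stage failure aborts with the
stage name and renames already-written outputs to `*.partial`. All
randomness flows from the single config seed; outputs are a pure function
of (inputs, config, seed) and reruns are byte-identical. Spacer spans
shorter than 10 columns (possible only on degenerate inputs) are skipped
in the per-region tree step rather than fitted.

Problem sizes used by the acceptance script: the full default simulation
(185 samples + outgroup, 630 bp, 1000 bootstrap replicates per region),
estimator calibration with 200 replicate pairs at L = 5000, and 100
random additive matrices for NJ; the whole script completes in about two
minutes on one CPU.

## Known limitations

- Center-star alignment and NNI-only search are adequate for shallow
  barcode divergence, not for deep or indel-rich phylogenetics.
- The published variable-site matrix shipped in `barcodekit.datasets`
  covers only the survey's printed positions (38 columns), so
  whole-alignment quantities (total variable-site count, absolute
  coordinates, distances) are not recomputable from it; tests against it
  check site classification, the diagnostic key and identification.
- Absolute column coordinates depend on the alignment; across different
  aligners only counts and states, not positions, are comparable.
- Frequency-weighted distance summaries and indel-state diagnostics exist
  but are off by default; both defaults follow common practice in this
  domain rather than a mathematical necessity.
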