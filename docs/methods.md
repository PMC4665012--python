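# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `viropanel`, in the order data flows through the package.

## Coordinates and alphabets

All in-memory coordinates are 0-based half-open. The single exception is
the excised-span header dialect `{SQ a-b}`, rendered 1-based inclusive
(`[2443, 2644)` internally becomes `{SQ 2444-2644}`); the convention is
fixed here and round-trips exactly through `parse_subseq_header`.
Residues are normalized on ingest to uppercase A/C/G/T/N; every other
IUPAC ambiguity code maps to N rather than raising, because real viral
records contain them and probes cannot be synthesized against them.
Lowercase (soft-masking) information is not preserved — the consolidation
step hard-masks.

## The identity metric

Every threshold decision in the package uses one metric: the *glocal*
(semi-global) alignment of the shorter sequence end-to-end against a
free-ended placement in the longer, scored with match +1, mismatch −1 and
affine gaps costing `open + g·extend` with open 2, extend 1. A gap of
either kind contributes columns; N never matches anything, including N.
Identity is matching columns over total alignment columns, so gaps count
against identity.

Score-co-optimal alignments are common, and different co-optima can have
different match/column counts. To make identity a *function* of the input
rather than of traceback order, the DP optimizes the lexicographic
objective (score, matches, −columns): each cell carries the triple,
encoded in one int64 (24-bit biased score, 20-bit matches, 19-bit column
field), which is order-preserving under the per-column additive updates.
The reported identity is therefore deterministic and needs no traceback.
The encoding bounds combined sequence length at 2^19 bp, asserted by the
wrappers — ample for viral genomes.

For equal-length pairs the query/target roles are assigned
lexicographically so that `identity(a, b) == identity(b, a)` exactly.
With `rc_aware` the better key of the forward and reverse-complement
placement wins, forward on ties. Thresholds are compared with a 1e-12
slack so that exact rationals like 90/100 pass a 0.90 threshold under
floating-point representation.

The same kernels provide Smith–Waterman local alignment (identity of the
top HSP) for divergent-contig recovery.

### Independent verification

The test suite carries a brute-force pure-Python Gotoh implementation of
the identical definition (tuple lexicographic comparison, full matrices).
The acceptance checks require *exact* equality of (score, matches,
columns) on 1000 random pairs up to 300 bp, including N-containing and
embedded-copy pairs.

## K-mer condensation

Neighbor genomes are decomposed exhaustively (k = 100, step 1), and each
k-mer is classified against the tiled parent: *represented* if its best
glocal identity anywhere in the parent (either strand) reaches the 90%
threshold, *divergent* otherwise. Divergent k-mer offsets are projected
to neighbor coordinates as `[offset, offset + k)` spans and merged;
bookended spans merge (step-1 k-mers overlap by k−1, making contiguity the
natural unit) while a single-base gap keeps spans separate. Merged spans
are excised as panel entries whose residues equal the neighbor slice
exactly. Neighbors are processed independently — no cross-neighbor
deduplication — and neighbors shorter than k are skipped with a warning
but counted in the input size. The reduction ratio is retained/input bp,
defined as 0 for empty input.

Classification can also fold divergent k-mers only against the parent,
never against previously retained material; this matches the
parent-as-sole-centroid reading of the procedure and keeps per-neighbor
results order-independent.

### Seeded acceleration

Exhaustive DP of every k-mer against a long parent is O(k·|parent|) per
k-mer — prohibitive for ~10⁴ k-mers × 10-kb parents. For parents of at
least 5 kb the batch classifier uses exact-seed screening with a
pigeonhole guarantee derived from (k, t):

- any alignment with identity ≥ t over a k-mer has at most
  `D = ⌊k(1−t)/t⌋` deletion columns, at most `E = ⌊(1−t)(k+D)⌋` error
  events and hence at most `R = E+1` maximal match runs over at least
  `M = ⌈tk⌉` matched k-mer positions;
- so it contains an exact run of `s = ⌈M/R⌉` bases (k = 100, t = 0.90
  gives s = 8) and at least `M − (s−1)·R` (= 6) seed windows, all on
  diagonals within a band of width E.

Candidate placements are therefore enumerated from a sorted index of
parent 8-mers, clustered by diagonal, and only clusters holding the
minimum seed count are aligned (windowed glocal DP, window padded by
D + 8), best-supported cluster first with early exit once the threshold is
reached. K-mers with no qualifying cluster are divergent without any
alignment — which is what makes novel-insert sequence cheap to detect.
Thresholds too permissive to admit a ≥ 6-bp seed fall back to the
exhaustive scan, as do k-mers whose seed matches overflow the candidate
buffer (low-complexity pathologies). Agreement between the seeded and
exhaustive paths is asserted in the test suite over mutated neighbors
with indels.

The guarantee is stated for the existence of qualifying alignments;
contrived inputs could in principle hold a higher-*scoring* sub-threshold
alignment outside every seeded window while a qualifying alignment sits
inside one, in which case the seeded path (which reports the seeded
windows' optimum) and the single global optimum disagree about which
alignment defines "the" identity. The decision itself — does any
placement reach the threshold — is unaffected.

## Long-set clustering

For collections too redundant even for k-mer condensation, full-length
sequences are clustered in a single greedy pass: each entry folds into the
*first* existing centroid meeting the threshold (no best-hit search — the
first qualifying centroid wins, deterministically), else founds a new
cluster. Parent references are concatenated and split into `n_segments`
near-equal pieces (sizes differing by ≤ 1 bp) that are fed to the
clusterer first, so canonical references always seed the early clusters;
remaining sequences follow length-descending. Only non-parent centroids
are retained, full length. The near-equal split is a documented choice —
the segment count, not any absolute segment size, is the knob. Chimeric
junctions created by concatenation are accepted: sequences spanning a
junction may fail to fold into any single segment and survive as
centroids, a conservative error in the direction of retaining sequence.

## Host filtering

Two independent screens: description labels against a blocklist
(case-insensitive substring), and sequence similarity to a host genome
"at the probe level": windows of 100 bp at step 50 (right-anchored so the
tail is screened; sub-window entries are compared full-length), each
scored with the same glocal engine against the host, both strands. The
window step and the removal unit are package choices, since only the
window size and the 75% threshold are externally fixed. The default
drops whole entries with any hit window — conservative against host
sequence riding on the panel; `mask_window` mode instead hard-masks the
hit windows. Both modes share the hit computation. Scanning cost is
O(window · host length) per window; the module is intended for
panel-design scale, not whole-chromosome screens, and deliberately avoids
a seeded heuristic search engine.

## Low-complexity masking

The symmetric-DUST family: within every subwindow of up to 64 bases, the
triplet score `Σ c_t(c_t−1)/2 / (n−1)` over the subwindow's n scored
triplets is compared against threshold/10 (threshold 20), and qualifying
subwindows are masked in full, by leftward extension from every right
edge (O(L·window)). Triplets containing N are excluded from scoring,
which gives idempotence: masked tracts contribute no triplets on a second
pass and remaining scores can only drop. Homopolymer runs ≥ 7 bp already
exceed the threshold; runs of a full window are masked end to end. The
historical DUST variant is under-specified upstream; the implemented
scoring is pinned by a brute-force triplet-counter oracle in the tests.

## Panel pooling, tiling and offset metrics

Pooling drops byte-identical duplicates and external probes whose
residues occur verbatim (either strand) inside a non-probe entry. Tiling
is naive and end-to-end: stride-aligned probes plus a right-anchored final
probe when the entry length is not a stride multiple (guaranteeing
terminal-base coverage); entries shorter than a probe yield one full-entry
probe; all-N probes are dropped. Offset coverage extends each probe span
by the offset, clipped to the entry, and reports covered non-N bases over
total non-N bases — masked bases are uncapturable by design, a documented
divergence risk against vendor metrics whose denominator is unstated.
Vendor probe redistribution, human-uniqueness screening of probes and
synthesis constraints are out of scope.

## Capture evaluation

Depth counts aligned-span bases (`[start, end)` per record); SAM ingestion
(pysam, mapped primary records only) collapses aligned blocks to one span,
so CIGAR deletions inside reads count as covered — a documented
approximation consistent with the simplified alignment-record contract.
Breadth is the percentage of positions with depth ≥ 1 (no minimum depth);
gaps are maximal zero-depth runs including uncovered reference ends, so
`Σ gaps = L − covered` holds exactly in bases. BoC gain is post minus pre
breadth in percentage points. Start-site deduplication keeps the
highest-quality read per (reference, start, orientation) — first
encountered on ties — bounding deduplicated depth at 2·L for L-bp reads
(200× for 100-bp reads), which the acceptance suite realizes exactly with
a saturating synthetic read set. Fold change in percent viral reads uses
a 1-read pseudo-count when no precapture viral reads were seen and is
rendered as a `>` lower bound. Reference selection per species maximizes
covered bases, ties to the lexicographically smallest id. Depth is
reported raw after deduplication; no further normalization is applied.

## Synthetic data

`simulate_parent` draws i.i.d. bases at a target GC. `simulate_neighbor`
applies i.i.d. substitutions (uniform over the three alternatives) and,
optionally, geometric-length indels, then splices in novel random
segments whose realized neighbor-coordinate spans are returned as ground
truth. The mutation model is deliberately minimal — no
transition/transversion bias, no rate heterogeneity, no sequencing error —
because the quantities under test are identity-threshold behaviors;
passing tests demonstrate threshold and bookkeeping correctness, not
robustness to realistic mutational spectra. `simulate_alignments` builds
paired pre/post read sets in which the viral/total composition is the
*rounded expected count* under the profile (the enrichment factor is the
condition under study, so composition is not given sampling noise) while
read placement, orientation and mapping quality are drawn at random.
Fixed seeds make every generator fully reproducible.

Default study conditions used by the acceptance suite: 10-kb parents, 20
neighbors per set, substitution rates 2% and 15% (straddling the 10%
divergence the 90% threshold detects), single 500-bp novel inserts,
10 replicate seeds; read sets of 10⁶ reads at 0.01% precapture viral
fraction with a 674× enrichment factor. These sizes keep the full suite
within a few minutes on one core while leaving every decision boundary
well away from its sampling noise.

## Known limitations

- The glocal engine is exact but quadratic; clustering very long sequence
  pairs (hundreds of kb) is slow and the encoding caps combined length at
  2^19 bp.
- Host filtering has no seeded search; screening against mammalian-scale
  genomes is out of intended scope.
- Greedy clustering is order-dependent by design (deterministic given the
  caller's ordering), as in the single-pass tools it mirrors.
- SAM ingestion ignores intra-read CIGAR structure beyond the aligned
  span, and breadth uses depth ≥ 1 with no mapping-quality filter.
- The synthetic mutation model is i.i.d.; recovered thresholds on real
  strain clouds with biased mutational processes may differ.
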