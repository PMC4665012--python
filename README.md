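# viropanel

Design and evaluation toolkit for **targeted sequence capture of viral
genomes**. Metagenomic shotgun sequencing of clinical samples routinely
yields only a handful of viral reads; hybridization capture with a probe
panel tiled across viral reference genomes enriches those reads by two to
three orders of magnitude. The obstacle is panel size: public viral
sequence collections hold far more strain-level redundancy than a capture
design can carry, so the redundant sequence must be condensed while the
*divergent* sequence — the part that makes variant strains capturable — is
preserved.

`viropanel` implements that condensation and the metrics used to evaluate
the resulting capture experiments, entirely on synthetic or user-supplied
inputs:

- **k-mer condensation** — every neighbor genome of a tiled parent
  reference is decomposed into overlapping *k*-mers (default k = 100,
  step 1); a k-mer whose best glocal identity anywhere in the parent is
  ≥ 90% is already represented by the parent tiling and discarded;
  divergent k-mers are merged by neighbor coordinate into contiguous spans
  and excised as panel entries, with the span recorded in the FASTA header
  as `{SQ start-end}` (1-based inclusive).
- **long-set clustering** — for extremely redundant collections, parent
  references are concatenated, split into near-equal seed segments, and
  candidate sequences are greedy-clustered (UCLUST-style single pass,
  length-sorted, parents seeded first) at the same identity threshold;
  only non-parent cluster centroids are retained.
- **consolidation** — blocked-taxon label filtering, host-genome
  similarity screening at the 100-bp probe level (≥ 75% identity), and
  DUST-style hard-masking of low-complexity tracts.
- **panel metrics** — naive end-to-end probe tiling and the 0-bp / 100-bp
  offset coverage metrics (fraction of target bases inside, or within
  100 bp of, a probe).
- **capture evaluation** — per-reference breadth/depth/gap statistics from
  alignments (SAM or TSV), breadth-of-coverage (BoC) gain, start-site
  deduplication with its 2·L depth ceiling, fold change in percent viral
  reads (with `>` lower bounds when no precapture reads were seen), and
  divergent-contig recovery via top-HSP identity.

## The identity metric

All thresholds use one definition: the **glocal** alignment of the shorter
sequence end-to-end against its best free-ended placement in the longer,
under affine gap scoring (match +1, mismatch −1, gap open 2, extend 1;
N never matches), with

```
identity = matching columns / alignment columns
```

Among score-co-optimal alignments the canonical one (max matches, then
fewest columns) is reported, so every identity is a deterministic rational
number. The engine is exact dynamic programming (numba kernels); batch
k-mer classification against large parents is accelerated by exact-seed
screening with a pigeonhole guarantee (see `docs/methods.md`) and verified
in the test suite against a brute-force pure-Python oracle.

## Worked example

`examples/01_condense_neighbors.py` condenses simulated strain clouds
around a 10-kb parent:

```
substitution rate 2%: 50000 bp in -> 0 bp retained (0 entries, reduction ratio 0.0000)
substitution rate 15%: 50000 bp in -> 49842 bp retained (13 entries, reduction ratio 0.9968)
novel 500-bp insert at 4000: recovered span [3919,4581) with flanks 81 / 81 bp
panel FASTA header: >parent_nb7 simulated neighbor {SQ 3920-4581}
```

At 2% divergence every 100-mer stays within the 90% identity threshold of
the parent, so nothing is retained; at 15% divergence almost every window
falls below it and the neighbors are kept nearly whole. A novel 500-bp
segment comes back as a single excised span whose flanks are bounded by
k − 1 = 99 bp, here 81 bp on each side.

`examples/04_capture_evaluation.py` evaluates a simulated capture
experiment (0.01% viral reads precapture, 674× enrichment, 10⁶ reads):

```
viral reads: 100 pre, 67400 post (of 10^6 each)
percent viral reads: 0.0100% -> 6.7400%, fold change 674
breadth of coverage: 63.6% -> 100.0% (BoC gain 36.4 points)
precapture gaps: median 51 bp, max 350 bp; post-capture: median 0 bp, max 0 bp
start-site dedup: 67400 -> 19146 reads, mean depth 674.0x -> 191.5x (theoretical max 200x for 100-bp reads)
```

The other examples cover long-set clustering (`02`) and panel pooling,
masking and offset metrics (`03`). A `viropanel` command-line interface
exposes the same pipeline (`viropanel --help`): `condense`,
`flu-condense`, `host-filter`, `mask`, `build-panel`, `panel-metrics`,
`eval-coverage` and `simulate`.

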