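"""Long-sequence clustering mode for very large redundant sets.

Concatenates parent references into a construct, splits it into seed
segments, then greedy-clusters candidate sequences at 90% identity.
Sequences folding into parent segments vanish; only centroids of
non-parent clusters are retained, full length.
"""

import numpy as np

from viropanel import SequenceRecord, build_parent_construct, condense_long_set

rng = np.random.default_rng(0)
BASES = np.array(list("ACGT"))


def random_seq(n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


parents = [SequenceRecord(f"ref_seg{i}", random_seq(800)) for i in range(3)]
construct = build_parent_construct(parents, n_segments=4)
print("construct segments:", [(s.id, s.length) for s in construct.segments])

# 10 near-copies of parent material + 2 unrelated genomes
def mutate(residues: str, rate: float) -> str:
    out = list(residues)
    for p in np.nonzero(rng.random(len(out)) < rate)[0]:
        out[p] = "ACGT".replace(out[p], "")[rng.integers(0, 3)]
    return "".join(out)


sequences = [
    SequenceRecord(f"strain{i}", mutate(construct.segments[i % 4].residues, 0.04))
    for i in range(10)
] + [SequenceRecord(f"novel{i}", random_seq(700)) for i in range(2)]

entries, stats, assignments = condense_long_set(parents, sequences, n_segments=4)
print(
    f"retained {stats.entries_out} of {len(sequences)} sequences "
    f"({stats.retained_bp} of {stats.input_bp} bp): "
    + ", ".join(e.source_id for e in entries)
)
folded = [a for a in assignments if not a.is_centroid]
print(f"{len(folded)} sequences folded into centroids at identity >= 0.90")
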