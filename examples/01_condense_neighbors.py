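"""Condense a simulated strain cloud against its parent genome.

Builds a 10-kb parent, derives neighbors at low (2%) and high (15%)
substitution divergence plus one neighbor carrying a 500-bp novel segment,
and condenses each set.  Low-divergence neighbors are almost entirely
redundant with the tiled parent (reduction ratio near 0); high-divergence
neighbors are retained nearly whole (ratio near 1); the novel segment comes
back as a single excised span with sub-k flanks.
"""

from viropanel import MutationSpec, condense_neighbors, simulate_neighbor, simulate_parent

parent = simulate_parent(10_000, seed=42)

for rate in (0.02, 0.15):
    neighbors = [
        simulate_neighbor(parent, MutationSpec(substitution_rate=rate, seed=i))[0]
        for i in range(5)
    ]
    entries, stats = condense_neighbors(parent, neighbors)
    print(
        f"substitution rate {rate:.0%}: {stats.input_bp} bp in -> "
        f"{stats.retained_bp} bp retained ({stats.entries_out} entries, "
        f"reduction ratio {stats.reduction_ratio:.4f})"
    )

nb, truth = simulate_neighbor(parent, MutationSpec(novel_inserts=((4000, 500),), seed=7))
entries, stats = condense_neighbors(parent, [nb])
(entry,) = entries
(ins,) = truth
print(
    f"novel 500-bp insert at {ins.start}: recovered span "
    f"[{entry.span.start},{entry.span.end}) with flanks "
    f"{ins.start - entry.span.start} / {entry.span.end - ins.end} bp"
)
print("panel FASTA header:", ">" + entry.header())
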