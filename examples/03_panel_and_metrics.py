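"""Pool panel entries, DUST-mask, tile naive probes, report offset coverage.

The 0-bp-offset metric counts target bases directly inside probes; the
100-bp-offset metric counts bases within 100 bp of one.  Full stride-100
tiling covers every unmasked base at zero offset by construction; sparser
tiling shows the gap the offset metric closes.
"""

import numpy as np

from viropanel import (
    Provenance,
    TargetEntry,
    dust_mask,
    offset_coverage,
    pool_entries,
    tile_probes,
)

rng = np.random.default_rng(3)
BASES = np.array(list("ACGT"))
seqs = ["".join(BASES[rng.integers(0, 4, size=n)]) for n in (700, 450, 230)]
# one entry carries a low-complexity tract that must not seed probes
seqs[1] = seqs[1][:200] + "AT" * 40 + seqs[1][280:]

entries = [
    TargetEntry(source_id=f"t{i}", residues=s, provenance=Provenance.PARENT_TILED)
    for i, s in enumerate(seqs)
]
probe = TargetEntry(
    source_id="external_probe",
    residues=seqs[0][100:170],
    provenance=Provenance.EXTERNAL_PROBE,
)
panel, stats = pool_entries([entries, [probe]])
print(f"pooled panel: {stats.entries} entries, {stats.total_bp} bp "
      f"(the external probe is already represented and was dropped)")

masked = [dust_mask(e) for e in panel]
n_masked = sum(m.residues.count("N") for m in masked)
print(f"DUST hard-masked {n_masked} low-complexity bases")

probes = tile_probes(masked, probe_length=100, stride=100)
for off in (0, 100):
    cov = offset_coverage(masked, probes, offset=off)
    print(f"stride-100 tiling, {off}-bp-offset coverage: {cov:.4f}")

sparse = tile_probes(masked, probe_length=100, stride=300)
for off in (0, 100):
    cov = offset_coverage(masked, sparse, offset=off)
    print(f"stride-300 tiling, {off}-bp-offset coverage: {cov:.4f}")
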