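"""Panel pooling, naive probe tiling and design-coverage metrics.

Entries from all sources (tiled parents, excised neighbor sub-sequences,
long-set centroids, external probe sets) are pooled into one panel.
External probes already present verbatim in a non-probe entry (either
strand) are dropped as redundant; byte-identical entries collapse.  Probes
are then tiled end-to-end per entry and coverage is assessed with the
offset metric: the fraction of non-N target bases lying within ``offset``
bp of a probe (0-bp-offset counts bases directly inside probes).  Vendor
probe redistribution is deliberately out of scope — tiling here is the
naive reference design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .seqio import GenomicInterval, Provenance, TargetEntry, revcomp

__all__ = ["Probe", "PanelStats", "pool_entries", "tile_probes", "offset_coverage"]


@dataclass(frozen=True)
class Probe:
    """A tiled oligo: a slice of one panel entry."""

    probe_id: str
    target_id: str
    span: GenomicInterval
    residues: str


@dataclass
class PanelStats:
    entries: int
    total_bp: int
    bp_by_provenance: dict[Provenance, int]

    @property
    def fraction_by_provenance(self) -> dict[Provenance, float]:
        if not self.total_bp:
            return {p: 0.0 for p in self.bp_by_provenance}
        return {p: bp / self.total_bp for p, bp in self.bp_by_provenance.items()}


def pool_entries(
    sources: list[list[TargetEntry]],
) -> tuple[list[TargetEntry], PanelStats]:
    """Pool entry lists into one panel, dropping redundancy.

    External-probe entries whose residues occur verbatim (either strand) as
    a substring of any non-probe entry are already represented by the panel
    and are dropped; exact duplicate entries collapse to one.
    """
    flat = [e for src in sources for e in src]
    backbone = "\n".join(
        e.residues for e in flat if e.provenance is not Provenance.EXTERNAL_PROBE
    )
    panel: list[TargetEntry] = []
    seen: set[tuple] = set()
    for e in flat:
        key = (e.provenance, e.source_id, e.span, e.residues)
        if key in seen:
            continue
        if e.provenance is Provenance.EXTERNAL_PROBE and (
            e.residues in backbone or revcomp(e.residues) in backbone
        ):
            continue
        seen.add(key)
        panel.append(e)

    bp: dict[Provenance, int] = {p: 0 for p in Provenance}
    for e in panel:
        bp[e.provenance] += e.length
    stats = PanelStats(
        entries=len(panel),
        total_bp=sum(bp.values()),
        bp_by_provenance=bp,
    )
    return panel, stats


def tile_probes(
    panel: list[TargetEntry], probe_length: int = 100, stride: int = 100
) -> list[Probe]:
    """End-to-end naive tiling of each entry.

    The final probe is right-anchored to the entry end when the length is
    not a multiple of the stride (guaranteeing terminal-base coverage);
    entries shorter than the probe length yield one full-entry probe.
    Probes lying wholly in masked (all-N) sequence are dropped.
    """
    if probe_length < 1 or stride < 1:
        raise ContractError("probe_length and stride must be >= 1")
    probes: list[Probe] = []
    for entry in panel:
        L = entry.length
        starts: list[int]
        if L <= probe_length:
            starts = [0]
        else:
            starts = list(range(0, L - probe_length + 1, stride))
            if starts[-1] + probe_length < L:
                starts.append(L - probe_length)
        for s in starts:
            e = min(L, s + probe_length)
            res = entry.residues[s:e]
            if set(res) == {"N"}:
                continue
            probes.append(
                Probe(
                    probe_id=f"{entry.entry_id}:{s}-{e}",
                    target_id=entry.entry_id,
                    span=GenomicInterval(entry.entry_id, s, e),
                    residues=res,
                )
            )
    return probes


def offset_coverage(
    panel: list[TargetEntry], probes: list[Probe], offset: int = 0
) -> float:
    """Fraction of non-N target bases within ``offset`` bp of a probe.

    Probe spans are extended by ``offset`` on each side (clipped to the
    entry); masked (N) bases are excluded from the denominator because they
    are uncapturable by design.  Defined as 0 for an empty panel.
    """
    if offset < 0:
        raise ContractError("offset must be >= 0")
    by_target: dict[str, list[Probe]] = {}
    for p in probes:
        by_target.setdefault(p.target_id, []).append(p)
    covered = 0
    total = 0
    for entry in panel:
        not_n = np.frombuffer(entry.residues.encode("ascii"), dtype=np.uint8) != ord("N")
        total += int(not_n.sum())
        cover = np.zeros(entry.length, dtype=bool)
        for p in by_target.get(entry.entry_id, []):
            s = max(0, p.span.start - offset)
            e = min(entry.length, p.span.end + offset)
            cover[s:e] = True
        covered += int((cover & not_n).sum())
    return covered / total if total else 0.0
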