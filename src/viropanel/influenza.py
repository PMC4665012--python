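"""Long-sequence clustering mode for very large redundant sets.

Highly sequenced viruses (influenza being the motivating case, with
hundreds of thousands of segment records) are condensed by clustering
full-length sequences rather than k-mers.  The canonical reference segments
are concatenated into one construct, split into a few large seed segments
so that single-pass greedy clustering always seeds with the canonical
references first, and every other sequence either folds into an existing
centroid at the identity threshold or founds a new cluster.  Only centroids
of non-reference clusters are retained, full-length (no excision here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import (
    ClusterAssignment,
    ClusterParams,
    greedy_cluster,
    select_nonparent_centroids,
)
from .condense import CondenseStats
from .errors import ContractError
from .seqio import GenomicInterval, Provenance, SequenceRecord, TargetEntry

__all__ = ["ParentConstruct", "build_parent_construct", "condense_long_set"]


@dataclass
class ParentConstruct:
    """Concatenated parent references split into near-equal seed segments.

    ``segment_provenance`` maps each segment id to the list of
    ``(parent_id, span)`` pieces it contains, with spans in construct
    coordinates, so every construct base remains attributable to its
    source parent.
    """

    segments: list[SequenceRecord]
    segment_provenance: dict[str, list[tuple[str, GenomicInterval]]]

    @property
    def segment_ids(self) -> set[str]:
        return {s.id for s in self.segments}


def build_parent_construct(
    parents: list[SequenceRecord],
    n_segments: int = 6,
    construct_id: str = "parent_construct",
) -> ParentConstruct:
    """Concatenate ``parents`` and split into near-equal segments.

    Segment sizes differ by at most 1 bp (the original design used a few
    large 18-26 kb segments; the count, not the absolute size, is the
    knob here).  The concatenation of the segments equals the
    concatenation of the inputs exactly.
    """
    if n_segments < 1:
        raise ContractError("n_segments must be >= 1")
    concat = "".join(p.residues for p in parents)
    total = len(concat)
    if total < n_segments:
        raise ContractError(
            f"total parent length {total} smaller than n_segments={n_segments}"
        )
    # parent extents in construct coordinates
    extents: list[tuple[str, int, int]] = []
    pos = 0
    for p in parents:
        extents.append((p.id, pos, pos + p.length))
        pos += p.length

    bounds = [round(i * total / n_segments) for i in range(n_segments + 1)]
    segments: list[SequenceRecord] = []
    provenance: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for i in range(n_segments):
        s, e = bounds[i], bounds[i + 1]
        seg_id = f"{construct_id}_seg{i + 1}"
        segments.append(
            SequenceRecord(
                id=seg_id,
                residues=concat[s:e],
                description=f"{seg_id} construct [{s},{e}) of {len(parents)} parents",
            )
        )
        pieces = [
            (pid, GenomicInterval(construct_id, max(ps, s), min(pe, e)))
            for pid, ps, pe in extents
            if ps < e and pe > s
        ]
        provenance[seg_id] = pieces
    return ParentConstruct(segments=segments, segment_provenance=provenance)


def condense_long_set(
    parents: list[SequenceRecord],
    sequences: list[SequenceRecord],
    params: ClusterParams = ClusterParams(),
    n_segments: int = 6,
) -> tuple[list[TargetEntry], CondenseStats, list[ClusterAssignment]]:
    """Greedy-cluster ``sequences`` against the parent construct segments.

    Clustering order is construct segments first, then sequences
    length-descending (stable on input order).  Retained entries are the
    centroids of non-parent clusters, kept full-length with provenance
    ``long_cluster_centroid``.  Stats count only the candidate sequences,
    not the construct.
    """
    construct = build_parent_construct(parents, n_segments=n_segments) if parents else None
    seg_ids: set[str] = construct.segment_ids if construct else set()
    ordered = (construct.segments if construct else []) + sorted(
        sequences, key=lambda r: -r.length
    )
    assignments = greedy_cluster(ordered, params=params)
    retained_ids = select_nonparent_centroids(assignments, seg_ids)

    by_id = {r.id: r for r in sequences}
    entries = [
        TargetEntry(
            source_id=rid,
            residues=by_id[rid].residues,
            provenance=Provenance.LONG_CLUSTER_CENTROID,
            span=None,
            description=by_id[rid].description,
        )
        for rid in retained_ids
    ]
    stats = CondenseStats(
        input_bp=sum(r.length for r in sequences),
        retained_bp=sum(e.length for e in entries),
        entries_out=len(entries),
    )
    return entries, stats, assignments
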