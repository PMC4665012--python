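"""The core panel reduction: keep divergent k-mers, merge, excise.

For each neighbor genome of a tiled parent: enumerate every k-mer, classify
it against the parent, project the divergent k-mers back onto neighbor
coordinates, merge the overlapping (and bookended) k-mer spans into
contiguous intervals, and excise those intervals as panel entries carrying
the ``{SQ a-b}`` header dialect.  Neighbors identical to the parent
contribute nothing; fully novel neighbors are retained whole.  This is what
condenses hundreds of megabases of redundant strain sequence into a compact
divergence-preserving target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterParams, ParentScanIndex
from .errors import ContractError
from .seqio import GenomicInterval, Provenance, SequenceRecord, TargetEntry

log = logging.getLogger(__name__)

__all__ = [
    "CondenseStats",
    "merge_spans",
    "condense_neighbors",
    "condense_species_set",
]


@dataclass
class CondenseStats:
    """Aggregate bookkeeping of one condensation run."""

    input_bp: int = 0
    retained_bp: int = 0
    entries_out: int = 0

    @property
    def reduction_ratio(self) -> float:
        """Retained over input bp; defined as 0 for empty input."""
        return self.retained_bp / self.input_bp if self.input_bp else 0.0


def merge_spans(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and bookended intervals into disjoint sorted spans.

    All intervals must lie on one sequence.  Bookended intervals
    (end == next start) merge because step-1 k-mers at consecutive offsets
    overlap by k-1 bases, making contiguity the natural unit; a single-base
    gap keeps spans separate.
    """
    if not intervals:
        return []
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) != 1:
        raise ContractError(f"merge_spans requires a single seq_id, got {sorted(seq_ids)}")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.start, v.end)):
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.seq_id, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def _divergent_spans(
    index: ParentScanIndex, neighbor: SequenceRecord
) -> list[GenomicInterval]:
    represented, _ = index.classify_offsets(neighbor)
    offsets = np.nonzero(~represented)[0]
    k = index.k
    spans = [GenomicInterval(neighbor.id, int(o), int(o) + k) for o in offsets]
    return merge_spans(spans)


def condense_neighbors(
    parent: SequenceRecord,
    neighbors: list[SequenceRecord],
    params: ClusterParams = ClusterParams(),
    k: int = 100,
) -> tuple[list[TargetEntry], CondenseStats]:
    """Condense a neighbor set against one tiled parent.

    Returns excised panel entries (provenance ``neighbor_subseq``) and
    aggregate stats.  Neighbors shorter than k are skipped with a warning
    but still counted in ``input_bp``.  Each neighbor is processed
    independently; there is no cross-neighbor deduplication.
    """
    if parent.length < k:
        raise ContractError(f"parent {parent.id} shorter than k={k}")
    index = ParentScanIndex(parent, k=k, params=params)
    entries: list[TargetEntry] = []
    stats = CondenseStats()
    for nb in neighbors:
        stats.input_bp += nb.length
        if nb.length < k:
            log.warning("neighbor %s (%d bp) shorter than k=%d; skipped", nb.id, nb.length, k)
            continue
        for span in _divergent_spans(index, nb):
            entries.append(
                TargetEntry(
                    source_id=nb.id,
                    residues=nb.slice(span.start, span.end),
                    provenance=Provenance.NEIGHBOR_SUBSEQ,
                    span=span,
                    description=nb.description,
                )
            )
            stats.retained_bp += span.length
            stats.entries_out += 1
    return entries, stats


def condense_species_set(
    parent: SequenceRecord,
    neighbors: list[SequenceRecord],
    params: ClusterParams = ClusterParams(),
    k: int = 100,
) -> tuple[list[TargetEntry], CondenseStats, pd.DataFrame]:
    """Batch wrapper adding a per-neighbor stats table.

    The table has one row per neighbor: ``neighbor_id``, ``length``,
    ``retained_bp``, ``entries`` — deterministic in input order.
    """
    entries, stats = condense_neighbors(parent, neighbors, params=params, k=k)
    per: dict[str, dict[str, int]] = {
        nb.id: {"length": nb.length, "retained_bp": 0, "entries": 0} for nb in neighbors
    }
    for e in entries:
        row = per[e.source_id]
        row["retained_bp"] += e.length
        row["entries"] += 1
    table = pd.DataFrame(
        [
            {"neighbor_id": nid, **row}
            for nid, row in per.items()
        ],
        columns=["neighbor_id", "length", "retained_bp", "entries"],
    )
    return entries, stats, table
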