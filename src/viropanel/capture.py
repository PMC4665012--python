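"""Pre/post-capture comparison metrics.

Everything downstream of read mapping: choosing one reference per species,
breadth/depth/gap accounting, breadth-of-coverage (BoC) gain, start-site
deduplication, fold change in percent viral reads, and recovery of
divergent contigs against the panel.

Depth counts aligned-span bases: a read contributes 1 to every reference
position in ``[start, end)``.  SAM ingestion collapses each mapped primary
record's aligned blocks to that single span (a documented approximation —
CIGAR deletions inside a read still count as covered).  Breadth is the
percentage of positions with depth >= 1; gaps are maximal zero-depth runs,
including uncovered reference ends, so breadth and gap totals are exactly
complementary in bases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .align import Orientation, local_identity
from .errors import ContractError
from .seqio import SequenceRecord, TargetEntry

__all__ = [
    "AlignmentRecord",
    "CoverageReport",
    "EnrichmentResult",
    "read_sam",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "select_species_reference",
    "coverage_report",
    "boc_gain",
    "dedup_by_start",
    "enrichment",
    "contig_recovery",
    "capture_report_table",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """A read placement on a reference (aligned span, no CIGAR detail)."""

    read_id: str
    ref_id: str
    start: int
    end: int
    orientation: Orientation
    quality: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ContractError(
                f"invalid alignment span [{self.start},{self.end}) for {self.read_id}"
            )
        if self.quality < 0:
            raise ContractError("quality must be >= 0")


@dataclass
class CoverageReport:
    ref_id: str
    ref_length: int
    reads: int
    breadth: float  # percent of positions with depth >= 1
    mean_depth: float
    gaps: list[int]
    median_gap: float
    max_gap: int

    @property
    def covered_bases(self) -> int:
        return self.ref_length - sum(self.gaps)


@dataclass
class EnrichmentResult:
    """Fold change in percent viral reads, pre- to post-capture."""

    pre_fraction: float  # percent
    post_fraction: float  # percent
    fold: float
    lower_bound: bool  # True when no precapture viral reads were seen
    boc_gain: float | None = None

    @property
    def fold_display(self) -> str:
        text = f"{self.fold:g}"
        return f">{text}" if self.lower_bound else text


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    """Read mapped primary records from a SAM file.

    Returns ``(records, total_primary_reads)`` where the total includes
    unmapped reads (needed for percent-viral-read denominators).
    """
    records: list[AlignmentRecord] = []
    total = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            total += 1
            if rec.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=rec.query_name or "read",
                    ref_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    orientation=Orientation.REVERSE if rec.is_reverse else Orientation.FORWARD,
                    quality=rec.mapping_quality,
                )
            )
    return records, total


_TSV_COLUMNS = ["read_id", "ref_id", "start", "end", "orientation", "quality"]


def write_alignment_tsv(records: list[AlignmentRecord], path: str | Path) -> None:
    """Documented tabular equivalent of the SAM subset this module uses."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_COLUMNS)
        for r in records:
            w.writerow([r.read_id, r.ref_id, r.start, r.end, r.orientation.value, r.quality])


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                AlignmentRecord(
                    read_id=row["read_id"],
                    ref_id=row["ref_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    orientation=Orientation(row["orientation"]),
                    quality=int(row["quality"]),
                )
            )
    return records


def select_species_reference(
    per_ref_covered_bases: dict[str, int], species_of: dict[str, str]
) -> dict[str, str]:
    """One reference per species, maximizing covered bases.

    Ties break to the lexicographically smallest reference id so the
    choice is deterministic.
    """
    best: dict[str, str] = {}
    for ref_id in sorted(per_ref_covered_bases):
        covered = per_ref_covered_bases[ref_id]
        species = species_of[ref_id]
        cur = best.get(species)
        if cur is None or covered > per_ref_covered_bases[cur]:
            best[species] = ref_id
    return best


def _depth(alignments: list[AlignmentRecord], ref_id: str, ref_length: int) -> np.ndarray:
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    for a in alignments:
        if a.ref_id != ref_id:
            raise ContractError(f"alignment {a.read_id} is on {a.ref_id}, not {ref_id}")
        if a.end > ref_length:
            raise ContractError(
                f"alignment {a.read_id} [{a.start},{a.end}) exceeds reference length {ref_length}"
            )
        diff[a.start] += 1
        diff[a.end] -= 1
    return np.cumsum(diff[:-1])


def coverage_report(
    alignments: list[AlignmentRecord], ref_id: str, ref_length: int
) -> CoverageReport:
    """Breadth, mean depth and gap statistics for one reference."""
    if ref_length < 1:
        raise ContractError("ref_length must be >= 1")
    depth = _depth(alignments, ref_id, ref_length)
    covered = depth > 0
    # maximal zero-depth runs, including uncovered reference ends
    boundaries = np.flatnonzero(np.diff(np.concatenate(([True], covered, [True]))))
    gaps = [int(boundaries[i + 1] - boundaries[i]) for i in range(0, len(boundaries), 2)]
    n_cov = int(covered.sum())
    return CoverageReport(
        ref_id=ref_id,
        ref_length=ref_length,
        reads=len(alignments),
        breadth=100.0 * n_cov / ref_length,
        mean_depth=float(depth.mean()),
        gaps=gaps,
        median_gap=float(np.median(gaps)) if gaps else 0.0,
        max_gap=max(gaps) if gaps else 0,
    )


def boc_gain(pre: CoverageReport, post: CoverageReport) -> float:
    """Post-capture breadth minus precapture breadth, in percentage points."""
    if pre.ref_id != post.ref_id:
        raise ContractError(
            f"BoC gain requires matching references ({pre.ref_id} vs {post.ref_id})"
        )
    return post.breadth - pre.breadth


def dedup_by_start(alignments: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Start-site deduplication: one best read per (ref, start, orientation).

    The highest-quality read wins (first encountered on quality ties).
    Forward and reverse reads sharing a start are both retained, so
    deduplicated L-bp reads can stack to at most 2L depth (the 200x
    theoretical maximum for 100-bp reads).
    """
    best: dict[tuple[str, int, Orientation], AlignmentRecord] = {}
    for a in alignments:
        key = (a.ref_id, a.start, a.orientation)
        cur = best.get(key)
        if cur is None or a.quality > cur.quality:
            best[key] = a
    return list(best.values())


def enrichment(
    pre_viral: int, pre_total: int, post_viral: int, post_total: int
) -> EnrichmentResult:
    """Fold change in percent viral reads.

    When no viral reads were seen precapture, the fold is computed with a
    single-read pseudo-count and flagged as a lower bound (rendered with a
    leading ``>``), matching how such samples are conventionally reported.
    """
    if pre_total <= 0 or post_total <= 0:
        raise ContractError("read totals must be positive")
    if min(pre_viral, post_viral) < 0:
        raise ContractError("viral read counts must be non-negative")
    pre_frac = 100.0 * pre_viral / pre_total
    post_frac = 100.0 * post_viral / post_total
    lower = pre_viral == 0
    denom = 100.0 * max(pre_viral, 1) / pre_total
    fold = post_frac / denom if denom else 0.0
    return EnrichmentResult(
        pre_fraction=pre_frac,
        post_fraction=post_frac,
        fold=fold,
        lower_bound=lower,
    )


def contig_recovery(
    contig: SequenceRecord,
    panel: list[TargetEntry],
    post_alignments: list[AlignmentRecord],
) -> tuple[float | None, float]:
    """How well a (possibly divergent) contig is recovered.

    Returns ``(top_hsp_identity_percent, contig_breadth_percent)``: the
    identity of the best local alignment between the contig and any panel
    entry (both strands; None for an empty panel), and the breadth of the
    post-capture alignments on the contig.
    """
    if contig.length < 100:
        raise ContractError("contig must be >= 100 bp")
    top: float | None = None
    for entry in panel:
        ident, _ = local_identity(contig.residues, entry.residues, rc_aware=True)
        if top is None or ident > top:
            top = ident
    breadth = coverage_report(post_alignments, contig.id, contig.length).breadth
    return (None if top is None else 100.0 * top), breadth


def capture_report_table(
    rows: list[tuple[str, CoverageReport, CoverageReport, EnrichmentResult]],
) -> pd.DataFrame:
    """Per-reference table mirroring the pre/post capture comparison.

    One row per reference: read counts and percent viral reads pre/post,
    breadth pre/post, BoC gain, post mean depth, post median/max gap and
    the fold change (with ``>`` lower bounds preserved as text).
    """
    out = []
    for ref_id, pre, post, enr in rows:
        out.append(
            {
                "ref_id": ref_id,
                "ref_length": post.ref_length,
                "pre_reads": pre.reads,
                "post_reads": post.reads,
                "pre_pct_reads": enr.pre_fraction,
                "post_pct_reads": enr.post_fraction,
                "pre_breadth": pre.breadth,
                "post_breadth": post.breadth,
                "boc_gain": boc_gain(pre, post),
                "post_mean_depth": post.mean_depth,
                "post_median_gap": post.median_gap,
                "post_max_gap": post.max_gap,
                "fold": enr.fold_display,
            }
        )
    return pd.DataFrame(out)
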