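"""Identity classification and greedy centroid clustering.

Two modes mirror the two condensation strategies:

* short k-mer vs long parent — is a candidate 100-bp probe already
  represented (identity >= threshold anywhere in the tiled parent, either
  strand) or divergent and therefore worth adding to the panel;
* long sequence vs long sequence — single-pass greedy clustering in which
  each entry folds into the first existing centroid meeting the threshold
  or becomes a new centroid itself (UCLUST-style, order-deterministic).

For batch k-mer classification against large parents,
:class:`ParentScanIndex` accelerates the exhaustive scan with exact seed
matches: any placement reaching identity t must contain a run of
``seed_len`` consecutive matching bases and at least ``min_hits`` such
seeds within a bounded diagonal band (pigeonhole over the at most
``runs_max`` match runs a qualifying alignment can have), so candidate
windows can be enumerated from an index of parent seeds and everything else
rejected without alignment.  The windowed DP inside candidate windows is
the same glocal engine used everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import _kernels
from ._kernels import COL_MAX, MATCH_MASK, MATCH_SHIFT, encode_seq
from .align import DEFAULT_SCORING, Orientation, Scoring, glocal_identity
from .errors import ContractError
from .kmers import PositionedKmer
from .seqio import SequenceRecord, revcomp

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "KmerClass",
    "pairwise_identity",
    "classify_kmer_vs_parent",
    "ParentScanIndex",
    "greedy_cluster",
    "select_nonparent_centroids",
    "write_assignments_tsv",
]

_EPS = 1e-12
_MIN_SEED_LEN = 6  # below this, seeding produces too many spurious hits
_SEEDED_MIN_PARENT = 5000  # exhaustive DP is fine for smaller parents


@dataclass(frozen=True)
class ClusterParams:
    """Identity threshold and strand handling for all clustering modes."""

    identity_threshold: float = 0.90
    rc_aware: bool = True
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ContractError(
                f"identity_threshold must be in (0, 1]: {self.identity_threshold}"
            )


@dataclass(frozen=True)
class ClusterAssignment:
    member_id: str
    centroid_id: str
    identity: float
    orientation: Orientation

    @property
    def is_centroid(self) -> bool:
        return self.member_id == self.centroid_id


class KmerClass(Enum):
    REPRESENTED = "represented"
    DIVERGENT = "divergent"


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    rc_aware: bool = True,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[float, Orientation]:
    """Glocal identity between two records (see :mod:`viropanel.align`)."""
    return glocal_identity(a.residues, b.residues, rc_aware=rc_aware, scoring=scoring)


@dataclass(frozen=True)
class SeedPlan:
    """Exact-seed screening parameters derived from (k, threshold).

    For identity >= t over a k-mer, any qualifying alignment has at most
    ``d_max`` deletion columns, at most ``runs_max`` maximal match runs and
    at least ``ceil(t*k)`` matched k-mer positions, hence contains an exact
    run of ``seed_len`` bases and at least ``min_hits`` seed windows, all
    within a diagonal band of width ``runs_max - 1``.
    """

    seed_len: int
    min_hits: int
    diag_gap: int
    pad: int
    viable: bool


def seed_plan(k: int, threshold: float) -> SeedPlan:
    t = threshold
    d_max = math.floor(k * (1.0 - t) / t)
    m_min = math.ceil(t * k)
    events_max = math.floor(k * (1.0 - t) + (1.0 - t) * d_max)
    runs_max = events_max + 1
    seed_len = min(31, k, math.ceil(m_min / runs_max))
    min_hits = max(1, m_min - (seed_len - 1) * runs_max)
    diag_gap = events_max + 1
    pad = d_max + 8
    return SeedPlan(
        seed_len=seed_len,
        min_hits=min_hits,
        diag_gap=diag_gap,
        pad=pad,
        viable=seed_len >= _MIN_SEED_LEN,
    )


def _best_identity_vs_parent(
    kmer_codes: np.ndarray,
    p_fwd: np.ndarray,
    p_rev: np.ndarray | None,
    scoring: Scoring,
) -> float:
    args = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    key = int(_kernels.semiglobal_key(kmer_codes, p_fwd, *args))
    if p_rev is not None:
        rev = int(_kernels.semiglobal_key(kmer_codes, p_rev, *args))
        if rev > key:
            key = rev
    matches = (key >> MATCH_SHIFT) & MATCH_MASK
    cols = COL_MAX - (key & COL_MAX)
    return matches / cols if cols else 0.0


def classify_kmer_vs_parent(
    kmer: PositionedKmer,
    parent: SequenceRecord,
    params: ClusterParams = ClusterParams(),
) -> KmerClass:
    """Exhaustive classification of one k-mer against a tiled parent.

    Represented means the best glocal placement of the k-mer anywhere in
    the parent (either strand when rc-aware) reaches the identity
    threshold; such k-mers are already covered by the parent's probe tiling
    and are discarded.  Divergent k-mers are retained for the panel.
    """
    if parent.length < len(kmer.residues):
        raise ContractError("parent must be at least as long as the k-mer")
    ident = _best_identity_vs_parent(
        encode_seq(kmer.residues),
        encode_seq(parent.residues),
        encode_seq(revcomp(parent.residues)) if params.rc_aware else None,
        params.scoring,
    )
    if ident >= params.identity_threshold - _EPS:
        return KmerClass.REPRESENTED
    return KmerClass.DIVERGENT


class ParentScanIndex:
    """Seed index of one parent for batch k-mer classification.

    Falls back transparently to the exhaustive glocal scan when the parent
    is short or the threshold does not admit a usable seed length.
    """

    def __init__(
        self,
        parent: SequenceRecord,
        k: int = 100,
        params: ClusterParams = ClusterParams(),
    ) -> None:
        if parent.length < k:
            raise ContractError(
                f"parent {parent.id} ({parent.length} bp) shorter than k={k}"
            )
        self.parent = parent
        self.k = int(k)
        self.params = params
        self.plan = seed_plan(self.k, params.identity_threshold)
        self.p_fwd = encode_seq(parent.residues)
        self.p_rev = encode_seq(revcomp(parent.residues)) if params.rc_aware else None
        self.seeded = self.plan.viable and parent.length >= _SEEDED_MIN_PARENT
        if self.seeded:
            self._fwd_index = self._build(self.p_fwd)
            self._rev_index = self._build(self.p_rev) if params.rc_aware else None

    def _build(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        seeds = _kernels.seed_codes(codes, self.plan.seed_len)
        valid = seeds != _kernels.SEED_INVALID
        pos = np.nonzero(valid)[0].astype(np.int64)
        vals = seeds[valid]
        order = np.argsort(vals, kind="stable")
        return vals[order], pos[order]

    def classify_offsets(
        self, neighbor: SequenceRecord, step: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Classify every k-mer offset of ``neighbor``.

        Returns ``(represented, identity)`` arrays over offsets
        ``0, step, 2*step, ...``; ``identity`` holds the best identity seen
        while deciding (0.0 where no candidate placement was examined —
        such k-mers share no seed with the parent and are divergent).
        """
        k, params = self.k, self.params
        if neighbor.length < k:
            raise ContractError(
                f"neighbor {neighbor.id} ({neighbor.length} bp) shorter than k={k}"
            )
        nc = encode_seq(neighbor.residues)
        n_kmers = (neighbor.length - k) // step + 1
        status = np.zeros(n_kmers, dtype=np.int8)
        ident = np.zeros(n_kmers, dtype=np.float64)
        s = params.scoring

        if self.seeded:
            ns = _kernels.seed_codes(nc, self.plan.seed_len)
            skip = np.zeros(n_kmers, dtype=np.bool_)
            _kernels.scan_strand(
                nc, ns, k, step, self.plan.seed_len,
                self.p_fwd, self._fwd_index[0], self._fwd_index[1],
                self.plan.diag_gap, self.plan.pad, self.plan.min_hits,
                params.identity_threshold,
                s.match, s.mismatch, s.gap_open, s.gap_extend,
                skip, status, ident,
            )
            if params.rc_aware:
                overflowed = status == 2
                skip = (status == 1) | overflowed
                _kernels.scan_strand(
                    nc, ns, k, step, self.plan.seed_len,
                    self.p_rev, self._rev_index[0], self._rev_index[1],
                    self.plan.diag_gap, self.plan.pad, self.plan.min_hits,
                    params.identity_threshold,
                    s.match, s.mismatch, s.gap_open, s.gap_extend,
                    skip, status, ident,
                )
                status[overflowed] = 2
            fallback = np.nonzero(status == 2)[0]
        else:
            fallback = np.arange(n_kmers)

        for idx in fallback:
            g = int(idx) * step
            iv = _best_identity_vs_parent(nc[g : g + k], self.p_fwd, self.p_rev, s)
            ident[idx] = iv
            status[idx] = 1 if iv >= params.identity_threshold - _EPS else 0
        return status == 1, ident


def greedy_cluster(
    entries: list[SequenceRecord], params: ClusterParams = ClusterParams()
) -> list[ClusterAssignment]:
    """Single-pass greedy clustering of caller-ordered entries.

    Each entry folds into the *first* existing centroid whose glocal
    identity meets the threshold, otherwise it becomes a new centroid.  The
    caller is responsible for ordering (length-descending, designated
    parent constructs first), exactly as length-sorted UCLUST-style
    clustering expects; the result is deterministic given the input order.
    """
    centroids: list[SequenceRecord] = []
    out: list[ClusterAssignment] = []
    thr = params.identity_threshold - _EPS
    for rec in entries:
        hit: ClusterAssignment | None = None
        for cen in centroids:
            ident, orient = pairwise_identity(
                rec, cen, rc_aware=params.rc_aware, scoring=params.scoring
            )
            if ident >= thr:
                hit = ClusterAssignment(rec.id, cen.id, ident, orient)
                break
        if hit is None:
            hit = ClusterAssignment(rec.id, rec.id, 1.0, Orientation.FORWARD)
            centroids.append(rec)
        out.append(hit)
    return out


def select_nonparent_centroids(
    assignments: list[ClusterAssignment], parent_ids: set[str]
) -> list[str]:
    """Centroid ids outside ``parent_ids``, in discovery order."""
    return [
        a.centroid_id
        for a in assignments
        if a.is_centroid and a.centroid_id not in parent_ids
    ]


def write_assignments_tsv(
    assignments: list[ClusterAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\tcentroid_id\tidentity\torientation\n")
        for a in assignments:
            fh.write(
                f"{a.member_id}\t{a.centroid_id}\t{a.identity:.4f}\t{a.orientation.value}\n"
            )
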