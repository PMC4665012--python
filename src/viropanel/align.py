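"""Pairwise alignment identity: affine-gap glocal and local alignment.

Identity is defined as matching columns divided by total alignment columns
of the *glocal* alignment: the shorter sequence aligned end-to-end against
its best free-ended placement in the longer sequence.  Gap columns count
against identity and N never counts as a match.  Among score-co-optimal
alignments the canonical one maximizing matches then minimizing columns is
reported, so results are fully deterministic (see ``_kernels``).

Scoring defaults — match +1, mismatch -1, gap open 2, gap extend 1 (a gap
of length g costs open + g*extend) — are fixed and exposed so results are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from . import _kernels
from ._kernels import COL_MAX, decode_key, encode_seq
from .errors import ContractError
from .seqio import revcomp

__all__ = [
    "Scoring",
    "Orientation",
    "AlignmentSummary",
    "glocal_alignment",
    "glocal_identity",
    "local_alignment",
    "local_identity",
]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ContractError("gap penalties must be non-negative")


DEFAULT_SCORING = Scoring()


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class AlignmentSummary:
    """Score and column bookkeeping of one canonical alignment."""

    score: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _check_lengths(a: str, b: str) -> None:
    if not a or not b:
        raise ContractError("alignment requires two non-empty sequences")
    if len(a) + len(b) >= COL_MAX:
        raise ContractError(
            f"combined length {len(a) + len(b)} exceeds supported maximum {COL_MAX}"
        )


def _orient(a: str, b: str) -> tuple[str, str]:
    """Canonical (query, target): query is the shorter sequence.

    Equal-length pairs order lexicographically so that identity(a, b) ==
    identity(b, a) exactly.
    """
    if len(a) < len(b) or (len(a) == len(b) and a <= b):
        return a, b
    return b, a


def glocal_alignment(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentSummary:
    """Glocal alignment of the shorter of ``a``/``b`` within the longer."""
    _check_lengths(a, b)
    q, t = _orient(a, b)
    key = _kernels.semiglobal_key(
        encode_seq(q),
        encode_seq(t),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    return AlignmentSummary(*decode_key(int(key)))


def glocal_identity(
    a: str,
    b: str,
    rc_aware: bool = True,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[float, Orientation]:
    """Best glocal identity of ``a`` vs ``b``, optionally trying both strands.

    When ``rc_aware`` the better of the forward and reverse-complement
    placement is returned (lexicographic key comparison; forward wins ties).
    """
    _check_lengths(a, b)
    q, t = _orient(a, b)
    qc, tc = encode_seq(q), encode_seq(t)
    args = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    fwd = int(_kernels.semiglobal_key(qc, tc, *args))
    if not rc_aware:
        return AlignmentSummary(*decode_key(fwd)).identity, Orientation.FORWARD
    rev = int(_kernels.semiglobal_key(qc, encode_seq(revcomp(t)), *args))
    if rev > fwd:
        return AlignmentSummary(*decode_key(rev)).identity, Orientation.REVERSE
    return AlignmentSummary(*decode_key(fwd)).identity, Orientation.FORWARD


def local_alignment(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentSummary:
    """Top-scoring local alignment (HSP) between ``a`` and ``b``."""
    _check_lengths(a, b)
    q, t = _orient(a, b)
    key = _kernels.local_key(
        encode_seq(q),
        encode_seq(t),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    return AlignmentSummary(*decode_key(int(key)))


def local_identity(
    a: str,
    b: str,
    rc_aware: bool = True,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[float, Orientation]:
    """Identity of the top HSP between ``a`` and ``b`` (both strands)."""
    _check_lengths(a, b)
    q, t = _orient(a, b)
    qc, tc = encode_seq(q), encode_seq(t)
    args = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    fwd = int(_kernels.local_key(qc, tc, *args))
    if not rc_aware:
        return AlignmentSummary(*decode_key(fwd)).identity, Orientation.FORWARD
    rev = int(_kernels.local_key(qc, encode_seq(revcomp(t)), *args))
    if rev > fwd:
        return AlignmentSummary(*decode_key(rev)).identity, Orientation.REVERSE
    return AlignmentSummary(*decode_key(fwd)).identity, Orientation.FORWARD
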