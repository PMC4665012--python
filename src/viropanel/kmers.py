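"""Exhaustive fixed-step k-merization of neighbor sequences.

The default ``k=100, step=1`` emits every possible 100-bp probe candidate
from a sequence — the exhaustive 1-bp sliding window used to enumerate all
potential capture-probe sequences in a genome-neighbor set.  K-mers
containing N are emitted; identity scoring downstream treats N as a
mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ContractError
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

__all__ = ["PositionedKmer", "kmerize"]


@dataclass(frozen=True)
class PositionedKmer:
    """A k-mer with its 0-based start offset in the source sequence."""

    source_id: str
    offset: int
    residues: str


def kmerize(seq: SequenceRecord, k: int = 100, step: int = 1) -> list[PositionedKmer]:
    """All k-mers of ``seq`` at offsets 0, step, 2*step, ...

    For a sequence of length L >= k this yields exactly
    ``floor((L - k) / step) + 1`` k-mers.  Sequences shorter than k yield an
    empty list with a logged warning (neighbor sets contain partial records).
    """
    if k <= 0 or step <= 0:
        raise ContractError(f"k and step must be positive (k={k}, step={step})")
    L = seq.length
    if L < k:
        log.warning("sequence %s (%d bp) shorter than k=%d; skipped", seq.id, L, k)
        return []
    res = seq.residues
    return [
        PositionedKmer(seq.id, off, res[off : off + k])
        for off in range(0, L - k + 1, step)
    ]
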