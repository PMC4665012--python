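"""DUST-style hard-masking of low-complexity sequence.

Low-complexity tracts (homopolymer runs, short tandem repeats) hybridize
promiscuously and must not seed capture probes, so they are converted to N
before tiling.  The detector is the symmetric triplet-counting family: for
a subwindow containing n scored triplets with counts c_t over the 64
triplet types, the score is

    S = sum_t c_t * (c_t - 1) / 2  /  (n - 1)

and every subwindow (within a sliding window of ``window`` bases) whose
score exceeds ``score_threshold / 10`` is masked in full.  Triplets
containing N are excluded from scoring, which makes masking idempotent:
masked tracts contribute no triplets on a second pass, and scores elsewhere
can only drop.  Defaults (threshold 20, window 64) follow the de facto
standard parameterization of symmetric DUST.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .seqio import SequenceRecord, TargetEntry

__all__ = ["DustParams", "dust_mask", "window_score", "mask_positions"]

_TRIPLET_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class DustParams:
    score_threshold: int = 20
    window: int = 64

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ContractError("window must be >= 3")
        if self.score_threshold < 0:
            raise ContractError("score_threshold must be >= 0")


def _triplet_codes(residues: str) -> list[int]:
    """Per-position triplet codes; -1 where the triplet contains N."""
    codes: list[int] = []
    vals = [_TRIPLET_BASE.get(c, -1) for c in residues]
    for i in range(len(residues) - 2):
        a, b, c = vals[i], vals[i + 1], vals[i + 2]
        codes.append(-1 if a < 0 or b < 0 or c < 0 else (a << 4) | (b << 2) | c)
    return codes


def window_score(residues: str) -> float:
    """Triplet score of one subwindow (0 when fewer than 2 scored triplets)."""
    counts = [0] * 64
    n = 0
    total = 0
    for code in _triplet_codes(residues):
        if code < 0:
            continue
        total += counts[code]
        counts[code] += 1
        n += 1
    return total / (n - 1) if n >= 2 else 0.0


def mask_positions(residues: str, params: DustParams = DustParams()) -> set[int]:
    """0-based positions flagged as low-complexity.

    Scans every subwindow of up to ``window`` bases by extending leftward
    from each right edge with incremental triplet counts (O(L x window)),
    masking subwindows whose score exceeds ``score_threshold / 10``.
    """
    codes = _triplet_codes(residues)
    T = len(codes)
    limit = params.score_threshold / 10.0
    wtrip = params.window - 2  # triplets per base window
    masked: set[int] = set()
    counts = [0] * 64
    for j in range(T):
        # reset and extend the subwindow [i, j] leftward from the right edge
        for c in range(64):
            counts[c] = 0
        total = 0
        n = 0
        for i in range(j, max(-1, j - wtrip), -1):
            code = codes[i]
            if code >= 0:
                total += counts[code]
                counts[code] += 1
                n += 1
            if n >= 2 and total / (n - 1) > limit:
                masked.update(range(i, j + 3))
    return masked


def dust_mask(
    seq: SequenceRecord | TargetEntry, params: DustParams = DustParams()
) -> SequenceRecord | TargetEntry:
    """Return a copy of ``seq`` with low-complexity positions set to N.

    Length is preserved; unmasked positions are untouched; applying the
    mask twice equals applying it once.
    """
    residues = seq.residues
    masked = mask_positions(residues, params)
    if not masked:
        return seq
    out = "".join("N" if i in masked else c for i, c in enumerate(residues))
    if isinstance(seq, TargetEntry):
        return TargetEntry(
            source_id=seq.source_id,
            residues=out,
            provenance=seq.provenance,
            span=seq.span,
            description=seq.description,
        )
    return SequenceRecord(id=seq.id, residues=out, description=seq.description)
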