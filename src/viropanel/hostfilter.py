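"""Host-genome screening of panel entries.

Entries matching the host are removed in two independent ways: by blocked
taxonomic label (endogenous-retrovirus annotations and the like, plain
case-insensitive substring match on the description) and by sequence
similarity to a host genome at the probe level — each entry is scanned in
sliding windows of the probe size and a window "hits" when its best glocal
identity anywhere in the host (either strand) reaches the threshold.
The default drops whole entries with any hit window (conservative against
host sequence on the panel); mask mode hard-masks only the hit windows.

Scanning uses the same exact glocal engine as clustering; the cost is
O(window x host length) per window, which is intended for the panel-design
scale of this package rather than whole-chromosome screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align import glocal_identity
from .cluster import _EPS
from .errors import ContractError
from .seqio import SequenceRecord, TargetEntry

__all__ = ["FilterMode", "HostFilterParams", "filter_by_label", "filter_by_host_similarity"]


class FilterMode(str, Enum):
    DROP_ENTRY = "drop_entry"
    MASK_WINDOW = "mask_window"


@dataclass(frozen=True)
class HostFilterParams:
    identity_threshold: float = 0.75
    window: int = 100
    mode: FilterMode = FilterMode.DROP_ENTRY

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ContractError("identity_threshold must be in (0, 1]")
        if self.window < 1:
            raise ContractError("window must be >= 1")


def filter_by_label(
    entries: list[TargetEntry], blocked_terms: list[str]
) -> tuple[list[TargetEntry], list[TargetEntry]]:
    """Partition entries by blocked description terms (case-insensitive)."""
    terms = [t.lower() for t in blocked_terms]
    kept: list[TargetEntry] = []
    removed: list[TargetEntry] = []
    for e in entries:
        desc = e.description.lower()
        (removed if any(t in desc for t in terms) else kept).append(e)
    return kept, removed


def _window_starts(length: int, window: int) -> list[int]:
    if length <= window:
        return [0]
    step = max(1, window // 2)
    starts = list(range(0, length - window + 1, step))
    if starts[-1] != length - window:
        starts.append(length - window)  # right-anchor so the tail is screened
    return starts


def hit_windows(
    entry: TargetEntry, host: SequenceRecord, params: HostFilterParams
) -> list[tuple[int, int]]:
    """Windows of ``entry`` whose best host identity reaches the threshold."""
    if host.length == 0:
        raise ContractError("host sequence must be non-empty")
    w = params.window
    hits: list[tuple[int, int]] = []
    for s in _window_starts(entry.length, w):
        e = min(entry.length, s + w)
        piece = entry.residues[s:e]
        if set(piece) == {"N"}:
            continue
        ident, _ = glocal_identity(piece, host.residues, rc_aware=True)
        if ident >= params.identity_threshold - _EPS:
            hits.append((s, e))
    return hits


def filter_by_host_similarity(
    entries: list[TargetEntry],
    host: SequenceRecord,
    params: HostFilterParams = HostFilterParams(),
) -> tuple[list[TargetEntry], list[TargetEntry]]:
    """Screen entries against a host genome at the probe-window level.

    ``drop_entry`` mode: entries with at least one hit window go to the
    removed list.  ``mask_window`` mode: hit windows are hard-masked to N
    in place of removal; the second list then holds the *original* entries
    that had hits (nothing is dropped).  Both modes agree on which windows
    hit.
    """
    kept: list[TargetEntry] = []
    flagged: list[TargetEntry] = []
    for entry in entries:
        hits = hit_windows(entry, host, params)
        if not hits:
            kept.append(entry)
            continue
        if params.mode is FilterMode.DROP_ENTRY:
            flagged.append(entry)
        else:
            res = list(entry.residues)
            for s, e in hits:
                res[s:e] = "N" * (e - s)
            kept.append(
                TargetEntry(
                    source_id=entry.source_id,
                    residues="".join(res),
                    provenance=entry.provenance,
                    span=entry.span,
                    description=entry.description,
                )
            )
            flagged.append(entry)
    return kept, flagged
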