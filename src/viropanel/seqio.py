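"""Sequence, interval and panel-entry types, plus FASTA/BED input-output.

Nucleotide sequences are normalized on ingest to the uppercase alphabet
``A/C/G/T/N``; any other IUPAC ambiguity code becomes ``N`` (real viral
records contain R/Y/S/W/... codes, and probes cannot be synthesized against
them anyway).  Coordinates are 0-based half-open everywhere in memory; the
only 1-based inclusive rendering is the ``{SQ a-b}`` excised-span dialect in
FASTA headers of neighbor-derived panel entries, e.g.::

    >gi|1249624|emb|A28090.1| HPV42 [partial] genomic sequence {SQ 2444-2644}

which names the source header followed by the excised span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ContractError, FastaParseError

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "Provenance",
    "TargetEntry",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "render_subseq_header",
    "parse_subseq_header",
    "normalize_residues",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uppercase, then map every letter outside ACGT to N; non-letters are rejected
_NORMALIZE = {}
for _c in range(256):
    ch = chr(_c)
    up = ch.upper()
    if up in "ACGTN":
        _NORMALIZE[_c] = up
    elif ch.isalpha():
        _NORMALIZE[_c] = "N"
_ALLOWED = {chr(c) for c in range(256) if chr(c).isalpha()}


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase ``raw`` and collapse non-ACGT letters to ``N``.

    Raises :class:`FastaParseError` on non-alphabetic characters (gaps,
    digits, stray punctuation) so silent corruption cannot pass through.
    """
    bad = set(raw) - _ALLOWED
    if bad:
        raise FastaParseError(
            f"{context}: invalid residue character(s) {sorted(bad)!r}"
        )
    return raw.translate(_NORMALIZE)


def revcomp(residues: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence.

    ``id`` is the first whitespace-delimited header token; ``description``
    is the full header text (including the id), matching common FASTA
    conventions so that excised-span headers can be rebuilt verbatim.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ContractError(f"sequence id must be a non-empty token: {self.id!r}")
        if not self.description:
            self.description = self.id

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        if not (0 <= start < end <= self.length):
            raise ContractError(
                f"slice [{start},{end}) out of bounds for {self.id} (length {self.length})"
            )
        return self.residues[start:end]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based span ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ContractError(
                f"invalid interval [{self.start},{self.end}) on {self.seq_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class Provenance(str, Enum):
    """Where a panel entry came from."""

    PARENT_TILED = "parent_tiled"
    NEIGHBOR_SUBSEQ = "neighbor_subseq"
    LONG_CLUSTER_CENTROID = "long_cluster_centroid"
    EXTERNAL_PROBE = "external_probe"


@dataclass
class TargetEntry:
    """A member of the capture panel.

    When ``span`` is present the entry is an excised sub-sequence and
    ``residues`` must equal the source slice exactly; when absent the entry
    is a full source sequence.
    """

    source_id: str
    residues: str
    provenance: Provenance
    span: GenomicInterval | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ContractError("panel entry must contain at least one residue")
        if self.span is not None and self.span.length != len(self.residues):
            raise ContractError(
                f"span length {self.span.length} != residue length "
                f"{len(self.residues)} for {self.source_id}"
            )
        if not self.description:
            self.description = self.source_id

    @property
    def entry_id(self) -> str:
        if self.span is None:
            return self.source_id
        return f"{self.source_id}:{self.span.start}-{self.span.end}"

    @property
    def length(self) -> int:
        return len(self.residues)

    def header(self) -> str:
        """FASTA header for this entry (``{SQ}`` dialect when excised)."""
        if self.span is None:
            return self.description
        return render_subseq_header(self)


_SQ_RE = re.compile(r"\s*\{SQ\s+(\d+)-(\d+)\}\s*$")


def render_subseq_header(entry: TargetEntry) -> str:
    """Render the excised-span header: source description + ``{SQ a-b}``.

    Coordinates in the header are 1-based inclusive, so internal
    ``[2443, 2644)`` renders as ``{SQ 2444-2644}``.
    """
    if entry.span is None:
        raise ContractError("render_subseq_header requires an excised span")
    span = entry.span
    return f"{entry.description} {{SQ {span.start + 1}-{span.end}}}"


def parse_subseq_header(header: str) -> tuple[str, GenomicInterval | None]:
    """Parse a header, splitting off a trailing ``{SQ a-b}`` span if present.

    Returns ``(description, interval-or-None)`` with the interval converted
    back to 0-based half-open coordinates on the header's first token.
    """
    m = _SQ_RE.search(header)
    if m is None:
        return header.strip(), None
    a, b = int(m.group(1)), int(m.group(2))
    if a < 1 or a > b:
        raise FastaParseError(f"invalid {{SQ {a}-{b}}} span in header: {header!r}")
    desc = header[: m.start()].strip()
    seq_id = desc.split()[0] if desc else ""
    if not seq_id:
        raise FastaParseError(f"{{SQ}} header has no description: {header!r}")
    return desc, GenomicInterval(seq_id, a - 1, b)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records in file order.

    Record ids are the first whitespace-delimited header token; residues are
    normalized to uppercase A/C/G/T/N.  Malformed headers and empty
    sequences raise :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(
                f"{path}:{header_line}: record {header.split()[0]!r} has an empty sequence"
            )
        records.append(
            SequenceRecord(id=header.split()[0], residues=residues, description=header)
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(
                    normalize_residues(line.strip(), context=f"{path}:{lineno}")
                )
        _flush()
    return records


def write_fasta(
    records: Iterable[SequenceRecord | TargetEntry],
    path: str | Path,
    *,
    width: int = 60,
) -> None:
    """Write records (or panel entries with ``{SQ}`` headers) at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.header() if isinstance(rec, TargetEntry) else rec.description
            fh.write(f">{head}\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 3-column BED (0-based half-open, tab-separated)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")
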