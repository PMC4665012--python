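"""Seeded synthetic fixtures with known ground truth.

Two generators drive the whole test surface:

* strain clouds — neighbors derived from a parent genome by i.i.d.
  substitutions and indels plus embedded novel segments, with the novel
  segment locations returned as truth intervals in neighbor coordinates;
* capture read sets — paired pre/post alignment sets over a reference in
  which the viral read fraction is inflated post-capture by a controlled
  enrichment factor.

The mutation model is uniform i.i.d. (no transition/transversion bias,
no rate heterogeneity) — adequate for exercising identity-threshold
behavior, and documented as a simplification.  Read-set composition
(viral/total counts) is deterministic given the profile: the enrichment
factor is the controlled condition, so only read placement, orientation
and quality are drawn at random.  Everything is reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Orientation
from .capture import AlignmentRecord
from .errors import ContractError
from .seqio import GenomicInterval, SequenceRecord

__all__ = [
    "MutationSpec",
    "EnrichmentProfile",
    "SimulatedReadSets",
    "simulate_parent",
    "simulate_neighbor",
    "simulate_alignments",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationSpec:
    """Divergence model for one simulated neighbor."""

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_length: float = 3.0  # geometric mean length, bp
    novel_inserts: tuple[tuple[int, int], ...] = ()  # (parent position, length)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ContractError(f"{name} must be in [0, 1): {r}")
        if self.indel_length < 1.0:
            raise ContractError("indel_length must be >= 1")
        positions = [p for p, _ in self.novel_inserts]
        if len(set(positions)) != len(positions):
            raise ContractError("novel inserts must not overlap")
        for p, ln in self.novel_inserts:
            if ln < 1:
                raise ContractError("novel insert length must be >= 1")
            if p < 0:
                raise ContractError("novel insert position must be >= 0")


def simulate_parent(
    length: int, gc: float = 0.5, seed: int = 0, seq_id: str = "parent"
) -> SequenceRecord:
    """A random parent genome with the requested GC content."""
    if length < 1:
        raise ContractError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ContractError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_gc = rng.random(length) < gc
    pick = rng.integers(0, 2, size=length)
    # G/C for gc draws, A/T otherwise
    codes = np.where(is_gc, 1 + pick, 3 * pick)  # C=1,G=2 / A=0,T=3
    residues = _BASES[codes].tobytes().decode("ascii")
    return SequenceRecord(id=seq_id, residues=residues, description=f"{seq_id} simulated")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, residues: str, rate: float) -> str:
    """Vectorized i.i.d. substitution to a uniformly chosen different base."""
    if rate <= 0.0:
        return residues
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(arr.shape, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    hit = (rng.random(arr.shape[0]) < rate) & (code < 4)
    shift = rng.integers(1, 4, size=arr.shape[0])
    newcode = (code + shift) % 4
    arr[hit] = _BASES[newcode[hit]]
    return arr.tobytes().decode("ascii")


def simulate_neighbor(
    parent: SequenceRecord, spec: MutationSpec
) -> tuple[SequenceRecord, list[GenomicInterval]]:
    """Mutate ``parent`` into a neighbor; truth lists novel-insert spans.

    Substitutions and indels are applied uniformly along the genome; novel
    inserts are placed at their parent positions and their realized spans
    returned in neighbor coordinates.  With all rates zero and no inserts,
    the neighbor equals the parent and the truth is empty.
    """
    for p, _ in spec.novel_inserts:
        if p > parent.length:
            raise ContractError(f"novel insert position {p} beyond parent length")
    rng = np.random.default_rng(spec.seed)
    nb_id = f"{parent.id}_nb{spec.seed}"
    inserts = dict(spec.novel_inserts)
    truth: list[GenomicInterval] = []

    if spec.indel_rate == 0.0:
        body = _substitute(rng, parent.residues, spec.substitution_rate)
        if not inserts:
            return SequenceRecord(nb_id, body, f"{nb_id} simulated neighbor"), truth
        pieces: list[str] = []
        cursor = 0
        out_len = 0
        for pos in sorted(inserts):
            pieces.append(body[cursor:pos])
            out_len += pos - cursor
            novel = _random_bases(rng, inserts[pos])
            truth.append(GenomicInterval(nb_id, out_len, out_len + len(novel)))
            pieces.append(novel)
            out_len += len(novel)
            cursor = pos
        pieces.append(body[cursor:])
        return (
            SequenceRecord(nb_id, "".join(pieces), f"{nb_id} simulated neighbor"),
            truth,
        )

    # general path: walk the parent base by base
    out: list[str] = []
    out_len = 0
    i = 0
    L = parent.length
    res = parent.residues
    sub_rate, indel_rate = spec.substitution_rate, spec.indel_rate
    p_geom = 1.0 / spec.indel_length
    while i <= L:
        if i in inserts:
            novel = _random_bases(rng, inserts[i])
            truth.append(GenomicInterval(nb_id, out_len, out_len + len(novel)))
            out.append(novel)
            out_len += len(novel)
        if i == L:
            break
        if rng.random() < indel_rate:
            length = int(rng.geometric(p_geom))
            if rng.random() < 0.5:  # deletion: skip parent bases
                i += length
                continue
            ins = _random_bases(rng, length)
            out.append(ins)
            out_len += length
        base = res[i]
        if base in "ACGT" and rng.random() < sub_rate:
            others = "ACGT".replace(base, "")
            base = others[rng.integers(0, 3)]
        out.append(base)
        out_len += 1
        i += 1
    return SequenceRecord(nb_id, "".join(out), f"{nb_id} simulated neighbor"), truth


@dataclass(frozen=True)
class EnrichmentProfile:
    """Read-set composition before and after capture."""

    viral_fraction: float = 1e-4  # precapture fraction of reads that are viral
    enrichment: float = 1.0  # fold inflation of the viral fraction post-capture

    def __post_init__(self) -> None:
        if not (0.0 <= self.viral_fraction <= 1.0):
            raise ContractError("viral_fraction must be in [0, 1]")
        if self.enrichment < 0.0:
            raise ContractError("enrichment must be >= 0")


@dataclass
class SimulatedReadSets:
    """Paired pre/post-capture read sets over one reference.

    Alignment lists hold the viral (on-reference) reads only; the totals
    include the off-target remainder needed for percent-viral-read
    denominators.
    """

    pre_alignments: list[AlignmentRecord]
    post_alignments: list[AlignmentRecord]
    pre_total: int
    post_total: int

    @property
    def pre_viral(self) -> int:
        return len(self.pre_alignments)

    @property
    def post_viral(self) -> int:
        return len(self.post_alignments)


def simulate_alignments(
    ref_length: int,
    n_reads: int,
    read_length: int = 100,
    profile: EnrichmentProfile = EnrichmentProfile(),
    seed: int = 0,
    ref_id: str = "ref",
) -> SimulatedReadSets:
    """Simulate pre/post-capture read sets with a controlled enrichment.

    Viral counts are the rounded expected counts under the profile
    (composition is the condition under study, not a noise source); read
    start positions are uniform over the reference, orientation is a fair
    coin and mapping quality uniform in [20, 60].
    """
    if n_reads < 0:
        raise ContractError("n_reads must be >= 0")
    if ref_length < read_length:
        raise ContractError("ref_length must be >= read_length")
    rng = np.random.default_rng(seed)

    def _arm(tag: str, fraction: float) -> list[AlignmentRecord]:
        n_viral = int(round(n_reads * min(fraction, 1.0)))
        starts = rng.integers(0, ref_length - read_length + 1, size=n_viral)
        strands = rng.integers(0, 2, size=n_viral)
        quals = rng.integers(20, 61, size=n_viral)
        return [
            AlignmentRecord(
                read_id=f"{tag}_{i}",
                ref_id=ref_id,
                start=int(s),
                end=int(s) + read_length,
                orientation=Orientation.REVERSE if st else Orientation.FORWARD,
                quality=int(q),
            )
            for i, (s, st, q) in enumerate(zip(starts, strands, quals))
        ]

    pre = _arm("pre", profile.viral_fraction) if n_reads else []
    post = (
        _arm("post", profile.viral_fraction * profile.enrichment) if n_reads else []
    )
    return SimulatedReadSets(
        pre_alignments=pre,
        post_alignments=post,
        pre_total=n_reads,
        post_total=n_reads,
    )
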