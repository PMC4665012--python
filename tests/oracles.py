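"""Independent brute-force oracles used to check the fast implementations.

These are written for clarity, not speed: plain Python loops, tuple
lexicographic comparison, per-position boolean arrays.  They implement the
same *definitions* as the package (glocal identity of the canonical
score/matches/columns-optimal affine alignment; interval union; triplet
scores) through entirely separate code paths.
"""

from __future__ import annotations

from collections import Counter

NEG = (-(10**9), 0, 0)


def _cell_max(*cands):
    best = cands[0]
    for c in cands[1:]:
        if c > best:
            best = c
    return best


def glocal_oracle(
    q: str,
    t: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = 2,
    gap_extend: int = 1,
):
    """Full Gotoh glocal DP carrying (score, matches, -columns) tuples.

    ``q`` aligns end-to-end against a free-ended placement in ``t``; a gap
    of length g costs gap_open + g*gap_extend.  N (or any non-ACGT symbol)
    never matches.  Returns (score, matches, columns) of the canonical
    optimum.
    """
    m, n = len(q), len(t)
    open_cost = gap_open + gap_extend

    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in q (consumes t)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in t (consumes q)

    for j in range(n + 1):
        H[0][j] = (0, 0, 0)  # leading t bases are free, not columns
    for i in range(1, m + 1):
        F[i][0] = (-(gap_open + gap_extend * i), 0, -i)
        H[i][0] = F[i][0]

    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            tj = t[j - 1]
            is_match = qi == tj and qi in "ACGT"
            d = H[i - 1][j - 1]
            diag = (
                d[0] + (match if is_match else mismatch),
                d[1] + (1 if is_match else 0),
                d[2] - 1,
            )
            e1 = E[i][j - 1]
            h1 = H[i][j - 1]
            E[i][j] = _cell_max(
                (e1[0] - gap_extend, e1[1], e1[2] - 1),
                (h1[0] - open_cost, h1[1], h1[2] - 1),
            )
            f1 = F[i - 1][j]
            h2 = H[i - 1][j]
            F[i][j] = _cell_max(
                (f1[0] - gap_extend, f1[1], f1[2] - 1),
                (h2[0] - open_cost, h2[1], h2[2] - 1),
            )
            H[i][j] = _cell_max(diag, E[i][j], F[i][j])

    best = _cell_max(*[H[m][j] for j in range(n + 1)])
    return best[0], best[1], -best[2]


def glocal_identity_oracle(q: str, t: str, **scoring) -> float:
    score, matches, columns = glocal_oracle(q, t, **scoring)
    return matches / columns if columns else 0.0


def revcomp_oracle(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(s))


def rc_aware_identity_oracle(a: str, b: str) -> float:
    """Best-of-both-strands glocal identity, shorter sequence as query."""
    if len(a) < len(b) or (len(a) == len(b) and a <= b):
        q, t = a, b
    else:
        q, t = b, a
    fwd = glocal_oracle(q, t)
    rev = glocal_oracle(q, revcomp_oracle(t))
    f = (fwd[0], fwd[1], -fwd[2])
    r = (rev[0], rev[1], -rev[2])
    best = r if r > f else f
    return best[1] / -best[2] if best[2] else 0.0


def best_window_identity_oracle(kmer: str, parent: str, rc_aware: bool = True) -> float:
    """Identity of the kmer's canonical glocal optimum over the whole parent."""
    fwd = glocal_oracle(kmer, parent)
    cands = [fwd]
    if rc_aware:
        cands.append(glocal_oracle(kmer, revcomp_oracle(parent)))
    best = _cell_max(*[(s, m, -c) for s, m, c in cands])
    return best[1] / -best[2] if best[2] else 0.0


def interval_union_oracle(intervals, length: int):
    """Per-position boolean-array union; returns sorted disjoint spans."""
    covered = [False] * length
    for s, e in intervals:
        for p in range(s, e):
            covered[p] = True
    spans = []
    p = 0
    while p < length:
        if covered[p]:
            s = p
            while p < length and covered[p]:
                p += 1
            spans.append((s, p))
        else:
            p += 1
    return spans


def triplet_score_oracle(window: str) -> float:
    """Triplet count score sum c(c-1)/2 / (n-1) via Counter."""
    triplets = [
        window[i : i + 3]
        for i in range(len(window) - 2)
        if set(window[i : i + 3]) <= set("ACGT")
    ]
    n = len(triplets)
    if n < 2:
        return 0.0
    counts = Counter(triplets)
    total = sum(c * (c - 1) // 2 for c in counts.values())
    return total / (n - 1)


def depth_oracle(alignments, length: int):
    """Per-position depth by direct increment."""
    depth = [0] * length
    for a in alignments:
        for p in range(a.start, a.end):
            depth[p] += 1
    return depth
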