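"""Numba kernels for affine-gap alignment and seeded k-mer scanning.

The dynamic programs carry a single int64 *key* per cell encoding the
lexicographic objective ``(score, matches, -columns)``:

    key = (score + SCORE_BIAS) * 2^39  +  matches * 2^19  +  (COL_MAX - columns)

Because every DP transition adds a fixed (score, matches, columns) increment,
the encoding is order-preserving under addition and the usual max-plus
recurrences select, among all alignments, the canonical one that maximizes
score, then matches, then minimizes alignment columns.  This makes the
reported identity (matches / columns) a deterministic function of the input
with no traceback required.

Field budget: 24 bits of biased score, 20 bits of matches, 19 bits of
columns — valid for combined sequence lengths below 2^19 bp, asserted by the
Python wrappers.

Gap model: a gap of length g costs ``gap_open + g * gap_extend``.  Residue
codes are A=0 C=1 G=2 T=3 N=4; N never matches anything, including N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SCORE_SHIFT = 39
MATCH_SHIFT = 19
SCORE_BIAS = 1 << 23
COL_MAX = (1 << 19) - 1
MATCH_MASK = (1 << 20) - 1
KEY_ZERO = (SCORE_BIAS << SCORE_SHIFT) + COL_MAX
NEG_KEY = -(1 << 60)
SEED_INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)

_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i


def encode_seq(residues: str) -> np.ndarray:
    """Map a residue string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def decode_key(key: int) -> tuple[int, int, int]:
    """Unpack a DP key into (score, matches, columns)."""
    score = (key >> SCORE_SHIFT) - SCORE_BIAS
    matches = (key >> MATCH_SHIFT) & MATCH_MASK
    columns = COL_MAX - (key & COL_MAX)
    return int(score), int(matches), int(columns)


@njit(cache=True)
def semiglobal_key(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Glocal DP key: q end-to-end against a free-ended placement in t.

    Row 0 is free (leading t bases are not alignment columns) and the answer
    is the lexicographic max over the last row (trailing t bases free).
    """
    m = q.shape[0]
    n = t.shape[0]
    S = np.int64(1) << SCORE_SHIFT
    M1 = np.int64(1) << MATCH_SHIFT
    match_d = match * S + M1 - 1
    mis_d = mismatch * S - 1
    open_d = -(gap_open + gap_extend) * S - 1
    ext_d = -gap_extend * S - 1

    hp = np.full(n + 1, KEY_ZERO, dtype=np.int64)  # row i-1
    hc = np.empty(n + 1, dtype=np.int64)  # row i
    f = np.full(n + 1, NEG_KEY, dtype=np.int64)  # vertical gap state

    for i in range(1, m + 1):
        f0 = f[0] + ext_d
        alt = hp[0] + open_d
        if alt > f0:
            f0 = alt
        f[0] = f0
        hc[0] = f0
        e = NEG_KEY
        diag_src = hp[0]
        qi = q[i - 1]
        for j in range(1, n + 1):
            fv = f[j] + ext_d
            alt = hp[j] + open_d
            if alt > fv:
                fv = alt
            f[j] = fv
            ev = e + ext_d
            alt = hc[j - 1] + open_d
            if alt > ev:
                ev = alt
            e = ev
            if qi == t[j - 1] and qi < 4:
                h = diag_src + match_d
            else:
                h = diag_src + mis_d
            if fv > h:
                h = fv
            if ev > h:
                h = ev
            diag_src = hp[j]
            hc[j] = h
        hp, hc = hc, hp

    best = hp[0]
    for j in range(1, n + 1):
        if hp[j] > best:
            best = hp[j]
    return best


@njit(cache=True)
def local_key(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Smith-Waterman key with the same lexicographic objective.

    Every cell may restart from the empty alignment; the answer is the best
    cell anywhere (the top-scoring HSP).
    """
    m = q.shape[0]
    n = t.shape[0]
    S = np.int64(1) << SCORE_SHIFT
    M1 = np.int64(1) << MATCH_SHIFT
    match_d = match * S + M1 - 1
    mis_d = mismatch * S - 1
    open_d = -(gap_open + gap_extend) * S - 1
    ext_d = -gap_extend * S - 1

    hp = np.full(n + 1, KEY_ZERO, dtype=np.int64)
    hc = np.empty(n + 1, dtype=np.int64)
    f = np.full(n + 1, NEG_KEY, dtype=np.int64)
    best = KEY_ZERO

    for i in range(1, m + 1):
        hc[0] = KEY_ZERO
        e = NEG_KEY
        diag_src = hp[0]
        qi = q[i - 1]
        for j in range(1, n + 1):
            fv = f[j] + ext_d
            alt = hp[j] + open_d
            if alt > fv:
                fv = alt
            f[j] = fv
            ev = e + ext_d
            alt = hc[j - 1] + open_d
            if alt > ev:
                ev = alt
            e = ev
            if qi == t[j - 1] and qi < 4:
                h = diag_src + match_d
            else:
                h = diag_src + mis_d
            if fv > h:
                h = fv
            if ev > h:
                h = ev
            if KEY_ZERO > h:
                h = KEY_ZERO
            diag_src = hp[j]
            hc[j] = h
            if h > best:
                best = h
        hp, hc = hc, hp
    return best


@njit(cache=True)
def seed_codes(codes, seed_len):  # pragma: no cover
    """2-bit pack every seed_len-mer; windows containing N get SEED_INVALID."""
    L = codes.shape[0]
    n = L - seed_len + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.empty(n, dtype=np.uint64)
    for i in range(n):
        c = np.uint64(0)
        ok = True
        for j in range(seed_len):
            b = codes[i + j]
            if b >= 4:
                ok = False
                break
            c = (c << np.uint64(2)) | np.uint64(b)
        out[i] = c if ok else SEED_INVALID
    return out


@njit(cache=True)
def scan_strand(
    neigh_codes,
    neigh_seed,
    k,
    step,
    seed_len,
    p_codes,
    p_seed_sorted,
    p_seed_pos,
    diag_gap,
    pad,
    min_hits,
    thr,
    match,
    mismatch,
    gap_open,
    gap_extend,
    skip,
    status,
    ident,
):  # pragma: no cover
    """Classify every k-mer of a neighbor against one parent strand.

    For each k-mer: gather exact-seed diagonals from the parent index,
    cluster them, and run the windowed glocal DP on clusters holding at
    least ``min_hits`` seeds, best-supported cluster first, stopping as soon
    as the identity threshold is reached.  Status codes: 0 undecided/
    divergent so far, 1 represented, 2 seed-buffer overflow (caller falls
    back to the exhaustive scan).  ``skip`` masks k-mers already decided.
    """
    Ln = neigh_codes.shape[0]
    n_kmers = (Ln - k) // step + 1
    Lp = p_codes.shape[0]
    cap = 4096
    buf = np.empty(cap, dtype=np.int64)
    eps = 1e-12

    for idx in range(n_kmers):
        if skip[idx]:
            continue
        g = idx * step
        nh = 0
        overflow = False
        for o in range(k - seed_len + 1):
            c = neigh_seed[g + o]
            if c == SEED_INVALID:
                continue
            lo = np.searchsorted(p_seed_sorted, c, side="left")
            hi = np.searchsorted(p_seed_sorted, c, side="right")
            for z in range(lo, hi):
                if nh >= cap:
                    overflow = True
                    break
                buf[nh] = p_seed_pos[z] - o
                nh += 1
            if overflow:
                break
        if overflow:
            status[idx] = 2
            continue
        if nh == 0:
            continue

        diags = np.sort(buf[:nh])
        # single-linkage clusters over sorted diagonals
        starts = np.empty(nh, dtype=np.int64)
        ends = np.empty(nh, dtype=np.int64)
        nclust = 0
        cs = 0
        for z in range(1, nh):
            if diags[z] - diags[z - 1] > diag_gap:
                starts[nclust] = cs
                ends[nclust] = z
                nclust += 1
                cs = z
        starts[nclust] = cs
        ends[nclust] = nh
        nclust += 1

        done = np.zeros(nclust, dtype=np.uint8)
        q = neigh_codes[g : g + k]
        best = ident[idx]
        while True:
            pick = -1
            pick_cnt = min_hits - 1
            for ci in range(nclust):
                if done[ci]:
                    continue
                cnt = ends[ci] - starts[ci]
                if cnt > pick_cnt:
                    pick = ci
                    pick_cnt = cnt
            if pick < 0:
                break
            done[pick] = 1
            w0 = diags[starts[pick]] - pad
            w1 = diags[ends[pick] - 1] + k + pad
            if w0 < 0:
                w0 = 0
            if w1 > Lp:
                w1 = Lp
            if w1 <= w0:
                continue
            key = semiglobal_key(
                q, p_codes[w0:w1], match, mismatch, gap_open, gap_extend
            )
            matches = (key >> MATCH_SHIFT) & MATCH_MASK
            cols = COL_MAX - (key & COL_MAX)
            iv = matches / cols if cols > 0 else 0.0
            if iv > best:
                best = iv
            if best >= thr - eps:
                status[idx] = 1
                break
        ident[idx] = best
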