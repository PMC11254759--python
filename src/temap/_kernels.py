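"""Numba-compiled dynamic-programming kernels.

Three small DP engines back the whole package:

* ``adapter_dp`` — unit-cost edit-distance of a short pattern against every
  end position of a read with a free start (cutadapt-style semantics).
* ``sw_local`` — affine-gap (Gotoh) local alignment with traceback.
* ``grna_dp`` — bounded semi-global alignment of a 20-nt protospacer to a
  PAM-anchored genomic window, minimising mismatches under a gap budget.

Sequences are passed as uint8 code arrays (A=0, C=1, G=2, T=3, other=4;
code 4 never matches anything, so Ns count as mismatches).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def adapter_dp(pat: np.ndarray, read: np.ndarray):
    """Free-start edit-distance DP.

    Returns (D, S): D[i, j] = minimum unit-cost edits aligning pat[:i] to
    read[s:j] over all starts s; S[i, j] = the start s achieving it.
    """
    m = pat.shape[0]
    n = read.shape[0]
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    S = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        D[0, j] = 0
        S[0, j] = j
    for i in range(1, m + 1):
        D[i, 0] = i
        S[i, 0] = 0
        pi = pat[i - 1]
        for j in range(1, n + 1):
            cost = 0 if (pi == read[j - 1] and pi < 4) else 1
            best = D[i - 1, j - 1] + cost
            src = S[i - 1, j - 1]
            alt = D[i - 1, j] + 1  # pattern base unmatched (deletion in read)
            if alt < best:
                best = alt
                src = S[i - 1, j]
            alt = D[i, j - 1] + 1  # extra read base (insertion)
            if alt < best:
                best = alt
                src = S[i, j - 1]
            D[i, j] = best
            S[i, j] = src
    return D, S


# sw_local op codes on the traceback path
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # consumes query only
OP_DEL = 3  # consumes ref only


@njit(cache=True)
def sw_local(q: np.ndarray, r: np.ndarray, match: int, mismatch: int,
             gap_open: int, gap_extend: int):
    """Gotoh local alignment with traceback.

    A gap of length L costs ``gap_open + L * gap_extend`` (both arguments
    negative). Returns (score, q_start, q_end, r_start, r_end, path) where
    path is an int8 array of per-column op codes in alignment order.
    """
    n = q.shape[0]
    m = r.shape[0]
    NEG = -(1 << 30)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    PH = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 E, 3 F
    PE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 opened from H
    PF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 0
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 0
            sub = match if (qi == r[j - 1] and qi < 4) else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    path = np.empty(n + m, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 -> H, 1 -> E, 2 -> F
    while i > 0 and j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    path[k] = OP_MATCH
                else:
                    path[k] = OP_MISMATCH
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            path[k] = OP_DEL
            k += 1
            if PE[i, j] == 1:
                state = 0
            j -= 1
        else:
            path[k] = OP_INS
            k += 1
            if PF[i, j] == 1:
                state = 0
            i -= 1
    return best, i, bi, j, bj, path[:k][::-1].copy()


@njit(cache=True)
def grna_dp(proto_rev: np.ndarray, window_rev: np.ndarray, max_gap: int):
    """Minimum mismatches aligning the full (reversed) protospacer to a
    prefix of the (reversed) PAM-anchored window with at most ``max_gap``
    total gap bases.

    Both inputs are reversed so that the PAM-proximal end is position 0 and
    the anchoring becomes a prefix condition. Returns
    (mismatches, gaps_used, window_consumed); mismatches is a large
    sentinel (>= 10**6) when no alignment exists within the gap budget.
    """
    m = proto_rev.shape[0]
    n = window_rev.shape[0]
    BIG = 1 << 20
    G = max_gap + 1
    D = np.full((m + 1, n + 1, G), BIG, dtype=np.int32)
    D[0, 0, 0] = 0
    for i in range(m + 1):
        for j in range(n + 1):
            for g in range(G):
                cur = D[i, j, g]
                if cur >= BIG:
                    continue
                if i < m and j < n:
                    cost = 0 if (proto_rev[i] == window_rev[j] and proto_rev[i] < 4) else 1
                    if cur + cost < D[i + 1, j + 1, g]:
                        D[i + 1, j + 1, g] = cur + cost
                if i < m and g + 1 < G:  # gap in genomic window (RNA bulge)
                    if cur < D[i + 1, j, g + 1]:
                        D[i + 1, j, g + 1] = cur
                if j < n and g + 1 < G:  # extra genomic base (DNA bulge)
                    if cur < D[i, j + 1, g + 1]:
                        D[i, j + 1, g + 1] = cur
    best_mm = BIG
    best_g = 0
    best_j = 0
    for j in range(n + 1):
        for g in range(G):
            mm = D[m, j, g]
            if mm < best_mm or (mm == best_mm and g < best_g):
                best_mm = mm
                best_g = g
                best_j = j
    return best_mm, best_g, best_j
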