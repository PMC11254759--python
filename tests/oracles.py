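"""Independent reference implementations used only to check temap.

These are deliberately written with different algorithms/libraries than
the package: edlib for adapter matching, an unvectorised textbook Gotoh
recursion for local alignment scores, all-pairs graph connectivity for
read clustering, and combinatorial gap-placement enumeration for the
protospacer similarity scan.
"""

from __future__ import annotations

import itertools
from typing import Optional

import edlib
import networkx as nx

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def adapter_oracle(
    read: str, pattern: str, min_overlap: int, rate: float, three_prime: bool
) -> Optional[tuple[int, int]]:
    """Best admissible (matched_pattern_length, errors) by edlib, ranking
    longer matches first, then fewer errors; None if nothing qualifies."""
    if not three_prime:
        read, pattern = read[::-1], pattern[::-1]
    m = len(pattern)
    candidates = []
    if m >= min_overlap:
        d = edlib.align(pattern, read, mode="HW")["editDistance"]
        if 0 <= d <= int(rate * m):
            candidates.append((m, d))
    rr = read[::-1]
    for i in range(min_overlap, m):
        rp = pattern[:i][::-1]
        d = edlib.align(rp, rr, mode="SHW")["editDistance"]
        if 0 <= d <= int(rate * i):
            candidates.append((i, d))
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[0], -c[1]))


def gotoh_local_score(
    q: str, r: str, match: int = 1, mismatch: int = -4,
    gap_open: int = -6, gap_extend: int = -1,
) -> int:
    """Best local alignment score; a gap of length L costs
    gap_open + L * gap_extend."""
    n, m = len(q), len(r)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            s = match if q[i - 1] == r[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def quality_trim_oracle(quals: list[int], cutoff: int) -> int:
    """Exhaustive minimisation over all cut points; returns the kept
    length (smallest cut index whose removed-tail sum is minimal and
    negative, else no trim)."""
    n = len(quals)
    best_sum, best_j = 0, n
    for j in range(n + 1):
        s = sum(q - cutoff for q in quals[j:])
        if s < best_sum or (s == best_sum and s < 0 and j < best_j):
            best_sum, best_j = s, j
    return best_j if best_sum < 0 else n


def _overlap_or_contained(a: str, b: str, min_overlap: int) -> bool:
    for bb in (b, rc(b)):
        if a in bb or bb in a:
            return True
        for L in range(min_overlap, min(len(a), len(bb)) + 1):
            if a[-L:] == bb[:L] or bb[-L:] == a[:L]:
                return True
    return False


def cluster_oracle(seqs: list[str], min_overlap: int) -> int:
    """All-pairs connectivity components (duplicates, containments and
    exact dovetail overlaps in any orientation collapse reads)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if seqs[i] == seqs[j] or seqs[i] == rc(seqs[j]):
                g.add_edge(i, j)
            elif _overlap_or_contained(seqs[i], seqs[j], min_overlap):
                g.add_edge(i, j)
    return nx.number_connected_components(g)


def _best_pam_alignment(
    proto: str, s: str, pam_n_index: int, max_bulge: int
) -> Optional[tuple[int, int, int]]:
    """Minimum (mismatches, gaps, consumed) aligning proto to a suffix of
    s ending at the PAM, enumerating every placement of <= max_bulge
    deletions in either sequence. Ties prefer fewer gaps, then smaller
    consumed length."""
    best = None
    for c in range(20 - max_bulge, 20 + max_bulge + 1):
        if pam_n_index - c < 0:
            continue
        window = s[pam_n_index - c : pam_n_index]
        for dw in range(0, max_bulge + 1):
            dp = dw - (c - 20)
            if dp < 0 or dw + dp > max_bulge:
                continue
            for wdel in itertools.combinations(range(c), dw):
                w2 = "".join(ch for k, ch in enumerate(window) if k not in wdel)
                for pdel in itertools.combinations(range(20), dp):
                    p2 = "".join(ch for k, ch in enumerate(proto) if k not in pdel)
                    mm = sum(x != y for x, y in zip(p2, w2))
                    cand = (mm, dw + dp, c)
                    if best is None or cand < best:
                        best = cand
    return best


def grna_oracle(
    seq: str, proto: str, max_mismatch: int, max_bulge: int
) -> set[tuple[str, int, int, int]]:
    """Qualifying (strand, pam_N_position_in_strand_coords, mismatches,
    gaps) for every NGG PAM in a sequence, both strands."""
    out = set()
    for strand, s in (("+", seq), ("-", rc(seq))):
        for p in range(len(s) - 2):
            if s[p + 1 : p + 3] != "GG":
                continue
            best = _best_pam_alignment(proto, s, p, max_bulge)
            if best is not None and best[0] <= max_mismatch:
                out.add((strand, p, best[0], best[1]))
    return out
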