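"""Error-tolerant pattern matching and small-scale alignment.

This module replaces the external trimmer/mapper steps of the wet-lab
workflow with in-package primitives:

* :func:`adapter_match` — cutadapt-style search for a short pattern in a
  read, allowing unit-cost edits up to ``floor(max_error_rate * matched
  pattern length)`` and terminal partial occurrences.
* :func:`quality_trim_3p` — BWA/cutadapt running-sum 3' quality trimming.
* :func:`align_local` — affine-gap (Gotoh) local alignment, both strands.
* :func:`map_read` — best placement of a read on a multi-sequence
  reference via exact k-mer seeding plus local-alignment extension.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from ._kernels import encode
from .io_utils import SeqRead, revcomp


class EndMode(Enum):
    """Which read end a pattern is anchored toward (cutadapt -g vs -a)."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


@dataclass(frozen=True)
class PatternMatch:
    read_span: tuple[int, int]
    pattern_span: tuple[int, int]
    errors: int
    end_mode: EndMode

    @property
    def matched_len(self) -> int:
        return self.pattern_span[1] - self.pattern_span[0]


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring; mapper-like defaults that make 20-nt exact
    anchors decisive. A gap of length L costs gap_open + L * gap_extend."""

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()

_OP_NAMES = ("match", "mismatch", "ins", "del")


@dataclass
class AlignmentResult:
    """A local alignment of a query against one reference sequence.

    ``strand == '-'`` means the reverse complement of the query aligns on
    the forward reference; query coordinates then refer to the
    reverse-complemented query.
    """

    ref_name: Optional[str]
    ref_start: int
    ref_end: int
    strand: str
    ops: list[tuple[str, int]]
    score: int
    edits: int
    query_start: int = 0
    query_end: int = 0
    query_len: int = 0

    def ref_consumed(self) -> int:
        return sum(n for op, n in self.ops if op in ("match", "mismatch", "del"))

    def query_consumed(self) -> int:
        return sum(n for op, n in self.ops if op in ("match", "mismatch", "ins"))


def _compress_path(path: np.ndarray) -> tuple[list[tuple[str, int]], int]:
    ops: list[tuple[str, int]] = []
    edits = 0
    for code in path:
        name = _OP_NAMES[code]
        if name != "match":
            edits += 1
        if ops and ops[-1][0] == name:
            ops[-1] = (name, ops[-1][1] + 1)
        else:
            ops.append((name, 1))
    return ops, edits


def adapter_match(
    read: str,
    pattern: str,
    min_overlap: int = 8,
    max_error_rate: float = 0.1,
    end_mode: EndMode = EndMode.THREE_PRIME,
) -> Optional[PatternMatch]:
    """Find the best occurrence of ``pattern`` in ``read``.

    Occurrences are either the full pattern anywhere in the read, or a
    terminal partial occurrence: for THREE_PRIME a pattern *prefix* at the
    read's 3' end, for FIVE_PRIME a pattern *suffix* at the 5' end.
    Allowed unit-cost edits are ``floor(max_error_rate * matched pattern
    length)``. Among admissible candidates the longest matched pattern
    length wins, then fewest errors, then proximity to the end named by
    ``end_mode``. Returns None when nothing qualifies.
    """
    if not (0 <= max_error_rate < 1):
        raise ValueError("max_error_rate must be in [0, 1)")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, m = len(read), len(pattern)
    if n == 0 or m == 0:
        return None
    flip = end_mode is EndMode.FIVE_PRIME
    r = read[::-1] if flip else read
    p = pattern[::-1] if flip else pattern
    D, S = _kernels.adapter_dp(encode(p), encode(r))
    candidates: list[tuple[int, int, int, int, int]] = []
    # full internal occurrences
    if m >= min_overlap:
        allowed = math.floor(max_error_rate * m)
        errs_row = D[m]
        for j in range(1, n + 1):
            e = int(errs_row[j])
            if e <= allowed:
                candidates.append((m, e, n - j, int(S[m, j]), j))
    # terminal partial occurrences (pattern runs off the 3' end of r)
    for i in range(min_overlap, m):
        allowed = math.floor(max_error_rate * i)
        e = int(D[i, n])
        if e <= allowed:
            candidates.append((i, e, 0, int(S[i, n]), n))
    if not candidates:
        return None
    mlen, errors, _, s, j = min(candidates, key=lambda c: (-c[0], c[1], c[2]))
    if flip:
        read_span = (n - j, n - s)
        pattern_span = (m - mlen, m)
    else:
        read_span = (s, j)
        pattern_span = (0, mlen)
    return PatternMatch(read_span, pattern_span, errors, end_mode)


def trim_by_match(read: SeqRead, match: PatternMatch, keep: str = "auto") -> SeqRead:
    """Return the read segment retained after removing a pattern match.

    ``keep='before'`` keeps the prefix in front of the match,
    ``keep='after'`` the suffix behind it; ``'auto'`` keeps the suffix for
    FIVE_PRIME matches and the prefix for THREE_PRIME matches.
    """
    s, e = match.read_span
    if not (0 <= s <= e <= len(read)):
        raise ValueError("match does not lie on the read")
    if keep == "auto":
        keep = "after" if match.end_mode is EndMode.FIVE_PRIME else "before"
    if keep == "before":
        return read.slice(0, s)
    if keep == "after":
        return read.slice(e, len(read))
    raise ValueError(f"keep must be 'before', 'after' or 'auto', got {keep!r}")


def quality_trim_3p(read: SeqRead, q_cutoff: int = 10) -> SeqRead:
    """Running-sum 3' quality trimming.

    Computes, for every cut point j, the partial sum of (quality - cutoff)
    over the removed tail read[j:]; the read is cut at the smallest j whose
    sum is minimal, and only if that minimum is negative.
    """
    best_sum = 0
    best_j = len(read)
    s = 0
    for j in range(len(read) - 1, -1, -1):
        s += read.qual[j] - q_cutoff
        if s <= best_sum:
            best_sum = s
            best_j = j
    if best_sum < 0:
        return read.slice(0, best_j)
    return read


def align_local(
    query: str,
    ref: str,
    scoring: Scoring = DEFAULT_SCORING,
    ref_name: Optional[str] = None,
    both_strands: bool = True,
) -> AlignmentResult:
    """Best local alignment of ``query`` against ``ref``.

    Both query orientations are tried when ``both_strands`` is set; ties
    favour the forward strand, then the smaller ref_start.
    """
    if not query or not ref:
        raise ValueError("align_local requires non-empty sequences")
    rcodes = encode(ref)
    results = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        score, qs, qe, rs, re_, path = _kernels.sw_local(
            encode(q), rcodes, scoring.match, scoring.mismatch,
            scoring.gap_open, scoring.gap_extend,
        )
        ops, edits = _compress_path(path)
        results.append(
            AlignmentResult(ref_name, int(rs), int(re_), strand, ops,
                            int(score), edits, int(qs), int(qe), len(q))
        )
    return min(results, key=lambda a: (-a.score, a.strand != "+", a.ref_start))


class GenomeIndex:
    """Sorted exact k-mer index over a set of reference sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 15):
        self.k = k
        self.names = list(sequences)
        self.seqs = dict(sequences)
        offsets = [0]
        vals_parts = []
        for name in self.names:
            codes = encode(self.seqs[name])
            n = len(codes)
            if n >= k:
                v = np.zeros(n - k + 1, dtype=np.uint64)
                bad = np.zeros(n - k + 1, dtype=bool)
                for t in range(k):
                    window = codes[t : n - k + 1 + t].astype(np.uint64)
                    v = (v << np.uint64(2)) | (window & np.uint64(3))
                    bad |= window >= 4
                v[bad] = np.iinfo(np.uint64).max
                vals_parts.append(v)
            else:
                vals_parts.append(np.empty(0, dtype=np.uint64))
            offsets.append(offsets[-1] + n)
        self.offsets = np.array(offsets, dtype=np.int64)
        if vals_parts:
            all_vals = np.concatenate(
                [np.pad(v, (0, 0)) for v in vals_parts]
            )
            pos_parts = [
                np.arange(len(v), dtype=np.int64) + self.offsets[i]
                for i, v in enumerate(vals_parts)
            ]
            all_pos = np.concatenate(pos_parts)
        else:
            all_vals = np.empty(0, dtype=np.uint64)
            all_pos = np.empty(0, dtype=np.int64)
        order = np.argsort(all_vals, kind="stable")
        self.sorted_vals = all_vals[order]
        self.sorted_pos = all_pos[order]
        self.total_len = int(self.offsets[-1])

    def lookup(self, kmer_val: int, cap: int = 64) -> np.ndarray:
        lo = int(np.searchsorted(self.sorted_vals, np.uint64(kmer_val), side="left"))
        hi = int(np.searchsorted(self.sorted_vals, np.uint64(kmer_val), side="right"))
        if hi - lo > cap:
            return np.empty(0, dtype=np.int64)
        return self.sorted_pos[lo:hi]

    def ref_of(self, global_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return self.names[i], global_pos - int(self.offsets[i])

    def ref_bounds(self, global_pos: int) -> tuple[int, int]:
        i = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return int(self.offsets[i]), int(self.offsets[i + 1])


def build_index(sequences: dict[str, str], k: int = 15) -> GenomeIndex:
    return GenomeIndex(sequences, k=k)


def _kmer_value(codes: np.ndarray, start: int, k: int) -> Optional[int]:
    v = 0
    for t in range(k):
        c = int(codes[start + t])
        if c >= 4:
            return None
        v = (v << 2) | c
    return v


def _seed_candidates(index: GenomeIndex, codes: np.ndarray, stride: int) -> list[tuple[int, int]]:
    k = index.k
    n = len(codes)
    diags: list[int] = []
    for off in range(0, max(n - k, 0) + 1, stride):
        val = _kmer_value(codes, off, k)
        if val is None:
            continue
        for p in index.lookup(val):
            diags.append(int(p) - off)
    diags.sort()
    groups: list[tuple[int, int, int]] = []  # (votes, lo, hi)
    i = 0
    while i < len(diags):
        j = i
        while j + 1 < len(diags) and diags[j + 1] - diags[j] <= 12:
            j += 1
        groups.append((j - i + 1, diags[i], diags[j]))
        i = j + 1
    groups.sort(key=lambda g: (-g[0], g[1]))
    return [(lo, hi) for _, lo, hi in groups[:4]]


def _hamming_alignment(
    q: str, ref_seq: str, ref_start: int, ref_name: str, scoring: Scoring
) -> Optional[AlignmentResult]:
    """Gapless alignment of the full query at a fixed reference offset;
    None when the mismatch load suggests indels (caller falls back to DP)."""
    if ref_start < 0 or ref_start + len(q) > len(ref_seq):
        return None
    window = ref_seq[ref_start : ref_start + len(q)]
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    wa = np.frombuffer(window.encode(), dtype=np.uint8)
    mm = qa != wa
    n_mm = int(mm.sum())
    if n_mm > max(2, int(0.04 * len(q))):
        return None
    ops: list[tuple[str, int]] = []
    for is_mm in mm:
        name = "mismatch" if is_mm else "match"
        if ops and ops[-1][0] == name:
            ops[-1] = (name, ops[-1][1] + 1)
        else:
            ops.append((name, 1))
    score = (len(q) - n_mm) * scoring.match + n_mm * scoring.mismatch
    return AlignmentResult(ref_name, ref_start, ref_start + len(q), "+",
                           ops, score, n_mm, 0, len(q), len(q))


def map_read_status(
    query: str,
    genome,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_frac: float = 0.5,
    index: Optional[GenomeIndex] = None,
    exhaustive_fallback: bool = True,
) -> tuple[Optional[AlignmentResult], str]:
    """Map a read to a multi-sequence reference.

    Returns ``(alignment, status)`` with status one of ``mapped``,
    ``unmapped``, ``low_score`` or ``multimap``. Ambiguous best placements
    (equal score at distinct loci) return None with ``multimap``, and such
    reads are excluded from site calling.
    """
    sequences = genome.sequences if hasattr(genome, "sequences") else dict(genome)
    if index is None:
        index = _get_cached_index(genome, sequences)
    if not query:
        return None, "unmapped"
    stride = max(1, min(20, (len(query) - index.k) // 10 or 1))
    pad = 16
    candidates: list[AlignmentResult] = []
    seen_windows: set[tuple[str, int, int]] = set()
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        codes = encode(q)
        if len(codes) < index.k:
            continue
        for lo, hi in _seed_candidates(index, codes, stride):
            b0, b1 = index.ref_bounds(min(max(lo, 0), index.total_len - 1))
            name, _ = index.ref_of(b0)
            ref_seq = index.seqs[name]
            if lo == hi:
                # consistent diagonal: try a cheap gapless placement first
                aln = _hamming_alignment(q, ref_seq, lo - b0, name, scoring)
                if aln is not None:
                    aln.strand = strand
                    candidates.append(aln)
                    continue
            gstart = max(lo - pad, b0)
            gend = min(hi + len(q) + pad, b1)
            local0 = gstart - b0
            key = (name + strand, gstart, gend)
            if key in seen_windows or gend <= gstart:
                continue
            seen_windows.add(key)
            window = ref_seq[local0 : local0 + (gend - gstart)]
            aln = align_local(q, window, scoring, ref_name=name, both_strands=False)
            aln.strand = strand
            aln.ref_start += local0
            aln.ref_end += local0
            candidates.append(aln)
    if not candidates and exhaustive_fallback and index.total_len <= 200_000:
        # small references: exhaustive fallback
        for name, seq in sequences.items():
            if not seq:
                continue
            for strand in ("+", "-"):
                q = query if strand == "+" else revcomp(query)
                aln = align_local(q, seq, scoring, ref_name=name, both_strands=False)
                aln.strand = strand
                candidates.append(aln)
    if not candidates:
        return None, "unmapped"
    best_score = max(a.score for a in candidates)
    if best_score < min_score_frac * scoring.match * len(query):
        return None, "low_score"
    best = [a for a in candidates if a.score == best_score]
    distinct = {(a.ref_name, a.ref_start, a.strand) for a in best}
    if len(distinct) > 1:
        return None, "multimap"
    return best[0], "mapped"


def map_read(
    query: str,
    genome,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_frac: float = 0.5,
    index: Optional[GenomeIndex] = None,
) -> Optional[AlignmentResult]:
    res, _ = map_read_status(query, genome, scoring, min_score_frac, index)
    return res


def _get_cached_index(genome, sequences: dict[str, str]) -> GenomeIndex:
    cached = getattr(genome, "_temap_index", None)
    if cached is not None:
        return cached
    index = GenomeIndex(sequences)
    try:
        genome._temap_index = index
    except (AttributeError, TypeError):
        pass
    return index


_CIGAR_CODE = {"match": "=", "mismatch": "X", "ins": "I", "del": "D"}


def render_sam_like(aln: AlignmentResult, query_id: str = "query") -> str:
    """Debug rendering of an alignment as a SAM-like text line."""
    cig = "".join(f"{n}{_CIGAR_CODE[op]}" for op, n in aln.ops)
    flag = 16 if aln.strand == "-" else 0
    return "\t".join(
        [query_id, str(flag), str(aln.ref_name), str(aln.ref_start + 1),
         "255", cig, f"AS:i:{aln.score}", f"NM:i:{aln.edits}"]
    )
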