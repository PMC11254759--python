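"""Amplicon-seq analysis of targeted-insertion junctions.

A junction read spans the boundary between the target-gene flank and the
inserted TE. Splitting anchors on the four 20-nt TE terminal sequences
(left/right end x forward/reverse-complement, cutadapt-style matching at
min_overlap 8, error rate 0.11); when no terminal anchor is found — the
delivered element may lack its terminal bases — a local-alignment
fallback against the full element recovers truncated-end junctions.

Downstream analyses:

* insertion-site offsets relative to the blunt cleavage coordinate, by
  aligning the genomic flank to the target window carrying the expected
  TSD at the cut;
* element intactness — does the junction-adjacent end of the aligned TE
  segment reach the element terminus;
* per-position junction variant profiles (reference / SNP /
  insertion-by-length / deletion-by-length) with forward and reverse
  element orientations merged into target-gene coordinates;
* a Pearson chi-square homogeneity comparison of per-position
  zero-polymorphism proportions between two profiles;
* a clustering lower bound on the number of distinct insertions
  (exact duplicates, containments, then exact overlaps >= min_overlap).

Junction-relative coordinates place the 3-nt TSD at positions 0..2; for
the left (5') junction the gene lies at negative positions and the
element at >= 3, mirrored for the right (3') junction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align_kernel import (
    AlignmentResult,
    EndMode,
    PatternMatch,
    Scoring,
    adapter_match,
    align_local,
)
from .core_model import TargetLocus, TEElement
from .io_utils import SeqRead, revcomp

SIDE_LEFT = "LEFT_5p"
SIDE_RIGHT = "RIGHT_3p"


@dataclass
class JunctionRead:
    """A read split at the TE/flank junction, normalized so the genomic
    flank reads in target-gene (+) orientation."""

    read_id: str
    side: str
    te_orientation: str  # forward | reverse
    te_segment: str
    flank_segment: str
    te_terminal_reached: bool
    insertion_coord: Optional[int] = None
    norm_seq: str = ""
    anchor_errors: int = 0
    # alignment of te_segment against the junction-oriented element
    te_align_start: int = 0
    te_align_end: int = 0
    te_oriented_len: int = 0

    @property
    def terminal_offset(self) -> int:
        """Distance of the junction-adjacent end of the TE alignment from
        the element terminus (0 = terminus reached = intact end)."""
        if self.side == SIDE_LEFT:
            return self.te_align_start
        return self.te_oriented_len - self.te_align_end


def _anchor_configs(te: TEElement, k: int) -> list[tuple[str, str, str, EndMode]]:
    left = te.left_anchor(k)
    right = te.right_anchor(k)
    return [
        (SIDE_LEFT, "forward", left, EndMode.THREE_PRIME),
        (SIDE_LEFT, "reverse", revcomp(right), EndMode.THREE_PRIME),
        (SIDE_RIGHT, "forward", right, EndMode.FIVE_PRIME),
        (SIDE_RIGHT, "reverse", revcomp(left), EndMode.FIVE_PRIME),
    ]


def split_junction_read(
    read: SeqRead | str,
    te: TEElement,
    min_te_anchor: int = 8,
    te_anchor_len: int = 20,
    max_error_rate: float = 0.11,
    min_flank: int = 1,
    scoring: Scoring = Scoring(),
) -> Optional[JunctionRead]:
    """Split a read into TE and genomic-flank segments, or None.

    Both the read and its reverse complement are searched against the four
    terminal anchors; among hits the fewest anchor errors win, ties going
    to the hit closest to a read end. Reads wholly inside the element (no
    flank) return None.
    """
    if isinstance(read, SeqRead):
        rid, seq = read.id, read.seq
    else:
        rid, seq = "read", read
    configs = _anchor_configs(te, te_anchor_len)
    best: Optional[tuple[int, int, str, str, str, PatternMatch]] = None
    for cand in (seq, revcomp(seq)):
        for side, orientation, pattern, mode in configs:
            m = adapter_match(cand, pattern, min_overlap=min_te_anchor,
                              max_error_rate=max_error_rate, end_mode=mode)
            if m is None:
                continue
            if side == SIDE_LEFT:
                flank_len = m.read_span[0]
            else:
                flank_len = len(cand) - m.read_span[1]
            if flank_len < min_flank:
                continue
            dist = min(m.read_span[0], len(cand) - m.read_span[1])
            key = (m.errors, dist)
            if best is None or key < (best[0], best[1]):
                best = (m.errors, dist, cand, side, orientation, m)
    if best is not None:
        errors, _, cand, side, orientation, m = best
        if side == SIDE_LEFT:
            te_segment = cand[m.read_span[0] :]
            flank_segment = cand[: m.read_span[0]]
        else:
            te_segment = cand[: m.read_span[1]]
            flank_segment = cand[m.read_span[1] :]
        jr = JunctionRead(rid, side, orientation, te_segment, flank_segment,
                          False, norm_seq=cand, anchor_errors=errors)
        _align_te_segment(jr, te, scoring)
        return jr
    return _split_by_alignment(rid, seq, te, te_anchor_len, min_flank, scoring)


def _split_by_alignment(
    rid: str, seq: str, te: TEElement, min_te_part: int, min_flank: int,
    scoring: Scoring,
) -> Optional[JunctionRead]:
    """Fallback for truncated element ends: locate the read segment that
    aligns inside the full element and require it to be terminal in the
    read with a genomic flank on the other side."""
    best = None
    for cand in (seq, revcomp(seq)):
        for orientation in ("forward", "reverse"):
            oriented = te.sequence if orientation == "forward" else revcomp(te.sequence)
            aln = align_local(cand, oriented, scoring, both_strands=False)
            span = aln.query_end - aln.query_start
            if span < min_te_part:
                continue
            # TE part at the 3' end of cand -> flank before it (left junction)
            if aln.query_end >= len(cand) - 2 and aln.query_start >= min_flank:
                entry = (aln.score, cand, SIDE_LEFT, orientation, aln)
            elif aln.query_start <= 2 and aln.query_end <= len(cand) - min_flank:
                entry = (aln.score, cand, SIDE_RIGHT, orientation, aln)
            else:
                continue
            if best is None or entry[0] > best[0]:
                best = entry
    if best is None:
        return None
    _, cand, side, orientation, aln = best
    if side == SIDE_LEFT:
        te_segment = cand[aln.query_start :]
        flank_segment = cand[: aln.query_start]
    else:
        te_segment = cand[: aln.query_end]
        flank_segment = cand[aln.query_end :]
    jr = JunctionRead(rid, side, orientation, te_segment, flank_segment,
                      False, norm_seq=cand, anchor_errors=aln.edits)
    jr.te_align_start = aln.ref_start
    jr.te_align_end = aln.ref_end
    jr.te_oriented_len = len(te.sequence)
    jr.te_terminal_reached = jr.terminal_offset == 0
    return jr


def _align_te_segment(jr: JunctionRead, te: TEElement, scoring: Scoring) -> None:
    oriented = te.sequence if jr.te_orientation == "forward" else revcomp(te.sequence)
    aln = align_local(jr.te_segment, oriented, scoring, both_strands=False)
    jr.te_align_start = aln.ref_start
    jr.te_align_end = aln.ref_end
    jr.te_oriented_len = len(oriented)
    jr.te_terminal_reached = jr.terminal_offset == 0


def resolve_junction_side(
    jr: JunctionRead, locus: TargetLocus, scoring: Scoring = Scoring()
) -> JunctionRead:
    """Resolve the mirror ambiguity of a split junction read.

    From the element alone, a (side, orientation) call is indistinguishable
    from its mirror (other side, other orientation) on the
    reverse-complemented read — the structures are identical and only the
    genomic flank tells them apart. Align the flank under both
    interpretations against the target window and flip the read in place
    when the mirror fits better."""
    tsd = "TTA" if jr.side == SIDE_LEFT else "TAA"
    mirror_side = SIDE_RIGHT if jr.side == SIDE_LEFT else SIDE_LEFT
    mirror_tsd = "TTA" if mirror_side == SIDE_LEFT else "TAA"
    if len(jr.flank_segment) == 0:
        return jr
    s_as_is = align_local(jr.flank_segment, _side_reference(locus, jr.side, tsd),
                          scoring, both_strands=False).score
    rc_flank = revcomp(jr.flank_segment)
    s_mirror = align_local(rc_flank, _side_reference(locus, mirror_side, mirror_tsd),
                           scoring, both_strands=False).score
    if s_mirror > s_as_is:
        L = jr.te_oriented_len
        jr.side = mirror_side
        jr.te_orientation = "reverse" if jr.te_orientation == "forward" else "forward"
        jr.flank_segment = rc_flank
        jr.te_segment = revcomp(jr.te_segment)
        jr.norm_seq = revcomp(jr.norm_seq)
        jr.te_align_start, jr.te_align_end = L - jr.te_align_end, L - jr.te_align_start
    return jr


def _side_reference(locus: TargetLocus, side: str, expected_tsd: str) -> str:
    cut = locus.cut_in_window
    if side == SIDE_LEFT:
        return locus.window_seq[:cut] + expected_tsd
    return expected_tsd + locus.window_seq[cut:]


def call_insertion_site(
    jr: JunctionRead,
    locus: TargetLocus,
    expected_tsd: Optional[str] = None,
    scoring: Scoring = Scoring(),
    min_align_frac: float = 0.5,
) -> Optional[int]:
    """Signed insertion-boundary offset from the cleavage coordinate.

    The genomic flank is aligned to the target window carrying the
    expected TSD at the cut; the junction-proximal aligned reference base
    (right-most for the left junction, left-most for the right junction)
    defines the boundary. 0 means insertion exactly at the cut with the
    TSD intact; deletions give negative (left) / positive (right)
    offsets. Returns None (read excluded) when the flank does not align.
    """
    if len(jr.flank_segment) < 10:
        return None
    tsd = expected_tsd or ("TTA" if jr.side == SIDE_LEFT else "TAA")
    ref = _side_reference(locus, jr.side, tsd)
    aln = align_local(jr.flank_segment, ref, scoring, both_strands=False)
    if aln.score < min_align_frac * scoring.match * len(jr.flank_segment):
        return None
    if jr.side == SIDE_LEFT:
        offset = aln.ref_end - len(ref)
    else:
        offset = aln.ref_start
    jr.insertion_coord = locus.cleavage_coord + offset
    return offset


@dataclass
class InsertionSiteHistogram:
    per_side: dict[str, Counter]
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"side": side, "offset": off, "n_reads": n}
            for side, counts in self.per_side.items()
            for off, n in sorted(counts.items())
        ]
        return pd.DataFrame(rows, columns=["side", "offset", "n_reads"])


def insertion_site_histogram(
    jrs: Iterable[JunctionRead], locus: TargetLocus, **kwargs
) -> InsertionSiteHistogram:
    hist = InsertionSiteHistogram({SIDE_LEFT: Counter(), SIDE_RIGHT: Counter()})
    for jr in jrs:
        off = call_insertion_site(jr, locus, **kwargs)
        if off is None:
            hist.n_excluded += 1
        else:
            hist.per_side[jr.side][off] += 1
    return hist


@dataclass
class IntactnessResult:
    """Distribution of junction-adjacent element-end offsets (0 = the
    alignment reaches the element terminus) and the intact fraction."""

    end_offsets: Counter
    fraction_intact: float
    n_used: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"terminal_offset": off, "n_reads": n}
            for off, n in sorted(self.end_offsets.items())
        ]
        return pd.DataFrame(rows, columns=["terminal_offset", "n_reads"])


def te_intactness(
    jrs: Iterable[JunctionRead], te: TEElement, min_anchor: int = 20
) -> IntactnessResult:
    """Element intactness over junction reads carrying >= ``min_anchor``
    nt of both flank and element sequence. Forward and reverse insertion
    orientations are merged (offsets are junction-relative)."""
    offsets: Counter = Counter()
    n_used = 0
    n_excluded = 0
    for jr in jrs:
        if len(jr.flank_segment) < min_anchor or len(jr.te_segment) < min_anchor:
            n_excluded += 1
            continue
        if jr.te_align_end <= jr.te_align_start:
            n_excluded += 1
            continue
        offsets[jr.terminal_offset] += 1
        n_used += 1
    frac = offsets.get(0, 0) / n_used if n_used else float("nan")
    return IntactnessResult(offsets, frac, n_used, n_excluded)


@dataclass
class JunctionVariantProfile:
    """Per-position junction variant tallies in junction-relative
    coordinates (TSD at 0..2; gene flank on its side of the junction)."""

    side: str
    positions: list[int]
    n_reads: np.ndarray
    n_ref: np.ndarray
    n_snp: np.ndarray
    n_ins: dict[int, np.ndarray]
    n_del: dict[int, np.ndarray]
    n_excluded: int = 0

    def zero_nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        return self.n_ref, self.n_reads - self.n_ref

    def to_frame(self) -> pd.DataFrame:
        data = {
            "position": self.positions,
            "n_reads": self.n_reads,
            "pct_ref": _pct(self.n_ref, self.n_reads),
            "pct_snp": _pct(self.n_snp, self.n_reads),
        }
        for L in sorted(self.n_ins):
            data[f"pct_ins{L}"] = _pct(self.n_ins[L], self.n_reads)
        for L in sorted(self.n_del):
            data[f"pct_del{L}"] = _pct(self.n_del[L], self.n_reads)
        return pd.DataFrame(data)


def _pct(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, 100.0 * num / np.maximum(den, 1), 0.0)


def _expected_side_reference(
    locus: TargetLocus, te: TEElement, side: str, orientation: str,
    flank_span: int, te_span: int,
) -> tuple[str, int]:
    """Expected junction sequence for one (side, orientation) group and
    the index of junction-relative position 0 (first TSD base)."""
    cut = locus.cut_in_window
    oriented = te.sequence if orientation == "forward" else revcomp(te.sequence)
    if side == SIDE_LEFT:
        ref = locus.window_seq[max(cut - flank_span, 0) : cut] + "TTA" + oriented[:te_span]
        zero_idx = min(flank_span, cut)
    else:
        ref = oriented[-te_span:] + "TAA" + locus.window_seq[cut : cut + flank_span]
        zero_idx = min(te_span, len(oriented))
    return ref, zero_idx


def junction_variant_profile(
    jrs: Sequence[JunctionRead],
    locus: TargetLocus,
    te: TEElement,
    side: str,
    flank_span: int = 30,
    te_span: int = 30,
    scoring: Scoring = Scoring(),
    min_align_frac: float = 0.3,
) -> JunctionVariantProfile:
    """Align each junction read of one side to its expected junction
    reference and tally a single called state per covered position:
    deletion (by run length, every deleted position counted), insertion
    (attached to the reference position immediately 5' in target-gene
    orientation), SNP, or reference-identical. Orientations are merged on
    the junction-relative axis."""
    npos = flank_span + 3 + te_span
    if side == SIDE_LEFT:
        positions = list(range(-flank_span, 3 + te_span))
    else:
        positions = list(range(-te_span, 3 + flank_span))
    n_reads = np.zeros(npos, dtype=np.int64)
    n_ref = np.zeros(npos, dtype=np.int64)
    n_snp = np.zeros(npos, dtype=np.int64)
    n_ins: dict[int, np.ndarray] = {}
    n_del: dict[int, np.ndarray] = {}
    n_excluded = 0
    pos_index = {p: i for i, p in enumerate(positions)}
    for orientation in ("forward", "reverse"):
        group = [jr for jr in jrs if jr.side == side and jr.te_orientation == orientation]
        if not group:
            continue
        ref, zero_idx = _expected_side_reference(
            locus, te, side, orientation, flank_span, te_span
        )
        for jr in group:
            aln = align_local(jr.norm_seq, ref, scoring, both_strands=False)
            if aln.score < min_align_frac * scoring.match * len(ref):
                n_excluded += 1
                continue
            states = _per_position_states(aln, len(ref))
            for idx, state in states.items():
                rel = idx - zero_idx
                i = pos_index.get(rel)
                if i is None:
                    continue
                n_reads[i] += 1
                kind, L = state
                if kind == "ref":
                    n_ref[i] += 1
                elif kind == "snp":
                    n_snp[i] += 1
                elif kind == "ins":
                    n_ins.setdefault(L, np.zeros(npos, dtype=np.int64))[i] += 1
                else:
                    n_del.setdefault(L, np.zeros(npos, dtype=np.int64))[i] += 1
    return JunctionVariantProfile(
        side, positions, n_reads, n_ref, n_snp, n_ins, n_del, n_excluded
    )


def _per_position_states(
    aln: AlignmentResult, ref_len: int
) -> dict[int, tuple[str, int]]:
    """One called state per reference position covered by the alignment.
    Non-reference states dominate: deletion > insertion > SNP > ref."""
    states: dict[int, tuple[str, int]] = {}
    r = aln.ref_start
    for op, L in aln.ops:
        if op == "match":
            for p in range(r, r + L):
                states.setdefault(p, ("ref", 0))
            r += L
        elif op == "mismatch":
            for p in range(r, r + L):
                prev = states.get(p)
                if prev is None or prev[0] == "ref":
                    states[p] = ("snp", 0)
            r += L
        elif op == "del":
            for p in range(r, r + L):
                states[p] = ("del", L)
            r += L
        else:  # ins
            p = r - 1
            if p >= 0:
                prev = states.get(p)
                if prev is None or prev[0] in ("ref", "snp"):
                    states[p] = ("ins", L)
    return states


def compare_polymorphism(
    profile_a: JunctionVariantProfile, profile_b: JunctionVariantProfile
) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test of per-position
    zero-polymorphism proportions between two junction profiles.

    Per covered position a 2x2 table (zero-polymorphism vs >= 1
    polymorphism, profile A vs B) contributes its Pearson statistic; the
    total is referred to a chi-square with df = number of positions with
    coverage in both profiles. Zero-coverage positions are excluded.
    """
    if profile_a.positions != profile_b.positions:
        raise ValueError("profiles cover different junction positions")
    za, nza = profile_a.zero_nonzero()
    zb, nzb = profile_b.zero_nonzero()
    chi2 = 0.0
    df = 0
    for i in range(len(profile_a.positions)):
        ra = za[i] + nza[i]
        rb = zb[i] + nzb[i]
        if ra == 0 or rb == 0:
            continue
        df += 1
        n = ra + rb
        col_z = za[i] + zb[i]
        col_nz = nza[i] + nzb[i]
        if col_z == 0 or col_nz == 0:
            continue
        num = n * (za[i] * nzb[i] - nza[i] * zb[i]) ** 2
        chi2 += num / (ra * rb * col_z * col_nz)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, p


def estimate_edit_spectrum(
    jrs: Sequence[JunctionRead],
    locus: TargetLocus,
    te: TEElement,
    max_del: int = 7,
    window: tuple[int, int] = (-4, 7),
) -> tuple[dict[str, float], int]:
    """Estimate the junction edit-class rates from variant profiles.

    Only terminal-intact junction reads are used — on reads delivering a
    truncated element the junction-adjacent reference is absent and edit
    states there are not interpretable. Deletion rates divide the
    per-position deletion-state counts by the run length (a del-k read
    contributes k positions); the SNP rate is read at the TSD base nearest
    the gene; the perfect rate is the complement. Returns (rates, n)."""
    used = [jr for jr in jrs if jr.te_terminal_reached]
    n = len(used)
    if n == 0:
        return {}, 0
    accum: dict[str, float] = {}
    for side in (SIDE_LEFT, SIDE_RIGHT):
        profile = junction_variant_profile(used, locus, te, side)
        idx = {pos: i for i, pos in enumerate(profile.positions)}
        win = [idx[x] for x in range(window[0], window[1]) if x in idx]
        for L in range(1, max_del + 1):
            if L in profile.n_del:
                accum[f"del{L}"] = accum.get(f"del{L}", 0.0) + profile.n_del[L][win].sum() / L
        if 1 in profile.n_ins:
            accum["ins1"] = accum.get("ins1", 0.0) + float(profile.n_ins[1][win].sum())
        snp_pos = idx[0 if side == SIDE_LEFT else 2]
        accum["snp1"] = accum.get("snp1", 0.0) + float(profile.n_snp[snp_pos])
    rates = {k: v / n for k, v in accum.items()}
    rates["perfect"] = 1.0 - sum(rates.values())
    return rates, n


# ---------------------------------------------------------------------------
# unique-insertion clustering


def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_unique_insertions(
    reads: Sequence[SeqRead] | Sequence[str],
    min_overlap: int = 20,
    k: int = 20,
) -> tuple[int, dict[str, int]]:
    """Lower bound on the number of distinct insertions.

    Stage 1 removes exact duplicates (including reverse-complement
    duplicates); stage 2 absorbs reads exactly contained in longer reads;
    stage 3 connects reads sharing an exact terminal overlap >=
    ``min_overlap``. Candidates are found by anchoring each read's
    terminal ``k``-mers (both orientations) in a k-mer position index of
    all reads, which pins the overlap length and makes every check a
    single string comparison; ``k`` is clamped to ``min_overlap`` so no
    admissible overlap is missed. PCR duplicates are indistinguishable in
    this library design, so the component count underestimates the true
    number of unique insertions.
    """
    k = min(k, min_overlap)
    items: list[tuple[str, str]] = []
    for i, r in enumerate(reads):
        if isinstance(r, SeqRead):
            items.append((r.id, r.seq))
        else:
            items.append((f"read{i}", r))
    uf = _UnionFind(len(items))
    by_canon: dict[str, int] = {}
    uniq: list[int] = []
    for i, (_, seq) in enumerate(items):
        key = _canonical(seq)
        if key in by_canon:
            uf.union(by_canon[key], i)
        else:
            by_canon[key] = i
            uniq.append(i)
    # k-mer position index over unique representatives (forward form)
    kmer_pos: dict[str, list[tuple[int, int]]] = {}
    for i in uniq:
        seq = items[i][1]
        for p in range(0, max(len(seq) - k, -1) + 1):
            kmer_pos.setdefault(seq[p : p + k], []).append((i, p))
    for j in uniq:
        seq = items[j][1]
        for orient in (seq, revcomp(seq)):
            if len(orient) < k:
                continue
            # prefix anchor: a-suffix == orient-prefix, or orient inside a
            for i, p in kmer_pos.get(orient[:k], ()):
                if i == j or uf.find(i) == uf.find(j):
                    continue
                a = items[i][1]
                tail = len(a) - p
                if tail >= len(orient):
                    if a[p : p + len(orient)] == orient:
                        uf.union(i, j)
                elif tail >= min_overlap and a[p:] == orient[:tail]:
                    uf.union(i, j)
            # suffix anchor: orient-suffix == a-prefix
            for i, p in kmer_pos.get(orient[-k:], ()):
                if i == j or uf.find(i) == uf.find(j):
                    continue
                a = items[i][1]
                overlap = p + k
                if overlap >= min_overlap and len(orient) >= overlap:
                    if orient[-overlap:] == a[:overlap]:
                        uf.union(i, j)
    roots: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for i, (rid, _) in enumerate(items):
        root = uf.find(i)
        cluster = roots.setdefault(root, len(roots))
        assignments[rid] = cluster
    return len(roots), assignments


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class JunctionAnalysis:
    junction_reads: list[JunctionRead]
    n_input: int
    n_no_anchor: int
    histogram: InsertionSiteHistogram
    intactness: IntactnessResult
    profiles: dict[str, JunctionVariantProfile]
    n_clusters: Optional[int] = None

    @property
    def side_counts(self) -> dict[str, int]:
        c: Counter = Counter()
        for jr in self.junction_reads:
            c[f"{jr.side}/{jr.te_orientation}"] += 1
        return dict(c)


def analyze_junctions(
    reads: Sequence[SeqRead],
    locus: TargetLocus,
    te: TEElement,
    min_te_anchor: int = 8,
    max_error_rate: float = 0.11,
    flank_span: int = 30,
    te_span: int = 30,
    cluster: bool = False,
    cluster_min_overlap: int = 20,
    cluster_k: int = 20,
) -> JunctionAnalysis:
    """End-to-end amplicon-junction analysis of a read set."""
    jrs: list[JunctionRead] = []
    n_no_anchor = 0
    for read in reads:
        jr = split_junction_read(
            read, te, min_te_anchor=min_te_anchor, max_error_rate=max_error_rate
        )
        if jr is None:
            n_no_anchor += 1
        else:
            jrs.append(resolve_junction_side(jr, locus))
    histogram = insertion_site_histogram(jrs, locus)
    intact = te_intactness(jrs, te)
    profiles = {
        side: junction_variant_profile(
            jrs, locus, te, side, flank_span=flank_span, te_span=te_span
        )
        for side in (SIDE_LEFT, SIDE_RIGHT)
    }
    n_clusters = None
    if cluster:
        covering = [
            SeqRead(jr.read_id + f"#{i}", jr.norm_seq)
            for i, jr in enumerate(jrs)
        ]
        n_clusters, _ = cluster_unique_insertions(
            covering, min_overlap=cluster_min_overlap, k=cluster_k
        )
    return JunctionAnalysis(
        jrs, len(reads), n_no_anchor, histogram, intact, profiles, n_clusters
    )
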