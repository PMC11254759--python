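"""Genome-wide TE insertion-site discovery from insertion-seq reads.

An insertion-seq read begins inside the element (from a TE-specific
primer), runs over the element terminus and into the genomic flank of
the insertion. The pipeline is:

1. 3' quality trimming (running-sum, Q10) and vector-adapter removal
   (``ATCACTAGTGAATTCGCGGCC``, min_overlap 10, error rate 0.1);
2. TE-prefix identification and removal from the 5' end (min_overlap 35,
   error rate 0.1); resulting flanks shorter than 30 nt are discarded;
3. donor filtering: flanks mapping to the donor construct are removed
   (reads reporting the element at its donor location);
4. genome mapping; the junction-adjacent base of each alignment is the
   insertion site (alignment start on +, alignment end on -; a
   ``naive_start`` flag reproduces the literal leftmost-base rule);
5. site counts summed over 10-nt non-overlapping bins, normalized to
   reads per million raw library reads (RPM);
6. bins >= 100 RPM called as free-transposition sites, with target-locus
   bins flagged and excluded from the free count;
7. replicate overlap on (ref, bin) sets, and a gRNA-similarity scan
   (<= 9 mismatches, <= 2 nt bulge, NGG PAM) to restrict sites to
   regions resembling the guide.

Read conservation (input = kept + dropped) is tracked per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernels
from ._kernels import encode
from .align_kernel import (
    EndMode,
    GenomeIndex,
    Scoring,
    adapter_match,
    map_read_status,
    quality_trim_3p,
    trim_by_match,
)
from .core_model import GenomeRef, TargetLocus
from .io_utils import SeqRead, revcomp

DEFAULT_ADAPTER = "ATCACTAGTGAATTCGCGGCC"
BIN_SIZE = 10
FREE_SITE_THRESHOLD_RPM = 100.0


@dataclass
class BinTrack:
    """Raw and RPM-normalized site counts over fixed non-overlapping bins.

    ``total_raw_reads`` is the pre-trimming library size — RPM values are
    normalized to the sequenced raw read count, not to the number of
    reads surviving the filters.
    """

    bin_size: int
    total_raw_reads: int
    raw: dict[tuple[str, int], int] = field(default_factory=dict)
    fwd: dict[tuple[str, int], int] = field(default_factory=dict)

    def rpm(self, key: tuple[str, int]) -> float:
        return self.raw[key] / self.total_raw_reads * 1e6

    @property
    def n_assigned(self) -> int:
        return sum(self.raw.values())

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for (ref, b), count in sorted(self.raw.items()):
                fh.write(
                    f"{ref}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}\t"
                    f"{self.rpm((ref, b)):.4f}\n"
                )


@dataclass(frozen=True)
class FreeSite:
    ref: str
    bin_start: int
    rpm: float
    is_target_site: bool
    orientation_counts: tuple[int, int]

    @property
    def bin_index(self) -> int:
        return self.bin_start // BIN_SIZE


@dataclass(frozen=True)
class OffTargetHit:
    """A protospacer-similar genomic window next to an NGG PAM.

    ``position`` is the window start in forward-genome coordinates;
    ``pam_position`` is the PAM 'N' index in scanned-strand coordinates
    (forward coordinates for +, reverse-complement coordinates for -)."""

    ref: str
    position: int
    strand: str
    mismatches: int
    bulge_nt: int
    pam_position: int = -1


def trim_vector_adapter(
    reads: Iterable[SeqRead],
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 10,
    max_error_rate: float = 0.1,
    q_cutoff: int = 10,
) -> list[SeqRead]:
    """Quality-trim the 3' end, then remove the 3' vector adapter and
    everything downstream of it. Reads are never dropped here."""
    out = []
    for read in reads:
        r = quality_trim_3p(read, q_cutoff)
        m = adapter_match(r.seq, adapter, min_overlap=min_overlap,
                          max_error_rate=max_error_rate,
                          end_mode=EndMode.THREE_PRIME)
        if m is not None:
            r = trim_by_match(r, m, keep="before")
        out.append(r)
    return out


def extract_te_flank(
    reads: Iterable[SeqRead],
    expected_te_prefix: str,
    min_overlap: int = 35,
    max_error_rate: float = 0.1,
    min_flank_len: int = 30,
) -> tuple[list[SeqRead], dict[str, int]]:
    """Keep only reads whose 5' end carries the expected TE prefix, trim
    the TE part, and discard flanks shorter than ``min_flank_len``."""
    kept = []
    counts = {"input": 0, "no_te_prefix": 0, "short_flank": 0, "kept": 0}
    for read in reads:
        counts["input"] += 1
        m = adapter_match(read.seq, expected_te_prefix, min_overlap=min_overlap,
                          max_error_rate=max_error_rate,
                          end_mode=EndMode.FIVE_PRIME)
        if m is None:
            counts["no_te_prefix"] += 1
            continue
        flank = trim_by_match(read, m, keep="after")
        if len(flank) < min_flank_len:
            counts["short_flank"] += 1
            continue
        counts["kept"] += 1
        kept.append(flank)
    return kept, counts


def filter_donor(
    flank_reads: Sequence[SeqRead],
    donor_ref: str,
    scoring: Scoring = Scoring(),
    min_score_frac: float = 0.5,
) -> tuple[list[SeqRead], int]:
    """Drop flank reads that map to the donor construct (the element at
    its donor location); return the rest plus the drop count."""
    donor = {"donor": donor_ref}
    index = GenomeIndex(donor)
    kept = []
    dropped = 0
    for read in flank_reads:
        aln, status = map_read_status(read.seq, donor, scoring, min_score_frac, index,
                                      exhaustive_fallback=False)
        if status in ("mapped", "multimap"):
            dropped += 1
        else:
            kept.append(read)
    return kept, dropped


def assign_sites(
    flank_reads: Sequence[SeqRead],
    genome: GenomeRef,
    scoring: Scoring = Scoring(),
    min_score_frac: float = 0.5,
    naive_start: bool = False,
) -> tuple[list[tuple[str, int, str]], dict[str, int]]:
    """Map each flank read and report its insertion site.

    The junction lies at the read's (trimmed) 5' end, so on the + strand
    the site is the alignment start and on the - strand the alignment end
    (junction-adjacent base). ``naive_start`` reports the leftmost
    aligned base regardless of strand. Unmapped, low-score and
    multimapping reads are counted and dropped.
    """
    counts = {"input": len(flank_reads), "mapped": 0, "unmapped": 0,
              "low_score": 0, "multimap": 0}
    sites: list[tuple[str, int, str]] = []
    for read in flank_reads:
        aln, status = map_read_status(read.seq, genome, scoring, min_score_frac)
        counts[status if status in counts else "unmapped"] += 1
        if aln is None:
            continue
        if naive_start or aln.strand == "+":
            pos = aln.ref_start
        else:
            pos = aln.ref_end - 1
        sites.append((aln.ref_name, pos, aln.strand))
    return sites, counts


def bin_and_normalize(
    sites: Sequence[tuple[str, int, str]],
    genome: GenomeRef,
    total_raw_reads: int,
    bin_size: int = BIN_SIZE,
) -> BinTrack:
    """Sum site counts over fixed non-overlapping bins (bin index =
    floor(position / bin_size)) and normalize to RPM of the raw library."""
    if total_raw_reads <= 0:
        raise ValueError("total_raw_reads must be positive")
    track = BinTrack(bin_size=bin_size, total_raw_reads=total_raw_reads)
    for ref, pos, strand in sites:
        key = (ref, pos // bin_size)
        track.raw[key] = track.raw.get(key, 0) + 1
        if strand == "+":
            track.fwd[key] = track.fwd.get(key, 0) + 1
    return track


def target_bins_for_locus(locus: TargetLocus, bin_size: int = BIN_SIZE) -> set[tuple[str, int]]:
    return {
        (locus.ref_name, b)
        for b in range(locus.window_start // bin_size, (locus.window_end - 1) // bin_size + 1)
    }


def call_free_sites(
    track: BinTrack,
    threshold_rpm: float = FREE_SITE_THRESHOLD_RPM,
    target_bins: Optional[set[tuple[str, int]]] = None,
) -> tuple[list[FreeSite], list[FreeSite]]:
    """All bins with RPM >= threshold, split into free-transposition
    sites and flagged target-locus bins (excluded from the free count).
    Free sites are returned sorted by decreasing RPM."""
    target_bins = target_bins or set()
    free: list[FreeSite] = []
    flagged: list[FreeSite] = []
    for key, count in track.raw.items():
        rpm = track.rpm(key)
        if rpm < threshold_rpm:
            continue
        fwd = track.fwd.get(key, 0)
        site = FreeSite(
            ref=key[0],
            bin_start=key[1] * track.bin_size,
            rpm=rpm,
            is_target_site=key in target_bins,
            orientation_counts=(fwd, count - fwd),
        )
        (flagged if site.is_target_site else free).append(site)
    free.sort(key=lambda s: (-s.rpm, s.ref, s.bin_start))
    flagged.sort(key=lambda s: (-s.rpm, s.ref, s.bin_start))
    return free, flagged


def replicate_overlap(
    sites_a: Iterable[FreeSite | tuple[str, int]],
    sites_b: Iterable[FreeSite | tuple[str, int]],
    slop_bins: int = 0,
) -> tuple[int, int, int]:
    """Overlap of two free-site lists on (ref, bin_index), optionally
    within +/- ``slop_bins``. Returns (nA_only, nB_only, n_shared)."""

    def keys(sites):
        out = set()
        for s in sites:
            if isinstance(s, FreeSite):
                out.add((s.ref, s.bin_index))
            else:
                out.add((s[0], s[1]))
        return out

    ka, kb = keys(sites_a), keys(sites_b)

    def matched(x, other):
        ref, b = x
        return any((ref, b + d) in other for d in range(-slop_bins, slop_bins + 1))

    shared_a = {x for x in ka if matched(x, kb)}
    shared_b = {x for x in kb if matched(x, ka)}
    return len(ka) - len(shared_a), len(kb) - len(shared_b), len(shared_a)


def grna_similarity_scan(
    genome: GenomeRef,
    protospacer: str,
    pam: str = "NGG",
    max_mismatch: int = 9,
    max_bulge: int = 2,
) -> list[OffTargetHit]:
    """Genomic windows alignable to the protospacer with at most
    ``max_mismatch`` substitutions and ``max_bulge`` total gap bases,
    adjacent to an NGG PAM, on either strand.

    The protospacer is aligned PAM-anchored by a bounded semi-global DP;
    PAM-proximal and PAM-distal mismatches count identically. The
    reported position is the start (+ strand coordinates) of the aligned
    protospacer-like window.
    """
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    if pam != "NGG":
        raise ValueError("only the NGG PAM dialect is supported")
    hits: list[OffTargetHit] = []
    proto_rev = encode(protospacer)[::-1].copy()
    span = 20 + max_bulge
    for ref, seq in genome.sequences.items():
        n = len(seq)
        for strand in ("+", "-"):
            s = seq if strand == "+" else revcomp(seq)
            codes = encode(s)
            if n < 23:
                continue
            gg = (codes[1:-1] == 2) & (codes[2:] == 2)
            pam_pos = np.nonzero(gg)[0]  # PAM N at index p
            for p in pam_pos:
                p = int(p)
                w0 = max(p - span, 0)
                if p - w0 < 20 - max_bulge:
                    continue
                window_rev = codes[w0:p][::-1].copy()
                mm, gaps, consumed = _kernels.grna_dp(proto_rev, window_rev, max_bulge)
                if mm > max_mismatch:
                    continue
                start_s = p - consumed
                if strand == "+":
                    position = start_s
                else:
                    position = n - (start_s + consumed)
                hits.append(OffTargetHit(ref, position, strand, int(mm), int(gaps), p))
    hits.sort(key=lambda h: (h.ref, h.position, h.strand))
    return hits


def restrict_to_grna_similar(
    free_sites: Sequence[FreeSite],
    hits: Sequence[OffTargetHit],
    bin_size: int = BIN_SIZE,
) -> list[FreeSite]:
    """Retain only free sites whose bin overlaps a gRNA-similar window."""
    similar_bins: set[tuple[str, int]] = set()
    for h in hits:
        for pos in range(h.position, h.position + 20):
            similar_bins.add((h.ref, pos // bin_size))
    return [s for s in free_sites if (s.ref, s.bin_index) in similar_bins]


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class InsertionSeqResult:
    sites: list[tuple[str, int, str]]
    track: BinTrack
    free_sites: list[FreeSite]
    target_sites: list[FreeSite]
    stage_counts: dict[str, int]

    @property
    def n_free_sites(self) -> int:
        return len(self.free_sites)


def run_insertion_seq(
    reads: Sequence[SeqRead],
    genome: GenomeRef,
    donor_ref: str,
    locus: Optional[TargetLocus],
    expected_te_prefix: str,
    adapter: str = DEFAULT_ADAPTER,
    threshold_rpm: float = FREE_SITE_THRESHOLD_RPM,
    naive_start: bool = False,
    scoring: Scoring = Scoring(),
) -> InsertionSeqResult:
    """End-to-end insertion-seq analysis of one library."""
    total_raw = len(reads)
    trimmed = trim_vector_adapter(reads, adapter=adapter)
    flanks, extract_counts = extract_te_flank(trimmed, expected_te_prefix)
    flanks, n_donor = filter_donor(flanks, donor_ref, scoring=scoring)
    sites, map_counts = assign_sites(flanks, genome, scoring=scoring,
                                     naive_start=naive_start)
    track = bin_and_normalize(sites, genome, total_raw)
    target_bins = target_bins_for_locus(locus) if locus is not None else set()
    free, flagged = call_free_sites(track, threshold_rpm, target_bins)
    stage_counts = {
        "raw_reads": total_raw,
        "te_prefix_reads": extract_counts["kept"],
        "no_te_prefix": extract_counts["no_te_prefix"],
        "short_flank": extract_counts["short_flank"],
        "donor_filtered": n_donor,
        "mapped": map_counts["mapped"],
        "unmapped": map_counts["unmapped"],
        "low_score": map_counts["low_score"],
        "multimap": map_counts["multimap"],
    }
    return InsertionSeqResult(sites, track, free, flagged, stage_counts)
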