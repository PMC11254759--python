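"""Domain model: transposable elements, donor constructs, target loci.

The element of interest is a class II ("cut-and-paste") TE: a short DNA
segment bounded by terminal inverted repeats (TIRs) that excises from a
donor site and reinserts elsewhere, duplicating a 3-nt host motif
(TTA/TAA) on both sides of the new insertion. A CRISPR nuclease
co-expressed with the transposase channels the excised element into the
gRNA-directed double-strand break; this module carries the coordinate
bookkeeping for that geometry: the blunt Cas9 cleavage coordinate, the
TE span inside the donor construct, and the PCR products expected from
the standard four-reaction genotyping design (genomic primers U/D
flanking the target site, TE-internal primers L/R near the element
ends).

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_utils import revcomp

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AmbiguousTargetError(ValueError):
    """Zero or multiple protospacer+PAM occurrences in a target window."""

    def __init__(self, message: str, hits: list[tuple[str, int]]):
        super().__init__(message)
        self.hits = hits


class DonorLayoutError(ValueError):
    """TE absent from, or duplicated in, a donor construct."""


class PrimerError(ValueError):
    """A primer does not occur (once, in the stated orientation) in its
    intended reference."""


def iupac_regex(pattern: str) -> str:
    return "".join(
        f"[{_IUPAC[b]}]" if len(_IUPAC.get(b, b)) > 1 else _IUPAC.get(b, b)
        for b in pattern.upper()
    )


def iupac_findall(seq: str, pattern: str) -> list[int]:
    """Start positions of (possibly overlapping) IUPAC-pattern matches."""
    rx = re.compile("(?=" + iupac_regex(pattern) + ")")
    return [m.start() for m in rx.finditer(seq)]


@dataclass(frozen=True)
class TEElement:
    """A mobilizable element: cargo sequence with terminal inverted repeats."""

    name: str
    sequence: str
    tir_len: int

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"TE {self.name}: sequence contains non-ACGT characters")
        if self.tir_len < 1 or 2 * self.tir_len > len(self.sequence):
            raise ValueError(f"TE {self.name}: invalid tir_len {self.tir_len}")
        left = self.sequence[: self.tir_len]
        right = self.sequence[-self.tir_len :]
        if left != revcomp(right):
            raise ValueError(
                f"TE {self.name}: first {self.tir_len} bases are not the reverse "
                "complement of the last (terminal inverted repeats broken)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def left_anchor(self, k: int = 20) -> str:
        return self.sequence[:k]

    def right_anchor(self, k: int = 20) -> str:
        return self.sequence[-k:]


@dataclass(frozen=True)
class DonorSite:
    """The TE location inside the donor construct, with its 3-nt flanks."""

    construct_seq: str
    te_span: tuple[int, int]
    left_flank_tsd: str
    right_flank_tsd: str

    @property
    def flanks_valid(self) -> bool:
        return self.left_flank_tsd in ("TTA", "TAA") and self.right_flank_tsd in ("TTA", "TAA")


@dataclass(frozen=True)
class TargetLocus:
    """A genomic window with a protospacer+PAM and the derived blunt cut.

    ``cleavage_coord`` is a genome coordinate naming the boundary between
    the two bases flanking the cut: the blunt SpCas9 cut 3 nt 5' of the
    PAM (between protospacer positions 17 and 18).
    """

    ref_name: str
    window_seq: str
    window_start: int
    protospacer: str
    pam: str
    strand: str
    cleavage_coord: int

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.window_seq)

    @property
    def cut_in_window(self) -> int:
        return self.cleavage_coord - self.window_start


@dataclass
class GenomeRef:
    """Ordered name -> sequence mapping for a (small) genome."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.total_len <= 0:
            raise ValueError("genome has zero total length")

    @property
    def total_len(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]


@dataclass(frozen=True)
class PrimerSet:
    """Four genotyping primers, written 5'->3' on their annealing strand.

    U anneals forward upstream of the cut, D reverse downstream; R anneals
    forward inside the TE near its right end, L reverse near its left end,
    so that (for a forward insertion) U pairs with L and D with R.
    """

    U: str
    D: str
    L: str
    R: str

    def pair(self, name: str) -> tuple[str, str]:
        a, b = name.split("+")
        return getattr(self, a), getattr(self, b)


def find_cleavage_site(
    window_seq: str,
    protospacer: str,
    pam_rule: str = "NGG",
    ref_name: str = "target",
    window_start: int = 0,
) -> TargetLocus:
    """Locate the unique protospacer+PAM in a window and derive the blunt
    cleavage coordinate (3 nt 5' of the PAM).

    Raises :class:`AmbiguousTargetError` on zero or multiple occurrences,
    naming every hit.
    """
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    window_seq = window_seq.upper()
    protospacer = protospacer.upper()
    plen = len(pam_rule)
    hits: list[tuple[str, int]] = []
    pam_rx = re.compile(iupac_regex(pam_rule))
    for i in iupac_findall(window_seq, protospacer):
        pam = window_seq[i + 20 : i + 20 + plen]
        if len(pam) == plen and pam_rx.fullmatch(pam):
            hits.append(("+", i))
    rc_proto = revcomp(protospacer)
    rc_pam = revcomp(pam_rule)
    rc_pam_rx = re.compile(iupac_regex(rc_pam))
    for i in iupac_findall(window_seq, rc_proto):
        pam = window_seq[i - plen : i]
        if i >= plen and rc_pam_rx.fullmatch(pam):
            hits.append(("-", i))
    if len(hits) != 1:
        raise AmbiguousTargetError(
            f"expected exactly one protospacer+PAM occurrence, found {len(hits)}: {hits}",
            hits,
        )
    strand, i = hits[0]
    if strand == "+":
        cut = window_start + i + 17
        pam = window_seq[i + 20 : i + 20 + plen]
    else:
        cut = window_start + i + 3
        pam = revcomp(window_seq[i - plen : i])
    return TargetLocus(
        ref_name=ref_name,
        window_seq=window_seq,
        window_start=window_start,
        protospacer=protospacer,
        pam=pam,
        strand=strand,
        cleavage_coord=cut,
    )


def locate_te_in_donor(construct_seq: str, te: TEElement) -> DonorSite:
    """Find the unique TE occurrence in a donor construct and record its
    flanking trinucleotides. Non-TTA/TAA flanks are reported via
    :attr:`DonorSite.flanks_valid` rather than raised."""
    construct_seq = construct_seq.upper()
    starts = []
    i = construct_seq.find(te.sequence)
    while i != -1:
        starts.append(i)
        i = construct_seq.find(te.sequence, i + 1)
    if len(starts) != 1:
        raise DonorLayoutError(
            f"TE {te.name} occurs {len(starts)} times in the donor construct (expected 1)"
        )
    s = starts[0]
    e = s + te.length
    return DonorSite(
        construct_seq=construct_seq,
        te_span=(s, e),
        left_flank_tsd=construct_seq[max(s - 3, 0) : s],
        right_flank_tsd=construct_seq[e : e + 3],
    )


STATES = ("donor", "excised", "inserted_fwd", "inserted_rev")
GENOTYPING_PAIRS = ("U+D", "U+R", "U+L", "D+R", "D+L")


def reconstruct_state_sequence(
    donor: DonorSite, locus: TargetLocus, te: TEElement, state: str
) -> str:
    """Target-locus sequence under each genotyping state, assuming a
    perfect TSD-retaining junction.

    A reverse insertion flips the whole excised unit (flank + TE + flank),
    so the flanking trinucleotides are reverse-complemented too (TTA<->TAA).
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    w = locus.window_seq
    cut = locus.cut_in_window
    if state in ("donor", "excised"):
        return w
    unit = donor.left_flank_tsd + te.sequence + donor.right_flank_tsd
    if state == "inserted_rev":
        unit = revcomp(unit)
    return w[:cut] + unit + w[cut:]


def _pcr_product(seq: str, fwd: str, rev: str) -> int | None:
    """Length of the product amplified by a forward and a reverse primer
    on ``seq``, or None when the pair cannot amplify. Either primer of a
    pair may play the forward role."""
    best: int | None = None
    for a, b in ((fwd, rev), (rev, fwd)):
        for s in iupac_findall(seq, a):
            for t in iupac_findall(seq, revcomp(b)):
                end = t + len(b)
                if end > s + len(a):
                    length = end - s
                    if best is None or length < best:
                        best = length
    return best


def predict_genotyping_amplicons(
    donor: DonorSite,
    locus: TargetLocus,
    primers: PrimerSet,
    te: TEElement,
    state: str,
) -> list[tuple[str, int | None]]:
    """Expected product length of each of the five primer pairs under the
    given locus state (four-reaction targeted-insertion assay plus the
    U+D span)."""
    for name in ("U", "D", "L", "R"):
        p = getattr(primers, name)
        ref = te.sequence if name in ("L", "R") else locus.window_seq
        n_occ = len(iupac_findall(ref, p)) + len(iupac_findall(ref, revcomp(p)))
        if n_occ != 1:
            raise PrimerError(
                f"primer {name} occurs {n_occ} times in its intended reference (expected 1)"
            )
    seq = reconstruct_state_sequence(donor, locus, te, state)
    out: list[tuple[str, int | None]] = []
    for pair_name in GENOTYPING_PAIRS:
        a, b = primers.pair(pair_name)
        out.append((pair_name, _pcr_product(seq, a, b)))
    return out
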