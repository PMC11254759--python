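"""Ground-truthed synthetic references, insertion events and FASTQ reads.

The generator emulates the two sequencing inputs of the study design at
desk scale:

* **amplicon-seq of targeted-insertion junctions** — single-end 300-bp
  reads spanning one junction between the target-gene flank and the
  inserted TE, with donor-derived TTA/TAA flanks, an NHEJ edit spectrum
  concentrated on 1-3 bp deletions and 1-bp SNPs/insertions (deletions up
  to 7 bp supported), per-end element truncation controlled by
  ``f_intact``, random insertion orientation, substitution sequencing
  errors and PCR duplication;
* **insertion-seq libraries** — reads beginning with a fixed TE-end
  prefix (the stretch from the sequencing primer to the TE terminus)
  followed by the genomic flank of the insertion, for free transposition
  at TTA/TAA sites with a duplicated 3-nt TSD, plus donor-construct
  background, target-site (CRISPR-channelled) read mass, non-TE noise
  reads and a trailing 3' vector adapter.

Everything is deterministic under a fixed seed; truth tables carry enough
per-event detail to score every downstream estimator without
re-simulation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_model import (
    DonorSite,
    GenomeRef,
    PrimerSet,
    TargetLocus,
    TEElement,
    find_cleavage_site,
    locate_te_in_donor,
)
from .io_utils import SeqRead, revcomp

TE_VARIANT_LENGTHS = {
    "core_430": 430,
    "hse_444": 444,
    "bar_cds_1002": 1002,
    "bar_1563": 1563,
    "epsps_8994": 8994,
}

#: 3' library adapter searched for during insertion-seq trimming
VECTOR_ADAPTER = "ATCACTAGTGAATTCGCGGCC"

DEFAULT_SPECTRUM = {
    "perfect": 0.40,
    "snp1": 0.10,
    "ins1": 0.10,
    "del1": 0.20,
    "del2": 0.10,
    "del3": 0.10,
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int = 0
    genome_len: int = 200_000
    n_chroms: int = 2
    te_variant: str = "core_430"
    tir_len: int = 15
    read_len: int = 300
    error_rate: float = 0.001
    n_reads: int = 5000
    f_intact: float = 0.7
    junction_edit_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    orientation_prob: float = 0.5
    n_free_sites: int = 8
    target_fraction: float = 0.05
    donor_fraction: float = 0.10
    noise_fraction: float = 0.05
    free_site_weight_ratio: float = 0.35
    pcr_duplication: float = 1.0
    te_prefix_len: int = 50

    def __post_init__(self) -> None:
        total = sum(self.junction_edit_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"junction edit spectrum sums to {total}, expected 1")
        for key in self.junction_edit_spectrum:
            if key in ("perfect", "snp1", "ins1"):
                continue
            if not key.startswith("del"):
                raise ValueError(f"unknown edit class {key!r}")
            k = int(key[3:])
            if not 1 <= k <= 7:
                raise ValueError("deletion classes are limited to 1-7 bp")
        if self.te_variant not in TE_VARIANT_LENGTHS:
            raise ValueError(f"unknown te_variant {self.te_variant!r}")
        if not 0 <= self.orientation_prob <= 1 or not 0 <= self.f_intact <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        frac = self.target_fraction + self.donor_fraction + self.noise_fraction
        if frac > 1:
            raise ValueError("target/donor/noise fractions exceed 1")
        if self.genome_len < self.n_chroms * 5_000:
            raise ValueError("genome too small for the requested chromosome count")
        if self.pcr_duplication < 1:
            raise ValueError("pcr_duplication is a mean copy number >= 1")


@dataclass
class TruthEvent:
    """One insertion event (targeted or free) with its junction truth."""

    kind: str  # targeted | free
    ref: str
    insertion_coord: int
    orientation: str  # forward | reverse
    delivered_span: tuple[int, int]
    left_edits: str
    right_edits: str
    tsd_left: Optional[str]
    tsd_right: Optional[str]
    read_id: Optional[str] = None
    side: Optional[str] = None  # junction covered by the read (amplicon sim)
    n_reads: int = 1


@dataclass
class SimRefs:
    genome: GenomeRef
    te: TEElement
    donor: DonorSite
    locus: TargetLocus
    planted_tta: list[tuple[str, int]]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _streams(cfg: SimConfig) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(cfg.seed).spawn(5)
    return [np.random.default_rng(s) for s in seqs]


def make_references(cfg: SimConfig) -> SimRefs:
    """Random genome with planted TTA/TAA sites, a TIR-bounded TE, a
    TTA/TAA-flanked donor construct and a protospacer+NGG target locus.

    Planted free-transposition sites are kept >=2 kb apart, away from the
    sequence ends and the target window, and placed away from 10-nt bin
    boundaries so each planted insertion occupies a single bin downstream.
    """
    rng = _streams(cfg)[0]
    chrom_len = cfg.genome_len // cfg.n_chroms
    chroms = {f"chr{i + 1}": list(_random_dna(rng, chrom_len)) for i in range(cfg.n_chroms)}
    names = list(chroms)

    # target locus on chr1
    window_len = min(400, chrom_len // 4)
    t0 = chrom_len // 2
    locus = None
    for _ in range(20):
        proto = _random_dna(rng, 20)
        seq = chroms[names[0]]
        seq[t0 + 150 : t0 + 150 + 23] = list(proto + "AGG")
        window_seq = "".join(seq[t0 : t0 + window_len])
        try:
            locus = find_cleavage_site(
                window_seq, proto, ref_name=names[0], window_start=t0
            )
            break
        except Exception:
            continue
    if locus is None:
        raise ValueError("could not place an unambiguous target locus (genome too small?)")

    # planted TTA/TAA free-transposition sites
    margin = 1_000
    planted: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {n: [] for n in names}
    taken[names[0]].extend(range(t0 - 2_000, t0 + window_len + 2_000, 1))
    attempts = 0
    while len(planted) < cfg.n_free_sites:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("insufficient room to plant TTA/TAA sites")
        name = names[int(rng.integers(0, len(names)))]
        p = int(rng.integers(margin, chrom_len - margin))
        p -= p % 10
        p += 4  # mid-bin placement: junction bases land away from bin edges
        if any(abs(p - q) < 2_000 for q in planted_pos(planted, name)):
            continue
        if name == names[0] and t0 - 2_000 <= p <= t0 + window_len + 2_000:
            continue
        motif = "TTA" if rng.random() < 0.5 else "TAA"
        chroms[name][p : p + 3] = list(motif)
        planted.append((name, p))
    planted.sort()

    genome = GenomeRef({n: "".join(s) for n, s in chroms.items()})
    # refresh locus window from the final genome (TTA planting never touches it)
    window_seq = genome[names[0]][t0 : t0 + window_len]
    locus = find_cleavage_site(
        window_seq, locus.protospacer, ref_name=names[0], window_start=t0
    )

    te_len = TE_VARIANT_LENGTHS[cfg.te_variant]
    tir = _random_dna(rng, cfg.tir_len)
    interior = _random_dna(rng, te_len - 2 * cfg.tir_len)
    te = TEElement(cfg.te_variant, tir + interior + revcomp(tir), cfg.tir_len)

    backbone_l = _random_dna(rng, 400)
    backbone_r = _random_dna(rng, 400)
    construct = backbone_l + "TTA" + te.sequence + "TAA" + backbone_r
    donor = locate_te_in_donor(construct, te)
    return SimRefs(genome=genome, te=te, donor=donor, locus=locus, planted_tta=planted)


def planted_pos(planted: list[tuple[str, int]], name: str) -> list[int]:
    return [p for n, p in planted if n == name]


def make_primer_set(refs: SimRefs) -> PrimerSet:
    """Genotyping primers for the fixture: genomic U/D 140-160 nt from the
    cut, TE-internal L/R 30-50 nt inside each element end."""
    cut = refs.locus.cut_in_window
    w = refs.locus.window_seq
    te = refs.te.sequence
    return PrimerSet(
        U=w[cut - 160 : cut - 140],
        D=revcomp(w[cut + 140 : cut + 160]),
        L=revcomp(te[30:50]),
        R=te[-50:-30],
    )


def _draw_edit(rng: np.random.Generator, spectrum: dict[str, float]) -> str:
    keys = sorted(spectrum)
    probs = np.array([spectrum[k] for k in keys])
    choice = keys[int(rng.choice(len(keys), p=probs / probs.sum()))]
    if choice.startswith("del"):
        direction = "gene" if rng.random() < 0.5 else "te"
        return f"{choice}@{direction}"
    return choice


def simulate_targeted_insertions(
    cfg: SimConfig, refs: SimRefs
) -> tuple[list[TruthEvent], list[SeqRead]]:
    """Amplicon-seq reads of targeted-insertion junctions.

    Each molecule is an independent insertion at the blunt cleavage
    coordinate: the TE (possibly end-truncated, per-end intact with
    probability ``f_intact``) carrying donor-derived TTA/TAA flanks, with
    one junction edit drawn per side from the edit spectrum. One
    junction-spanning fragment per molecule is emitted and sequenced.
    """
    rngs = _streams(cfg)
    rng = rngs[1]
    locus, te = refs.locus, refs.te
    cut = locus.cut_in_window
    w = locus.window_seq
    flank_left_full = w[:cut]
    flank_right_full = w[cut:]
    events: list[TruthEvent] = []
    fragments: list[tuple[str, str]] = []
    for i in range(cfg.n_reads):
        orientation = "forward" if rng.random() < cfg.orientation_prob else "reverse"
        side = "LEFT_5p" if rng.random() < 0.5 else "RIGHT_3p"
        intact_l = rng.random() < cfg.f_intact
        intact_r = rng.random() < cfg.f_intact
        lt = 0 if intact_l else int(rng.integers(5, 41))
        rt = 0 if intact_r else int(rng.integers(5, 41))
        e_left = _draw_edit(rng, cfg.junction_edit_spectrum)
        e_right = _draw_edit(rng, cfg.junction_edit_spectrum)
        oriented = te.sequence if orientation == "forward" else revcomp(te.sequence)
        deliv = oriented[lt : len(oriented) - rt]
        tsd_l, tsd_r = "TTA", "TAA"

        read_id = f"amp{i}"
        if side == "LEFT_5p":
            fl = int(rng.integers(25, 121))
            flank = flank_left_full[-fl:]
            tsd, te_part = tsd_l, deliv
            # apply the left edit at the gene|TSD|TE junction
            flank, tsd, te_part, tsd_l = _edit_left(e_left, flank, tsd, te_part, rng)
            room = cfg.read_len - len(flank) - len(tsd)
            frag = flank + tsd + te_part[: max(room, 0)]
        else:
            fr = int(rng.integers(25, 121))
            flank = flank_right_full[:fr]
            tsd, te_part = tsd_r, deliv
            flank, tsd, te_part, tsd_r = _edit_right(e_right, flank, tsd, te_part, rng)
            room = cfg.read_len - len(flank) - len(tsd)
            frag = te_part[-max(room, 0) :] + tsd + flank
        if rng.random() < 0.5:
            frag = revcomp(frag)
        fragments.append((read_id, frag))
        events.append(
            TruthEvent(
                kind="targeted",
                ref=locus.ref_name,
                insertion_coord=locus.cleavage_coord,
                orientation=orientation,
                delivered_span=(lt, te.length - rt),
                left_edits=e_left,
                right_edits=e_right,
                tsd_left=tsd_l,
                tsd_right=tsd_r,
                read_id=read_id,
                side=side,
            )
        )
    reads = read_simulator(
        fragments, cfg.read_len, cfg.error_rate, cfg.pcr_duplication, rngs[3]
    )
    return events, reads


def _edit_left(edit: str, flank: str, tsd: str, te_part: str,
               rng: np.random.Generator) -> tuple[str, str, str, str]:
    """Edit at the genome-left junction (layout gene-flank | TSD | TE).
    Returns (flank, tsd, te_part, surviving_tsd)."""
    if edit == "perfect":
        return flank, tsd, te_part, tsd
    if edit == "snp1":
        new = _mutate_base(rng, tsd[0]) + tsd[1:]
        return flank, new, te_part, new
    if edit == "ins1":
        return flank + _random_dna(rng, 1), tsd, te_part, tsd
    k = int(edit[3:].split("@")[0])
    if edit.endswith("@gene"):
        return flank[: len(flank) - k], tsd, te_part, tsd
    combined = tsd + te_part
    remaining = combined[k:]
    new_tsd = remaining[: max(len(tsd) - k, 0)]
    return flank, "", remaining, new_tsd if k < len(tsd) else ""


def _edit_right(edit: str, flank: str, tsd: str, te_part: str,
                rng: np.random.Generator) -> tuple[str, str, str, str]:
    """Edit at the genome-right junction (layout TE | TSD | gene-flank)."""
    if edit == "perfect":
        return flank, tsd, te_part, tsd
    if edit == "snp1":
        new = tsd[:-1] + _mutate_base(rng, tsd[-1])
        return flank, new, te_part, new
    if edit == "ins1":
        return _random_dna(rng, 1) + flank, tsd, te_part, tsd
    k = int(edit[3:].split("@")[0])
    if edit.endswith("@gene"):
        return flank[k:], tsd, te_part, tsd
    combined = te_part + tsd
    remaining = combined[: len(combined) - k]
    new_tsd = tsd[: max(len(tsd) - k, 0)] if k < len(tsd) else ""
    return flank, "", remaining, new_tsd


def simulate_free_transposition(
    cfg: SimConfig, refs: SimRefs
) -> tuple[list[TruthEvent], list[SeqRead]]:
    """Insertion-seq reads: TE-prefix + genomic flank at planted TTA/TAA
    sites (intact 3-nt TSD), plus donor-construct background, target-site
    channelled reads and non-TE noise.

    Molecule counts per category are allocated by largest-remainder
    rounding of the configured fractions; per-site weights decay
    geometrically (``free_site_weight_ratio``) so site read support spans
    orders of magnitude, as in real insertion-seq tracks.
    """
    if cfg.n_free_sites > len(refs.planted_tta):
        raise ValueError("fewer planted TTA/TAA sites than requested free sites")
    rngs = _streams(cfg)
    rng = rngs[2]
    sites = refs.planted_tta[: cfg.n_free_sites]
    f_free = 1.0 - cfg.target_fraction - cfg.donor_fraction - cfg.noise_fraction
    weights = np.array([cfg.free_site_weight_ratio ** i for i in range(len(sites))])
    if len(sites):
        weights = weights / weights.sum() * f_free
    fracs = [cfg.target_fraction, cfg.donor_fraction, cfg.noise_fraction] + list(weights)
    counts = _largest_remainder(fracs, cfg.n_reads)
    n_target, n_donor, n_noise = counts[0], counts[1], counts[2]
    site_counts = counts[3:]

    te_prefix = refs.te.sequence[-cfg.te_prefix_len :]
    flank_len = cfg.read_len - cfg.te_prefix_len
    genome = refs.genome
    locus = refs.locus
    events: list[TruthEvent] = []
    fragments: list[tuple[str, str]] = []

    for s, ((ref, p), n_mol) in enumerate(zip(sites, site_counts)):
        seq = genome[ref]
        motif = seq[p : p + 3]
        n_fwd = 0
        for j in range(n_mol):
            fwd = rng.random() < cfg.orientation_prob
            n_fwd += fwd
            if fwd:
                flank = seq[p : p + flank_len]
            else:
                flank = revcomp(seq[max(p + 3 - flank_len, 0) : p + 3])
            fragments.append((f"free{s}_{j}", te_prefix + flank))
        events.append(
            TruthEvent(
                kind="free",
                ref=ref,
                insertion_coord=p,
                orientation=f"{n_fwd}fwd/{n_mol - n_fwd}rev",
                delivered_span=(0, refs.te.length),
                left_edits="perfect",
                right_edits="perfect",
                tsd_left=motif,
                tsd_right=motif,
                n_reads=n_mol,
            )
        )

    c = locus.cleavage_coord
    tseq = genome[locus.ref_name]
    for j in range(n_target):
        if rng.random() < cfg.orientation_prob:
            flank = "TAA" + tseq[c : c + flank_len - 3]
        else:
            flank = "TAA" + revcomp(tseq[max(c - flank_len + 3, 0) : c])
        fragments.append((f"tgt_{j}", te_prefix + flank))
    if n_target:
        events.append(
            TruthEvent(
                kind="targeted",
                ref=locus.ref_name,
                insertion_coord=c,
                orientation="mixed",
                delivered_span=(0, refs.te.length),
                left_edits="perfect",
                right_edits="perfect",
                tsd_left="TTA",
                tsd_right="TAA",
                n_reads=n_target,
            )
        )

    donor_seq = refs.donor.construct_seq
    te_end = refs.donor.te_span[1]
    for j in range(n_donor):
        fragments.append((f"donor_{j}", te_prefix + donor_seq[te_end : te_end + flank_len]))

    names = list(genome.sequences)
    for j in range(n_noise):
        name = names[int(rng.integers(0, len(names)))]
        seq = genome[name]
        start = int(rng.integers(0, max(len(seq) - cfg.read_len, 1)))
        frag = seq[start : start + cfg.read_len - len(VECTOR_ADAPTER)] + VECTOR_ADAPTER
        fragments.append((f"noise_{j}", frag))

    reads = read_simulator(
        fragments, cfg.read_len, cfg.error_rate, cfg.pcr_duplication, rngs[4]
    )
    return events, reads


def _largest_remainder(fracs: list[float], total: int) -> list[int]:
    raw = [f * total for f in fracs]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(fracs)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def read_simulator(
    fragments: list[tuple[str, str]],
    read_len: int,
    error_rate: float,
    pcr_duplication: float,
    rng: np.random.Generator,
) -> list[SeqRead]:
    """Sequence each fragment: truncate to ``read_len``, apply uniform
    substitution errors, then emit a geometric number of identical PCR
    duplicates (mean ``pcr_duplication``). Qualities are constant and
    consistent with the error rate."""
    q = int(min(40, round(-10 * math.log10(max(error_rate, 1e-4)))))
    reads: list[SeqRead] = []
    for frag_id, seq in fragments:
        s = list(seq[:read_len])
        if error_rate > 0:
            hits = np.nonzero(rng.random(len(s)) < error_rate)[0]
            for h in hits:
                s[h] = _mutate_base(rng, s[h])
        final = "".join(s)
        copies = 1
        if pcr_duplication > 1:
            copies = int(rng.geometric(1.0 / pcr_duplication))
        for c in range(copies):
            rid = frag_id if c == 0 else f"{frag_id}:dup{c}"
            reads.append(SeqRead(rid, final, [q] * len(final)))
    return reads


def truth_to_frame(events: list[TruthEvent]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in events])


def write_truth_tsv(events: list[TruthEvent], path: str | Path) -> None:
    truth_to_frame(events).to_csv(path, sep="\t", index=False)
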