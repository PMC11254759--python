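# Methods

`temap` analyses two kinds of single-end sequencing experiments around a
cut-and-paste transposable element (TE) that is mobilized in trans and
channelled into a CRISPR/Cas9-directed double-strand break:

* **junction amplicon-seq** — deep sequencing of PCR products spanning
  the junctions between the target-gene flank and the inserted element,
  used to measure insertion-site precision, element intactness and the
  spectrum of junction edits;
* **insertion-seq** — a library design in which each read starts inside
  the element (at a TE-specific primer), crosses the element terminus
  and continues into the genomic flank, used to map every insertion in
  the genome and count free-transposition events.

This note records the model, the tunable parameters, the synthetic-data
generator's scope, and the numerical choices made where the design was
genuinely open.

## Domain model

The element is a class II TE bounded by terminal inverted repeats
(TIRs): the first `tir_len` bases are the reverse complement of the last
`tir_len` (15 bp for the canonical 430-bp fixture element; cargo
variants of 444, 1002, 1563 and 8994 bp are supported). Free
transposition targets TTA/TAA motifs and duplicates the 3-nt motif on
both sides of the insertion (target-site duplication, TSD). In the
donor construct the element is flanked by engineered TTA/TAA
trinucleotides; upon excision these travel with the element as 3-nt
overhangs, so a CRISPR-targeted insertion carries donor-derived TTA/TAA
flanks even when the target site itself has none.

The target locus is a genomic window containing a unique 20-nt
protospacer followed by an NGG PAM (N matches any base). The blunt
cleavage coordinate is placed 3 nt 5' of the PAM — between protospacer
positions 17 and 18 — the canonical SpCas9 cut. Cas12a-style staggered
cuts are not modelled. Coordinates are 0-based and half-open
everywhere internally; only human-readable report columns are 1-based.

A reverse-orientation insertion inverts the whole excised unit
(flank + TE + flank); because rc(TTA) = TAA the genome-left flank is
TTA and the genome-right flank TAA in both orientations.

## Alignment primitives

All trimming and mapping is done in-package:

* **Adapter matching** uses unit-cost edits (mismatch = insertion =
  deletion = 1). A pattern may occur in full anywhere in the read or as
  a terminal partial occurrence (a pattern prefix at the 3' end for
  3'-anchored search, a suffix at the 5' end for 5'-anchored search).
  The error budget is `floor(max_error_rate x matched pattern length)`
  — floored, never rounded — so a 9-nt overlap at rate 0.11 tolerates
  zero errors while a 20-nt match tolerates two. Among admissible
  candidates the longest matched pattern wins, then fewest errors, then
  the occurrence closest to the anchored read end.
* **Quality trimming** of 3' ends follows the running-sum rule: for
  every cut point, sum (quality − cutoff) over the removed tail; cut at
  the smallest index whose sum is minimal, and only if that minimum is
  negative.
* **Local alignment** is an affine-gap Gotoh DP (numba-compiled) with
  defaults match +1, mismatch −4, gap open −6, gap extend −1; a gap of
  length L costs `gap_open + L x gap_extend`. Both query orientations
  are tried; ties favour the forward strand, then the smaller reference
  start. These mapper-like defaults make a 20-nt exact anchor decisive.
* **Read mapping** seeds candidate loci with exact 15-mers against a
  sorted k-mer index, groups seed diagonals, and extends. When all
  seeds agree on a single diagonal a gapless (Hamming) placement of the
  full read is tried first — this is exact for substitution-only reads
  and, usefully, does not clip terminal mismatches, so junction-adjacent
  bases survive sequencing errors; otherwise the Gotoh kernel aligns the
  read against a padded window. Reads scoring below
  `min_score_frac x match x read length` (default 0.5) are counted as
  unmapped; equal-best placements at distinct loci are flagged
  multimapping and excluded from site calling, since reported site
  positions must be unique.

## Junction amplicon analysis

**Splitting.** A junction read is split at the element boundary by
searching the four 20-nt TE terminal anchors (left/right end x
forward/reverse complement) in the read and its reverse complement with
adapter-style matching (min_overlap 8, error rate 0.11). Among hits the
fewest anchor errors win, ties going to the hit closest to a read end.
When no terminal anchor is found — the delivered element may lack its
terminal bases — a local-alignment fallback against the full element
recovers truncated-end junctions; reads lying wholly inside the element
(no genomic flank) are rejected.

**Mirror ambiguity.** From the element alone, a (side, orientation)
call is indistinguishable from its mirror (other side, other
orientation, reverse-complemented read): the two layouts are literally
identical and only the genomic flank tells them apart. After splitting,
the flank is aligned under both interpretations against the target
window and the better fit wins. The published workflow avoids this
ambiguity by processing each junction/orientation combination with its
own primer-specific adapter call; a per-read resolution step is the
equivalent for a pooled read stream.

**Insertion-site offsets.** The genomic flank is aligned to the target
window carrying the expected TSD at the cut ("the flanking TTA was
included in the reference"), and the junction-proximal aligned
reference base — right-most for the left junction, left-most for the
right junction — is reported as a signed offset from the cleavage
coordinate. Offset 0 means insertion exactly at the cut with an intact
TSD. Deletions that remove TSD or flank bases shift the offset by their
length; because the aligner clips junction-proximal unaligned bases
(exactly as an external mapper would soft-clip them), a deletion of the
gene-side bases can report the TSD length in addition to the deletion
length. Error-free perfect junctions always report 0.

**Intactness.** On reads carrying >= 20 nt of both flank and element
sequence, the element segment is aligned to the element reference; the
junction-adjacent end of that alignment is at distance 0 from the
element terminus iff the full end was delivered. Forward and reverse
orientations are merged on this junction-relative axis. The intact
fraction is the share of reads at distance 0.

**Variant profiles.** Each junction read is aligned to the expected
junction reference for its (side, orientation) group — gene flank +
TSD + element end — and every covered reference position receives
exactly one state per read: deletion (by run length, every deleted
position counted), else insertion (length attached to the position
immediately 5' in target-gene orientation), else SNP, else
reference-identical. Orientations are merged on junction-relative
coordinates (TSD at positions 0..2). Because the expected junction
reference extends ~30 nt into the element, junction deletions are
interior to the alignment and must be represented as gap operations,
which makes the edit-class rates directly recoverable. Edit-spectrum
estimation uses terminal-intact reads only: on a truncated element the
junction-adjacent reference content is absent and states there are not
interpretable.

**Chi-square contrast.** The published comparison of junction
polymorphism between two protein configurations is stated only as "the
percentage of reads reporting 0 polymorphisms at each position ...
Pearson's chi-square". The construction here — an interpretation,
flagged as such — is a homogeneity test: per junction position a 2x2
table (zero-polymorphism vs >= 1 polymorphism, configuration A vs B)
contributes its Pearson statistic, the total is referred to a
chi-square distribution with df = number of positions covered in both
profiles, and zero-coverage positions are excluded. Identical profiles
give chi-square 0, p = 1; the statistic is symmetric in its arguments.

**Unique-insertion clustering.** Library construction tagged reads
after PCR, so PCR duplicates are indistinguishable and only a lower
bound on distinct insertions is reported: exact duplicates (including
reverse-complement duplicates) are removed, reads exactly contained in
longer reads are absorbed, and reads sharing an exact terminal overlap
>= 20 nt (candidate pairs seeded by shared 20-mers) are connected; the
number of connected components is the minimum number of distinct
insertions.

## Insertion-seq analysis

Stages, each logging kept + dropped = input:

1. 3' quality trim (Q10) and removal of the 3' vector adapter
   `ATCACTAGTGAATTCGCGGCC` (min_overlap 10, rate 0.1);
2. 5' TE-prefix identification and removal (min_overlap 35, rate 0.1);
   flanks shorter than 30 nt are discarded;
3. donor filtering: flanks mapping to the donor construct are dropped
   (they report the element at its donor location, not a new
   insertion); the donor reference span is configurable;
4. genome mapping and site assignment. The junction lies at the
   trimmed read's 5' end, so the junction-adjacent base is the
   alignment start on the + strand and the alignment end on the −
   strand. Whether the published "start position" was strand-corrected
   is not stated; `naive_start=True` reproduces the literal
   leftmost-base behaviour. The two conventions differ by at most the
   read length and almost always fall in the same or adjacent bin.
5. site counts summed over 10-nt non-overlapping bins (bin index =
   floor(position/10), per reference, 0-based) and normalized to reads
   per million **raw** library reads — the pre-trimming read count, a
   choice that changes RPM values and is therefore fixed here;
6. bins with >= 100 RPM called as free-transposition sites, sorted by
   decreasing RPM; bins overlapping the target window are flagged and
   excluded from the free count;
7. replicate overlap as set intersection on (reference, bin index),
   optionally within +/- a bin slop;
8. a protospacer-similarity scan (<= 9 mismatches, <= 2 nt total bulge,
   NGG PAM required, both strands) to restrict free sites to
   gRNA-similar bins. The scan anchors a bounded semi-global DP at
   each PAM; PAM-proximal and PAM-distal mismatches count identically,
   and bulges may fall in either the genomic window (DNA bulge) or the
   protospacer (RNA bulge), with the total gap length bounded.

A simple Manhattan-style plot of bin RPM along concatenated reference
coordinates is provided, with a dashed guide line at 10,000 RPM and
target bins highlighted.

## Synthetic data generator

The generator defines the study conditions for all tests; its defaults
are fixed once and are not tuning knobs.

* **References**: a uniform-random genome (default 200 kb over 2
  chromosomes; 5 Mb in the free-site scenario) with planted TTA/TAA
  sites (>= 2 kb apart, >= 1 kb from sequence ends, away from the
  target window); a TE with 15-nt TIRs and the configured cargo length;
  a donor construct `backbone + TTA + TE + TAA + backbone`; a target
  locus with a unique protospacer+AGG. Planted sites are placed at
  offset 4 within their 10-nt bin so that a planted insertion occupies
  exactly one bin even when a sequencing error clips a junction base or
  the two TSD-edge conventions differ — the pipeline itself has no such
  knowledge.
* **Targeted junctions**: each molecule is an independent insertion at
  the cleavage coordinate. Each element end is intact with probability
  `f_intact` (default 0.7), otherwise truncated by uniform 5–40 nt —
  large enough to be unambiguous against alignment-end jitter. One
  junction edit per side is drawn from the spectrum (default: perfect
  0.4, snp1 0.1, ins1 0.1, del1 0.2, del2 0.1, del3 0.1; deletion
  classes up to 7 bp are supported). A deletion removes bases adjacent
  to the TSD/flank boundary, going into the TSD/element side or into
  the gene with equal probability — the study reports deletions in
  both directions without proportions. `snp1` mutates the TSD base
  nearest the gene; `ins1` inserts one random base at the boundary.
  Sides are edited independently (the study plots them separately; no
  left/right correlation is modelled). One junction-spanning fragment
  per molecule is emitted with 25–120 nt of flank, sequenced in a
  random direction.
* **Free transposition**: molecules are allocated to categories
  (target-channelled, donor background, non-TE noise, and the planted
  free sites) by largest-remainder rounding of the configured
  fractions; per-site weights decay geometrically (ratio 0.35), so
  site support spans ~3 orders of magnitude as in real insertion-seq
  tracks and the weakest site sits a factor ~3 above the 100 RPM
  threshold at the default read depth. Raising the target fraction
  (CRISPR channelling) shrinks the free-site read mass and pushes the
  weakest sites below threshold. Free insertions carry an intact 3-nt
  TSD on both sides by construction. Reads are TE-prefix + flank;
  noise reads end in the vector adapter.
* **Read simulator**: fragments are truncated to the read length
  (default 300 nt, single-end), uniform substitution errors are applied
  (default 0.1%), Phred qualities are constant and consistent with the
  error rate, and each molecule is emitted as a geometric number of
  identical PCR duplicates (default mean 1, i.e. off).

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real data: indel sequencing errors and
position-dependent quality decay (quality-trimming tests plant explicit
low-quality tails instead); restriction-fragment library structure
(digestion shapes library composition, not the per-read computation,
so junction fragments are emitted directly); chimeric PCR artifacts;
genome repeat structure (uniform-random sequence under-represents
multimapping); correlated left/right junction edits; donor excision
footprints beyond perfect religation.

## Numerical choices and degenerate inputs

* Error budgets are floored; thresholds are inclusive (>= 100 RPM is
  called, 99.9 is not).
* The chi-square excludes zero-coverage positions and reports df
  accordingly; df = 0 returns p = 1.
* Empty read sets propagate as empty outputs with exit code 0.
* The element-alignment terminal offset can be over-extended by up to
  ~4 nt when TSD (or inserted) bases coincidentally match element
  interior sequence; truncations are drawn >= 5 nt so intact/truncated
  calls are unaffected.
* Determinism: every stage draws from generators spawned in fixed
  order from one seed; identical seeds give byte-identical FASTQ,
  truth tables and reports.

## Problem sizes

Test and acceptance runs use desk-scale versions of the study designs:
oracle equivalence on 10^4 random adapter cases, <= 200-nt alignment
instances, <= 30-read cluster sets and a 2-kb off-target toy genome;
junction parameter recovery on 5,000 reads over a 100-kb genome;
free-site calling on 10^5 reads over a 5-Mb genome with 8 planted
sites; the polymorphism contrast on 2,000 reads per arm. The pipeline
is genome-size-agnostic but untested beyond tens of Mb.

## Known limitations

* The insertion-site offset inherits the clip-vs-gap ambiguity of
  flank-only mapping near the junction (see above); the variant
  profiles, which align across the junction, are the cleaner read-out
  of the edit spectrum.
* `align_local` tie-breaking among equal-scoring alignments is
  deterministic but not guaranteed to pick the smallest reference
  start on every tie topology.
* The off-target scan reports one hit per qualifying PAM; overlapping
  PAMs near one protospacer-like region produce multiple hits, as with
  standard off-target finders.
* Only the NGG PAM dialect is implemented; IUPAC degeneracy is honoured
  in primers but protospacers are exact-ACGT.
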