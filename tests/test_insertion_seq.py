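"""Insertion-seq pipeline stages: trimming, TE-prefix extraction, donor
filtering, site assignment, binning/RPM, free-site calling, replicate
overlap and the protospacer similarity scan."""

import dataclasses

import numpy as np
import pytest

from oracles import grna_oracle
from temap.core_model import GenomeRef
from temap.insertion_seq import (
    BIN_SIZE,
    BinTrack,
    assign_sites,
    bin_and_normalize,
    call_free_sites,
    extract_te_flank,
    filter_donor,
    grna_similarity_scan,
    replicate_overlap,
    restrict_to_grna_similar,
    run_insertion_seq,
    target_bins_for_locus,
    trim_vector_adapter,
)
from temap.io_utils import SeqRead, revcomp
from temap.synthetic_data import (
    VECTOR_ADAPTER,
    SimConfig,
    make_references,
    simulate_free_transposition,
)

BASES = np.array(list("ACGT"))


def rand_dna(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestVectorAdapterTrim:
    def test_exact_adapter_and_downstream_removed(self):
        rng = np.random.default_rng(0)
        core = rand_dna(rng, 100)
        read = SeqRead("r", core + VECTOR_ADAPTER + rand_dna(rng, 30))
        out = trim_vector_adapter([read])[0]
        assert out.seq == core

    def test_read_without_adapter_unchanged(self):
        rng = np.random.default_rng(1)
        read = SeqRead("r", rand_dna(rng, 120))
        assert trim_vector_adapter([read])[0].seq == read.seq

    def test_adapter_with_two_errors_trimmed(self):
        # floor(0.1 * 21) = 2 edits allowed on the 21-nt adapter
        rng = np.random.default_rng(2)
        core = rand_dna(rng, 90)
        bad = list(VECTOR_ADAPTER)
        bad[4] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[4]]
        bad[15] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[15]]
        read = SeqRead("r", core + "".join(bad) + rand_dna(rng, 10))
        assert trim_vector_adapter([read])[0].seq == core

    def test_low_quality_tail_removed_first(self):
        rng = np.random.default_rng(3)
        core = rand_dna(rng, 80)
        read = SeqRead("r", core + rand_dna(rng, 15), [35] * 80 + [2] * 15)
        assert trim_vector_adapter([read])[0].seq == core


class TestExtractTeFlank:
    def test_exact_prefix_trimmed(self, refs, small_cfg):
        prefix = refs.te.sequence[-small_cfg.te_prefix_len:]
        rng = np.random.default_rng(4)
        flank = rand_dna(rng, 120)
        kept, counts = extract_te_flank([SeqRead("r", prefix + flank)], prefix)
        assert counts["kept"] == 1
        assert kept[0].seq == flank

    def test_non_te_read_dropped(self, refs, small_cfg):
        prefix = refs.te.sequence[-small_cfg.te_prefix_len:]
        rng = np.random.default_rng(5)
        kept, counts = extract_te_flank([SeqRead("r", rand_dna(rng, 200))], prefix)
        assert kept == [] and counts["no_te_prefix"] == 1

    def test_29nt_flank_dropped_30_kept(self, refs, small_cfg):
        prefix = refs.te.sequence[-small_cfg.te_prefix_len:]
        rng = np.random.default_rng(6)
        r29 = SeqRead("a", prefix + rand_dna(rng, 29))
        r30 = SeqRead("b", prefix + rand_dna(rng, 30))
        kept, counts = extract_te_flank([r29, r30], prefix)
        assert [r.id for r in kept] == ["b"]
        assert counts["short_flank"] == 1

    def test_read_conservation(self, insertion_sim, refs, small_cfg):
        _, reads = insertion_sim
        prefix = refs.te.sequence[-small_cfg.te_prefix_len:]
        kept, counts = extract_te_flank(trim_vector_adapter(reads), prefix)
        assert counts["kept"] + counts["no_te_prefix"] + counts["short_flank"] == counts["input"]
        assert counts["input"] == len(reads)


class TestDonorFilter:
    def test_donor_flank_removed_genomic_kept(self, refs):
        te_end = refs.donor.te_span[1]
        donor_flank = SeqRead("d", refs.donor.construct_seq[te_end : te_end + 120])
        genomic = SeqRead("g", refs.genome["chr2"][4000:4120])
        kept, dropped = filter_donor([donor_flank, genomic], refs.donor.construct_seq)
        assert dropped == 1
        assert [r.id for r in kept] == ["g"]

    def test_empty_input(self, refs):
        kept, dropped = filter_donor([], refs.donor.construct_seq)
        assert kept == [] and dropped == 0


class TestAssignSites:
    def test_planted_site_recovered_both_strands(self, refs):
        seq = refs.genome["chr1"]
        fwd = SeqRead("f", seq[9000:9200])
        rev = SeqRead("r", revcomp(seq[8800:9000]))
        sites, counts = assign_sites([fwd, rev], refs.genome)
        assert counts["mapped"] == 2
        assert sites[0] == ("chr1", 9000, "+")
        # junction-adjacent base of the minus-strand read is the alignment end
        assert sites[1] == ("chr1", 8999, "-")

    def test_naive_start_reports_leftmost_base(self, refs):
        seq = refs.genome["chr1"]
        rev = SeqRead("r", revcomp(seq[8800:9000]))
        sites, _ = assign_sites([rev], refs.genome, naive_start=True)
        assert sites[0] == ("chr1", 8800, "-")

    def test_unmapped_read_counted_and_dropped(self, refs):
        rng = np.random.default_rng(7)
        sites, counts = assign_sites([SeqRead("x", rand_dna(rng, 100))], refs.genome)
        assert sites == []
        assert counts["unmapped"] + counts["low_score"] == 1


class TestBinning:
    def test_rpm_arithmetic(self, refs):
        sites = [("chr1", 1234, "+")] * 500
        track = bin_and_normalize(sites, refs.genome, total_raw_reads=1_000_000)
        assert track.rpm(("chr1", 123)) == pytest.approx(500.0)

    def test_bin_boundary_splits_sites(self, refs):
        sites = [("chr1", 19, "+"), ("chr1", 20, "+")]
        track = bin_and_normalize(sites, refs.genome, 100)
        assert track.raw[("chr1", 1)] == 1 and track.raw[("chr1", 2)] == 1

    def test_count_conservation_and_rpm_identity(self, refs):
        rng = np.random.default_rng(8)
        sites = [("chr2", int(rng.integers(0, 20_000)), "+") for _ in range(777)]
        track = bin_and_normalize(sites, refs.genome, 10_000)
        assert track.n_assigned == 777
        total_rpm = sum(track.rpm(k) for k in track.raw)
        assert total_rpm * 10_000 / 1e6 == pytest.approx(777)


class TestFreeSiteCalling:
    def test_threshold_is_inclusive_boundary(self, refs):
        # 100.0 RPM is called (>= threshold); 99.9 RPM is not
        track = BinTrack(bin_size=10, total_raw_reads=10_000)
        track.raw = {("chr1", 5): 1, ("chr1", 9): 2}  # 100.0 and 200.0 RPM
        free, _ = call_free_sites(track, threshold_rpm=100.0)
        assert {(s.ref, s.bin_index) for s in free} == {("chr1", 5), ("chr1", 9)}
        below = BinTrack(bin_size=10, total_raw_reads=10_010)
        below.raw = {("chr1", 5): 1, ("chr1", 9): 2}  # 99.9 and 199.8 RPM
        free, _ = call_free_sites(below, threshold_rpm=100.0)
        assert {(s.ref, s.bin_index) for s in free} == {("chr1", 9)}

    def test_target_bin_flagged_and_excluded(self, refs):
        track = BinTrack(bin_size=10, total_raw_reads=1000)
        tb = next(iter(target_bins_for_locus(refs.locus)))
        track.raw = {tb: 500, ("chr2", 3): 50}
        free, flagged = call_free_sites(track, 100.0, target_bins_for_locus(refs.locus))
        assert [s.is_target_site for s in flagged] == [True]
        assert {(s.ref, s.bin_index) for s in free} == {("chr2", 3)}

    def test_sorted_by_rpm_descending(self, refs):
        track = BinTrack(bin_size=10, total_raw_reads=1000)
        track.raw = {("chr1", i): c for i, c in enumerate([5, 50, 20])}
        free, _ = call_free_sites(track, 100.0)
        assert [s.rpm for s in free] == sorted((s.rpm for s in free), reverse=True)


class TestReplicateOverlap:
    def test_disjoint_identical_partial(self):
        a = [("chr1", 1), ("chr1", 5), ("chr2", 9)]
        b = [("chr1", 5), ("chr2", 9), ("chr2", 40)]
        assert replicate_overlap(a, []) == (3, 0, 0)
        assert replicate_overlap(a, a) == (0, 0, 3)
        assert replicate_overlap(a, b) == (1, 1, 2)

    def test_slop_bins(self):
        a = [("chr1", 10)]
        b = [("chr1", 11)]
        assert replicate_overlap(a, b) == (1, 1, 0)
        assert replicate_overlap(a, b, slop_bins=1) == (0, 0, 1)


class TestGrnaScan:
    def test_exact_protospacer_hit(self):
        rng = np.random.default_rng(9)
        proto = rand_dna(rng, 20)
        g = GenomeRef({"c": rand_dna(rng, 200) + proto + "AGG" + rand_dna(rng, 200)})
        hits = grna_similarity_scan(g, proto, max_mismatch=0, max_bulge=0)
        assert any(h.position == 200 and h.strand == "+" and h.mismatches == 0
                   and h.bulge_nt == 0 for h in hits)

    def test_too_many_mismatches_absent(self):
        rng = np.random.default_rng(10)
        proto = "A" * 20
        window = "C" * 10 + "A" * 10  # 10 mismatches
        g = GenomeRef({"c": rand_dna(rng, 50) + window + "AGG" + rand_dna(rng, 50)})
        hits = grna_similarity_scan(g, proto, max_mismatch=9, max_bulge=0)
        # the window in front of the planted PAM (N at +70) has 10 mismatches
        assert all(not (h.pam_position == 70 and h.strand == "+") for h in hits)
        # at a 10-mismatch budget it is reported
        lax = grna_similarity_scan(g, proto, max_mismatch=10, max_bulge=0)
        assert any(h.pam_position == 70 and h.strand == "+" and h.mismatches == 10
                   for h in lax)

    def test_matches_enumeration_oracle_on_toy_genome(self):
        """Scan decisions equal exhaustive gap-placement enumeration."""
        rng = np.random.default_rng(11)
        proto = rand_dna(rng, 20)
        seq = rand_dna(rng, 800)
        # plant near-matches: 2 mismatches; 1-nt bulge each way
        mut = list(proto)
        mut[4] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[4]]
        mut[15] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[15]]
        seq = seq[:100] + "".join(mut) + "CGG" + seq[123:]
        seq = seq[:300] + (proto[:8] + proto[9:]) + "TGG" + seq[322:]
        seq = seq[:500] + (proto[:12] + "A" + proto[12:]) + "AGG" + seq[524:]
        g = GenomeRef({"toy": seq})
        max_mm, max_bulge = 3, 2
        got = {
            (h.strand, h.pam_position, h.mismatches, h.bulge_nt)
            for h in grna_similarity_scan(g, proto, max_mismatch=max_mm, max_bulge=max_bulge)
        }
        expected = grna_oracle(seq, proto, max_mm, max_bulge)
        assert got == expected

    def test_restrict_free_sites_to_similar_bins(self, refs):
        hits = [type("H", (), {"ref": "chr1", "position": 100})()]
        from temap.insertion_seq import FreeSite
        near = FreeSite("chr1", 110, 500.0, False, (1, 0))
        far = FreeSite("chr1", 900, 500.0, False, (1, 0))
        assert restrict_to_grna_similar([near, far], hits) == [near]


@pytest.fixture(scope="module")
def flat_cfg():
    return SimConfig(
        seed=31, n_reads=2000, genome_len=100_000, n_chroms=2,
        error_rate=0.001, free_site_weight_ratio=0.8,
        target_fraction=0.05, donor_fraction=0.1, noise_fraction=0.05,
    )


class TestEndToEnd:

    def test_planted_free_sites_recovered_exactly(self, flat_cfg):
        refs = make_references(flat_cfg)
        events, reads = simulate_free_transposition(flat_cfg, refs)
        prefix = refs.te.sequence[-flat_cfg.te_prefix_len:]
        res = run_insertion_seq(reads, refs.genome, refs.donor.construct_seq,
                                refs.locus, prefix, threshold_rpm=5000.0)
        truth = {(e.ref, e.insertion_coord // BIN_SIZE) for e in events if e.kind == "free"}
        called = {(s.ref, s.bin_index) for s in res.free_sites}
        assert called == truth
        assert len(res.target_sites) == 1

    def test_channelling_decreases_free_site_count(self, flat_cfg):
        refs = make_references(flat_cfg)
        prefix = refs.te.sequence[-flat_cfg.te_prefix_len:]
        chan = dataclasses.replace(flat_cfg, target_fraction=0.90,
                                   donor_fraction=0.05, noise_fraction=0.0)
        counts = {}
        for label, cfg in (("base", flat_cfg), ("chan", chan)):
            _, reads = simulate_free_transposition(cfg, refs)
            res = run_insertion_seq(reads, refs.genome, refs.donor.construct_seq,
                                    refs.locus, prefix, threshold_rpm=5000.0)
            counts[label] = res.n_free_sites
        assert counts["chan"] < counts["base"]

    def test_stage_read_conservation(self, insertion_sim, refs, small_cfg):
        _, reads = insertion_sim
        prefix = refs.te.sequence[-small_cfg.te_prefix_len:]
        res = run_insertion_seq(reads, refs.genome, refs.donor.construct_seq,
                                refs.locus, prefix)
        c = res.stage_counts
        assert c["te_prefix_reads"] + c["no_te_prefix"] + c["short_flank"] == c["raw_reads"]
        assert (c["mapped"] + c["unmapped"] + c["low_score"] + c["multimap"]
                + c["donor_filtered"] + c["no_te_prefix"] + c["short_flank"]) == c["raw_reads"]
        assert res.track.n_assigned == len(res.sites) == c["mapped"]
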