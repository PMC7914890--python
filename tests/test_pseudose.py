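"""Pair merging, combined qualities, mismatch filtering, oligo(A) exemption."""
from __future__ import annotations

import pytest

from stablefrag.pseudose import (
    DiscordantPair,
    PseudoSEConfig,
    merge_pair,
    mismatch_filter,
    passthrough_se,
    pseudose_convert,
)
from stablefrag.records import AlignmentRecord, PairedUnit, ReadAlignmentGroup
from stablefrag.seqs import Genome, revcomp


def _pair(genome, chrom, s1, e1, s2, e2, q1=35, q2=35, seq1=None, seq2=None, rid="p"):
    """Concordant pair: mate1 plus-strand [s1,e1), mate2 minus-strand [s2,e2)."""
    b1 = seq1 if seq1 is not None else genome.fetch(chrom, s1, e1)
    b2g = seq2 if seq2 is not None else genome.fetch(chrom, s2, e2)
    a1 = AlignmentRecord(rid, chrom, "+", s1, e1, 0, (), 1, False, b1, (q1,) * (e1 - s1))
    a2 = AlignmentRecord(rid, chrom, "-", s2, e2, 0, (), 2, False, revcomp(b2g), (q2,) * (e2 - s2))
    return a1, a2


class TestMergePair:
    def test_overlap_agreeing_quality_sums_capped(self, genome2k):
        a1, a2 = _pair(genome2k, "chrSim", 100, 130, 110, 140, q1=35, q2=35)
        m = merge_pair(a1, a2, genome2k)
        assert (m.start0, m.end0) == (100, 140)
        assert m.bases == genome2k.fetch("chrSim", 100, 140)
        assert m.quals[10:30] == [41] * 20  # overlap: min(35+35, 41)
        assert m.quals[:10] == [35] * 10 and m.quals[30:] == [35] * 10
        assert m.gap_filled == 0

    def test_gap_filled_from_genome_at_max_quality(self, genome2k):
        a1, a2 = _pair(genome2k, "chrSim", 100, 120, 130, 150)
        m = merge_pair(a1, a2, genome2k)
        assert (m.start0, m.end0) == (100, 150)
        assert m.bases[20:30] == genome2k.fetch("chrSim", 120, 130)
        assert m.quals[20:30] == [41] * 10
        assert m.gap_filled == 10

    def test_disagreement_keeps_higher_quality_base_at_quality_difference(self, genome2k):
        ref = genome2k.fetch("chrSim", 100, 130)
        # force position 15 to disagree between mates: mate1 A (q40), mate2 C (q20)
        seq1 = ref[:15] + "A" + ref[16:]
        seq2 = ref[:15] + "C" + ref[16:]
        a1 = AlignmentRecord("p", "chrSim", "+", 100, 130, 0, (), 1, False, seq1, (40,) * 30)
        a2 = AlignmentRecord(
            "p", "chrSim", "-", 100, 130, 0, (), 2, False, revcomp(seq2), (20,) * 30
        )
        m = merge_pair(a1, a2, genome2k)
        assert m.bases[15] == "A"
        assert m.quals[15] == 20  # 40 - 20

    def test_minus_strand_insert_keeps_mate1_strand(self, genome2k):
        # insert on '-': mate1 aligns '-', mate2 '+'
        ref = genome2k.fetch("chrSim", 200, 240)
        a1 = AlignmentRecord("p", "chrSim", "-", 210, 240, 0, (), 1, False,
                             revcomp(ref[10:]), (35,) * 30)
        a2 = AlignmentRecord("p", "chrSim", "+", 200, 230, 0, (), 2, False,
                             ref[:30], (35,) * 30)
        m = merge_pair(a1, a2, genome2k)
        assert m.strand == "-"
        assert (m.start0, m.end0) == (200, 240)
        assert m.bases == ref

    def test_discordant_raises(self, genome2k):
        a1, a2 = _pair(genome2k, "chrSim", 100, 130, 110, 140)
        bad = AlignmentRecord("p", "chrSim", "+", 110, 140, 0, (), 2, False, a2.seq, a2.quals)
        with pytest.raises(DiscordantPair):
            merge_pair(a1, bad, genome2k)

    def test_merged_quality_bounds(self, genome2k):
        a1, a2 = _pair(genome2k, "chrSim", 300, 340, 320, 360, q1=12, q2=30)
        m = merge_pair(a1, a2, genome2k)
        assert all(0 <= q <= 41 for q in m.quals)
        assert all(q >= 12 for q in m.quals[20:40])  # agreeing overlap >= min(q1,q2)


def _interval_without_terminal_A(genome, length=30):
    """First interval whose final three genomic bases contain no A, so an
    appended AAA tail is fully untemplated."""
    seq = genome.seqs["chrSim"]
    for e in range(length, len(seq)):
        if "A" not in seq[e - 3 : e]:
            return e - length, e
    raise AssertionError("no suitable interval in fixture genome")


class TestMismatchFilter:
    def test_untemplated_terminal_As_exempted(self, genome2k):
        s, e = _interval_without_terminal_A(genome2k)
        ref = genome2k.fetch("chrSim", s, e)
        seq = ref[:-3] + "AAA"
        a = AlignmentRecord("r", "chrSim", "+", s, e, -18, (), 0, False, seq, (40,) * 30)
        ps = passthrough_se(a)
        status = mismatch_filter(ps, genome2k, max_mm=2, oligoA_exempt=True)
        assert status == "kept" and ps.oligoA_len == 3 and ps.n_mismatch == 0

    def test_exemption_off_discards(self, genome2k):
        s, e = _interval_without_terminal_A(genome2k)
        ref = genome2k.fetch("chrSim", s, e)
        seq = ref[:-3] + "AAA"
        ps = passthrough_se(
            AlignmentRecord("r", "chrSim", "+", s, e, -18, (), 0, False, seq, (40,) * 30)
        )
        status = mismatch_filter(ps, genome2k, max_mm=2, oligoA_exempt=False)
        assert status == "discarded_mm" and ps.n_mismatch == 3

    def test_internal_mismatches_never_exempted(self, genome2k):
        s, e = 500, 530
        ref = genome2k.fetch("chrSim", s, e)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        seq = "".join(flip[c] if i in (5, 10, 15) else c for i, c in enumerate(ref))
        ps = passthrough_se(
            AlignmentRecord("r", "chrSim", "+", s, e, -18, (), 0, False, seq, (40,) * 30)
        )
        assert mismatch_filter(ps, genome2k, max_mm=2, oligoA_exempt=True) == "discarded_mm"

    def test_templated_terminal_As_not_counted_as_tail(self, genome2k):
        # interval ending in a genomic A: that base matches, so oligoA_len stays 0
        seq0 = genome2k.seqs["chrSim"]
        e = seq0.index("A", 600) + 1
        s = e - 30
        ps = passthrough_se(
            AlignmentRecord("r", "chrSim", "+", s, e, 0, (), 0, False,
                            genome2k.fetch("chrSim", s, e), (40,) * 30)
        )
        assert mismatch_filter(ps, genome2k) == "kept"
        assert ps.oligoA_len == 0 and ps.n_mismatch == 0

    def test_minus_strand_tail_is_leftmost_genomic_Ts(self, genome2k):
        # on '-', the read's 3' end is the genomic left edge; untemplated A's
        # appear there as T's in the genome-forward record
        seq0 = genome2k.seqs["chrSim"]
        s = next(i for i in range(600, 1900) if "T" not in seq0[i : i + 2])
        e = s + 30
        ref = genome2k.fetch("chrSim", s, e)
        oriented = revcomp(ref)[:-2] + "AA"  # mismatching tail by construction
        a = AlignmentRecord("r", "chrSim", "-", s, e, -12, (), 0, False, oriented, (40,) * 30)
        ps = passthrough_se(a)
        status = mismatch_filter(ps, genome2k, max_mm=0, oligoA_exempt=True)
        assert status == "kept" and ps.oligoA_len == 2


class TestPassthroughAndConvert:
    def test_passthrough_has_no_gap_fill(self, genome2k):
        a = AlignmentRecord("r", "chrSim", "+", 100, 130, 0, (), 0, False,
                            genome2k.fetch("chrSim", 100, 130), (33,) * 30)
        ps = passthrough_se(a)
        assert ps.gap_filled == 0
        assert ps.length == 30 == len(ps.bases) == len(ps.quals)

    def test_nh_equals_retained_mapping_count(self, genome_dup):
        genome, truth = genome_dup
        (s1, e1), (s2, e2) = truth.duplicated_loci[0]
        seq = genome.fetch("chrSim", s1 + 5, s1 + 35)
        units = [
            AlignmentRecord("r", "chrSim", "+", s1 + 5, s1 + 35, 0, (), 0, False, seq, (40,) * 30),
            AlignmentRecord("r", "chrSim", "+", s2 + 5, s2 + 35, 0, (), 0, False, seq, (40,) * 30),
        ]
        kept, _, t = pseudose_convert(
            [ReadAlignmentGroup("r", units)], genome, PseudoSEConfig()
        )
        assert len(kept) == 2 and all(m.nh == 2 for m in kept)
        assert t["kept_reads"] == 1 and t["kept_mappings"] == 2

    def test_max_nh_discards_multimapper(self, genome_dup):
        genome, truth = genome_dup
        (s1, e1), (s2, e2) = truth.duplicated_loci[0]
        seq = genome.fetch("chrSim", s1 + 5, s1 + 35)
        units = [
            AlignmentRecord("r", "chrSim", "+", s, s + 30, 0, (), 0, False, seq, (40,) * 30)
            for s in (s1 + 5, s2 + 5)
        ]
        kept, sidecars, t = pseudose_convert(
            [ReadAlignmentGroup("r", units)], genome, PseudoSEConfig(max_nh=1)
        )
        assert kept == [] and t["discarded_multi"] == 1
        assert len(sidecars["too_many_hits"]) == 2

    def test_conservation_identity(self, genome2k):
        cfg = PseudoSEConfig(max_mm=0)
        groups = []
        ref = genome2k.fetch("chrSim", 100, 130)
        ok = AlignmentRecord("a", "chrSim", "+", 100, 130, 0, (), 0, False, ref, (40,) * 30)
        bad_seq = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in ref[:3]) + ref[3:]
        bad = AlignmentRecord("b", "chrSim", "+", 100, 130, -18, (), 0, False, bad_seq, (40,) * 30)
        groups = [ReadAlignmentGroup("a", [ok]), ReadAlignmentGroup("b", [bad])]
        kept, _, t = pseudose_convert(groups, genome2k, cfg)
        assert t["kept_reads"] + t["discarded_mm"] + t["discarded_multi"] == t["input_reads"] == 2
        assert [m.read_id for m in kept] == ["a"]


def test_zero_noise_round_trip_all_inserts_genomic():
    """Zero-jitter, no-oligoA PE simulation: every merged insert equals its
    genomic substring exactly, and the conservation identity holds."""
    from stablefrag.align import AlignParams
    from stablefrag.simdata import (
        DEFAULT_ADAPTER3, make_annotation, make_genome, plant_products, simulate_reads,
    )
    from stablefrag.stratum import sensitive_align
    from stablefrag.trim import TrimConfig, trim_library

    genome, truth = make_genome(15000, 0.5, seed=50)
    feats = make_annotation(truth, {"tRNA": 3, "ncRNA": 2})
    plant_products(truth, feats, n_intergenic=1, abundance=30)
    sim = simulate_reads(genome, truth, end_jitter_sd=0, paired=True,
                         oligoA_rate=0.0, noise_read_rate=0.0, seed=51)
    kept, *_ = trim_library(list(zip(sim.r1, sim.r2)), "PE", TrimConfig(adapter3=DEFAULT_ADAPTER3))
    groups, unaligned, _ = sensitive_align(kept, genome, AlignParams())
    mappings, _, t = pseudose_convert(groups, genome, PseudoSEConfig())
    assert t["kept_reads"] + t["discarded_mm"] + t["discarded_multi"] == t["input_reads"]
    assert mappings, "no mappings survived"
    for m in mappings:
        assert m.bases == genome.fetch("chrSim", m.start0, m.end0)
        assert m.n_mismatch == 0
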