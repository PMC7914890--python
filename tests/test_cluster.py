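"""Relative coverage, candidate filtering, overlap/sequence clustering, contigs."""
from __future__ import annotations

import numpy as np
import pytest

from stablefrag.cluster import (
    ClusterConfig,
    build_contigs,
    cluster_by_overlap,
    cluster_by_sequence,
    attach_sequences,
    combine_unique,
    coverage_arrays,
    endpoint_distance,
    filter_candidates,
    relative_coverage,
    sliding_identity,
)
from stablefrag.records import Contig, ProcessingProduct, PseudoSERead
from stablefrag.seqs import Genome


def _map(chrom, strand, s, e, rid="r", nh=1):
    n = e - s
    return PseudoSERead(rid, chrom, strand, s, e, "A" * n, [40] * n, nh=nh)


def _prod(s, e, strand="+", chrom="c", count=0, lib="lib"):
    p = ProcessingProduct(chrom, strand, s, e)
    if count:
        p.counts[lib] = count
    return p


@pytest.fixture(scope="module")
def flat_genome():
    return Genome({"c": "ACGT" * 1000})


class TestRelativeCoverage:
    def test_formula(self, flat_genome):
        # 8 assigned + 2 background reads over the same interval: 8/10
        assigned = [_map("c", "+", 100, 130, rid=f"a{i}") for i in range(8)]
        background = [_map("c", "+", 100, 130, rid=f"b{i}") for i in range(2)]
        p = _prod(100, 130)
        acov = coverage_arrays(assigned, flat_genome)
        allcov = coverage_arrays(assigned + background, flat_genome)
        assert relative_coverage(p, acov, allcov) == pytest.approx(0.8)

    def test_identity_when_only_reads(self, flat_genome):
        reads = [_map("c", "+", 100, 130, rid=f"a{i}") for i in range(5)]
        cov = coverage_arrays(reads, flat_genome)
        assert relative_coverage(_prod(100, 130), cov, cov) == 1.0

    def test_zero_when_nothing_aligned(self, flat_genome):
        assert relative_coverage(_prod(100, 130), {}, {}) == 0.0

    def test_always_within_unit_interval(self, flat_genome):
        rng = np.random.default_rng(8)
        reads = [
            _map("c", "+", int(s), int(s) + 30, rid=f"r{i}")
            for i, s in enumerate(rng.integers(0, 3000, size=50))
        ]
        allcov = coverage_arrays(reads, flat_genome)
        for s in range(0, 3000, 97):
            p = _prod(s, s + 30)
            sub = [r for r in reads if r.start0 <= s and s + 30 <= r.end0]
            acov = coverage_arrays(sub, flat_genome) if sub else {}
            rc = relative_coverage(p, acov, allcov)
            assert 0.0 <= rc <= 1.0


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "count,relcov,kept",
        [(12, 0.9, True), (12, 0.1, False), (9, 0.9, False), (10, 0.5, True)],
    )
    def test_truth_table(self, count, relcov, kept):
        p = _prod(0, 30, count=count)
        p.relative_coverage["lib"] = relcov
        out = filter_candidates([p], min_count=10, min_relcov=0.5, library="lib")
        assert (out == [p]) is kept

    def test_zero_min_relcov_disables_background_filter(self):
        p = _prod(0, 30, count=10)
        p.relative_coverage["lib"] = 0.0
        assert filter_candidates([p], 10, 0.0, "lib") == [p]


from _oracles import oracle_overlap_cluster  # noqa: E402  (test-local oracle)


class TestClusterByOverlap:
    def test_hand_example_leftmost_tiebreak(self):
        p1, p2, p3 = _prod(100, 140), _prod(101, 141), _prod(100, 170)
        clusters = cluster_by_overlap([p1, p2, p3], tolerance=2)
        assert [c.representative for c in clusters] == [p1, p3]
        assert clusters[0].members == [p1, p2]

    def test_tolerance_zero_gives_singletons(self):
        ps = [_prod(100, 130), _prod(101, 130), _prod(200, 230)]
        clusters = cluster_by_overlap(ps, tolerance=0)
        assert len(clusters) == 3

    def test_representative_is_member_and_within_tolerance(self):
        rng = np.random.default_rng(9)
        ps = [
            _prod(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 500, 40), rng.integers(20, 40, 40))
        ]
        for c in cluster_by_overlap(ps, tolerance=3):
            assert c.representative in c.members
            for m in c.members:
                assert endpoint_distance(c.representative, m) <= 3

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(10)
        for trial in range(50):
            n = int(rng.integers(2, 13))
            ps = []
            for i in range(n):
                s = int(rng.integers(0, 60))
                ps.append(_prod(s, s + int(rng.integers(20, 30)), count=int(rng.integers(1, 50))))
            tol = int(rng.integers(0, 6))
            got = [
                (c.representative.key, tuple(sorted(m.key for m in c.members)))
                for c in cluster_by_overlap(ps, tol)
            ]
            want = [
                (ps[i].key, tuple(sorted(ps[j].key for j in cov)))
                for i, cov in oracle_overlap_cluster(ps, tol)
            ]
            assert got == want

    def test_clusters_partition_input(self):
        rng = np.random.default_rng(11)
        ps = [
            _prod(int(s), int(s) + 25)
            for s in rng.integers(0, 200, size=30)
        ]
        ps = list({p.key: p for p in ps}.values())  # unique, as contracted
        clusters = cluster_by_overlap(ps, tolerance=2)
        seen = [m.key for c in clusters for m in c.members]
        assert sorted(seen) == sorted(p.key for p in ps)

    def test_raising_tolerance_never_increases_representatives(self):
        rng = np.random.default_rng(12)
        ps = list({
            (int(s), int(s) + 24): _prod(int(s), int(s) + 24)
            for s in rng.integers(0, 100, size=20)
        }.values())
        n_prev = None
        for tol in (0, 2, 5, 10):
            n = len(cluster_by_overlap(ps, tol))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestContigs:
    def test_single_island(self, flat_genome):
        reads = [_map("c", "+", 95, 130), _map("c", "+", 120, 160)]
        contigs = build_contigs(reads, flat_genome)
        assert [(c.start0, c.end0) for c in contigs] == [(95, 160)]
        assert contigs[0].sequence == flat_genome.fetch("c", 95, 160)

    def test_zero_coverage_base_splits_contigs(self, flat_genome):
        reads = [_map("c", "+", 100, 130), _map("c", "+", 131, 160)]
        contigs = build_contigs(reads, flat_genome)
        assert [(c.start0, c.end0) for c in contigs] == [(100, 130), (131, 160)]

    def test_strands_kept_separate(self, flat_genome):
        reads = [_map("c", "+", 100, 130), _map("c", "-", 110, 140)]
        contigs = build_contigs(reads, flat_genome)
        assert {(c.strand, c.start0, c.end0) for c in contigs} == {
            ("+", 100, 130), ("-", 110, 140),
        }


class TestSlidingIdentity:
    def test_exact_substring(self):
        assert sliding_identity("ACGT", "TTACGTTT") == 1.0

    def test_best_offset_chosen(self):
        assert sliding_identity("AAAA", "CAAAAC") == 1.0
        assert sliding_identity("AAAT", "CCAAAACC") == pytest.approx(0.75)


def _dup_genome():
    """Genome with a 60-bp segment duplicated exactly, and a second pair of
    loci sharing the 30-bp core but with different flanks."""
    rng = np.random.default_rng(13)
    core = "".join(rng.choice(list("ACGT"), 30))
    ctx = "".join(rng.choice(list("ACGT"), 15))
    seg = ctx + core + ctx
    other_flank = "".join(rng.choice(list("ACGT"), 15))
    filler = lambda n: "".join(rng.choice(list("ACGT"), n))
    seq = filler(200) + seg + filler(200) + seg + filler(200) \
        + other_flank + core + other_flank + filler(200)
    g = Genome({"c": seq})
    dup1 = 200 + 15          # core at first copy
    dup2 = 200 + 60 + 200 + 15
    diff = 200 + 60 + 200 + 60 + 200 + 15
    return g, core, dup1, dup2, diff


class TestClusterBySequence:
    def test_identical_products_in_identical_context_merge(self):
        g, core, dup1, dup2, _ = _dup_genome()
        p1 = _prod(dup1, dup1 + 30, chrom="c", count=5)
        p2 = _prod(dup2, dup2 + 30, chrom="c", count=3)
        reads = [_map("c", "+", dup1 - 15, dup1 + 45), _map("c", "+", dup2 - 15, dup2 + 45)]
        contigs = build_contigs(reads, g)
        attach_sequences([p1, p2], g)
        finals, membership = cluster_by_sequence([p1, p2], contigs)
        assert len(finals) == 1
        assert finals[0].total_count == 8  # member counts merged

    def test_identical_products_in_different_context_not_merged(self):
        g, core, dup1, _, diff = _dup_genome()
        p1 = _prod(dup1, dup1 + 30, chrom="c")
        p2 = _prod(diff, diff + 30, chrom="c")
        reads = [_map("c", "+", dup1 - 15, dup1 + 45), _map("c", "+", diff - 15, diff + 45)]
        contigs = build_contigs(reads, g)
        attach_sequences([p1, p2], g)
        finals, _ = cluster_by_sequence([p1, p2], contigs)
        assert len(finals) == 2

    def test_contig_length_ratio_below_cutoff_blocks_merge(self):
        g, core, dup1, dup2, _ = _dup_genome()
        p1 = _prod(dup1, dup1 + 30, chrom="c")
        p2 = _prod(dup2, dup2 + 30, chrom="c")
        # contig at copy 2 is 2.5x longer than at copy 1: ratio 0.4 < 0.5
        reads = [_map("c", "+", dup1 - 5, dup1 + 35)] + [
            _map("c", "+", dup2 - 35, dup2 + 65, rid=f"w{i}") for i in range(3)
        ]
        contigs = build_contigs(reads, g)
        lens = sorted(c.length for c in contigs)
        assert lens[0] / lens[1] < 0.5
        attach_sequences([p1, p2], g)
        finals, _ = cluster_by_sequence([p1, p2], contigs)
        assert len(finals) == 2

    def test_idempotent_on_final_representatives(self):
        g, core, dup1, dup2, _ = _dup_genome()
        p1 = _prod(dup1, dup1 + 30, chrom="c", count=5)
        p2 = _prod(dup2, dup2 + 30, chrom="c", count=3)
        reads = [_map("c", "+", dup1 - 15, dup1 + 45), _map("c", "+", dup2 - 15, dup2 + 45)]
        contigs = build_contigs(reads, g)
        attach_sequences([p1, p2], g)
        finals, _ = cluster_by_sequence([p1, p2], contigs)
        again, membership = cluster_by_sequence(finals, contigs)
        assert again == finals


def test_combine_unique_merges_library_annotations():
    a = _prod(100, 130, count=5, lib="l1")
    b = _prod(100, 130, count=7, lib="l2")
    c = _prod(200, 230, count=3, lib="l1")
    combined = combine_unique({"l1": [a, c], "l2": [b]})
    assert len(combined) == 2
    first = [p for p in combined if p.start0 == 100][0]
    assert first.counts == {"l1": 5, "l2": 7}
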