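"""Redundancy reduction across libraries.

Per-library products are filtered by assigned read count and by relative
coverage (mean depth of assigned reads over the product interval divided by
mean depth of all same-strand reads there - low values mean the candidate
sits on a high background and is likely a shoulder of something else).
Unique candidates are then clustered twice: by overlap (endpoint distance)
with greedy maximum-coverage representative selection, and by sequence
identity gated on the similarity of the surrounding coverage contigs, which
collapses copies of the same product at duplicated loci without conflating
identical sequences from genuinely different contexts.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .records import Contig, OverlapCluster, ProcessingProduct
from .seqs import Genome, seq_to_array


@dataclass
class ClusterConfig:
    min_count: int = 10
    min_relcov: float = 0.5
    tolerance: int = 2
    id_contig: float = 0.9
    len_cutoff: float = 0.5


def coverage_arrays(mappings, genome: Genome):
    """Per (chrom, strand) depth vectors from a set of mappings."""
    cov: dict[tuple[str, str], np.ndarray] = {}
    for key in {(m.chrom, m.strand) for m in mappings}:
        cov[key] = np.zeros(genome.lengths[key[0]] + 1, dtype=np.int64)
    for m in mappings:
        a = cov[(m.chrom, m.strand)]
        a[m.start0] += 1
        a[m.end0] -= 1
    return {key: np.cumsum(a[:-1]) for key, a in cov.items()}


def mean_depth(cov: dict, chrom: str, strand: str, start0: int, end0: int) -> float:
    arr = cov.get((chrom, strand))
    if arr is None or end0 <= start0:
        return 0.0
    return float(arr[start0:end0].mean())


def relative_coverage(product, assigned_cov: dict, all_cov: dict) -> float:
    """Assigned mean depth over the product interval divided by total mean
    depth there; 0 when nothing aligns."""
    denom = mean_depth(all_cov, product.chrom, product.strand, product.start0, product.end0)
    if denom == 0:
        return 0.0
    num = mean_depth(assigned_cov, product.chrom, product.strand, product.start0, product.end0)
    return num / denom


def filter_candidates(products, min_count: int, min_relcov: float, library: str):
    """Keep products with enough assigned reads and low enough background."""
    return [
        p
        for p in products
        if p.counts.get(library, 0) >= min_count
        and p.relative_coverage.get(library, 0.0) >= min_relcov
    ]


def combine_unique(per_lib_products: dict):
    """Pool per-library product lists into unique species, merging the
    per-library counts/relative-coverage annotations."""
    by_key: dict[tuple, ProcessingProduct] = {}
    for lib in sorted(per_lib_products):
        for p in per_lib_products[lib]:
            prev = by_key.get(p.key)
            if prev is None:
                by_key[p.key] = p
            else:
                prev.counts.update(p.counts)
                prev.relative_coverage.update(p.relative_coverage)
                prev.five_support = max(prev.five_support, p.five_support)
                prev.three_support = max(prev.three_support, p.three_support)
    return sorted(by_key.values(), key=lambda p: (p.chrom, p.start0, p.end0, p.strand))


def endpoint_distance(p, q) -> float:
    """Symmetric endpoint distance; infinite across chrom/strand."""
    if (p.chrom, p.strand) != (q.chrom, q.strand):
        return float("inf")
    return abs(p.start0 - q.start0) + abs(p.end0 - q.end0)


def cluster_by_overlap(products, tolerance: int = 2) -> list[OverlapCluster]:
    """Greedy maximum-coverage clustering by endpoint distance.

    Repeatedly pick the not-yet-represented product that represents (distance
    <= tolerance) the most not-yet-represented products; ties go to the higher
    total read count, then the leftmost start.
    """
    n = len(products)
    covers = [
        {j for j in range(n) if endpoint_distance(products[i], products[j]) <= tolerance}
        for i in range(n)
    ]
    unrep = set(range(n))
    clusters = []
    while unrep:
        best = min(
            unrep,
            key=lambda i: (
                -len(covers[i] & unrep),
                -products[i].total_count,
                products[i].chrom,
                products[i].start0,
                products[i].end0,
                products[i].strand,
            ),
        )
        members = sorted(covers[best] & unrep)
        clusters.append(
            OverlapCluster(products[best], [products[j] for j in members], tolerance)
        )
        unrep -= set(members)
    return clusters


def build_contigs(mappings, genome: Genome) -> list[Contig]:
    """Maximal intervals of strictly positive pooled coverage per chrom/strand."""
    cov = coverage_arrays(mappings, genome)
    contigs = []
    for (chrom, strand) in sorted(cov):
        arr = cov[(chrom, strand)] > 0
        padded = np.concatenate([[False], arr, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            contigs.append(
                Contig(chrom, strand, int(s), int(e), genome.fetch_oriented(chrom, int(s), int(e), strand))
            )
    return contigs


def _containing_contig(product, contigs_by_cs) -> Contig | None:
    for c in contigs_by_cs.get((product.chrom, product.strand), ()):
        if c.start0 <= product.start0 and product.end0 <= c.end0:
            return c
    return None


def sliding_identity(a: str, b: str) -> float:
    """Ungapped identity of the shorter sequence within the longer, maximised
    over offsets: matches / len(shorter)."""
    if len(a) > len(b):
        a, b = b, a
    if not a:
        return 0.0
    sa = seq_to_array(a)
    sb = seq_to_array(b)
    best = 0
    for off in range(len(b) - len(a) + 1):
        best = max(best, int((sb[off : off + len(a)] == sa).sum()))
        if best == len(a):
            break
    return best / len(a)


def cluster_by_sequence(
    representatives,
    contigs,
    id_contig: float = 0.9,
    len_cutoff: float = 0.5,
):
    """Merge representatives with identical sequences from near-identical
    contexts.

    Longest-first greedy: a product joins an earlier representative iff its
    (5'->3') sequence occurs verbatim inside the representative's sequence
    (100 % identity of the shorter over its full length) AND their containing
    contigs align ungapped at >= ``id_contig`` identity with a shorter/longer
    length ratio >= ``len_cutoff``. Returns (final representatives,
    membership list of (representative, member) pairs).
    """
    contigs_by_cs: dict[tuple[str, str], list[Contig]] = defaultdict(list)
    for c in contigs:
        contigs_by_cs[(c.chrom, c.strand)].append(c)
    order = sorted(
        representatives,
        key=lambda p: (-p.length, -p.total_count, p.chrom, p.start0, p.end0, p.strand),
    )
    finals: list[ProcessingProduct] = []
    seqs: dict[int, str] = {}
    ctg: dict[int, Contig | None] = {}
    membership: list[tuple[ProcessingProduct, ProcessingProduct]] = []

    for p in order:
        pseq = getattr(p, "_oriented_seq", None)
        if pseq is None:
            raise ValueError("product sequence not attached; call attach_sequences first")
        pc = _containing_contig(p, contigs_by_cs)
        joined = False
        for fi, rep in enumerate(finals):
            if pseq not in seqs[fi]:
                continue
            rc = ctg[fi]
            if pc is None or rc is None:
                continue
            ratio = min(pc.length, rc.length) / max(pc.length, rc.length)
            if ratio < len_cutoff:
                continue
            if sliding_identity(pc.sequence, rc.sequence) < id_contig:
                continue
            membership.append((rep, p))
            for lib, c in p.counts.items():
                rep.counts[lib] = rep.counts.get(lib, 0) + c
            joined = True
            break
        if not joined:
            finals.append(p)
            seqs[len(finals) - 1] = pseq
            ctg[len(finals) - 1] = pc
            membership.append((p, p))
    finals.sort(key=lambda p: (p.chrom, p.start0, p.end0, p.strand))
    return finals, membership


def attach_sequences(products, genome: Genome) -> None:
    """Attach the 5'->3' genomic sequence to each product (used by the
    sequence-identity stage)."""
    for p in products:
        p._oriented_seq = genome.fetch_oriented(p.chrom, p.start0, p.end0, p.strand)


def cluster_products(
    per_lib_products: dict,
    per_lib_mappings: dict,
    genome: Genome,
    config: ClusterConfig,
    identify_cfg=None,
):
    """Full cluster stage.

    Computes per-library relative coverage, filters candidates, combines
    unique species, clusters by overlap then by sequence+contig context.
    Returns (final representatives, overlap clusters, membership, tallies).
    """
    from .identify import count_reads_to_products

    nonov_read = getattr(identify_cfg, "nonoverlap_read", 2)
    nonov_feat = getattr(identify_cfg, "nonoverlap_feature", 2)
    filtered: dict[str, list[ProcessingProduct]] = {}
    for lib in sorted(per_lib_products):
        products = per_lib_products[lib]
        mappings = per_lib_mappings[lib]
        all_cov = coverage_arrays(mappings, genome)
        _, assigned = count_reads_to_products(mappings, products, nonov_read, nonov_feat)
        for p, idxs in zip(products, assigned):
            acov = coverage_arrays([mappings[i] for i in idxs], genome)
            p.relative_coverage[lib] = relative_coverage(p, acov, all_cov)
        filtered[lib] = filter_candidates(products, config.min_count, config.min_relcov, lib)
    combined = combine_unique(filtered)
    overlap_clusters = cluster_by_overlap(combined, config.tolerance)
    reps = [c.representative for c in overlap_clusters]
    pooled = [m for lib in sorted(per_lib_mappings) for m in per_lib_mappings[lib]]
    contigs = build_contigs(pooled, genome)
    attach_sequences(reps, genome)
    finals, membership = cluster_by_sequence(reps, contigs, config.id_contig, config.len_cutoff)
    tallies = {
        "candidates_filtered": sum(len(v) for v in filtered.values()),
        "candidates_unique": len(combined),
        "overlap_clusters": len(overlap_clusters),
        "representatives": len(finals),
        "contigs": len(contigs),
    }
    return finals, overlap_clusters, membership, tallies
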