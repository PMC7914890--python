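"""Quantification of representative products across libraries.

Counting follows the identify-stage assignment rule (stranded, overlap
tolerance 2, every mapping of a multi-mapped read counts, a mapping may
count toward several overlapping products). Per-candidate statistics
(relative coverage, per-position coverage, consensus sequence and quality,
genomic sequence, uniqueness) are gathered library-wise. Counts are
normalised to RPM (reads per million mapped reads), RPM of biotype and RPM
of biotype group; a product is retained when it reaches the RPM threshold
(default 10) in at least one library.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cluster import coverage_arrays, relative_coverage
from .identify import count_reads_to_products
from .records import ProcessingProduct
from .seqs import Genome, revcomp

BIOTYPE_PRIORITY = ("rRNA", "tRNA", "ncRNA", "CDS")

#: Default biotype -> biotype-group mapping (config-exposed).
DEFAULT_BIOTYPE_GROUPS = {
    "rRNA": "structural",
    "tRNA": "structural",
    "ncRNA": "ncRNA",
    "CDS": "mRNA-derived",
    "intergenic": "other",
    "antisense": "other",
}


class InputError(ValueError):
    pass


@dataclass
class QuantifyConfig:
    rpm_threshold: float = 10.0
    nonoverlap_read: int = 2
    nonoverlap_feature: int = 2
    biotype_priority: tuple = BIOTYPE_PRIORITY
    biotype_groups: dict = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_GROUPS))


@dataclass
class CandidateStats:
    relative_coverage: float
    coverage: list
    consensus_seq: str
    consensus_qual: list
    genomic_seq: str
    uniqueness: float


def product_id(chrom: str, strand: str, start0: int, length: int, genome_lengths: dict) -> str:
    """Canonical product identifier: FM_<strand><chrom>_<1-based start,
    zero-padded to the digit count of the chromosome length>_<length>."""
    width = len(str(genome_lengths[chrom]))
    return f"FM_{strand}{chrom}_{start0 + 1:0{width}d}_{length}"


def assign_ids(products, genome: Genome) -> None:
    for p in products:
        p.id = product_id(p.chrom, p.strand, p.start0, p.length, genome.lengths)


def consensus(product, assigned_reads, genome: Genome):
    """Per-position majority base among covering reads (ties go to the
    genomic base); consensus quality is the rounded mean Phred of the
    contributing bases. Uncovered positions take the genomic base at
    quality 0. Returned 5'->3' (read orientation)."""
    n = product.length
    ref = genome.fetch(product.chrom, product.start0, product.end0)
    votes = [defaultdict(int) for _ in range(n)]
    qsums = [defaultdict(int) for _ in range(n)]
    for r in assigned_reads:
        off = r.start0 - product.start0
        for i, (b, q) in enumerate(zip(r.bases, r.quals)):
            j = off + i
            if 0 <= j < n:
                votes[j][b] += 1
                qsums[j][b] += q
    seq = []
    qual = []
    for j in range(n):
        if not votes[j]:
            seq.append(ref[j])
            qual.append(0)
            continue
        top = max(votes[j].values())
        winners = [b for b, c in votes[j].items() if c == top]
        base = ref[j] if ref[j] in winners else sorted(winners)[0]
        seq.append(base)
        qual.append(int(round(qsums[j][base] / votes[j][base])) if votes[j][base] else 0)
    if product.strand == "-":
        seq = list(revcomp("".join(seq)))
        qual = qual[::-1]
    return "".join(seq), qual


def quantify_library(
    mappings,
    representatives,
    genome: Genome,
    config: QuantifyConfig,
    library: str = "lib",
):
    """Counts and per-candidate statistics for one library.

    Each mapping of a multi-mapped read contributes one count to each product
    it is assigned to. Returns (counts list, stats list aligned with
    ``representatives``).
    """
    for m in mappings:
        if m.chrom not in genome.lengths:
            raise InputError(f"SAM chromosome {m.chrom!r} absent from the genome")
    counts, assigned = count_reads_to_products(
        mappings, representatives, config.nonoverlap_read, config.nonoverlap_feature
    )
    all_cov = coverage_arrays(mappings, genome) if mappings else {}
    stats = []
    for p, idxs in zip(representatives, assigned):
        reads = [mappings[i] for i in idxs]
        if reads:
            acov = coverage_arrays(reads, genome)
            arr = acov.get((p.chrom, p.strand))
            covvec = [int(x) for x in arr[p.start0 : p.end0]] if arr is not None else [0] * p.length
            relcov = relative_coverage(p, acov, all_cov)
            uniq = sum(1 for r in reads if r.nh == 1) / len(reads)
        else:
            covvec = [0] * p.length
            relcov = 0.0
            uniq = 0.0
        cseq, cqual = consensus(p, reads, genome)
        gseq = genome.fetch_oriented(p.chrom, p.start0, p.end0, p.strand)
        if p.strand == "-":
            covvec = covvec[::-1]
        stats.append(CandidateStats(relcov, covvec, cseq, cqual, gseq, uniq))
    return counts, stats


def assign_biotype(product, features, priority=BIOTYPE_PRIORITY) -> str:
    """Biotype of the highest-priority same-strand overlapping feature;
    "antisense" when only opposite-strand features overlap, "intergenic"
    when none do."""
    sense, anti = [], []
    for f in features:
        if f.chrom != product.chrom:
            continue
        if f.start0 < product.end0 and product.start0 < f.end0:
            (sense if f.strand == product.strand else anti).append(f.ftype)
    for bt in priority:
        if bt in sense:
            return bt
    if sense:
        return sense[0]
    if anti:
        return "antisense"
    return "intergenic"


class FeatureIndex:
    """Interval index over GFF3 features for fast biotype lookup."""

    def __init__(self, features):
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in features:
            self.trees[f.chrom][f.start0 : f.end0] = f

    def overlapping(self, chrom: str, start0: int, end0: int):
        return [iv.data for iv in self.trees.get(chrom, IntervalTree()).overlap(start0, end0)]


def assign_biotypes(products, features, priority=BIOTYPE_PRIORITY) -> None:
    index = FeatureIndex(features)
    for p in products:
        p.biotype = assign_biotype(
            p, index.overlapping(p.chrom, p.start0, p.end0), priority
        )


@dataclass
class CountMatrix:
    raw: pd.DataFrame  # products x libraries
    rpm: pd.DataFrame
    rpm_biotype: pd.DataFrame
    rpm_biotype_group: pd.DataFrame
    library_totals: dict
    biotypes: dict  # product id -> biotype


def normalize(
    raw: pd.DataFrame,
    library_totals: dict,
    biotypes: dict,
    groups: dict | None = None,
) -> CountMatrix:
    """RPM layers. Library totals are mapped pseudo-SE reads after filtering;
    the biotype denominator is the summed raw count of that biotype's
    products in that library (likewise for biotype groups)."""
    groups = dict(DEFAULT_BIOTYPE_GROUPS) if groups is None else groups
    totals = pd.Series({lib: library_totals[lib] for lib in raw.columns}, dtype=float)
    if (totals <= 0).any():
        raise InputError("library totals must be positive")
    rpm = raw / totals * 1e6
    bt = pd.Series({pid: biotypes[pid] for pid in raw.index})
    grp = bt.map(lambda b: groups.get(b, "other"))

    def _per_class(classes: pd.Series) -> pd.DataFrame:
        class_totals = raw.groupby(classes).sum()  # class x library
        denom = class_totals.reindex(classes).set_axis(raw.index)
        out = pd.DataFrame(0.0, index=raw.index, columns=raw.columns)
        nz = denom > 0
        assert not ((~nz) & (raw > 0)).any().any(), "nonzero count with zero class total"
        out[nz] = raw[nz] / denom[nz] * 1e6
        return out

    return CountMatrix(raw, rpm, _per_class(bt), _per_class(grp), dict(library_totals), dict(bt))


def rpm_retention_filter(matrix: CountMatrix, threshold: float = 10.0) -> list[str]:
    """Products reaching ``threshold`` RPM in at least one library."""
    keep = matrix.rpm.max(axis=1) >= threshold
    return [pid for pid in matrix.raw.index if keep[pid]]


def run_statistics(per_library_tallies: dict) -> pd.DataFrame:
    """One row per library combining the tallies of every pipeline stage."""
    rows = []
    for lib in sorted(per_library_tallies):
        row = {"library": lib}
        for stage in sorted(per_library_tallies[lib]):
            for key, val in per_library_tallies[lib][stage].items():
                row[f"{stage}.{key}"] = val
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.fillna(0)
        for c in df.columns:
            if c != "library":
                df[c] = df[c].astype(int)
    return df


def quantify_libraries(
    per_lib_mappings: dict,
    representatives,
    genome: Genome,
    features,
    config: QuantifyConfig,
    library_totals: dict | None = None,
):
    """Full quantify stage: counts, stats, biotypes, RPM layers, retention.

    ``library_totals`` defaults to the number of distinct mapped reads per
    library (multi-mapped reads count once).
    """
    assign_ids(representatives, genome)
    assign_biotypes(representatives, features, config.biotype_priority)
    libs = sorted(per_lib_mappings)
    raw = pd.DataFrame(0, index=[p.id for p in representatives], columns=libs)
    all_stats: dict[str, list] = {}
    for lib in libs:
        counts, stats = quantify_library(
            per_lib_mappings[lib], representatives, genome, config, lib
        )
        for p, c in zip(representatives, counts):
            raw.loc[p.id, lib] = c
            p.counts[lib] = c
        all_stats[lib] = stats
    if library_totals is None:
        library_totals = {
            lib: len({m.read_id for m in per_lib_mappings[lib]}) for lib in libs
        }
    biotypes = {p.id: p.biotype for p in representatives}
    matrix = normalize(raw, library_totals, biotypes, config.biotype_groups)
    retained = rpm_retention_filter(matrix, config.rpm_threshold)
    return matrix, all_stats, retained
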