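"""Native ungapped all-alignments read mapper.

The scoring model is deliberately simple so that it can be checked exactly
against a brute-force scorer: a flat penalty per mismatch (default 6, no
indels, no quality weighting) and a linear minimum-score function
``f(L) = a + b * L`` (default 0 - 2L), which admits roughly one mismatch per
three bases - permissive on purpose, so that RNAs carrying modifications
(which read out as mismatches) are kept.

Candidate loci come from staged seeding: exact k-mer windows over the whole
read (stride 1); if those produce no valid alignment, every one-substitution
neighbour of every window is also looked up. Escalation cannot change the
result when the first stage succeeds, because a spurious exact k-mer hit on a
desk-scale genome is essentially impossible while any alignment in the best
stratum shares at least one clean window with the reference.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .records import AlignmentRecord
from .seqs import Genome, revcomp, seq_to_array


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    seed_len: int = 22
    seed_mismatches: int = 1  # 0 or 1
    min_score_a: float = 0.0
    min_score_b: float = -2.0
    mismatch_penalty: int = 6
    report_all: bool = True
    max_insert: int = 400  # PE concordance bound, used by the stratum stage
    sensitive: bool = True  # two-pass seed 22 -> 14
    exhaustive_rescue: bool = True  # final full-scan tier for unseedable reads

    def min_score(self, length: int) -> float:
        return self.min_score_a + self.min_score_b * length


class SeedIndex:
    """Exact k-mer -> genomic positions map (forward strand only;
    reverse-strand hits come from querying the reverse complement)."""

    def __init__(self, genome: Genome, k: int):
        if k < 1:
            raise ValueError("seed length must be positive")
        self.k = k
        self.genome = genome
        self.kmers: dict[bytes, list[tuple[str, int]]] = {}
        acgt = frozenset(b"ACGT")
        for chrom, seq in genome.seqs.items():
            data = seq.encode("ascii")
            for pos in range(len(data) - k + 1):
                kmer = data[pos : pos + k]
                if not acgt.issuperset(kmer):
                    continue  # ambiguous bases never seed
                self.kmers.setdefault(kmer, []).append((chrom, pos))

    def lookup(self, kmer: bytes | str):
        if isinstance(kmer, str):
            kmer = kmer.encode("ascii")
        return self.kmers.get(kmer, ())


def _extend(
    genome: Genome,
    query: str,
    qarr: np.ndarray,
    chrom: str,
    start: int,
    strand: str,
    params: AlignParams,
    read_id: str,
    mate: int,
    quals,
    read_len: int,
):
    """Score an ungapped candidate placement; None if out of bounds/invalid."""
    if start < 0 or start + read_len > genome.lengths[chrom]:
        return None
    ref = genome.arrays[chrom][start : start + read_len]
    mm = np.flatnonzero(ref != qarr)
    score = -params.mismatch_penalty * len(mm)
    if score < params.min_score(read_len):
        return None
    if strand == "+":
        positions = tuple(int(i) for i in mm)
        seq = query
        qv = tuple(quals) if quals else ()
    else:
        positions = tuple(sorted(read_len - 1 - int(i) for i in mm))
        seq = revcomp(query)
        qv = tuple(quals) if quals else ()
    return AlignmentRecord(
        read_id, chrom, strand, start, start + read_len, int(score), positions, mate, False, seq, qv
    )


def align_read(
    seq: str,
    index: SeedIndex,
    params: AlignParams,
    read_id: str = "read",
    mate: int = 0,
    quals=None,
) -> list[AlignmentRecord]:
    """All valid ungapped alignments of one read, deduplicated by locus."""
    if not seq:
        raise InputError("empty read")
    L = len(seq)
    k = min(index.k, L)
    genome = index.genome
    queries = {"+": seq, "-": revcomp(seq)}
    qarrs = {s: seq_to_array(q) for s, q in queries.items()}

    def seeds_exact():
        for strand, query in queries.items():
            data = query.encode("ascii")
            for off in range(L - k + 1):
                for chrom, pos in index.lookup(data[off : off + k]):
                    yield chrom, strand, pos - off

    def seeds_neighbors():
        alt = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}  # A C G T
        for strand, query in queries.items():
            data = query.encode("ascii")
            for off in range(L - k + 1):
                window = bytearray(data[off : off + k])
                for j in range(k):
                    orig = window[j]
                    for b in alt.get(orig, b""):
                        window[j] = b
                        for chrom, pos in index.lookup(bytes(window)):
                            yield chrom, strand, pos - off
                    window[j] = orig

    def collect(seed_iter):
        seen: set[tuple[str, str, int]] = set()
        out = []
        for chrom, strand, start in seed_iter:
            key = (chrom, strand, start)
            if key in seen:
                continue
            seen.add(key)
            rec = _extend(
                genome, queries[strand], qarrs[strand], chrom, start, strand,
                params, read_id, mate, quals, L,
            )
            if rec is not None:
                out.append(rec)
        return out

    records = collect(seeds_exact())
    if not records and params.seed_mismatches >= 1:
        records = collect(seeds_neighbors())
    records.sort(key=lambda r: (r.chrom, r.start0, r.strand))
    if not params.report_all and len(records) > 1:
        best = max(r.score for r in records)
        records = [r for r in records if r.score == best][:1]
    return records


def exhaustive_scan(
    seq: str,
    genome: Genome,
    params: AlignParams,
    read_id: str = "read",
    mate: int = 0,
    quals=None,
) -> list[AlignmentRecord]:
    """All valid alignments by scoring every genomic placement (vectorised).

    Used as the last sensitivity tier for reads no seed can reach (short reads
    dense with mismatches); cost is one pass over the genome per read.
    """
    if not seq:
        raise InputError("empty read")
    L = len(seq)
    records = []
    for strand in ("+", "-"):
        query = seq if strand == "+" else revcomp(seq)
        qarr = seq_to_array(query)
        for chrom, arr in genome.arrays.items():
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm_counts = (windows != qarr).sum(axis=1)
            max_mm = int(-params.min_score(L) // params.mismatch_penalty)
            for start in np.flatnonzero(mm_counts <= max_mm):
                rec = _extend(
                    genome, query, qarr, chrom, int(start), strand,
                    params, read_id, mate, quals, L,
                )
                if rec is not None:
                    records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.start0, r.strand))
    return records


def params_with_seed(params: AlignParams, seed_len: int) -> AlignParams:
    return replace(params, seed_len=seed_len)
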