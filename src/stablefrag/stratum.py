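"""Best-stratum filtering and the sensitive two-pass alignment orchestration.

A read's stratum is the set of its alignments sharing the maximal score; for
paired-end data the unit is a concordant mate pair and scores are summed.
Sensitive mode first aligns with the default seed length (22), then re-runs
still-unaligned reads with a shorter seed (14); a final exhaustive-scan
rescue tier (config-exposed) catches short reads dense with mismatches that
no seeded scheme can reach.
"""
from __future__ import annotations

from .align import AlignParams, SeedIndex, align_read, exhaustive_scan, params_with_seed
from .records import FastqRead, PairedUnit, ReadAlignmentGroup
from .seqs import Genome


def join_pairs(alns1, alns2, max_insert: int = 400) -> list[PairedUnit]:
    """Concordant mate-pair combinations (same chrom, FR orientation,
    fragment span <= max_insert)."""
    units = []
    for a1 in alns1:
        for a2 in alns2:
            if a1.chrom != a2.chrom or a1.strand == a2.strand:
                continue
            plus, minus = (a1, a2) if a1.strand == "+" else (a2, a1)
            if plus.start0 > minus.start0 or plus.end0 > minus.end0:
                continue  # not FR / dovetailing
            span = max(a1.end0, a2.end0) - min(a1.start0, a2.start0)
            if span > max_insert:
                continue
            units.append(PairedUnit(a1, a2))
    return units


def best_stratum_filter(groups):
    """Retain exactly the units achieving the maximal (pair-)score per read.

    Returns (filtered groups, read_ids with no unit at all). Idempotent.
    """
    filtered = []
    unaligned = []
    for g in groups:
        if not g.units:
            unaligned.append(g.read_id)
            continue
        best = max(u.score for u in g.units)
        units = [u for u in g.units if u.score == best]
        filtered.append(ReadAlignmentGroup(g.read_id, units, best))
    return filtered, unaligned


def _align_item(item, index, params):
    """Alignment units of one SE read or one PE pair."""
    if isinstance(item, FastqRead):
        return align_read(item.bases, index, params, item.id, item.mate, item.quals)
    r1, r2 = item
    a1 = align_read(r1.bases, index, params, r1.id, 1, r1.quals)
    a2 = align_read(r2.bases, index, params, r2.id, 2, r2.quals)
    return join_pairs(a1, a2, params.max_insert)


def _rescue_item(item, genome, params):
    if isinstance(item, FastqRead):
        return exhaustive_scan(item.bases, genome, params, item.id, item.mate, item.quals)
    r1, r2 = item
    a1 = exhaustive_scan(r1.bases, genome, params, r1.id, 1, r1.quals)
    a2 = exhaustive_scan(r2.bases, genome, params, r2.id, 2, r2.quals)
    return join_pairs(a1, a2, params.max_insert)


def _item_id(item) -> str:
    return item.id if isinstance(item, FastqRead) else item[0].id


def _pass(items, index, params):
    aligned, leftover = [], []
    for item in items:
        units = _align_item(item, index, params)
        groups, _ = best_stratum_filter([ReadAlignmentGroup(_item_id(item), units)])
        if groups:
            aligned.append(groups[0])
        else:
            leftover.append(item)
    return aligned, leftover


def sensitive_align(items, genome: Genome, params: AlignParams):
    """Align a library (list of FastqRead or of (R1, R2) pairs).

    Returns (groups, unaligned_items, tallies). In non-sensitive mode only the
    first pass runs; a read never appears in more than one pass's output.
    """
    index1 = SeedIndex(genome, params.seed_len)
    groups, leftover = _pass(items, index1, params)
    tallies = {"aligned_pass1": len(groups), "aligned_pass2": 0, "aligned_rescue": 0}
    if params.sensitive and leftover:
        params2 = params_with_seed(params, 14)
        index2 = SeedIndex(genome, 14)
        more, leftover = _pass(leftover, index2, params2)
        tallies["aligned_pass2"] = len(more)
        groups += more
    if params.exhaustive_rescue and leftover:
        still = []
        for item in leftover:
            units = _rescue_item(item, genome, params)
            sub, _ = best_stratum_filter([ReadAlignmentGroup(_item_id(item), units)])
            if sub:
                groups += sub
                tallies["aligned_rescue"] += 1
            else:
                still.append(item)
        leftover = still
    tallies["unaligned"] = len(leftover)
    return groups, leftover, tallies
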