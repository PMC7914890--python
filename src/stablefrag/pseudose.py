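"""Pseudo-SE conversion: merge mate pairs into full-insert alignments.

Overlapping mate positions are consolidated base by base: agreeing bases
keep the base with quality min(q1+q2, 41); disagreeing positions keep the
higher-quality base with quality (q_high - q_low). A gap between
non-overlapping mates is filled from the genome at the maximum quality (41).

Mismatch filtering runs per mapping; untemplated 3'-oligo(A) tails are
exempted from the mismatch count by default (oligo/polyadenylation marks
some bacterial RNAs for decay, so such reads are biology, not noise), and
oligo(A) reads are additionally copied to a sidecar.
"""
from __future__ import annotations

from dataclasses import dataclass

from .records import AlignmentRecord, PairedUnit, PseudoSERead
from .seqs import Genome, QMAX, revcomp


@dataclass
class PseudoSEConfig:
    max_mm: int = 2
    max_nh: int = 50
    oligoA_exempt: bool = True
    max_insert: int = 400


class DiscordantPair(ValueError):
    pass


def _forward_view(aln: AlignmentRecord) -> tuple[str, list[int]]:
    """Mate bases/quals in genome-forward orientation."""
    if aln.strand == "+":
        return aln.seq, list(aln.quals)
    return revcomp(aln.seq), list(aln.quals)[::-1]


def merge_pair(aln1: AlignmentRecord, aln2: AlignmentRecord, genome: Genome) -> PseudoSERead:
    """Merge a concordant mate pair into one full-insert record."""
    if aln1.chrom != aln2.chrom or aln1.strand == aln2.strand:
        raise DiscordantPair(f"{aln1.read_id}: mates not concordant")
    s = min(aln1.start0, aln2.start0)
    e = max(aln1.end0, aln2.end0)
    n = e - s
    bases: list[str | None] = [None] * n
    quals = [0] * n
    layers = []
    for aln in (aln1, aln2):
        seq, qv = _forward_view(aln)
        layers.append((aln.start0 - s, seq, qv))
    # lay down mate 2 first so that on quality ties mate 1's base wins
    for off, seq, qv in (layers[1], layers[0]):
        for i, (b, q) in enumerate(zip(seq, qv)):
            j = off + i
            if bases[j] is None:
                bases[j] = b
                quals[j] = q
            elif bases[j] == b:
                quals[j] = min(quals[j] + q, QMAX)
            elif q > quals[j]:
                bases[j], quals[j] = b, q - quals[j]
            else:
                quals[j] = quals[j] - q
    gap_filled = 0
    ref = genome.fetch(aln1.chrom, s, e)
    for j in range(n):
        if bases[j] is None:
            bases[j] = ref[j]
            quals[j] = QMAX
            gap_filled += 1
    return PseudoSERead(
        aln1.read_id, aln1.chrom, aln1.strand, s, e, "".join(bases), quals,
        gap_filled=gap_filled,
    )


def passthrough_se(aln: AlignmentRecord) -> PseudoSERead:
    """Identity conversion of an SE alignment (no merge, no gap fill)."""
    seq, qv = _forward_view(aln)
    return PseudoSERead(aln.read_id, aln.chrom, aln.strand, aln.start0, aln.end0, seq, qv)


def mismatch_filter(
    read: PseudoSERead,
    genome: Genome,
    max_mm: int = 2,
    max_nh: int = 50,
    oligoA_exempt: bool = True,
) -> str:
    """Classify one mapping: "kept" | "discarded_mm" | "discarded_multi".

    Sets ``n_mismatch`` (after the oligo(A) exemption) and ``oligoA_len`` on
    the record. The exempted run must be terminal at the 3' end in read
    orientation and mismatching; templated (genome-matching) terminal A's are
    ordinary matches.
    """
    seq = read.oriented_bases()
    ref = genome.fetch_oriented(read.chrom, read.start0, read.end0, read.strand)
    oligoa = 0
    if oligoA_exempt:
        i = len(seq) - 1
        while i >= 0 and seq[i] == "A" and seq[i] != ref[i]:
            oligoa += 1
            i -= 1
    mm = sum(1 for i in range(len(seq) - oligoa) if seq[i] != ref[i])
    read.n_mismatch = mm
    read.oligoA_len = oligoa
    if mm > max_mm:
        return "discarded_mm"
    if read.nh > max_nh:
        return "discarded_multi"
    return "kept"


def pseudose_convert(groups, genome: Genome, config: PseudoSEConfig):
    """Convert best-stratum alignment groups to filtered pseudo-SE mappings.

    Per read: every unit is merged (or passed through), mismatch-filtered
    individually, NH = number of surviving mappings. Reads whose mappings all
    fail the mismatch filter are ``discarded_mm``; reads with NH > max_nh are
    ``discarded_multi``. Returns (kept mappings, sidecars dict, tallies);
    kept + discarded_mm + discarded_multi == input read count.
    """
    kept: list[PseudoSERead] = []
    sidecars = {"too_many_mm": [], "too_many_hits": [], "oligoA": []}
    tallies = {
        "input_reads": 0,
        "kept_reads": 0,
        "discarded_mm": 0,
        "discarded_multi": 0,
        "oligoA_reads": 0,
        "kept_mappings": 0,
    }
    for group in sorted(groups, key=lambda g: g.read_id):
        tallies["input_reads"] += 1
        converted = []
        for unit in group.units:
            if isinstance(unit, PairedUnit):
                rec = merge_pair(unit.a1, unit.a2, genome)
            else:
                rec = passthrough_se(unit)
            status = mismatch_filter(rec, genome, config.max_mm, config.max_nh, config.oligoA_exempt)
            converted.append((status, rec))
        surviving = [rec for status, rec in converted if status != "discarded_mm"]
        if not surviving:
            tallies["discarded_mm"] += 1
            sidecars["too_many_mm"].extend(rec for _, rec in converted)
            continue
        nh = len(surviving)
        for rec in surviving:
            rec.nh = nh
        if nh > config.max_nh:
            tallies["discarded_multi"] += 1
            sidecars["too_many_hits"].extend(surviving)
            continue
        if any(rec.oligoA_len > 0 for rec in surviving):
            tallies["oligoA_reads"] += 1
            sidecars["oligoA"].extend(rec for rec in surviving if rec.oligoA_len > 0)
        kept.extend(surviving)
        tallies["kept_reads"] += 1
        tallies["kept_mappings"] += nh
    return kept, sidecars, tallies
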