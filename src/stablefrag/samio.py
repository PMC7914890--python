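"""SAM round-tripping via pysam.

Alignment records store read-oriented sequences internally; SAM stores the
reverse complement for minus-strand records, per convention. Custom tags:
ZM (B,i) carries mismatch read-offsets so round-trips are lossless, ZP (i)
numbers the mate-pair unit a record belongs to (needed to re-join
multi-mapped pairs), ZA (i) the exempted 3'-oligo(A) run length on pseudo-SE
records, ZG (i) the number of gap-filled bases.
"""
from __future__ import annotations

import pysam

from .records import AlignmentRecord, PairedUnit, PseudoSERead
from .seqs import Genome, revcomp


class SamParseError(ValueError):
    pass


def make_header(genome: Genome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in genome.lengths.items()],
            "PG": [{"ID": "stablefrag", "PN": "stablefrag"}],
        }
    )


def _segment(header, rec: AlignmentRecord, nh: int | None = None, unit: int | None = None,
             paired: bool = False) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.read_id
    flag = 0
    if rec.strand == "-":
        flag |= 0x10
    if paired:
        flag |= 0x1 | 0x2
        flag |= 0x40 if rec.mate == 1 else 0x80
    if rec.is_secondary:
        flag |= 0x100
    seg.flag = flag
    seg.reference_id = header.get_tid(rec.chrom)
    seg.reference_start = rec.start0
    seg.mapping_quality = 255
    seg.cigartuples = [(0, rec.length)]
    seq = rec.seq if rec.strand == "+" else revcomp(rec.seq)
    seg.query_sequence = seq
    if rec.quals:
        quals = list(rec.quals) if rec.strand == "+" else list(rec.quals)[::-1]
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals)
        )
    seg.set_tag("AS", rec.score, "i")
    seg.set_tag("NM", rec.n_mismatch, "i")
    if rec.mismatch_positions:
        seg.set_tag("ZM", list(rec.mismatch_positions))
    if nh is not None:
        seg.set_tag("NH", nh, "i")
    if unit is not None:
        seg.set_tag("ZP", unit, "i")
    return seg


def _record(seg: pysam.AlignedSegment) -> AlignmentRecord:
    strand = "-" if seg.is_reverse else "+"
    seq = seg.query_sequence or ""
    quals = list(seg.query_qualities) if seg.query_qualities is not None else []
    if strand == "-":
        seq = revcomp(seq)
        quals = quals[::-1]
    mate = 0
    if seg.is_paired:
        mate = 1 if seg.is_read1 else 2
    zm = tuple(int(x) for x in seg.get_tag("ZM")) if seg.has_tag("ZM") else ()
    return AlignmentRecord(
        seg.query_name,
        seg.reference_name,
        strand,
        seg.reference_start,
        seg.reference_end,
        int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
        zm,
        mate,
        seg.is_secondary,
        seq,
        tuple(quals),
    )


def write_sam(path, genome: Genome, alignments) -> None:
    """Write plain AlignmentRecords (SE or unpaired view)."""
    header = make_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in alignments:
            fh.write(_segment(header, rec))


def read_sam(path) -> list[AlignmentRecord]:
    out = []
    lineno = 0
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for seg in fh:
                lineno += 1
                out.append(_record(seg))
    except (ValueError, OSError) as exc:
        raise SamParseError(f"{path}: malformed SAM near record {lineno + 1}: {exc}") from exc
    return out


def write_unit_sam(path, genome: Genome, groups, paired: bool) -> None:
    """Write best-stratum alignment units; pair members share a ZP serial."""
    header = make_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for group in groups:
            nh = len(group.units)
            for unit_no, unit in enumerate(group.units):
                if isinstance(unit, PairedUnit):
                    fh.write(_segment(header, unit.a1, nh=nh, unit=unit_no, paired=True))
                    fh.write(_segment(header, unit.a2, nh=nh, unit=unit_no, paired=True))
                else:
                    fh.write(_segment(header, unit, nh=nh, unit=unit_no))


def read_unit_sam(path):
    """Rebuild {read_id: [unit, ...]} from a unit SAM (pairs joined on ZP)."""
    from collections import defaultdict

    units: dict[str, dict[int, list]] = defaultdict(dict)
    paired = False
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            rec = _record(seg)
            unit_no = int(seg.get_tag("ZP")) if seg.has_tag("ZP") else 0
            slot = units[rec.read_id].setdefault(unit_no, [])
            slot.append(rec)
            if seg.is_paired:
                paired = True
    grouped = {}
    for read_id, by_unit in units.items():
        out = []
        for unit_no in sorted(by_unit):
            recs = by_unit[unit_no]
            if len(recs) == 2:
                r1, r2 = sorted(recs, key=lambda r: r.mate)
                out.append(PairedUnit(r1, r2))
            else:
                out.append(recs[0])
        grouped[read_id] = out
    return grouped, paired


def write_pseudose_sam(path, genome: Genome, reads) -> None:
    header = make_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.flag = 0x10 if r.strand == "-" else 0
            seg.reference_id = header.get_tid(r.chrom)
            seg.reference_start = r.start0
            seg.mapping_quality = 255
            seg.cigartuples = [(0, r.length)]
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            seg.set_tag("NH", r.nh, "i")
            seg.set_tag("NM", r.n_mismatch, "i")
            seg.set_tag("ZA", r.oligoA_len, "i")
            seg.set_tag("ZG", r.gap_filled, "i")
            fh.write(seg)


def read_pseudose_sam(path) -> list[PseudoSERead]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            out.append(
                PseudoSERead(
                    seg.query_name,
                    seg.reference_name,
                    "-" if seg.is_reverse else "+",
                    seg.reference_start,
                    seg.reference_end,
                    seg.query_sequence,
                    list(seg.query_qualities),
                    nh=int(seg.get_tag("NH")) if seg.has_tag("NH") else 1,
                    n_mismatch=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    oligoA_len=int(seg.get_tag("ZA")) if seg.has_tag("ZA") else 0,
                    gap_filled=int(seg.get_tag("ZG")) if seg.has_tag("ZG") else 0,
                )
            )
    return out
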