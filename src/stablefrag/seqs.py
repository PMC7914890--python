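"""Sequence containers and FASTA/FASTQ/GFF3 file helpers.

FASTA and FASTQ round-trips go through Biopython; compressed FASTQ
(``.gz``/``.bz2``/``.xz``) is transparently supported.
"""
from __future__ import annotations

import bz2
import gzip
import lzma
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import FastqRead, GffFeature

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Illumina Phred+33 ceiling, also the quality assigned to gap-filled bases.
QMAX = 41


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """ASCII bytes view of a sequence, for vectorised mismatch counting."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def open_text(path, mode: str = "rt"):
    """Open plain or gz/bz2/xz-compressed text by file suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    if path.suffix == ".bz2":
        return bz2.open(path, mode)
    if path.suffix == ".xz":
        return lzma.open(path, mode)
    return open(path, mode)


class Genome:
    """In-memory reference genome with O(1) substring access."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = {c: s.upper() for c, s in seqs.items()}
        self.arrays = {c: seq_to_array(s) for c, s in self.seqs.items()}
        self.lengths = {c: len(s) for c, s in self.seqs.items()}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        return self.seqs[chrom][start0:end0]

    def fetch_oriented(self, chrom: str, start0: int, end0: int, strand: str) -> str:
        s = self.fetch(chrom, start0, end0)
        return s if strand == "+" else revcomp(s)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        with open_text(path) as fh:
            return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")})

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(s), id=c, description="") for c, s in self.seqs.items()]
        with open_text(path, "wt") as fh:
            SeqIO.write(recs, fh, "fasta")


def read_fastq(path, mate: int = 0) -> list[FastqRead]:
    reads = []
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append(
                FastqRead(
                    rec.id,
                    str(rec.seq),
                    list(rec.letter_annotations["phred_quality"]),
                    mate,
                )
            )
    return reads


def write_fastq(path, reads) -> None:
    with open_text(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, fh, "fastq")


# -- GFF3 ------------------------------------------------------------------
# The annotations handled here are flat feature lists (no parent/child
# hierarchy), so a minimal reader/writer keeps the on-disk format standard
# (1-based inclusive coordinates, 9 tab-separated columns).

def write_gff3(path, features) -> None:
    with open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.chrom, f.start0, f.end0)):
            attrs = f"ID={f.attr_id}" if f.attr_id else "."
            fh.write(
                f"{f.chrom}\tstablefrag\t{f.ftype}\t{f.start0 + 1}\t{f.end0}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[GffFeature]:
    feats = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attr_id = ""
            for kv in cols[8].split(";"):
                if kv.startswith("ID="):
                    attr_id = kv[3:]
            feats.append(
                GffFeature(cols[0], cols[2], int(cols[3]) - 1, int(cols[4]), cols[6], attr_id)
            )
    return feats
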