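"""Core record types shared by all pipeline stages.

Coordinates are 0-based half-open throughout the library; conversion to the
1-based conventions of SAM/GFF3 happens only at file boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FastqRead:
    """One sequencing read (possibly trimmed).

    ``mate`` is 1 or 2 for paired-end data, 0 for single-end.
    """

    id: str
    bases: str
    quals: list[int]
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def truncated(self, n: int) -> "FastqRead":
        """Copy keeping only the first ``n`` bases."""
        return FastqRead(self.id, self.bases[:n], self.quals[:n], self.mate)


@dataclass
class TrimOutcome:
    """Result of cleaning one read: kept, or rejected with a reason."""

    status: str  # "kept" | "rejected_short" | "rejected_untrimmed"
    read: FastqRead
    adapter_found: bool
    bases_quality_trimmed: int
    bases_adapter_trimmed: int


@dataclass(frozen=True)
class AlignmentRecord:
    """One ungapped placement of a read on the genome.

    ``seq``/``quals`` are stored in read orientation (5'->3' of the read);
    ``mismatch_positions`` are read offsets. ``score`` is <= 0 (flat
    per-mismatch penalty).
    """

    read_id: str
    chrom: str
    strand: str  # "+" | "-"
    start0: int
    end0: int
    score: int
    mismatch_positions: tuple[int, ...] = ()
    mate: int = 0
    is_secondary: bool = False
    seq: str = ""
    quals: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class PairedUnit:
    """A concordant mate-pair of alignments with summed score."""

    a1: AlignmentRecord
    a2: AlignmentRecord

    @property
    def score(self) -> int:
        return self.a1.score + self.a2.score

    @property
    def chrom(self) -> str:
        return self.a1.chrom

    @property
    def strand(self) -> str:
        # the biological strand of the insert is the strand mate 1 aligned to
        return self.a1.strand

    @property
    def start0(self) -> int:
        return min(self.a1.start0, self.a2.start0)

    @property
    def end0(self) -> int:
        return max(self.a1.end0, self.a2.end0)


@dataclass
class ReadAlignmentGroup:
    """All alignment units (single records or mate pairs) of one read."""

    read_id: str
    units: list
    best_score: int | None = None


@dataclass
class PseudoSERead:
    """Full-insert alignment reconstructed from a pair (or passed-through SE read).

    ``bases``/``quals`` are stored genome-forward over [start0, end0); use
    :meth:`oriented_bases` for the 5'->3' sequence of the RNA.
    """

    read_id: str
    chrom: str
    strand: str
    start0: int
    end0: int
    bases: str
    quals: list[int]
    nh: int = 1
    n_mismatch: int = 0
    oligoA_len: int = 0
    gap_filled: int = 0

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    def oriented_bases(self) -> str:
        from .seqs import revcomp

        return self.bases if self.strand == "+" else revcomp(self.bases)

    def oriented_quals(self) -> list[int]:
        return self.quals if self.strand == "+" else self.quals[::-1]


@dataclass
class ProcessingProduct:
    """A stranded genomic interval predicted as a stable RNA fragment."""

    chrom: str
    strand: str
    start0: int
    end0: int
    five_support: int = 0
    three_support: int = 0
    fraction: str = ""
    counts: dict = field(default_factory=dict)  # library -> assigned count
    relative_coverage: dict = field(default_factory=dict)  # library -> fraction
    biotype: str = ""
    id: str = ""

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.start0, self.end0)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Contig:
    """Maximal interval of strictly positive pooled read coverage."""

    chrom: str
    strand: str
    start0: int
    end0: int
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end0 - self.start0


@dataclass
class OverlapCluster:
    representative: ProcessingProduct
    members: list
    tolerance: int


@dataclass(frozen=True)
class GffFeature:
    """One flat GFF3 feature (0-based half-open internally)."""

    chrom: str
    ftype: str  # rRNA | tRNA | ncRNA | CDS | ...
    start0: int
    end0: int
    strand: str
    attr_id: str = ""

    @property
    def length(self) -> int:
        return self.end0 - self.start0
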