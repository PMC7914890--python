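"""Synthetic small RNA-seq data generator and recovery scoring.

The generator emulates the structure of a bacterial small-RNA library:
a random genome with optional duplicated loci (to exercise multi-mapping),
a flat biotype annotation (rRNA/tRNA/ncRNA/CDS), planted processing
products whose reads carry 3' sequencing adapters, end-position jitter,
and optional untemplated 3'-oligo(A) tails. Everything is deterministic
given a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import FastqRead, GffFeature
from .seqs import Genome, revcomp, write_fastq, write_gff3

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

#: Insert-size range of the emulated gel cut (nt).
INSERT_RANGE = (18, 300)

#: Default insert-length mixture: tRF-sized peaks and a longer structured-RNA
#: peak (free choice; the real libraries' insert distribution is not modelled).
LENGTH_MIXTURE = ((25.0, 2.0, 0.4), (34.0, 3.0, 0.3), (90.0, 8.0, 0.3))

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ParameterError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class TruthProduct:
    chrom: str
    strand: str
    start0: int
    end0: int
    biotype: str
    abundance: int

    @property
    def length(self) -> int:
        return self.end0 - self.start0


@dataclass
class SyntheticTruth:
    genome_id: str
    genome_length: int
    seed: int
    products: list = field(default_factory=list)
    duplicated_loci: list = field(default_factory=list)  # [((s0,e0),(s0,e0)), ...]


def make_genome(
    length: int,
    gc: float = 0.5,
    n_duplicated_loci: int = 0,
    dup_len: int = 60,
    seed: int = 0,
    genome_id: str = "chrSim",
) -> tuple[Genome, SyntheticTruth]:
    """Random genome with ``n_duplicated_loci`` verbatim-copied segments."""
    if length < 1000:
        raise ParameterError("genome length must be >= 1000")
    if not 0 < gc < 1:
        raise ParameterError("gc must be in (0, 1)")
    if n_duplicated_loci and length < 4 * n_duplicated_loci * dup_len:
        raise ParameterError("genome too small to host requested duplications")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASE_BYTES, size=length, p=p)

    truth = SyntheticTruth(genome_id, length, seed)
    if n_duplicated_loci:
        # carve disjoint slots on a coarse grid, first half sources, second copies
        spacing = 2 * dup_len
        slots = np.arange(0, length - dup_len, spacing)
        idx = rng.choice(len(slots), size=2 * n_duplicated_loci, replace=False)
        starts = slots[np.sort(idx)]
        rng.shuffle(starts)
        for i in range(n_duplicated_loci):
            src, dst = int(starts[2 * i]), int(starts[2 * i + 1])
            arr[dst : dst + dup_len] = arr[src : src + dup_len]
            truth.duplicated_loci.append(((src, src + dup_len), (dst, dst + dup_len)))
    genome = Genome({genome_id: arr.tobytes().decode("ascii")})
    return genome, truth


_FEATURE_LEN = {
    "rRNA": (110, 300),
    "tRNA": (72, 90),
    "ncRNA": (60, 200),
    "CDS": (200, 600),
}


def make_annotation(
    truth: SyntheticTruth,
    biotype_spec: dict[str, int],
    seed: int | None = None,
    min_gap: int = 20,
    max_tries: int = 20000,
) -> list[GffFeature]:
    """Place non-overlapping features of the requested biotypes on the genome."""
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    total = sum(
        n * (sum(_FEATURE_LEN.get(bt, (100, 200))) // 2 + min_gap)
        for bt, n in biotype_spec.items()
    )
    if total > truth.genome_length:
        raise GenerationError("requested features do not fit in the genome")
    placed: list[GffFeature] = []
    occupied: list[tuple[int, int]] = []
    serial = 0
    for biotype in sorted(biotype_spec):
        lo, hi = _FEATURE_LEN.get(biotype, (100, 200))
        for _ in range(biotype_spec[biotype]):
            for attempt in range(max_tries):
                flen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, truth.genome_length - flen))
                end = start + flen
                if all(end + min_gap <= s or e + min_gap <= start for s, e in occupied):
                    break
            else:
                raise GenerationError("could not place features without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            serial += 1
            placed.append(
                GffFeature(truth.genome_id, biotype, start, end, strand, f"{biotype}_{serial}")
            )
            occupied.append((start, end))
    return placed


def _draw_length(rng: np.random.Generator, mixture=LENGTH_MIXTURE) -> int:
    w = np.array([m[2] for m in mixture])
    mean, sd, _ = mixture[rng.choice(len(mixture), p=w / w.sum())]
    length = int(round(rng.normal(mean, sd)))
    return int(np.clip(length, *INSERT_RANGE))


def plant_products(
    truth: SyntheticTruth,
    features: list[GffFeature],
    n_intergenic: int = 0,
    abundance: int = 100,
    seed: int | None = None,
    min_gap: int = 20,
    mixture=LENGTH_MIXTURE,
    avoid_duplicated: bool = True,
    max_tries: int = 20000,
) -> list[TruthProduct]:
    """Plant one product inside every feature plus ``n_intergenic`` products.

    Products keep >= ``min_gap`` nt of clearance from each other so their end
    densities are resolvable; intergenic products avoid annotated features and
    (by default) duplicated loci.
    """
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    occupied = [(f.start0, f.end0) for f in features]
    if avoid_duplicated:
        occupied += [iv for pair in truth.duplicated_loci for iv in pair]
    products: list[TruthProduct] = []
    for f in features:
        length = min(_draw_length(rng, mixture), f.length)
        start = int(rng.integers(f.start0, f.end0 - length + 1))
        products.append(
            TruthProduct(f.chrom, f.strand, start, start + length, f.ftype, abundance)
        )
    for _ in range(n_intergenic):
        for attempt in range(max_tries):
            length = _draw_length(rng, mixture)
            start = int(rng.integers(0, truth.genome_length - length))
            end = start + length
            if all(end + min_gap <= s or e + min_gap <= start for s, e in occupied):
                break
        else:
            raise GenerationError("could not place intergenic products")
        strand = "+" if rng.random() < 0.5 else "-"
        products.append(
            TruthProduct(truth.genome_id, strand, start, end, "intergenic", abundance)
        )
        occupied.append((start, end))
    truth.products = products
    return products


@dataclass
class SimulatedReads:
    r1: list
    r2: list | None  # None in SE mode
    per_product_reads: list  # emitted read count per truth product
    n_noise: int


def _read_quals(rng, n: int, decay: int, decay_len: int = 8) -> list[int]:
    q = rng.integers(32, 41, size=n)
    if decay > 0:
        ramp = np.linspace(0, decay, min(decay_len, n))
        q[-len(ramp):] = np.maximum(q[-len(ramp):] - ramp.astype(int), 2)
    return [int(x) for x in q]


def simulate_reads(
    genome: Genome,
    truth: SyntheticTruth,
    depth_per_product: int = 100,
    end_jitter_sd: float = 0.0,
    adapter3: str = DEFAULT_ADAPTER3,
    paired: bool = True,
    read_len: int = 50,
    oligoA_rate: float = 0.0,
    noise_read_rate: float = 0.0,
    quality_decay: int = 0,
    seed: int = 0,
) -> SimulatedReads:
    """Simulate adaptered reads for every planted product plus noise reads.

    Each product emits exactly ``abundance`` reads (``depth_per_product`` when
    the planted abundance is unset/zero); noise reads start at uniform random
    genomic positions. Inserts shorter than ``read_len`` read through into the
    adapter.
    """
    if not adapter3:
        raise ParameterError("adapter3 must be non-empty")
    if read_len < INSERT_RANGE[0]:
        raise ParameterError("read_len shorter than the minimum insert length")
    rng = np.random.default_rng(seed)
    chrom_len = truth.genome_length
    r1: list[FastqRead] = []
    r2: list[FastqRead] = []
    per_product = []

    def emit(chrom: str, strand: str, s: int, e: int, rid: str) -> None:
        insert = genome.fetch_oriented(chrom, s, e, strand)
        if rng.random() < oligoA_rate:
            insert += "A" * int(rng.integers(1, 5))
        filler = (adapter3 * (read_len // len(adapter3) + 2))
        seq1 = (insert + filler)[:read_len]
        r1.append(FastqRead(rid, seq1, _read_quals(rng, len(seq1), quality_decay), 1 if paired else 0))
        if paired:
            seq2 = (revcomp(insert) + filler)[:read_len]
            r2.append(FastqRead(rid, seq2, _read_quals(rng, len(seq2), quality_decay), 2))

    for pi, prod in enumerate(truth.products):
        n = prod.abundance if prod.abundance else depth_per_product
        per_product.append(n)
        for i in range(n):
            if end_jitter_sd > 0:
                j5 = int(round(rng.normal(0, end_jitter_sd)))
                j3 = int(round(rng.normal(0, end_jitter_sd)))
            else:
                j5 = j3 = 0
            s = max(0, prod.start0 + j5)
            e = min(chrom_len, prod.end0 + j3)
            if e - s < 15:  # degenerate jitter draw; fall back to true ends
                s, e = prod.start0, prod.end0
            emit(prod.chrom, prod.strand, s, e, f"sim_{pi:03d}_{i:05d}")

    n_noise = int(round(noise_read_rate * sum(per_product)))
    for i in range(n_noise):
        length = int(rng.integers(20, 41))
        s = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        emit(truth.genome_id, strand, s, s + length, f"noise_{i:05d}")

    return SimulatedReads(r1, r2 if paired else None, per_product, n_noise)


# -- recovery scoring -------------------------------------------------------

@dataclass
class RecoveryResult:
    precision: float
    recall: float
    matches: pd.DataFrame  # truth_index, pred_index, d_start, d_end

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def evaluate_recovery(truth: SyntheticTruth, predicted, end_tolerance: int = 2) -> RecoveryResult:
    """Greedy one-to-one matching of predictions to planted products.

    A truth product is recovered when a prediction on the same chrom/strand
    has both the start and the end within ``end_tolerance`` nt; candidate
    pairs are consumed in order of smallest total end offset.
    """
    cands = []
    for ti, t in enumerate(truth.products):
        for pi, p in enumerate(predicted):
            if (p.chrom, p.strand) != (t.chrom, t.strand):
                continue
            ds, de = abs(p.start0 - t.start0), abs(p.end0 - t.end0)
            if ds <= end_tolerance and de <= end_tolerance:
                cands.append((ds + de, ti, pi, ds, de))
    cands.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    rows = []
    for cost, ti, pi, ds, de in cands:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        rows.append({"truth_index": ti, "pred_index": pi, "d_start": ds, "d_end": de})
    matches = pd.DataFrame(rows, columns=["truth_index", "pred_index", "d_start", "d_end"])
    precision = len(rows) / len(predicted) if predicted else 0.0
    recall = len(rows) / len(truth.products) if truth.products else 0.0
    return RecoveryResult(precision, recall, matches)


# -- file bundle ------------------------------------------------------------

def write_truth_tables(outdir, truth: SyntheticTruth, sim: SimulatedReads | None = None) -> None:
    """Truth intervals as BED6 (0-based half-open) + expected-count TSV."""
    outdir = Path(outdir)
    width = len(str(truth.genome_length))
    rows = []
    with open(outdir / "truth.bed", "w") as fh:
        for i, p in enumerate(truth.products):
            name = f"FM_{p.strand}{p.chrom}_{p.start0 + 1:0{width}d}_{p.length}"
            fh.write(f"{p.chrom}\t{p.start0}\t{p.end0}\t{name}\t{p.abundance}\t{p.strand}\n")
            rows.append(
                {
                    "product": name,
                    "biotype": p.biotype,
                    "expected_reads": sim.per_product_reads[i] if sim else p.abundance,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "expected_counts.tsv", sep="\t", index=False)


def simulate_dataset(
    outdir,
    length: int = 50000,
    gc: float = 0.5,
    n_duplicated_loci: int = 0,
    biotype_spec: dict | None = None,
    n_intergenic: int = 4,
    depth_per_product: int = 100,
    end_jitter_sd: float = 1.0,
    adapter3: str = DEFAULT_ADAPTER3,
    paired: bool = True,
    read_len: int = 50,
    oligoA_rate: float = 0.05,
    noise_read_rate: float = 0.02,
    quality_decay: int = 0,
    libraries: int = 1,
    seed: int = 0,
    compress: bool = False,
):
    """Generate a complete on-disk dataset; returns (genome, truth, features)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if biotype_spec is None:
        biotype_spec = {"rRNA": 4, "tRNA": 10, "ncRNA": 6, "CDS": 6}
    genome, truth = make_genome(length, gc, n_duplicated_loci, seed=seed)
    features = make_annotation(truth, biotype_spec)
    plant_products(truth, features, n_intergenic=n_intergenic, abundance=depth_per_product)
    genome.to_fasta(outdir / "genome.fa")
    write_gff3(outdir / "annotation.gff3", features)
    ext = ".fastq.gz" if compress else ".fastq"
    sim = None
    for lib in range(libraries):
        sim = simulate_reads(
            genome,
            truth,
            depth_per_product=depth_per_product,
            end_jitter_sd=end_jitter_sd,
            adapter3=adapter3,
            paired=paired,
            read_len=read_len,
            oligoA_rate=oligoA_rate,
            noise_read_rate=noise_read_rate,
            quality_decay=quality_decay,
            seed=seed + 100 + lib,
        )
        name = f"lib{lib + 1}"
        write_fastq(outdir / f"{name}_R1{ext}", sim.r1)
        if paired:
            write_fastq(outdir / f"{name}_R2{ext}", sim.r2)
    write_truth_tables(outdir, truth, sim)
    return genome, truth, features
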