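"""Task orchestration: config parsing, per-task file contracts, resumability.

The seven tasks (trim, align, sam_sort, pseudoSE, identify, cluster,
quantify) run in a fixed canonical order; each task reads the artifacts of
its predecessor from ``<out>/<task>/`` and writes its own there, so any
suffix of the pipeline can be re-run against pre-existing upstream outputs.
In sensitive mode align and sam_sort are one combined step (the second,
short-seed alignment pass needs the first pass's unaligned reads), and their
outputs land under ``sam_sort/``.
"""
from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import AlignParams
from .cluster import ClusterConfig, cluster_products
from .identify import IdentifyConfig, identify_products
from .pseudose import PseudoSEConfig, pseudose_convert
from .quantify import QuantifyConfig, quantify_libraries, run_statistics
from .records import ProcessingProduct
from .samio import read_pseudose_sam, read_unit_sam, write_pseudose_sam, write_unit_sam
from .seqs import Genome, read_fastq, read_gff3, write_fastq
from .stratum import sensitive_align
from .trim import TrimConfig, trim_library

TASK_ORDER = ("trim", "align", "sam_sort", "pseudose", "identify", "cluster", "quantify")

#: upstream artifact -> task that produces it (for actionable error messages)
_PRODUCER = {
    "trim": "trim",
    "sam_sort": "sam_sort",
    "pseudose": "pseudose",
    "identify": "identify",
    "cluster": "cluster",
}


class ConfigError(ValueError):
    pass


class MissingInputError(FileNotFoundError):
    pass


@dataclass
class PipelineConfig:
    genome: str = ""
    annotation: str = ""
    out_dir: str = "starpa_out"
    mode: str = "PE"  # PE | SE
    seed: int = 0
    libraries: dict = field(default_factory=dict)  # name -> (r1, r2 | None)
    trim: TrimConfig = field(default_factory=lambda: TrimConfig(adapter3="TGGAATTCTCGGGTGCCAAGG"))
    align: AlignParams = field(default_factory=AlignParams)
    pseudose: PseudoSEConfig = field(default_factory=PseudoSEConfig)
    identify: IdentifyConfig = field(default_factory=IdentifyConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)


_SECTION_KEYS = {
    "pipeline": {"genome", "annotation", "out_dir", "mode", "seed"},
    "trim": {"adapter3", "quality_cutoff", "min_length", "max_error_rate",
             "min_overlap_pe", "min_overlap_se"},
    "align": {"seed_len", "seed_mismatches", "min_score_a", "min_score_b",
              "mismatch_penalty", "max_insert", "sensitive", "exhaustive_rescue"},
    "pseudose": {"max_mm", "max_nh", "oligoa_exempt"},
    "identify": {"bins", "quant_threshold", "mask_window", "nonoverlap_read",
                 "nonoverlap_feature", "min_end_reads"},
    "cluster": {"min_count", "min_relcov", "tolerance", "id_contig", "len_cutoff"},
    "quantify": {"rpm_threshold", "nonoverlap_read", "nonoverlap_feature"},
}

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _coerce(current, raw: str):
    if isinstance(current, bool):
        try:
            return _BOOL[raw.strip().lower()]
        except KeyError:
            raise ConfigError(f"expected boolean, got {raw!r}")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def parse_config(path) -> PipelineConfig:
    """Parse the flat ``key = value`` sections-per-task config file.

    Unknown sections or keys are rejected (typo safety).
    """
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    cfg = PipelineConfig()
    for section in cp.sections():
        if section == "libraries":
            for name, val in cp.items(section):
                parts = [p.strip() for p in val.split(",")]
                cfg.libraries[name] = (parts[0], parts[1] if len(parts) > 1 else None)
            continue
        if section not in _SECTION_KEYS:
            raise ConfigError(f"unknown config section [{section}]")
        known = _SECTION_KEYS[section]
        target = cfg if section == "pipeline" else getattr(cfg, section)
        for key, raw in cp.items(section):
            if key not in known:
                raise ConfigError(f"unknown key {key!r} in section [{section}]")
            if section == "identify" and key == "bins":
                bins = tuple(
                    tuple(int(x) for x in b.split("-")) for b in raw.split(",")
                )
                cfg.identify.bins = bins
                continue
            if section == "identify" and key == "min_end_reads":
                cfg.identify.min_end_reads = int(raw)
                continue
            if section == "pseudose" and key == "oligoa_exempt":
                cfg.pseudose.oligoA_exempt = _coerce(True, raw)
                continue
            if section == "align":
                # AlignParams is frozen; rebuild via replace
                from dataclasses import replace

                cur = getattr(cfg.align, key)
                cfg.align = replace(cfg.align, **{key: _coerce(cur, raw)})
                continue
            cur = getattr(target, key)
            setattr(target, key, _coerce(cur, raw))
    return cfg


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"missing input {path}; run task '{producer}' first"
        )
    return path


def _write_tallies(task_dir: Path, tallies: dict) -> None:
    with open(task_dir / "tallies.json", "w") as fh:
        json.dump(tallies, fh, indent=1, sort_keys=True)


def _read_tallies(task_dir: Path) -> dict:
    p = task_dir / "tallies.json"
    if p.exists():
        with open(p) as fh:
            return json.load(fh)
    return {}


def _out(cfg: PipelineConfig, task: str) -> Path:
    d = Path(cfg.out_dir) / task
    d.mkdir(parents=True, exist_ok=True)
    return d


def _load_genome(cfg: PipelineConfig) -> Genome:
    if not cfg.genome:
        raise ConfigError("no genome configured")
    return Genome.from_fasta(cfg.genome)


# -- tasks ------------------------------------------------------------------

def task_trim(cfg: PipelineConfig) -> dict:
    out = _out(cfg, "trim")
    tallies = {}
    for lib in sorted(cfg.libraries):
        r1_path, r2_path = cfg.libraries[lib]
        if cfg.mode == "PE":
            if r2_path is None:
                raise ConfigError(f"library {lib}: PE mode needs two FASTQ files")
            pairs = list(zip(read_fastq(r1_path, 1), read_fastq(r2_path, 2)))
            kept, short, untrimmed, t = trim_library(pairs, "PE", cfg.trim)
            write_fastq(out / f"{lib}_R1.fastq", [p[0] for p in kept])
            write_fastq(out / f"{lib}_R2.fastq", [p[1] for p in kept])
        else:
            reads = read_fastq(r1_path)
            kept, short, untrimmed, t = trim_library(reads, "SE", cfg.trim)
            write_fastq(out / f"{lib}_R1.fastq", kept)
        write_fastq(out / f"{lib}.too_short.fastq", short)
        write_fastq(out / f"{lib}.untrimmed.fastq", untrimmed)
        tallies[lib] = t
    _write_tallies(out, tallies)
    return tallies


def task_align_sort(cfg: PipelineConfig, genome: Genome | None = None) -> dict:
    """Combined align + sam_sort (sensitive mode pairs the two passes)."""
    genome = genome or _load_genome(cfg)
    trim_dir = Path(cfg.out_dir) / "trim"
    out = _out(cfg, "sam_sort")
    tallies = {}
    for lib in sorted(cfg.libraries):
        r1 = read_fastq(_require(trim_dir / f"{lib}_R1.fastq", "trim"), 1)
        if cfg.mode == "PE":
            r2 = read_fastq(_require(trim_dir / f"{lib}_R2.fastq", "trim"), 2)
            items = list(zip(r1, r2))
        else:
            items = r1
        groups, unaligned, t = sensitive_align(items, genome, cfg.align)
        groups.sort(key=lambda g: g.read_id)
        write_unit_sam(out / f"{lib}.sam", genome, groups, cfg.mode == "PE")
        flat = []
        for item in unaligned:
            flat.extend(item if isinstance(item, tuple) else [item])
        write_fastq(out / f"{lib}.unaligned.fastq", flat)
        tallies[lib] = t
    _write_tallies(out, tallies)
    return tallies


def task_pseudose(cfg: PipelineConfig, genome: Genome | None = None) -> dict:
    genome = genome or _load_genome(cfg)
    sam_dir = Path(cfg.out_dir) / "sam_sort"
    out = _out(cfg, "pseudose")
    tallies = {}
    for lib in sorted(cfg.libraries):
        grouped, _paired = read_unit_sam(_require(sam_dir / f"{lib}.sam", "sam_sort"))
        from .records import ReadAlignmentGroup

        groups = [ReadAlignmentGroup(rid, units) for rid, units in grouped.items()]
        kept, sidecars, t = pseudose_convert(groups, genome, cfg.pseudose)
        kept.sort(key=lambda r: (r.chrom, r.start0, r.end0, r.read_id))
        write_pseudose_sam(out / f"{lib}.sam", genome, kept)
        for name, reads in sidecars.items():
            write_pseudose_sam(out / f"{lib}.{name}.sam", genome, reads)
        tallies[lib] = t
    _write_tallies(out, tallies)
    return tallies


_PRODUCT_COLS = [
    "chrom", "strand", "start0", "end0", "five_support", "three_support",
    "fraction", "count",
]


def task_identify(cfg: PipelineConfig) -> dict:
    ps_dir = Path(cfg.out_dir) / "pseudose"
    out = _out(cfg, "identify")
    tallies = {}
    for lib in sorted(cfg.libraries):
        mappings = read_pseudose_sam(_require(ps_dir / f"{lib}.sam", "pseudose"))
        products, t = identify_products(mappings, cfg.identify, lib)
        rows = [
            {
                "chrom": p.chrom, "strand": p.strand, "start0": p.start0,
                "end0": p.end0, "five_support": p.five_support,
                "three_support": p.three_support, "fraction": p.fraction,
                "count": p.counts.get(lib, 0),
            }
            for p in products
        ]
        pd.DataFrame(rows, columns=_PRODUCT_COLS).to_csv(
            out / f"{lib}.products.tsv", sep="\t", index=False
        )
        with open(out / f"{lib}.products.bed", "w") as fh:
            for p in products:
                fh.write(
                    f"{p.chrom}\t{p.start0}\t{p.end0}\t{p.fraction}\t"
                    f"{p.counts.get(lib, 0)}\t{p.strand}\n"
                )
        tallies[lib] = t
    _write_tallies(out, tallies)
    return tallies


def _read_products(path, lib: str) -> list[ProcessingProduct]:
    df = pd.read_csv(path, sep="\t")
    products = []
    for row in df.itertuples(index=False):
        p = ProcessingProduct(
            row.chrom, row.strand, int(row.start0), int(row.end0),
            int(row.five_support), int(row.three_support), str(row.fraction),
        )
        p.counts[lib] = int(row.count)
        products.append(p)
    return products


def task_cluster(cfg: PipelineConfig, genome: Genome | None = None) -> dict:
    genome = genome or _load_genome(cfg)
    id_dir = Path(cfg.out_dir) / "identify"
    ps_dir = Path(cfg.out_dir) / "pseudose"
    out = _out(cfg, "cluster")
    per_lib_products, per_lib_mappings = {}, {}
    for lib in sorted(cfg.libraries):
        per_lib_products[lib] = _read_products(
            _require(id_dir / f"{lib}.products.tsv", "identify"), lib
        )
        per_lib_mappings[lib] = read_pseudose_sam(_require(ps_dir / f"{lib}.sam", "pseudose"))
    finals, overlap_clusters, membership, tallies = cluster_products(
        per_lib_products, per_lib_mappings, genome, cfg.cluster, cfg.identify
    )
    with open(out / "representatives.bed", "w") as fh:
        for p in finals:
            fh.write(
                f"{p.chrom}\t{p.start0}\t{p.end0}\t{p.fraction}\t{p.total_count}\t{p.strand}\n"
            )
    with open(out / "representatives.fa", "w") as fh:
        for p in finals:
            fh.write(
                f">{p.chrom}:{p.start0}-{p.end0}({p.strand})\n"
                f"{genome.fetch_oriented(p.chrom, p.start0, p.end0, p.strand)}\n"
            )
    with open(out / "membership.tsv", "w") as fh:
        fh.write("representative\tmember\n")
        for rep, mem in membership:
            fh.write(
                f"{rep.chrom}:{rep.start0}-{rep.end0}({rep.strand})\t"
                f"{mem.chrom}:{mem.start0}-{mem.end0}({mem.strand})\n"
            )
    _write_tallies(out, {"all": tallies})
    return {"all": tallies}


def task_quantify(cfg: PipelineConfig, genome: Genome | None = None) -> dict:
    genome = genome or _load_genome(cfg)
    cl_dir = Path(cfg.out_dir) / "cluster"
    ps_dir = Path(cfg.out_dir) / "pseudose"
    out = _out(cfg, "quantify")
    bed = _require(cl_dir / "representatives.bed", "cluster")
    reps = []
    with open(bed) as fh:
        for line in fh:
            chrom, s, e, frac, _count, strand = line.rstrip("\n").split("\t")
            reps.append(ProcessingProduct(chrom, strand, int(s), int(e), fraction=frac))
    per_lib_mappings = {
        lib: read_pseudose_sam(_require(ps_dir / f"{lib}.sam", "pseudose"))
        for lib in sorted(cfg.libraries)
    }
    features = read_gff3(cfg.annotation) if cfg.annotation else []
    matrix, stats, retained = quantify_libraries(
        per_lib_mappings, reps, genome, features, cfg.quantify
    )
    matrix.raw.to_csv(out / "counts_raw.tsv", sep="\t", index_label="product")
    matrix.rpm.round(4).to_csv(out / "counts_rpm.tsv", sep="\t", index_label="product")
    matrix.rpm_biotype.round(4).to_csv(
        out / "counts_rpm_biotype.tsv", sep="\t", index_label="product"
    )
    matrix.rpm_biotype_group.round(4).to_csv(
        out / "counts_rpm_biotype_group.tsv", sep="\t", index_label="product"
    )
    by_id = {p.id: p for p in reps}
    with open(out / "retained.bed", "w") as fh:
        for pid in retained:
            p = by_id[pid]
            fh.write(
                f"{p.chrom}\t{p.start0}\t{p.end0}\t{pid}\t{p.total_count}\t{p.strand}\n"
            )
    rows = []
    for lib in sorted(stats):
        for p, st in zip(reps, stats[lib]):
            rows.append(
                {
                    "library": lib, "product": p.id, "biotype": p.biotype,
                    "count": int(matrix.raw.loc[p.id, lib]),
                    "relative_coverage": round(st.relative_coverage, 4),
                    "uniqueness": round(st.uniqueness, 4),
                    "consensus_seq": st.consensus_seq,
                    "consensus_qual": ",".join(map(str, st.consensus_qual)),
                    "genomic_seq": st.genomic_seq,
                    "coverage": ",".join(map(str, st.coverage)),
                }
            )
    pd.DataFrame(rows).to_csv(out / "candidate_stats.tsv", sep="\t", index=False)
    # single-file run statistics across all stages
    per_lib: dict[str, dict] = {lib: {} for lib in cfg.libraries}
    for task in ("trim", "sam_sort", "pseudose", "identify"):
        t = _read_tallies(Path(cfg.out_dir) / task)
        for lib, vals in t.items():
            per_lib.setdefault(lib, {})[task] = vals
    for lib in per_lib:
        per_lib[lib]["quantify"] = {
            "representatives": len(reps),
            "retained_rpm": len(retained),
            "library_total": matrix.library_totals.get(lib, 0),
        }
    run_statistics(per_lib).to_csv(out / "run_statistics.tsv", sep="\t", index=False)
    return {"retained": len(retained), "representatives": len(reps)}


def run(cfg: PipelineConfig, tasks=None) -> dict:
    """Run the requested tasks (default: all) in canonical order."""
    requested = set(tasks or TASK_ORDER)
    unknown = requested - set(TASK_ORDER)
    if unknown:
        raise ConfigError(f"unknown tasks: {sorted(unknown)}")
    genome = _load_genome(cfg) if requested - {"trim"} else None
    summary = {}
    if "trim" in requested:
        summary["trim"] = task_trim(cfg)
    if {"align", "sam_sort"} & requested:
        summary["sam_sort"] = task_align_sort(cfg, genome)
    if "pseudose" in requested:
        summary["pseudose"] = task_pseudose(cfg, genome)
    if "identify" in requested:
        summary["identify"] = task_identify(cfg)
    if "cluster" in requested:
        summary["cluster"] = task_cluster(cfg, genome)
    if "quantify" in requested:
        summary["quantify"] = task_quantify(cfg, genome)
    return summary
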